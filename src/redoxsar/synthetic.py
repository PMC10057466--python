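"""Synthetic kinetics traces and descriptor matrices with known truth.

Two generators make every pipeline stage testable without measured data:

* :func:`gen_kinetics` emulates the scavenger experiment — first-order
  photocatalytic decay after a dark adsorption period, with the four
  condition arms (no scavenger, +DMSO, +BQ, +both) and multiplicative
  measurement noise. The default sampling schedule is the experimental
  grid (-20 and -10 min dark, then 0-20 min under irradiation).
* :func:`gen_qsar` plants a sparse linear signal in a descriptor-like
  matrix (correlated Gaussian columns plus binary columns) whose response
  lives in (0, 1] like the transformed K, so selection and validation
  can be checked against ground truth.

Scavenger suppression is modeled as complete pathway shutdown (the
experiment's 200-fold scavenger excess), in branching-share form: each
scavenged arm shows its pathway's share k_j/(k_HO + k_O2) of the
unscavenged decay 1 - exp(-(k_HO + k_O2) t). The shares then satisfy
X_none = X_dmso + X_bq exactly and the complement estimator recovers
K = k_HO/k_O2 at zero noise. A literal first-order alternative
(``suppression="rate"``: each arm decays with its remaining rate
constant) is kept as a sensitivity hook; a ``suppression_factor`` < 1
leaves that fraction of the scavenged pathway active.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import KineticsRecord, transform_response

#: the experimental sampling grid, minutes (negative = dark period)
DEFAULT_SCHEDULE = (-20.0, -10.0, 0.0, 2.5, 5.0, 10.0, 15.0, 20.0)


@dataclass(frozen=True)
class SyntheticKineticsParams:
    """Ground-truth parameters of one synthetic scavenger experiment."""

    k_HO: float = 0.08
    k_O2: float = 0.02
    ads_fraction: float = 0.0
    noise_sd: float = 0.02
    c0: float = 0.05
    schedule: tuple = DEFAULT_SCHEDULE
    suppression: str = "share"
    suppression_factor: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.k_HO < 0 or self.k_O2 < 0:
            raise ValueError("rate constants must be non-negative")
        if not 0.0 <= self.ads_fraction < 1.0:
            raise ValueError("ads_fraction must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.suppression not in ("share", "rate"):
            raise ValueError("suppression must be 'share' or 'rate'")
        if not 0.0 <= self.suppression_factor < 1.0:
            raise ValueError("suppression_factor must lie in [0, 1)")

    @property
    def true_K(self) -> float:
        if self.k_O2 == 0:
            return math.inf
        return self.k_HO / self.k_O2


def gen_kinetics(params: SyntheticKineticsParams) -> tuple[dict[str, KineticsRecord], dict]:
    """Generate the four condition traces and the ground truth.

    The dark period removes ``ads_fraction`` of the initial amount
    (linearly from the first dark sample to t = 0); under irradiation the
    unscavenged arm decays with k_HO + k_O2 and each scavenged arm shows
    the surviving pathway's contribution (see module docstring), the
    dual-scavenger arm stays constant. Gaussian multiplicative noise is
    applied to every sample and clipped at zero.
    """
    k_tot = params.k_HO + params.k_O2
    if k_tot == 0 and params.suppression == "share":
        raise ValueError("both rate constants are zero: no bulk degradation to share")
    rng = np.random.default_rng(params.seed)
    times = np.asarray(params.schedule, dtype=float)
    if not np.any(times < 0) or 0.0 not in times:
        raise ValueError("schedule must include a dark-period sample and t = 0")
    t_first = times[0]
    c_t0 = params.c0 * (1.0 - params.ads_fraction)

    # pathway activity per condition: fraction of each pathway left on
    f = params.suppression_factor
    activity = {
        "none": (1.0, 1.0),
        "dmso": (f, 1.0),   # DMSO quenches HO*
        "bq": (1.0, f),     # BQ quenches O2*-
        "both": (f, f),
    }

    records: dict[str, KineticsRecord] = {}
    for cond, (a_ho, a_o2) in activity.items():
        conc = np.empty_like(times)
        for i, t in enumerate(times):
            if t <= 0:
                frac = (t - t_first) / (0.0 - t_first)
                conc[i] = params.c0 * (1.0 - params.ads_fraction * frac)
            else:
                if params.suppression == "share":
                    share = (a_ho * params.k_HO + a_o2 * params.k_O2) / k_tot
                    decayed = share * (1.0 - math.exp(-k_tot * t))
                else:
                    k_cond = a_ho * params.k_HO + a_o2 * params.k_O2
                    decayed = 1.0 - math.exp(-k_cond * t)
                conc[i] = c_t0 * (1.0 - decayed)
        if params.noise_sd > 0:
            conc = conc * (1.0 + rng.normal(0.0, params.noise_sd, size=conc.shape))
            conc = np.clip(conc, 0.0, None)
        records[cond] = KineticsRecord(
            compound_id="synthetic", condition=cond, times=times, concentrations=conc
        )
    truth = {
        "K": params.true_K,
        "t_response": transform_response(params.true_K) if math.isfinite(params.true_K) else 0.0,
        "k_HO": params.k_HO,
        "k_O2": params.k_O2,
        "ads_fraction": params.ads_fraction,
    }
    return records, truth


@dataclass(frozen=True)
class SyntheticQSARParams:
    """Planted-signal descriptor matrix parameters.

    Defaults mirror the study's modeling conditions: 30 compounds, a
    response in (0, 1] with residual noise of a few hundredths, and at
    most five active descriptors.
    """

    n: int = 30
    p: int = 20
    active: tuple = (0, 1, 2)
    coefficients: tuple = (-0.30, 0.20, -0.15)
    intercept: float = 0.55
    correlation: float = 0.0
    binary_fraction: float = 0.3
    noise_sd: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        if len(self.active) != len(self.coefficients):
            raise ValueError("active and coefficients must have equal length")
        if len(self.active) > 5:
            raise ValueError("at most 5 active descriptors")
        if max(self.active, default=-1) >= self.p:
            raise ValueError("active indices must address existing columns")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation must lie in [0, 1)")
        if not 0.0 <= self.binary_fraction <= 1.0:
            raise ValueError("binary_fraction must lie in [0, 1]")


def gen_qsar(params: SyntheticQSARParams) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Descriptor matrix with a planted sparse linear response.

    Continuous columns are equicorrelated standard Gaussians (pairwise
    correlation ``params.correlation``); the last ``binary_fraction`` of
    columns are Bernoulli 0/1 to mimic atom-pair/pharmacophore counts.
    The response y = intercept + X_active @ coefficients + noise is
    scaled to live in (0, 1] — the range of the transformed K of a
    non-negative K coefficient — by clipping only as a guard (clipped
    rows are counted in the truth dict). Identical seeds give
    byte-identical outputs.
    """
    rng = np.random.default_rng(params.seed)
    n, p = params.n, params.p
    n_bin = int(round(params.binary_fraction * p))
    n_cont = p - n_bin

    rho = params.correlation
    common = rng.standard_normal((n, 1))
    X_cont = math.sqrt(rho) * common + math.sqrt(1.0 - rho) * rng.standard_normal((n, n_cont))
    # min-max scale continuous columns to [0,1], like the normalized
    # descriptor matrix the models are fitted on; the per-column affine
    # map preserves correlations and keeps the planted response linear
    span = X_cont.max(axis=0) - X_cont.min(axis=0)
    span[span == 0] = 1.0
    X_cont = (X_cont - X_cont.min(axis=0)) / span
    X_bin = (rng.random((n, n_bin)) < 0.5).astype(float)
    X = np.concatenate([X_cont, X_bin], axis=1)

    names = [f"X{j + 1:02d}" for j in range(p)]
    frame = pd.DataFrame(X, columns=names,
                         index=pd.Index([f"cmp{i + 1:02d}" for i in range(n)], name="abbr"))

    coefs = np.zeros(p)
    for idx, c in zip(params.active, params.coefficients):
        coefs[idx] = c
    y_clean = params.intercept + X @ coefs
    y = y_clean + rng.normal(0.0, params.noise_sd, size=n)
    eps = 1e-6
    clipped = int(np.sum((y <= 0.0) | (y > 1.0)))
    y = np.clip(y, eps, 1.0)

    truth = {
        "active": [names[i] for i in params.active],
        "coefficients": dict(zip([names[i] for i in params.active], params.coefficients)),
        "intercept": params.intercept,
        "noise_sd": params.noise_sd,
        "n_clipped": clipped,
    }
    return frame, pd.Series(y, index=frame.index, name="t_response"), truth
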