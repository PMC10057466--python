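"""K coefficients from scavenger kinetics and the response transformation.

A photocatalytic run records a compound's concentration through a dark
adsorption period (negative times) and an irradiation period. Three runs
per compound — no scavenger, +DMSO (quenches HO*), +BQ (quenches O2*-) —
let the bulk degradation be split into an oxidative share M_HO and a
reductive share M_O2. Their ratio K = M_HO / M_O2 summarizes the
mechanistic preference: K >> 1 means oxidation by hydroxyl radicals
dominates, K << 1 reduction by superoxide.

For regression the K range (two orders of magnitude across the dataset)
is compressed with t = (K + 1)^(-1/2), a strictly decreasing bijection of
[0, inf) onto (0, 1]; any model prediction in (0, 1] maps back to a
non-negative K, so negative rates are impossible by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: scavenging rate constants (documentation constants, M^-1 s^-1):
#: DMSO + HO* and BQ + O2*-. At 10 mM scavenger vs 0.05 mM substrate the
#: scavenged pathway is effectively switched off.
K_DMSO_HO = 6.6e9
K_BQ_O2 = 5.88e10

CONDITIONS = ("none", "dmso", "bq", "both")


@dataclass(frozen=True)
class KineticsRecord:
    """Time-concentration trace for one compound under one condition.

    Times are minutes; negative values are the dark adsorption period and
    0 marks the start of irradiation. Concentrations are mM.
    """

    compound_id: str
    condition: str
    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and concentrations must be 1-D arrays of equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if 0.0 not in t:
            raise ValueError("trace must contain a sample at t = 0 (irradiation start)")
        if not np.any(t < 0):
            raise ValueError("trace must contain at least one dark-period sample")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")

    def at(self, time: float) -> float:
        idx = np.nonzero(self.times == time)[0]
        if idx.size == 0:
            raise KeyError(f"no sample at t = {time}")
        return float(self.concentrations[idx[0]])


@dataclass(frozen=True)
class DegradationSummary:
    """Adsorption-corrected degradation shares and the K coefficient."""

    X_ads: float
    X_none: float
    X_dmso: float
    X_bq: float
    M_HO: float
    M_O2: float
    K: float
    t_response: float
    infinite_preference: bool = False
    estimator: str = "complement"


def transform_response(K):
    """Map a K coefficient to the modeling response t = (K + 1)^(-1/2)."""
    K = np.asarray(K, dtype=float)
    if np.any(K < 0):
        raise ValueError("K must be non-negative")
    out = (K + 1.0) ** -0.5
    return float(out) if out.ndim == 0 else out


def inverse_transform(t):
    """Invert the response transform: K = t^-2 - 1 for t in (0, 1]."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0) or np.any(t > 1):
        raise ValueError("transformed response must lie in (0, 1]")
    out = t**-2 - 1.0
    return float(out) if out.ndim == 0 else out


def adsorption_extent(rec: KineticsRecord) -> float:
    """Fraction of the initial amount adsorbed during the dark period.

    (C_first_dark - C_at_t0) / C_first_dark, clipped to [0, 1]; clipping
    absorbs measurement noise that puts C(0) above the initial value.
    """
    c0 = rec.concentrations[0]
    if c0 <= 0:
        raise ValueError("initial (first dark sample) concentration must be positive")
    return float(np.clip((c0 - rec.at(0.0)) / c0, 0.0, 1.0))


def bulk_extent(rec: KineticsRecord, *, end_time: float = 20.0) -> float:
    """Share of the initial amount degraded in the bulk during irradiation.

    (C_at_t0 - C_end) / C_first_dark with C_end the last sample at
    t <= ``end_time``; referencing the pre-adsorption concentration makes
    the extents of the three runs commensurable.
    """
    c0 = rec.concentrations[0]
    if c0 <= 0:
        raise ValueError("initial (first dark sample) concentration must be positive")
    mask = (rec.times > 0) & (rec.times <= end_time)
    if not np.any(mask):
        raise ValueError(f"no irradiation sample at 0 < t <= {end_time}")
    c_end = rec.concentrations[np.nonzero(mask)[0][-1]]
    return float(np.clip((rec.at(0.0) - c_end) / c0, 0.0, 1.0))


def compute_K(
    X_none: float,
    X_dmso: float,
    X_bq: float,
    *,
    X_ads: float = 0.0,
    estimator: str = "complement",
    compound_id: str | None = None,
) -> DegradationSummary:
    """Split bulk degradation into pathway shares and form K = M_HO / M_O2.

    ``complement`` (default) reads each pathway's share off the run where
    the *other* radical is scavenged: M_HO = X_bq, M_O2 = X_dmso. With a
    200-fold scavenger excess the suppressed pathway is fully off, so the
    remaining decay is entirely the unscavenged pathway. ``difference``
    subtracts instead: M_HO = X_none - X_dmso, M_O2 = X_none - X_bq
    (negatives clipped to 0); both agree when X_none = X_dmso + X_bq.

    A vanishing M_O2 yields ``infinite_preference=True`` with K = inf and
    t_response 0 (the open end of the transform's range).
    """
    for name, x in (("X_none", X_none), ("X_dmso", X_dmso), ("X_bq", X_bq)):
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"{name} must be a fraction in [0, 1], got {x}")
    if estimator == "complement":
        M_HO, M_O2 = X_bq, X_dmso
    elif estimator == "difference":
        M_HO = max(X_none - X_dmso, 0.0)
        M_O2 = max(X_none - X_bq, 0.0)
    else:
        raise ValueError("estimator must be 'complement' or 'difference'")

    if M_O2 == 0.0:
        return DegradationSummary(
            X_ads=X_ads, X_none=X_none, X_dmso=X_dmso, X_bq=X_bq,
            M_HO=M_HO, M_O2=M_O2, K=math.inf, t_response=0.0,
            infinite_preference=True, estimator=estimator,
        )
    K = M_HO / M_O2
    return DegradationSummary(
        X_ads=X_ads, X_none=X_none, X_dmso=X_dmso, X_bq=X_bq,
        M_HO=M_HO, M_O2=M_O2, K=K, t_response=transform_response(K),
        estimator=estimator,
    )


def summarize_traces(
    records: dict[str, KineticsRecord],
    *,
    estimator: str = "complement",
    end_time: float = 20.0,
) -> DegradationSummary:
    """Full trace-to-K pipeline for one compound's condition set.

    ``records`` maps condition names to traces and must contain at least
    ``none``, ``dmso`` and ``bq``. Adsorption is read from the no-scavenger
    run.
    """
    for cond in ("none", "dmso", "bq"):
        if cond not in records:
            raise KeyError(f"missing condition {cond!r}")
    return compute_K(
        bulk_extent(records["none"], end_time=end_time),
        bulk_extent(records["dmso"], end_time=end_time),
        bulk_extent(records["bq"], end_time=end_time),
        X_ads=adsorption_extent(records["none"]),
        estimator=estimator,
        compound_id=records["none"].compound_id,
    )


def load_kinetics_csv(path) -> dict[str, dict[str, KineticsRecord]]:
    """Read traces from a CSV ``compound,condition,time_min,conc_mM``."""
    frame = pd.read_csv(path)
    required = {"compound", "condition", "time_min", "conc_mM"}
    if not required.issubset(frame.columns):
        raise ValueError(f"kinetics CSV must have columns {sorted(required)}")
    out: dict[str, dict[str, KineticsRecord]] = {}
    for (cid, cond), grp in frame.groupby(["compound", "condition"], sort=False):
        grp = grp.sort_values("time_min")
        out.setdefault(str(cid), {})[str(cond)] = KineticsRecord(
            compound_id=str(cid),
            condition=str(cond),
            times=grp["time_min"].to_numpy(float),
            concentrations=grp["conc_mM"].to_numpy(float),
        )
    return out
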