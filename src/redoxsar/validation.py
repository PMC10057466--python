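"""Internal/external validation statistics and the applicability domain.

Covers leave-one-out cross-validation (Q2, PRESS and its standard
errors), leave-many-out resampling, response scrambling (the
chance-correlation control), external test-set R2, and the Williams plot
of leverage against standardized residuals that delimits the model's
applicability domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .selection import FittedModel, ols_fit, predict


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(X.shape[0]), X])


@dataclass
class LooResult:
    q2: float
    press: float
    s_press: float
    s_dep: float


def q2_loo(X: pd.DataFrame, y: pd.Series, ids=None) -> LooResult:
    """Leave-one-out Q2 via the leverage shortcut.

    The deleted residual of an OLS fit is e_i/(1 - h_ii), so PRESS is a
    single fit plus hat-diagonal, no refits: PRESS = sum (e_i/(1-h_ii))^2,
    Q2 = 1 - PRESS/TSS, S_DEP = sqrt(PRESS/n), S_PRESS =
    sqrt(PRESS/(n-m-1)). Points with h_ii = 1 (exact-fit points, where the
    shortcut divides by zero) fall back to an explicit refit without the
    point.
    """
    if ids is not None:
        X, y = X.loc[list(ids)], y.loc[list(ids)]
    arr = X.to_numpy(float)
    yv = np.asarray(y, dtype=float)
    n, m = arr.shape
    if n <= m + 2:
        raise ValueError(f"need n > m + 2 rows for LOO (n={n}, m={m})")
    Xd = _design(arr)
    Q, R = np.linalg.qr(Xd)
    beta = np.linalg.solve(R, Q.T @ yv)
    resid = yv - Xd @ beta
    h = (Q**2).sum(axis=1)
    press = 0.0
    for i in range(n):
        if 1.0 - h[i] > 1e-10:
            press += (resid[i] / (1.0 - h[i])) ** 2
        else:  # exact-fit point: explicit refit without row i
            mask = np.ones(n, bool)
            mask[i] = False
            beta_i, *_ = np.linalg.lstsq(Xd[mask], yv[mask], rcond=None)
            press += (yv[i] - Xd[i] @ beta_i) ** 2
    tss = float(((yv - yv.mean()) ** 2).sum())
    return LooResult(
        q2=1.0 - press / tss,
        press=float(press),
        s_press=math.sqrt(press / (n - m - 1)),
        s_dep=math.sqrt(press / n),
    )


@dataclass
class LmoResult:
    values: np.ndarray
    leave_fraction: float
    iterations: int
    skipped: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0


def q2_lmo(
    X: pd.DataFrame,
    y: pd.Series,
    leave_fraction: float = 0.3,
    iterations: int = 1000,
    seed: int | None = None,
) -> LmoResult:
    """Leave-many-out Q2 distribution.

    Each iteration drops a random ``leave_fraction`` of the rows, refits
    on the rest, and scores the left-out predictions against the retained
    mean: Q2 = 1 - sum (y_out - yhat_out)^2 / sum (y_out - ybar_in)^2.
    Singular refits are skipped and counted.
    """
    rng = np.random.default_rng(seed)
    arr = X.to_numpy(float)
    yv = np.asarray(y, dtype=float)
    n, m = arr.shape
    n_out = max(1, int(round(leave_fraction * n)))
    if n - n_out <= m + 1:
        raise ValueError("too few retained rows to refit after leaving the fraction out")
    values, skipped = [], 0
    for _ in range(iterations):
        out = rng.choice(n, size=n_out, replace=False)
        mask = np.ones(n, bool)
        mask[out] = False
        Xd_in = _design(arr[mask])
        if np.linalg.matrix_rank(Xd_in) < m + 1:
            skipped += 1
            continue
        beta, *_ = np.linalg.lstsq(Xd_in, yv[mask], rcond=None)
        pred_out = _design(arr[out]) @ beta
        denom = float(((yv[out] - yv[mask].mean()) ** 2).sum())
        if denom <= 0:
            skipped += 1
            continue
        values.append(1.0 - float(((yv[out] - pred_out) ** 2).sum()) / denom)
    return LmoResult(
        values=np.asarray(values), leave_fraction=leave_fraction,
        iterations=iterations, skipped=skipped,
    )


@dataclass
class YScramblingResult:
    r2: np.ndarray
    q2: np.ndarray

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.r2)) if len(self.r2) else math.nan

    @property
    def max_r2(self) -> float:
        return float(np.max(self.r2)) if len(self.r2) else math.nan

    @property
    def mean_q2(self) -> float:
        return float(np.mean(self.q2)) if len(self.q2) else math.nan


def y_scrambling(
    X: pd.DataFrame,
    y: pd.Series,
    permutations: int = 300,
    seed: int | None = None,
) -> YScramblingResult:
    """Refit the fixed subset against permuted responses.

    A real structure-activity relationship collapses when the responses
    are shuffled; under the null the expected R2 of an m-variable fit on
    n rows is about m/(n-1). Returns the R2 and Q2 distributions over
    permutations (empty arrays for ``permutations=0``).
    """
    rng = np.random.default_rng(seed)
    arr = X.to_numpy(float)
    yv = np.asarray(y, dtype=float)
    n, m = arr.shape
    Xd = _design(arr)
    Q, R = np.linalg.qr(Xd)
    h = (Q**2).sum(axis=1)
    r2s, q2s = [], []
    for _ in range(permutations):
        yp = rng.permutation(yv)
        beta = np.linalg.solve(R, Q.T @ yp)
        resid = yp - Xd @ beta
        tss = float(((yp - yp.mean()) ** 2).sum())
        rss = float(resid @ resid)
        r2s.append(1.0 - rss / tss)
        denom = 1.0 - h
        if np.all(denom > 1e-10):
            press = float(((resid / denom) ** 2).sum())
            q2s.append(1.0 - press / tss)
    return YScramblingResult(r2=np.asarray(r2s), q2=np.asarray(q2s))


def external_validation(
    model: FittedModel, X_test: pd.DataFrame, y_test: pd.Series, y_train: pd.Series
) -> float:
    """External R2 on held-out rows.

    R2_ext = 1 - sum_test (y - yhat)^2 / sum_test (y - ybar_train)^2,
    referencing the training mean so a no-information predictor scores 0.
    """
    if len(X_test) == 0:
        raise ValueError("empty test set")
    pred = predict(model, X_test)["t_pred"].to_numpy()
    yv = np.asarray(y_test, dtype=float)
    ybar = float(np.mean(np.asarray(y_train, dtype=float)))
    denom = float(((yv - ybar) ** 2).sum())
    if denom <= 0:
        raise ValueError("degenerate test responses (zero variance about training mean)")
    return 1.0 - float(((yv - pred) ** 2).sum()) / denom


@dataclass
class ADReport:
    """Williams-plot data: leverages, standardized residuals, outlier flags."""

    table: pd.DataFrame
    h_star: float
    sigma: float
    m: int
    n_train: int

    @property
    def x_outliers(self) -> list[str]:
        return list(self.table.index[self.table["x_outlier"]])

    @property
    def response_outliers(self) -> list[str]:
        return list(self.table.index[self.table["response_outlier"]])


def williams_ad(
    model: FittedModel,
    X_train: pd.DataFrame,
    y_train: pd.Series,
    X_other: pd.DataFrame | None = None,
    y_other: pd.Series | None = None,
    residual_limit: float = 3.0,
) -> ADReport:
    """Applicability domain via the Williams plot.

    Leverage h_ii = x_i^T (X^T X)^-1 x_i with an intercept column and
    (X^T X) from the training rows; the warning threshold is
    h* = 3(m+1)/n with n the training-set size, also when extra rows
    (e.g. the test set) are projected into the plot. Standardized
    residuals are e_i/s with s the residual standard error of the
    training fit; |std res| > 3 sigma flags a response outlier,
    h_ii > h* a structural (X) outlier.
    """
    cols = model.names
    Xt = _design(X_train[cols].to_numpy(float))
    n, mp1 = Xt.shape
    xtx = Xt.T @ Xt
    if np.linalg.matrix_rank(xtx) < mp1:
        raise ValueError("singular X'X on training rows")
    xtx_inv = np.linalg.inv(xtx)
    h_star = 3.0 * mp1 / n
    sigma = model.s

    def _block(Xb: pd.DataFrame, yb: pd.Series, is_train: bool) -> pd.DataFrame:
        Xd = _design(Xb[cols].to_numpy(float))
        h = np.einsum("ij,jk,ik->i", Xd, xtx_inv, Xd)
        resid = np.asarray(yb, float) - predict(model, Xb)["t_pred"].to_numpy()
        std_resid = resid / sigma if sigma > 0 else np.zeros_like(resid)
        return pd.DataFrame(
            {
                "leverage": h,
                "std_residual": std_resid,
                "x_outlier": h > h_star,
                "response_outlier": np.abs(std_resid) > residual_limit,
                "in_train": is_train,
            },
            index=Xb.index,
        )

    blocks = [_block(X_train, y_train, True)]
    if X_other is not None and y_other is not None and len(X_other):
        blocks.append(_block(X_other, y_other, False))
    table = pd.concat(blocks)
    return ADReport(table=table, h_star=h_star, sigma=sigma, m=len(cols), n_train=n)


def plot_williams(report: ADReport, path=None):
    """Render the Williams plot (leverage vs standardized residual)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for in_train, marker, label in ((True, "o", "training"), (False, "s", "test")):
        sub = report.table[report.table["in_train"] == in_train]
        if len(sub):
            ax.scatter(sub["leverage"], sub["std_residual"], marker=marker, label=label)
    ax.axvline(report.h_star, ls="--", c="gray")
    ax.axhline(3.0, ls="--", c="gray")
    ax.axhline(-3.0, ls="--", c="gray")
    ax.set_xlabel("leverage $h_{ii}$")
    ax.set_ylabel(r"standardized residual")
    ax.set_title(f"Williams plot (h* = {report.h_star:.2f})")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


@dataclass
class ValidationReport:
    """Bundle of internal and external validation statistics."""

    loo: LooResult
    lmo: LmoResult
    scrambling: YScramblingResult
    r2_ext: float | None

    def to_dict(self) -> dict:
        out = {
            "Q2_loo": self.loo.q2, "PRESS": self.loo.press,
            "S_PRESS": self.loo.s_press, "S_DEP": self.loo.s_dep,
            "Q2_lmo_mean": self.lmo.mean, "Q2_lmo_sd": self.lmo.sd,
            "lmo_iterations": self.lmo.iterations, "lmo_skipped": self.lmo.skipped,
            "R2_scr_mean": self.scrambling.mean_r2, "R2_scr_max": self.scrambling.max_r2,
            "Q2_scr_mean": self.scrambling.mean_q2,
        }
        if self.r2_ext is not None:
            out["R2_ext"] = self.r2_ext
        return out


def validate_model(
    model: FittedModel,
    X_train: pd.DataFrame,
    y_train: pd.Series,
    X_test: pd.DataFrame | None = None,
    y_test: pd.Series | None = None,
    lmo_fraction: float = 0.3,
    lmo_iterations: int = 1000,
    permutations: int = 300,
    seed: int | None = None,
) -> ValidationReport:
    """Run the full validation battery for a fitted subset model."""
    Xs = X_train[model.names]
    loo = q2_loo(Xs, y_train)
    lmo = q2_lmo(Xs, y_train, lmo_fraction, lmo_iterations, seed=seed)
    scr = y_scrambling(Xs, y_train, permutations, seed=None if seed is None else seed + 1)
    r2_ext = None
    if X_test is not None and y_test is not None and len(X_test):
        r2_ext = external_validation(model, X_test, y_test, y_train)
    return ValidationReport(loo=loo, lmo=lmo, scrambling=scr, r2_ext=r2_ext)
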