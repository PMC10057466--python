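"""GA-driven subset selection of ordinary-least-squares QSA/PR models.

Model building follows the screening discipline standard in descriptor
regression: candidate subsets of at most five descriptors (rule of thumb:
at least five training compounds per variable), the QUIK collinearity
rule (any pairwise |r| >= 0.6 among included descriptors discards the
model), and post-fit significance filters (model F-test p_M and every
per-coefficient t-test p_T below 0.05). The search over subsets is a
fixed-cardinality genetic algorithm with tournament selection, repaired
uniform crossover, per-gene mutation and elitism; fitness is either
leave-one-out Q2 (default, more protective against chance correlation) or
training R2.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .kinetics import inverse_transform

QUIK_LIMIT = 0.6
ALPHA = 0.05


@dataclass
class FittedModel:
    """An OLS model on a descriptor subset with its fit statistics."""

    names: list[str]
    coef: pd.Series
    se: pd.Series
    p_t: pd.Series
    intercept: float
    intercept_se: float
    intercept_p: float
    n_train: int
    r2: float
    s: float
    F: float
    p_M: float
    fitted: pd.Series
    residuals: pd.Series
    max_intercorrelation: float
    rejected: bool = False
    rejection_reasons: list[str] = field(default_factory=list)
    fitness: float | None = None

    @property
    def m(self) -> int:
        return len(self.names)

    def summary_row(self) -> dict:
        return {
            "descriptors": "+".join(self.names),
            "n": self.n_train,
            "R2": self.r2,
            "s": self.s,
            "F": self.F,
            "p_M": self.p_M,
            "max_rij": self.max_intercorrelation,
            "rejected": self.rejected,
        }


@dataclass
class GAConfig:
    """Genetic-algorithm search settings (population of random models,
    generation count, per-gene mutation probability)."""

    population_size: int = 200
    generations: int = 2000
    mutation_prob: float = 0.20
    fitness: str = "q2_loo"
    seed: int | None = None
    tournament_size: int = 3
    elite: int = 2

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population size must be >= 2")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation probability must lie in [0, 1]")
        if self.fitness not in ("q2_loo", "r2"):
            raise ValueError("fitness must be 'q2_loo' or 'r2'")


def quik_check(X: pd.DataFrame) -> tuple[bool, float]:
    """QUIK collinearity rule: fail iff any pairwise |r| >= 0.6.

    Single-column subsets pass vacuously with max |r| = 0.
    """
    if X.shape[1] < 2:
        return True, 0.0
    corr = np.corrcoef(X.to_numpy(float), rowvar=False)
    np.fill_diagonal(corr, 0.0)
    corr = np.nan_to_num(corr)  # constant columns correlate with nothing
    max_r = float(np.abs(corr).max())
    return max_r < QUIK_LIMIT, max_r


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(X.shape[0]), X])


def _fast_stats(X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(R2, Q2_loo) via QR; used inside the GA loop."""
    Xd = _design(X)
    Q, R = np.linalg.qr(Xd)
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - Xd @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    if tss <= 0:
        return -math.inf, -math.inf
    rss = float(resid @ resid)
    r2 = 1.0 - rss / tss
    h = (Q**2).sum(axis=1)
    denom = 1.0 - h
    if np.any(denom < 1e-12):
        return r2, -math.inf
    press = float(((resid / denom) ** 2).sum())
    return r2, 1.0 - press / tss


def ols_fit(X: pd.DataFrame, y: pd.Series, ids=None) -> FittedModel:
    """Ordinary least squares of the transformed response on a subset.

    Reports coefficients with standard errors and t-test p-values, the
    intercept, R2, residual standard error s = sqrt(RSS/(n-m-1)), the
    model F statistic with its p-value, and flags the model rejected when
    it fails the QUIK rule or either significance filter (p_M or any
    slope p_T >= 0.05).
    """
    if ids is not None:
        X = X.loc[list(ids)]
        y = y.loc[list(ids)]
    y = pd.Series(np.asarray(y, dtype=float), index=X.index, name="t_response")
    n, m = X.shape
    if n <= m + 1:
        raise ValueError(f"too few rows (n={n}) for {m} descriptors plus intercept")
    arr = X.to_numpy(float)
    if np.linalg.matrix_rank(_design(arr)) < m + 1:
        raise ValueError("rank-deficient design matrix (collinear or constant columns)")

    tss = float(((y - y.mean()) ** 2).sum())
    if tss <= 0:
        fitted = pd.Series(np.full(n, y.mean()), index=X.index)
        return FittedModel(
            names=list(X.columns), coef=pd.Series(0.0, index=X.columns),
            se=pd.Series(np.nan, index=X.columns), p_t=pd.Series(np.nan, index=X.columns),
            intercept=float(y.mean()), intercept_se=math.nan, intercept_p=math.nan,
            n_train=n, r2=0.0, s=0.0, F=math.nan, p_M=math.nan,
            fitted=fitted, residuals=y - fitted, max_intercorrelation=0.0,
            rejected=True, rejection_reasons=["degenerate response (zero variance)"],
        )

    res = sm.OLS(y.to_numpy(), sm.add_constant(arr)).fit()
    coef = pd.Series(res.params[1:], index=X.columns)
    se = pd.Series(res.bse[1:], index=X.columns)
    p_t = pd.Series(res.pvalues[1:], index=X.columns)
    fitted = pd.Series(res.fittedvalues, index=X.index)
    passed_quik, max_r = quik_check(X)

    reasons = []
    if not passed_quik:
        reasons.append(f"QUIK rule violated (max |r| = {max_r:.3f} >= {QUIK_LIMIT})")
    if not np.isnan(res.f_pvalue) and res.f_pvalue >= ALPHA:
        reasons.append(f"model not significant (p_M = {res.f_pvalue:.3g})")
    if np.any(p_t.to_numpy() >= ALPHA):
        worst = p_t.idxmax()
        reasons.append(f"insignificant term {worst} (p_T = {p_t.max():.3g})")

    return FittedModel(
        names=list(X.columns), coef=coef, se=se, p_t=p_t,
        intercept=float(res.params[0]), intercept_se=float(res.bse[0]),
        intercept_p=float(res.pvalues[0]), n_train=n,
        r2=float(res.rsquared), s=float(np.sqrt(res.mse_resid)),
        F=float(res.fvalue), p_M=float(res.f_pvalue),
        fitted=fitted, residuals=y - fitted, max_intercorrelation=max_r,
        rejected=bool(reasons), rejection_reasons=reasons,
    )


def predict(model: FittedModel, X: pd.DataFrame) -> pd.DataFrame:
    """Predict transformed responses and back-transform to K.

    Rows predicting t > 1 are flagged and their K clamped to 0; t <= 0
    predictions (outside the transform's range) yield K = inf flagged the
    same way. Back-transformed K is never negative.
    """
    missing = [c for c in model.names if c not in X.columns]
    if missing:
        raise KeyError(f"descriptor columns missing from X: {missing}")
    t_hat = X[model.names].to_numpy(float) @ model.coef.to_numpy() + model.intercept
    clamped = (t_hat > 1.0) | (t_hat <= 0.0)
    K_hat = np.empty_like(t_hat)
    for i, t in enumerate(t_hat):
        if t > 1.0:
            K_hat[i] = 0.0
        elif t <= 0.0:
            K_hat[i] = math.inf
        else:
            K_hat[i] = inverse_transform(t)
    return pd.DataFrame(
        {"t_pred": t_hat, "K_pred": K_hat, "out_of_range": clamped}, index=X.index
    )


# --------------------------------------------------------------------------
# genetic algorithm
# --------------------------------------------------------------------------


@dataclass
class GAResult:
    """Ranked surviving models plus bookkeeping of discarded candidates."""

    models: list[FittedModel]
    n_evaluated: int
    reason_counts: dict[str, int]

    @property
    def best(self) -> FittedModel | None:
        return self.models[0] if self.models else None


def _evaluate_subset(subset, arr, y, col_corr, fitness) -> float:
    idx = list(subset)
    if len(idx) >= 2:
        sub = np.abs(col_corr[np.ix_(idx, idx)])
        np.fill_diagonal(sub, 0.0)
        if sub.max() >= QUIK_LIMIT:
            return -math.inf
    r2, q2 = _fast_stats(arr[:, idx], y)
    return q2 if fitness == "q2_loo" else r2


def ga_select(X: pd.DataFrame, y: pd.Series, m: int, cfg: GAConfig | None = None) -> GAResult:
    """Search descriptor subsets of size ``m`` with a genetic algorithm.

    Chromosomes are fixed-cardinality index sets. Subsets violating the
    QUIK rule score -inf during evolution; after the search the best
    distinct subsets are refit with full statistics and those failing the
    significance filters are discarded. The run is fully reproducible
    from ``cfg.seed``; ties in fitness break lexicographically by
    descriptor names.
    """
    cfg = cfg or GAConfig()
    n, p = X.shape
    if m < 1 or m > 5:
        raise ValueError("subset size m must be 1..5")
    if m > p:
        raise ValueError(f"cannot select {m} of {p} columns")
    if 5 * m > n:
        raise ValueError(f"rule of thumb violated: {m} variables need >= {5 * m} training rows")
    rng = np.random.default_rng(cfg.seed)
    arr = X.to_numpy(float)
    yv = np.asarray(y, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        col_corr = np.nan_to_num(np.corrcoef(arr, rowvar=False))
    names = list(X.columns)

    cache: dict[frozenset, float] = {}

    def fitness_of(subset: frozenset) -> float:
        if subset not in cache:
            cache[subset] = _evaluate_subset(subset, arr, yv, col_corr, cfg.fitness)
        return cache[subset]

    def random_subset() -> frozenset:
        return frozenset(rng.choice(p, size=m, replace=False).tolist())

    # exhaustive search is exact and cheaper than evolving when tiny
    n_comb = math.comb(p, m)
    if n_comb <= cfg.population_size:
        for combo in itertools.combinations(range(p), m):
            fitness_of(frozenset(combo))
    else:
        population = [random_subset() for _ in range(cfg.population_size)]
        for _ in range(cfg.generations):
            scored = sorted(
                population,
                key=lambda s: (-fitness_of(s), tuple(sorted(names[i] for i in s))),
            )
            next_pop = scored[: cfg.elite]
            while len(next_pop) < cfg.population_size:
                contenders = rng.choice(len(population), size=cfg.tournament_size, replace=False)
                pa = min(contenders, key=lambda i: -fitness_of(population[i]))
                contenders = rng.choice(len(population), size=cfg.tournament_size, replace=False)
                pb = min(contenders, key=lambda i: -fitness_of(population[i]))
                a, b = population[pa], population[pb]
                shared = list(a & b)
                pool = list(a ^ b)
                rng.shuffle(pool)
                child = set(shared) | set(pool[: m - len(shared)])
                # per-gene mutation: swap a member for a random outsider
                for g in list(child):
                    if rng.random() < cfg.mutation_prob:
                        outside = [i for i in range(p) if i not in child]
                        if outside:
                            child.discard(g)
                            child.add(int(rng.choice(outside)))
                while len(child) < m:  # repair (duplicate collapse)
                    child.add(int(rng.integers(p)))
                next_pop.append(frozenset(child))
            population = next_pop
        for s in population:
            fitness_of(s)

    ranked = sorted(
        cache.items(),
        key=lambda kv: (-kv[1], tuple(sorted(names[i] for i in kv[0]))),
    )
    reason_counts = {"quik_or_degenerate": sum(1 for _, f in ranked if f == -math.inf)}
    survivors: list[FittedModel] = []
    for subset, fit_val in ranked[:50]:
        if fit_val == -math.inf:
            continue
        cols = sorted((names[i] for i in subset), key=lambda c: names.index(c))
        model = ols_fit(X[cols], y)
        model.fitness = fit_val
        if model.rejected:
            for reason in model.rejection_reasons:
                key = "p_filter" if "significant" in reason or "p_T" in reason else "quik_or_degenerate"
                reason_counts[key] = reason_counts.get(key, 0) + 1
            continue
        survivors.append(model)
    return GAResult(models=survivors, n_evaluated=len(cache), reason_counts=reason_counts)


@dataclass
class StepwiseResult:
    champions: dict[int, FittedModel]
    comparison: pd.DataFrame


def stepwise_build(
    X: pd.DataFrame,
    y: pd.Series,
    cfg: GAConfig | None = None,
    sizes=range(1, 6),
    X_test: pd.DataFrame | None = None,
    y_test: pd.Series | None = None,
) -> StepwiseResult:
    """Best surviving model per subset size 1..5 plus a comparison table.

    The comparison lists training correlation coefficient R (and the
    test-set R when a test set is supplied) per model size.
    """
    cfg = cfg or GAConfig()
    champions: dict[int, FittedModel] = {}
    rows = []
    for i, m in enumerate(sizes):
        sub_cfg = GAConfig(
            population_size=cfg.population_size, generations=cfg.generations,
            mutation_prob=cfg.mutation_prob, fitness=cfg.fitness,
            seed=None if cfg.seed is None else cfg.seed + i,
            tournament_size=cfg.tournament_size, elite=cfg.elite,
        )
        result = ga_select(X, y, m, sub_cfg)
        if result.best is None:
            continue
        champ = result.best
        champions[m] = champ
        row = {"m": m, "descriptors": "+".join(champ.names),
               "R_train": math.sqrt(max(champ.r2, 0.0)), "R2_train": champ.r2}
        if X_test is not None and y_test is not None and len(X_test):
            pred = predict(champ, X_test)["t_pred"]
            r = np.corrcoef(pred.to_numpy(), np.asarray(y_test, float))[0, 1]
            row["R_test"] = float(r)
        rows.append(row)
    return StepwiseResult(champions=champions, comparison=pd.DataFrame(rows))


# --------------------------------------------------------------------------
# estimator facade
# --------------------------------------------------------------------------


class GAMLRSelector(BaseEstimator, RegressorMixin):
    """GA + multiple linear regression subset selection as an estimator.

    fit(X, y) runs the genetic search for ``n_features`` descriptors on a
    DataFrame of (normalized) descriptors and keeps the best surviving
    model; predict(X) returns transformed-response predictions.

    Fitted attributes: ``support_`` (boolean mask over columns),
    ``selected_names_``, ``model_`` (FittedModel), ``coef_``,
    ``intercept_``, ``ga_result_``.
    """

    def __init__(
        self,
        n_features: int = 5,
        population_size: int = 200,
        generations: int = 2000,
        mutation_prob: float = 0.20,
        fitness: str = "q2_loo",
        random_state: int | None = None,
    ):
        self.n_features = n_features
        self.population_size = population_size
        self.generations = generations
        self.mutation_prob = mutation_prob
        self.fitness = fitness
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = pd.Series(np.asarray(y, dtype=float), index=X.index)
        cfg = GAConfig(
            population_size=self.population_size, generations=self.generations,
            mutation_prob=self.mutation_prob, fitness=self.fitness,
            seed=self.random_state,
        )
        result = ga_select(X, y, self.n_features, cfg)
        if result.best is None:
            raise RuntimeError(
                f"no model of size {self.n_features} survived the filters; "
                f"discard reasons: {result.reason_counts}"
            )
        self.ga_result_ = result
        self.model_ = result.best
        self.selected_names_ = list(self.model_.names)
        self.support_ = np.asarray([c in self.selected_names_ for c in X.columns])
        self.coef_ = self.model_.coef.to_numpy()
        self.intercept_ = self.model_.intercept
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def predict(self, X) -> np.ndarray:
        X = pd.DataFrame(X)
        return predict(self.model_, X)["t_pred"].to_numpy()
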