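"""Sex-stratified multiple imputation of ACE constructs by chained equations,
with Rubin's-rules pooling.

Imputation operates on the 19 derived constructs, not the individual
questionnaire items: with hundreds of items and essentially no complete
cases an item-level joint imputation model is not estimable, so the
construct level is the pragmatic unit. Strata (by default the two sexes)
are imputed separately and then concatenated, which preserves any
sex-by-adversity interaction for downstream analysis.

Within a stratum, each construct with missing values is modelled
conditionally on all other constructs and the screened auxiliary variables
using Bayesian logistic regression: the coefficient vector is drawn from a
normal approximation to its posterior (a weakly informative ridge prior
keeps separated fits proper), then missing outcomes are drawn from the
resulting Bernoulli predictive distribution. The parameter-draw-then-
outcome-draw convention matters: plug-in maximum-likelihood draws would
understate between-imputation variance. When a conditional fit fails or a
stratum's observed outcomes are constant, the engine falls back to donor
draws from the observed values of that column (logged).

Reproducibility: one master seed; dataset d of stratum s uses the
independent stream ``SeedSequence(seed, spawn_key=(s, d))``, so the stack
is bit-identical across runs and machines for a fixed spec.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .categories import ACE_CATEGORIES
from .scoring import (
    DEFAULT_CLASSIC_BINS,
    DEFAULT_EXTENDED_BINS,
    ScoreBins,
    categorise,
    classic_score,
    extended_score,
)

logger = logging.getLogger(__name__)


class ImputationError(ValueError):
    pass


@dataclass
class ImputationSpec:
    """Settings for a stratified chained-equations run.

    ``m`` and ``iterations`` default to 90 completed datasets with 30
    chained-equation cycles each — generous for construct-level missingness;
    :func:`choose_m` gives the floor implied by the incomplete-case
    fraction, never the default. ``min_exposed`` is the screening floor for
    binary adversity auxiliaries (too-rare exposures destabilise the
    conditional models without adding information).
    """

    m: int = 90
    iterations: int = 30
    strata: str = "sex"
    auxiliaries: list[str] | None = None
    min_exposed: int = 50
    seed: int = 0
    ridge: float = 1e-3

    def __post_init__(self):
        if self.m < 1:
            raise ImputationError("m must be >= 1")
        if self.iterations < 1:
            raise ImputationError("iterations must be >= 1")
        if self.min_exposed < 0:
            raise ImputationError("min_exposed must be >= 0")


@dataclass
class ImputedStack:
    """m completed construct tables plus the generating spec and traces.

    ``traces[stratum][variable]`` is an (m, iterations) array of the mean
    imputed value per cycle — flat traces indicate a converged chain.
    ``fallbacks`` lists (stratum, dataset, variable) triples where donor
    draws replaced a failed conditional model.
    """

    datasets: list[pd.DataFrame]
    spec: ImputationSpec
    strata: pd.Series
    traces: dict = field(default_factory=dict)
    fallbacks: list = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.datasets)

    def score_tables(
        self,
        classic_bins: ScoreBins = DEFAULT_CLASSIC_BINS,
        extended_bins: ScoreBins = DEFAULT_EXTENDED_BINS,
    ) -> list[pd.DataFrame]:
        """Per-dataset score tables (scores computed within each completed
        dataset, never imputed directly)."""
        out = []
        for d in self.datasets:
            cs, es = classic_score(d), extended_score(d)
            out.append(
                pd.DataFrame(
                    {
                        "classic_score": cs,
                        "extended_score": es,
                        "classic_category": categorise(cs, classic_bins),
                        "extended_category": categorise(es, extended_bins),
                    }
                )
            )
        return out


@dataclass
class PooledEstimate:
    """Rubin's-rules pooled estimate for a vector of quantities.

    total variance T = W + (1 + 1/m) B, with W the mean within-imputation
    variance and B the between-imputation variance of the m estimates.
    """

    estimate: pd.Series
    within: pd.Series
    between: pd.Series
    total: pd.Series
    m: int

    @property
    def se(self) -> pd.Series:
        return np.sqrt(self.total)


def choose_m(incomplete_fraction: float) -> int:
    """Minimum number of imputed datasets by the percentage-of-incomplete-
    cases rule of thumb: ceil(100 * fraction), floored at 2 (a single
    dataset cannot support between-imputation variance)."""
    if not 0 <= incomplete_fraction <= 1:
        raise ImputationError(f"fraction must be in [0,1], got {incomplete_fraction}")
    return max(2, math.ceil(100 * incomplete_fraction))


def screen_auxiliaries(
    aux: pd.DataFrame,
    adversity_cols: list[str] | None = None,
    min_exposed: int = 50,
) -> list[str]:
    """Screen auxiliary variables for use in the imputation model.

    Binary adversity auxiliaries (by default those whose name starts with
    ``adv_``) are dropped when fewer than ``min_exposed`` participants are
    exposed; constant columns of any type are dropped as uninformative.
    Sociodemographic auxiliaries are exempt from the exposed-count rule.
    """
    if adversity_cols is None:
        adversity_cols = [c for c in aux.columns if c.startswith("adv_")]
    retained = []
    for col in aux.columns:
        series = aux[col]
        if series.dropna().nunique() <= 1:
            logger.info("auxiliary %r dropped: constant", col)
            continue
        if col in adversity_cols:
            exposed = int((series == 1).sum())
            if exposed < min_exposed:
                logger.info(
                    "adversity auxiliary %r dropped: %d exposed < %d",
                    col, exposed, min_exposed,
                )
                continue
        retained.append(col)
    return retained


# ---------------------------------------------------------------------------
# Conditional model
# ---------------------------------------------------------------------------


def _bayes_logistic_draw(
    X: np.ndarray, y: np.ndarray, rng: np.random.Generator, ridge: float
) -> np.ndarray:
    """Draw a coefficient vector from the approximate posterior of a
    ridge-penalised logistic regression (Laplace approximation)."""
    p = X.shape[1]
    beta = np.zeros(p)
    H = None
    for _ in range(30):
        eta = np.clip(X @ beta, -30, 30)
        mu = expit(eta)
        w = mu * (1 - mu) + 1e-12
        H = (X.T * w) @ X + ridge * np.eye(p)
        grad = X.T @ (y - mu) - ridge * beta
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    if not np.all(np.isfinite(beta)):
        raise FloatingPointError("logistic fit diverged")
    cov = np.linalg.inv(H)
    cov = (cov + cov.T) / 2
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(p))
    return beta + L @ rng.standard_normal(p)


def _mice_one_dataset(
    data: np.ndarray,
    miss_mask: np.ndarray,
    aux: np.ndarray,
    iterations: int,
    rng: np.random.Generator,
    ridge: float,
    colnames: list[str],
):
    """Chained-equations completion of one stratum for one dataset.

    ``data`` (n x k constructs, float, nan where missing) is modified on a
    copy; ``aux`` (n x a) must be complete. Returns (completed, trace,
    fallbacks) with trace of shape (iterations, k).
    """
    n, k = data.shape
    work = data.copy()
    # initial fill: draw from the observed margin of each column
    for j in range(k):
        mis = miss_mask[:, j]
        if not mis.any():
            continue
        obs = work[~mis, j]
        if obs.size == 0:
            work[mis, j] = rng.integers(0, 2, mis.sum()).astype(float)
        else:
            work[mis, j] = rng.choice(obs, size=mis.sum(), replace=True)
    order = np.argsort(miss_mask.sum(axis=0))  # least missing first
    trace = np.full((iterations, k), np.nan)
    fallbacks = []
    ones = np.ones((n, 1))
    for it in range(iterations):
        for j in order:
            mis = miss_mask[:, j]
            if not mis.any():
                continue
            others = np.delete(work, j, axis=1)
            X = np.hstack([ones, others, aux])
            y_obs = data[~mis, j]
            drawn = None
            if np.unique(y_obs).size >= 2:
                try:
                    beta = _bayes_logistic_draw(X[~mis], y_obs, rng, ridge)
                    p_mis = expit(np.clip(X[mis] @ beta, -30, 30))
                    drawn = (rng.random(mis.sum()) < p_mis).astype(float)
                except (np.linalg.LinAlgError, FloatingPointError):
                    pass
            if drawn is None:  # constant outcome or failed fit -> donor draws
                fallbacks.append(colnames[j])
                if y_obs.size:
                    drawn = rng.choice(y_obs, size=mis.sum(), replace=True)
                else:
                    drawn = rng.integers(0, 2, mis.sum()).astype(float)
            work[mis, j] = drawn
            trace[it, j] = drawn.mean()
    return work, trace, fallbacks


def impute_stratified(
    constructs: pd.DataFrame,
    aux: pd.DataFrame,
    spec: ImputationSpec,
) -> ImputedStack:
    """Impute missing constructs separately within each stratum.

    ``constructs`` is participants x ACE columns in {0,1,nan}; ``aux`` is a
    complete auxiliary table aligned on the same index containing the
    stratification column and the (already screened or screenable)
    auxiliary predictors. Strata with no missing cells pass through.
    Observed cells are preserved verbatim in all m datasets.
    """
    if not constructs.index.equals(aux.index):
        raise ImputationError("constructs and auxiliaries must share an index")
    if spec.strata not in aux.columns:
        raise ImputationError(f"stratification column {spec.strata!r} not in auxiliaries")
    strata = aux[spec.strata]
    if strata.isna().any():
        raise ImputationError("stratification variable must be complete")

    aux_cols = spec.auxiliaries
    if aux_cols is None:
        candidates = aux.drop(columns=[spec.strata])
        aux_cols = screen_auxiliaries(candidates, min_exposed=spec.min_exposed)
    aux_model = aux[aux_cols].astype(float)
    if aux_model.isna().any().any():
        raise ImputationError(
            "auxiliary predictors must be complete; impute or drop incomplete auxiliaries first"
        )

    levels = sorted(strata.dropna().unique(), key=str)
    colnames = list(constructs.columns)
    datasets: list[pd.DataFrame] = []
    traces: dict = {lv: {} for lv in levels}
    fallbacks: list = []

    stratum_parts = {}
    for s_idx, level in enumerate(levels):
        rows = strata == level
        sub = constructs.loc[rows].to_numpy(dtype=float)
        a = aux_model.loc[rows].to_numpy(dtype=float)
        # standardise continuous auxiliaries for numerical stability
        sd = a.std(axis=0)
        sd[sd == 0] = 1.0
        a = (a - a.mean(axis=0)) / sd
        stratum_parts[level] = (s_idx, rows, sub, np.isnan(sub), a)

    for d in range(spec.m):
        parts = []
        for level in levels:
            s_idx, rows, sub, mask, a = stratum_parts[level]
            if not mask.any():
                parts.append(constructs.loc[rows])
                continue
            rng = np.random.default_rng(
                np.random.SeedSequence(spec.seed, spawn_key=(s_idx, d))
            )
            completed, trace, fb = _mice_one_dataset(
                sub, mask, a, spec.iterations, rng, spec.ridge, colnames
            )
            for var in set(fb):
                fallbacks.append((level, d, var))
            for j, c in enumerate(colnames):
                traces[level].setdefault(c, []).append(trace[:, j])
            parts.append(
                pd.DataFrame(completed, index=constructs.index[rows], columns=colnames)
            )
        datasets.append(pd.concat(parts).loc[constructs.index])

    for level in traces:
        traces[level] = {c: np.asarray(v) for c, v in traces[level].items()}
    if fallbacks:
        logger.info("donor-draw fallbacks used for %d (stratum, dataset, variable) cells", len(fallbacks))
    return ImputedStack(
        datasets=datasets, spec=spec, strata=strata, traces=traces, fallbacks=fallbacks
    )


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------


def rubin_pool(estimates: pd.DataFrame, variances: pd.DataFrame) -> PooledEstimate:
    """Pool m per-dataset estimates (rows) of k quantities (columns).

    With m = 1 the point estimate is returned with undefined (NaN)
    variances, reported as such rather than silently zero.
    """
    m = len(estimates)
    point = estimates.mean(axis=0)
    if m < 2:
        nanv = pd.Series(np.nan, index=point.index)
        return PooledEstimate(estimate=point, within=nanv, between=nanv, total=nanv, m=m)
    within = variances.mean(axis=0)
    between = estimates.var(axis=0, ddof=1)
    total = within + (1 + 1 / m) * between
    return PooledEstimate(estimate=point, within=within, between=between, total=total, m=m)


def pool(stack: ImputedStack, quantity: str = "prevalence") -> PooledEstimate:
    """Pool a named quantity over an imputed stack.

    Quantities: ``prevalence`` (per-ACE exposure proportion),
    ``mean_classic_score`` / ``mean_extended_score``, and
    ``classic_category_proportions`` / ``extended_category_proportions``.
    """
    n = len(stack.datasets[0])
    if quantity == "prevalence":
        est = pd.DataFrame([d.mean(axis=0) for d in stack.datasets])
        var = est * (1 - est) / n
        return rubin_pool(est, var)
    if quantity in ("mean_classic_score", "mean_extended_score"):
        fn = classic_score if "classic" in quantity else extended_score
        cols = [fn(d) for d in stack.datasets]
        est = pd.DataFrame({quantity: [c.mean() for c in cols]})
        var = pd.DataFrame({quantity: [c.var(ddof=1) / len(c) for c in cols]})
        return rubin_pool(est, var)
    if quantity in ("classic_category_proportions", "extended_category_proportions"):
        which = "classic" if "classic" in quantity else "extended"
        bins = DEFAULT_CLASSIC_BINS if which == "classic" else DEFAULT_EXTENDED_BINS
        rows_e, rows_v = [], []
        for table in stack.score_tables():
            cats = table[f"{which}_category"]
            props = cats.value_counts(normalize=True).reindex(bins.labels, fill_value=0.0)
            rows_e.append(props)
            rows_v.append(props * (1 - props) / n)
        return rubin_pool(pd.DataFrame(rows_e), pd.DataFrame(rows_v))
    raise ImputationError(f"unknown quantity {quantity!r}")
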