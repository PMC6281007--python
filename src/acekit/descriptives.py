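"""Prevalence summaries, pairwise ACE associations and reporting-structure
breakdowns.

Cramér's V between two binary constructs is computed on pairwise-complete
observations as sqrt(chi-square / n) for the 2x2 contingency table without
continuity correction (with correction a perfectly concordant small table
would score below 1). For 2x2 tables V equals the absolute phi coefficient.
"""

from __future__ import annotations

import logging
from fractions import Fraction

import numpy as np
import pandas as pd

from .categories import REPORTER_SOURCE
from .derivation import ConstructTable, ItemTable
from .imputation import ImputedStack, pool

logger = logging.getLogger(__name__)


def prevalence(constructs: pd.DataFrame | ConstructTable) -> pd.DataFrame:
    """Per-ACE exposure proportion among non-missing, with the non-missing N.

    An all-missing construct yields NaN prevalence with N = 0, reported
    rather than dropped.
    """
    df = constructs.data if isinstance(constructs, ConstructTable) else constructs
    n = df.notna().sum(axis=0)
    prev = df.mean(axis=0)
    return pd.DataFrame({"prevalence": prev, "n": n})


def cramers_v(x: pd.Series, y: pd.Series) -> float:
    """Cramér's V between two binary columns on pairwise-complete rows.

    For a 2x2 table with cells (a, b; c, d):
    chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)) and V = sqrt(chi2 / n).
    Degenerate margins (either variable constant on the complete pairs, or
    fewer than 2 pairs) give NaN.
    """
    ok = x.notna() & y.notna()
    xv = x[ok].astype(int).to_numpy()
    yv = y[ok].astype(int).to_numpy()
    n = len(xv)
    if n < 2:
        return float("nan")
    a = int(((xv == 1) & (yv == 1)).sum())
    b = int(((xv == 1) & (yv == 0)).sum())
    c = int(((xv == 0) & (yv == 1)).sum())
    d = int(((xv == 0) & (yv == 0)).sum())
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return float("nan")
    chi2 = n * (a * d - b * c) ** 2 / denom
    return float(np.sqrt(chi2 / n))


def association_matrix(constructs: pd.DataFrame | ConstructTable):
    """Symmetric matrix of pairwise Cramér's V plus pairwise-complete counts.

    Computed on the derived (pre-imputation) constructs by default; pass a
    completed dataset from an imputed stack to compute within-imputation
    associations instead.
    """
    df = constructs.data if isinstance(constructs, ConstructTable) else constructs
    cols = list(df.columns)
    k = len(cols)
    V = np.eye(k)
    N = np.zeros((k, k), dtype=int)
    for i in range(k):
        N[i, i] = int(df[cols[i]].notna().sum())
        for j in range(i + 1, k):
            pairwise = int((df[cols[i]].notna() & df[cols[j]].notna()).sum())
            v = cramers_v(df[cols[i]], df[cols[j]])
            V[i, j] = V[j, i] = v
            N[i, j] = N[j, i] = pairwise
    return (
        pd.DataFrame(V, index=cols, columns=cols),
        pd.DataFrame(N, index=cols, columns=cols),
    )


def stratified_prevalence(
    constructs: pd.DataFrame | ConstructTable,
    stratum: pd.Series,
) -> pd.DataFrame:
    """Per-ACE prevalence within each level of a stratification variable.

    Empty strata are omitted (with a warning), not reported as zero.
    Long format: columns stratum / ace / prevalence / n.
    """
    df = constructs.data if isinstance(constructs, ConstructTable) else constructs
    rows = []
    for level in sorted(stratum.dropna().unique(), key=str):
        members = stratum == level
        if not members.any():
            logger.warning("stratum %r has no members; omitted", level)
            continue
        p = prevalence(df.loc[members])
        for ace, rec in p.iterrows():
            rows.append(
                {"stratum": level, "ace": ace, "prevalence": rec["prevalence"], "n": int(rec["n"])}
            )
    return pd.DataFrame(rows)


def pooled_stratified_prevalence(stack: ImputedStack) -> pd.DataFrame:
    """Stratified prevalence pooled across an imputed stack (means of the
    per-dataset stratum prevalences)."""
    frames = [
        stratified_prevalence(d, stack.strata).assign(dataset=i)
        for i, d in enumerate(stack.datasets)
    ]
    allf = pd.concat(frames)
    return (
        allf.groupby(["stratum", "ace"], sort=False)
        .agg(prevalence=("prevalence", "mean"), n=("n", "first"))
        .reset_index()
    )


def report_breakdown(
    items: ItemTable, coverage: float | Fraction = Fraction(1, 2)
) -> pd.DataFrame:
    """Prevalence per (ACE, reporting age, data source) cell.

    Within each cell the derivation coverage rule applies: a participant
    contributes only if they answered at least half of that cell's items,
    and is coded exposed if any answered item is positive. Cells with zero
    items simply do not appear. Long format with columns
    ace / report_age / source / prevalence / n_items / n.
    """
    coverage = Fraction(coverage).limit_denominator(10**9)
    meta = items.meta.copy()
    meta["source"] = meta["reporter"].map(REPORTER_SOURCE)
    rows = []
    for (ace, age, source), cell in meta.groupby(
        ["ace_category", "report_age", "source"], sort=True
    ):
        ids = list(cell.index)
        block = items.data[ids].to_numpy(dtype=float)
        answered = (~np.isnan(block)).sum(axis=1)
        covered = answered * coverage.denominator >= len(ids) * coverage.numerator
        covered &= answered > 0
        if not covered.any():
            continue
        exposed = np.nansum(block[covered], axis=1) >= 1
        rows.append(
            {
                "ace": ace,
                "report_age": int(age),
                "source": source,
                "prevalence": float(exposed.mean()),
                "n_items": len(ids),
                "n": int(covered.sum()),
            }
        )
    return pd.DataFrame(rows)


def plot_report_breakdown(breakdown: pd.DataFrame, path) -> None:
    """Minimal scatter of cell prevalence by reporting age, one panel per
    source, marker size by item count."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sources = sorted(breakdown["source"].unique())
    fig, axes = plt.subplots(1, len(sources), figsize=(4 * len(sources), 4), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, source in zip(axes, sources):
        sub = breakdown[breakdown["source"] == source]
        ax.scatter(sub["report_age"], sub["prevalence"], s=8 * sub["n_items"], alpha=0.5)
        ax.set_title(source)
        ax.set_xlabel("age at reporting (years)")
    axes[0].set_ylabel("prevalence")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def comparison_table(
    constructs: ConstructTable,
    stack: ImputedStack | None = None,
) -> pd.DataFrame:
    """Derived-group vs imputed summary, one row per ACE plus score rows.

    Columns: N (derived-group non-missing count), derived (% exposed or
    mean score among the derived group) and, when a stack is given, imputed
    (pooled estimate over the completed datasets, single total N).
    Percentages are on the 0-100 scale; scores are means.
    """
    from .scoring import classic_score, extended_score

    prev = prevalence(constructs)
    rows = {}
    cs = classic_score(constructs.data)
    es = extended_score(constructs.data)
    rows["classic_score_mean"] = {"N": int(cs.notna().sum()), "derived": cs.mean()}
    rows["extended_score_mean"] = {"N": int(es.notna().sum()), "derived": es.mean()}
    for ace, rec in prev.iterrows():
        rows[ace] = {"N": int(rec["n"]), "derived": 100 * rec["prevalence"]}
    table = pd.DataFrame.from_dict(rows, orient="index")
    if stack is not None:
        pooled_prev = pool(stack, "prevalence").estimate
        table.loc[list(pooled_prev.index), "imputed"] = 100 * pooled_prev
        table.loc["classic_score_mean", "imputed"] = pool(
            stack, "mean_classic_score"
        ).estimate.iloc[0]
        table.loc["extended_score_mean", "imputed"] = pool(
            stack, "mean_extended_score"
        ).estimate.iloc[0]
    return table
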