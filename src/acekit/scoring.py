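"""Cumulative ACE scores and their categorical bins.

The classic ACE score sums exposure over the ten classic categories (range
0-10); the extended score sums all nineteen (0-19). Before imputation a
score is defined only for participants with every component construct
non-missing; after imputation scores are recomputed inside each completed
dataset, never imputed directly.

Default bins: classic {0}, {1}, {2-3}, {4+}; extended {0-1}, {2}, {3-5},
{6+}. An alternative extended binning {0-1}, {2}, {3-6}, {7+} is shipped as
``TEXT_EXTENDED_BINS`` — both conventions circulate and the choice is
config-driven rather than silently corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .categories import ACE_CATEGORIES, CLASSIC_ACES


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class ScoreBins:
    """Ordered, exhaustive, non-overlapping integer bins over a score range."""

    edges: tuple[tuple[int, int, str], ...]  # (lo, hi, label), closed intervals

    def __post_init__(self):
        lo0 = self.edges[0][0]
        prev_hi = lo0 - 1
        for lo, hi, _ in self.edges:
            if lo != prev_hi + 1 or hi < lo:
                raise ScoringError(f"bins do not partition the range: {self.edges}")
            prev_hi = hi

    @property
    def span(self) -> tuple[int, int]:
        return self.edges[0][0], self.edges[-1][1]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for _, _, label in self.edges)

    def label_for(self, score: int) -> str:
        for lo, hi, label in self.edges:
            if lo <= score <= hi:
                return label
        raise ScoringError(f"score {score} outside bin range {self.span}")


DEFAULT_CLASSIC_BINS = ScoreBins((
    (0, 0, "0"), (1, 1, "1"), (2, 3, "2-3"), (4, 10, "4+"),
))
DEFAULT_EXTENDED_BINS = ScoreBins((
    (0, 1, "0-1"), (2, 2, "2"), (3, 5, "3-5"), (6, 19, "6+"),
))
#: alternative extended binning used in some descriptions of the score
TEXT_EXTENDED_BINS = ScoreBins((
    (0, 1, "0-1"), (2, 2, "2"), (3, 6, "3-6"), (7, 19, "7+"),
))


def _complete_sum(constructs: pd.DataFrame, columns) -> pd.Series:
    missing_cols = [c for c in columns if c not in constructs.columns]
    if missing_cols:
        raise ScoringError(f"constructs table lacks columns {missing_cols}")
    block = constructs[list(columns)]
    total = block.sum(axis=1)
    return total.where(block.notna().all(axis=1))


def classic_score(constructs: pd.DataFrame) -> pd.Series:
    """Sum of the ten classic ACE constructs; missing unless all ten present."""
    return _complete_sum(constructs, CLASSIC_ACES).rename("classic_score")


def extended_score(constructs: pd.DataFrame) -> pd.Series:
    """Sum of all nineteen ACE constructs; missing unless all present."""
    return _complete_sum(constructs, ACE_CATEGORIES).rename("extended_score")


def categorise(score, bins: ScoreBins):
    """Map integer score(s) to bin labels; missing propagates."""
    if isinstance(score, pd.Series):
        return score.map(
            lambda s: np.nan if pd.isna(s) else bins.label_for(int(s))
        )
    if pd.isna(score):
        return np.nan
    return bins.label_for(int(score))


def score_table(
    constructs: pd.DataFrame,
    classic_bins: ScoreBins = DEFAULT_CLASSIC_BINS,
    extended_bins: ScoreBins = DEFAULT_EXTENDED_BINS,
) -> pd.DataFrame:
    """Classic and extended scores plus their categorical bins."""
    cs = classic_score(constructs)
    es = extended_score(constructs)
    return pd.DataFrame(
        {
            "classic_score": cs,
            "extended_score": es,
            "classic_category": categorise(cs, classic_bins),
            "extended_category": categorise(es, extended_bins),
        },
        index=constructs.index,
    )
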