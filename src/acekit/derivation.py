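"""Derive binary ACE constructs from dichotomised questionnaire items.

The derivation chain is: split dual-period questions into single-window
indicators, filter participants by overall response eligibility, retain the
items whose coverage window is contained in the target window, then derive
one binary construct per ACE category under a response-coverage rule.

Coverage rule: a participant's construct for an ACE is derivable only if
they answered at least half of that ACE's in-window items (the inclusive
reading of the rule: twelve items require exactly six answers). Comparison
is exact rational arithmetic (``answered * q >= total * p`` for a coverage
fraction p/q), never floating point. Among the answered items the construct
is coded any-positive by default — exposed if any answered item indicates
exposure — with a majority coding available as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .categories import ACE_CATEGORIES
from .dictionary import DUAL_CODE_MAP, QuestionRecord

logger = logging.getLogger(__name__)

META_COLUMNS = [
    "ace_category",
    "window_start",
    "window_end",
    "report_age",
    "reporter",
    "timing",
    "dual_period",
    "second_window_start",
    "second_window_end",
]


def metadata_frame(records: Sequence[QuestionRecord]) -> pd.DataFrame:
    """Column metadata (indexed by item_id) from question records."""
    rows = {
        r.item_id: {
            "ace_category": r.ace_category,
            "window_start": r.window_start,
            "window_end": r.window_end,
            "report_age": r.report_age,
            "reporter": r.reporter,
            "timing": r.timing,
            "dual_period": r.dual_period,
            "second_window_start": r.second_window_start,
            "second_window_end": r.second_window_end,
        }
        for r in records
    }
    return pd.DataFrame.from_dict(rows, orient="index")[META_COLUMNS]


@dataclass
class ItemTable:
    """Participants x items with per-column window/reporter metadata.

    ``data`` holds floats in {0.0, 1.0, nan}; dual-period columns (before
    splitting) hold the four-level codes {1,2,3,4} instead and are flagged
    in ``meta['dual_period']``.
    """

    data: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        if list(self.data.columns) != list(self.meta.index):
            self.meta = self.meta.loc[list(self.data.columns)]

    @property
    def n_participants(self) -> int:
        return len(self.data)

    @property
    def n_items(self) -> int:
        return self.data.shape[1]

    def answered_fraction(self) -> pd.Series:
        """Per-participant fraction of items answered (non-missing)."""
        return self.data.notna().mean(axis=1)

    def subset(self, item_ids: Sequence[str]) -> "ItemTable":
        ids = list(item_ids)
        return ItemTable(data=self.data[ids], meta=self.meta.loc[ids])


@dataclass
class ConstructTable:
    """Participants x 19 binary ACE constructs, with derivation provenance.

    ``answered_counts`` records how many in-window items each participant
    answered per ACE; ``items_used`` the item ids behind each construct;
    ``empty_aces`` the categories with zero in-window items (all-missing,
    flagged rather than silently dropped).
    """

    data: pd.DataFrame
    window: tuple[int, int]
    items_used: dict[str, list[str]]
    answered_counts: pd.DataFrame
    empty_aces: list[str] = field(default_factory=list)
    coding: str = "any-positive"

    def non_missing_n(self) -> pd.Series:
        """Per-ACE count of participants with a derivable construct."""
        return self.data.notna().sum(axis=0)


class DerivationError(ValueError):
    pass


# ---------------------------------------------------------------------------


def split_dual_period(items: ItemTable) -> ItemTable:
    """Replace each dual-period column by two single-window binary columns.

    The four-level coding maps as: first-period-only -> (1,0),
    second-period-only -> (0,1), both -> (1,1), neither -> (0,0),
    missing -> (missing, missing). Non-dual columns pass through unchanged.
    The split columns are named ``<item_id>__p1`` / ``<item_id>__p2`` and
    carry their own single window.
    """
    cols: dict[str, pd.Series] = {}
    meta_rows: dict[str, dict] = {}
    for item_id in items.data.columns:
        m = items.meta.loc[item_id]
        col = items.data[item_id]
        if not m["dual_period"]:
            cols[item_id] = col
            meta_rows[item_id] = m.to_dict()
            continue
        codes = pd.to_numeric(col, errors="coerce")
        bad = codes.dropna()[~codes.dropna().isin(list(DUAL_CODE_MAP))]
        if len(bad):
            raise DerivationError(
                f"dual-period item {item_id!r} carries codes {sorted(bad.unique())} "
                f"outside the four-level coding {sorted(DUAL_CODE_MAP)}"
            )
        first = codes.map({c: p[0] for c, p in DUAL_CODE_MAP.items()}).astype(float)
        second = codes.map({c: p[1] for c, p in DUAL_CODE_MAP.items()}).astype(float)
        base = m.to_dict()
        for suffix, series, (ws, we) in (
            ("__p1", first, (m["window_start"], m["window_end"])),
            ("__p2", second, (m["second_window_start"], m["second_window_end"])),
        ):
            new_id = f"{item_id}{suffix}"
            cols[new_id] = series
            meta_rows[new_id] = dict(
                base,
                window_start=int(ws),
                window_end=int(we),
                dual_period=False,
                second_window_start=None,
                second_window_end=None,
            )
    data = pd.DataFrame(cols, index=items.data.index)
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")[META_COLUMNS]
    return ItemTable(data=data, meta=meta)


def merge_dual_period(first: pd.Series, second: pd.Series) -> pd.Series:
    """Inverse of the dual-period split: dummy pair -> four-level code."""
    inverse = {pair: code for code, pair in DUAL_CODE_MAP.items()}
    out = pd.Series(np.nan, index=first.index, dtype=float)
    both = first.notna() & second.notna()
    out[both] = [
        inverse[(int(a), int(b))] for a, b in zip(first[both], second[both])
    ]
    return out


def select_window(items: ItemTable, target_start: int, target_end: int) -> ItemTable:
    """Retain items whose coverage window lies inside the target window.

    Containment is subset-or-equal on closed integer intervals: an item
    spanning 0-11 years is excluded from a 0-8 target even though the
    windows overlap, because its answer cannot be attributed to the target
    period alone. Items are never partially counted.
    """
    if not (0 <= target_start <= target_end <= 18):
        raise DerivationError(f"invalid target window {target_start}-{target_end}")
    if items.meta["dual_period"].any():
        raise DerivationError("window selection requires dual-period items to be split first")
    keep = [
        item_id
        for item_id in items.data.columns
        if target_start <= items.meta.at[item_id, "window_start"]
        and items.meta.at[item_id, "window_end"] <= target_end
    ]
    kept = items.subset(keep)
    counts = kept.meta["ace_category"].value_counts()
    logger.info(
        "window %d-%d: retained %d of %d items; per-ACE: %s",
        target_start, target_end, kept.n_items, items.n_items, counts.to_dict(),
    )
    return kept


def eligibility_filter(items: ItemTable, min_fraction: float = 0.10) -> ItemTable:
    """Retain participants answering at least ``min_fraction`` of all items.

    Applied to the full (pre-window-selection) item set, so the denominator
    is every question in the dictionary regardless of the analysis window.
    Comparison is exact: answered/total >= min_fraction as rationals.
    """
    if not (0 < min_fraction <= 1):
        raise DerivationError(f"min_fraction must be in (0, 1], got {min_fraction}")
    frac = Fraction(min_fraction).limit_denominator(10**9)
    answered = items.data.notna().sum(axis=1)
    total = items.n_items
    keep = answered.map(lambda a: Fraction(int(a), total) >= frac)
    out = ItemTable(data=items.data.loc[keep], meta=items.meta)
    logger.info(
        "eligibility >= %s of %d items: retained %d of %d participants",
        frac, total, out.n_participants, items.n_participants,
    )
    return out


def _coverage_met(answered: np.ndarray, total: int, coverage: Fraction) -> np.ndarray:
    # answered/total >= coverage, in exact integer arithmetic
    return answered * coverage.denominator >= total * coverage.numerator


def derive_construct(
    items: ItemTable,
    ace: str,
    coverage: float | Fraction = Fraction(1, 2),
    coding: str = "any-positive",
) -> tuple[pd.Series, dict]:
    """Derive one ACE's binary construct from its (window-selected) items.

    Returns the construct column and a provenance dict with the item ids
    used and per-participant answered counts. With zero in-window items the
    column is all-missing and flagged.
    """
    if coding not in ("any-positive", "majority"):
        raise DerivationError(f"unknown exposure coding {coding!r}")
    coverage = Fraction(coverage).limit_denominator(10**9)
    ids = [c for c in items.data.columns if items.meta.at[c, "ace_category"] == ace]
    info = {"ace": ace, "items": ids, "n_items": len(ids), "empty": not ids}
    if not ids:
        logger.warning("ACE %r has zero in-window items; construct all-missing", ace)
        col = pd.Series(np.nan, index=items.data.index, name=ace, dtype=float)
        info["answered"] = pd.Series(0, index=items.data.index)
        return col, info

    block = items.data[ids].to_numpy(dtype=float)
    answered = (~np.isnan(block)).sum(axis=1)
    positives = np.nansum(block, axis=1)
    covered = _coverage_met(answered, len(ids), coverage)
    if coding == "any-positive":
        exposed = positives >= 1
    else:  # majority of answered items positive
        exposed = positives * 2 > answered
    values = np.where(covered, exposed.astype(float), np.nan)
    col = pd.Series(values, index=items.data.index, name=ace)
    info["answered"] = pd.Series(answered, index=items.data.index)
    return col, info


def derive_all(
    items: ItemTable,
    window: tuple[int, int] = (0, 16),
    coverage: float | Fraction = Fraction(1, 2),
    coding: str = "any-positive",
    categories: Iterable[str] = ACE_CATEGORIES,
) -> ConstructTable:
    """Window-select then derive every ACE construct.

    ``items`` must already be dual-period split. Returns a
    :class:`ConstructTable` whose per-ACE non-missing counts are the
    derived-group N for each construct.
    """
    selected = select_window(items, *window)
    cols, items_used, answered, empty = {}, {}, {}, []
    for ace in categories:
        col, info = derive_construct(selected, ace, coverage=coverage, coding=coding)
        cols[ace] = col
        items_used[ace] = info["items"]
        answered[ace] = info["answered"]
        if info["empty"]:
            empty.append(ace)
    data = pd.DataFrame(cols, index=items.data.index)
    return ConstructTable(
        data=data,
        window=(int(window[0]), int(window[1])),
        items_used=items_used,
        answered_counts=pd.DataFrame(answered, index=items.data.index),
        empty_aces=empty,
        coding=coding,
    )
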