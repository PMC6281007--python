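"""Question dictionary: item metadata, dichotomisation rules, and their
application to raw coded questionnaire responses.

Every adversity item is described by a :class:`QuestionRecord` carrying the
ACE category it measures, the age window it covers (closed integer-year
interval), who reported it and when, and a reference into a :class:`RuleSet`
of dichotomisation rules. Applying the dictionary to a raw response table
turns arbitrary questionnaire codings into a uniform {0, 1, missing} item
table, with dual-period items (one question covering two disjoint age
windows through a four-level coding) passed through as codes for later
splitting.

Rules are total over their declared raw-code domain; raw codes outside the
domain map to *missing* with a logged warning rather than raising, because
real questionnaire exports contain stray codes and silently coercing them
to exposed/unexposed would bias prevalence.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

import numpy as np
import pandas as pd
import yaml

from .categories import ACE_CATEGORIES, REPORTERS, TIMINGS

logger = logging.getLogger(__name__)

MISSING = float("nan")

#: canonical four-level coding of dual-period questions:
#: code -> (exposed in first window, exposed in second window)
DUAL_CODE_MAP = {1: (1, 0), 2: (0, 1), 3: (1, 1), 4: (0, 0)}


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip() == "":
        return True
    return False


class DictionaryError(ValueError):
    """Raised when a dictionary or rule set fails validation."""


# ---------------------------------------------------------------------------
# Dichotomisation rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdRule:
    """Dichotomise a numeric scale against a cut-off.

    ``direction`` is one of ``gt, ge, lt, le``; a value on the exposed side
    of the cut-off maps to 1. The canonical instance is the Edinburgh
    Postnatal Depression Scale rule "score > 12 indicates probable
    depression". ``domain`` is the closed numeric range of valid raw values.
    """

    direction: str
    cutoff: float
    domain: tuple[float, float] | None = None

    def __post_init__(self):
        if self.direction not in ("gt", "ge", "lt", "le"):
            raise DictionaryError(f"unknown threshold direction {self.direction!r}")

    def apply(self, value) -> float:
        if _is_missing(value):
            return MISSING
        try:
            v = float(value)
        except (TypeError, ValueError):
            logger.warning("threshold rule: non-numeric code %r -> missing", value)
            return MISSING
        if self.domain is not None and not (self.domain[0] <= v <= self.domain[1]):
            logger.warning("threshold rule: code %r outside domain %s -> missing", value, self.domain)
            return MISSING
        if self.direction == "gt":
            return float(v > self.cutoff)
        if self.direction == "ge":
            return float(v >= self.cutoff)
        if self.direction == "lt":
            return float(v < self.cutoff)
        return float(v <= self.cutoff)


@dataclass(frozen=True)
class CategorySetRule:
    """Map an explicit set of raw codes to exposed, another to unexposed.

    Codes in neither set are out of domain and map to missing.
    """

    exposed: frozenset
    unexposed: frozenset

    def __post_init__(self):
        overlap = self.exposed & self.unexposed
        if overlap:
            raise DictionaryError(f"codes {sorted(overlap)} in both exposed and unexposed sets")

    def apply(self, value) -> float:
        if _is_missing(value):
            return MISSING
        code = _normalise_code(value)
        if code in self.exposed:
            return 1.0
        if code in self.unexposed:
            return 0.0
        logger.warning("category-set rule: code %r not in declared domain -> missing", value)
        return MISSING


@dataclass(frozen=True)
class OrderedFrequencyRule:
    """Dichotomise an ordered frequency scale at a minimum exposed level.

    ``levels`` lists the raw codes from least to most frequent; codes at or
    above ``min_level`` (a member of ``levels``) map to exposed.
    """

    levels: tuple
    min_level: object

    def __post_init__(self):
        if self.min_level not in self.levels:
            raise DictionaryError(f"min_level {self.min_level!r} not among levels {self.levels}")

    def apply(self, value) -> float:
        if _is_missing(value):
            return MISSING
        code = _normalise_code(value)
        levels = tuple(_normalise_code(l) for l in self.levels)
        if code not in levels:
            logger.warning("ordered-frequency rule: code %r not a declared level -> missing", value)
            return MISSING
        return float(levels.index(code) >= levels.index(_normalise_code(self.min_level)))


@dataclass(frozen=True)
class DualPeriodRule:
    """Marker rule for dual-period questions carrying the four-level coding.

    Dual-period questions are not scalar-dichotomisable; they are split into
    two single-window binary indicators by the derivation stage using
    :data:`DUAL_CODE_MAP`. Calling :meth:`apply` is an error by design.
    """

    code_map: Mapping[int, tuple[int, int]] = field(
        default_factory=lambda: dict(DUAL_CODE_MAP)
    )

    def apply(self, value):  # pragma: no cover - contract guard
        raise DictionaryError(
            "dual-period questions carry a four-level coding and must be "
            "split into two single-window indicators, not dichotomised"
        )


Rule = Union[ThresholdRule, CategorySetRule, OrderedFrequencyRule, DualPeriodRule]
RuleSet = dict[str, Rule]


def _normalise_code(value):
    """Fold numeric-looking codes onto floats so 1, 1.0 and "1" compare equal."""
    if isinstance(value, bool):
        return float(value)
    if isinstance(value, (int, float, np.integer, np.floating)):
        return float(value)
    if isinstance(value, str):
        try:
            return float(value)
        except ValueError:
            return value.strip()
    return value


def _rule_from_config(rule_id: str, cfg: Mapping) -> Rule:
    kind = cfg.get("type")
    if kind == "threshold":
        domain = cfg.get("domain")
        return ThresholdRule(
            direction=cfg["direction"],
            cutoff=float(cfg["cutoff"]),
            domain=tuple(float(x) for x in domain) if domain is not None else None,
        )
    if kind == "category_set":
        return CategorySetRule(
            exposed=frozenset(_normalise_code(c) for c in cfg["exposed"]),
            unexposed=frozenset(_normalise_code(c) for c in cfg["unexposed"]),
        )
    if kind == "ordered_frequency":
        return OrderedFrequencyRule(levels=tuple(cfg["levels"]), min_level=cfg["min_level"])
    if kind == "dual_period":
        return DualPeriodRule()
    raise DictionaryError(f"rule {rule_id!r}: unknown rule type {kind!r}")


def load_rules(path: str | Path) -> RuleSet:
    """Load a rule set from a YAML or JSON file keyed by rule_id."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, Mapping) or not raw:
        raise DictionaryError(f"{path}: no rules found")
    return {rid: _rule_from_config(rid, cfg) for rid, cfg in raw.items()}


def rules_to_config(rules: RuleSet) -> dict:
    """Inverse of :func:`load_rules`, for writing rule sets back out."""
    out: dict = {}
    for rid, rule in rules.items():
        if isinstance(rule, ThresholdRule):
            out[rid] = {
                "type": "threshold",
                "direction": rule.direction,
                "cutoff": rule.cutoff,
                "domain": list(rule.domain) if rule.domain else None,
            }
        elif isinstance(rule, CategorySetRule):
            out[rid] = {
                "type": "category_set",
                "exposed": sorted(rule.exposed, key=repr),
                "unexposed": sorted(rule.unexposed, key=repr),
            }
        elif isinstance(rule, OrderedFrequencyRule):
            out[rid] = {
                "type": "ordered_frequency",
                "levels": list(rule.levels),
                "min_level": rule.min_level,
            }
        elif isinstance(rule, DualPeriodRule):
            out[rid] = {"type": "dual_period"}
    return out


# ---------------------------------------------------------------------------
# Question records
# ---------------------------------------------------------------------------

DICTIONARY_COLUMNS = [
    "item_id",
    "ace_category",
    "report_age",
    "window_start",
    "window_end",
    "reporter",
    "timing",
    "dual_period",
    "second_window_start",
    "second_window_end",
    "rule_id",
    "text",
]


@dataclass(frozen=True)
class QuestionRecord:
    """Metadata for one adversity questionnaire item."""

    item_id: str
    ace_category: str
    report_age: int
    window_start: int
    window_end: int
    reporter: str
    timing: str
    dual_period: bool
    second_window_start: int | None
    second_window_end: int | None
    rule_id: str
    text: str = ""

    def validate(self, categories: Iterable[str] = ACE_CATEGORIES) -> None:
        if self.ace_category not in tuple(categories):
            raise DictionaryError(
                f"item {self.item_id!r}: unknown ace_category {self.ace_category!r}"
            )
        if self.window_start > self.window_end:
            raise DictionaryError(
                f"item {self.item_id!r}: window_start {self.window_start} > "
                f"window_end {self.window_end}"
            )
        if self.reporter not in REPORTERS:
            raise DictionaryError(f"item {self.item_id!r}: unknown reporter {self.reporter!r}")
        if self.timing not in TIMINGS:
            raise DictionaryError(f"item {self.item_id!r}: unknown timing {self.timing!r}")
        if self.dual_period:
            if self.second_window_start is None or self.second_window_end is None:
                raise DictionaryError(
                    f"item {self.item_id!r}: dual_period item lacks a second window"
                )
            if self.second_window_start > self.second_window_end:
                raise DictionaryError(
                    f"item {self.item_id!r}: second window reversed"
                )
            if self.second_window_start <= self.window_end:
                raise DictionaryError(
                    f"item {self.item_id!r}: dual windows must be disjoint and ordered"
                )
        elif self.second_window_start is not None or self.second_window_end is not None:
            raise DictionaryError(
                f"item {self.item_id!r}: second window given but dual_period is false"
            )


@dataclass
class ACEDictionary:
    """A validated question dictionary plus its rule set."""

    records: list[QuestionRecord]
    rules: RuleSet

    def __post_init__(self):
        self.validate()

    def validate(self, categories: Iterable[str] = ACE_CATEGORIES) -> None:
        if not self.records:
            raise DictionaryError("no records")
        seen: set[str] = set()
        for rec in self.records:
            if rec.item_id in seen:
                raise DictionaryError(f"duplicate item_id {rec.item_id!r}")
            seen.add(rec.item_id)
            rec.validate(categories)
            if rec.rule_id not in self.rules:
                raise DictionaryError(
                    f"item {rec.item_id!r}: rule {rec.rule_id!r} not in rule set"
                )
            if rec.dual_period and not isinstance(self.rules[rec.rule_id], DualPeriodRule):
                raise DictionaryError(
                    f"item {rec.item_id!r}: dual_period item must reference a dual_period rule"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_dual(self) -> int:
        return sum(r.dual_period for r in self.records)

    @property
    def n_analysis_variables(self) -> int:
        """Number of single-window variables after dual-period splitting."""
        return len(self.records) + self.n_dual

    def per_category_counts(self, post_split: bool = True) -> pd.Series:
        """Item counts per ACE category, in canonical category order.

        With ``post_split`` (default) dual-period questions count twice,
        matching the number of analysis variables each contributes.
        """
        counts = {c: 0 for c in ACE_CATEGORIES}
        for rec in self.records:
            counts[rec.ace_category] += 2 if (post_split and rec.dual_period) else 1
        return pd.Series(counts, name="n_items")

    def by_id(self) -> dict[str, QuestionRecord]:
        return {r.item_id: r for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "item_id": r.item_id,
                    "ace_category": r.ace_category,
                    "report_age": r.report_age,
                    "window_start": r.window_start,
                    "window_end": r.window_end,
                    "reporter": r.reporter,
                    "timing": r.timing,
                    "dual_period": r.dual_period,
                    "second_window_start": r.second_window_start,
                    "second_window_end": r.second_window_end,
                    "rule_id": r.rule_id,
                    "text": r.text,
                }
            )
        return pd.DataFrame(rows, columns=DICTIONARY_COLUMNS)

    def save(self, dict_path: str | Path, rules_path: str | Path) -> None:
        self.to_frame().to_csv(dict_path, index=False)
        Path(rules_path).write_text(yaml.safe_dump(rules_to_config(self.rules)))


def load_dictionary(path: str | Path, rules: RuleSet | str | Path) -> ACEDictionary:
    """Load and validate a question dictionary from delimited text.

    Parameters
    ----------
    path:
        CSV with a header row and the columns in :data:`DICTIONARY_COLUMNS`.
    rules:
        A :class:`RuleSet` or the path to a YAML/JSON rule file.

    Returns
    -------
    ACEDictionary
        Validated records plus rules; per-category counts are logged in the
        shape of the package's per-ACE item-count summary.
    """
    if not isinstance(rules, dict):
        rules = load_rules(rules)
    frame = pd.read_csv(path)
    if frame.empty:
        raise DictionaryError(f"{path}: no records")
    missing_cols = set(DICTIONARY_COLUMNS) - {"text"} - set(frame.columns)
    if missing_cols:
        raise DictionaryError(f"{path}: missing columns {sorted(missing_cols)}")

    records = []
    for row in frame.itertuples(index=False):
        dual = bool(row.dual_period)
        records.append(
            QuestionRecord(
                item_id=str(row.item_id),
                ace_category=str(row.ace_category),
                report_age=int(row.report_age),
                window_start=int(row.window_start),
                window_end=int(row.window_end),
                reporter=str(row.reporter),
                timing=str(row.timing),
                dual_period=dual,
                second_window_start=int(row.second_window_start)
                if dual and not _is_missing(row.second_window_start)
                else None,
                second_window_end=int(row.second_window_end)
                if dual and not _is_missing(row.second_window_end)
                else None,
                rule_id=str(row.rule_id),
                text="" if _is_missing(getattr(row, "text", "")) else str(row.text),
            )
        )
    dictionary = ACEDictionary(records=records, rules=rules)
    logger.info(
        "loaded %d question records (%d dual-period; %d analysis variables)",
        len(dictionary), dictionary.n_dual, dictionary.n_analysis_variables,
    )
    logger.info("per-ACE analysis-variable counts:\n%s", dictionary.per_category_counts())
    return dictionary


# ---------------------------------------------------------------------------
# Applying the dictionary
# ---------------------------------------------------------------------------


def dichotomise(raw_value, rule: Rule) -> float:
    """Map one raw coded value to {0.0, 1.0, nan} under a rule.

    Deterministic; missing in -> missing out; values outside the rule's
    declared domain -> missing with a logged warning.
    """
    return rule.apply(raw_value)


def apply_dictionary(raw: pd.DataFrame, dictionary: ACEDictionary):
    """Dichotomise a raw response table into an item table.

    ``raw`` is participants x items (index = participant_id). Single-window
    items are dichotomised by their rule; dual-period items are validated
    against the four-level coding and carried through as codes for
    :func:`acekit.derivation.split_dual_period`. Dictionary items with no
    data column are carried as all-missing columns with a warning.

    Returns an :class:`acekit.derivation.ItemTable`.
    """
    from .derivation import ItemTable, metadata_frame

    unknown = set(raw.columns) - {r.item_id for r in dictionary.records}
    if unknown:
        raise DictionaryError(f"raw columns not in dictionary: {sorted(unknown)}")

    columns = {}
    for rec in dictionary.records:
        rule = dictionary.rules[rec.rule_id]
        if rec.item_id not in raw.columns:
            logger.warning("item %r has no data column; carried as all-missing", rec.item_id)
            columns[rec.item_id] = pd.Series(MISSING, index=raw.index, dtype=float)
            continue
        col = raw[rec.item_id]
        if rec.dual_period:
            codes = pd.to_numeric(col, errors="coerce")
            valid = codes.isin(list(DUAL_CODE_MAP)) | codes.isna()
            if not valid.all():
                bad = codes[~valid].unique()
                logger.warning(
                    "dual item %r: codes %s outside four-level coding -> missing",
                    rec.item_id, list(bad),
                )
                codes = codes.where(valid)
            columns[rec.item_id] = codes.astype(float)
        else:
            columns[rec.item_id] = col.map(lambda v, _rule=rule: _rule.apply(v)).astype(float)

    data = pd.DataFrame(columns, index=raw.index)
    data.index.name = "participant_id"
    return ItemTable(data=data, meta=metadata_frame(dictionary.records))
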