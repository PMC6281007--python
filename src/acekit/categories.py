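"""The closed set of adverse-childhood-experience (ACE) categories.

Ten "classic" ACEs (the ones summed into the conventional 0-10 ACE score)
plus nine extended categories. Downstream score widths (10 classic / 19
extended) are fixed by this enumeration; user dictionaries may rename
categories via ``category_aliases`` in a run configuration but may not
extend the set without ``allow_extra_categories``.
"""

from __future__ import annotations

CLASSIC_ACES: tuple[str, ...] = (
    "physical_abuse",
    "sexual_abuse",
    "emotional_abuse",
    "emotional_neglect",
    "bullying",
    "substance_household",
    "violence_between_parents",
    "parental_mental_health",
    "parent_convicted",
    "parental_separation",
)

EXTENDED_ACES: tuple[str, ...] = (
    "social_class",
    "financial_difficulties",
    "neighbourhood_satisfaction",
    "social_support_parent",
    "social_support_child",
    "violence_child_partner",
    "physical_illness_child",
    "physical_illness_parent",
    "parent_child_bond",
)

ACE_CATEGORIES: tuple[str, ...] = CLASSIC_ACES + EXTENDED_ACES

N_CLASSIC = len(CLASSIC_ACES)
N_ACES = len(ACE_CATEGORIES)

REPORTERS = ("mother", "partner", "child", "school")
TIMINGS = ("prospective", "retrospective")

#: reporter -> data source used in reporting-age breakdowns
REPORTER_SOURCE = {
    "mother": "parent",
    "partner": "parent",
    "child": "child",
    "school": "school",
}
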