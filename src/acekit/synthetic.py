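"""Synthetic birth-cohort generator with known ground truth.

Emulates the structure of a large longitudinal cohort's childhood-adversity
questionnaire data: ~12,000 participants, 19 ACE categories measured by 541
questions (41 of them dual-period, giving 582 analysis variables after
splitting), parent/child/school reporters at different ages, socially
patterned item nonresponse, and auxiliary sociodemographic and off-window
adversity variables.

The generative model is a single-factor latent structure: each participant
has a standard-normal deprivation factor (``ses``, oriented so higher =
more deprived). Exposure to each ACE is Bernoulli with
``logit p = alpha + loading * ses + effect_female * female``; the intercept
``alpha`` is calibrated by quadrature so the *marginal* prevalence hits the
configured target exactly. The shared factor induces the low-to-medium
pairwise associations seen between real ACE constructs with one
interpretable knob, and keeps the implied covariance trivially valid.
Exposure is persistent across childhood: a participant exposed to an ACE is
exposed in every item window, so with perfect items the derivation is an
exact function of the latent state.

Items report the latent exposure with configurable sensitivity and
specificity, conditionally independently given exposure. Both default to 1
(report = truth) so that the missingness scenarios isolate missing-data
bias; the "noisy" scenario turns measurement error on. Note that under
any-positive derivation over k items, independent item errors make the
derived construct a consistent estimator of the *implied* construct
prevalence P(any item fires), not of the latent prevalence —
:meth:`GroundTruth.expected_derived_prevalence` provides that implied
value for checks.

Item nonresponse is logistic in the deprivation factor, the reporter
(child self-reports are missed more often), the reporting age, and a
participant-level normal random intercept. The random intercept clusters
nonresponse within participants — whole questionnaires go unanswered —
which is what makes the 10%-answered eligibility rule bind at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .categories import ACE_CATEGORIES
from .dictionary import (
    ACEDictionary,
    CategorySetRule,
    DualPeriodRule,
    OrderedFrequencyRule,
    QuestionRecord,
    RuleSet,
    ThresholdRule,
)

# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

#: analysis variables (post dual-split) per ACE; sums to 582
DEFAULT_ITEM_COUNTS: dict[str, int] = {
    "physical_abuse": 49,
    "sexual_abuse": 12,
    "emotional_abuse": 46,
    "emotional_neglect": 23,
    "bullying": 19,
    "substance_household": 70,
    "violence_between_parents": 48,
    "parental_mental_health": 82,
    "parent_convicted": 25,
    "parental_separation": 48,
    "social_class": 6,
    "financial_difficulties": 44,
    "neighbourhood_satisfaction": 11,
    "social_support_parent": 14,
    "social_support_child": 17,
    "violence_child_partner": 13,
    "physical_illness_child": 11,
    "physical_illness_parent": 23,
    "parent_child_bond": 21,
}

#: dual-period questions per ACE (each contributes 2 analysis variables);
#: sums to 41, so raw questions sum to 582 - 41 = 541
DEFAULT_DUAL_COUNTS: dict[str, int] = {
    "physical_abuse": 3,
    "sexual_abuse": 1,
    "emotional_abuse": 3,
    "emotional_neglect": 2,
    "bullying": 1,
    "substance_household": 5,
    "violence_between_parents": 3,
    "parental_mental_health": 6,
    "parent_convicted": 2,
    "parental_separation": 3,
    "social_class": 0,
    "financial_difficulties": 3,
    "neighbourhood_satisfaction": 1,
    "social_support_parent": 1,
    "social_support_child": 1,
    "violence_child_partner": 1,
    "physical_illness_child": 1,
    "physical_illness_parent": 2,
    "parent_child_bond": 2,
}

#: target marginal exposure prevalences per ACE (population scale)
DEFAULT_PREVALENCE: dict[str, float] = {
    "physical_abuse": 0.176,
    "sexual_abuse": 0.037,
    "emotional_abuse": 0.225,
    "emotional_neglect": 0.221,
    "bullying": 0.253,
    "substance_household": 0.137,
    "violence_between_parents": 0.241,
    "parental_mental_health": 0.470,
    "parent_convicted": 0.094,
    "parental_separation": 0.322,
    "social_class": 0.117,
    "financial_difficulties": 0.184,
    "neighbourhood_satisfaction": 0.108,
    "social_support_parent": 0.126,
    "social_support_child": 0.138,
    "violence_child_partner": 0.139,
    "physical_illness_child": 0.099,
    "physical_illness_parent": 0.271,
    "parent_child_bond": 0.225,
}

#: female-vs-male log-odds shifts used by the sex-interaction scenario
SEX_INTERACTION_EFFECTS: dict[str, float] = {
    "sexual_abuse": 0.95,
    "physical_abuse": 0.21,
    "emotional_neglect": -0.22,
    "bullying": -0.26,
    "social_support_child": -0.45,
    "violence_child_partner": -0.33,
    "physical_illness_child": -0.48,
}

_WINDOW_CYCLE = [
    (0, 2), (1, 3), (2, 4), (3, 5), (4, 6), (5, 7), (6, 8), (7, 9),
    (8, 10), (9, 11), (10, 12), (11, 13), (12, 14), (13, 15), (14, 16),
    (0, 8), (8, 16), (0, 16), (0, 11), (0, 18), (16, 18),
]
_DUAL_WINDOW_CYCLE = [
    ((5, 7), (8, 9)), ((8, 9), (10, 11)), ((10, 11), (12, 13)),
    ((6, 7), (8, 8)), ((12, 13), (14, 16)),
]


def default_rules() -> RuleSet:
    return {
        "binary_yesno": CategorySetRule(exposed=frozenset({1.0}), unexposed=frozenset({2.0})),
        "epds_gt12": ThresholdRule(direction="gt", cutoff=12, domain=(0, 30)),
        "freq_weekly": OrderedFrequencyRule(levels=(1, 2, 3, 4), min_level=3),
        "dual_fourlevel": DualPeriodRule(),
    }


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults are the reference study conditions.

    ``prevalence`` is the target marginal exposure prevalence per ACE;
    ``ses_loading`` the log-odds shift per SD of the deprivation factor;
    ``sex_effects`` female-vs-male log-odds shifts. Missingness is logistic:
    ``logit p_miss = intercept + b_ses*ses + b_child*1[child report]
    + b_age*(report_age - 8) + u`` with ``u ~ N(0, participant_sd)``.
    An intercept of ``-inf`` switches nonresponse off entirely.
    """

    n_participants: int = 12_000
    male_fraction: float = 0.514
    prevalence: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    ses_loading: dict[str, float] | float = 1.2
    sex_effects: dict[str, float] = field(default_factory=dict)
    item_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_ITEM_COUNTS))
    dual_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_DUAL_COUNTS))
    sensitivity: float = 1.0
    specificity: float = 1.0
    missing_intercept: float = -1.6
    missing_ses: float = 0.9
    missing_child: float = 0.3
    missing_age: float = 0.03
    missing_participant_sd: float = 1.2
    seed: int = 7

    def loading_for(self, ace: str) -> float:
        if isinstance(self.ses_loading, dict):
            return float(self.ses_loading.get(ace, 0.0))
        return float(self.ses_loading)

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        if not 0 <= self.male_fraction <= 1:
            raise ValueError("male_fraction must be in [0,1]")
        for prob_name in ("sensitivity", "specificity"):
            p = getattr(self, prob_name)
            if not 0 <= p <= 1:
                raise ValueError(f"{prob_name} must be in [0,1]")
        for ace in ACE_CATEGORIES:
            p = self.prevalence.get(ace)
            if p is None or not 0 < p < 1:
                raise ValueError(f"target prevalence for {ace!r} must be in (0,1), got {p}")
            if not math.isfinite(self.loading_for(ace)):
                raise ValueError(f"ses loading for {ace!r} must be finite")
            if self.dual_counts.get(ace, 0) * 2 > self.item_counts.get(ace, 0):
                raise ValueError(f"{ace!r}: more dual analysis variables than items")
        if self.missing_participant_sd < 0:
            raise ValueError("missing_participant_sd must be >= 0")


@dataclass
class GroundTruth:
    """Per-participant latent state stored alongside every generated cohort.

    Never visible to the pipeline stages under test; used only by tests and
    acceptance checks to compare estimates with the generating truth.
    """

    exposure: pd.DataFrame  # participants x 19, 0/1
    ses: pd.Series
    sex: pd.Series  # "M"/"F"
    target_prevalence: dict[str, float]
    config: SyntheticConfig

    def latent_prevalence(self) -> pd.Series:
        """Empirical prevalence of the latent exposures in this cohort."""
        return self.exposure.mean(axis=0)

    def sex_prevalence(self) -> pd.DataFrame:
        return self.exposure.groupby(self.sex).mean()

    def expected_derived_prevalence(
        self, dictionary: ACEDictionary, window: tuple[int, int] = (0, 16)
    ) -> pd.Series:
        """Expected any-positive construct prevalence under the item noise
        model, for complete data: P*(1-(1-sens)^k) + (1-P)*(1-spec^k) with
        k the number of in-window analysis variables for the ACE."""
        sens, spec = self.config.sensitivity, self.config.specificity
        k = {ace: 0 for ace in ACE_CATEGORIES}
        for rec in dictionary.records:
            windows = [(rec.window_start, rec.window_end)]
            if rec.dual_period:
                windows.append((rec.second_window_start, rec.second_window_end))
            for ws, we in windows:
                if window[0] <= ws and we <= window[1]:
                    k[rec.ace_category] += 1
        p = self.latent_prevalence()
        out = {}
        for ace in ACE_CATEGORIES:
            if k[ace] == 0:
                out[ace] = float("nan")
                continue
            out[ace] = p[ace] * (1 - (1 - sens) ** k[ace]) + (1 - p[ace]) * (
                1 - spec ** k[ace]
            )
        return pd.Series(out)


class Cohort(NamedTuple):
    dictionary: ACEDictionary
    responses: pd.DataFrame  # raw coded values, participants x 541 questions
    aux: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Dictionary fixture
# ---------------------------------------------------------------------------


def build_dictionary(config: SyntheticConfig | None = None) -> ACEDictionary:
    """Deterministically build the synthetic question dictionary.

    Per-ACE analysis-variable counts follow ``config.item_counts`` (the
    reference conditions give 541 questions, 41 dual-period, 582 analysis
    variables). Windows, reporters, timing and rules cycle through fixed
    schedules so that every structural case occurs: retrospective young-
    adult self-reports, child and school reporters, wide windows that a
    0-16 target excludes, and all three scalar rule types.
    """
    config = config or SyntheticConfig()
    records: list[QuestionRecord] = []
    for ace in ACE_CATEGORIES:
        n_post = config.item_counts[ace]
        n_dual = config.dual_counts.get(ace, 0)
        n_single = n_post - 2 * n_dual
        for i in range(n_single):
            ws, we = _WINDOW_CYCLE[i % len(_WINDOW_CYCLE)]
            retro = i % 9 == 5
            if retro:
                reporter, timing, age = "child", "retrospective", 22
            else:
                timing = "prospective"
                age = min(we + 1, 18)
                if we >= 8 and i % 3 == 0:
                    reporter = "child"
                elif i % 7 == 6:
                    reporter = "partner"
                elif ace == "bullying" and i % 4 == 1:
                    reporter = "school"
                else:
                    reporter = "mother"
            if i % 7 == 3:
                rule = "epds_gt12"
            elif i % 5 == 2:
                rule = "freq_weekly"
            else:
                rule = "binary_yesno"
            records.append(
                QuestionRecord(
                    item_id=f"{ace}_q{i:03d}",
                    ace_category=ace,
                    report_age=age,
                    window_start=ws,
                    window_end=we,
                    reporter=reporter,
                    timing=timing,
                    dual_period=False,
                    second_window_start=None,
                    second_window_end=None,
                    rule_id=rule,
                    text=f"synthetic {ace.replace('_', ' ')} question {i}",
                )
            )
        for i in range(n_dual):
            (w1s, w1e), (w2s, w2e) = _DUAL_WINDOW_CYCLE[i % len(_DUAL_WINDOW_CYCLE)]
            records.append(
                QuestionRecord(
                    item_id=f"{ace}_d{i:02d}",
                    ace_category=ace,
                    report_age=min(w2e + 1, 18),
                    window_start=w1s,
                    window_end=w1e,
                    reporter="mother",
                    timing="prospective",
                    dual_period=True,
                    second_window_start=w2s,
                    second_window_end=w2e,
                    rule_id="dual_fourlevel",
                    text=f"synthetic dual-period {ace.replace('_', ' ')} question {i}",
                )
            )
    return ACEDictionary(records=records, rules=default_rules())


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(61)
_GH_NORM = _GH_WEIGHTS.sum()


def _calibrate_intercept(
    target: float, loading: float, effect_female: float, male_fraction: float
) -> float:
    """Solve for the intercept making the marginal prevalence hit the target,
    integrating over the standard-normal deprivation factor and the sexes."""

    def marginal(alpha: float) -> float:
        pm = _GH_WEIGHTS @ expit(alpha + loading * _GH_NODES) / _GH_NORM
        pf = _GH_WEIGHTS @ expit(alpha + loading * _GH_NODES + effect_female) / _GH_NORM
        return male_fraction * pm + (1 - male_fraction) * pf

    lo, hi = -40.0, 40.0
    if not marginal(lo) < target < marginal(hi):
        raise ValueError(
            f"target prevalence {target} infeasible for loading {loading} "
            f"and sex effect {effect_female}"
        )
    return brentq(lambda a: marginal(a) - target, lo, hi, xtol=1e-12)


def _report(exposure: np.ndarray, sens: float, spec: float, rng: np.random.Generator):
    if sens == 1.0 and spec == 1.0:
        return exposure.copy()
    u = rng.random(exposure.shape)
    return np.where(exposure == 1, (u < sens), (u > spec)).astype(np.int64)


def generate_cohort(config: SyntheticConfig | None = None) -> Cohort:
    """Draw a full synthetic cohort: raw responses, auxiliaries, truth.

    Deterministic for a fixed config (including its seed): same seed, same
    bytes. Raises before sampling if the configuration is infeasible.
    """
    config = config or SyntheticConfig()
    config.validate()
    dictionary = build_dictionary(config)
    # calibrate all intercepts up front so infeasible configs fail early
    alphas = {
        ace: _calibrate_intercept(
            config.prevalence[ace],
            config.loading_for(ace),
            float(config.sex_effects.get(ace, 0.0)),
            config.male_fraction,
        )
        for ace in ACE_CATEGORIES
    }

    n = config.n_participants
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    index = pd.RangeIndex(1, n + 1, name="participant_id")

    ses = rng.standard_normal(n)
    male = rng.random(n) < config.male_fraction
    female = (~male).astype(float)
    u_miss = (
        rng.standard_normal(n) * config.missing_participant_sd
        if config.missing_participant_sd > 0
        else np.zeros(n)
    )

    exposure = {}
    for ace in ACE_CATEGORIES:
        logit = alphas[ace] + config.loading_for(ace) * ses + config.sex_effects.get(ace, 0.0) * female
        exposure[ace] = (rng.random(n) < expit(logit)).astype(np.int64)
    exposure_df = pd.DataFrame(exposure, index=index)

    no_missing = np.isneginf(config.missing_intercept)
    columns: dict[str, np.ndarray] = {}
    for rec in dictionary.records:
        e = exposure[rec.ace_category]
        if rec.dual_period:
            r1 = _report(e, config.sensitivity, config.specificity, rng)
            r2 = _report(e, config.sensitivity, config.specificity, rng)
            code = np.select(
                [(r1 == 1) & (r2 == 0), (r1 == 0) & (r2 == 1), (r1 == 1) & (r2 == 1)],
                [1, 2, 3],
                default=4,
            ).astype(float)
            values = code
        else:
            r = _report(e, config.sensitivity, config.specificity, rng)
            if rec.rule_id == "epds_gt12":
                values = np.where(
                    r == 1, rng.integers(13, 29, n), rng.integers(0, 13, n)
                ).astype(float)
            elif rec.rule_id == "freq_weekly":
                values = np.where(
                    r == 1, rng.integers(3, 5, n), rng.integers(1, 3, n)
                ).astype(float)
            else:
                values = np.where(r == 1, 1.0, 2.0)
        if not no_missing:
            base = (
                config.missing_intercept
                + config.missing_child * (rec.reporter == "child")
                + config.missing_age * (rec.report_age - 8)
            )
            p_miss = expit(base + config.missing_ses * ses + u_miss)
            values = np.where(rng.random(n) < p_miss, np.nan, values)
        columns[rec.item_id] = values
    responses = pd.DataFrame(columns, index=index)

    aux = pd.DataFrame(index=index)
    aux["sex"] = np.where(male, "M", "F")
    aux["maternal_age"] = np.clip(28 - 1.5 * ses + rng.standard_normal(n) * 4, 16, 45)
    aux["home_ownership"] = (rng.random(n) < expit(1.2 - 1.3 * ses)).astype(int)
    edu_latent = -ses + rng.standard_normal(n)
    aux["maternal_education"] = np.digitize(edu_latent, [-0.5, 0.8])
    aux["parity"] = rng.poisson(np.exp(0.1 * ses))
    aux["birthweight"] = 3400 - 90 * ses + rng.standard_normal(n) * 480
    for name, (a0, b) in {
        "adv_prebirth_depression": (-2.2, 0.9),
        "adv_prebirth_financial": (-2.0, 1.0),
        "adv_prebirth_separation": (-2.4, 0.8),
        "adv_young_adult_partner_violence": (-2.6, 0.7),
        "adv_young_adult_antidepressant": (-2.0, 0.8),
    }.items():
        aux[name] = (rng.random(n) < expit(a0 + b * ses)).astype(int)

    truth = GroundTruth(
        exposure=exposure_df,
        ses=pd.Series(ses, index=index, name="ses"),
        sex=pd.Series(np.where(male, "M", "F"), index=index, name="sex"),
        target_prevalence=dict(config.prevalence),
        config=config,
    )
    return Cohort(dictionary=dictionary, responses=responses, aux=aux, truth=truth)


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------


def mcar_variant(config: SyntheticConfig) -> SyntheticConfig:
    """Zero the SES/reporter/age missingness coefficients, keeping only the
    intercept (and any participant random effect, itself independent of the
    data): the completely-at-random null scenario."""
    return replace(config, missing_ses=0.0, missing_child=0.0, missing_age=0.0)


def scenario_suite(n_participants: int = 12_000, seed: int = 7) -> dict[str, SyntheticConfig]:
    """Named generator configurations for the standard test scenarios.

    - ``complete``: perfect items, no nonresponse; derivation must equal
      the latent truth exactly.
    - ``noisy``: imperfect items (sensitivity 0.95, specificity 0.999),
      no nonresponse; isolates measurement error.
    - ``mcar``: nonresponse independent of everything observable.
    - ``mar-ses``: deprivation-patterned nonresponse (the realistic case);
      complete-case prevalence is biased downward because the more deprived
      are both more exposed and less observed.
    - ``sex-interaction``: mar-ses plus sex-specific exposure shifts
      (females higher sexual/physical abuse; males higher emotional
      neglect, bullying, lack of support, partner violence, illness).
    """
    base = SyntheticConfig(n_participants=n_participants, seed=seed)
    return {
        "complete": replace(
            base,
            missing_intercept=float("-inf"),
            missing_ses=0.0,
            missing_child=0.0,
            missing_age=0.0,
            missing_participant_sd=0.0,
        ),
        "noisy": replace(
            base,
            sensitivity=0.95,
            specificity=0.999,
            missing_intercept=float("-inf"),
            missing_ses=0.0,
            missing_child=0.0,
            missing_age=0.0,
            missing_participant_sd=0.0,
        ),
        "mcar": replace(
            base,
            missing_intercept=-1.1,
            missing_ses=0.0,
            missing_child=0.0,
            missing_age=0.0,
            missing_participant_sd=0.8,
        ),
        "mar-ses": base,
        "sex-interaction": replace(base, sex_effects=dict(SEX_INTERACTION_EFFECTS)),
    }
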