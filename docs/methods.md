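# Methods

This note records the statistical model behind `acekit`, the defaults and why
they were chosen, what the synthetic generator does and does not emulate, and
the numerical conventions. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Construct derivation

**Dichotomisation.** Every questionnaire item carries a rule: a threshold on
a numeric scale (direction + cut-off, e.g. a depression screen exposed when
the score is *strictly* greater than 12), an explicit exposed/unexposed code
set, or an ordered-frequency scale cut at a minimum exposed level. Rules are
total over their declared domain; out-of-domain codes map to **missing with a
warning** rather than raising or coercing, because questionnaire exports
contain stray codes and coercion would bias prevalence in an unknowable
direction. Missing always propagates.

**Dual-period items.** An item whose response distinguishes exposure in two
disjoint age windows (codes: first only / second only / both / neither) is
split into two single-window dummies; the mapping is a bijection, so the
original code is exactly recoverable from the dummy pair (tested as a
round-trip identity). The reference dictionary has 541 questions, 41 of them
dual-period, hence 582 analysis variables.

**Window selection.** Ages and windows are integer years and windows are
closed intervals; the dictionary, not the code, carries the interpretation of
each question's recall period. An item enters a target window only if its
window is a subset of the target — an item spanning 0–11 cannot inform a 0–8
construct and partial counting is never attempted. Retention is therefore
monotone in the target window (property-tested).

**Coverage rule.** A construct is derivable iff the participant answered at
least half of the ACE's in-window items. We read "half" inclusively — twelve
items require exactly six answers — and implement the comparison as exact
integer arithmetic (`answered × q ≥ total × p` for threshold p/q), never
floating point, so boundary cases are deterministic. The general threshold is
configurable.

**Exposure coding.** Among answered items the construct is **any-positive**:
exposed iff at least one answered item indicates exposure. This is the only
coding consistent with per-item yes/no exposure recodes, but since source
derivations do not always state it, a `majority` alternative is exposed as a
config option; any-positive is the default.

**Eligibility.** Participants answering fewer than 10 % of *all* questions
(the full 0–18 item set, pre-window-selection) are excluded before
derivation. The comparison is again exact rational arithmetic: 54 of 541 is
below the threshold, 55 is not.

## Scores

The classic score sums the ten classic constructs (0–10), the extended score
all nineteen (0–19). Pre-imputation, a score is missing unless every
component is observed — this is deliberately strict; imputation, not
proration, handles the missingness. Post-imputation, scores are recomputed
inside each completed dataset and pooled, never imputed directly.

Default bins are classic {0}, {1}, {2–3}, {4+} and extended {0–1}, {2},
{3–5}, {6+}. Both conventions that circulate for the extended bins are
shipped ({3–5}/{6+} default, {3–6}/{7+} selectable); the choice is
config-driven rather than silently corrected because published descriptions
of the binning disagree with one another.

## Multiple imputation

Imputation operates on the 19 derived constructs, not the 582 items: with
essentially no complete cases at item level, a joint item-level model is not
estimable, and the construct level is the pragmatic unit.

Within each stratum (default: sex, to preserve sex-by-adversity interactions
for downstream analysis), the engine runs chained equations. Each incomplete
construct is modelled by logistic regression on all other constructs plus the
screened auxiliaries. Draws follow the posterior-predictive convention: the
coefficient vector is drawn from the Laplace (normal) approximation to the
posterior of a ridge-penalised fit (ridge 10⁻³, which keeps separated fits
proper), then missing outcomes are drawn Bernoulli from the linear predictor.
Plug-in maximum-likelihood draws would understate between-imputation
variance, which is why the parameter draw matters. If a conditional fit fails
or the observed outcome is constant in a stratum, that variable falls back to
donor draws from its observed margin; every fallback is recorded in the stack
provenance. Variables are visited in order of increasing missingness; initial
values are drawn from the observed margins.

Auxiliary screening drops constant columns and binary adversity auxiliaries
with fewer than 50 exposed participants (too-rare exposures destabilise the
conditional fits without adding information); sociodemographic auxiliaries
are exempt from the count rule. The engine requires complete auxiliaries and
imputes constructs only.

Defaults are m = 90 completed datasets and 30 cycles each — generous for
construct-level missingness; `choose_m` gives the floor implied by the
incomplete-case percentage rule of thumb (`max(2, ceil(100·fraction))`),
never the default. Tests and the acceptance script use m = 20 with 10 cycles
at n = 4,000, sizes at which the pooled estimates are already stable and a
full run takes well under a minute on one core; convergence traces (mean
imputed value per cycle) are exposed for inspection rather than asserting a
convergence criterion.

**Reproducibility.** One master seed; dataset *d* of stratum *s* uses the
independent stream `SeedSequence(seed, spawn_key=(s, d))`. Two runs with the
same spec are bit-identical (tested), and datasets/strata are mutually
independent streams.

**Pooling.** Rubin's rules: point estimate = mean of per-dataset estimates;
total variance `T = W̄ + (1 + 1/m)·B`. Within-imputation variances are
`p(1−p)/n` for proportions and `s²/n` for means. With m = 1 the SE is
reported as undefined, not zero.

## The synthetic cohort generator

The generator exists so every pipeline stage can be tested against known
truth. It emulates: ~12,000 participants; 19 ACE categories measured by 541
questions (item counts per ACE matching the reference dictionary, 41
dual-period); mother/partner/child/school reporters at realistic ages
including retrospective young-adult self-reports; three scalar rule types;
socially patterned item nonresponse; and auxiliary sociodemographic and
off-window adversity variables.

**Exposure model.** A single standard-normal deprivation factor per
participant (higher = more deprived). Exposure to ACE *j* is Bernoulli with
`logit p = α_j + λ_j·ses + γ_j·female`; α_j is calibrated by Gauss–Hermite
quadrature so the marginal prevalence hits the configured target exactly
(defaults: population-scale prevalences in the 4 %–47 % range typical of UK
cohort reports). The default loading λ = 1.2 log-odds/SD produces the
low-to-medium pairwise Cramér's V pattern (≈ 0–0.22) seen between real ACE
constructs. A single shared factor, rather than a full copula, keeps the
implied dependence trivially valid with one interpretable knob; real
inter-ACE dependence is richer than any one factor, and the loading is a knob,
not a fidelity claim. Exposure is persistent across childhood (one indicator
per ACE covering all windows), so with perfect items derivation is an exact
function of the latent state — the identity used by the recovery tests.

**Items.** Each item reports its ACE's exposure with configurable
sensitivity/specificity, conditionally independently given exposure; dual
items report the two periods independently. Both default to 1. This is
deliberate: under any-positive derivation over k items, independent item
errors make the derived prevalence converge to the *implied* prevalence
`P·(1−(1−sens)^k) + (1−P)·(1−spec^k)`, not to the latent prevalence — false
positives accumulate across items. The `noisy` scenario (sensitivity 0.95,
specificity 0.999 — misreporting of sensitive exposures is overwhelmingly
under-report, so the false-positive rate is kept very low) is therefore
checked against that implied value, which the ground-truth object computes
analytically, while the missingness scenarios keep perfect items so that
missing-data bias is isolated from measurement bias.

**Nonresponse.** Item-level logistic model:
`logit p_miss = intercept + 0.9·ses + 0.3·1[child report] + 0.03·(age−8) + u`,
with a participant-level random intercept `u ~ N(0, 1.2²)`. The random
intercept is an extension beyond the cell-level logistic terms: without it,
nonresponse is independent across 541 items and virtually no participant
falls below the 10 % eligibility rule; clustered whole-questionnaire dropout
is what makes that rule (and construct-level missingness of 10–30 %) realistic.
Under these defaults the more deprived are both more exposed and less
observed, so complete-case prevalence is biased downward — the pattern the
imputation exists to correct. The `mcar` scenario zeroes the patterned terms;
`sex-interaction` adds female/male log-odds shifts (females higher sexual and
physical abuse, males higher neglect, bullying, lack of support, partner
violence, child illness).

**Auxiliaries.** Complete by construction: sex, maternal age, home ownership,
maternal education, parity, birthweight (all correlated with the deprivation
factor) and five binary off-window adversity indicators (`adv_*`). Real
cohort auxiliaries are themselves incomplete; handling that would require
imputing auxiliaries jointly, which the engine deliberately does not do.

**What passing tests show.** The generator shares the pipeline's own
abstractions (binary exposures, logistic structure, MAR by construction), so
green tests demonstrate correctness of the derivation/imputation machinery
and the direction and correctability of MAR selection bias — not that real
cohort data meet MAR, nor that real items are conditionally independent, nor
real effect sizes.

## Numerical conventions and edge cases

- Coverage and eligibility comparisons in exact integer/rational arithmetic.
- Cramér's V without continuity correction (correction would put a perfectly
  concordant small table below 1, breaking the V(x,x)=1 invariant); computed
  on pairwise-complete observations of the derived constructs by default,
  with per-imputed-dataset computation available. Degenerate margins give
  NaN, reported as undefined rather than 0.
- An ACE with zero in-window items yields an all-missing construct plus a
  named flag, never a silent drop; empty strata are omitted with a warning.
- Logistic IRLS is clipped at |η| ≤ 30 and capped at 30 Newton steps; the
  posterior covariance is symmetrised with jitter 10⁻¹² before Cholesky.
- Problem sizes in tests/acceptance: exact-recovery cohorts n = 12,000;
  missingness comparisons n = 4,000 with m = 20 and 10 cycles; oracle
  equivalence on 1,000 random small tables — sizes at which Monte-Carlo
  error is far below the effects being measured.

## Known limitations

- Equal-weight cumulative scores assume each ACE has the same direction and
  magnitude of effect; severity or subjective impact is not modelled.
- No not-missing-at-random sensitivity models; MAR is assumed, untestable.
- The imputation engine handles binary constructs and complete numeric
  auxiliaries only; it is not a general-purpose MICE replacement.
- The synthetic dictionary is structurally faithful (counts, windows,
  reporters, rule types) but its per-item rules and wordings are
  illustrative, not reproductions of any cohort's instruments.
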