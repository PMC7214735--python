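# Methods

This note documents the statistical model behind `approvalmeta`, the
conventions it fixes where several were defensible, and what its synthetic
corpora do and do not emulate.

## Data model

A corpus is a list of approvals (one marketing authorisation per
drug × route × indication), each holding randomised trials, their arms, and
investigational-vs-comparator arm contrasts. Every contrast carries a
*reporting tier* describing how completely the dossier reports it:

| tier | what the dossier gives | derivation |
|---|---|---|
| `arm_stats` | per-arm means/SDs of change, or event counts | pooled-SD Cohen's d / log-OR conversion |
| `contrast_only` | the arm contrast and its SE | t = contrast/SE, d = t·√(1/n₁+1/n₂) |
| `p_and_n_only` | a two-sided p, group sizes, direction | t-quantile inversion |
| `insufficient` | neither | excluded, counted |

Missing values are encoded as empty CSV cells / JSON nulls, never sentinel
numbers, because an unreported dose or non-inferiority boundary is not a
zero. The CSV bundle carries its schema version in a `manifest.json`;
readers reject unknown versions. Pooled non-inferiority analyses (a verdict
derived from pooling several trials) are stored as analysis-level records
flagged `pooled_analysis`; they are graded per analysis but never counted as
studies or arm comparisons.

## Effect sizes

All effects are standardized mean differences oriented so that **negative d
favours the investigational drug**, whatever the outcome scale's direction
(`better_is`) or, for binary outcomes, whether the event is desirable.

* Continuous arm statistics: `d = (m_inv − m_comp)/s_pooled` with the
  bias-free pooled SD, `var(d) = (n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))`.
* Binary arm statistics: `d = ln(OR)·√3/π` (the logistic conversion),
  `var(d) = 3/π²·Σ 1/cell`, with a 0.5 continuity correction added to all
  four cells only when a zero cell occurs. A table whose two arms are both
  all-events or both no-events carries no information: the estimate is
  flagged degenerate and excluded from pooling.
* No small-sample correction is applied by default, since the quantity of
  interest is Cohen's d; Hedges' J = 1 − 3/(4·df − 1) is available behind
  the `hedges` option everywhere.

**p-value convention.** Two-sided p-values for continuous and contrast-based
estimates are computed from the two-sample t statistic
`t = d·√(n₁n₂/(n₁+n₂))` on `n₁+n₂−2` df — the statistic a trial report
itself prints — rather than from the Wald ratio `d/se(d)` whose variance
includes the `d²` term. This makes the imputation tier an exact inverse:
feeding an estimate's (p, n₁, n₂, direction) back through the t-quantile
recovers d to numerical precision, so mixing tiers inside one meta-analysis
cannot introduce a systematic p↔d inconsistency. Binary estimates use the
Wald statistic on the log-odds scale (which equals `d/se(d)`), referred to
the same t reference for uniformity. A comparison reported only as a
p-value *without* a direction is never signed by guesswork; it is counted in
the insufficient tier.

## Random-effects pooling

Pooling keys are (drug, daily dose, design phase, comparator class) plus,
by default, the approval's indication; `ignore_indication` merges across
indications. Multi-arm trials contribute one comparison per investigational
dose arm against the shared control, with no shared-control correction —
comparisons are treated as the unit of analysis throughout. Only
investigational arms dosed inside the approval's `[approved_dose_min,
approved_dose_max]` enter meta-analyses; arms outside the range are excluded
with a logged record id, and approvals lacking dose bounds retain their arms
with a warning rather than silently dropping evidence.

The estimator is DerSimonian–Laird:
`Q = Σwᵢ(dᵢ − d_FE)²` with fixed weights `wᵢ = 1/varᵢ`,
`τ² = max(0, (Q − (k−1))/(Σwᵢ − Σwᵢ²/Σwᵢ))`, random weights
`wᵢ* = 1/(varᵢ + τ²)`, Wald (normal) 95% CI and two-sided p. With k = 1 the
pooled estimate is the single study's; with estimated τ² = 0 it reduces
exactly to inverse-variance fixed-effect pooling. REML, Paule–Mandel and the
Hartung–Knapp adjustment are deliberately out of scope: the classic moment
estimator is the reference behaviour this pipeline reproduces. A known
consequence, measured by the package's own simulations, is that the Wald CI
undercovers at small k under heterogeneity — at k = 5, n = 100/arm,
τ² = 0.05 the empirical 95% CI coverage is ≈ 0.90 rather than 0.95. The
point estimate is essentially unbiased there (mean pooled d within 0.02 of
truth), with a slight attenuation toward zero because the d-dependent
variance term downweights larger effects.

Each pooled estimate is classified at the two-sided 0.05 level as
`favours_drug` (significant, negative), `favours_comparator` (significant,
positive) or `no_evidence_of_difference` — "negative" trial results in this
domain usually mean exactly "non-significant", so the same threshold is used
everywhere.

## Evidence grading

Per trial and comparator class: a superiority trial is *positive* iff some
primary comparison is significant in the drug's favour; *negative* if
compared without such a result (an insufficiently reported comparison still
counts as compared); *uncompared* if a comparator arm exists but no
drug-vs-comparator contrast is reported — the "internal positive control for
assay sensitivity" pattern, which the grading deliberately surfaces rather
than treats as evidence. Non-inferiority trials are judged by the dossier's
reported verdict; when none is recorded and a contrast CI plus
non-inferiority boundary are available, the trial is positive iff the CI
bound on the unfavourable side stays within the boundary (upper bound for
lower-is-better outcomes, lower bound otherwise).

Per approval, each of five base evidence columns (superiority vs active,
non-inferiority vs active, superiority vs placebo — all initiation — and the
two continuation columns) is graded `robust` (≥2 positives), `single`
(exactly 1), `none` (0) or `not_required` when the dossier's flags say that
kind of evidence was not needed. The two grouped columns take the
*max-evidence* category across the initiation and continuation columns of
the same comparator class (not the summed positives: one positive initiation
plus one positive continuation trial is still a single-study grade, matching
how grouped columns are tallied in this literature). Percentages are rounded
half-away-from-zero and always published next to their raw fraction, because
source reports round inconsistently (21/26 appears as both 80% and 81%).

## Synthetic corpora

`generate(GeneratorConfig(...))` draws, per trial, a true standardized
effect `δᵢ ~ Normal(μ_comparator, τ²)`; continuous arms have unit population
SD with the drug arm shifted by δᵢ and sampling noise on both the observed
mean (normal) and SD (scaled χ); binary arms fix the comparator event rate
(default 0.4) and set the drug arm's rate so the log-odds conversion equals
δᵢ. Reporting completeness is censored per comparison into the four tiers.
Defaults mirror the corpus the pipeline was built to analyse: 27 approvals,
Poisson(5) trials each, 100 subjects/arm, μ_placebo = −0.3, μ_active = 0,
τ² = 0.05, 80% continuous outcomes, tier probabilities
(0.60, 0.10, 0.05, 0.25), 30% active comparators, 10% continuation trials.

Randomness uses one root seed with per-approval substreams
(`SeedSequence(seed, spawn_key=(i,))`), so extending a corpus never perturbs
existing approvals; tier draws use a separate substream, so
`generate_paired` yields a censored and a fully reported view of the *same*
realisation — that pairing is how the imputation cascade's consistency is
measured (the mean difference between censored and uncensored pooled
estimates is ≈ 0.002, well under the 0.03 acceptance bound). A binary
comparison drawn into the contrast tier is promoted to full arm statistics,
since a difference in proportions has no continuous-scale SE to report.

What the generator does **not** emulate: dropout and withdrawal mechanisms,
cross-over or adaptive designs, correlated comparisons within multi-arm
trials, non-inferiority hypotheses, and selective (outcome-dependent)
reporting — censoring is independent of the realised result. Passing tests
therefore show the pipeline's internal consistency under clean missingness,
not robustness to informative missingness in real dossiers.

`reference_corpus()` is a deterministic 27-approval corpus whose *tallies* —
evidence categories per column, non-inferiority verdicts, safety/tolerance
reporting counts, routes, the 48/137 suicidal-exclusion flags, and the
158/29/12/67 reporting-tier split over 266 dose-eligible comparisons in 137
studies (one study sits entirely below its approved dose range and is
excluded from meta-analyses) — match a published appraisal of psychotropic
approvals. Its individual study effect values are schematic round numbers
chosen only to make "positive" comparisons clearly significant
(d = −0.5 or −0.6 at 120/arm) and "negative" ones clearly not (d = −0.05);
per-approval flag values beyond the printed tallies are arbitrary and
documented as such. Consequently corpus-level *medians* of pooled effects
from the fixture are not estimates of the published medians, which would
require the unpublished per-study extraction; the published medians are
instead covered qualitatively by the generator's parameter-recovery
simulations. The fixture is shipped both as code and as a checked-in CSV
bundle (`load_fixture_corpus()`), with a test pinning the two together.

## Numerical details and edge cases

* Quantile/CDF work uses scipy's t and normal distributions; the
  p-and-n inversion is exact to the precision of `t.isf`
  (round-trip < 1e−6; below p ≈ 1e−12 quantile precision dominates).
* Empty strata yield explicit empty results (`n_keys = 0`, `None` medians),
  never zeros; zero denominators yield `None` percentages.
* The sample median averages the two middle order statistics for even
  counts.
* Validation collects *all* violations with record identifiers before
  failing, so a corrupt corpus is diagnosed in one pass.
* Writers are deterministic (stable field and record order); the CLI writes
  through temporary files and renames, leaving no partial outputs.

## Problem sizes used by the checks

The simulation-based checks use 500 replicates for parameter recovery and
coverage (k = 5 trials of 100/arm), 2 500 null comparisons for the type-I
error, and 150 paired corpora of 10 trials for the censoring comparison —
sizes at which the Monte-Carlo error of each target quantity is several
times smaller than its acceptance band, while the whole suite stays fast
enough to run on every change.
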