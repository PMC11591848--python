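# Methods

## Task administration

A session is a deterministic state machine over a board of `n = 10`
blocks. At each level `k` (starting at 2) the engine draws
`trials_per_level = 3` targets — each a uniform ordered sample of `k`
distinct blocks, fresh per trial — collects a response per trial, and
advances to `k + 1` iff at least `pass_min_correct = 1` response
reproduces its target exactly. The session ends at the first failed level
or after level `max_level = 10` (sequences never repeat a block, so 10 is
also the hard geometric cap). All three trials of a level are always
administered before the pass decision. Timing constants (1 s highlight,
0.5 s inter-block, 5 s preparation) are carried as metadata only; the
engine is callback-driven and never sleeps, because it simulates the
procedure rather than presenting stimuli. Each session uses one seeded
`numpy` generator recorded in the transcript, so transcripts are
bit-reproducible from `(config, seed)`.

The board ships with a fixed irregular 10-block layout (top-left origin,
cm units). Positions are arbitrary: the procedure depends only on block
identity. Layouts with other block counts (≥ 2) are permitted so that
sequence-distribution tests can enumerate small boards exhaustively.

## Scoring

`score_trial` credits one item per position `i < min(|target|,
|response|)` with `response[i] == target[i]`. There is no credit for a
correct block in a wrong position; clicks beyond the target length earn
nothing and void full correctness. The session score is
`FinalResult = L − 1 + avLevelScore/L` with `L` the last administered
level (including a failed terminal level — forced by the worked example,
where no level-3 trial is fully correct yet `L = 3`).

Two readings of the `avLevelScore` divisor circulate: the number of
trials at the terminal level, and the sequence length. The worked
arithmetic `(2 + 2 + 1)/3` at level 3 with three trials cannot
distinguish them; we default to the trial count, which keeps
`avLevelScore/L ∈ [0, 1]` and `FinalResult ∈ [L − 1, L]` at every level,
and expose the alternative as `divisor="level"`. A hard-threshold
respondent with span `s` (perfect up to length `s`, empty beyond) scores
exactly `s`: it fails level `s + 1` with zero credit, giving
`(s + 1) − 1 + 0`.

All internal arithmetic is unrounded; report-time rounding is half-up at
two decimals (`1.6667 → 1.67`, `2.5556 → 2.56`). The good/poor
performance split used by the contingency analysis defaults to a
threshold of 7.0 points (consistent with the study's binning of scores at
7) and is fully configurable, since "good performance" has no canonical
definition.

## Synthetic cohort

No session-level data are deposited, so the package ships a generative
stand-in (explicitly not a cognitive model):

- **Recall.** A respondent with latent span `s` recalls each item of a
  length-`k` sequence independently with
  `p_item(k) = (1 − lapse) · logistic((s − k)/τ)`. A failed item is
  replaced by a uniformly chosen wrong block not yet used in the
  response, so responses keep the target's length and a "certain-failure"
  respondent scores exactly zero credits.
- **Spans.** `s = base_span + δ_group·musician + δ_sex·male +
  β_age·(age − 24) + N(0, σ_group)`, with per-group σ because the two
  groups' observed score SDs differ (0.78 vs 1.10). `β_age` defaults to
  0, matching the null age effect within 18–40.
- **Demographics.** Ages are truncated normal per group (musicians
  23.6 ± 3.6 in 19–35; non-musicians 24.62 ± 6.17 in 18–40); sex is
  Bernoulli (47.5% / 48% male); musicians' years of music reading are
  lognormal calibrated to mean 8.25, SD 5.25, clipped to 1–25 and
  uncorrelated with span (matching the null experience correlation).
- **Self-assessment.** Perceived span is `s + N(0, meta_sigma)`; the
  participant claims "good" iff it reaches a common reference span,
  otherwise "bad", except with probabilities 11.8% / 2.6% of answering
  "normal" / "unable" (those participants are generated for realism and
  excluded from inference, mirroring the study's exclusions). Musicians
  get `meta_sigma = 0.35` versus 5.0 for non-musicians: sharper
  metacognition is the single mechanism behind the claim-accuracy
  asymmetry.

### Calibration

`τ = 0.4` and `lapse = 0.02` fix the within-person session noise (score
SD ≈ 0.48 at fixed span, score ≈ 0.96·span − offset in the operating
range). Given those, `base_span = 6.50`, `δ_group = 0.78`,
`δ_sex = 0.76`, `σ_mus = 0.645`, `σ_non = 1.05` were fitted once by
iterative Monte-Carlo so that, at n = 10 000/group, simulated final
scores reproduce the study conditions: musicians ≈ 7.04 (SD 0.78),
non-musicians ≈ 6.30 (SD 1.10), male − female ≈ 0.72. The
`meta_reference = 7.2` and the two `meta_sigma` values were chosen so the
replicate-level direction of the accuracy asymmetry is stable (musicians
more accurate in ≳ 96% of 200 replicate studies) while keeping roughly
half the cohort claiming "good"; this trades a few points of the observed
"good" margin (≈ 50% simulated vs 59% observed) for a robust asymmetry,
which we consider the scientifically meaningful feature. A sharper
threshold `τ` was preferred over a larger metacognitive gap because
session noise, not self-assessment noise, is what dilutes claim accuracy.

The null specification used for type-I-error studies removes the group
shift and pools the span SD at 0.85 across groups: group heteroscedasticity
is not part of the null hypothesis being calibrated.

### What the generator does not emulate

Serial-position effects, chunking strategies, proactive interference,
practice and fatigue, response latencies, and any correlation between
musical experience and span. Passing tests therefore validate the
*pipeline* — scoring, progression, estimator calibration, error rates —
not any claim about human memory.

## Statistical procedures

All statistics are computed from explicit formulas/linear algebra;
`scipy`'s distribution functions supply p-values (never table lookups);
`pingouin`/`scipy` appear only as independent cross-checks in the tests.

- **ANCOVA.** OLS of score on a dummy-coded factor plus covariates
  (categorical covariates dummy-coded, drop-first). Each term's F is the
  partial (Type-III equivalent) model-comparison F — standard and
  order-invariant with one factor and continuous covariates — and
  `η_p² = SS_term/(SS_term + SS_residual)`. Adjusted means are model
  predictions at covariate means. Rank-deficient designs raise an error
  naming the columns. A scale-aware guard returns F = 0 for perfectly
  fit (constant) outcomes where both sums of squares are numerical noise.
- **Assumption checks.** Levene's test (ANOVA on absolute deviations;
  mean-centered classic variant by default, median optional), covariate
  independence (one-way ANOVA of the covariate on the factor), and
  homogeneity of slopes (partial F of the factor × covariate interaction
  added to `dv ~ factor + covariate`).
- **Simple tests.** Pearson r with a t-test on n − 2 df; Pearson χ² with
  margin-product expecteds; Mann-Whitney U with exact enumeration for
  combined n ≤ 10 and a tie-corrected, continuity-corrected normal
  approximation otherwise; pooled-Student and Welch t with Cohen's d
  (pooled SD) and a CI for the mean difference. Two-sided p-values
  throughout except χ² (upper tail). No multiple-testing correction is
  applied anywhere, matching the analysis plan being reproduced.
- **Metacompetence table.** Group × (claim, performance) counts on the
  good/bad-filtered sample; percentages default to the claim-good
  denominator (the four cells summing to 100), configurable to the full
  filtered sample. The χ² test runs on the generic r×c count table; the
  exact cell structure behind the study's reported df = 4 is not
  recoverable from a 2 × 4 layout, so the statistic is reported for the
  table as constructed.
- **Experience split.** One-way ANOVA across strata `years < 8` vs
  `≥ 8` (configurable cut), which satisfies `F = t²` against the pooled
  t-test.

`run_full_analysis` chains the stages in the study's order — exclusion
filter, matching checks (age t-test; Mann-Whitney on sex coded 0/1),
assumption checks, ANCOVA, descriptives (group and group × claim with
Student-t 95% CIs), correlations, contingency analysis, experience
split — and returns one JSON-serializable report.

## Validation strategy and problem sizes

Monte-Carlo checks use sizes chosen to keep the whole suite comfortably
reproducible on a laptop while leaving Monte-Carlo error well inside the
asserted bands: 90 000 draws for sequence-frequency uniformity, 10 000
random trials for scorer-oracle equivalence, 1 000 replicate studies
(n = 30/group) for the ANCOVA type-I error band 0.05 ± 0.02, 10 000
participants/group for generator calibration (±0.15 band), 500
simulations for the uniformity of interaction-test p-values, and 200
replicate studies for the metacompetence direction. Seeds are fixed in
the tests; every simulation is reproducible from its seed.

## Known limitations

- The latent-span/Bernoulli-recall model is a convenience prior for
  pipeline validation, not an account of visuospatial memory.
- Observed F/p values of the original study are not reproducible without
  its raw data; the pipeline validates against its own simulations and
  the study's closed-form/arithmetic quantities only.
- The self-assessment model cannot represent systematic over- or
  under-confidence (its noise is zero-mean by construction), so the
  simulated "good"-claim margin undershoots the observed one.
- Backward/descending presentation formats, reaction times, and GUI
  presentation are out of scope.
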