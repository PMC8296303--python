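# Methods

This note records the scoring conventions, statistical procedures,
simulation model and numerical choices the package implements, and what
its synthetic-data tests do and do not establish.

## Transcript scoring

A transcript is an ordered list of tokens with onsets in seconds from task
start. Scoring proceeds in three steps.

**Labelling.** Each token is trimmed, case-folded, and matched exactly
against the taxonomy's canonical names and variants (no fuzzy matching:
transcripts come from human transcribers, so spelling is controlled). A
token whose identity key — canonical form when in-lexicon, case-folded raw
text otherwise — repeats any earlier response is a *perseveration*,
regardless of whether the earlier response was correct; this makes a
repeated non-animal word a perseveration rather than a second intrusion,
and makes "puppy" after "dog" a perseveration because variants collapse to
their canonical before duplicate detection. Otherwise the token is
*correct* if in-lexicon and an *intrusion* if not.

**Windowing.** Responses with onset beyond the scoring window (default
60 s) are discarded before labelling. The half boundary is half-open:
onset < window/2 counts toward the first half, onset = window/2 toward the
second, so `total = first_half + second_half` always. Untimed transcripts
get `None` half scores; an explicit fallback (`untimed_index_split`)
splits the response list at its midpoint instead, and the risk equation
refuses untimed scores unless that fallback was used.

**Cluster segmentation.** Correct responses are partitioned left-to-right
into maximal runs; a run extends while the intersection of the subcategory
sets of all its members stays non-empty (running-intersection semantics).
Because any prefix of a valid run is valid, the greedy left-maximal
partition is exactly the partition whose run-length sequence is
lexicographically largest among all valid compositions — which is what the
brute-force enumeration oracle in the test suite checks, exhaustively, for
every distinct-animal sequence of length ≤ 8 over a three-subcategory toy
taxonomy. Perseverations and intrusions are skipped and neither join nor
break a run (the cluster definition counts *correct* responses only); the
alternative convention is available as `errors_break_clusters=True`, and
pairwise adjacency chaining (each neighbouring pair shares a subcategory,
no global intersection) as `chain_mode="pairwise"`. Cluster size is member
count − 1; the clustering score is the mean cluster size, defined as 0 for
mute transcripts so the risk score stays computable; switching is
max(#clusters − 1, 0).

The bundled lexicon (191 English animals, 35 subcategories, multiple
membership allowed) follows standard semantic-fluency subcategory norms.
Subcategory granularity materially affects clustering/switching scores,
and the original instrument's (Korean) lexicon is unpublished, so all
scoring is taxonomy-file-driven and any language or scheme can be
substituted.

## Risk score

The WS is a pure dot product of {sex, age, education, first-half,
switching, clustering, perseveration} with a fixed coefficient set; total,
second-half and intrusion scores are deliberately excluded and never
silently added. Coefficients are data, not code. The published equation
contains two age terms ("0.474 × age + 0.003 × age") and no sex term;
taken verbatim it yields WS values an order of magnitude outside the
published group means (2.3 ± 1.4 cases, −0.1 ± 1.7 controls), whereas
reading 0.474 as a male-sex indicator — the natural slot in a
demographics-adjusted logistic model — lands inside that range. Both
readings ship as presets (`as_printed`, `sex_age`); `sex_age` is the
default and the active preset is logged loudly. Education is interpreted
as years (the published cohort table reports years). The logit maps to a
probability by the logistic function; classification is positive at
`ws >= cutoff` (ties positive — a screen errs toward sensitivity), default
cutoff 1.143, and the probability maps onto a three-colour band
(green < 0.33 ≤ yellow < 0.66 ≤ red) for lay-facing reporting.

## Validation statistics

*ROC/AUC.* Thresholds sit at midpoints between adjacent distinct observed
scores plus ±∞ endpoints, which is why published cutoffs (1.143, 25.5)
fall between observed values. AUC is computed as the Mann-Whitney
concordance probability with midranks; it equals trapezoidal integration
of the empirical curve. Orientation (higher- vs lower-is-case) is an
explicit attribute per score, never inferred: WS, age, clustering and
perseveration are higher-in-cases; MMSE, total, half scores, switching
and intrusion are lower-in-cases.

*Youden cutoff.* The threshold maximising sensitivity + specificity − 1;
ties break toward higher sensitivity, then the more liberal threshold.
The published cutoff tables contain rows where a neighbouring threshold
has equal sensitivity and strictly higher specificity than the row marked
optimal; whatever selection rule produced that marking is not documented,
so this package applies its own deterministic rule and does not attempt to
reproduce that specific selection. PPV/NPV derive from
TP = sens·n_cases, FP = (1−spec)·n_controls; zero denominators yield NaN
flags rather than exceptions.

*Paired AUC comparison.* The comparison of two scores measured on the same
participants uses the DeLong structural-components covariance estimator
with a two-sided normal z test — the de facto standard for correlated ROC
curves and the natural reading of a paired "z-test of AUCs" on a
same-subjects design. The implementation is cross-checked in the test
suite against R's pROC `roc.test` and, for the single-AUC variance,
against simulation. Comparing a score with itself returns z = 0, p = 1.

*Reliability and adjusted association.* Cronbach's alpha uses the raw
covariance formula (a standardized variant is available); because the
original item set is not documented, the default items are the
per-10-second-bin correct counts (6 bins over 60 s), which are derivable
from any timed transcript and measure the internal consistency of the
production process — an interpretation, flagged as such; the seven index
scores are available as an alternative item set. Partial (covariate-
adjusted) Pearson correlation residualises both variables on the
covariates plus intercept and tests with n − k − 2 degrees of freedom.
The adjusted group comparison fits an OLS model with a case indicator and
covariates and tests the single-df group term (F = t²; with no covariates
this is exactly the squared pooled two-sample t). Baseline tables use
Student's t for continuous variables and Pearson chi-square *without*
continuity correction for categorical ones — the uncorrected statistic
reproduces the published administration-order p ≈ 0.04, the corrected one
does not. Test-retest reliability is the adjusted correlation between
administrations after listwise exclusion. p values are reported at machine
precision with no multiple-testing correction.

## Synthetic cohorts

No public dataset of timed, labelled fluency transcripts exists for this
instrument, so the generator is openly a stand-in calibrated to published
summary statistics; every calibrated constant carries a comment naming its
target. Word onsets follow an inhomogeneous Poisson process with rate
r0·exp(−λt), sampled exactly by time rescaling — chosen because roughly
three-quarters of correct words are produced in the first 30 s (79.2 %
cases, 73.7 % controls), which pins λ per group, with r0 then set from the
target mean totals (7.7 / 16.7). At each emission the speaker perseverates
or intrudes with small probabilities (set from the target error-score
means) or produces a correct word, staying in the current subcategory with
probability p_stay (targeting the switching means) and otherwise switching
to a fresh one; exhausted subcategories force a switch. A participant-level
latent ability shifts the log rate and is shared across administrations
and instruments; the fraction of ability variance carried between
occasions is the retest-reliability target. Age and education also shift
the log rate, so adjusted analyses face genuine confounding. Demographics
are truncated normals (age ≥ 60, education ≥ 0, MMSE clipped to 0–30)
matching the published group tables. All draws flow through one seeded
numpy generator; output is fully reproducible.

Known limitation: the published clustering and switching means are
mutually inconsistent with the stated definitions (control total 16.7 and
switching 7.7 imply ≈ 8.7 clusters and mean cluster size ≈ 0.9, not the
printed 1.7), so the generator targets total, first-half fraction,
switching and the error scores; clustering means are emergent and sit
below the printed values. The generator also produces English tokens with
no transcription noise, no covariance structure among index scores beyond
what the mechanism induces, and occasion effects that are pure noise (no
practice effect). Passing recovery tests therefore show that the pipeline
recovers the structure this mechanism encodes — not that the instrument
performs as published on clinical data.

## Problem sizes and tolerances

The acceptance computations use: exhaustive segmentation over all 109,600
distinct-animal sequences of length ≤ 8; 200 random instances each for the
AUC and Youden oracles; 2,000 Monte Carlo replicates at n = 100+100 for
each type-I-error calibration (accepted band 0.05 ± 0.02); and one
200-per-group synthetic cohort for parameter recovery (WS AUC expected in
[0.75, 0.95] — a recovery band, not a reproduction of the published 0.861;
mean totals within ±1.5 of targets; first-half fractions within ±0.05).
Numerical ties in Youden selection and cluster segmentation are broken by
the documented deterministic rules; floating-point comparisons in oracle
agreement use absolute tolerance 1e-12.
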