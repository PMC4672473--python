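# Methods

This note documents the model, its tunable parameters, the numerical
conventions the implementation fixes, what the synthetic-data generator
does and does not emulate, and known limitations.

## The model

The tariff method is a nearest-prototype-style additive classifier over
binary items.  Its core assumption is that individual question and text
items are consistently associated with particular causes of death, so a
cause can be characterized by which items its deaths endorse more (or
less) often than deaths from other causes.

Training proceeds in four stages:

1. **Endorsement rates.**  For each cause *i* and item *j*,
   `r(i, j) = (# cause-i deaths endorsing j) / (# cause-i deaths)`.
   Every cause must have at least one training death; missing responses
   are coded 0 at load time (the scoring equation admits only {0, 1}),
   with per-column counts logged so data-quality problems stay visible.
2. **Tariffs.**  `tariff(i, j) = (r(i, j) − median) / IQR`, median and
   IQR taken across causes for item *j*.  The tariff is a robust z-score:
   it is large when cause *i* endorses item *j* far outside the typical
   range across causes, and it is insensitive to a few extreme causes.
3. **Significance filtering.**  Tariffs estimated from few endorsements
   are noisy and, uncorrected, can drive assignments.  We draw 500
   bootstrap replicates of the training set (resampling records with
   replacement *within* cause, up to each cause's original count),
   recompute unrounded tariffs per replicate, and keep a (cause, item)
   cell only when the empirical 95% interval of its replicate tariffs has
   strictly same-signed endpoints.  The percentile interval is used
   directly; no normal approximation.
4. **Top-40 masking and rank pools.**  Per cause, the ≤ 40 surviving
   items with the largest absolute tariff are kept (ties at the boundary
   break by lexicographic item id, so training is deterministic).  The
   training set is then resampled with replacement to a uniform cause
   distribution — m records per cause, m defaulting to the largest
   observed cause count so every death stays eligible — and every
   resampled record is scored against every cause.  The per-cause
   descending score pools are the yardstick that makes scores comparable
   across causes with inherently different tariff magnitudes.

Assignment of a new death: score against every cause; rank each score in
that cause's pool (1 = best; midrank for ties, rounded up); remove causes
disallowed by restriction rules (sex/age/site predicates from a CSV, not
hard-coded); a cause survives if its rank ≤ q·(pool size) and its score
is strictly above the absolute minimum; the surviving cause with the best
rank wins, ties breaking by larger raw score then lexicographic cause id.
No survivor → indeterminate, with a reason code (all causes disallowed /
below the absolute threshold / below every cause-rank threshold).

Redistribution: each indeterminate death is split across causes using
weights that average (a) the per-cause probability of a *training* death
being classified indeterminate (normalized to sum 1) and (b) an external
cause-fraction weight table stratified by module, sex, and age band, then
renormalize.  The renormalization after averaging makes downstream
conservation exact even when the inputs carry rounding error.  Assigned
deaths contribute one full death to their cause, so the population CSMF
always sums to 1.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `bootstrap_b` | 500 | bootstrap replicates for significance filtering |
| `ui_level` | 0.95 | width of the bootstrap uncertainty interval |
| `rounding` | 0.5 | tariff rounding granularity (0 = none); published tariff tables use half-unit granularity |
| `top_k` | 40 | items retained per cause by absolute tariff |
| `rank_quantile` | 0.18 | cause-specific rank threshold as a fraction of the uniform pool |
| `min_score` | 0.0 | absolute score threshold (strict inequality) |
| `resample_per_cause` | max cause count | uniform-resample size per cause |
| `min_count` (text) | 50 | minimum corpus occurrences for a narrative stem to become an item |
| `n_splits` / `train_frac` / `alpha` | 500 / 0.75 / 1.0 | validation design: splits, training fraction, Dirichlet concentration |

The two assignment thresholds are calibration choices, not published
values — the method's description requires both thresholds but does not
print their numbers.  The 0.18 rank quantile is sized for operational
cause lists of 30+ causes, where one cause's own deaths fill only a few
percent of the uniform pool; with very short cause lists (4–6 causes, as
in small synthetic studies) one cause fills 20–25% of the pool and the
same cut is considerably more aggressive, raising the indeterminate rate.
Both thresholds are echoed into the serialized model metadata.

## Numerical conventions

- **Quartiles** are computed with the exclusive (n+1)-position
  linear-interpolation convention (R type 6, `numpy` method
  `"weibull"`).  The choice matters: under the inclusive convention an
  item endorsed by only one cause out of five has across-cause IQR
  exactly 0 and would carry tariff 0 for every cause, so a perfectly
  discriminating item could never be retained.  Under the exclusive
  convention the same item has IQR 0.5 and tariff +2 for its cause in
  every bootstrap replicate.  The brute-force oracle in the test suite
  encodes the same convention independently.
- **IQR = 0** (identical rates across causes) defines tariff 0: such an
  item carries no spread information.  A small-epsilon denominator floor
  was rejected because it manufactures unbounded tariffs from degenerate
  items.
- **Rounding** to the nearest 0.5 happens after the significance test
  (which uses unrounded replicate tariffs) and before top-40 selection.
- **Midranks** for ties in pools, rounded up; winner ties break
  score-then-lexicographic.  All tie-breaks are deterministic, so a
  trained model serializes identically across runs with one seed.
- **Splits** are reproducible from (master seed, split index) via
  independent seed sequences for partitioning, Dirichlet resampling, and
  training.
- **Percentiles** for split summaries use linear interpolation
  (`numpy` default), fixed for reproducibility.
- Degenerate inputs: an all-negative record scores 0 everywhere and the
  strict absolute threshold makes it indeterminate — never an error;
  an empty assignment list or empty metric vector is an error.

## Metrics

CCC rescales per-cause sensitivity so random allocation over N causes
scores 0 and perfection scores 1; the summary statistic is the median
across causes with at least one true death (a cause absent from a test
side has undefined sensitivity and is excluded).  Indeterminate
predictions count as wrong for every true cause, so liberal indeterminate
thresholds depress CCC while improving population-level accuracy — this
trade-off is intrinsic to the method, not a bug.

CSMF accuracy normalizes total absolute composition error by its maximum
possible value, attained when all predicted mass sits on the cause with
the smallest true fraction.  Uniformly random assignment to populations
with Dirichlet-drawn compositions still achieves ≈ 0.632 (close to
1 − 1/e, the large-N limit of the expected normalized error under a flat
Dirichlet), so chance-corrected CSMF accuracy subtracts this floor.  The
floor is recomputable with `validation.chance_floor`; the default
simulated population size (1,961 deaths) matches a 25% test side of the
7,846 adult gold-standard deaths, the setting in which the 0.632
reference value was derived.  At much smaller population sizes (e.g. 250
deaths) multinomial realization noise in both the truth and the uniform
predictions drags the mean noticeably below 0.632 (≈ 0.59); this is a
property of the simulation size, not of the metric.

## The synthetic generator

`simulate.generate` emulates the *structure* the method assumes: each
cause has signature items endorsed with probability `p_sig` by its own
deaths and `p_bg` by others; shared background items are pure noise;
per-cause HCE-dependent items make the with/without-HCE conditions
differ; narratives emit per-cause vocabulary words.  With probability
`p_drop` a record is an informant-knowledge dropout — the whole response
vector zeroed and the narrative blanked — emulating interviews with too
little information to support any cause.  Causes are balanced by default:
training is insensitive to training composition because of the uniform
resample, and test composition is controlled by the Dirichlet anyway.

Deliberately **not** emulated: realistic marginal endorsement rates and
inter-item correlation of real instruments, site effects, recall bias,
age/sex-dependent symptom profiles, and cross-cause symptom overlap
beyond a single background rate.  Passing tests on generator output
therefore demonstrate the *mechanics* of the pipeline (recovery of
planted signatures, correct thresholds and conservation, metric
behavior), not field performance on real verbal autopsies, which can only
be established against a gold-standard database.

Default study conditions used by the end-to-end checks: 5 causes, 8
signature items per cause, 10 background items, 2 HCE items per cause,
`p_sig = 0.9`, `p_bg = 0.05`, `p_drop = 0.05`, 200 deaths per cause, and
50 validation splits — sizes chosen so the full pipeline (including the
500-replicate bootstrap per split) runs in seconds on one CPU while
leaving enough sampling noise to exercise the significance filter.

## Design choices where the design was open

- **Missing responses** are coded as non-endorsement (0); refusals and
  "don't know" are not distinguishable in the supported input format.
- **The no-HCE condition** drops free-text items as well as
  HCE-dependent questions (symptom and risk-behavior question items
  only); `strip_hce(..., keep_text=True)` keeps text for sensitivity
  analyses.
- **Filter order**: significance before top-40, so insignificant
  high-magnitude tariffs cannot occupy top-40 slots.
- **Rank pools are per cause** (every uniformly resampled death scored
  against that cause), consistent with the goal of making scores for
  different causes comparable, rather than one pooled ranking.
- **Text frequency threshold** counts total corpus occurrences pooled
  across sites, not document frequency.
- **Stem conflation**: Porter maps "injuries"/"injury" to `injuri` but
  "injured" to `injur`; stems differing only by a trailing `i` are merged
  onto the with-i form so such families form one item.  Tokens shorter
  than 3 characters are dropped as noise.
- **Indeterminate redistribution weights** combine by arithmetic mean and
  renormalize; with no external weight file a flat vector is used, so
  redistribution is still conservative in tests.

## Known limitations

- Individual-level output is a single cause or indeterminate; no
  per-individual cause probabilities (by design — indeterminates are
  reallocated only at the population level).
- Narrative processing is English-only and single-word; translation and
  phrase detection are out of scope.
- The bootstrap treats items independently within a replicate; it does
  not model inter-item correlation.
- The rank-threshold calibration interacts with cause-list length (see
  above); users analyzing short cause lists should re-examine
  `rank_quantile`.
- External weights and restriction rules ship only as illustrative
  examples; operational use requires locally appropriate files.
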