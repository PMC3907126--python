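# Methods

## Scoring model

An instrument is an ordered bank of Likert items on a 4-category duration
scale with forward scores 0–3. Reverse-phrased items score `3 − forward`,
the only mapping under which a higher total always means more of the trait.
The bundled RAADS-14 definition carries the published item order and text,
the single reverse flag on item 6, the 7/4/3 subscale partition
(mentalizing deficits / social anxiety / sensory reactivity), the 14-point
total cut-off and the 4-point short-form (items 1–5) cut-off.

**Missing answers.** Records with more than 4 missing items are invalid.
For retained records a missing item scores 0 — deterministic and
conservative (it can only lower a total, never manufacture a positive
screen) — and `n_missing` is always reported. Prorating
(`total × k / n_answered`) is available as an explicit option, never the
default, because it fabricates fractional item scores.

**Straight-lining.** A record whose answered items (at least two of them)
all carry one category is invalid whenever the instrument contains a
reverse-phrased item: no coherent respondent endorses both an ability and
its absence identically. Missing answers are ignored by the check; the
comparison runs on forward scores so a mixed label/numeric dialect cannot
mask the pattern. Instruments without reversed items never flag it, since
uniform answering is then indistinguishable from a genuine extreme
respondent.

## Statistical kernel

All rank statistics use mid-ranks; the data are small-range integers, so
ties dominate and tie handling is the difference between exact and
approximate identities.

- **Mann–Whitney U.** `U` is reported as min(U₁, U₂), the convention of
  the major statistics packages; the case-loss-oriented statistic
  (`u_case_loss`, pairs where the case scores below the control, ties
  counted half) is retained separately because it is the one linked to the
  ROC area by `AUC = 1 − U/(n₁n₂)` without restriction. The normal deviate
  uses the tie-corrected variance and no continuity correction; *z* is
  oriented negative when cases score higher, and p-values are two-sided.
  Effect size is *r = |z|/√N* with the usual 0.1/0.3/0.5 benchmarks.
- **ROC.** One operating point per distinct score under the rule
  "score ≥ t ⇒ positive"; AUC by trapezoidal integration, which under
  mid-rank tie handling equals the U-based AUC to machine precision — this
  identity is asserted property-wise in the tests rather than assumed.
- **Cut-off selection.** Sensitivity is non-increasing in the threshold, so
  thresholds keeping sensitivity ≥ 93% form an interval down to the minimum
  score. The selector returns the *highest* qualifying integer threshold:
  "the lowest score still counted positive" is the score value labelling
  the positive class, and any lower threshold only sacrifices specificity.
  The other endpoint is available via `rule="lowest"`. Verified against
  exhaustive search on every random test instance.
- **Reliability.** Cronbach's α from sample variances (ddof = 1); corrected
  item-total correlation of an item is its Pearson correlation with the sum
  of the remaining items (of its scale or domain).
- **Discrimination index.** Point-biserial correlation of the item with the
  case indicator × the corrected item-total correlation within the item's
  domain. Zero-variance items are undefined and flagged, never silently
  ranked.
- **Factor analysis.** Iterated principal-axis factoring: squared multiple
  correlations start the communalities; each iteration eigendecomposes the
  reduced correlation matrix and updates communalities from the leading
  loadings (max 100 iterations, tolerance 1e-6, communalities clipped to
  0.999 to avoid Heywood blow-ups). The automatic factor count is the
  number of reduced-matrix eigenvalues at or above their mean — a stand-in
  for the scree judgment, and deliberately overridable since the published
  three-factor solution was a visual choice. Varimax rotation by default;
  the unrotated loadings are always retained. `variance_explained` is
  λᵢ/k. Singular correlation matrices and zero-variance items raise a
  degenerate-data error rather than returning noise.

## Item-reduction pipeline

Phase 1 ranks items by discrimination index *within* each original-scale
domain and keeps fixed per-domain quotas (bundled default 4/2/8/4 = 18,
proportional to the source scale), preserving content coverage while
maximizing case/control separation. Phase 2 computes per-item AUC (cases vs
the remaining psychiatric records — the clinically hard discrimination) and
drops the `n_drop = 4` lowest. Survivors are re-ordered: the five highest-AUC
items lead (enabling the short form), and the remainder is interleaved
across subscales by always picking from the largest remaining subscale that
differs from the previous pick — deterministic, and adjacency-free whenever
feasible. Every tie anywhere in the pipeline resolves by ascending item id,
and each stage logs its full ranking table so any step can be re-checked.
The published 80→18 selection itself is not reproducible (the source data
are unpublished); the pipeline is validated on synthetic banks with planted
informative and null items.

Phase 3 (`evaluate_final`) assembles per-group summaries (n, mean, SD,
median, range over valid records), Mann–Whitney comparisons and ROC curves
against the case group, operating points at both cut-offs, α per group and
subscale, and the factor solution computed with the case group *excluded*:
with cases included their uniform endorsement swamps the correlation matrix
and a single factor emerges, which is itself reproduced by the generator.

## Synthetic cohorts

Each subject draws a general factor G and three subscale deviations
correlated ρ (default 0.5); item *i* of subscale *s* sees the latent value
`θ = μ_g + σ_g (√(1−v) G + √v D_s)` with loading share v (default 0.4), and
emits a 0–3 score through a cumulative-logit graded-response model with
discrimination aᵢ (1.8 for the short-form items, 1.3 otherwise) and three
ordered thresholds spread across items. The emitted category is the one
whose forward score equals the model score (complemented for reversed
items), so instrument scoring recovers the model exactly; threshold spacing
governs how often the two intermediate duration categories occur. Skew is a
consequence of trait location against the bounded score range, not a
transform: the case group sits near the ceiling (left skew), controls near
the floor (right skew). Contamination is applied last: straight-liners
(default 3%, one uniformly chosen category) and per-item missingness
(default 1%).

**Calibration.** Group trait parameters (μ_g, σ_g) are fitted to the
published total-score moments by a deterministic coarse-grid search
(μ ∈ [−3.5, 3.5] × σ ∈ [0.3, 2.4]) followed by local refinement, scoring
candidates with common random numbers (5,000 subjects coarse, 20,000
refined) under a fixed internal seed, minimizing squared (mean, SD) error.
The procedure is independent of user-facing seeds and cached per process
(~15 s once). The calibrated defaults hit all four group means and SDs
within 1.0 point and reproduce the skew directions and the
ASD > ADHD > OPD > non-psychiatric ordering.

**What the generator does not emulate.** Real item-level response
distributions, item-specific differential functioning between diagnostic
groups, demographic effects (age, the reported sex difference in sensory
reactivity), and informative missingness are all absent; contamination is
independent of the trait. Passing tests therefore demonstrate the
*analyses* behave correctly on data with the published group structure, not
that the generator matches real RAADS-14 item parameters. One visible
consequence: at the published case-group moments the left-skewed
graded-response shape puts ~95% of cases at or above the 14-point cut-off,
whereas a discretized normal at the same moments gives ~98%, bracketing the
published 97% sensitivity; the sensitivity checks use the distributional
assumption appropriate to each claim. Degenerate profiles behave as the
latent model dictates: an extremely low trait pins totals to 0 (the
reverse-phrased item is *endorsed* by trait-free respondents and scores 0),
an extremely high trait pins them to 42.

## Problem sizes and numerics

Default test-bed sizes: 2,000 per group for calibrated-cohort checks, 3,000
for factor recovery, 10,000 for sensitivity fractions, 20 replicates for the
pruning-recovery rate — sizes at which the sampling error of each checked
quantity is several times smaller than its test tolerance. Planted-structure
factor recovery is checked at loading 0.7 (clean orthogonal factors) and,
for the generator path, loading share 0.7 with ρ = 0.15, where the block
structure dominates the general trait; Tucker congruence ≥ 0.9 per factor is
the acceptance line in both. Display rounding is 2 decimals for
rates/AUC/r and 1 for means/SDs; machine-readable outputs keep full
precision, and report rendering is a pure function of the serialized
document so re-rendering is byte-stable.
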