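# Methods

This note records the models implemented in `hespat`, the numerical
conventions adopted where the standard formulations are silent, and
what the synthetic benchmark does and does not establish.

## Data model

The unit of analysis is a **decision matrix** `G = (g_ij)`: `m ≥ 2`
countries (alternatives) scored on `n ≥ 1` indicators (criteria), every
cell present and inside declared bounds (default 0–100, the GHSI
convention; configurable, since neither the entropy nor the CoCoSo
algebra needs them). Missing values are rejected, never imputed: the
assessments this pipeline targets publish complete matrices, and
imputation would manufacture data. Row and column order are preserved
through every stage, and all outputs carry country/indicator names.

## Entropy weighting

Weights are objective functions of the data’s dispersion:

* shares `n_ij = g_ij / Σ_i g_ij` (requires nonnegative scores and a
  positive column sum — negative scores are rejected rather than
  shifted, since the share construction presumes nonnegative ratings);
* entropy `Ent_j = −(1/ln m) Σ_i n_ij ln n_ij` with the standard
  information-theoretic convention `0·ln 0 ≡ 0` and the natural
  logarithm throughout; `Ent_j ∈ [0, 1]`, floating-point excursions
  clipped at the boundaries;
* weights `W_j = (1 − Ent_j)/Σ_j(1 − Ent_j)`; a constant column has
  `Ent_j = 1` and receives weight exactly 0.

A matrix whose columns are *all* constant admits no objective weighting
and raises an error; `EntropyWeighter(uniform_fallback=True)` opts into
uniform weights for robustness studies. Key invariants (tested):
column-scale invariance (the share construction cancels any positive
per-column factor), permutation equivariance in both axes, and strict
entropy decrease as a two-country column concentrates away from
(0.5, 0.5).

## CoCoSo ranking

Scores are min-max normalized per column, `(g − g⁻)/(g⁺ − g⁻)` for
benefit criteria and the flipped form for cost criteria. All six GHSI
pillars are treated as benefit criteria by default (the index scores
every pillar so that higher is better, including Risk Environment);
orientation is configurable per indicator. A constant column
normalizes to all zeros by convention — in this pipeline it carries
entropy weight 0, so the convention cannot move the result; a warning
is logged for standalone use.

From normalized values and weights:

* `CS_i = Σ_j w_j n_ij ∈ [0, 1]` and `P_i = Σ_j n_ij^{w_j} ∈ [0, n]`,
  with `0^w ≡ 0` for `w > 0` and zero-weight columns contributing 1
  (the `w → 0` limit);
* `k_a` (share of `P + CS`), `k_b = CS/min CS + P/min P` (both ratios
  are ≥ 1 at every row, so `k_b ≥ 2`), and
  `k_c = (λ·CS + (1−λ)·P)/(λ·max CS + (1−λ)·max P)` with balance
  coefficient `λ ∈ [0, 1]`, default 0.5 (parity between the additive
  and multiplicative views; `λ = 0`/`λ = 1` reduce `k_c` to
  `P/max P`/`CS/max CS`);
* `C_i = (k_a k_b k_c)^{1/3} + (k_a + k_b + k_c)/3`, ranked descending
  with competition ranking on ties (ties are reported; real assessment
  tables rarely contain them).

**Degenerate minimum.** A country at the column minimum of every
criterion has `CS_i = 0`, making `k_b` undefined. This is surfaced as a
hard error naming the offending row rather than silently regularized;
`CocosoRanker(eps=...)` offers an explicit epsilon shift of the
normalized values for callers who want it (off by default — no
regularization is applied unless requested). The single-criterion case
always trips this, which is why the cross-method reduction test covers
CoCoSo separately.

Tested invariants: positive affine maps of benefit columns leave the
normalized matrix, `C_i`, and all ranks unchanged; elementwise
dominance forces a strictly better `CS` and weakly better `P`, hence a
better rank.

## Comparator methods

The cross-validation re-ranks the same weighted matrix with four
further MCDM methods in their canonical published forms (the variants
are configuration-visible so alternates can be tested): TOPSIS with
vector normalization and closeness `d⁻/(d⁺ + d⁻)`; EDAS with
positive/negative distances from the column-average solution; WASPAS
with linear max normalization and joint coefficient `λ_w = 0.5`; VIKOR
with min-max S/R/Q, `v = 0.5`, ranked by ascending Q (compromise-set
conditions out of scope). VIKOR’s rank orientation is harmonized at
the `MethodRanking` boundary so rank 1 is best for every method.
Agreement is Spearman’s rho with average-rank tie correction, averaged
arithmetically across assessment periods. Because published studies
rarely state their comparator variants exactly, agreement grids are
expected to reproduce published values closely (±0.02) but not
digit-for-digit under these defaults.

## Tier clustering

K-means on the 1-D composite-score vector (multi-dimensional feature
matrices are supported but not the default), objective
`J = Σ_k Σ_{i∈L_k} ‖X_i − μ_k‖²`. The Lloyd iterations are delegated to
scikit-learn’s `KMeans` with `init="random"` (centroids sampled from
the data points), `n_init = 50` restarts keeping the lowest-WCSS
solution, `max_iter = 300`, tolerance 1e-10, and a fixed seed
(default 0). On one-dimensional data with tens of points this reliably
attains the global optimum: the test suite checks it against an
exhaustive search over all contiguous partitions of the sorted scores
(for 1-D data the optimal clusters are always contiguous), for
hundreds of random instances with `m ≤ 12`, `k ≤ 3`.

Clusters are relabelled by descending centroid into tiers, tier 1 =
highest; with `k = 3` the labels High / Intermediate / Dangerous are
attached. The elbow diagnostic reports the best WCSS for `k = 1..k_max`
and recommends the `k` with the largest second difference (maximum
curvature), flagging a weak elbow when the curvature profile is flat —
the final choice of `k` remains the analyst’s.

## Shift analysis

Two sign conventions coexist deliberately, matching how such results
are conventionally reported: indicator-weight shifts are *later −
earlier* (positive = the indicator gained discriminating power), while
country rank/tier shifts are *earlier − later* (positive = the country
improved, because smaller ranks are better). Both conventions are
carried on every `ShiftTable`. Shifts are always computed from
unrounded weights/ranks; differencing independently rounded published
values can disagree with published shift tables in the last digit,
which is why reproduction tolerances of ±0.002 are used there.
Improvement summaries partition countries by shift sign and report
percentages to 2 decimals. Aggregated multi-year matrices (e.g. a
2017–2021 average) are treated as just another input period; their
construction is the data supplier’s concern.

## Synthetic benchmark

`generate_matrix` draws
`score(i,j) = clip(base_mean_j + tier_offset(i) + dispersion_j·noise_sd_j·z_ij, bounds)`
with standard normal `z` from a single seeded generator. The default
(`eu_like_spec`) mirrors the EU-27 scale: 27 countries, six pillars,
tiers of 11/12/4 countries at offsets +15/0/−20, noise sd 5 with
dispersion multipliers (4, 2, 1, 1, 0.5, 0.5), and base means
(55, 50, 45, 55, 65, 75) chosen as GHSI-like pillar levels. Gaussian
noise with clipping was chosen for simplicity; the clip fraction is
returned with the ground truth and stays below 1% under the defaults,
because heavy clipping would distort the planted dispersion ordering.
Panels reuse one country set with per-period seeds derived as
`seed + p`, and optional per-period tier-offset drift makes cross-period
rank/tier shifts known by construction (drifted offsets may reorder
tiers — tier identity is fixed by the base spec).

Two recovery properties are tested statistically over 200 seeds, each
under conditions that satisfy its premise:

* **Weight-order recovery** uses equal base means. Entropy weights
  respond to column *share concentration* (a coefficient-of-variation-
  like quantity), not raw variance, so unequal means confound the
  planted dispersion ordering; equalizing means isolates the mechanism
  the property is about. Under the default unequal means the argmax
  recovery rate drops to roughly 92%.
* **Tier recovery** uses uniform dispersion multipliers so that the
  planted offsets exceed three times the within-tier composite-score
  spread (median ratio ≈ 5), the separation regime in which the
  property is stated; k-means then recovers the planted tiers with
  adjusted Rand index ≥ 0.9 in well over 95% of seeds.

What passing these tests shows: the pipeline recovers planted
dispersion and tier structure from bounded, Gaussian-noised,
independent-column data at the study’s scale. What it does not show:
robustness to the inter-indicator correlation, skew, and bounded-tail
effects of real GHSI scores, which the generator deliberately does not
model.

## Published-value regression anchors

`hespat.reference` carries the published EU-27 results (composite
indices, ranks, tiers, regional weights, shift and agreement tables)
at their printed 3-decimal precision. The always-runnable checks
re-derive what is derivable from print alone: ranks from composite
scores, tiers from k-means on composite scores, improvement counts
from rank columns, the composite aggregation from published appraisal
triples (tolerance ±0.005, since the inputs are rounded at 3 dp), and
the entropy/weight chain from the published per-column share-entropy
sums. Full reproduction of weights, composites, and agreement from raw
decision matrices requires the externally distributed supplementary
workbook (see README, “Obtaining the study data”); those tests fail
with a pointer when the converted CSVs are absent.

## Problem sizes

Default test and acceptance runs use the study-scale 27×6 matrices,
1,000 small random matrices for the entropy invariants, 200 random
1-D instances for the clustering oracle, and 200 seeds for the
synthetic recovery rates — sizes at which every stage’s global
behaviour (including best-of-50-restart clustering) is exercised in a
few seconds.

## Known limitations

* Entropy weighting is dispersion-driven: an indicator uniformly poor
  across countries gets a *low* weight even if substantively critical.
  This is a property of the method, not a defect of the implementation.
* CoCoSo’s `k_b` is undefined when some alternative is worst on every
  criterion; the epsilon shift changes ranks only in that degenerate
  neighbourhood but is still a modelling choice the caller must own.
* Comparator variants (normalization families, VIKOR `v`, WASPAS
  `λ_w`) materially affect third-decimal agreement values.
* The elbow recommendation is a heuristic on second differences; flat
  WCSS curves yield arbitrary recommendations and are flagged as weak.
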