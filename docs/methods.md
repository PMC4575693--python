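# Methods

## Data model

A projection table stores one status per ordered pair of distinct
cortical areas: `unknown`, `absent`, or present with ordinal density
`sparse`/`intermediate`/`dense` (TSV cell codes `NA/0/1/2/3`).  The
distinction between *absent* (examined, explicitly reported
unconnected) and *unknown* (never examined) is load-bearing: relative
frequencies, the discriminant's normalized grid, and the robustness
scan all condition on examination status.  Pairs missing from a file
are unknown; self-projections are outside the model.  Most analyses run
on a *binarized* view in which the three densities collapse to
`present`, so that projection frequencies can be normalized across
variables without per-density stratification.

The parcellation is an ordered list of named areas plus a symmetric
border-adjacency graph.  A published list of corrections to the cat
adjacency matrix (reconciling it with the printed parcellation map)
ships as `data.CAT_ADJACENCY_EDITS` and is applied with idempotent
semantics: removing a missing edge or adding an existing one warns
rather than fails.

## Anatomical variables

* `delta_dist(a, b)`: unweighted shortest-path length between the two
  areas in the adjacency graph (breadth-first search; only lengths are
  used, so tie-breaking among equal-length paths is irrelevant).
  Disconnected pairs get a missing value and a logged warning.
* `delta_type = type(source) − type(target)`, antisymmetric; missing if
  either area is untyped.
* `delta_level = level(source) − level(target)` in a *named* hierarchy
  supplied as input (hierarchies are data, never derived here — deriving
  them from projection directions and then correlating with directions
  would be circular).

Pairs lacking an attribute are excluded per-analysis, not globally, so
the nested subsets (all examined pairs ⊃ pairs with distance and type ⊃
pairs additionally with level) fall out naturally.

## Ordinal statistics

All variables are ordinal, so the toolbox is rank-based: Spearman's ρ,
Wilcoxon rank-sum (W, with standardized z), Kruskal–Wallis H with
Bonferroni-corrected pairwise post hocs, and Jonckheere–Terpstra (JT)
for ordered-trend alternatives.  Conventions, chosen once:

* Ties take average ranks everywhere; W and H use the tie-corrected
  variance; JT counts ties as one half and uses the no-tie variance — a
  documented limitation, acceptable because the JT inputs here (range
  proportions, module types) have modest tie mass.
* Two-tailed α = 0.05 throughout.  The Bonferroni denominator is an
  explicit parameter (default: the number of pairwise comparisons),
  since conventions differ on the size of the test family.
* For pooled samples of at most 8 observations, all four tests return
  exact permutation p-values (complete enumeration); the t/normal/
  chi-square approximations are used above that.  This matters because
  the relative-frequency profiles correlated against their variable
  values have only 5–10 entries.
* JT's z is signed by the observed trend in the caller-supplied group
  order; the `alternative` argument records the tested direction.

## The discriminant model

Predictors are `abs_type` ∈ {0..4} and `delta_dist` ∈ {1..max}.  The
parcellation makes predictor combinations unequally available, so per
cell (a, d) the observed absent/present counts are divided by
`n_possible`, the number of ordered typed pairs with that combination
(counted from the parcellation alone, regardless of examination), giving
percentages `pct_absent` and `pct_present` whose sum is below 100 — the
remainder is unexamined.  Each cell then contributes
`round(pct_absent)` absent and `round(pct_present)` present cases
(round half up; the rounding rule is a package choice, as percentages
are rarely integers).  `n_possible` counts *ordered* pairs, matching the
directed projection table; the model itself is symmetric in direction.

The discriminant assumes two Gaussian classes with a shared covariance
and uniform priors.  The pooled covariance is the bias-corrected
within-class estimator (denominator N − 2); if numerically singular, a
ridge of 1e−8 × trace is added once, and failure after that raises with
the condition number.  The posterior is the exact two-Gaussian Bayes
posterior, `logistic(wᵀx + b)`; tests verify it pointwise against the
closed form in 1-D and against an independent reference implementation
in 2-D.  Standardized coefficients are reported as magnitudes
|w_j| · s_j (s_j the pooled within-class SD), making the two predictors'
contributions comparable.

Cross-validation draws the 10% holdout over *constructed cases* (cases
are the unit the model is fitted on; holding out grid cells instead
would test a different question), refits, classifies held-out cases at
each θ ∈ {0.60, 0.65, ..., 0.90}, excludes unclassified cases from the
accuracies, and averages over 200 cycles.  Cycles whose training set
loses a class are redrawn (counted, capped at 1,000).  Unexamined pairs
with a defined predictor pair receive a posterior and a decision per
threshold; pairs with an undefined predictor stay unpredicted.

## Topology and laminar analyses

Degree = in-degree + out-degree over present projections; weighted
degree substitutes 10⁰/10¹/10² for sparse/intermediate/dense,
approximating the orders-of-magnitude spread of real projection
strengths.  Connection range uses the proportions of an area's present
projections at distance 1–2 (short) and 4–5 (long); distance ≥ 6
projections belong to neither bin and are counted in the log.
Degree–type correlations are restricted to typed areas, with an
optional exclusion set (e.g. the hub areas) to test whether the
rich-club alone drives an association.

The undersampling robustness scan augments each area's degree by
q × (its number of unknown pairs) for q on a grid (default 0..1 step
0.01) and recomputes the degree–type correlation; fractional augmented
degrees are kept as-is, since q·n_unknown is an expectation.  Unknown
pairs are counted over ordered pairs within the typed-area set.

Projection directions are coded ascending = 1, lateral = 2,
descending = 3; with this coding the direction correlates positively
with Δ_level (descending projections run down the hierarchy) and
negatively with Δ_type.  Reversing the coding exactly negates every ρ
(tested).  Directions flagged unreliable are included by default and
excludable by flag; exclusion should change n, not signs.

## Synthetic generator

The generator emulates the statistical structure the analyses assume,
at the scale of a whole-cortex collation.  Defaults:

| parameter | default | meaning |
|---|---|---|
| n_areas | 64 | areas in the parcellation |
| adjacency_model | random-geometric | unit-square geometric graph; `grid` also available |
| radius | 0.30 | geometric connection radius; yields graph diameter ≈ 5, so border distances span ≈ 1–6 as in a compact cortical sheet |
| type_field_smoothness | 0.18 | Gaussian correlation length of the type field; short, so the differentiation gradient repeats across the sheet and |Δ_type| stays near-independent of distance |
| beta0, beta_dist, beta_type | 2.0, 0.6, 0.8 | existence model: P(present) = logistic(β₀ − β_d·Δ_dist − β_t·|Δ_type|) |
| unknown_rate | 0.67 | fraction of ordered pairs masked unknown, missing completely at random |
| strength_decay | 0.5 | dense projections disfavored with distance |
| hierarchy_noise | 0.5 | SD of the level noise around 2(6 − type) − 1 |
| direction_flip_rate | 0.10 | chance a direction label is re-drawn at random |

Types are quantile-quantized from the smooth field with skewed cut
points (40/25/17/11/7% for types 1..5): under a pure |Δ_type| existence
model a symmetric type distribution would make expected degree an
inverted-U in type, whereas the skew (low-differentiation areas
predominating, as they do outside the primary sensory cores) produces
the negative degree–type coupling the analyses probe.  Hierarchy levels
exist on the module-like subset with the most typed areas; directions
derive from level differences with flip noise, so the direction–type
correlation emerges indirectly through the level–type coupling.  Hubs
are the top-degree typed areas (11 of 64, scaled).  Everything is driven
by one seeded generator; equal seeds give byte-identical output.

The shipped stand-in collation (`synth.synthetic_collation`) uses
n_areas = 65 with 16 untyped areas and raises the intercept to
β₀ = 3.9 = logit(0.77) + β_d·E[d] + β_t·E[|Δt|], so that ≈77% of
examined pairs are present, the proportion characteristic of real
collations (which rarely probe for absences).

**What the generator does not emulate** — and hence what passing tests
do not show about real data: no geometric embedding realism (no sulci,
no Euclidean coordinates, no unequal area sizes distorting border
distance); the unknown mask is independent of status, whereas real
examination effort is biased toward expected-present pairs (only the
robustness scan addresses sampling bias); no direction-asymmetric
connectivity; type assignment noise and inter-collator disagreement are
absent; module labels are spatial quadrants, not connectivity-derived
communities, so module-type gradients in the synthetic data are
incidental rather than structured.

## Problem sizes and stochastic-test calibration

The test suite and the acceptance script run the full pipeline at the
collation scale (65 areas, ≈4,200 ordered pairs) and batches of 20
default-sized (64-area) generator draws; 200 cross-validation cycles
complete in seconds.  Exhaustive-oracle checks enumerate all connected
graphs on 5 nodes, random graphs to 8 nodes, and all rank-test inputs
over small value alphabets with ≤ 8 observations.

Two stochastic recovery checks deserve candor.  Strict monotonicity of
the relative-frequency profile across *all* distance classes (Spearman
exactly −1) is fragile in the thinnest top distance class: with two
thirds of pairs masked, a geometric parcellation leaves only tens of
examined pairs at the largest distances, and binomial noise there
produces occasional inversions or ties; the measured per-seed rate is
about 70% for distance (the |Δ_type| profile, whose classes are better
populated, sits near 90–95%).  Likewise, with a spatially smooth type
field both type and degree are functions of position, which shrinks the
effective sample of the null degree–type correlation test and inflates
its false-positive rate above the nominal 5%.  Both effects are
properties of the stated study conditions, not of the estimators; the
corresponding acceptance assertions are kept strict rather than widened
to fit.  The discriminant-orientation recovery check compares the
*median* fitted weight ratio across seeds against β_t/β_d, because the
per-seed ratio has sampling noise wider than the 20% band even for an
exact logistic-regression oracle on the raw pairs.

## Known limitations

* The shipped collation is synthetic; per-pair values match no
  published dataset, and analyses whose targets are facts about the
  real cat collation (specific counts, specific correlation magnitudes)
  cannot be reproduced from it.
* JT uses the no-tie variance; with heavy ties its z is conservative or
  anticonservative depending on configuration.
* The discriminant is fitted to rounded percentage cases; cells with
  percentages below 0.5 contribute nothing, slightly down-weighting the
  sparsest predictor combinations.
* `q_max_significant` in the robustness scan is the largest significant
  q on the grid, which need not bound a contiguous significant range if
  the correlation is non-monotone in q.
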