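# Methods

## Model

`mamfis` builds Mamdani-type fuzzy rule-based classifiers.  A model is a
set of fuzzy variables (each a family of triangular/trapezoidal membership
functions over the variable's observed range) and a list of IF–THEN rules
over those sets.  Inference is the classical min/max pipeline: membership
degrees of the crisp inputs, rule firing strength = weight × min over
antecedent degrees (max for OR rules), implication = min-clipping of each
rule's consequent set, aggregation = pointwise max across rules, and
centroid defuzzification of the aggregate.  The crisp output is decoded to
a class by taking the output set with maximal membership at the defuzzified
value (ties toward the lower set index).

The modelling assumptions are those of any per-variable fuzzification
scheme: class structure is expressible as axis-aligned value bands, and
interactions between variables are captured only through rule
*combinations* of per-variable sets, not through oblique decision
boundaries.  Variables whose information lies in linear combinations of
features will be represented poorly.

## Knowledge-base induction

**Fuzzy sets from clusters.**  Each variable is clustered independently in
one dimension — Ward-linkage agglomerative clustering on Euclidean
distances for tables up to 10,000 rows, seeded k-means (10 restarts)
above.  Clusters are relabelled so index order follows ascending cluster
minimum; this canonicalisation is what makes the rest of the pipeline
invariant to the clustering library's arbitrary label order.  Cluster *i*
with observed extrema (mᵢ, Mᵢ) becomes a membership function with plateau
[b, c] = [mᵢ, Mᵢ] (a triangle peaked at b when mᵢ = Mᵢ).  The outer feet
are a gap the clustering itself does not determine; they are placed at the
neighbouring cluster's nearest extreme (aᵢ = Mᵢ₋₁, dᵢ = mᵢ₊₁, with the
first/last foot collapsed onto its own plateau edge).  Adjacent sets then
cross linearly over the inter-cluster gap and the family is a Ruspini
partition (degrees sum to 1 across the range) — the most common convention
for cluster-derived sets, and the one that guarantees the inference engine
full coverage.  Nominal variables bypass distance clustering: every
category code is its own singleton cluster (categories have no metric).
Output (class) columns are always treated this way.

**Rules from unique rows.**  Training rows are mapped to cluster-index
vectors; the sorted unique rows of that table are the rule base.  Rows that
share an antecedent but disagree on the class are *contradictory*; both are
kept by default (they are genuinely distinct observations, and min/max
inference resolves them softly through the aggregate), with a warning and
an optional majority-vote resolution (`resolve_contradictions=True`, ties
toward the lower consequent index).

**Fuzzy-set sizing.**  A variable with *u* distinct values gets *u* sets
when *u* ≤ 20, else round(√u) (half away from zero), never fewer than 2.
Cluster extrema are computed on the training split of each candidate, never
on validation rows.

## Model search

Candidates are (feature subset, per-variable cluster-count vector) pairs.
They are streamed in order of ascending subset size, then ascending total
cluster count, with a seeded shuffle inside each (size, total) stratum, and
the stream is truncated by the iteration budget (default 3000).  Ordering
by total cluster count inside each size keeps the budget on parsimonious
models first: the cheapest two-set-per-variable candidates of *every*
subset are all visited before any more finely partitioned variant, which
is also what makes small-budget structure recovery well-posed.

Two partition schemes are supported.  *Random sampling* draws one seeded
70/30 train/validation split (fractions configurable, optional
stratification) shared by all candidates.  *Cross-validation* partitions
once into k = 10 shuffled folds shared by all candidates; a candidate's
metrics are fold averages and its delivered system is rebuilt on the full
table.  Ranking maximises a configurable metric (accuracy by default);
ties break toward fewer input variables, then fewer rules, then the
earlier iteration, so results are deterministic for a given seed.

## Evaluation

Binary confusion-matrix metrics follow the defining ratios
(ACC = (TP+TN)/N, sensitivity = recall = TP/(TP+FN),
specificity = TN/(TN+FP), precision = TP/(TP+FP), F = harmonic mean of
precision and recall); any 0/0 is reported as 0 with a structured warning
rather than NaN so report tables stay comparable.  Cohen's κ uses the
standard marginal-product chance correction.  AUC is the Mann–Whitney
rank form — the probability that a random positive's crisp output exceeds
a random negative's, ties at half credit — computed from midranks, with the
continuous defuzzified output as the score.  The verbal AUC bands are
lower-inclusive (≥ 0.9 excellent, 0.8–0.9 good, 0.7–0.8 fair, 0.6–0.7
poor, 0.5–0.6 failure, < 0.5 flagged worse-than-chance).  The positive
class defaults to the higher class code.

## Numerical choices

* **Output grid.**  1001 evenly spaced points per output range
  (configurable).  The centroid integrals treat the sampled aggregate as
  piecewise linear and integrate each segment in closed form, so the only
  error is the grid discretisation of the aggregate's shape, not an extra
  quadrature error; symmetric aggregates defuzzify to their centre exactly.
* **Vertical edges.**  A zero-width ramp (a = b or c = d) evaluates to
  degree 1 at the breakpoint (upper semi-continuity), so touching sets from
  adjacent integer-code clusters never open a measure-zero coverage gap.
* **Out-of-range inputs** are clamped to the variable's training range —
  validation rows routinely exceed it.
* **No rule fired.**  If an input yields an identically-zero aggregate the
  engine returns the output-range midpoint, flags the row, and counts it in
  `system.diagnostics`; batch evaluation never aborts.
* **Maximum-finding** for som/mom/lom uses a 1e-12 tolerance on the peak.
* **k-means seeding** derives from the run seed; Ward is deterministic.

## Synthetic data

The generator plants axis-aligned class structure so that recovery is
measurable: each informative feature draws from a class-specific band
(uniform integer codes, or clipped normals for continuous biomarkers),
noise features draw identically for all classes.  With within-band spread
s, the edge-to-edge gap between consecutive class bands is `separation`·s,
so bands are disjoint for any separation > 0; `separation = 0` is treated
as the null case in which all classes share one band (no signal at all) —
note this is deliberately discontinuous at zero, since a "touching bands"
limit would still leak class information through the band means.  Optional
ingredients: multiple sub-bands per class (`clusters_per_feature`), a
`band_leak` fraction of cells drawn from the full range regardless of
class (measurement spillover; it also makes integer features span their
whole code range, as public tumour-grading tables do), `"?"` missing cells
at a configurable rate, and unbalanced class prevalences.  The
`generate_wbcd_like` preset emulates a 699-row cytology table: nine
integer 1–10 features, ~65/35 benign/malignant prevalence, five
informative features, one marker with missing cells, leak 0.08.

What the generator does **not** emulate: correlations between features,
monotone dose–response within a class, heavy-tailed marginals of real
biomarker panels, or label noise.  Passing tests therefore show that the
pipeline recovers axis-aligned band structure under realistic sizes and
noise features — not that it matches any published benchmark accuracy.

Problem sizes used by the test suite were chosen for statistical soundness
at desk scale: structure recovery uses 300-row tables (2 informative + 3
noise features, separation 3, 70/30 split, 200-candidate budget, 5 seeds);
the no-signal leakage guard uses 200-row tables under 10-fold
cross-validation, because selecting the best of 30 candidates on a single
60-row validation split inflates the maximum accuracy by ~2 standard
errors through selection bias alone, which would mask a genuine leak.

## Known limitations

* Sensitivity/specificity/precision/F/AUC are binary-only; multi-class
  tasks degrade to accuracy (and kappa where defined).
* Ward linkage is O(n²) in memory; the automatic switch to k-means above
  10,000 rows changes cluster boundaries slightly.
* Retained contradictory rules pull the aggregate toward both classes;
  heavily overlapping data may classify better with majority resolution.
* The crisp-to-class decoding (argmax membership at the centroid) is one of
  several defensible conventions; with two classes it is equivalent to
  thresholding the crisp output midway between the class codes.
* Greedy Ward cuts are not guaranteed to minimise within-cluster variance
  globally, although for well-separated 1-D data they coincide with the
  exhaustive optimum (property-tested at small n).
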