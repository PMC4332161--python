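# Methods

`connectoclass` implements a complete graph-theoretic classification analysis
of two-group structural-connectome cohorts.  This note documents the models,
conventions and numerical choices the code embodies, and what the synthetic
data generator does and does not emulate.

## Input model and preprocessing

A subject is a weighted, symmetric, nonnegative connectivity matrix with a
zero diagonal — one row/column per cortical region (68 bilateral regions by
default, the Desikan–Killiany parcellation, left-hemisphere block first).
Weights are interpreted as tractography fiber counts, but the pipeline is
deliberately invariant to any strictly increasing rescaling of the raw
weights: the min–max normalization (affine map of the off-diagonal values to
[0, 1]) and the rank-based sparsity threshold together discard all scale
information.

The sparsity threshold retains the strongest fraction *s* (default 0.25) of
**all possible** node pairs — `k = floor(s·n(n−1)/2)` edges, i.e. 569 of the
2278 pairs at n = 68 — so every subject's graph has an identical edge count.
An alternative basis (fraction of *observed nonzero* edges) is available via
`basis="nonzero"`.  Ties at the cutoff weight are resolved deterministically
by (lower node index, lower partner index) after sorting by weight
descending.  Remaining edges are binarized; all metrics operate on the
resulting simple undirected graph.  Constant matrices (no spread to
normalize) raise a `DegenerateMatrixError` rather than silently producing
empty or complete graphs.

## Graph metrics

Nine global metrics form the classifier feature space (fixed order):
assortativity, global flow coefficient, global total flow, global
betweenness, global efficiency, modularity, characteristic path length,
transitivity, small-worldness.  Nodal **degree centrality** (neighbor count)
supports the regional analysis.  Conventions that required a decision:

* **Betweenness** is unnormalized and counts *ordered* source–target pairs,
  the Brain Connectivity Toolbox convention.  For a connected graph the node
  mean then satisfies `mean(BC) = (n−1)(L−1)`, giving values near 50–65 on
  68-node graphs at 25% density.  (Halving to unordered pairs would simply
  scale all values by 0.5.)
* **Flow coefficient** of a node with degree `k ≥ 2` is the fraction of its
  unordered neighbor pairs with no direct edge between them — exactly the
  pairs whose length-two route through the node is a genuine shortest path.
  Counting *all* neighbor pairs would make the coefficient identically 1.
  Nodes with `k < 2` contribute flow 0.  Global total flow is the node mean
  of the open-pair counts.
* **Characteristic path length** averages shortest-path distances over
  reachable ordered pairs; a disconnected graph triggers a warning and
  averages over finite pairs only.  (At 25% density on 68 nodes, graphs are
  essentially always connected.)  Global efficiency uses `1/∞ = 0` and needs
  no such policy.
* **Modularity** is the *mean achieved* Newman modularity over 10 runs of a
  stochastic Louvain optimizer (randomized node order, multi-level
  aggregation), not the best-of-runs optimum — the metric deliberately
  reflects the optimizer's run-to-run variation, which is why it is averaged.
  On all connected graphs with ≤ 6 nodes the optimizer's best-of-restarts
  attains the exhaustively enumerated optimal partition (asserted in the
  test suite).
* **Small-worldness** is `(T/⟨T_null⟩) / (L/⟨L_null⟩)`: the ratio of means
  over 10 independent degree-preserving null graphs (not the mean of
  ratios).  Null graphs come from repeated double-edge swaps (10·|E|
  attempted swaps; degree sequence preserved exactly; graphs admitting no
  valid swap, e.g. stars, are returned unchanged with a warning).
* Metrics undefined for a graph (assortativity with zero degree variance
  over edge ends; transitivity with no connected triplets; modularity of an
  edgeless graph) raise `UndefinedMetricError`; the cohort-level feature
  table records them as NaN with the subject identifiable by row.

Every stochastic operation takes an explicit seed; cohort-level runs derive
independent per-subject streams from one master seed via `SeedSequence`
spawning, so results do not depend on evaluation order.

## Classifier

The classifier is a linear soft-margin SVM with **squared** slack penalties
and per-sample class weights:

    min_{w,b,v}  ½⟨w,w⟩ + Σᵢ Dᵢ vᵢ²    s.t.  yᵢ(⟨w,xᵢ⟩+b) ≥ 1−vᵢ,  vᵢ ≥ 0,

with `Dᵢ = N/(2·N_G(i))`, so each class contributes equal total penalty mass
(Σ over a class = N/2); with 18 controls and 14 patients the weights are
0.889 and 1.143.  The squared-slack loss matters: most library SVMs default
to the L1 hinge and are *not* equivalent.  Because the slack enters squared,
the nonnegativity constraints are inactive at the optimum and the problem
reduces to a smooth strictly convex piecewise quadratic, which the package
minimizes by a finite active-set Newton iteration (deterministic; falls back
to L-BFGS on the smooth objective if the active set cycles, and verifies the
gradient at the solution either way).  Tests cross-check the attained
objective against an independent SLSQP solve of the constrained program.

Performance is estimated by leave-one-out cross-validation: n folds, each
training on n−1 subjects and predicting the held-out one.  Features are
z-scored per fold using training-fold statistics only (the nine metrics
differ by orders of magnitude; an unscaled linear SVM would be dominated by
the largest-scale feature).  Scaling can be disabled (`scale=False`) for
sensitivity analysis.  Accuracy, sensitivity (correct fraction of the −1
patient class) and specificity (+1 control class) are pooled over folds.
Feature importance uses |w| ranks per fold (rank 1 = largest; ties averaged,
though ties are measure-zero in floating point), averaged across folds.

## Subset evaluation and tests

All `2⁹ − 1 = 511` nonempty feature subsets are cross-validated on one shared
fold partition (leave-one-out is deterministic, and z-scoring is
feature-wise, hence mask-independent).  A subset is significant when its
correct-fold count reaches the exact two-sided sign-test threshold at
α = 0.05.  The two-sided p is `2·min(P(X≤k), P(X≥k))` capped at 1 for
X ~ Binomial(n, ½).  At n = 32 the exact p at k = 22 is 0.0501, so the
threshold is 22 correct folds under the default two-decimal rounding policy
and 23 under exact comparison — both policies are first-class because the
boundary differs.  The count of significant subsets is tested two-sided
against Binomial(511, 0.05).  Per-metric aggregation summarizes the 256
subsets containing each metric (mean/SD accuracy, significant count), and a
one-sample t-test compares a metric's 256 accuracies against chance (df =
255; note the subsets share data, so this df treats correlated accuracies as
independent — reproduced as the design specifies, caveat noted).

Group inference uses permutation two-sample two-tailed t-tests: the group
labels are shuffled `n_perm` times (default 100,000) and each shuffle's
pooled-variance t-test p-value is compared with the observed one; the
reported p is the add-one estimator `(#{p_perm ≤ p_obs}+1)/(n_perm+1)`,
which is exactly valid and never zero (the raw proportion is an option, as
is Welch's form).  With fixed group sizes this is equivalent to comparing
|t|.  Multiplicity over the 9 metrics or the 68 regions is controlled with
Benjamini–Hochberg step-up FDR at q = 0.05.  Clinical correlations are
Pearson r with pairwise deletion of missing covariates.

## Synthetic cohorts

No imaging data ship with the package, so the generator is the test bed.  It
emulates what matters for the downstream statistics:

* a shared weighted template — preferential-attachment skeleton at
  `base_density = 0.6` with i.i.d. log-normal edge weights (median 30,
  σ = 1.0) — giving degree heterogeneity and heavy-tailed fiber counts;
* subject-level multiplicative log-normal noise (`sd = 0.3` on the log
  scale), producing the strong inter-subject correlation real connectomes
  show;
* group effects applied to the template *before* subject noise: a nodal
  effect multiplies the patient template's weights incident to one region by
  `1 + direction·size`; a global effect rewires each patient-template edge
  with some probability, perturbing clustering and path structure at a fixed
  edge count;
* covariates drawn uniformly within realistic per-group ranges (patient
  BDI-II 22–43, GAF 35–60, onset 3–26 y, duration 3–39 y; control BDI-II
  0–11, GAF 75–99), uncoupled from topology unless `covariate_coupling` is
  set;
* default cohort sizes 18 controls / 14 patients over 68 nodes.

It does **not** emulate anatomical geometry, hemispheric symmetry of
connections, distance-dependent wiring, or realistic small-world structure
(template graphs have S ≈ 1, versus ≈ 1.5 for real cortical graphs at this
density).  Passing tests therefore demonstrate the *statistical machinery* —
calibration under the null and recovery of planted effects — not that real
depressed and healthy connectomes are separable.

The density/weight parameters are stated modeling assumptions: fiber-count
distributions are not published for the target cohorts, so the template
was fixed once at values a practitioner would call plausible (a dense raw
fiber graph thresholded to 25%; tens of fibers per typical edge).

## Problem sizes in tests and the acceptance script

Simulation-based tests use reduced problem sizes chosen for the precision
they need, not tuned to outcomes: permutation tests run at n_perm = 199–1999
(the default 100,000 is an analysis-time setting); calibration suites use
8–15 replicate cohorts or 200–1000 replicate draws, with acceptance bands
frozen in advance at ≈ 4 binomial standard errors around the expected value.
Two bands encode known biases rather than symmetric chance bands: the null
LOOCV mean-accuracy band is asymmetric (0.33–0.62) because leave-one-out is
mildly pessimistic under the null, and FDR-flag counts allow small nonzero
slack.  `scripts/acceptance.py` regenerates everything from scratch at the
study's cohort conditions with a user-supplied seed (regional permutation
tests at n_perm = 20,000; calibration at 500 replicates).

## Known limitations

* Louvain is a heuristic; on large graphs the averaged Q is a lower bound on
  the optimum (by design, mirrored by the averaging convention).
* Double-edge-swap nulls are not exactly uniform over the degree-sequence
  ensemble; 10·|E| attempted swaps is a standard mixing heuristic
  (configurable via `swap_factor`).
* The permutation test assumes exchangeability under the null; the generator
  satisfies it exactly, real data only approximately.
* LOOCV has high variance at n = 32, and subset accuracies are strongly
  correlated across the 511 subsets; the across-subset binomial test
  inherits that correlation (its null is conservative only in expectation).
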