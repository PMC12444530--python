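# Methods

## Molecular graphs

`enthalpograph.graphs` parses SMILES with RDKit (sanitization on; valence
and element checks raise typed errors) and converts the molecule into an
**explicit-hydrogen simple graph**:

- node order: heavy atoms in SMILES order, then hydrogens appended in
  owner order (all H of atom 0, then of atom 1, …);
- edges are unweighted and undirected; bond order and aromaticity are
  ignored.  A double bond and a single bond both contribute one edge.

This convention is load-bearing: it is the only one under which the
published index values for benzene (Estrada 28.7159, Gutman 570, Wiener
174), heptadecylbenzene (16494 / 60801), nonacosylcyclopentane
(256.1882 / 65003) and pentatriacontylbenzene (292.2678 / 98034 / 374055)
are all reproduced.  Supported elements: H, B, C, N, O, P, S, F, Cl, Br,
I; multi-fragment inputs are rejected.

## Descriptors

All quantities are computed on the explicit-hydrogen graph with adjacency
matrix A and BFS distance matrix D (exact integers; disconnected graphs
raise).

- **Estrada index** EE = Σᵢ exp(λᵢ) over the full adjacency spectrum
  (symmetric eigendecomposition, not a truncated series).
- **Wiener index** W = Σ_{i<j} D_{ij}; **Gutman index**
  Σ_{i<j} D_{ij}·deg(i)·deg(j); both exact integers.
- **Centralities** (molecule level = mean over nodes by default; sum and
  max available): degree; betweenness as unnormalized unordered
  source–target pairs with endpoints excluded (networkx Brandes,
  `normalized=False`), so leaves score 0; closeness as the *unnormalized*
  reciprocal distance sum 1/Σ_t d(v,t) — no (n−1) factor; eigenvector
  centrality as the nonnegative principal eigenvector of A with unit
  Euclidean norm.  The principal eigenvector is taken from an exact
  symmetric eigendecomposition rather than power iteration: long-chain
  molecules have near-degenerate leading eigenvalues and power iteration
  stalls.

## Fixed predictor and fitted models

The fixed three-index predictor is applied with frozen coefficients:

    −Δ_cH° = 90·EE − 1.0789·W + 0.2822·Gutman − 417.6882   [kJ·mol⁻¹]

Fitted estimators, all behind one `spec` dict interface
(`{"kind": ..., ...}`):

- **OLS** via `numpy.linalg.lstsq` with an explicit rank check
  (rank-deficient designs raise rather than silently minimum-norm-solve).
- **Ridge** in closed form on centered data; the intercept is not
  penalized.
- **Huber** via scikit-learn's `HuberRegressor` (same epsilon/alpha
  objective; its solver is more robust than a hand-rolled IRLS).
- **CART / random forest / extra-trees** are implemented here. Splits
  score the weighted mean-squared-error impurity over midpoint candidate
  thresholds; ties resolve to the lowest feature index, then the lowest
  threshold (first strict improvement wins).  Forests draw a per-tree
  seed, then a bootstrap resample (when enabled) and per-node `mtry`
  feature subsampling; extra-trees draw one uniform random threshold per
  sampled feature.  Prediction is the mean over trees; impurity
  importances are normalized to sum 1.  Models serialize to JSON.

## Metrics

MAE, RMSE, MAPE (reported as a fraction; percent view available), RMSLE
(log1p) and R².  Targets are positive magnitudes: a zero target makes
MAPE undefined and a negative target makes RMSLE undefined — both raise a
domain error naming the offending index.  Negative *predictions*, which
unconstrained regressors legitimately emit when extrapolating, are
clamped to 0 inside the RMSLE log term only; MAE/RMSE/MAPE/R² always use
the raw predictions, so cross-validation reports stay defined without
distorting the other metrics.

## Protocols

- **Standardization**: z-score with population standard deviation
  (ddof = 0); constant columns map to 0. Scalers are fitted on training
  rows only and refitted inside every CV fold — no leakage.
- **Hold-out**: `round(fraction·n)` training rows from a seeded
  permutation (n ≥ 10 required).
- **k-fold**: seeded permutation + `array_split`; folds smaller than 2
  rows are an argument error. Fold metrics are reported as mean ± std
  (ddof = 1) per metric, with the per-fold values retained.
- **Random search** draws specs from declared distributions and ranks by
  inner-CV mean RMSE; **nested CV** uses 5 outer × 3 inner folds;
  **learning curves** sweep training fractions (fraction 1.0 coincides
  with plain k-fold).

## Attribution

Monte-Carlo Shapley values (Štrumbelj–Kononenko): each permutation draws
one background row, builds the chain of hybrid instances, batch-predicts
it, and takes telescoping marginals (`np.diff` along the chain).  The
per-feature Monte-Carlo standard error is reported; contributions plus
the background mean prediction reconstruct the instance prediction
exactly in expectation.  For linear models the estimate converges to
βⱼ·(xⱼ − mean background xⱼ), which the tests exploit as a closed-form
oracle.

## Clustering

Index-space features are z-scored by default.  K-Means uses scikit-learn
(k-means++, one init, Lloyd); DBSCAN defaults to eps 0.1 / min_samples 20
in standardized space.  Validity reports mean silhouette and
Davies–Bouldin (noise points excluded); fewer than two effective clusters
raise an "undefined validity" error.  Hand-enumerated fixtures pin both
scores: on `[[0],[1],[10],[11]]` with labels `[0,0,1,1]` every point has
a = 1, the outer points have b = 10.5 and the inner points b = 9.5, so
the mean silhouette is ((1−1/10.5)+(1−1/9.5))/2 ≈ 0.8997 and
Davies–Bouldin is (0.5+0.5)/10 = 0.1.

## Synthetic data

The homologous-series generator covers eleven families (n-alkanes,
1-alkenes, 1-alkynes, n-alkylbenzenes, n-alkylcyclopentanes,
n-alkylcyclohexanes, 1-alkanols, alkanals, alkanoic acids, primary
amines, 1-thiols) with IUPAC stem names from C1 to C40.  Targets are
simulated as

    −Δ_cH° = β₀ + β₁·EE + ε,   ε ~ N(0, σ²)

with defaults β₀ = −417.6882, β₁ = 90, σ = 50 — the intercept and Estrada
coefficient of the fixed predictor, with noise on the order of its
reported residuals.  This is realistic in the sense that matters for the
recovery suites: within a homologous series the enthalpy magnitude is
almost exactly linear in the Estrada index with per-CH₂ increments of
several hundred kJ·mol⁻¹, so σ = 50 gives the same signal-to-noise regime
as the real regressions.  Nonpositive simulated targets are truncated to
1e-6 with a warning (targets are positive magnitudes by definition);
generation parameters are recorded in the frame's `attrs`.  The defaults
are study conditions: they were fixed before the test outcomes and are
not tuned.

## Numerical choices

- Exact integer arithmetic for Wiener/Gutman (int64 distance matrices).
- `scipy.linalg.eigvalsh` / `eigh` for spectra — symmetric-exact, no
  iterative tolerance in the descriptor path.
- Dijkstra/BFS (`scipy.sparse.csgraph.shortest_path`, unweighted) for
  distances; a hand-written Floyd–Warshall is the test oracle only.
- Seeded `numpy.random.default_rng` everywhere; identical seeds give
  bit-identical models, splits, searches and attributions.

## Limitations

- Indices are defined on connected single-fragment molecules only; salts
  and mixtures are rejected.
- The fixed predictor is applied as printed; its provenance (full-set vs
  70 % fit) is not modeled.
- Silhouette/Davies–Bouldin are Euclidean only; DBSCAN validity excludes
  noise, which can flatter sparse clusterings.
- The Huber estimator delegates to scikit-learn; its iteration trace is
  not exposed.
- Monte-Carlo Shapley errors scale as 1/√n_perm; the defaults
  (n_perm = 200) suit molecule-level screening, not tight inference.
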