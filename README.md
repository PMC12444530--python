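# enthalpograph

Predicting the standard combustion enthalpy of organic compounds from the
topology of their molecular graphs.

## The science

The standard combustion enthalpy Δ<sub>c</sub>H° of an organic compound —
reported throughout as the positive magnitude −Δ<sub>c</sub>H° in
kJ·mol⁻¹ — correlates strongly with size- and branching-sensitive
*topological indices* of the molecule's graph.  `enthalpograph` implements
that QSPR (quantitative structure–property relationship) pipeline end to
end:

1. **Graphs.** A SMILES string is parsed into a molecular graph with
   *explicit hydrogens*: heavy atoms in SMILES order, then each atom's
   hydrogens appended in owner order.  Edges are unweighted regardless of
   bond order or aromaticity — that convention is what reproduces the
   published index values (e.g. Gutman 570 and Estrada 28.7159 for
   benzene's 12-node graph).
2. **Descriptors.** Three molecule-level indices — Estrada
   EE = Σᵢ exp(λᵢ) over the adjacency spectrum, Wiener
   W = Σ<sub>i&lt;j</sub> d(i,j), and Gutman
   Σ<sub>i&lt;j</sub> d(i,j)·deg(i)·deg(j) — plus four aggregated node
   centralities (degree, betweenness, closeness, eigenvector).
3. **Models.** A fixed three-index linear predictor
   (−Δ<sub>c</sub>H° = 90·EE − 1.0789·W + 0.2822·Gutman − 417.6882),
   OLS/Ridge/Huber linear regression, and our own CART regression trees,
   random forests and extra-trees.
4. **Protocols.** Hold-out splits, k-fold cross-validation with per-fold
   standardization, random hyper-parameter search, nested CV and learning
   curves; metrics MAE, RMSE, MAPE, RMSLE and R².
5. **Interpretation.** Monte-Carlo Shapley feature attributions,
   impurity importances, and clustering of molecules in index space
   (K-Means, DBSCAN) with silhouette and Davies–Bouldin validity.
6. **Data.** A generator for eleven homologous series (n-alkanes,
   n-alkylbenzenes, alcohols, acids, amines, …) with IUPAC names up to
   C40, and a simulator of enthalpy targets for parameter-recovery
   studies.

## Worked example

Indices and the fixed predictor for heptadecylbenzene:

```python
from enthalpograph import from_smiles, featurize, eq13_predict

g = from_smiles("CCCCCCCCCCCCCCCCCc1ccccc1", name="heptadecylbenzene")
v = featurize(g)
print(f"{v.name}: {g.n} atoms in the explicit-hydrogen graph")
print(f"  Estrada = {v.estrada:.4f}   Wiener = {v.wiener}   Gutman = {v.gutman}")
print(f"  predicted -dcH = {eq13_predict(v.estrada, v.wiener, v.gutman):.1f} kJ/mol")
```

prints

```text
heptadecylbenzene: 63 atoms in the explicit-hydrogen graph
  Estrada = 156.7106   Wiener = 16494   Gutman = 60801
  predicted -dcH = 13048.9 kJ/mol
```

Fitting your own model uses the Model → Results pattern:

```python
from enthalpograph.series import SeriesSpec, series_features, simulate_enthalpy
from enthalpograph.qspr import QSPRModel

feats = simulate_enthalpy(
    series_features([SeriesSpec("n-alkane", 1, 25),
                     SeriesSpec("n-alkylbenzene", 0, 20)]),
    sigma=50.0, seed=7,
)
model = QSPRModel.from_dataframe(feats)
res = model.fit({"kind": "ols"}, test_fraction=0.3, seed=7)
print(res.summary())
```

prints

```text
QSPR results
========================================================
estimator: {'kind': 'ols'}
n = 46, features = ['estrada', 'wiener', 'gutman', 'degree', 'betweenness', 'closeness', 'eigenvector']
hold-out: 32 train / 14 test (seed 7)
--------------------------------------------------------
coefficients (kJ·mol⁻¹ per scaled-feature unit):
         estrada       5604.6724
          wiener       -127.5305
          gutman        827.5740
          degree        -43.6375
     betweenness      -1538.5127
       closeness        -94.7947
     eigenvector        240.7952
       intercept       9225.2254
--------------------------------------------------------
train: mae=28.0903  rmse=34.3955  mape=0.0043  rmsle=0.0060  r2=0.9999
 test: mae=42.3559  rmse=47.9954  mape=0.0075  rmsle=0.0106  r2=0.9999
```

The same pipeline is available on the command line
(`enthalpograph descriptors / fit / evaluate / tune / explain / cluster /
generate`); every JSON output is stamped with the seed, a config hash and
the package version.

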