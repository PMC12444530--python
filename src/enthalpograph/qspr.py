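"""Model/Results facade over the QSPR stack.

`QSPRModel` binds a descriptor table and an enthalpy target;
:meth:`QSPRModel.fit` dispatches to the estimator named in the model spec
and returns a :class:`QSPRResults` carrying the fitted parameters,
hold-out/CV diagnostics, importances and attribution hooks, with a
:meth:`QSPRResults.summary` table.

    >>> model = QSPRModel.from_smiles(["CC", "CCC"], y=[1560.7, 2220.0])
    >>> res = model.fit({"kind": "ols"})
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models as qm
from . import shapley as shap
from .descriptors import FEATURE_COLUMNS, featurize_many
from .graphs import from_smiles
from .metrics import METRIC_NAMES, MetricReport, evaluate
from .selection import (
    CVReport,
    SplitPlan,
    holdout,
    kfold_evaluate,
    make_estimator,
    zscore,
)


class QSPRModel:
    """A combustion-enthalpy QSPR problem: descriptors X plus target y.

    Parameters
    ----------
    X : DataFrame
        Feature table; non-numeric columns (name, smiles) are kept as
        metadata and excluded from the design matrix.
    y : array-like
        Positive magnitudes −Δ_cH° in kJ·mol⁻¹.
    features : sequence of str, optional
        Subset/order of feature columns to use (default: the canonical
        seven descriptor columns that are present).
    scale : bool
        z-score the design matrix inside every fit/protocol (fit on the
        training rows only).  The fixed-coefficient model always sees raw
        features.
    """

    def __init__(self, X: pd.DataFrame, y, features=None, scale: bool = True):
        self.table = X.reset_index(drop=True)
        self.y = np.asarray(y, dtype=float)
        if len(self.table) != self.y.size:
            raise ValueError("X and y lengths differ")
        if features is None:
            features = [c for c in FEATURE_COLUMNS if c in self.table.columns]
            if not features:
                features = [
                    c for c in self.table.columns
                    if pd.api.types.is_numeric_dtype(self.table[c])
                ]
        self.features = list(features)
        self.scale = scale

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_smiles(cls, smiles, y, names=None, aggregation="mean", **kw):
        names = names or [None] * len(smiles)
        graphs = [from_smiles(s, name=n) for s, n in zip(smiles, names)]
        return cls(featurize_many(graphs, aggregation=aggregation), y, **kw)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, target: str = "minus_dcH", **kw):
        y = df[target].to_numpy(dtype=float)
        return cls(df.drop(columns=[target]), y, **kw)

    # -- design matrix ----------------------------------------------------
    @property
    def exog(self) -> np.ndarray:
        return self.table[self.features].to_numpy(dtype=float)

    # -- fitting ----------------------------------------------------------
    def fit(
        self,
        spec: dict | None = None,
        split: SplitPlan | None = None,
        test_fraction: float | None = 0.3,
        seed: int = 42,
    ) -> "QSPRResults":
        """Fit the estimator named by ``spec`` (default random forest).

        A 70/30-style hold-out is drawn unless ``test_fraction`` is None
        (fit on everything) or an explicit ``split`` is given; scaling is
        fitted on the training rows only.
        """
        spec = dict(spec or {"kind": "rf", "n_estimators": 100, "seed": seed})
        n = self.y.size
        if split is None and test_fraction:
            split = holdout(n, fraction=1.0 - test_fraction, seed=seed)
        train = split.train if split else np.arange(n)
        test = split.test if split else np.array([], dtype=int)
        X = self.exog
        scaler = None
        Xtr = X[train]
        if self.scale and spec["kind"] != "fixed":
            scaler = zscore(Xtr)
            Xtr = scaler.apply(Xtr)
        if spec["kind"] == "fixed":
            est = make_estimator(spec).fit(self.table.iloc[train], self.y[train])
        else:
            # keep column names so linear coefficients come back named
            Xtr = pd.DataFrame(Xtr, columns=self.features)
            est = make_estimator(spec).fit(Xtr, self.y[train])
        return QSPRResults(model=self, spec=spec, estimator=est, scaler=scaler,
                           split=split, seed=seed)

    def cross_validate(self, spec: dict, k: int = 10, seed: int = 42) -> CVReport:
        """k-fold CV over the full table (scaling refitted per fold)."""
        X = self.table if spec.get("kind") == "fixed" else self.exog
        return kfold_evaluate(spec, X, self.y, k=k, seed=seed, scale=self.scale)


@dataclass
class QSPRResults:
    """Fitted-model results: parameters, diagnostics, and summary table."""

    model: QSPRModel
    spec: dict
    estimator: object
    scaler: object | None
    split: SplitPlan | None
    seed: int
    _cache: dict = field(default_factory=dict, repr=False)

    # -- prediction -------------------------------------------------------
    def _design(self, table_or_array) -> np.ndarray:
        if hasattr(table_or_array, "loc"):
            X = table_or_array[self.model.features].to_numpy(dtype=float)
        else:
            X = np.asarray(table_or_array, dtype=float)
            X = X[None, :] if X.ndim == 1 else X
        return self.scaler.apply(X) if self.scaler is not None else X

    def predict(self, X=None) -> np.ndarray:
        if self.spec["kind"] == "fixed":
            table = self.model.table if X is None else X
            return self.estimator.predict(table)
        if X is None:
            X = self.model.exog
            X = self.scaler.apply(X) if self.scaler is not None else X
            return self.estimator.predict(X)
        return self.estimator.predict(self._design(X))

    @property
    def params(self) -> pd.Series | None:
        """Named coefficients for linear fits; None for forests."""
        m = self.estimator.model
        if isinstance(m, qm.LinearModel):
            return pd.Series(m.coefficients | {"intercept": m.intercept})
        return None

    @property
    def importances(self) -> pd.Series | None:
        """Impurity importances for forest fits; None otherwise."""
        m = self.estimator.model
        if isinstance(m, qm.ForestModel):
            return pd.Series(qm.impurity_importance(m), index=self.model.features)
        return None

    # -- diagnostics ------------------------------------------------------
    def _subset_metrics(self, idx) -> MetricReport:
        table = self.model.table.iloc[idx]
        y = self.model.y[idx]
        if self.spec["kind"] == "fixed":
            return evaluate(y, self.estimator.predict(table))
        return evaluate(y, self.estimator.predict(self._design(table)))

    def metrics(self, subset: str = "test") -> MetricReport:
        """MetricReport on the hold-out 'test' or 'train' rows."""
        if subset not in self._cache:
            n = self.model.y.size
            if self.split is None:
                idx = np.arange(n)
            else:
                idx = self.split.test if subset == "test" else self.split.train
            if idx.size == 0:
                raise ValueError("no hold-out rows; fit with test_fraction")
            self._cache[subset] = self._subset_metrics(idx)
        return self._cache[subset]

    def shapley(self, instances=None, n_perm: int = 200, seed: int | None = None):
        """Monte-Carlo Shapley attributions against a training background."""
        n = self.model.y.size
        train = self.split.train if self.split else np.arange(n)
        rng = np.random.default_rng(self.seed if seed is None else seed)
        bg_idx = train if train.size <= 200 else np.sort(
            rng.choice(train, size=200, replace=False)
        )
        background = self._design(self.model.table.iloc[bg_idx])
        if instances is None:
            instances = background
        else:
            instances = self._design(instances)
        return shap.attribute_many(
            self.estimator.model.predict if self.spec["kind"] != "fixed"
            else (lambda Z: self.estimator.model.predict(Z)),
            background,
            instances,
            n_perm=n_perm,
            seed=self.seed if seed is None else seed,
            feature_names=self.model.features,
        )

    # -- presentation -----------------------------------------------------
    def summary(self) -> str:
        lines = [
            "QSPR results",
            "=" * 56,
            f"estimator: {self.spec}",
            f"n = {self.model.y.size}, features = {self.model.features}",
        ]
        if self.split is not None:
            lines.append(
                f"hold-out: {len(self.split.train)} train / "
                f"{len(self.split.test)} test (seed {self.split.seed})"
            )
        p = self.params
        if p is not None:
            lines.append("-" * 56)
            lines.append("coefficients (kJ·mol⁻¹ per scaled-feature unit):")
            for k, v in p.items():
                lines.append(f"  {k:>14s}  {v:14.4f}")
        imp = self.importances
        if imp is not None:
            lines.append("-" * 56)
            lines.append("impurity importances (sum 1):")
            for k, v in imp.sort_values(ascending=False).items():
                lines.append(f"  {k:>14s}  {v:10.4f}")
        if self.split is not None and len(self.split.test):
            lines.append("-" * 56)
            for subset in ("train", "test"):
                r = self.metrics(subset)
                lines.append(
                    f"{subset:>5s}: "
                    + "  ".join(f"{m}={getattr(r, m):.4f}" for m in METRIC_NAMES)
                )
        return "\n".join(lines)
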