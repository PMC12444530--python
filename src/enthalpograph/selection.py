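"""Evaluation protocols: scaling, hold-out, k-fold CV, random search,
nested CV and learning curves.

Scalers are always fitted on training rows only, and refitted inside every
fold, so no information leaks from validation or test targets/features into
a fit.  All protocols are deterministic given a seed.  Fold statistics use
the sample standard deviation (ddof = 1).

Model specifications are plain dicts, e.g. ``{"kind": "rf",
"n_estimators": 100, "seed": 0}`` — JSON-friendly so they can travel
through config files and search spaces.  Recognised kinds: ``fixed``,
``ols``, ``ridge``, ``huber``, ``tree``, ``rf``, ``et``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models as qm
from .metrics import METRIC_NAMES, MetricReport, evaluate

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------


@dataclass
class Scaler:
    """Column-wise z-score scaler (population std); constant columns map to 0."""

    mean: np.ndarray
    std: np.ndarray
    constant: np.ndarray

    def apply(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        X = X[None, :] if X.ndim == 1 else X
        safe = np.where(self.constant, 1.0, self.std)
        out = (X - self.mean) / safe
        out[:, self.constant] = 0.0
        return out


def zscore(X) -> Scaler:
    """Fit a z-score scaler on training rows (zero mean, unit std)."""
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    constant = np.isclose(std, 0.0)
    if constant.any():
        logger.warning(
            "constant columns at positions %s mapped to 0", np.flatnonzero(constant)
        )
    return Scaler(mean=mean, std=std, constant=constant)


# ---------------------------------------------------------------------------
# model-spec factory
# ---------------------------------------------------------------------------


class _SpecEstimator:
    """fit/predict wrapper over the model functions, driven by a spec dict."""

    def __init__(self, spec: dict):
        self.spec = dict(spec)
        self.kind = self.spec.pop("kind")
        self.model = None

    def fit(self, X, y):
        s = self.spec
        if self.kind == "fixed":
            self.model = qm.fixed_index_model()
        elif self.kind == "ols":
            self.model = qm.ols_fit(X, y)
        elif self.kind == "ridge":
            self.model = qm.ridge_fit(X, y, alpha=s.get("alpha", 1.0))
        elif self.kind == "huber":
            cfg = qm.HuberConfig(
                epsilon=s.get("epsilon", 1.35),
                alpha=s.get("alpha", 0.0001),
                tol=s.get("tol", 1e-6),
                max_iter=s.get("max_iter", 1000),
            )
            self.model = qm.huber_fit(X, y, cfg)
        elif self.kind == "tree":
            self.model = qm.tree_fit(
                X,
                y,
                max_depth=s.get("max_depth"),
                min_samples_leaf=s.get("min_samples_leaf", 1),
                seed=s.get("seed", 0),
            )
        elif self.kind in ("rf", "et"):
            cfg = qm.ForestConfig(
                kind=self.kind,
                n_estimators=s.get("n_estimators", 100),
                bootstrap=s.get("bootstrap", True),
                mtry=s.get("mtry"),
                min_samples_leaf=s.get("min_samples_leaf", 1),
                max_depth=s.get("max_depth"),
                seed=s.get("seed", 0),
            )
            self.model = qm.forest_fit(X, y, cfg)
        else:
            raise ValueError(f"unknown model kind {self.kind!r}")
        return self

    def predict(self, X) -> np.ndarray:
        if self.kind == "fixed":
            # fixed model expects raw (unscaled) named features
            return self.model.predict(X)
        return self.model.predict(np.asarray(X, dtype=float))


def make_estimator(spec: dict) -> _SpecEstimator:
    return _SpecEstimator(spec)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplitPlan:
    train: np.ndarray
    test: np.ndarray
    fraction: float
    seed: int


def holdout(n: int, fraction: float = 0.7, seed: int = 0) -> SplitPlan:
    """Uniform random permutation split; |train| = round(fraction·n)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if n < 10:
        raise ValueError("need n >= 10 for a meaningful hold-out")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(fraction * n))
    return SplitPlan(
        train=np.sort(perm[:n_train]),
        test=np.sort(perm[n_train:]),
        fraction=fraction,
        seed=seed,
    )


def _kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVReport:
    """Per-fold metric reports with mean ± std (ddof = 1) per metric."""

    folds: list[MetricReport]
    k: int
    seed: int
    meta: dict = field(default_factory=dict)

    def mean(self, metric: str) -> float:
        return float(np.mean([getattr(f, metric) for f in self.folds]))

    def std(self, metric: str) -> float:
        vals = [getattr(f, metric) for f in self.folds]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def as_dict(self) -> dict:
        return {
            m: {
                "mean": self.mean(m),
                "std": self.std(m),
                "folds": [getattr(f, m) for f in self.folds],
            }
            for m in METRIC_NAMES
        } | {"k": self.k, "seed": self.seed, "std_ddof": 1}

    def as_frame(self) -> pd.DataFrame:
        """One row per metric, Table-style (mean, std)."""
        return pd.DataFrame(
            {
                "metric": METRIC_NAMES,
                "mean": [self.mean(m) for m in METRIC_NAMES],
                "std": [self.std(m) for m in METRIC_NAMES],
            }
        )


def _fit_and_score(spec, X, y, train_idx, val_idx, scale):
    Xm = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if spec.get("kind") == "fixed":
        # fixed coefficients are defined on raw index features
        est = make_estimator(spec)
        if hasattr(X, "loc"):
            est.fit(X.iloc[train_idx], y[train_idx])
            return evaluate(y[val_idx], est.predict(X.iloc[val_idx]))
        est.fit(Xm[train_idx], y[train_idx])
        return evaluate(y[val_idx], est.predict(Xm[val_idx]))
    Xtr, Xval = Xm[train_idx], Xm[val_idx]
    if scale:
        scaler = zscore(Xtr)
        Xtr, Xval = scaler.apply(Xtr), scaler.apply(Xval)
    est = make_estimator(spec).fit(Xtr, y[train_idx])
    return evaluate(y[val_idx], est.predict(Xval))


def kfold_evaluate(
    spec: dict, X, y, k: int = 10, seed: int = 0, scale: bool = True
) -> CVReport:
    """k-fold cross-validation: train on k−1 folds, score the held-out one,
    rotating; scaling refitted inside every training fold."""
    n = len(np.asarray(y))
    if k > n:
        raise ValueError("k cannot exceed n")
    folds = _kfold_indices(n, k, seed)
    if min(len(f) for f in folds) < 2:
        raise ValueError("validation fold smaller than 2 samples")
    all_idx = np.arange(n)
    reports = []
    for val_idx in folds:
        train_idx = np.setdiff1d(all_idx, val_idx)
        reports.append(_fit_and_score(spec, X, y, train_idx, val_idx, scale))
    return CVReport(folds=reports, k=k, seed=seed, meta={"spec": spec})


def random_search(
    base_spec: dict,
    space: dict[str, list],
    X,
    y,
    n_iter: int = 10,
    cv: int = 5,
    seed: int = 0,
    metric: str = "rmse",
    scale: bool = True,
):
    """Random grid search scored by inner-CV mean of ``metric`` (lower is
    better; R² is negated).  Returns (best spec, best CVReport, trace)."""
    if not space or any(len(v) == 0 for v in space.values()):
        raise ValueError("empty search space")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    sign = -1.0 if metric == "r2" else 1.0
    trace = []
    best = None
    for i in range(n_iter):
        spec = dict(base_spec)
        for param, choices in space.items():
            spec[param] = choices[int(rng.integers(len(choices)))]
        report = kfold_evaluate(spec, X, y, k=cv, seed=seed + i + 1, scale=scale)
        score = sign * report.mean(metric)
        trace.append({"spec": spec, "score": score})
        if best is None or score < best[0]:
            best = (score, spec, report)
    return best[1], best[2], trace


def nested_cv(
    base_spec: dict,
    space: dict[str, list],
    X,
    y,
    outer: int = 5,
    inner: int = 3,
    n_iter: int = 10,
    seed: int = 0,
    metric: str = "rmse",
    scale: bool = True,
) -> CVReport:
    """Nested CV: hyperparameters are chosen only on the inner folds of each
    outer-training set; outer test folds never influence selection."""
    n = len(np.asarray(y))
    if n < outer * 2:
        raise ValueError("need n >= 2*outer")
    folds = _kfold_indices(n, outer, seed)
    all_idx = np.arange(n)
    reports = []
    chosen = []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        Xtr = X.iloc[train_idx] if hasattr(X, "loc") else np.asarray(X)[train_idx]
        ytr = np.asarray(y)[train_idx]
        best_spec, _, _ = random_search(
            base_spec,
            space,
            Xtr,
            ytr,
            n_iter=n_iter,
            cv=inner,
            seed=seed * 1000 + f,
            metric=metric,
            scale=scale,
        )
        chosen.append(best_spec)
        reports.append(_fit_and_score(best_spec, X, y, train_idx, test_idx, scale))
    return CVReport(
        folds=reports, k=outer, seed=seed, meta={"chosen_specs": chosen}
    )


def learning_curve(
    spec: dict,
    X,
    y,
    fractions=(0.2, 0.4, 0.6, 0.8, 1.0),
    k: int = 5,
    seed: int = 0,
    scale: bool = True,
) -> pd.DataFrame:
    """Train/validation metrics versus training-set size.

    For each fraction, each CV fold trains on a seeded subsample of its
    training part; fraction 1.0 reproduces plain ``kfold_evaluate``.
    """
    fr = list(fractions)
    if any(not 0 < f <= 1 for f in fr) or fr != sorted(fr):
        raise ValueError("fractions must be increasing in (0, 1]")
    n = len(np.asarray(y))
    Xm = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    folds = _kfold_indices(n, k, seed)
    all_idx = np.arange(n)
    rows = []
    for frac in fr:
        train_reports, val_reports, sizes = [], [], []
        for f, val_idx in enumerate(folds):
            train_idx = np.setdiff1d(all_idx, val_idx)
            if frac < 1.0:
                rng = np.random.default_rng(seed * 7919 + f)
                m = max(2, int(round(frac * len(train_idx))))
                train_idx = np.sort(rng.choice(train_idx, size=m, replace=False))
            Xtr, Xval = Xm[train_idx], Xm[val_idx]
            if scale:
                scaler = zscore(Xtr)
                Xtr, Xval = scaler.apply(Xtr), scaler.apply(Xval)
            est = make_estimator(spec).fit(Xtr, ya[train_idx])
            train_reports.append(evaluate(ya[train_idx], est.predict(Xtr)))
            val_reports.append(evaluate(ya[val_idx], est.predict(Xval)))
            sizes.append(len(train_idx))
        row = {"fraction": frac, "n_train": float(np.mean(sizes))}
        for m in METRIC_NAMES:
            row[f"train_{m}"] = float(np.mean([getattr(r, m) for r in train_reports]))
            row[f"val_{m}"] = float(np.mean([getattr(r, m) for r in val_reports]))
        rows.append(row)
    return pd.DataFrame(rows)
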