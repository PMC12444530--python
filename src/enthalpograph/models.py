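"""QSPR regression models.

Linear side: the fixed-coefficient three-index predictor

    −Δ_cH° = 90·EE − 1.0789·W + 0.2822·Gutman − 417.6882   (kJ·mol⁻¹),

ordinary least squares, ridge (intercept unpenalized) and Huber robust
regression.  Tree side: CART regression trees grown by exact best-split
search minimising the weighted node MSE

    min_{j,s} [ |S_L|/|S| · MSE(S_L) + |S_R|/|S| · MSE(S_R) ],

random forests (bootstrap + per-node feature subsampling, prediction =
arithmetic mean over trees) and the extra-trees variant where each sampled
feature receives one uniformly drawn threshold and the best of those random
splits is kept.

All estimators are deterministic given a seed, and all serialise to plain
JSON so fits are inspectable and portable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import HuberRegressor

from .errors import NotFittedError, RankDeficiencyError

#: Fixed coefficients of the three-index multilinear predictor (kJ·mol⁻¹).
EQ_COEFFS = {"estrada": 90.0, "wiener": -1.0789, "gutman": 0.2822}
EQ_INTERCEPT = -417.6882


# ---------------------------------------------------------------------------
# linear models
# ---------------------------------------------------------------------------


@dataclass
class LinearModel:
    """Affine predictor with named coefficients (kJ·mol⁻¹ per feature unit)."""

    coefficients: dict[str, float]
    intercept: float
    kind: str  # ols | ridge | huber | fixed

    @property
    def feature_names(self) -> list[str]:
        return list(self.coefficients)

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X, self.feature_names)
        beta = np.array([self.coefficients[f] for f in self.feature_names])
        return X @ beta + self.intercept

    def to_dict(self) -> dict:
        return {
            "type": "linear",
            "kind": self.kind,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
        }


def _as_matrix(X, feature_names=None) -> np.ndarray:
    if hasattr(X, "loc") and feature_names is not None:
        X = X[list(feature_names)].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    return X[None, :] if X.ndim == 1 else X


def _names_of(X, p: int) -> list[str]:
    if hasattr(X, "columns"):
        return [str(c) for c in X.columns]
    return [f"x{j}" for j in range(p)]


def fixed_index_model() -> LinearModel:
    """The printed three-index predictor with frozen coefficients."""
    return LinearModel(coefficients=dict(EQ_COEFFS), intercept=EQ_INTERCEPT, kind="fixed")


def eq13_predict(estrada: float, wiener: float, gutman: float) -> float:
    """Apply the fixed three-index equation to one molecule's indices."""
    return (
        EQ_COEFFS["estrada"] * estrada
        + EQ_COEFFS["wiener"] * wiener
        + EQ_COEFFS["gutman"] * gutman
        + EQ_INTERCEPT
    )


def ols_fit(X, y) -> LinearModel:
    """Ordinary least squares with intercept.

    Raises :class:`RankDeficiencyError` on singular normal equations.
    """
    Xm = _as_matrix(X)
    names = _names_of(X, Xm.shape[1])
    y = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n < p + 1:
        raise ValueError(f"OLS needs at least {p + 1} rows, got {n}")
    design = np.column_stack([np.ones(n), Xm])
    if np.linalg.matrix_rank(design) < p + 1:
        raise RankDeficiencyError("singular normal equations (collinear columns)")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return LinearModel(
        coefficients=dict(zip(names, beta[1:].tolist())),
        intercept=float(beta[0]),
        kind="ols",
    )


def ridge_fit(X, y, alpha: float = 1.0) -> LinearModel:
    """L2-penalized least squares; the intercept is not penalized.

    With ``alpha = 0`` this reduces to OLS.
    """
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    Xm = _as_matrix(X)
    names = _names_of(X, Xm.shape[1])
    y = np.asarray(y, dtype=float)
    xm, ym = Xm.mean(axis=0), y.mean()
    Xc, yc = Xm - xm, y - ym
    p = Xm.shape[1]
    beta = np.linalg.solve(Xc.T @ Xc + alpha * np.eye(p), Xc.T @ yc)
    intercept = float(ym - xm @ beta)
    return LinearModel(
        coefficients=dict(zip(names, beta.tolist())), intercept=intercept, kind="ridge"
    )


@dataclass(frozen=True)
class HuberConfig:
    """Huber robust-regression hyperparameters.

    ``epsilon`` is the switch point between the quadratic and linear loss
    regimes, on the studentized-residual scale; ``alpha`` weights an L2
    penalty on the coefficients.
    """

    epsilon: float = 1.35
    alpha: float = 0.0001
    tol: float = 1e-6
    max_iter: int = 1000

    def __post_init__(self):
        if self.epsilon < 1.0:
            raise ValueError("epsilon must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


def huber_fit(X, y, cfg: HuberConfig | None = None) -> LinearModel:
    """Minimise the Huber loss (quadratic for small residuals, linear for
    large) plus an L2 coefficient penalty."""
    cfg = cfg or HuberConfig()
    Xm = _as_matrix(X)
    names = _names_of(X, Xm.shape[1])
    est = HuberRegressor(
        epsilon=cfg.epsilon, alpha=cfg.alpha, tol=cfg.tol, max_iter=cfg.max_iter
    )
    est.fit(Xm, np.asarray(y, dtype=float))
    return LinearModel(
        coefficients=dict(zip(names, est.coef_.tolist())),
        intercept=float(est.intercept_),
        kind="huber",
    )


# ---------------------------------------------------------------------------
# regression trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Leaf (value = mean target of its subset) or internal split node."""

    value: float
    n: int
    impurity: float
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def predict_one(self, x: np.ndarray) -> float:
        node = self
        while not node.is_leaf:
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node.value

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X)
        return np.array([self.predict_one(row) for row in X])

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"value": self.value, "n": self.n}
        return {
            "feature": self.feature,
            "threshold": self.threshold,
            "n": self.n,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }


def _node_mse(y: np.ndarray) -> float:
    return float(np.mean((y - y.mean()) ** 2)) if y.size else 0.0


def _best_split_exact(X, y, features, min_leaf):
    """Exact best (feature, threshold) by weighted child MSE.

    Thresholds are midpoints of consecutive sorted unique values; ties are
    broken by lowest feature index, then lowest threshold (features and
    thresholds are scanned in ascending order and only strict improvements
    are accepted).
    """
    n = y.size
    best = None  # (score, j, s)
    for j in features:
        order = np.argsort(X[:, j], kind="stable")
        xs, ys = X[order, j], y[order]
        # prefix sums for O(n) scoring of all cut positions
        csum = np.cumsum(ys)
        csq = np.cumsum(ys**2)
        total, total_sq = csum[-1], csq[-1]
        for cut in range(min_leaf, n - min_leaf + 1):
            if cut == 0 or cut == n or xs[cut - 1] == xs[cut]:
                continue
            nl, nr = cut, n - cut
            sl, sr = csum[cut - 1], total - csum[cut - 1]
            ql, qr = csq[cut - 1], total_sq - csq[cut - 1]
            score = (ql - sl**2 / nl) / n + (qr - sr**2 / nr) / n
            if best is None or score < best[0] - 1e-12 * max(1.0, abs(best[0])):
                s = (xs[cut - 1] + xs[cut]) / 2.0
                best = (score, j, s)
    return best


def _best_split_random(X, y, features, min_leaf, rng):
    """Extra-trees split: one uniform random threshold per sampled feature,
    best of those kept."""
    n = y.size
    best = None
    for j in features:
        col = X[:, j]
        lo, hi = col.min(), col.max()
        if lo == hi:
            continue
        s = rng.uniform(lo, hi)
        mask = col <= s
        nl = int(mask.sum())
        if nl < min_leaf or n - nl < min_leaf:
            continue
        yl, yr = y[mask], y[~mask]
        score = nl / n * _node_mse(yl) + (n - nl) / n * _node_mse(yr)
        if best is None or score < best[0]:
            best = (score, j, s)
    return best


def tree_fit(
    X,
    y,
    *,
    max_depth: int | None = None,
    min_samples_leaf: int = 1,
    max_features: int | None = None,
    random_thresholds: bool = False,
    seed: int | None = None,
) -> TreeNode:
    """Grow a CART regression tree by recursive best-split search.

    Recursion stops at purity, the depth limit, or when no split leaves
    ``min_samples_leaf`` samples on each side while reducing the weighted
    MSE.  ``max_features`` enables per-node feature subsampling (for forest
    use); ``random_thresholds`` switches to the extra-trees split rule.
    """
    Xm = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty training data")
    if y.size < 2 * min_samples_leaf:
        raise ValueError("need at least 2*min_samples_leaf samples")
    rng = np.random.default_rng(seed)
    p = Xm.shape[1]
    k = p if max_features is None else max(1, min(max_features, p))

    def grow(Xn, yn, depth):
        node = TreeNode(value=float(yn.mean()), n=yn.size, impurity=_node_mse(yn))
        if (
            node.impurity <= 1e-15
            or (max_depth is not None and depth >= max_depth)
            or yn.size < 2 * min_samples_leaf
        ):
            return node
        if k < p:
            features = np.sort(rng.choice(p, size=k, replace=False))
        else:
            features = np.arange(p)
        if random_thresholds:
            best = _best_split_random(Xn, yn, features, min_samples_leaf, rng)
        else:
            best = _best_split_exact(Xn, yn, features, min_samples_leaf)
        if best is None or best[0] >= node.impurity - 1e-15:
            return node
        _, j, s = best
        mask = Xn[:, j] <= s
        node.feature, node.threshold = int(j), float(s)
        node.left = grow(Xn[mask], yn[mask], depth + 1)
        node.right = grow(Xn[~mask], yn[~mask], depth + 1)
        return node

    return grow(Xm, y, 0)


# ---------------------------------------------------------------------------
# forests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ForestConfig:
    """Ensemble configuration.

    ``kind`` is ``rf`` (exact best splits) or ``et`` (random thresholds).
    ``mtry`` is the number of features considered per split; ``None`` means
    all features, the regression default of the framework the printed
    ensembles were fitted with.  Bootstrap defaults to True for both kinds
    to match the printed ensemble settings (canonical extra-trees would use
    the full sample; set ``bootstrap=False`` for that mode).
    """

    kind: str = "rf"
    n_estimators: int = 100
    bootstrap: bool = True
    mtry: int | None = None
    min_samples_leaf: int = 1
    max_depth: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("rf", "et"):
            raise ValueError("kind must be 'rf' or 'et'")
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")


@dataclass
class ForestModel:
    """Ensemble of regression trees; prediction is the mean over trees."""

    trees: list[TreeNode]
    config: ForestConfig
    feature_names: list[str]
    oob_indices: list[np.ndarray] = field(default_factory=list)

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X, self.feature_names if hasattr(X, "loc") else None)
        preds = np.stack([t.predict(X) for t in self.trees])
        return preds.mean(axis=0)

    def to_dict(self) -> dict:
        return {
            "type": "forest",
            "kind": self.config.kind,
            "n_estimators": self.config.n_estimators,
            "feature_names": self.feature_names,
            "trees": [t.to_dict() for t in self.trees],
        }


def forest_fit(X, y, cfg: ForestConfig) -> ForestModel:
    """Fit a random forest or extra-trees ensemble.

    Per tree: a bootstrap resample (when enabled), per-node subsampling of
    ``mtry`` features, and either exact or random thresholds depending on
    ``cfg.kind``.  Bit-identical results for identical seeds.
    """
    Xm = _as_matrix(X)
    names = _names_of(X, Xm.shape[1])
    y = np.asarray(y, dtype=float)
    n = y.size
    rng = np.random.default_rng(cfg.seed)
    trees, oob = [], []
    for _ in range(cfg.n_estimators):
        tree_seed = int(rng.integers(2**31))
        if cfg.bootstrap:
            idx = rng.integers(0, n, size=n)
            oob.append(np.setdiff1d(np.arange(n), idx))
        else:
            idx = np.arange(n)
            oob.append(np.array([], dtype=int))
        trees.append(
            tree_fit(
                Xm[idx],
                y[idx],
                max_depth=cfg.max_depth,
                min_samples_leaf=cfg.min_samples_leaf,
                max_features=cfg.mtry,
                random_thresholds=(cfg.kind == "et"),
                seed=tree_seed,
            )
        )
    return ForestModel(trees=trees, config=cfg, feature_names=names, oob_indices=oob)


def forest_predict(model: ForestModel, X) -> np.ndarray:
    return model.predict(X)


def impurity_importance(model: ForestModel) -> np.ndarray:
    """Mean decrease in impurity per feature, normalized to sum to 1.

    Each split contributes (n_node/n_root)·(parent MSE − weighted child
    MSE); contributions are summed per tree and averaged over the forest.
    """
    if not model.trees:
        raise NotFittedError("forest has no trees")
    p = len(model.feature_names)
    total = np.zeros(p)
    for tree in model.trees:
        imp = np.zeros(p)
        root_n = tree.n

        def walk(node):
            if node.is_leaf:
                return
            child = (
                node.left.n * node.left.impurity + node.right.n * node.right.impurity
            ) / node.n
            imp[node.feature] += node.n / root_n * (node.impurity - child)
            walk(node.left)
            walk(node.right)

        walk(tree)
        total += imp
    total /= len(model.trees)
    s = total.sum()
    return total / s if s > 0 else total


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def model_to_json(model: LinearModel | ForestModel) -> str:
    return json.dumps(model.to_dict(), indent=2)


def _tree_from_dict(d: dict) -> TreeNode:
    if "feature" not in d:
        return TreeNode(value=d["value"], n=d["n"], impurity=0.0)
    node = TreeNode(
        value=0.0,
        n=d["n"],
        impurity=0.0,
        feature=d["feature"],
        threshold=d["threshold"],
        left=_tree_from_dict(d["left"]),
        right=_tree_from_dict(d["right"]),
    )
    return node


def model_from_json(text: str) -> LinearModel | ForestModel:
    d = json.loads(text)
    if d["type"] == "linear":
        return LinearModel(
            coefficients=d["coefficients"], intercept=d["intercept"], kind=d["kind"]
        )
    if d["type"] == "forest":
        cfg = ForestConfig(kind=d["kind"], n_estimators=d["n_estimators"])
        return ForestModel(
            trees=[_tree_from_dict(t) for t in d["trees"]],
            config=cfg,
            feature_names=d["feature_names"],
        )
    raise ValueError(f"unknown model type {d.get('type')!r}")
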