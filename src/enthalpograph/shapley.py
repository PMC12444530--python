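"""Monte-Carlo Shapley attribution for fitted predictors.

Model-agnostic additive attribution: for a random permutation of the
features and a background row z, features of the explained instance are
switched in one at a time in permutation order, and the marginal change in
model output is credited to the feature that was switched (the
Štrumbelj–Kononenko sampling estimator of the Shapley value).  Per
permutation the marginals telescope to f(x) − f(z), so the averaged
contributions satisfy additivity around the background mean prediction up
to Monte-Carlo error, which is reported per feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class AttributionVector:
    """Per-feature contributions (kJ·mol⁻¹ for enthalpy models)."""

    contributions: np.ndarray
    stderr: np.ndarray
    baseline: float
    prediction: float
    n_perm: int
    seed: int
    feature_names: list[str] | None = None

    def as_series(self) -> pd.Series:
        names = self.feature_names or [f"x{j}" for j in range(len(self.contributions))]
        return pd.Series(self.contributions, index=names)


def mc_shapley(
    predict,
    background: np.ndarray,
    instance: np.ndarray,
    n_perm: int = 200,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> AttributionVector:
    """Estimate Shapley contributions of one instance's features.

    ``predict`` maps a 2-D array to a 1-D array of outputs; ``background``
    supplies the feature complements (one row drawn per permutation).
    Requires ``n_perm >= 50`` for a usable standard-error estimate.
    """
    background = np.atleast_2d(np.asarray(background, dtype=float))
    x = np.asarray(instance, dtype=float).ravel()
    if background.shape[0] == 0:
        raise ValueError("background set is empty")
    if n_perm < 50:
        raise ValueError("n_perm must be >= 50")
    p = x.size
    rng = np.random.default_rng(seed)
    samples = np.zeros((n_perm, p))
    for t in range(n_perm):
        order = rng.permutation(p)
        z = background[int(rng.integers(background.shape[0]))]
        # rows 0..p: z with the first i features (in permutation order)
        # replaced by x; batch-evaluate the whole chain at once
        chain = np.tile(z, (p + 1, 1))
        for i, j in enumerate(order):
            chain[i + 1 :, j] = x[j]
        outputs = np.asarray(predict(chain), dtype=float).ravel()
        samples[t, order] = np.diff(outputs)
    contributions = samples.mean(axis=0)
    stderr = samples.std(axis=0, ddof=1) / np.sqrt(n_perm)
    baseline = float(np.mean(np.asarray(predict(background), dtype=float)))
    prediction = float(np.asarray(predict(x[None, :]), dtype=float)[0])
    return AttributionVector(
        contributions=contributions,
        stderr=stderr,
        baseline=baseline,
        prediction=prediction,
        n_perm=n_perm,
        seed=seed,
        feature_names=list(feature_names) if feature_names else None,
    )


def attribute_many(
    predict,
    background: np.ndarray,
    instances: np.ndarray,
    n_perm: int = 200,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> list[AttributionVector]:
    """Attribute every row of ``instances`` (seeds derived per row)."""
    instances = np.atleast_2d(np.asarray(instances, dtype=float))
    rng = np.random.default_rng(seed)
    return [
        mc_shapley(
            predict,
            background,
            row,
            n_perm=n_perm,
            seed=int(rng.integers(2**31)),
            feature_names=feature_names,
        )
        for row in instances
    ]


def rank_features(attributions: list[AttributionVector]) -> pd.DataFrame:
    """Features ordered by mean |contribution| over the attributed sample,
    descending — the summary-plot ordering semantics."""
    if not attributions:
        raise ValueError("no attributions given")
    mat = np.stack([a.contributions for a in attributions])
    mean_abs = np.abs(mat).mean(axis=0)
    names = attributions[0].feature_names or [f"x{j}" for j in range(mat.shape[1])]
    order = np.argsort(-mean_abs, kind="stable")
    return pd.DataFrame(
        {
            "feature": [names[j] for j in order],
            "mean_abs_contribution": mean_abs[order],
        }
    )


def attributions_table(attributions: list[AttributionVector]) -> pd.DataFrame:
    """Instance × feature contribution table (plus baseline and prediction),
    ready for CSV export."""
    names = attributions[0].feature_names or [
        f"x{j}" for j in range(len(attributions[0].contributions))
    ]
    rows = []
    for i, a in enumerate(attributions):
        row = {"instance": i} | dict(zip(names, a.contributions))
        row["baseline"] = a.baseline
        row["prediction"] = a.prediction
        rows.append(row)
    return pd.DataFrame(rows)
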