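"""Feature-relevance ranking for yield prediction and classification.

Two complementary views:

- **RReliefF** for the continuous yield target: features are scored by how
  strongly their differences track target differences among nearest
  neighbors, so interactions and non-linear responses are credited without
  fitting a model.  This is the regression Relief estimator
  ``W[f] = P(diff f | diff y, near) - P(diff f | same y, near)`` computed by
  the standard weighted accumulation over sampled instances.
- **Gain ratio** for the binary high/low-yield view: information gain of a
  (discretized) feature about the class, normalized by the feature's split
  information, so many-valued features are not favored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .feature_table import FeatureMatrix


class UndefinedRelevanceError(ValueError):
    """Relevance is undefined (constant target or single class)."""


@dataclass
class RelevanceReport:
    """Per-feature relevance scores with the ranking and run parameters."""

    method: str
    scores: dict[str, float]
    params: dict[str, object] = field(default_factory=dict)

    @property
    def ranking(self) -> list[str]:
        return sorted(self.scores, key=lambda f: (-self.scores[f], f))

    def to_frame(self) -> pd.DataFrame:
        ranking = self.ranking
        return pd.DataFrame(
            {
                "feature": ranking,
                "score": [self.scores[f] for f in ranking],
                "rank": np.arange(1, len(ranking) + 1),
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def top(self, among: Sequence[str] | None = None) -> str:
        """Best-ranked feature, optionally restricted to a candidate subset."""
        pool = self.ranking if among is None else [f for f in self.ranking if f in set(among)]
        if not pool:
            raise ValueError("no candidate features in the report")
        return pool[0]

    def plot(self, path, title: str | None = None) -> None:
        """Horizontal bar chart of scores, best feature on top."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        frame = self.to_frame().iloc[::-1]
        fig, ax = plt.subplots(figsize=(7, max(2.5, 0.3 * len(frame))))
        ax.barh(frame["feature"], frame["score"], color="#41658a")
        ax.set_xlabel(f"{self.method} score")
        if title:
            ax.set_title(title)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _feature_diffs(
    X: np.ndarray, ranges: np.ndarray, is_categorical: np.ndarray, i: int
) -> np.ndarray:
    """Range-normalized per-feature differences between row i and all rows."""
    diffs = np.abs(X - X[i])
    with np.errstate(divide="ignore", invalid="ignore"):
        diffs = np.where(ranges > 0, diffs / ranges, 0.0)
    if is_categorical.any():
        diffs[:, is_categorical] = (X[:, is_categorical] != X[i, is_categorical]).astype(float)
    return diffs


def rrelieff(
    matrix: FeatureMatrix,
    target: pd.Series | np.ndarray | None = None,
    k: int = 10,
    iterations: int | None = None,
    seed: int = 0,
    sigma: float = 20.0,
) -> RelevanceReport:
    """RReliefF relevance scores for a continuous target.

    For each sampled instance the k nearest neighbors (range-normalized
    Manhattan distance; categorical features contribute 0/1) are weighted by
    rank, ``w_r ~ exp(-(r/sigma)^2)`` normalized per instance, and the
    weighted probabilities of a target difference, a feature difference, and
    their co-occurrence are accumulated into

        W[f] = N_dC&dF[f]/N_dC - (N_dF[f] - N_dC&dF[f]) / (m - N_dC).

    Parameters
    ----------
    k : int
        Neighbors per instance (default 10).
    iterations : int or None
        Instances to sample; ``None`` uses every instance once in a
        seed-driven order.
    sigma : float
        Rank-weighting scale (default 20).
    """
    if matrix.has_missing():
        raise ValueError("RReliefF requires a complete (imputed) matrix")
    y = np.asarray(matrix.target if target is None else target, dtype=float)
    n, n_feat = matrix.X.shape
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of rows ({n})")
    y_range = float(y.max() - y.min())
    if y_range == 0:
        raise UndefinedRelevanceError("constant target: relevance undefined")

    X = matrix.X.to_numpy(dtype=float)
    columns = matrix.columns
    is_categorical = np.array([c in matrix.codebook for c in columns])
    ranges = X.max(axis=0) - X.min(axis=0)

    m = n if iterations is None else min(int(iterations), n)
    rng = np.random.default_rng(int(seed) % (2**31))
    sample = rng.permutation(n)[:m]

    rank_w = np.exp(-(((np.arange(1, k + 1)) / sigma) ** 2))
    rank_w = rank_w / rank_w.sum()

    n_dc = 0.0
    n_df = np.zeros(n_feat)
    n_dcdf = np.zeros(n_feat)
    for i in sample:
        diffs = _feature_diffs(X, ranges, is_categorical, i)
        dist = diffs.sum(axis=1)
        dist[i] = np.inf  # exclude self
        neighbors = np.argsort(dist, kind="stable")[:k]
        t_diff = np.abs(y[neighbors] - y[i]) / y_range
        nd = diffs[neighbors]  # (k, n_feat)
        n_dc += float(rank_w @ t_diff)
        n_df += rank_w @ nd
        n_dcdf += (rank_w * t_diff) @ nd

    if n_dc == 0 or n_dc == m:
        raise UndefinedRelevanceError("degenerate target-difference accumulation")
    scores = n_dcdf / n_dc - (n_df - n_dcdf) / (m - n_dc)
    return RelevanceReport(
        method="rrelieff",
        scores=dict(zip(columns, scores.tolist())),
        params={"k": k, "iterations": m, "seed": int(seed), "sigma": sigma},
    )


def _entropy(counts: np.ndarray) -> float:
    """Shannon entropy in bits of a count vector."""
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def gain_ratio(
    matrix: FeatureMatrix,
    class_labels: pd.Series | np.ndarray | None = None,
    bins: int = 4,
) -> RelevanceReport:
    """Gain-ratio relevance of each feature for a binary class.

    Continuous features are discretized into ``bins`` equal-frequency bins;
    categorical (coded) features and features with at most ``bins`` distinct
    values keep their own levels.  ``gain ratio = IG / split information``,
    with 0 when the split information vanishes.
    """
    if matrix.has_missing():
        raise ValueError("gain ratio requires a complete (imputed) matrix")
    labels = np.asarray(matrix.target if class_labels is None else class_labels)
    classes, y = np.unique(labels, return_inverse=True)
    if classes.size < 2:
        raise UndefinedRelevanceError("single class: entropy undefined")

    n = y.size
    class_counts = np.bincount(y)
    h_class = _entropy(class_counts)

    scores: dict[str, float] = {}
    for col in matrix.columns:
        values = matrix.X[col]
        if col in matrix.codebook or values.nunique() <= bins:
            groups = values.astype("category").cat.codes.to_numpy()
        else:
            groups = pd.qcut(values, q=bins, labels=False, duplicates="drop")
            groups = np.asarray(groups, dtype=int)
        n_groups = int(groups.max()) + 1
        conditional = 0.0
        split_counts = np.zeros(n_groups)
        for g in range(n_groups):
            mask = groups == g
            split_counts[g] = mask.sum()
            conditional += (mask.sum() / n) * _entropy(np.bincount(y[mask], minlength=classes.size))
        info_gain = max(0.0, h_class - conditional)
        split_info = _entropy(split_counts)
        scores[col] = info_gain / split_info if split_info > 0 else 0.0

    return RelevanceReport(method="gain_ratio", scores=scores, params={"bins": bins})
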