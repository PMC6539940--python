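"""Minimum-Redundancy-Maximum-Relevance (mRMR) feature selection.

Filter selection over descriptor columns: features are ranked greedily so
that each new pick maximizes ψ = D − R, where D is the mean mutual
information of the candidate set with the class label (relevance) and R the
mean pairwise mutual information within the set (redundancy). Mutual
information is the plug-in estimate on a discretized contingency table, in
nats; continuous features are discretized into equal-frequency bins first.

Selection is intended to be fit on training folds only; the chosen index
set is then frozen and applied unchanged to held-out data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FeatureTable:
    """Samples × features matrix with names and binary ±1 labels."""

    matrix: np.ndarray
    feature_names: tuple[str, ...]
    labels: np.ndarray

    def __post_init__(self):
        X = np.asarray(self.matrix, dtype=float)
        y = np.asarray(self.labels)
        if X.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if not np.all(np.isfinite(X)):
            raise ValueError("feature matrix contains non-finite values")
        if len(y) != X.shape[0]:
            raise ValueError("labels length must match n_samples")
        if len(self.feature_names) != X.shape[1]:
            raise ValueError("feature_names length must match n_features")
        object.__setattr__(self, "matrix", X)
        object.__setattr__(self, "labels", y)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str) -> "FeatureTable":
        feats = [c for c in df.columns if c != label_column]
        return cls(matrix=df[feats].to_numpy(float),
                   feature_names=tuple(feats),
                   labels=df[label_column].to_numpy())


@dataclass(frozen=True)
class MRMRRanking:
    """Greedy selection order with the ψ score recorded at each step."""

    order: tuple[int, ...]
    scores: tuple[float, ...]

    def __post_init__(self):
        if len(set(self.order)) != len(self.order):
            raise ValueError("selected indices must be unique")
        if len(self.scores) != len(self.order):
            raise ValueError("one score per selection step")

    def to_dataframe(self, feature_names=None) -> pd.DataFrame:
        rows = {"step": np.arange(1, len(self.order) + 1),
                "feature_index": list(self.order),
                "psi_score": list(self.scores)}
        if feature_names is not None:
            rows["feature_name"] = [feature_names[i] for i in self.order]
        return pd.DataFrame(rows)


def discretize(x: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Equal-frequency binning of a continuous vector into integer codes.

    Vectors that already take few distinct values (≤ n_bins) are passed
    through as categorical codes; constant vectors get a single code.
    """
    x = np.asarray(x)
    uniq = np.unique(x)
    if len(uniq) <= n_bins:
        return np.searchsorted(uniq, x)
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(qs, x, side="right")


def mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int = 10) -> float:
    """Plug-in mutual information I(X;Y) in nats.

    I = Σ p(x,y) ln[p(x,y)/(p(x)p(y))] over the empirical joint table of the
    discretized vectors. Non-negative up to floating error and symmetric in
    its arguments; a constant vector gives exactly 0.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    xc = discretize(x, n_bins)
    yc = discretize(y, n_bins)
    joint = pd.crosstab(xc, yc).to_numpy(float)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    return float(np.sum(pxy[mask] * np.log(pxy[mask] / (px @ py)[mask])))


def mrmr_select(table: FeatureTable, k: int, n_bins: int = 10) -> MRMRRanking:
    """Greedy forward mRMR selection of ``k`` features.

    Each step adds the candidate maximizing ψ(S ∪ {i}) = D − R with
    D = mean_{j∈S∪{i}} I(x_j, y) and R the mean mutual information over
    distinct pairs within S ∪ {i} (self-information terms are excluded —
    they are entropies, not redundancies, and would bias the criterion
    against high-entropy features). With a single candidate R = 0, so step 1
    reduces to pure max-relevance. Ties break toward the lowest feature
    index, so runs are deterministic.
    """
    X, y = table.matrix, table.labels
    n_feat = table.n_features
    if not 1 <= k <= n_feat:
        raise ValueError(f"k must be in [1, {n_feat}]")
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")

    codes = [discretize(X[:, j], n_bins) for j in range(n_feat)]
    relevance = np.array([mutual_information(codes[j], y, n_bins)
                          for j in range(n_feat)])
    pair_cache: dict[tuple[int, int], float] = {}

    def pair_mi(i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        if key not in pair_cache:
            pair_cache[key] = mutual_information(codes[key[0]], codes[key[1]],
                                                 n_bins)
        return pair_cache[key]

    selected: list[int] = []
    scores: list[float] = []
    remaining = list(range(n_feat))
    for _ in range(k):
        best_idx, best_psi = None, -np.inf
        for i in remaining:
            cand = selected + [i]
            D = relevance[cand].mean()
            pairs = [pair_mi(a, b) for a in cand for b in cand if a < b]
            R = float(np.mean(pairs)) if pairs else 0.0
            psi = D - R
            if psi > best_psi + 1e-15 or best_idx is None:
                best_idx, best_psi = i, psi
        selected.append(best_idx)
        scores.append(float(best_psi))
        remaining.remove(best_idx)
    return MRMRRanking(order=tuple(selected), scores=tuple(scores))
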