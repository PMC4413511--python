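"""Maximum-relevance / minimum-redundancy feature ranking.

Continuous features are discretized into three states (below mean - theta*sigma,
within, above mean + theta*sigma) and mutual information is the empirical
plug-in estimate in bits (log base 2). Ranking is greedy forward selection:
the first feature maximizes relevance I(f, c); each subsequent step picks

    argmax_{f_j in candidates}  I(f_j, c) - (1/m) * sum_{f_i selected} I(f_j, f_i)

with m the number of already-selected features. Ties break toward the
smaller feature index, so the ranking is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from glypred.features import FeatureMatrix, feature_name


@dataclass(frozen=True)
class DiscretizationScheme:
    """Three-state per-feature discretization at mean +/- theta * std."""

    theta: float = 1.0

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError(f"theta must be positive, got {self.theta}")


@dataclass
class MRMRRanking:
    """Greedy mRMR ranking: full feature order with per-step diagnostics."""

    order: list[int]  # canonical 1-based feature indices, best first
    relevance: np.ndarray  # I(f_j, c) per feature, original column order
    step_scores: list[float]  # criterion value at each selection step
    feature_names: list[str] = field(default_factory=list)

    def top(self, n: int) -> list[int]:
        return self.order[:n]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("rank\tfeature_index\tfeature_name\trelevance\tcriterion_score\n")
            for r, (idx, score) in enumerate(zip(self.order, self.step_scores), start=1):
                name = self.feature_names[idx - 1] if self.feature_names else ""
                fh.write(f"{r}\t{idx}\t{name}\t{self.relevance[idx - 1]:.10g}\t{score:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MRMRRanking":
        order: list[int] = []
        scores: list[float] = []
        rel: dict[int, float] = {}
        names: dict[int, str] = {}
        with open(path) as fh:
            fh.readline()
            for line in fh:
                _, idx_s, name, rel_s, score_s = line.rstrip("\n").split("\t")
                idx = int(idx_s)
                order.append(idx)
                scores.append(float(score_s))
                rel[idx] = float(rel_s)
                names[idx] = name
        n = max(order)
        relevance = np.zeros(n)
        name_list = [""] * n
        for idx in order:
            relevance[idx - 1] = rel[idx]
            name_list[idx - 1] = names[idx]
        return cls(order, relevance, scores, name_list)


def discretize(
    values: np.ndarray,
    scheme: DiscretizationScheme = DiscretizationScheme(),
    categorical: bool = False,
) -> np.ndarray:
    """Map a real vector to states {0, 1, 2} = {low, mid, high}.

    Values below mean - theta*std map to 0, above mean + theta*std to 2,
    the rest to 1. Constant vectors map entirely to mid. When
    ``categorical`` is set the values are re-coded to dense integer
    states without thresholding.
    """
    values = np.asarray(values)
    if values.size == 0:
        raise ValueError("empty vector")
    if categorical:
        _, codes = np.unique(values, return_inverse=True)
        return codes.astype(np.int8)
    mu = values.mean()
    sigma = values.std()  # population std; sigma = 0 -> all mid
    out = np.ones(values.shape, dtype=np.int8)
    out[values < mu - scheme.theta * sigma] = 0
    out[values > mu + scheme.theta * sigma] = 2
    return out


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Empirical mutual information in bits between two categorical vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError(f"need equal-length 1-D vectors, got {x.shape} and {y.shape}")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= x.size
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    return float(np.sum(joint[mask] * np.log2(joint[mask] / (px @ py)[mask])))


def _onehot(states: np.ndarray, n_states: int = 3) -> np.ndarray:
    """(n, k) one-hot for a state matrix column-stacked: returns (n, k*n_states)."""
    n, k = states.shape
    out = np.zeros((n, k * n_states), dtype=np.float64)
    cols = np.arange(k) * n_states + states
    out[np.arange(n)[:, None], cols] = 1.0
    return out


def _mi_against_all(
    sel_onehot: np.ndarray, all_onehot: np.ndarray, n_features: int, n_states: int = 3
) -> np.ndarray:
    """Vectorized MI (bits) of one discretized vector against every feature."""
    n = sel_onehot.shape[0]
    joint = (sel_onehot.T @ all_onehot) / n  # (n_states, n_features*n_states)
    joint = joint.reshape(n_states, n_features, n_states).transpose(1, 0, 2)
    px = joint.sum(axis=2, keepdims=True)
    py = joint.sum(axis=1, keepdims=True)
    denom = px * py
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(np.where(joint > 0, joint / np.where(denom > 0, denom, 1), 1))
    return terms.sum(axis=(1, 2))


def mrmr_rank(
    matrix: FeatureMatrix,
    scheme: DiscretizationScheme = DiscretizationScheme(),
    top_k: int | None = None,
) -> MRMRRanking:
    """Rank features by greedy mRMR forward selection.

    Runs to a full permutation by default; ``top_k`` stops early after
    that many selections (every returned prefix is identical to the
    corresponding prefix of the full ranking).
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    labels = matrix.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("degenerate label vector: single class")

    n, p = matrix.values.shape
    states = np.empty((n, p), dtype=np.int8)
    for j in range(p):
        states[:, j] = discretize(matrix.values[:, j], scheme)
    y = discretize(labels, categorical=True).astype(np.int8)

    all_oh = _onehot(states)
    y_oh = _onehot(y.reshape(-1, 1))[:, :3]
    relevance = _mi_against_all(y_oh, all_oh, p)

    k = p if top_k is None else min(top_k, p)
    selected: list[int] = []
    step_scores: list[float] = []
    red_sum = np.zeros(p)  # sum of I(f_j, f_i) over selected i
    candidate = np.ones(p, dtype=bool)
    for _ in range(k):
        m = len(selected)
        crit = relevance - (red_sum / m if m else 0.0)
        crit = np.where(candidate, crit, -np.inf)
        # scores within 1e-12 are ties; break toward the smaller index
        best = int(np.flatnonzero(crit >= crit.max() - 1e-12)[0])
        selected.append(best)
        step_scores.append(float(crit[best]))
        candidate[best] = False
        sel_oh = _onehot(states[:, best].reshape(-1, 1))
        red_sum += _mi_against_all(sel_oh, all_oh, p)

    order = [j + 1 for j in selected]  # 1-based
    return MRMRRanking(order, relevance, step_scores, list(matrix.feature_names))
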