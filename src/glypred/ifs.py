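"""Incremental feature selection with a grid-searched RBF SVM.

Prefixes of an mRMR ranking are evaluated one by one: for each prefix
size the columns are restricted to the top-ranked features, a (C, gamma)
grid is searched under stratified k-fold cross-validation, test-fold
predictions are pooled into a single confusion table, and the prefix
with the best MCC wins (ties -> smallest prefix). The final predictor is
an RBF SVM trained on the optimal subset with features linearly scaled
to [-1, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.svm import SVC

from glypred.features import FeatureMatrix, FeatureSpace, encode_all
from glypred.mrmr import MRMRRanking
from glypred.sequence_io import PeptideWindow

MODEL_SCHEMA_VERSION = 1

#: Default (C, gamma) lattice: C = 2^-5 .. 2^15, gamma = 2^-15 .. 2^3, steps of 2^2.
DEFAULT_GRID = (
    tuple(2.0**e for e in range(-5, 16, 2)),
    tuple(2.0**e for e in range(-15, 4, 2)),
)


@dataclass(frozen=True)
class SVMConfig:
    C: float
    gamma: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError(f"C and gamma must be positive, got {self.C}, {self.gamma}")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            TP=int(np.sum((y_true == 1) & (y_pred == 1))),
            TN=int(np.sum((y_true == -1) & (y_pred == -1))),
            FP=int(np.sum((y_true == -1) & (y_pred == 1))),
            FN=int(np.sum((y_true == 1) & (y_pred == -1))),
        )


@dataclass(frozen=True)
class Metrics:
    Sn: float
    Sp: float
    Ac: float
    MCC: float


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity, accuracy and Matthews correlation.

    MCC is defined as 0 whenever any factor of its denominator is 0;
    Sn/Sp fall back to 0 on an empty class.
    """
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    if counts.total == 0:
        raise ValueError("all-zero confusion counts")
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    ac = (tp + tn) / counts.total
    denom = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    mcc = (tp * tn - fn * fp) / math.sqrt(denom) if denom else 0.0
    return Metrics(Sn=sn, Sp=sp, Ac=ac, MCC=mcc)


def stratified_folds(labels: np.ndarray, k: int = 10, seed: int = 1) -> np.ndarray:
    """Deterministic stratified fold assignment.

    Guarantees per-fold class counts within 1 of each other for every
    class, and total fold sizes within 1 of each other (class remainders
    are dealt to the currently smallest folds).
    """
    labels = np.asarray(labels)
    n = labels.size
    classes, class_counts = np.unique(labels, return_counts=True)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > class_counts.min():
        raise ValueError(
            f"k={k} exceeds minority class count {class_counts.min()}"
        )
    rng = np.random.default_rng(seed)
    assign = np.empty(n, dtype=int)
    fold_sizes = np.zeros(k, dtype=int)
    # larger classes first so their remainders are spread before the
    # smaller classes fill the gaps
    for cls in classes[np.argsort(-class_counts, kind="stable")]:
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        base, rem = divmod(idx.size, k)
        counts = np.full(k, base)
        order = np.lexsort((rng.permutation(k), fold_sizes))
        counts[order[:rem]] += 1
        fold_sizes += counts
        start = 0
        for f in range(k):
            assign[idx[start: start + counts[f]]] = f
            start += counts[f]
    return assign


def _scale_bounds(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    span = hi - lo
    span[span == 0] = 1.0  # constant columns map to -1; harmless to the SVM
    return lo, span


def _scale(x: np.ndarray, lo: np.ndarray, span: np.ndarray) -> np.ndarray:
    return 2.0 * (x - lo) / span - 1.0


def _cv_confusion(
    x: np.ndarray, y: np.ndarray, folds: np.ndarray, config: SVMConfig
) -> ConfusionCounts:
    """Pooled test-fold confusion counts for one (C, gamma) setting."""
    y_pred = np.empty_like(y)
    for f in np.unique(folds):
        test = folds == f
        train = ~test
        lo, span = _scale_bounds(x[train])
        clf = SVC(C=config.C, gamma=config.gamma, kernel="rbf")
        clf.fit(_scale(x[train], lo, span), y[train])
        y_pred[test] = clf.predict(_scale(x[test], lo, span))
    return ConfusionCounts.from_predictions(y, y_pred)


def grid_search_cv(
    matrix: FeatureMatrix,
    grid: tuple[Sequence[float], Sequence[float]] = DEFAULT_GRID,
    k: int = 10,
    seed: int = 1,
    folds: np.ndarray | None = None,
) -> tuple[SVMConfig, ConfusionCounts]:
    """Search the (C, gamma) lattice under stratified k-fold CV.

    Returns the config maximizing pooled-CV MCC; ties resolve to larger
    accuracy, then smaller C, then smaller gamma.
    """
    cs, gammas = grid
    if not cs or not gammas:
        raise ValueError("empty grid")
    y = matrix.labels
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate label vector: single class")
    if folds is None:
        folds = stratified_folds(y, k, seed)
    best: tuple | None = None
    for c in sorted(cs):
        for g in sorted(gammas):
            config = SVMConfig(C=c, gamma=g)
            counts = _cv_confusion(matrix.values, y, folds, config)
            m = compute_metrics(counts)
            key = (m.MCC, m.Ac, -c, -g)
            if best is None or key > best[0]:
                best = (key, config, counts)
    return best[1], best[2]


@dataclass
class IFSRecord:
    size: int
    config: SVMConfig
    counts: ConfusionCounts
    metrics: Metrics


@dataclass
class IFSResult:
    curve: list[IFSRecord]
    optimal_size: int
    optimal_features: list[int]  # canonical 1-based indices
    optimal_config: SVMConfig
    seed: int

    @property
    def best_metrics(self) -> Metrics:
        return next(r.metrics for r in self.curve if r.size == self.optimal_size)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("size\tC\tgamma\tTP\tFP\tTN\tFN\tSn\tSp\tAc\tMCC\n")
            for r in self.curve:
                c, m = r.counts, r.metrics
                fh.write(
                    f"{r.size}\t{r.config.C:g}\t{r.config.gamma:g}\t"
                    f"{c.TP}\t{c.FP}\t{c.TN}\t{c.FN}\t"
                    f"{m.Sn:.6f}\t{m.Sp:.6f}\t{m.Ac:.6f}\t{m.MCC:.6f}\n"
                )


def run_ifs(
    matrix: FeatureMatrix,
    ranking: MRMRRanking,
    sizes: Sequence[int] | str = "all",
    k: int = 10,
    seed: int = 1,
    grid: tuple[Sequence[float], Sequence[float]] = DEFAULT_GRID,
    stride: int = 1,
) -> IFSResult:
    """Evaluate growing prefixes of the ranking; return the best by MCC.

    ``sizes`` may be an explicit list of prefix sizes or ``"all"`` for
    1..n_ranked (thinned by ``stride``; the full ranking length is always
    included). The same fold split is reused across all prefix sizes and
    grid points so curves are comparable.
    """
    n_ranked = len(ranking.order)
    if sizes == "all":
        size_list = list(range(1, n_ranked + 1, stride))
        if size_list[-1] != n_ranked:
            size_list.append(n_ranked)
    else:
        size_list = sorted(set(int(s) for s in sizes))
    if not size_list:
        raise ValueError("empty size list")
    if size_list[-1] > n_ranked:
        raise ValueError(f"prefix size {size_list[-1]} exceeds ranking length {n_ranked}")

    folds = stratified_folds(matrix.labels, k, seed)
    curve: list[IFSRecord] = []
    for size in size_list:
        sub = matrix.subset(ranking.top(size))
        config, counts = grid_search_cv(sub, grid, k, seed, folds=folds)
        curve.append(IFSRecord(size, config, counts, compute_metrics(counts)))

    best = max(curve, key=lambda r: (r.metrics.MCC, -r.size))
    return IFSResult(
        curve=curve,
        optimal_size=best.size,
        optimal_features=ranking.top(best.size),
        optimal_config=best.config,
        seed=seed,
    )


@dataclass
class PredictorModel:
    """Final fitted predictor: feature subset, scaling and decision function."""

    feature_indices: list[int]  # canonical 1-based
    feature_names: list[str]
    config: SVMConfig
    scale_lo: np.ndarray
    scale_span: np.ndarray
    svc: SVC
    window_size: int = 23
    kmax: int = 4
    normalize_cksaap: bool = True
    schema_version: int = MODEL_SCHEMA_VERSION

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "PredictorModel":
        model = joblib.load(path)
        if not isinstance(model, cls) or model.schema_version != MODEL_SCHEMA_VERSION:
            raise ValueError(f"{path}: not a schema-v{MODEL_SCHEMA_VERSION} model file")
        return model


def train_final(
    matrix: FeatureMatrix,
    features: Sequence[int],
    config: SVMConfig,
    window_size: int = 23,
    kmax: int = 4,
    normalize_cksaap: bool = True,
) -> PredictorModel:
    """Fit the final RBF SVM on the given canonical feature subset."""
    sub = matrix.subset(features)
    lo, span = _scale_bounds(sub.values)
    svc = SVC(C=config.C, gamma=config.gamma, kernel="rbf")
    svc.fit(_scale(sub.values, lo, span), sub.labels)
    return PredictorModel(
        feature_indices=list(features),
        feature_names=list(sub.feature_names),
        config=config,
        scale_lo=lo,
        scale_span=span,
        svc=svc,
        window_size=window_size,
        kmax=kmax,
        normalize_cksaap=normalize_cksaap,
    )


def predict(
    model: PredictorModel, windows: Sequence[PeptideWindow]
) -> tuple[np.ndarray, np.ndarray]:
    """Score windows with a trained model.

    Returns ``(labels, decision_values)``; label = sign of the decision
    value (+1 predicted site, -1 non-site).
    """
    if not windows:
        return np.array([], dtype=int), np.array([])
    widths = {len(w.peptide) for w in windows}
    if widths != {model.window_size}:
        raise ValueError(
            f"windows of width {sorted(widths)} do not match model window size "
            f"{model.window_size}"
        )
    matrix = encode_all(windows, kmax=model.kmax, normalize=model.normalize_cksaap)
    x = _scale(matrix.subset(model.feature_indices).values, model.scale_lo, model.scale_span)
    dec = model.svc.decision_function(x)
    # decision_function sign follows class order (-1, +1): positive -> +1
    labels = np.where(dec >= 0, 1, -1)
    return labels, dec


AA_CLASSES = {
    "nonpolar": set("AGILMPVFW"),
    "polar": set("STCNQY"),
    "charged": set("DEKRH"),
    "aromatic": set("FWYH"),
}


def summarize_optimal_features(
    optimal_features: Sequence[int] | IFSResult, space: FeatureSpace
) -> dict[str, dict]:
    """Tally an optimal feature set by block, residue class, site and letter.

    Residue classes overlap (e.g. F is nonpolar and aromatic); CKSAAP
    features contribute both of their letters, frequency features their
    single letter, factor features none.
    """
    if isinstance(optimal_features, IFSResult):
        optimal_features = optimal_features.optimal_features
    blocks = {"frequency": 0, "factor": 0, "cksaap": 0}
    by_class = {name: 0 for name in AA_CLASSES}
    by_site: dict[int, int] = {}
    by_letter: dict[str, int] = {}
    for idx in optimal_features:
        d = space[idx]
        blocks[d.block] += 1
        letters = []
        if d.block == "frequency":
            letters = [d.letter]
        elif d.block == "factor":
            by_site[d.site] = by_site.get(d.site, 0) + 1
        else:
            letters = [d.a, d.b]
            for ch in letters:
                if ch != "O":
                    by_letter[ch] = by_letter.get(ch, 0) + 1
        for ch in letters:
            for name, members in AA_CLASSES.items():
                if ch in members:
                    by_class[name] += 1
    return {
        "by_block": blocks,
        "by_class": by_class,
        "by_site": dict(sorted(by_site.items())),
        "by_letter": dict(sorted(by_letter.items())),
    }


def write_summary(summary: dict[str, dict], path: str | Path) -> None:
    """Write a feature-set summary as TSV (section, key, count)."""
    with open(path, "w") as fh:
        fh.write("section\tkey\tcount\n")
        for section, table in summary.items():
            for key, count in table.items():
                fh.write(f"{section}\t{key}\t{count}\n")
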