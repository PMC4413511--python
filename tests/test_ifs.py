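import math

import numpy as np
import pytest

from glypred.features import FeatureMatrix, FeatureSpace, encode_all
from glypred.ifs import (
    ConfusionCounts,
    IFSResult,
    Metrics,
    PredictorModel,
    SVMConfig,
    compute_metrics,
    grid_search_cv,
    predict,
    run_ifs,
    stratified_folds,
    summarize_optimal_features,
    train_final,
)
from glypred.mrmr import MRMRRanking, mrmr_rank


def metrics_oracle(tp, tn, fp, fn):
    """Independent closed-form evaluation of Sn/Sp/Ac/MCC."""
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    ac = (tp + tn) / (tp + tn + fp + fn)
    d = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    mcc = (tp * tn - fn * fp) / math.sqrt(d) if d else 0.0
    return sn, sp, ac, mcc


def separable_matrix(n_per_class: int = 20, seed: int = 0) -> FeatureMatrix:
    rng = np.random.default_rng(seed)
    pos = rng.normal(loc=+3.0, size=(n_per_class, 2))
    neg = rng.normal(loc=-3.0, size=(n_per_class, 2))
    values = np.vstack([pos, neg])
    labels = np.array([1] * n_per_class + [-1] * n_per_class)
    return FeatureMatrix(values, ["f1", "f2"], labels)


SMALL_GRID = ((1.0, 8.0), (0.125, 1.0))


class TestComputeMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(TP=10, TN=10, FP=0, FN=0))
        assert m == Metrics(Sn=1.0, Sp=1.0, Ac=1.0, MCC=1.0)

    def test_hand_derived_example(self):
        m = compute_metrics(ConfusionCounts(TP=3, FP=1, TN=4, FN=2))
        assert m.Sn == pytest.approx(0.6)
        assert m.Sp == pytest.approx(0.8)
        assert m.Ac == pytest.approx(0.7)
        assert m.MCC == pytest.approx(10 / math.sqrt(600))

    def test_degenerate_predictor_zero_mcc(self):
        m = compute_metrics(ConfusionCounts(TP=0, FN=5, TN=5, FP=0))
        assert (m.Sn, m.Sp, m.Ac, m.MCC) == (0.0, 1.0, 0.5, 0.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_fuzz_against_formula_oracle(self, rng):
        for _ in range(1000):
            tp, tn, fp, fn = rng.integers(0, 50, size=4)
            if tp + tn + fp + fn == 0:
                continue
            m = compute_metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            sn, sp, ac, mcc = metrics_oracle(tp, tn, fp, fn)
            assert (m.Sn, m.Sp, m.Ac) == pytest.approx((sn, sp, ac))
            assert m.MCC == pytest.approx(mcc)

    def test_class_swap_symmetry(self, rng):
        for _ in range(100):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 30, size=4))
            if tp + tn + fp + fn == 0:
                continue
            m = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
            swapped = compute_metrics(ConfusionCounts(TP=tn, TN=tp, FP=fn, FN=fp))
            assert swapped.MCC == pytest.approx(m.MCC)
            assert swapped.Ac == pytest.approx(m.Ac)
            assert (swapped.Sn, swapped.Sp) == pytest.approx((m.Sp, m.Sn))


class TestStratifiedFolds:
    def test_perfectly_divisible(self):
        labels = np.array([1] * 10 + [-1] * 10)
        folds = stratified_folds(labels, k=10, seed=3)
        for f in range(10):
            mask = folds == f
            assert mask.sum() == 2
            assert labels[mask].sum() == 0  # one of each class

    def test_determinism(self):
        labels = np.array([1] * 30 + [-1] * 45)
        np.testing.assert_array_equal(
            stratified_folds(labels, seed=7), stratified_folds(labels, seed=7)
        )
        assert not np.array_equal(
            stratified_folds(labels, seed=7), stratified_folds(labels, seed=8)
        )

    def test_benchmark_shape_89_126(self):
        labels = np.array([1] * 89 + [-1] * 126)
        folds = stratified_folds(labels, k=10, seed=1)
        sizes = np.bincount(folds, minlength=10)
        assert sizes.max() - sizes.min() <= 1
        pos_per_fold = np.bincount(folds[labels == 1], minlength=10)
        assert set(pos_per_fold) <= {8, 9}

    def test_k_exceeding_minority_class(self):
        labels = np.array([1] * 5 + [-1] * 50)
        with pytest.raises(ValueError, match="minority"):
            stratified_folds(labels, k=10)


class TestGridSearchCV:
    def test_separable_reaches_mcc_one(self):
        config, counts = grid_search_cv(separable_matrix(), SMALL_GRID, k=5, seed=1)
        assert compute_metrics(counts).MCC == 1.0

    def test_pooled_counts_cover_all_samples(self):
        matrix = separable_matrix()
        _, counts = grid_search_cv(matrix, SMALL_GRID, k=5, seed=1)
        assert counts.TP + counts.FN == (matrix.labels == 1).sum()
        assert counts.TN + counts.FP == (matrix.labels == -1).sum()

    def test_permuted_labels_near_zero_mcc(self, rng):
        values = rng.normal(size=(200, 5))
        labels = np.array([1] * 100 + [-1] * 100)
        rng.shuffle(labels)
        matrix = FeatureMatrix(values, [f"f{i}" for i in range(5)], labels)
        _, counts = grid_search_cv(matrix, SMALL_GRID, k=10, seed=1)
        assert abs(compute_metrics(counts).MCC) < 0.3

    def test_single_point_grid(self):
        config, counts = grid_search_cv(
            separable_matrix(), ((2.0,), (0.5,)), k=5, seed=1
        )
        assert config == SVMConfig(C=2.0, gamma=0.5)
        assert counts.total == 40

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty grid"):
            grid_search_cv(separable_matrix(), ((), (1.0,)))

    def test_single_class_rejected(self):
        matrix = FeatureMatrix(np.ones((10, 1)), ["f"], np.ones(10, dtype=int))
        with pytest.raises(ValueError, match="single class"):
            grid_search_cv(matrix, SMALL_GRID)


def _planted_matrix(seed: int = 5, n: int = 60) -> FeatureMatrix:
    """One informative column among noise, in a small named matrix."""
    rng = np.random.default_rng(seed)
    labels = np.array([1] * (n // 2) + [-1] * (n // 2))
    values = rng.normal(size=(n, 4))
    values[:, 0] = labels * 2.0 + rng.normal(scale=0.3, size=n)
    return FeatureMatrix(values, [f"f{i}" for i in range(4)], labels)


class TestRunIFS:
    def test_planted_signal_peaks_early(self):
        matrix = _planted_matrix()
        ranking = mrmr_rank(matrix)
        assert ranking.order[0] == 1
        result = run_ifs(matrix, ranking, sizes="all", k=5, seed=1, grid=SMALL_GRID)
        assert 1 in result.optimal_features
        assert result.best_metrics.MCC >= 0.9

    def test_single_size_run(self):
        matrix = _planted_matrix()
        ranking = mrmr_rank(matrix)
        result = run_ifs(matrix, ranking, sizes=[3], k=5, seed=1, grid=SMALL_GRID)
        assert [r.size for r in result.curve] == [3]
        assert result.optimal_size == 3
        assert len(result.optimal_features) == 3

    def test_determinism(self):
        matrix = _planted_matrix()
        ranking = mrmr_rank(matrix)
        r1 = run_ifs(matrix, ranking, sizes=[1, 2, 4], k=5, seed=9, grid=SMALL_GRID)
        r2 = run_ifs(matrix, ranking, sizes=[1, 2, 4], k=5, seed=9, grid=SMALL_GRID)
        assert [rec.metrics for rec in r1.curve] == [rec.metrics for rec in r2.curve]
        assert r1.optimal_size == r2.optimal_size

    def test_pooled_counts_every_size(self):
        matrix = _planted_matrix()
        ranking = mrmr_rank(matrix)
        result = run_ifs(matrix, ranking, sizes=[1, 2, 3, 4], k=5, seed=1, grid=SMALL_GRID)
        n_pos = (matrix.labels == 1).sum()
        n_neg = (matrix.labels == -1).sum()
        for rec in result.curve:
            assert rec.counts.TP + rec.counts.FN == n_pos
            assert rec.counts.TN + rec.counts.FP == n_neg

    def test_optimal_tie_prefers_smaller_size(self):
        matrix = separable_matrix()
        ranking = mrmr_rank(matrix)
        result = run_ifs(matrix, ranking, sizes=[1, 2], k=5, seed=1, grid=SMALL_GRID)
        mccs = [r.metrics.MCC for r in result.curve]
        if mccs[0] == mccs[1]:
            assert result.optimal_size == 1

    def test_empty_sizes_rejected(self):
        matrix = separable_matrix()
        ranking = mrmr_rank(matrix)
        with pytest.raises(ValueError):
            run_ifs(matrix, ranking, sizes=[], k=5, seed=1, grid=SMALL_GRID)

    def test_curve_tsv(self, tmp_path):
        matrix = _planted_matrix()
        ranking = mrmr_rank(matrix)
        result = run_ifs(matrix, ranking, sizes=[1, 2], k=5, seed=1, grid=SMALL_GRID)
        path = tmp_path / "curve.tsv"
        result.to_tsv(path)
        lines = path.read_text().splitlines()
        assert lines[0].split("\t") == [
            "size", "C", "gamma", "TP", "FP", "TN", "FN", "Sn", "Sp", "Ac", "MCC"
        ]
        assert len(lines) == 3


class TestTrainPredict:
    def _windows(self, seed=11, n=30):
        from glypred.sequence_io import build_dataset
        from glypred.simulate import FixtureSpec, PlantedPair, generate

        spec = FixtureSpec(
            n_pos=n, n_neg=n, planted_pairs=(PlantedPair("S", "W", 4, 1.0),), seed=seed
        )
        proteins, annotations = generate(spec)
        return build_dataset(proteins, annotations)

    def test_resubstitution_accuracy_on_separable(self):
        windows = self._windows()
        matrix = encode_all(windows)
        ranking = mrmr_rank(matrix, top_k=5)
        config, counts = grid_search_cv(
            matrix.subset(ranking.top(5)), SMALL_GRID, k=5, seed=1
        )
        cv_ac = compute_metrics(counts).Ac
        model = train_final(matrix, ranking.top(5), config)
        labels, _ = predict(model, windows)
        train_ac = (labels == matrix.labels).mean()
        assert train_ac >= cv_ac

    def test_empty_window_list(self):
        matrix = _planted_matrix()
        model = train_final(matrix, [1, 2], SVMConfig(C=1.0, gamma=0.5), window_size=23)
        labels, decisions = predict(model, [])
        assert labels.size == 0 and decisions.size == 0

    def test_motif_window_scores_higher_than_counterpart(self):
        from conftest import make_window

        windows = self._windows()
        matrix = encode_all(windows)
        ranking = mrmr_rank(matrix, top_k=5)
        model = train_final(matrix, ranking.top(5), SVMConfig(C=8.0, gamma=0.125))
        base = "AGAGAGAGAGAKAGAGAGAGAGA"
        with_motif = base[:12] + "S" + base[13:17] + "W" + base[18:]
        _, dec = predict(model, [make_window(with_motif), make_window(base)])
        assert dec[0] > dec[1]

    def test_wrong_window_width(self):
        model = train_final(_planted_matrix(), [1], SVMConfig(C=1.0, gamma=0.5))
        from conftest import make_window

        with pytest.raises(ValueError, match="window size"):
            predict(model, [make_window("A" * 21)])

    def test_model_round_trip_bit_identical(self, tmp_path):
        windows = self._windows()
        matrix = encode_all(windows)
        model = train_final(matrix, [1793, 33, 91], SVMConfig(C=2.0, gamma=0.25))
        path = tmp_path / "model.joblib"
        model.save(path)
        reloaded = PredictorModel.load(path)
        _, d1 = predict(model, windows[:5])
        _, d2 = predict(reloaded, windows[:5])
        np.testing.assert_array_equal(d1, d2)
        assert reloaded.feature_indices == model.feature_indices


class TestSummarize:
    def test_direct_tally(self):
        space = FeatureSpace()
        summary = summarize_optimal_features([1793, 33, 91], space)
        assert summary["by_block"] == {"frequency": 0, "factor": 2, "cksaap": 1}

    def test_full_space_tally(self):
        space = FeatureSpace()
        summary = summarize_optimal_features(list(range(1, 1901)), space)
        assert summary["by_block"] == {"frequency": 21, "factor": 115, "cksaap": 1764}

    def test_site_histogram(self):
        space = FeatureSpace()
        summary = summarize_optimal_features([33, 91, 129], space)
        assert summary["by_site"] == {3: 1, 14: 1, 22: 1}

    def test_letter_and_class_tally(self):
        space = FeatureSpace()
        summary = summarize_optimal_features([1793], space)  # S^^^^W
        assert summary["by_letter"] == {"S": 1, "W": 1}
        assert summary["by_class"]["polar"] == 1      # S
        assert summary["by_class"]["nonpolar"] == 1   # W
        assert summary["by_class"]["aromatic"] == 1   # W
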