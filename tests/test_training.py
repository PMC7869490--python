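"""Training loop, dataset splitting, cross-validation, ensembles, metrics."""

import numpy as np
import pytest

from contactsol.model import ModelConfig, init_parameters
from contactsol.training import (
    SolubilityDataset,
    TrainConfig,
    compute_metrics,
    cross_validate,
    ensemble_predict,
    predict_dataset,
    split_dataset,
    threshold_sweep,
    train,
    _fold_indices,
)


def auc_mann_whitney(scores, labels):
    """Independent AUC oracle: pairwise concordance with half-credit ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestTrain:
    def test_zero_epochs_returns_initialization(self, small_dataset, tiny_config):
        tcfg = TrainConfig(epochs=0, seed=11)
        params = train(small_dataset, tiny_config, tcfg)
        init = init_parameters(tiny_config, seed=11)
        for a, b in zip(params.to_flat_list(), init.to_flat_list()):
            assert np.array_equal(a, b)

    def test_overfits_single_protein(self, small_dataset, tiny_config):
        one = small_dataset.subset([0])
        params = train(one, tiny_config,
                       TrainConfig(epochs=500, seed=0, patience=0))
        pred = predict_dataset(params, tiny_config, one)[0]
        assert abs(pred - one.targets[0]) < 0.05

    def test_loss_trend_non_increasing(self, small_dataset, tiny_config):
        log = []
        train(small_dataset, tiny_config,
              TrainConfig(epochs=40, seed=0, patience=0), log=log)
        rmse = np.array([e["train_rmse"] for e in log])
        smoothed = np.convolve(rmse, np.ones(5) / 5, mode="valid")
        assert smoothed[-1] < smoothed[0]

    def test_fixed_seed_reproducible(self, small_dataset, tiny_config):
        tcfg = TrainConfig(epochs=5, seed=9)
        a = train(small_dataset, tiny_config, tcfg)
        b = train(small_dataset, tiny_config, tcfg)
        for x, y in zip(a.to_flat_list(), b.to_flat_list()):
            assert np.array_equal(x, y)

    def test_training_log_written(self, small_dataset, tiny_config, tmp_path):
        import json
        path = tmp_path / "log.jsonl"
        train(small_dataset, tiny_config, TrainConfig(epochs=3, seed=0),
              log_path=path)
        entries = [json.loads(l) for l in path.read_text().splitlines()]
        assert [e["epoch"] for e in entries] == [0, 1, 2]

    def test_empty_dataset_rejected(self, tiny_config):
        with pytest.raises(ValueError, match="empty"):
            train(SolubilityDataset([]), tiny_config, TrainConfig())


def _dummy_dataset(n):
    """Identifier-only dataset; graphs are unused by split/fold logic."""
    from contactsol.features import NodeFeatureMatrix
    from contactsol.graphs import EdgeScheme, ProteinGraph
    g = ProteinGraph(NodeFeatureMatrix(np.zeros((3, 2)), ("AAPHY7",)),
                     np.zeros((3, 3)), EdgeScheme())
    return SolubilityDataset([(g, 0.5, f"p{i}") for i in range(n)])


class TestSplitting:
    def test_esol_sized_split(self):
        train_ds, test_ds = split_dataset(_dummy_dataset(2737), 0.75, seed=0)
        assert (len(train_ds), len(test_ds)) == (2052, 685)

    def test_floor_rule(self):
        train_ds, test_ds = split_dataset(_dummy_dataset(10), 0.75, seed=1)
        assert (len(train_ds), len(test_ds)) == (7, 3)

    def test_full_fraction_boundary(self):
        train_ds, test_ds = split_dataset(_dummy_dataset(5), 1.0, seed=0)
        assert len(train_ds) == 5 and len(test_ds) == 0

    def test_disjoint_and_exhaustive(self):
        ds = _dummy_dataset(50)
        train_ds, test_ds = split_dataset(ds, 0.6, seed=3)
        ids = set(train_ds.identifiers) | set(test_ds.identifiers)
        assert len(set(train_ds.identifiers) & set(test_ds.identifiers)) == 0
        assert ids == set(ds.identifiers)

    def test_fold_sizes_balanced(self):
        folds = _fold_indices(103, 5, seed=0)
        assert sorted(len(f) for f in folds) == [20, 20, 21, 21, 21]
        # remainder goes to the first n mod k folds
        assert [len(f) for f in folds] == [21, 21, 21, 20, 20]

    @pytest.mark.parametrize("n,k", [(23, 5), (5, 5), (40, 4)])
    def test_folds_partition_for_every_seed(self, n, k):
        for seed in range(3):
            folds = _fold_indices(n, k, seed)
            joined = np.concatenate(folds)
            assert sorted(joined) == list(range(n))


class TestCrossValidate:
    def test_k_times_seeds_models_and_loo_boundary(self, small_cohort, tiny_config):
        from contactsol.graphs import EdgeScheme
        from contactsol.synthetic import build_dataset
        dataset, _ = build_dataset(small_cohort[:5], EdgeScheme())
        result = cross_validate(dataset, tiny_config,
                                TrainConfig(epochs=2, seed=0),
                                k=5, n_seed_repeats=2)
        assert len(result.models) == 10
        assert len(result.table) == 10
        agg = result.aggregate()
        assert "mean" in agg.columns and "std" in agg.columns
        # recomputable aggregate
        assert agg.loc["rmse", "mean"] == pytest.approx(result.table["rmse"].mean())

    def test_too_few_records_rejected(self, small_dataset, tiny_config):
        with pytest.raises(ValueError, match="at least"):
            cross_validate(small_dataset.subset([0, 1]), tiny_config,
                           TrainConfig(epochs=1), k=5)


class TestEnsemble:
    def test_mean_of_two_known_outputs(self, small_dataset, tiny_config):
        g = small_dataset.records[0][0]
        lo = init_parameters(tiny_config, seed=0)
        hi = init_parameters(tiny_config, seed=0)
        # force specific member outputs via the head bias
        lo.head_weights[-1][:] = 0
        hi.head_weights[-1][:] = 0
        lo.head_biases[-1][:] = np.log(0.2 / 0.8)
        hi.head_biases[-1][:] = np.log(0.6 / 0.4)
        out = ensemble_predict([lo, hi], g, tiny_config)
        assert out == pytest.approx(0.4, abs=1e-12)

    def test_identical_members_equal_single(self, small_dataset, tiny_config):
        from contactsol.model import predict_solubility
        g = small_dataset.records[0][0]
        params = init_parameters(tiny_config, seed=2)
        single = predict_solubility(g, params, tiny_config)
        assert ensemble_predict([params] * 5, g, tiny_config) == pytest.approx(single)

    def test_ensemble_rmse_not_worse_than_worst_member(self, small_dataset, tiny_config):
        members = [train(small_dataset, tiny_config,
                         TrainConfig(epochs=5, seed=s)) for s in range(3)]
        y = small_dataset.targets
        member_rmses, preds = [], []
        for m in members:
            p = predict_dataset(m, tiny_config, small_dataset)
            preds.append(p)
            member_rmses.append(np.sqrt(np.mean((p - y) ** 2)))
        ens = np.mean(preds, axis=0)
        ens_rmse = np.sqrt(np.mean((ens - y) ** 2))
        assert ens_rmse <= max(member_rmses) + 1e-12

    def test_empty_ensemble_rejected(self, small_dataset, tiny_config):
        with pytest.raises(ValueError, match="at least one"):
            ensemble_predict([], small_dataset.records[0][0], tiny_config)


class TestMetrics:
    def test_contingency_example(self):
        # TP=3 FP=1 FN=1 TN=5 at threshold 0.5
        actual = np.array([0.9, 0.8, 0.7, 0.6, 0.1, 0.2, 0.3, 0.2, 0.1, 0.4])
        predicted = np.array([0.9, 0.8, 0.7, 0.4, 0.6, 0.2, 0.3, 0.2, 0.1, 0.4])
        m = compute_metrics(predicted, actual)
        assert (m.tp, m.fp, m.fn, m.tn) == (3, 1, 1, 5)
        assert m.precision == 0.75 and m.recall == 0.75
        assert m.f1 == pytest.approx(0.75)
        assert m.accuracy == pytest.approx(0.8)

    def test_perfect_predictor(self):
        y = np.array([0.1, 0.6, 0.8, 0.3])
        m = compute_metrics(y, y)
        assert m.rmse == 0 and m.r2 == 1 and m.f1 == 1 and m.auc == 1

    def test_f1_is_harmonic_mean(self, rng):
        predicted = rng.uniform(size=50)
        actual = rng.uniform(size=50)
        m = compute_metrics(predicted, actual)
        if m.precision + m.recall > 0:
            assert m.f1 == pytest.approx(
                2 * m.precision * m.recall / (m.precision + m.recall))
        assert m.tp + m.fp + m.tn + m.fn == 50

    @pytest.mark.parametrize("n", [10, 50, 200])
    def test_auc_matches_mann_whitney_oracle(self, n):
        rng = np.random.default_rng(n)
        scores = np.round(rng.uniform(size=n), 2)  # rounded: forces ties
        actual = rng.uniform(size=n)
        m = compute_metrics(scores, actual)
        oracle = auc_mann_whitney(scores, actual >= 0.5)
        assert m.auc == pytest.approx(oracle, abs=1e-12)

    def test_constant_actuals_flag_r2(self):
        with pytest.warns(UserWarning, match="zero variance"):
            m = compute_metrics(np.array([0.6, 0.7]), np.array([0.6, 0.6]))
        assert np.isnan(m.r2)

    def test_no_predicted_positives_warns(self):
        with pytest.warns(UserWarning, match="no predicted positives"):
            m = compute_metrics(np.array([0.1, 0.2, 0.3]),
                                np.array([0.9, 0.8, 0.2]))
        assert m.precision == 0.0


class TestThresholdSweep:
    def test_zero_threshold_full_recall(self, rng):
        predicted = rng.uniform(size=30)
        actual = rng.uniform(size=30)
        out = threshold_sweep(predicted, actual, [0.0, 0.5])
        row = out["table"].iloc[0]
        assert row["recall"] == 1.0  # everything called soluble

    def test_default_threshold_row_matches_compute_metrics(self, rng):
        predicted, actual = rng.uniform(size=40), rng.uniform(size=40)
        out = threshold_sweep(predicted, actual, [0.5])
        expected = compute_metrics(predicted, actual).to_dict()
        got = out["table"].iloc[0].to_dict()
        for key, val in expected.items():
            assert got[key] == pytest.approx(val)
        assert out["roc"] is not None and out["pr"] is not None

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(123)
        predicted, actual = rng.uniform(size=1000), rng.uniform(size=1000)
        m = compute_metrics(predicted, actual)
        assert abs(m.auc - 0.5) < 0.05

    def test_out_of_range_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="0, 1"):
            threshold_sweep(rng.uniform(size=5), rng.uniform(size=5), [1.5])
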