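"""Metrics, AUC, repeated k-fold / LOO protocols, window search, profiles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import glypre as g
from glypre.evaluation import ConfusionCounts
from glypre.pipeline import fit_fold


# ---------------------------------------------------------------------------
# Scalar metrics


def metrics_oracle(y_true, y_pred):
    """Recompute Sen/Spe/Acc/MCC directly from the label vectors."""
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
    n = len(y_true)
    sen = tp / (tp + fn) if tp + fn else 0.0
    spe = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / n
    d = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(d) if d else 0.0
    return {"sen": sen, "spe": spe, "acc": acc, "mcc": mcc}


class TestMetrics:
    def test_hand_worked_counts(self):
        out = g.metrics_from_counts(ConfusionCounts(TP=9, FN=2, TN=8, FP=1))
        assert out["sen"] == pytest.approx(0.8182, abs=5e-5)
        assert out["spe"] == pytest.approx(0.8889, abs=5e-5)
        assert out["acc"] == pytest.approx(0.85)
        assert out["mcc"] == pytest.approx(70 / np.sqrt(9900), abs=1e-12)

    def test_perfect_prediction(self):
        out = g.metrics_from_counts(ConfusionCounts(TP=5, TN=10, FP=0, FN=0))
        assert out == {"sen": 1.0, "spe": 1.0, "acc": 1.0, "mcc": 1.0}

    def test_no_true_positives_with_positives_present(self):
        out = g.metrics_from_counts(ConfusionCounts(TP=0, FN=5, TN=10, FP=0))
        assert out["sen"] == 0.0
        assert out["mcc"] == 0.0  # a zero factor under the root

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            g.metrics_from_counts(ConfusionCounts(0, 0, 0, 0))

    def test_agrees_with_label_vector_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(1, 30))
            y_true = rng.integers(0, 2, size=n)
            y_pred = rng.integers(0, 2, size=n)
            counts = ConfusionCounts.from_predictions(y_true, y_pred)
            assert counts.n == n
            got = g.metrics_from_counts(counts)
            want = metrics_oracle(y_true, y_pred)
            for key in want:
                assert got[key] == pytest.approx(want[key], abs=1e-12)


# ---------------------------------------------------------------------------
# AUC


def auc_oracle(scores, labels):
    """Exhaustive concordant-pair fraction with half-credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p, q in itertools.product(pos, neg):
        total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([0.9, 0.8, 0.7, 0.1], [1, 1, 0, 0], 1.0),
            ([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0], 0.75),
            ([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0], 0.5),
        ],
    )
    def test_hand_cases(self, scores, labels, expected):
        assert g.auc_score(scores, labels) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            g.auc_score([0.1, 0.9], [1, 1])

    @given(st.integers(0, 2 ** 16 - 1))
    def test_equals_exhaustive_pair_counting_up_to_n_12(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        labels = rng.integers(0, 2, size=n)
        if len(np.unique(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        # Coarse grid of score values to force ties regularly.
        scores = rng.choice([0.1, 0.25, 0.5, 0.75, 0.9], size=n)
        assert g.auc_score(scores, labels) == pytest.approx(
            auc_oracle(scores, labels), abs=1e-12)


# ---------------------------------------------------------------------------
# Cross-validation protocols (tiny corpus)


FAST = g.PipelineConfig()


class TestRepeatedKFold:
    def test_deterministic_given_base_seed(self, tiny_setup):
        _, _, encoded = tiny_setup
        a = g.repeated_kfold(encoded, FAST, k=3, repeats=2, base_seed=9)
        b = g.repeated_kfold(encoded, FAST, k=3, repeats=2, base_seed=9)
        assert a.mean == b.mean and a.sd == b.sd

    def test_sd_is_zero_for_single_repeat(self, tiny_setup):
        _, _, encoded = tiny_setup
        rep = g.repeated_kfold(encoded, FAST, k=3, repeats=1, base_seed=0)
        assert all(v == 0.0 for v in rep.sd.values())
        assert set(rep.mean) == {"sen", "spe", "acc", "mcc", "auc"}

    def test_stratified_fold_sizes(self):
        from glypre.evaluation import _stratified_folds

        y = np.array([1] * 210 + [0] * 420)
        folds = _stratified_folds(y, 10, seed=0)
        for _, test in folds:
            assert len(test) == 63
            assert np.sum(y[test] == 1) == 21

    def test_report_serialization(self, tiny_setup, tmp_path):
        _, _, encoded = tiny_setup
        rep = g.repeated_kfold(encoded, FAST, k=3, repeats=2, base_seed=0)
        rep.to_json(tmp_path / "m.json")
        rep.to_tsv(tmp_path / "m.tsv")
        back = pd.read_csv(tmp_path / "m.tsv", sep="\t")
        assert len(back) == 2

    def test_no_leakage_on_pure_noise(self, aaindex_table):
        """Honest per-fold selection keeps null AUC at chance; global
        selection on the same data inflates it."""
        from glypre.synthetic_data import MotifSpec, SyntheticConfig, generate_corpus

        corpus = generate_corpus(
            SyntheticConfig(n_proteins=25, positives_per_protein=2,
                            length_range=(200, 260), helix_bias=0.0, seed=21),
            MotifSpec(effect_size=0.0),
        )
        ds = g.build_dataset(corpus.proteins, corpus.annotations, 31, 2.0,
                             seed=21)
        encoded = g.prepare_corpus(corpus.proteins, ds, corpus.profiles,
                                   aaindex_table, g.EncoderConfig())
        honest = g.repeated_kfold(encoded, g.PipelineConfig(), k=5,
                                  repeats=3, base_seed=1)
        assert abs(honest.mean["auc"] - 0.5) <= 0.15


class TestLOO:
    def test_n_predictions_and_determinism(self, aaindex_table):
        from glypre.synthetic_data import SyntheticConfig, generate_corpus

        corpus = generate_corpus(
            SyntheticConfig(n_proteins=4, positives_per_protein=2,
                            length_range=(220, 280), seed=2))
        ds = g.build_dataset(corpus.proteins, corpus.annotations, 31, 2.0,
                             seed=2)
        encoded = g.prepare_corpus(corpus.proteins, ds, corpus.profiles,
                                   aaindex_table, g.EncoderConfig())
        rep = g.loo_cv(encoded, FAST, seed=0)
        assert rep.k == len(encoded) == 24
        assert rep.n_repeats == 1
        again = g.loo_cv(encoded, FAST, seed=0)
        assert rep.mean == again.mean


class TestWindowSearch:
    def test_singleton_grid_and_table_shape(self, tiny_setup, aaindex_table):
        corpus, dataset, _ = tiny_setup
        best, table = g.optimize_window_sizes(
            corpus.proteins, dataset, corpus.profiles, aaindex_table,
            grid=[11], k=3, seed=0)
        assert best == {"pssf": 11, "ss": 11, "aaindex": 11, "cksaap": 11}
        assert len(table) == 4  # |grid| x 4 groups

    def test_even_window_rejected(self, tiny_setup, aaindex_table):
        corpus, dataset, _ = tiny_setup
        with pytest.raises(ValueError, match="odd"):
            g.optimize_window_sizes(corpus.proteins, dataset, corpus.profiles,
                                    aaindex_table, grid=[12])

    def test_empty_grid_rejected(self, tiny_setup, aaindex_table):
        corpus, dataset, _ = tiny_setup
        with pytest.raises(ValueError, match="empty"):
            g.optimize_window_sizes(corpus.proteins, dataset, corpus.profiles,
                                    aaindex_table, grid=[])


# ---------------------------------------------------------------------------
# Positional profiles


class TestPositionalProfiles:
    def test_pure_column_conservation(self, micro):
        ds = g.LabelledDataset(
            micro.positive_windows + micro.negative_windows,
            [1] * 4 + [0] * 2, 0.5, 0)
        prof = g.positional_profiles(micro.proteins, ds, property="conservation_M",
                                     window=5)
        pos_m1 = prof[(prof["class"] == "positive") & (prof.position == -1)]
        neg_m1 = prof[(prof["class"] == "negative") & (prof.position == -1)]
        assert pos_m1.value.iloc[0] == pytest.approx(19.0)
        assert pos_m1.value.iloc[0] > neg_m1.value.iloc[0]

    def test_ss_frequencies_sum_to_one_per_position_and_class(self, micro):
        ds = g.LabelledDataset(
            micro.positive_windows + micro.negative_windows,
            [1] * 4 + [0] * 2, 0.5, 0)
        prof = g.positional_profiles(micro.proteins, ds, micro.profiles,
                                     property="ss_frequency", window=5)
        sums = prof.groupby(["position", "class"]).value.sum()
        in_chain = sums[sums > 0]
        np.testing.assert_allclose(in_chain.values, 1.0)

    def test_aaindex_means_are_classwise_and_finite(self, micro, aaindex_table):
        ds = g.LabelledDataset(
            micro.positive_windows + micro.negative_windows,
            [1] * 4 + [0] * 2, 0.5, 0)
        prof = g.positional_profiles(micro.proteins, ds, table=aaindex_table,
                                     property="aaindex_mean", window=5)
        # 5 positions x 2 classes x 20 accessions
        assert len(prof) == 200
        assert prof.accession.nunique() == 20
        assert np.isfinite(prof.value).all()

    def test_unknown_property_rejected(self, micro):
        ds = g.LabelledDataset(micro.positive_windows + micro.negative_windows,
                               [1] * 4 + [0] * 2, 0.5, 0)
        with pytest.raises(ValueError, match="unknown property"):
            g.positional_profiles(micro.proteins, ds, property="banana")


# ---------------------------------------------------------------------------
# Leakage instrumentation


class TestStandardizationLeak:
    def test_scaler_statistics_come_from_training_rows_only(self, tiny_setup):
        _, _, encoded = tiny_setup
        train = np.arange(0, len(encoded), 2)
        fold = fit_fold(encoded, train, g.PipelineConfig(), seed=0)
        scaler = fold.trained.pipeline.named_steps["scale"]
        np.testing.assert_allclose(scaler.mean_, fold.X[train].mean(axis=0),
                                   atol=1e-12)
        held_out_mean = fold.X.mean(axis=0)
        assert not np.allclose(scaler.mean_, held_out_mean)
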