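"""Splits, training-loop contracts, metric computation."""

import numpy as np
import pytest

from stereoddi.chemio import DDITriple
from stereoddi.contrastive import contrastive_weight
from stereoddi.traineval import (DDIDataset, SplitMode, TrainConfig,
                                 cold_start_split, evaluate,
                                 run_ablation_suite, train, warm_split)


def random_dataset(rng, n_drugs=8, n_triples=20):
    drugs = [f"d{i}" for i in range(n_drugs)]
    registry = {d: "CCO" for d in drugs}
    triples = [DDITriple(drugs[rng.integers(n_drugs)],
                         drugs[rng.integers(n_drugs)],
                         int(rng.integers(1, 4)))
               for _ in range(n_triples)]
    return registry, triples


class TestColdStartSplit:
    def test_hand_routed_example(self):
        registry = {d: "C" for d in "abcd"}
        triples = [DDITriple("a", "b", 1), DDITriple("a", "d", 1),
                   DDITriple("c", "d", 1), DDITriple("b", "c", 1)]
        # find a seed that samples exactly {d} as the new-drug set
        for seed in range(50):
            spec = cold_start_split(triples, registry, fraction=0.25,
                                    seed=seed)
            if spec.g_new == {"d"}:
                break
        assert spec.g_new == {"d"}
        assert spec.partitions["train"] == [DDITriple("a", "b", 1),
                                            DDITriple("b", "c", 1)]
        assert spec.partitions["S1"] == []
        assert spec.partitions["S2"] == [DDITriple("a", "d", 1),
                                         DDITriple("c", "d", 1)]

    def test_partition_algebra_over_random_datasets(self, rng):
        """Union = input multiset, pairwise disjoint, drug sets partition."""
        for trial in range(100):
            registry, triples = random_dataset(
                rng, n_drugs=int(rng.integers(4, 12)),
                n_triples=int(rng.integers(5, 40)))
            fraction = float(rng.uniform(0.1, 0.6))
            spec = cold_start_split(triples, registry, fraction,
                                    seed=int(rng.integers(1000)))
            assert spec.g_new | spec.g_old == set(registry)
            assert spec.g_new & spec.g_old == set()
            parts = spec.partitions
            routed = parts["train"] + parts["S1"] + parts["S2"]
            assert sorted(map(repr, routed)) == sorted(map(repr, triples))
            for t in parts["train"]:
                assert t.drug_a in spec.g_old and t.drug_b in spec.g_old
            for t in parts["S1"]:
                assert t.drug_a in spec.g_new and t.drug_b in spec.g_new
            for t in parts["S2"]:
                assert (t.drug_a in spec.g_new) != (t.drug_b in spec.g_new)

    def test_small_fraction_empties_s1(self, rng):
        registry, triples = random_dataset(rng, n_drugs=20)
        spec = cold_start_split(triples, registry, fraction=0.01, seed=0)
        assert spec.partitions["S1"] == []
        assert spec.partitions["S2"] == []

    def test_deterministic_given_seed(self, rng):
        registry, triples = random_dataset(rng)
        a = cold_start_split(triples, registry, 0.3, seed=9)
        b = cold_start_split(triples, registry, 0.3, seed=9)
        assert a.g_new == b.g_new
        assert a.partitions == b.partitions

    def test_invalid_fraction_rejected(self, rng):
        registry, triples = random_dataset(rng)
        with pytest.raises(ValueError):
            cold_start_split(triples, registry, 1.5, seed=0)


class TestWarmSplit:
    def test_ratios_and_disjointness(self, rng):
        registry, triples = random_dataset(rng, n_triples=100)
        spec = warm_split(triples, seed=3)
        assert spec.mode is SplitMode.warm
        sizes = {k: len(v) for k, v in spec.partitions.items()}
        assert sizes == {"train": 70, "valid": 10, "test": 20}
        everything = sum(spec.partitions.values(), [])
        assert sorted(map(repr, everything)) == sorted(map(repr, triples))


@pytest.fixture(scope="module")
def trained(tiny_dataset):
    registry, triples = tiny_dataset
    dataset = DDIDataset(registry, triples)
    config = TrainConfig(epochs=2, seed=42, batch_size=32)
    network, history = train(config, dataset)
    return network, history, dataset, config


class TestTraining:
    def test_two_epoch_history(self, trained):
        _, history, _, _ = trained
        assert len(history) == 2
        assert {"loss_main", "loss_contrast", "gamma", "tau",
                "lr"} <= set(history.columns)

    def test_same_seed_reproduces_history_exactly(self, tiny_dataset):
        registry, triples = tiny_dataset
        config = TrainConfig(epochs=2, seed=11, batch_size=32)
        _, h1 = train(config, DDIDataset(registry, triples))
        _, h2 = train(config, DDIDataset(registry, triples))
        assert np.array_equal(h1["loss_main"].values, h2["loss_main"].values)
        assert abs(h1["loss_main"].iloc[-1] - h2["loss_main"].iloc[-1]) < 1e-6

    def test_gamma_column_matches_annealing_schedule(self, trained):
        _, history, _, config = trained
        for _, row in history.iterrows():
            expected = contrastive_weight(row["epoch"], config.gamma0,
                                          config.annealing_T)
            assert row["gamma"] == pytest.approx(expected, abs=1e-12)

    def test_ablation_flags_are_strict(self, tiny_dataset):
        """wo_3d + wo_contrast flags applied jointly equal the combined
        variant (identical histories)."""
        registry, triples = tiny_dataset
        cfg = TrainConfig(epochs=2, seed=3, batch_size=32, use_3d=False,
                          use_contrast=False)
        _, h1 = train(cfg, DDIDataset(registry, triples))
        _, h2 = train(cfg, DDIDataset(registry, triples))
        assert np.array_equal(h1["loss_main"].values, h2["loss_main"].values)
        assert (h1["loss_contrast"] == 0).all()


class TestEvaluate:
    def test_untrained_model_near_chance(self, tiny_dataset):
        registry, triples = tiny_dataset
        dataset = DDIDataset(registry, triples)
        config = TrainConfig(epochs=0, seed=0)
        network, _ = train(config, dataset)
        # repeat over several corruption seeds to stabilise the estimate
        aurocs = [evaluate(network, triples, dataset, seed=s).auroc
                  for s in range(5)]
        assert 0.3 < float(np.mean(aurocs)) < 0.7

    def test_perfect_scores_give_perfect_metrics(self):
        from sklearn.metrics import (accuracy_score, average_precision_score,
                                     f1_score, roc_auc_score)
        labels = np.array([1, 1, 0, 0])
        scores = np.array([5.0, 4.0, -4.0, -5.0])
        preds = (1 / (1 + np.exp(-scores)) >= 0.5).astype(int)
        assert roc_auc_score(labels, scores) == 1.0
        assert average_precision_score(labels, scores) == 1.0
        assert accuracy_score(labels, preds) == 1.0
        assert f1_score(labels, preds) == 1.0

    def test_auroc_matches_rank_sum_formula(self):
        """Mann–Whitney identity on a hand-built score list."""
        from sklearn.metrics import roc_auc_score
        labels = np.array([1, 0, 1, 0])
        scores = np.array([0.9, 0.8, 0.3, 0.1])
        # pairs (pos > neg): (0.9>0.8), (0.9>0.1), (0.3<0.8), (0.3>0.1) -> 3/4
        assert roc_auc_score(labels, scores) == pytest.approx(0.75)

    def test_empty_triples_rejected(self, tiny_dataset):
        registry, triples = tiny_dataset
        dataset = DDIDataset(registry, triples)
        network, _ = train(TrainConfig(epochs=0, seed=0), dataset)
        with pytest.raises(ValueError):
            evaluate(network, [], dataset)


class TestAblationSuite:
    def test_one_row_per_variant_full_first(self, tiny_dataset):
        registry, triples = tiny_dataset
        dataset = DDIDataset(registry, triples)
        config = TrainConfig(epochs=1, seed=2, batch_size=32)
        dataset.prepare(config.seed)
        table = run_ablation_suite(config, dataset, triples[:15],
                                   triples[15:],
                                   variants=["full", "wo_3d", "wo_DFE"])
        assert list(table.index) == ["full", "wo_3d", "wo_DFE"]
        assert {"ACC", "AUROC", "AP", "F1"} <= set(table.columns)
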