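import itertools

import numpy as np
import pytest

from pygleason import LevelConfig, NODE_SPLITS, OracleClassifier
from pygleason.cascade import (
    CascadeNodeSpec,
    LevelCascade,
    TuningConfig,
    balance_training_set,
    load_level_cascade,
    make_node_dataset,
    patches_to_float,
    save_level_cascade,
    train_level_cascade,
    train_node,
)
from pygleason.tiling import extract_window, selection_records


class TestNodeSpecs:
    def test_splits_match_hierarchy(self):
        assert NODE_SPLITS[1] == ((1, 2), (3, 4, 5))
        assert NODE_SPLITS[2] == ((1,), (2,))
        assert NODE_SPLITS[3] == ((3,), (4, 5))
        assert NODE_SPLITS[4] == ((4,), (5,))

    def test_splits_disjoint_and_exhaustive(self):
        for neg, pos in NODE_SPLITS.values():
            assert not set(neg) & set(pos)
        assert set(NODE_SPLITS[1][0]) | set(NODE_SPLITS[1][1]) == {1, 2, 3, 4, 5}
        assert set(NODE_SPLITS[2][0]) | set(NODE_SPLITS[2][1]) == set(NODE_SPLITS[1][0])
        assert set(NODE_SPLITS[3][0]) | set(NODE_SPLITS[3][1]) == set(NODE_SPLITS[1][1])
        assert set(NODE_SPLITS[4][0]) | set(NODE_SPLITS[4][1]) == set(NODE_SPLITS[3][1])

    def test_bad_node_id(self):
        with pytest.raises(ValueError):
            CascadeNodeSpec(5, 100)


class _StubNet:
    """Fixed-probability stand-in for a trained TinyConvNet."""

    def __init__(self, p_pos: float):
        self.p_pos = p_pos

    def predict_proba(self, x):
        n = len(x)
        return np.tile([1 - self.p_pos, self.p_pos], (n, 1))


def _stub_cascade(p1, p2, p3, p4, size=8):
    nodes = {
        i + 1: type("N", (), {"predict_proba": _StubNet(p).predict_proba, "net": None})()
        for i, p in enumerate((p1, p2, p3, p4))
    }
    return LevelCascade(input_size=size, nodes=nodes)


class TestRouting:
    @pytest.mark.parametrize(
        "probs,expected",
        [
            ((0.1, 0.1, 0.5, 0.5), 1),
            ((0.1, 0.9, 0.5, 0.5), 2),
            ((0.9, 0.5, 0.1, 0.5), 3),
            ((0.9, 0.5, 0.9, 0.1), 4),
            ((0.9, 0.5, 0.9, 0.9), 5),
        ],
    )
    def test_tree_paths(self, probs, expected):
        cascade = _stub_cascade(*probs)
        x = np.zeros((3, 8, 8, 3), dtype=np.float32)
        assert (cascade.classify(x) == expected).all()

    def test_routing_completeness(self):
        # every hard-decision pattern of the four nodes yields one label in 1..5
        seen = set()
        for bits in itertools.product([0.05, 0.95], repeat=4):
            label = int(_stub_cascade(*bits).classify(np.zeros((1, 8, 8, 3)))[0])
            assert label in {1, 2, 3, 4, 5}
            seen.add(label)
        assert seen == {1, 2, 3, 4, 5}

    def test_path_product_agrees_on_confident_nodes(self):
        for bits in itertools.product([0.02, 0.98], repeat=4):
            cascade = _stub_cascade(*bits)
            x = np.zeros((1, 8, 8, 3))
            assert cascade.classify(x, routing="argmax")[0] == cascade.classify(
                x, routing="path_product"
            )[0]

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="size"):
            _stub_cascade(0.5, 0.5, 0.5, 0.5, size=16).classify(np.zeros((1, 8, 8, 3)))

    def test_unknown_routing_rejected(self):
        with pytest.raises(ValueError, match="routing"):
            _stub_cascade(0.5, 0.5, 0.5, 0.5).classify(np.zeros((1, 8, 8, 3)), routing="soft")


class TestBalanceTrainingSet:
    def _patches(self, counts):
        return {lab: [np.full((4, 4, 3), lab, np.uint8)] * n for lab, n in counts.items()}

    def test_all_classes_at_rarest_count(self):
        balanced = balance_training_set(
            self._patches({1: 400, 2: 300, 3: 200, 4: 150, 5: 100}), seed=0
        )
        assert {k: len(v) for k, v in balanced.items()} == {k: 100 for k in range(1, 6)}

    def test_already_balanced_unchanged(self):
        balanced = balance_training_set(self._patches({k: 7 for k in range(1, 6)}), seed=0)
        assert all(len(v) == 7 for v in balanced.values())

    def test_deterministic(self):
        pool = {lab: [np.full((2, 2, 3), i, np.uint8) for i in range(20)] for lab in range(1, 6)}
        a = balance_training_set(pool, seed=42)
        b = balance_training_set(pool, seed=42)
        for lab in a:
            for p, q in zip(a[lab], b[lab]):
                np.testing.assert_array_equal(p, q)

    def test_empty_class_error_names_class(self):
        with pytest.raises(ValueError, match="class 4"):
            balance_training_set(self._patches({1: 5, 2: 5, 3: 5, 4: 0, 5: 5}), seed=0)


class TestMakeNodeDataset:
    def test_node2_sees_only_labels_1_and_2(self):
        balanced = {lab: [np.full((4, 4, 3), lab * 10, np.uint8)] * 3 for lab in range(1, 6)}
        x, y = make_node_dataset(balanced, CascadeNodeSpec(2, 4))
        assert len(x) == 6
        assert sorted(np.unique(y)) == [0, 1]
        # the node-2 inputs come only from the label-1/2 pools
        raw = np.unique((x + 0.5) * 255.0)
        np.testing.assert_allclose(sorted(raw), [10, 20], atol=0.5)

    def test_empty_side_rejected(self):
        balanced = {4: [np.zeros((4, 4, 3), np.uint8)]}
        with pytest.raises(ValueError, match="empty"):
            make_node_dataset(balanced, CascadeNodeSpec(4, 4))


class TestOracleClassifier:
    def test_homogeneous_window(self):
        win = np.full((10, 10), 3, np.uint8)
        assert OracleClassifier().classify_windows([win])[0] == 3

    def test_no_tissue_falls_back_to_1(self):
        assert OracleClassifier().classify_windows([np.zeros((5, 5), np.uint8)])[0] == 1

    def test_matches_algorithm1_labels_on_selected_patches(self, small_slide):
        # with the oracle backend, classification equals the training label
        oracle = OracleClassifier()
        lm = small_slide.label_map
        for rec in selection_records(small_slide, LevelConfig(50)):
            if rec.selected:
                win = extract_window(lm, rec.ref.origin, 50, 0)
                assert oracle.classify_windows([win])[0] == rec.mv


def _toy_balanced(rng, side=12, n_per_class=14):
    """Five classes with distinct mean colors; trivially learnable."""
    colors = {1: (220, 80, 80), 2: (80, 220, 80), 3: (80, 80, 220), 4: (220, 220, 80), 5: (140, 60, 200)}
    out = {}
    for lab, c in colors.items():
        base = np.array(c, np.float64)
        ps = []
        for _ in range(n_per_class):
            noise = rng.normal(scale=10, size=(side, side, 3))
            ps.append(np.clip(base + noise, 0, 255).astype(np.uint8))
        out[lab] = ps
    return out


class TestTrainNode:
    def test_trains_to_high_accuracy_on_toy_textures(self, rng):
        balanced = _toy_balanced(rng)
        tuning = TuningConfig(n_trials=1, epochs=12, patience=12, seed=3,
                              filter_choices=((4,),), fc_choices=(8,), batch_choices=(16,))
        node = train_node(CascadeNodeSpec(1, 12), balanced, tuning)
        assert node.val_accuracy >= 0.9
        assert len(node.history.train_loss) >= 1

    def test_random_search_picks_best_trial(self, rng):
        balanced = _toy_balanced(rng, n_per_class=8)
        tuning = TuningConfig(n_trials=2, epochs=4, patience=4, seed=0,
                              filter_choices=((3,),), fc_choices=(6,), batch_choices=(8,))
        node = train_node(CascadeNodeSpec(4, 12), balanced, tuning)
        assert 0.0 <= node.val_accuracy <= 1.0
        assert set(node.hyperparams) == {"lr", "dropout", "filters", "fc_units", "batch_size"}

    def test_bad_n_trials(self):
        with pytest.raises(ValueError, match="n_trials"):
            TuningConfig(n_trials=0).validate()


class TestSerialization:
    def test_roundtrip_preserves_predictions(self, tmp_path, rng):
        balanced = _toy_balanced(rng, n_per_class=8)
        tuning = TuningConfig(n_trials=1, epochs=3, patience=3, seed=1,
                              filter_choices=((3,),), fc_choices=(6,), batch_choices=(8,))
        cascade = train_level_cascade(12, balanced, tuning)
        desc = save_level_cascade(cascade, tmp_path)
        back = load_level_cascade(desc)
        x = patches_to_float([p for ps in balanced.values() for p in ps])
        np.testing.assert_array_equal(cascade.classify(x), back.classify(x))
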