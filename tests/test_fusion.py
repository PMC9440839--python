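import numpy as np
import pytest

from biodocsim.corpus_io import RelevanceTable
from biodocsim.fusion import (
    FusionNetwork,
    FusionWeights,
    PairTrainingSet,
    build_training_pairs,
    fnn_predict,
    fuse_linear,
    normalize_similarity,
    semantic_similarity_matrix,
    train_fnn,
)
from biodocsim.similarity_matrix import SimilarityMatrix


def _matrix(ids, values):
    return SimilarityMatrix(ids, np.asarray(values, dtype=np.float64))


def _random_matrix(rng, ids):
    n = len(ids)
    a = rng.random((n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return SimilarityMatrix(ids, a)


class TestTrainingPairs:
    @pytest.fixture()
    def setup(self):
        ids = ["a", "b", "c", "d"]
        rng = np.random.default_rng(0)
        rel = RelevanceTable(
            [("a", "T1", "DR"), ("b", "T1", "DR"), ("c", "T1", "PR"), ("d", "T2", "PR")]
        )
        return _random_matrix(rng, ids), _random_matrix(rng, ids), rel

    def test_target_assignment_rules(self, setup):
        sm, swe, rel = setup
        pairs = build_training_pairs(sm, swe, rel)
        by_pair = dict(zip(pairs.doc_pairs, pairs.targets))
        assert by_pair[("a", "b")] == 0.9  # DR+DR same topic
        assert by_pair[("a", "c")] == 0.1  # DR+PR same topic falls to "otherwise"
        assert by_pair[("c", "d")] == 0.1  # PR+PR different topics
        assert len(pairs) == 6  # n(n-1)/2

    def test_pr_pr_same_topic_is_half(self):
        ids = ["x", "y"]
        rel = RelevanceTable([("x", "T", "PR"), ("y", "T", "PR")])
        m = _matrix(ids, [[1, 0.5], [0.5, 1]])
        pairs = build_training_pairs(m, m, rel)
        assert pairs.targets.tolist() == [0.5]

    def test_inputs_taken_from_matrices(self, setup):
        sm, swe, rel = setup
        pairs = build_training_pairs(sm, swe, rel)
        k = pairs.doc_pairs.index(("b", "d"))
        assert pairs.inputs[k, 0] == sm.entry("b", "d")
        assert pairs.inputs[k, 1] == swe.entry("b", "d")

    def test_doc_missing_from_relevance_rejected(self, setup):
        sm, swe, _ = setup
        rel = RelevanceTable([("a", "T1", "DR")])
        with pytest.raises(ValueError, match="missing"):
            build_training_pairs(sm, swe, rel)

    def test_misaligned_matrices_rejected(self, setup):
        sm, _, rel = setup
        other = _matrix(["a", "b"], [[1, 0], [0, 1]])
        with pytest.raises(ValueError, match="aligned"):
            build_training_pairs(sm, other, rel)

    def test_targets_outside_scheme_rejected(self):
        with pytest.raises(ValueError, match="targets"):
            PairTrainingSet(np.array([[0.5, 0.5]]), np.array([0.7]), [("a", "b")])


class TestTraining:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        pairs = PairTrainingSet(
            rng.random((50, 2)), rng.choice([0.9, 0.5, 0.1], size=50), [("a", "b")] * 50
        )
        n1 = train_fnn(pairs, epochs=20, seed=7)
        n2 = train_fnn(pairs, epochs=20, seed=7)
        np.testing.assert_array_equal(n1.w1, n2.w1)
        np.testing.assert_array_equal(n1.w2, n2.w2)
        assert n1.training_meta["loss_curve"] == n2.training_meta["loss_curve"]

    def test_constant_target_converges_to_it(self):
        x = np.full((80, 2), 0.6)
        pairs = PairTrainingSet(x, np.full(80, 0.9), [("a", "b")] * 80)
        net = train_fnn(pairs, epochs=100, seed=0)
        pred = fnn_predict(net, 0.6, 0.6)
        assert abs(pred - 0.9) < 0.05

    def test_loss_never_increases_overall(self):
        rng = np.random.default_rng(2)
        pairs = PairTrainingSet(
            rng.random((100, 2)), rng.choice([0.9, 0.5, 0.1], size=100), [("a", "b")] * 100
        )
        net = train_fnn(pairs, epochs=50, seed=3)
        curve = net.training_meta["loss_curve"]
        assert curve[-1] <= curve[0]

    def test_conflicting_targets_train_without_error(self):
        x = np.full((40, 2), 0.5)
        y = np.array([0.9, 0.1] * 20)
        net = train_fnn(PairTrainingSet(x, y, [("a", "b")] * 40), epochs=30, seed=0)
        assert net.training_meta["loss_curve"][-1] > 0.0

    def test_separable_inputs_keep_class_order(self):
        rng = np.random.default_rng(4)
        xs, ys = [], []
        for t in (0.9, 0.5, 0.1):
            xs.append(np.clip(rng.normal(t, 0.03, size=(60, 2)), 0, 1))
            ys.extend([t] * 60)
        pairs = PairTrainingSet(np.vstack(xs), np.array(ys), [("a", "b")] * 180)
        net = train_fnn(pairs, epochs=100, seed=0)
        p_dr = fnn_predict(net, 0.88, 0.9)
        p_pr = fnn_predict(net, 0.5, 0.52)
        p_nr = fnn_predict(net, 0.12, 0.1)
        assert p_dr > p_pr > p_nr

    def test_round_trip_serialization(self, tmp_path):
        rng = np.random.default_rng(5)
        pairs = PairTrainingSet(
            rng.random((20, 2)), rng.choice([0.9, 0.5, 0.1], size=20), [("a", "b")] * 20
        )
        net = train_fnn(pairs, epochs=5, seed=1)
        f = tmp_path / "net.json"
        net.save(f)
        back = FusionNetwork.load(f)
        np.testing.assert_array_equal(net.w1, back.w1)
        assert fnn_predict(net, 0.3, 0.7) == fnn_predict(back, 0.3, 0.7)


class TestForwardPass:
    def test_output_strictly_in_unit_interval(self):
        rng = np.random.default_rng(6)
        net = FusionNetwork(
            w1=rng.normal(size=(300, 2)), b1=rng.normal(size=300),
            w2=rng.normal(size=(1, 300)), b2=0.3,
        )
        for x in ([0, 0], [1, 1], [0.5, 0.2]):
            p = fnn_predict(net, *x)
            assert 0.0 < p < 1.0

    def test_zero_network_outputs_half(self):
        net = FusionNetwork(
            w1=np.zeros((300, 2)), b1=np.zeros(300), w2=np.zeros((1, 300)), b2=0.0
        )
        assert fnn_predict(net, 0.8, 0.2) == 0.5

    def test_single_hidden_unit_arithmetic_oracle(self):
        """One active hidden unit: sigmoid(w2 * relu(a*x1 + b*x2 + c) + d)."""
        w1 = np.zeros((300, 2)); w1[0] = [2.0, -1.0]
        b1 = np.zeros(300); b1[0] = 0.1
        w2 = np.zeros((1, 300)); w2[0, 0] = 1.5
        net = FusionNetwork(w1=w1, b1=b1, w2=w2, b2=-0.2)
        x1, x2 = 0.6, 0.3
        hidden = max(2.0 * x1 - 1.0 * x2 + 0.1, 0.0)
        expected = 1.0 / (1.0 + np.exp(-(1.5 * hidden - 0.2)))
        assert fnn_predict(net, x1, x2) == pytest.approx(expected, abs=1e-12)

    def test_continuity_under_tiny_perturbation(self):
        rng = np.random.default_rng(8)
        pairs = PairTrainingSet(
            rng.random((30, 2)), rng.choice([0.9, 0.5, 0.1], size=30), [("a", "b")] * 30
        )
        net = train_fnn(pairs, epochs=20, seed=2)
        base = fnn_predict(net, 0.4, 0.6)
        assert abs(fnn_predict(net, 0.4 + 1e-9, 0.6 - 1e-9) - base) < 1e-6


class TestSemanticMatrix:
    def test_equals_per_pair_prediction(self):
        rng = np.random.default_rng(10)
        ids = ["a", "b", "c"]
        sm, swe = _random_matrix(rng, ids), _random_matrix(rng, ids)
        pairs = PairTrainingSet(
            rng.random((10, 2)), rng.choice([0.9, 0.1], size=10), [("x", "y")] * 10
        )
        net = train_fnn(pairs, epochs=5, seed=0)
        out = semantic_similarity_matrix(net, sm, swe)
        out.validate()
        for i in range(3):
            for j in range(3):
                if i == j:
                    assert out.values[i, j] == 1.0
                else:
                    expected = fnn_predict(net, sm.values[i, j], swe.values[i, j])
                    assert out.values[i, j] == pytest.approx(expected, abs=1e-15)

    def test_constant_inputs_give_constant_output(self):
        ids = ["a", "b", "c"]
        ones = _matrix(ids, np.ones((3, 3)))
        net = FusionNetwork(
            w1=np.ones((300, 2)), b1=np.zeros(300), w2=np.full((1, 300), 0.01), b2=0.0
        )
        out = semantic_similarity_matrix(net, ones, ones)
        off = out.values[~np.eye(3, dtype=bool)]
        assert np.all(off == off[0])

    def test_misaligned_ids_rejected(self):
        a = _matrix(["x", "y"], np.eye(2))
        b = _matrix(["x", "z"], np.eye(2))
        net = FusionNetwork(np.zeros((300, 2)), np.zeros(300), np.zeros((1, 300)), 0.0)
        with pytest.raises(ValueError, match="aligned"):
            semantic_similarity_matrix(net, a, b)


class TestNormalization:
    def test_minmax_affine_map(self):
        m = _matrix(
            ["a", "b", "c"],
            [[1.0, 0.2, 0.4], [0.2, 1.0, 0.6], [0.4, 0.6, 1.0]],
        )
        out = normalize_similarity(m)
        assert out.entry("a", "b") == 0.0
        assert out.entry("a", "c") == pytest.approx(0.5)
        assert out.entry("b", "c") == 1.0
        assert np.all(np.diag(out.values) == 1.0)

    def test_idempotent_on_spanning_matrix(self):
        m = _matrix(["a", "b", "c"], [[1, 0, 0.5], [0, 1, 1], [0.5, 1, 1]])
        out = normalize_similarity(m)
        np.testing.assert_array_equal(out.values, m.values)

    def test_constant_off_diagonal_maps_to_zero(self):
        m = _matrix(["a", "b", "c"], np.full((3, 3), 0.7) + 0.3 * np.eye(3))
        out = normalize_similarity(m)
        assert np.all(out.values[~np.eye(3, dtype=bool)] == 0.0)

    def test_sumnorm_lands_in_unit_interval(self):
        rng = np.random.default_rng(11)
        m = _random_matrix(rng, list("abcde"))
        out = normalize_similarity(m, method="sumnorm")
        out.validate()
        off = out.values[~np.eye(5, dtype=bool)]
        assert off.min() == 0.0 and off.max() == 1.0

    def test_single_doc_rejected(self):
        with pytest.raises(ValueError):
            normalize_similarity(_matrix(["a"], [[1.0]]))


class TestLinearFusion:
    @pytest.fixture()
    def mats(self):
        rng = np.random.default_rng(12)
        ids = list("abcd")
        return _random_matrix(rng, ids), _random_matrix(rng, ids)

    def test_w_zero_reproduces_semantic_exactly(self, mats):
        con, sem = mats
        out = fuse_linear(con, sem, 0.0)
        np.testing.assert_array_equal(out.values, sem.values)

    def test_w_one_reproduces_content_exactly(self, mats):
        con, sem = mats
        out = fuse_linear(con, sem, 1.0)
        np.testing.assert_array_equal(out.values, con.values)

    def test_pointwise_arithmetic(self):
        con = _matrix(["a", "b"], [[1.0, 0.5], [0.5, 1.0]])
        sem = _matrix(["a", "b"], [[1.0, 0.3], [0.3, 1.0]])
        out = fuse_linear(con, sem, FusionWeights(0.7))
        assert out.entry("a", "b") == pytest.approx(0.44, abs=1e-12)

    def test_affine_in_w(self, mats):
        con, sem = mats
        f0 = fuse_linear(con, sem, 0.0).values
        f1 = fuse_linear(con, sem, 1.0).values
        for w in (0.0, 0.25, 0.5, 1.0):
            fw = fuse_linear(con, sem, w).values
            np.testing.assert_allclose(fw, f0 + w * (f1 - f0), atol=1e-12)

    def test_result_between_inputs(self, mats):
        con, sem = mats
        out = fuse_linear(con, sem, 0.3).values
        lo = np.minimum(con.values, sem.values)
        hi = np.maximum(con.values, sem.values)
        assert np.all(out >= lo - 1e-12) and np.all(out <= hi + 1e-12)

    def test_weight_out_of_range_rejected(self, mats):
        con, sem = mats
        with pytest.raises(ValueError):
            fuse_linear(con, sem, 1.5)
        with pytest.raises(ValueError):
            FusionWeights(-0.1)
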