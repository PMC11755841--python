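"""Joint training: scores, loss, sampling, gradients and fit behaviour."""

import math

import numpy as np
import pytest

from jeli.datasets import make_synthetic_dataset
from jeli.kg import build_knowledge_graph
from jeli.metrics import auc
from jeli.model import (
    JELIModel,
    JELIParams,
    _mure_backward,
    _mure_forward,
    _rhofm_pair_backward,
    _rhofm_pair_forward,
    edge_score,
    margin_ranking_loss,
    mure_score,
    sample_negatives,
    train_test_split_cells,
)
from jeli.rhofm import RHOFMParams


class TestMuRE:
    def test_exact_translation_scores_zero(self, rng):
        e_h, e_r = rng.normal(size=3), rng.normal(size=3)
        assert mure_score(e_h, e_r, e_h - e_r, np.eye(3)) == pytest.approx(0.0)

    def test_hand_example(self):
        score = mure_score([1.0, 2.0], [1.0, 0.0], [0.0, 1.0],
                           np.diag([2.0, 1.0]), 0.5, 0.5)
        assert score == pytest.approx(-1.0)

    def test_affine_in_biases(self, rng):
        e_h, e_r, e_t = (rng.normal(size=2) for _ in range(3))
        R = rng.normal(size=(2, 2))
        base = mure_score(e_h, e_r, e_t, R, 0.0, 0.0)
        assert mure_score(e_h, e_r, e_t, R, 1.3, 1.3) == pytest.approx(base + 2.6)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mure_score(np.ones(2), np.ones(3), np.ones(2), np.eye(2))


def _toy_params(rng, F=3, d=2):
    return JELIParams(
        rhofm=RHOFMParams(W=rng.normal(size=(F, d)), omega0=rng.normal()),
        rel_matrices={"item-sim": rng.normal(size=(d, d))},
        rel_embeddings={"item-sim": rng.normal(size=d)},
        entity_biases={"i1": 0.2, "i2": -0.1},
    )


class TestEdgeScore:
    def test_signed_antisymmetry(self, rng):
        params = _toy_params(rng)
        feats = {"i1": rng.normal(size=3), "u1": rng.normal(size=3)}
        plus = edge_score(params, "i1", "+", "u1", feats)
        minus = edge_score(params, "i1", "-", "u1", feats)
        assert minus == pytest.approx(-plus)

    def test_zero_structure_reduces_to_intercept(self, rng):
        params = _toy_params(rng)
        params.rhofm.W[:] = 0.0
        feats = {"i1": rng.normal(size=3), "u1": rng.normal(size=3)}
        assert edge_score(params, "i1", "+", "u1", feats) == pytest.approx(
            params.rhofm.omega0
        )

    def test_similarity_score_ignores_unsupported_rows(self, rng):
        # linear structure: rows of W outside the support of both feature
        # vectors cannot influence the MuRE edge score
        params = _toy_params(rng, F=4)
        xa = np.array([1.0, 2.0, 0.0, 0.0])
        xb = np.array([0.5, -1.0, 0.0, 0.0])
        feats = {"i1": xa, "i2": xb}
        before = edge_score(params, "i1", "item-sim", "i2", feats)
        params.rhofm.W[2:] += rng.normal(size=(2, 2))
        assert edge_score(params, "i1", "item-sim", "i2", feats) == pytest.approx(before)

    def test_unknown_relation_rejected(self, rng):
        with pytest.raises(ValueError):
            edge_score(_toy_params(rng), "i1", "likes", "u1", {})


class TestMarginLoss:
    def test_equal_scores_forced_closed_form(self):
        assert margin_ranking_loss([2.0], [2.0]) == pytest.approx(math.log(1 + math.e))

    def test_gap_equal_to_margin_gives_log_two(self):
        assert margin_ranking_loss([3.0], [2.0], margin=1.0) == pytest.approx(math.log(2))

    def test_vanishes_for_dominating_positives(self):
        assert margin_ranking_loss([1e4], [0.0]) == pytest.approx(0.0, abs=1e-12)

    def test_empty_input_and_mismatch(self):
        assert margin_ranking_loss([], []) == 0.0
        with pytest.raises(ValueError):
            margin_ranking_loss([1.0, 2.0], [1.0])

    def test_zero_parameter_initial_loss_closed_form(self):
        # with every score identically zero the loss is #pairs * log(1+e^margin)
        n = 17
        expected = n * math.log(1 + math.exp(1.0))
        assert margin_ranking_loss(np.zeros(n), np.zeros(n)) == pytest.approx(expected)

    def test_strict_paper_sign_flips_orientation(self):
        std = margin_ranking_loss([5.0], [0.0])
        flipped = margin_ranking_loss([5.0], [0.0], strict_paper_sign=True)
        assert flipped > std


class TestNegativeSampling:
    @pytest.fixture()
    def toy_graph(self, rng):
        A = rng.choice([-1, 0, 1], size=(10, 4), p=[0.2, 0.5, 0.3])
        S, P = rng.normal(size=(3, 10)), rng.normal(size=(3, 4))
        return build_knowledge_graph(A, S, P, tau=0.4), S, P

    def test_zero_k_is_empty(self, toy_graph):
        kg, S, P = toy_graph
        assert sample_negatives(kg, S, P, k=0, seed=0) == []

    def test_corruptions_absent_from_graph_and_same_partition(self, toy_graph):
        kg, S, P = toy_graph
        existing = set(kg.triplets)
        parts = kg.partitions
        negs = sample_negatives(kg, S, P, k=2, seed=1)
        assert negs
        for h, r, t in negs:
            assert (h, r, t) not in existing
        by_tail = {(r, t): parts[h] for h, r, t in negs}
        for (h, r, t) in kg.triplets:
            if (r, t) in by_tail:
                assert by_tail[(r, t)] == parts[h]

    def test_corruption_frequencies_uniform(self):
        # one positive triplet, 10-item partition: corruptions should be
        # uniform over the 9 valid items within 3 binomial sd
        A = np.zeros((10, 1))
        A[0, 0] = 1
        S = np.ones((2, 10)) * np.arange(1, 11)
        P = np.ones((2, 1))
        kg = build_knowledge_graph(A, S, P, tau=1.0)
        kg.triplets = [t for t in kg.triplets if t[1] == "+"]
        draws = sample_negatives(kg, S, P, k=10_000, seed=2)
        counts = {}
        for h, _, _ in draws:
            counts[h] = counts.get(h, 0) + 1
        assert "i1" not in counts  # (i1, +, u1) is the true triplet
        n, p = len(draws), 1 / 9
        sd = math.sqrt(n * p * (1 - p))
        for c in counts.values():
            assert abs(c - n * p) < 3 * sd


class TestGradients:
    """Analytic gradients of the batched scores against finite differences."""

    @pytest.mark.parametrize("order", [2, 3])
    def test_rhofm_pair_gradient(self, order):
        rng = np.random.default_rng(order)
        B, F, d = 4, 3, 2
        W = rng.normal(size=(F, d))
        omega1 = np.ones(d)
        omega2m = np.ones(order - 1)
        Xi, Xu = rng.normal(size=(B, F)), rng.normal(size=(B, F))
        w = rng.normal(size=B)

        def total(Wf):
            s, _ = _rhofm_pair_forward(Wf, 0.5, omega1, omega2m, order, Xi, Xu)
            return float(w @ s)

        _, cache = _rhofm_pair_forward(W, 0.5, omega1, omega2m, order, Xi, Xu)
        dW, do0, _, _ = _rhofm_pair_backward(w, cache, W, omega1, omega2m, order, Xi, Xu)
        eps = 1e-6
        for f in range(F):
            for k in range(d):
                Wp, Wm = W.copy(), W.copy()
                Wp[f, k] += eps
                Wm[f, k] -= eps
                num = (total(Wp) - total(Wm)) / (2 * eps)
                assert dW[f, k] == pytest.approx(num, rel=1e-4, abs=1e-6)
        assert do0 == pytest.approx(w.sum())

    def test_fast_and_dp_paths_agree(self):
        rng = np.random.default_rng(7)
        B, F, d = 5, 4, 3
        W = rng.normal(size=(F, d))
        Xi, Xu = rng.normal(size=(B, F)), rng.normal(size=(B, F))
        s_fast, cache_fast = _rhofm_pair_forward(W, 0.1, np.ones(d), np.ones(1), 2, Xi, Xu)
        # force the dynamic-programming path by inflating then slicing order
        s_dp, cache_dp = _rhofm_pair_forward(W, 0.1, np.ones(d), np.array([1.0, 0.0]), 3, Xi, Xu)
        np.testing.assert_allclose(s_fast, s_dp, atol=1e-10)
        w = rng.normal(size=B)
        dW_fast = _rhofm_pair_backward(w, cache_fast, W, np.ones(d), np.ones(1), 2, Xi, Xu)[0]
        dW_dp = _rhofm_pair_backward(w, cache_dp, W, np.ones(d), np.array([1.0, 0.0]), 3, Xi, Xu)[0]
        np.testing.assert_allclose(dW_fast, dW_dp, atol=1e-10)

    def test_mure_gradient(self):
        rng = np.random.default_rng(3)
        B, d = 4, 2
        Eh, Et = rng.normal(size=(B, d)), rng.normal(size=(B, d))
        R = rng.normal(size=(d, d))
        er = rng.normal(size=d)
        w = rng.normal(size=B)

        def total(Ehf, Etf, Rf, erf):
            s, _ = _mure_forward(Ehf, Etf, Rf, erf, np.zeros(B), np.zeros(B))
            return float(w @ s)

        _, u = _mure_forward(Eh, Et, R, er, np.zeros(B), np.zeros(B))
        dEh, dEt, der, dR = _mure_backward(w, u, Eh, R)
        eps = 1e-6
        for arr, grad, name in ((Eh, dEh, "Eh"), (Et, dEt, "Et"), (R, dR, "R")):
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                plus = [Eh.copy(), Et.copy(), R.copy(), er.copy()]
                minus = [Eh.copy(), Et.copy(), R.copy(), er.copy()]
                pos = {"Eh": 0, "Et": 1, "R": 2}[name]
                plus[pos][idx] += eps
                minus[pos][idx] -= eps
                num = (total(*plus) - total(*minus)) / (2 * eps)
                assert grad[idx] == pytest.approx(num, rel=1e-5, abs=1e-7)


@pytest.fixture(scope="module")
def fitted():
    ds = make_synthetic_dataset(F=10, d=2, n_i=50, n_u=50, mask_rate=0.0,
                                sparsity=0.5, seed=21)
    model = JELIModel.from_dataset(ds)
    return ds, model, model.fit(seed=5, epochs=30)


class TestFit:
    def test_loss_decreases_and_settles(self, fitted):
        _, _, res = fitted
        loss = res.loss_history
        start = int(0.2 * len(loss))
        assert loss[-1] < loss[0]
        # the mean loss trends down over the last 80% of epochs: each
        # quarter-block average is below the previous one (minibatch noise
        # allows single-epoch upticks)
        tail = loss[start:]
        blocks = [chunk.mean() for chunk in np.array_split(tail, 4)]
        assert np.all(np.diff(blocks) < 1e-6)
        assert loss[-1] < loss[start]

    def test_separable_toy_reaches_high_auc(self, fitted):
        ds, _, res = fitted
        rep = res.evaluate("test")
        assert rep.auc >= 0.9

    def test_seeded_determinism(self, fitted):
        ds, model, res = fitted
        res2 = model.fit(seed=5, epochs=30)
        np.testing.assert_array_equal(res.params.rhofm.W, res2.params.rhofm.W)
        np.testing.assert_array_equal(
            [res.params.entity_biases[k] for k in sorted(res.params.entity_biases)],
            [res2.params.entity_biases[k] for k in sorted(res2.params.entity_biases)],
        )
        np.testing.assert_array_equal(res.loss_history, res2.loss_history)

    def test_fitted_edge_scores_keep_antisymmetry(self, fitted):
        ds, _, res = fitted
        feats = {"i3": ds.item_features[:, 2], "u4": ds.user_features[:, 3]}
        plus = edge_score(res.params, "i3", "+", "u4", feats)
        assert edge_score(res.params, "i3", "-", "u4", feats) == pytest.approx(-plus)

    def test_summary_mentions_dimensions(self, fitted):
        _, _, res = fitted
        text = res.summary()
        assert "items:" in text and "feature importance" in text

    def test_rejects_empty_association_matrix(self):
        model = JELIModel(np.zeros((4, 4)), np.zeros((2, 4)), np.zeros((2, 4)))
        with pytest.raises(ValueError):
            model.fit(epochs=1)

    def test_rejects_invalid_labels(self):
        with pytest.raises(ValueError, match="cell"):
            JELIModel(np.array([[2]]), np.zeros((1, 1)), np.zeros((1, 1)))


class TestPrediction:
    def test_zero_model_outputs_constant_probability(self, rng):
        from jeli.model import predict_scores

        params = JELIParams(
            rhofm=RHOFMParams(W=np.zeros((3, 2)), omega0=0.7),
            rel_matrices={}, rel_embeddings={}, entity_biases={},
        )
        probs, labels = predict_scores(params, rng.normal(size=(3, 4)), rng.normal(size=(3, 5)))
        np.testing.assert_allclose(probs, 1 / (1 + math.exp(-0.7)))
        assert np.all(labels == 1)

    def test_duplicate_item_column_scores_identically(self, rng):
        params = JELIParams(
            rhofm=RHOFMParams(W=rng.normal(size=(3, 2)), omega0=0.1),
            rel_matrices={}, rel_embeddings={}, entity_biases={},
        )
        from jeli.model import predict_scores

        S = rng.normal(size=(3, 4))
        S2 = np.hstack([S, S[:, :1]])
        probs, _ = predict_scores(params, S2, rng.normal(size=(3, 5)))
        np.testing.assert_allclose(probs[0], probs[-1])

    def test_labels_match_probability_threshold(self, rng):
        params = JELIParams(
            rhofm=RHOFMParams(W=rng.normal(size=(3, 2))),
            rel_matrices={}, rel_embeddings={}, entity_biases={},
        )
        from jeli.model import predict_scores

        probs, labels = predict_scores(params, rng.normal(size=(3, 6)), rng.normal(size=(3, 6)))
        np.testing.assert_array_equal(labels == 1, probs > 0.5)


class TestSplit:
    def test_split_partitions_nonzero_cells(self, rng):
        A = rng.choice([-1, 0, 1], size=(12, 9))
        train, test = train_test_split_cells(A, 0.25, seed=0)
        all_cells = {tuple(c) for c in np.argwhere(A != 0)}
        got = {tuple(c) for c in train} | {tuple(c) for c in test}
        assert got == all_cells
        assert len(test) == round(0.25 * len(all_cells))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            train_test_split_cells(np.zeros((3, 3)), 0.2, seed=0)
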