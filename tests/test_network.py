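import itertools
import math

import numpy as np
import pytest

from gazetag.features import FeatureConfig
from gazetag.network import (
    CRFParams,
    LossWeights,
    LSTMParams,
    TaggerModel,
    bilstm_encode,
    bio_constraint_mask,
    combined_loss,
    crf_log_partition,
    crf_nll,
    crf_nll_grad,
    crf_score,
    lstm_step,
    seg_bce_loss,
    seg_forward,
    viterbi_decode,
)
from gazetag.training import forward_backward


# ---------------------------------------------------------------------------
# oracles


def scalar_lstm_oracle(x, h, c, w):
    """Independent scalar transcription of the LSTM recurrence."""
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    i = sig(w["xi"] * x + w["hi"] * h + w["bi"])
    f = sig(w["xf"] * x + w["hf"] * h + w["bf"])
    cc = f * c + i * math.tanh(w["xc"] * x + w["hc"] * h + w["bc"])
    o = sig(w["xo"] * x + w["ho"] * h + w["bo"])
    return o * math.tanh(cc), cc


def enumerate_paths(emissions, crf):
    """All L^n paths with their scores (brute-force oracle)."""
    n, L = emissions.shape
    out = []
    for path in itertools.product(range(L), repeat=n):
        s = crf.start[path[0]] + emissions[0, path[0]]
        for i in range(1, n):
            s += crf.pair[path[i - 1], path[i]] + emissions[i, path[i]]
        out.append((list(path), s))
    return out


def random_crf(rng, L, scale=1.0):
    return CRFParams(
        transition_weights=scale * rng.standard_normal((L + 1, L)),
        transition_bias=scale * rng.standard_normal((L + 1, L)),
    )


def zero_crf(L):
    return CRFParams(np.zeros((L + 1, L)), np.zeros((L + 1, L)))


def tiny_model(n_labels=3, hidden=5, char_dim=4, rad_dim=3, vocab=6, seed=0):
    return TaggerModel.build(
        labels=["O", "B-a", "I-a"][:n_labels],
        vocab={f"c{i}": i for i in range(vocab)},
        n_radicals=3,
        feature_config=FeatureConfig(char_dim=char_dim, radical_dim=rad_dim),
        hidden_size=hidden,
        dropout_rate=0.0,
        seed=seed,
    )


def random_batch(model, rng, B=2, T=5):
    char_ids = rng.integers(0, len(model.vocab), (B, T))
    rad_ids = rng.integers(0, model.n_radicals, (B, T))
    dictf = rng.integers(0, 2, (B, T, 30)).astype(float)
    lens = [T] + [int(rng.integers(1, T + 1)) for _ in range(B - 1)]
    mask = np.zeros((B, T))
    for b, n in enumerate(lens):
        mask[b, :n] = 1
    seg = rng.integers(0, 2, (B, T)).astype(float) * mask
    paths = [rng.integers(0, model.n_labels, n) for n in lens]
    return (char_ids, rad_ids, dictf, mask, seg, paths, lens)


# ---------------------------------------------------------------------------


class TestLSTM:
    def test_zero_parameters_zero_state(self):
        H = 4
        p = LSTMParams.from_fused(np.zeros((3, 4 * H)), np.zeros((H, 4 * H)), np.zeros(4 * H))
        h, c = lstm_step(np.ones(3), np.zeros(H), np.zeros(H), p)
        np.testing.assert_allclose(h, 0.0)
        np.testing.assert_allclose(c, 0.0)

    def test_zero_parameters_carry_half_cell(self):
        H = 4
        p = LSTMParams.from_fused(np.zeros((3, 4 * H)), np.zeros((H, 4 * H)), np.zeros(4 * H))
        c_prev = np.linspace(-1, 1, H)
        h, c = lstm_step(np.zeros(3), np.zeros(H), c_prev, p)
        np.testing.assert_allclose(c, 0.5 * c_prev)
        np.testing.assert_allclose(h, 0.5 * np.tanh(0.5 * c_prev))

    def test_matches_scalar_oracle(self, rng):
        for _ in range(50):
            w = {k: float(rng.standard_normal()) for k in
                 ["xi", "hi", "bi", "xf", "hf", "bf", "xc", "hc", "bc", "xo", "ho", "bo"]}
            p = LSTMParams(
                W_xi=np.array([[w["xi"]]]), W_hi=np.array([[w["hi"]]]),
                W_xf=np.array([[w["xf"]]]), W_hf=np.array([[w["hf"]]]),
                W_xc=np.array([[w["xc"]]]), W_hc=np.array([[w["hc"]]]),
                W_xo=np.array([[w["xo"]]]), W_ho=np.array([[w["ho"]]]),
                b_i=np.array([w["bi"]]), b_f=np.array([w["bf"]]),
                b_c=np.array([w["bc"]]), b_o=np.array([w["bo"]]),
            )
            x, h0, c0 = (float(v) for v in rng.standard_normal(3))
            h, c = lstm_step(np.array([x]), np.array([h0]), np.array([c0]), p)
            eh, ec = scalar_lstm_oracle(x, h0, c0, w)
            assert abs(h[0] - eh) < 1e-10 and abs(c[0] - ec) < 1e-10

    def test_shape_mismatch_rejected(self):
        p = LSTMParams.from_fused(np.zeros((3, 8)), np.zeros((2, 8)), np.zeros(8))
        with pytest.raises(ValueError):
            lstm_step(np.ones(4), np.zeros(2), np.zeros(2), p)


class TestBiLSTM:
    def test_output_width_is_twice_hidden(self, rng):
        model = tiny_model(hidden=7)
        out = bilstm_encode(rng.standard_normal((1, model.feature_config.input_dim)), model)
        assert out.shape == (1, 14)

    def test_zero_parameter_model_outputs_zero(self, rng):
        model = tiny_model()
        for k in ("fw_Wx", "fw_Wh", "fw_b", "bw_Wx", "bw_Wh", "bw_b"):
            model.params[k][:] = 0.0
        out = bilstm_encode(rng.standard_normal((4, model.feature_config.input_dim)), model)
        np.testing.assert_allclose(out, 0.0)

    def test_direction_symmetry_under_reversal(self, rng):
        model = tiny_model(hidden=6)
        H = 6
        for name in ("Wx", "Wh", "b"):  # tie directions so reversal is a symmetry
            model.params[f"bw_{name}"] = model.params[f"fw_{name}"].copy()
        X = rng.standard_normal((9, model.feature_config.input_dim))
        fwd = bilstm_encode(X, model)
        rev = bilstm_encode(X[::-1], model)
        # reversing the input swaps the directions and reverses time
        np.testing.assert_allclose(rev[:, :H], fwd[::-1, H:], atol=1e-12)
        np.testing.assert_allclose(rev[:, H:], fwd[::-1, :H], atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bilstm_encode(np.zeros((0, 5)), tiny_model())


class TestSegmentationHead:
    def test_zero_head_gives_half(self, rng):
        z = rng.standard_normal((6, 4))
        np.testing.assert_allclose(seg_forward(z, np.zeros(4), 0.0), 0.5)

    def test_probabilities_strictly_inside_unit_interval(self, rng):
        # scores up to ~±30; beyond ~37 the sigmoid saturates in float64,
        # which is why the loss clamps probabilities
        z = 3 * rng.standard_normal((20, 4))
        q = seg_forward(z, rng.standard_normal(4), 1.0)
        assert np.all(q > 0) and np.all(q < 1)

    def test_matches_direct_recomputation(self, rng):
        z = rng.standard_normal((8, 5))
        w, b = rng.standard_normal(5), 0.3
        np.testing.assert_allclose(seg_forward(z, w, b), 1 / (1 + np.exp(-(z @ w + b))))

    def test_perfect_prediction_loss_vanishes(self):
        y = np.array([1.0, 0.0, 1.0])
        assert seg_bce_loss(y, y, np.ones(3)) < 1e-9

    def test_uninformative_prediction_analytic_value(self):
        n = 7
        loss = seg_bce_loss(np.full(n, 0.5), np.ones(n), np.ones(n))
        assert abs(loss - n * math.log(2)) < 1e-12

    def test_matches_handsummed_oracle_and_masking(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 20))
            q = rng.uniform(0.01, 0.99, n)
            y = rng.integers(0, 2, n).astype(float)
            m = rng.integers(0, 2, n).astype(float)
            expected = -sum(
                m[i] * (y[i] * math.log(q[i]) + (1 - y[i]) * math.log(1 - q[i]))
                for i in range(n)
            )
            assert abs(seg_bce_loss(q, y, m) - expected) < 1e-10


class TestCRF:
    def test_length_one_score_is_emission_plus_start(self, rng):
        L = 4
        crf = random_crf(rng, L)
        em = rng.standard_normal((1, L))
        assert abs(crf_score(em, crf, [2]) - (crf.start[2] + em[0, 2])) < 1e-12
        assert abs(crf_log_partition(em, crf) - np.log(np.exp(crf.start + em[0]).sum())) < 1e-10

    def test_zero_parameters(self):
        crf = zero_crf(3)
        em = np.zeros((4, 3))
        assert crf_score(em, crf, [0, 1, 2, 0]) == 0.0
        assert abs(crf_log_partition(em, crf) - 4 * math.log(3)) < 1e-10

    def test_path_probabilities_normalize_and_match_enumeration(self, rng):
        for _ in range(60):
            n, L = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            crf = random_crf(rng, L)
            em = rng.standard_normal((n, L))
            paths = enumerate_paths(em, crf)
            logZ_brute = math.log(sum(math.exp(s) for _, s in paths))
            assert abs(crf_log_partition(em, crf) - logZ_brute) < 1e-8
            total_prob = sum(math.exp(s - logZ_brute) for _, s in paths)
            assert abs(total_prob - 1.0) < 1e-8
            path = [int(rng.integers(L)) for _ in range(n)]
            prob = math.exp(crf_score(em, crf, path) - logZ_brute)
            assert abs(crf_nll(em, crf, path) + math.log(prob)) < 1e-8

    def test_nll_nonnegative_and_single_label_degenerate(self, rng):
        crf = random_crf(rng, 1)
        em = rng.standard_normal((5, 1))
        assert abs(crf_nll(em, crf, [0] * 5)) < 1e-10
        crf3 = random_crf(rng, 3)
        em3 = rng.standard_normal((4, 3))
        assert crf_nll(em3, crf3, [0, 1, 2, 0]) >= 0

    def test_viterbi_matches_bruteforce_max(self, rng):
        for _ in range(60):
            n, L = int(rng.integers(1, 6)), int(rng.integers(1, 5))
            crf = random_crf(rng, L)
            em = rng.standard_normal((n, L))
            path, score = viterbi_decode(em, crf)
            best = max(s for _, s in enumerate_paths(em, crf))
            assert abs(score - best) < 1e-8
            assert abs(crf_score(em, crf, path) - score) < 1e-10
            assert score <= crf_log_partition(em, crf) + 1e-10

    def test_viterbi_tie_breaks_toward_lowest_index(self):
        crf = zero_crf(3)
        path, score = viterbi_decode(np.zeros((4, 3)), crf)
        assert path == [0, 0, 0, 0] and score == 0.0

    def test_viterbi_invariant_to_constant_emission_shift(self, rng):
        crf = random_crf(rng, 3)
        em = rng.standard_normal((5, 3))
        path, _ = viterbi_decode(em, crf)
        em2 = em.copy()
        em2[2] += 7.5  # constant added to every label at one position
        path2, _ = viterbi_decode(em2, crf)
        assert path == path2

    def test_label_out_of_range_rejected(self, rng):
        crf = random_crf(rng, 3)
        with pytest.raises(ValueError):
            crf_score(rng.standard_normal((2, 3)), crf, [0, 3])

    def test_gradient_matches_finite_differences(self, rng):
        n, L = 4, 3
        crf = random_crf(rng, L)
        em = rng.standard_normal((n, L))
        gold = [int(rng.integers(L)) for _ in range(n)]
        nll, d_em, d_tr = crf_nll_grad(em, crf, gold)
        assert abs(nll - crf_nll(em, crf, gold)) < 1e-10
        eps = 1e-6
        for i in range(n):
            for j in range(L):
                em[i, j] += eps
                up = crf_nll(em, crf, gold)
                em[i, j] -= 2 * eps
                dn = crf_nll(em, crf, gold)
                em[i, j] += eps
                assert abs((up - dn) / (2 * eps) - d_em[i, j]) < 1e-4
        for i in range(L + 1):
            for j in range(L):
                crf.transition_weights[i, j] += eps
                up = crf_nll(em, crf, gold)
                crf.transition_weights[i, j] -= 2 * eps
                dn = crf_nll(em, crf, gold)
                crf.transition_weights[i, j] += eps
                assert abs((up - dn) / (2 * eps) - d_tr[i, j]) < 1e-4

    def test_bio_constraint_blocks_stray_inside_tags(self, rng):
        labels = ["O", "B-a", "I-a", "B-b", "I-b"]
        mask = bio_constraint_mask(labels)
        assert mask[labels.index("O"), labels.index("I-a")] == -np.inf
        assert mask[labels.index("B-a"), labels.index("I-a")] == 0.0
        assert mask[labels.index("B-b"), labels.index("I-a")] == -np.inf
        assert mask[5, labels.index("I-b")] == -np.inf  # START row
        crf = CRFParams(
            rng.standard_normal((6, 5)), rng.standard_normal((6, 5)), constraint=mask
        )
        for _ in range(20):
            em = 3 * rng.standard_normal((6, 5))
            path, _ = viterbi_decode(em, crf)
            prev = None
            for lab in (labels[j] for j in path):
                if lab.startswith("I-"):
                    assert prev in (f"B-{lab[2:]}", f"I-{lab[2:]}")
                prev = lab


class TestJointLoss:
    def test_default_weights_are_two_to_three(self):
        w = LossWeights()
        assert (w.alpha, w.beta) == (0.4, 0.6)
        assert combined_loss(10.0, 20.0, w) == pytest.approx(0.4 * 10 + 0.6 * 20)

    def test_single_task_limit(self):
        assert combined_loss(123.0, 7.0, LossWeights(0.0, 0.6)) == pytest.approx(0.6 * 7.0)

    def test_linearity(self, rng):
        w = LossWeights(0.3, 0.7)
        a, b = rng.standard_normal(2)
        lhs = combined_loss(a + b, 0.0, w) - combined_loss(a, 0.0, w)
        rhs = combined_loss(b, 0.0, w) - combined_loss(0.0, 0.0, w)
        assert lhs == pytest.approx(rhs)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(-0.1, 0.5)
        with pytest.raises(ValueError):
            LossWeights(0.0, 0.0)


class TestFullModelGradients:
    def test_finite_difference_check(self, rng):
        """Numerical gradients of the joint loss match the analytic backward
        pass on a small model (dropout disabled)."""
        model = tiny_model()
        batch = random_batch(model, rng)
        w = LossWeights(0.4, 0.6)
        _, _, L0, grads = forward_backward(model, batch, w, None)
        eps = 1e-6
        check_rng = np.random.default_rng(99)
        for k, v in model.params.items():
            idxs = list(np.ndindex(v.shape)) if v.ndim else [()]
            if len(idxs) > 12:
                idxs = [idxs[i] for i in check_rng.choice(len(idxs), 12, replace=False)]
            for idx in idxs:
                orig = v[idx]
                v[idx] = orig + eps
                _, _, up, _ = forward_backward(model, batch, w, None)
                v[idx] = orig - eps
                _, _, dn, _ = forward_backward(model, batch, w, None)
                v[idx] = orig
                num = (up - dn) / (2 * eps)
                assert abs(num - grads[k][idx]) < 1e-4, f"gradient mismatch in {k}{idx}"

    def test_gradients_linear_in_task_weights(self, rng):
        model = tiny_model(seed=3)
        batch = random_batch(model, rng)
        _, _, _, g_seg = forward_backward(model, batch, LossWeights(1.0, 0.0), None)
        _, _, _, g_crf = forward_backward(model, batch, LossWeights(0.0, 1.0), None)
        _, _, _, g_mix = forward_backward(model, batch, LossWeights(0.4, 0.6), None)
        for k in model.params:
            np.testing.assert_allclose(
                g_mix[k], 0.4 * g_seg[k] + 0.6 * g_crf[k], atol=1e-12
            )

    def test_crf_loss_independent_of_segmentation_head(self, rng):
        """Parallel heads: the recognition loss on a fixed batch does not
        move when the segmentation head's parameters change."""
        model = tiny_model(seed=5)
        batch = random_batch(model, rng)
        _, l2_before, _, g = forward_backward(model, batch, LossWeights(0.0, 1.0), None)
        model.params["seg_w"] += rng.standard_normal(model.params["seg_w"].shape)
        model.params["seg_b"] += 2.0
        _, l2_after, _, _ = forward_backward(model, batch, LossWeights(0.0, 1.0), None)
        assert l2_after == pytest.approx(l2_before, abs=1e-12)
        np.testing.assert_allclose(g["seg_w"], 0.0)  # alpha=0 freezes the seg head
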