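"""The attention network: blocks, forward pass, loss, training loop."""

import numpy as np
import pytest
from autograd import value_and_grad
from autograd.misc.flatten import flatten

from p2an.model import (ModelConfig, P2ANModel, Scaler, attention,
                        attention_weights, decoder_block, init_params,
                        layer_norm, leaky_relu, loss_total,
                        p2an_forward, p2an_loss_and_grad, residual_embed,
                        stack_bsp, train)


@pytest.fixture(scope="module")
def tiny_cfg():
    return ModelConfig(n_res=2, n_attn=2, d_k=8, d_ff=12, dropout_p=0.0, seed=3)


@pytest.fixture(scope="module")
def tiny_params(tiny_cfg):
    return init_params(tiny_cfg, 16, rng=np.random.default_rng(0))


class TestResidualEmbed:
    def test_preserves_spatial_positions(self, tiny_cfg, tiny_params, rng):
        x = rng.standard_normal((10, 40))
        out = residual_embed(x, tiny_params, tiny_cfg)
        assert out.shape == (10, 40)

    def test_receptive_field_extent(self):
        """Impulse response of 6 blocks x 2 convs x kernel 3 spans 25 samples."""
        cfg = ModelConfig(n_res=6, dropout_p=0.0, seed=0)
        params = init_params(cfg, 8, rng=np.random.default_rng(1))
        L = 101
        base = np.zeros((4, L))
        mid = np.zeros((4, L))
        # channel-varying impulse (a channel-constant one is invisible to
        # the channel-axis LayerNorm)
        mid[:, L // 2] = [1.0, -2.0, 0.5, 3.0]
        delta = np.asarray(residual_embed(mid, params, cfg)) - np.asarray(
            residual_embed(base, params, cfg)
        )
        # LayerNorm couples channels at a given time, not across time, so
        # the temporal support of the impulse response is the receptive field
        nz = np.nonzero(np.abs(delta).max(axis=0) > 1e-12)[0]
        width = nz.max() - nz.min() + 1
        assert width == 6 * 2 * (3 - 1) + 1

    def test_deterministic(self, tiny_cfg, tiny_params, rng):
        x = rng.standard_normal((6, 30))
        a = np.asarray(residual_embed(x, tiny_params, tiny_cfg))
        b = np.asarray(residual_embed(x, tiny_params, tiny_cfg))
        assert np.array_equal(a, b)

    def test_rejects_non_finite(self, tiny_cfg, tiny_params):
        x = np.full((4, 10), np.nan)
        with pytest.raises(ValueError):
            residual_embed(x, tiny_params, tiny_cfg)


class TestAttention:
    def test_self_attention_is_cross_with_itself(self, rng):
        proj = {
            "Wq": rng.standard_normal((5, 4)),
            "Wk": rng.standard_normal((5, 4)),
            "Wv": rng.standard_normal((5, 5)),
        }
        x = rng.standard_normal((7, 5))
        assert np.allclose(attention(x, x, proj), attention(x, x.copy(), proj))

    def test_rows_sum_to_one(self, rng):
        proj = {
            "Wq": rng.standard_normal((5, 4)),
            "Wk": rng.standard_normal((5, 4)),
            "Wv": rng.standard_normal((5, 5)),
        }
        w = attention_weights(rng.standard_normal((9, 5)),
                              rng.standard_normal((6, 5)), proj)
        assert w.shape == (9, 6)
        assert np.allclose(w.sum(axis=1), 1.0, atol=1e-6)

    def test_two_token_hand_case(self):
        """d_k = 2, identity projections, hand-computed softmax weights."""
        x = np.array([[1.0, 0.0], [0.0, 1.0]])
        c = np.array([[2.0, 0.0], [0.0, 2.0]])
        proj = {"Wq": np.eye(2), "Wk": np.eye(2), "Wv": np.eye(2)}
        # scores = x c^T / sqrt(2): row0 = [2, 0]/sqrt2 = [sqrt2, 0]
        s = np.sqrt(2.0)
        w0 = np.exp([s, 0]) / np.exp([s, 0]).sum()
        w1 = np.exp([0, s]) / np.exp([0, s]).sum()
        expect = np.vstack([w0 @ c, w1 @ c])
        assert np.allclose(attention(x, c, proj), expect, atol=1e-12)

    def test_zero_dk_rejected(self, rng):
        proj = {"Wq": np.zeros((3, 0)), "Wk": np.zeros((3, 0)),
                "Wv": np.eye(3)}
        with pytest.raises(ValueError):
            attention(rng.standard_normal((2, 3)), rng.standard_normal((2, 3)), proj)


class TestDecoderBlock:
    def test_token_count_preserved(self, tiny_params, rng):
        blk = tiny_params["decoder"][0]
        x = rng.standard_normal((9, 16))
        c = rng.standard_normal((12, 16))
        out = decoder_block(x, c, blk)
        assert np.asarray(out).shape == (9, 16)

    def test_eval_mode_deterministic(self, tiny_params, rng):
        blk = tiny_params["decoder"][0]
        x = rng.standard_normal((9, 16))
        c = rng.standard_normal((12, 16))
        a = np.asarray(decoder_block(x, c, blk, dropout_p=0.5, training=False))
        b = np.asarray(decoder_block(x, c, blk, dropout_p=0.5, training=False))
        assert np.array_equal(a, b)

    def test_matches_line_by_line_transliteration(self, tiny_params, rng):
        """Oracle: the three sublayers written out explicitly."""
        from p2an.model import attention as attn, feed_forward

        blk = tiny_params["decoder"][1]
        x = rng.standard_normal((7, 16))
        c = rng.standard_normal((5, 16))
        x1 = layer_norm(x + attn(x, x, blk["self"]), blk["ln1_g"], blk["ln1_b"])
        x2 = layer_norm(x + attn(x1, c, blk["cross"]), blk["ln2_g"], blk["ln2_b"])
        expect = layer_norm(x2 + feed_forward(x2, blk["ff"]),
                            blk["ln3_g"], blk["ln3_b"])
        got = decoder_block(x, c, blk)
        assert np.allclose(np.asarray(got), np.asarray(expect), atol=1e-6)


class TestStackBsp:
    def test_doubles_positions(self, rng):
        x = rng.standard_normal((64, 30))
        assert stack_bsp(x).shape == (128, 30)

    def test_halves_are_identical_and_invertible(self, rng):
        x = rng.standard_normal((16, 10))
        s = np.asarray(stack_bsp(x))
        assert np.array_equal(s[:16], s[16:])
        assert np.array_equal(s[:16], x)

    def test_mismatched_stack_rejected_in_forward(self, tiny_cfg, tiny_params, rng):
        bsp = rng.standard_normal((5, 20))     # 2N = 10 != M = 16
        prior = rng.standard_normal((16, 20))
        with pytest.raises(ValueError, match="2N = M"):
            p2an_forward(bsp, prior, tiny_params, tiny_cfg)


class TestP2ANForward:
    def test_output_shape_and_determinism(self, tiny_cfg, tiny_params, rng):
        bsp = rng.standard_normal((8, 20))
        prior = rng.standard_normal((16, 20))
        a = np.asarray(p2an_forward(bsp, prior, tiny_params, tiny_cfg))
        b = np.asarray(p2an_forward(bsp, prior, tiny_params, tiny_cfg))
        assert a.shape == (16, 20)
        assert np.array_equal(a, b)

    def test_composition_equals_chained_components(self, tiny_cfg, tiny_params, rng):
        """Monolithic forward == embed both, stack, decode, linear output,
        plus the standard-TMP skip when enabled."""
        import dataclasses

        bsp = rng.standard_normal((8, 20))
        prior = rng.standard_normal((16, 20))
        x = residual_embed(bsp, tiny_params, tiny_cfg)
        c = residual_embed(prior, tiny_params, tiny_cfg)
        x = stack_bsp(x)
        xt, ct = np.asarray(x).T, np.asarray(c).T
        for blk in tiny_params["decoder"]:
            xt = np.asarray(decoder_block(xt, ct, blk))
        head = (xt @ tiny_params["out"]["W"] + tiny_params["out"]["b"]).T
        plain_cfg = dataclasses.replace(tiny_cfg, prior_skip=False)
        got_plain = np.asarray(p2an_forward(bsp, prior, tiny_params, plain_cfg))
        assert np.allclose(got_plain, head, atol=1e-10)
        skip_cfg = dataclasses.replace(tiny_cfg, prior_skip=True)
        got_skip = np.asarray(p2an_forward(bsp, prior, tiny_params, skip_cfg))
        assert np.allclose(got_skip, head + prior, atol=1e-10)

    def test_batched_matches_per_case(self, tiny_cfg, tiny_params, rng):
        bsp = rng.standard_normal((3, 8, 20))
        prior = rng.standard_normal((16, 20))
        batch = np.asarray(p2an_forward(bsp, prior, tiny_params, tiny_cfg))
        for i in range(3):
            single = np.asarray(
                p2an_forward(bsp[i], prior, tiny_params, tiny_cfg)
            )
            assert np.allclose(batch[i], single, atol=1e-12)


class TestLoss:
    def test_zero_at_exact_solution(self, rng):
        H = rng.standard_normal((4, 6))
        U = rng.standard_normal((6, 5))
        total, fwd, con = loss_total(U, H @ U, U, H, 0.01)
        assert total == pytest.approx(0.0, abs=1e-20)

    def test_lambda_zero_is_forward_only(self, rng):
        H = rng.standard_normal((4, 6))
        U, Us = rng.standard_normal((2, 6, 5))
        omega = rng.standard_normal((4, 5))
        total, fwd, _ = loss_total(U, omega, Us, H, 0.0)
        assert total == fwd

    def test_hand_arithmetic_2x2(self):
        """H = I; residuals chosen so the components are easy by hand."""
        H = np.eye(2)
        omega = np.zeros((2, 2))
        U_hat = np.array([[1.0, 1.0], [1.0, 1.0]])
        U_std = np.array([[0.0, 0.0], [3.0, 3.0]])
        total, fwd, con = loss_total(U_hat, omega, U_std, H, 0.01)
        # fwd = mean(1) = 1; con = mean([1,1,4,4]) = 2.5
        assert fwd == pytest.approx(1.0)
        assert con == pytest.approx(2.5)
        assert total == pytest.approx(1.0 + 0.01 * 2.5)

    def test_decomposition_identity(self, rng):
        H = rng.standard_normal((4, 6))
        U, Us = rng.standard_normal((2, 6, 5))
        omega = rng.standard_normal((4, 5))
        total, fwd, con = loss_total(U, omega, Us, H, 0.7)
        assert total == pytest.approx(fwd + 0.7 * con, rel=1e-15)


class TestManualGradients:
    def test_matches_autodiff(self, rng):
        """Hand-derived backward pass == autograd on the reference forward."""
        cfg = ModelConfig(n_res=2, n_attn=2, d_k=8, d_ff=12, dropout_p=0.0,
                          seed=3)
        M, N, L, B = 16, 8, 20, 3
        params = init_params(cfg, M, rng=rng)
        bsp = rng.standard_normal((B, N, L))
        cnet = rng.standard_normal((M, L))
        H = rng.standard_normal((N, M)) * 0.1
        flat, unflat = flatten(params)

        def ag_loss(f):
            u = p2an_forward(bsp, cnet, unflat(f), cfg, training=False)
            return loss_total(u, bsp, cnet, H, 0.01)[0]

        v_ag, g_ag = value_and_grad(ag_loss)(flat)
        v_man, gtree, _ = p2an_loss_and_grad(
            params, bsp, cnet, H, 0.01, cfg, training=False, dtype=np.float64
        )
        g_man, _ = flatten(gtree)
        assert v_man == pytest.approx(v_ag, rel=1e-12)
        assert np.max(np.abs(g_ag - g_man)) < 1e-10 * np.max(np.abs(g_ag))


class TestTraining:
    @pytest.fixture(scope="class")
    def toy_run(self, small_config, small_env):
        from p2an.pipeline import simulate_task, train_solver

        eval_cases, train_cases = simulate_task(small_config, small_env, "MI")
        model = train_solver(small_config, small_env, train_cases, "p2an")
        return eval_cases, train_cases, model

    def test_loss_descends(self, toy_run):
        _, _, model = toy_run
        hist = model.result.loss_history
        assert hist[-1] < hist[0]

    def test_seed_reproducibility(self, small_config, small_env):
        from p2an.pipeline import simulate_task, train_solver

        _, train_cases = simulate_task(small_config, small_env, "MI")
        cfg = dict(small_config.p2an, epochs=2)
        import dataclasses

        c2 = dataclasses.replace(small_config, p2an=cfg)
        a = train_solver(c2, small_env, train_cases, "p2an")
        b = train_solver(c2, small_env, train_cases, "p2an")
        fa, _ = flatten(a.result.params)
        fb, _ = flatten(b.result.params)
        assert np.array_equal(fa, fb)

    def test_trained_beats_random_init(self, toy_run, small_env):
        """Learning sanity: reconstruction RE improves over the untrained net."""
        from p2an.metrics import relative_error
        from p2an.model import TrainResult

        eval_cases, _, model = toy_run
        cfg = model.result.config
        rng0 = np.random.default_rng(999)
        random_params = init_params(cfg, small_env.U_std.shape[0], rng=rng0)
        # genuinely random network: the head is randomized too (init_params
        # zero-initializes it, which would make "untrained" equal the prior)
        C = small_env.U_std.shape[0]
        random_params["out"]["W"] = 0.1 * rng0.standard_normal((C, C))
        untrained = P2ANModel(
            TrainResult(random_params, [], cfg, model.result.scaler, 0),
            small_env.U_std,
        )
        re_trained = np.mean(
            [relative_error(model.reconstruct(c.bsp_clean), c.U_true)
             for c in eval_cases]
        )
        re_random = np.mean(
            [relative_error(untrained.reconstruct(c.bsp_clean), c.U_true)
             for c in eval_cases]
        )
        assert re_trained < re_random

    def test_prior_constraint_pulls_toward_standard(self, small_config, small_env):
        """With a huge lambda the reconstruction hugs the standard TMP."""
        import dataclasses

        from p2an.pipeline import simulate_task, train_solver

        _, train_cases = simulate_task(small_config, small_env, "MI")
        base = dict(small_config.p2an, epochs=6)
        runs = {}
        for lam in (0.0, 1000.0):
            cfg = dataclasses.replace(
                small_config, p2an=dict(base, lambda_weight=lam)
            )
            model = train_solver(cfg, small_env, train_cases, "p2an")
            u = model.reconstruct(train_cases[0].bsp_clean)
            runs[lam] = np.linalg.norm(u - small_env.U_std)
        assert runs[1000.0] < runs[0.0]

    def test_empty_training_set_rejected(self, small_env):
        with pytest.raises(ValueError):
            train([], ModelConfig(), small_env.H.entries)

    def test_checkpoint_round_trip(self, toy_run, small_env, tmp_path):
        from p2an.model import load_checkpoint, save_checkpoint

        _, _, model = toy_run
        path = tmp_path / "ckpt.zip"
        save_checkpoint(path, model.result)
        back = load_checkpoint(path, small_env.U_std.shape[0])
        fa, _ = flatten(model.result.params)
        fb, _ = flatten(back.params)
        assert np.array_equal(fa, fb)
        assert back.loss_history == model.result.loss_history
        case_bsp = np.asarray(small_env.scaler.bsp_to_net(
            np.zeros((small_env.H.shape[0], len(small_env.time_grid)))))
        m2 = P2ANModel(back, small_env.U_std)
        assert np.allclose(
            m2.reconstruct(case_bsp), model.reconstruct(case_bsp), rtol=1e-12
        )
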