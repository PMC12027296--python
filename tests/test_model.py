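import math

import numpy as np
import pytest

from specfresh.model.autodiff import (
    Tensor,
    concat,
    cross_entropy,
    layer_norm,
    log_softmax,
    relu,
    softmax,
)
from specfresh.model.network import (
    DBHSNet,
    DBHSNetConfig,
    attend,
    cross_attend,
    dynamic_weight,
    hcm_forward,
    head_role_masks,
    msmha_fuse,
    multiscale_pool,
    positional_encode,
    total_loss,
)

# ---------------------------------------------------------------------------
# independent dense-arithmetic oracle (plain numpy loops, no autodiff)
# ---------------------------------------------------------------------------


def oracle_softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def oracle_attention(q_in, kv_in, wq, wk, wv, wo=None, mask=None):
    """Row-by-row scaled dot-product attention with explicit loops."""
    q = q_in @ wq
    k = kv_in @ wk
    v = kv_in @ wv
    dk = q.shape[-1]
    out = np.zeros((q.shape[0], v.shape[1]))
    for i in range(q.shape[0]):
        scores = np.array([q[i] @ k[j] / math.sqrt(dk) for j in range(k.shape[0])])
        if mask is not None:
            scores = scores + mask[i]
        w = oracle_softmax(scores)
        out[i] = sum(w[j] * v[j] for j in range(v.shape[0]))
    if wo is not None:
        out = out @ wo
    return out


# ---------------------------------------------------------------------------
# autodiff
# ---------------------------------------------------------------------------


class TestAutodiff:
    def test_finite_difference_full_graph(self):
        """Backprop matches central finite differences through a deep graph."""
        rng = np.random.default_rng(0)
        w1 = Tensor(rng.normal(size=(3, 4)), requires_grad=True)
        w2 = Tensor(rng.normal(size=(4, 2)), requires_grad=True)
        x = rng.normal(size=(5, 3))
        labels = np.array([0, 1, 0, 1, 1])

        def loss_value():
            h = relu(Tensor(x) @ w1)
            return cross_entropy(layer_norm(h) @ w2, labels)

        loss = loss_value()
        loss.backward()
        eps = 1e-6
        for w in (w1, w2):
            g = w.grad
            flat = w.data.ravel()
            for idx in range(0, flat.size, 3):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = float(loss_value().data)
                flat[idx] = orig - eps
                down = float(loss_value().data)
                flat[idx] = orig
                fd = (up - down) / (2 * eps)
                assert g.ravel()[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_softmax_rows_sum_to_one(self):
        x = Tensor(np.random.default_rng(1).normal(size=(4, 7)))
        assert np.allclose(softmax(x).data.sum(axis=-1), 1.0, atol=1e-12)

    def test_log_softmax_consistency(self):
        x = Tensor(np.random.default_rng(2).normal(size=(3, 5)))
        assert np.allclose(np.exp(log_softmax(x).data), softmax(x).data, atol=1e-12)

    def test_cross_entropy_uniform_logits(self):
        logits = Tensor(np.zeros((6, 4)))
        ce = cross_entropy(logits, np.zeros(6, dtype=int))
        assert float(ce.data) == pytest.approx(math.log(4), abs=1e-12)

    def test_broadcast_add_grad(self):
        b = Tensor(np.zeros(3), requires_grad=True)
        x = Tensor(np.ones((4, 3)))
        (x + b).sum().backward()
        assert np.allclose(b.grad, 4.0)

    def test_concat_grad_routing(self):
        a = Tensor(np.ones((2, 2)), requires_grad=True)
        b = Tensor(np.ones((3, 2)), requires_grad=True)
        out = concat([a, b], axis=0)
        (out * Tensor(np.arange(10.0).reshape(5, 2))).sum().backward()
        assert np.allclose(a.grad, [[0, 1], [2, 3]])
        assert np.allclose(b.grad, [[4, 5], [6, 7], [8, 9]])


# ---------------------------------------------------------------------------
# positional encoding
# ---------------------------------------------------------------------------


class TestPositionalEncode:
    def test_x_zero_row(self):
        row = positional_encode(np.array([0.0]), 8)[0]
        assert np.allclose(row, [0, 1, 0, 1, 0, 1, 0, 1])

    def test_unit_argument_first_pair(self):
        row = positional_encode(np.array([1.0]), 6)[0]
        assert row[0] == pytest.approx(math.sin(1), abs=1e-12)
        assert row[1] == pytest.approx(math.cos(1), abs=1e-12)

    def test_full_table_matches_scalar_formula(self):
        d = 4
        table = positional_encode(np.array([0.0, 1.0, 2.0]), d)
        for t, x in enumerate([0.0, 1.0, 2.0]):
            for i in range(d // 2):
                arg = x / 10000 ** (2 * i / d)
                assert table[t, 2 * i] == pytest.approx(math.sin(arg), abs=1e-12)
                assert table[t, 2 * i + 1] == pytest.approx(math.cos(arg), abs=1e-12)

    def test_odd_d_model_rejected(self):
        with pytest.raises(ValueError):
            positional_encode(np.array([0.0]), 5)


# ---------------------------------------------------------------------------
# attention blocks vs oracle
# ---------------------------------------------------------------------------


def _params(rng, d, dk, prefix_pairs):
    params = {}
    for prefix in prefix_pairs:
        params[f"{prefix}_wq"] = Tensor(rng.normal(size=(d, dk)))
        params[f"{prefix}_wk"] = Tensor(rng.normal(size=(d, dk)))
        params[f"{prefix}_wv"] = Tensor(rng.normal(size=(d, dk)))
        params[f"{prefix}_wo"] = Tensor(rng.normal(size=(dk, d)))
    return params


class TestCrossAttend:
    def test_single_local_token_returns_its_value(self):
        d = 4
        eye = Tensor(np.eye(d))
        params = {
            "pbca_g_wq": eye, "pbca_g_wk": eye, "pbca_g_wv": eye, "pbca_g_wo": eye,
            "pbca_l_wq": eye, "pbca_l_wk": eye, "pbca_l_wv": eye, "pbca_l_wo": eye,
        }
        g = Tensor(np.random.default_rng(0).normal(size=(1, 3, d)))
        l = Tensor(np.random.default_rng(1).normal(size=(1, 1, d)))
        z_g, _, _ = cross_attend(g, l, params, residual_layernorm=False)
        for row in range(3):
            assert np.allclose(z_g.data[0, row], l.data[0, 0], atol=1e-12)

    def test_identical_keys_give_uniform_mean(self):
        d = 4
        eye = Tensor(np.eye(d))
        params = {k: eye for k in (
            "pbca_g_wq", "pbca_g_wk", "pbca_g_wv", "pbca_g_wo",
            "pbca_l_wq", "pbca_l_wk", "pbca_l_wv", "pbca_l_wo")}
        rng = np.random.default_rng(2)
        g = Tensor(rng.normal(size=(1, 2, d)))
        local = np.tile(rng.normal(size=(1, 1, d)), (1, 4, 1))
        local[0, :, 0] = local[0, 0, 0]  # identical keys but check values too
        z_g, _, aux = cross_attend(g, Tensor(local), params, residual_layernorm=False)
        assert np.allclose(aux["attn_global"][0], 0.25, atol=1e-9)
        assert np.allclose(z_g.data[0, 0], local[0].mean(axis=0), atol=1e-9)

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(3)
        d, dk = 4, 3
        params = _params(rng, d, dk, ["pbca_g", "pbca_l"])
        g = rng.normal(size=(2, 2, d))
        l = rng.normal(size=(2, 2, d))
        z_g, z_l, aux = cross_attend(Tensor(g), Tensor(l), params, residual_layernorm=False)
        for b in range(2):
            og = oracle_attention(g[b], l[b], params["pbca_g_wq"].data,
                                  params["pbca_g_wk"].data, params["pbca_g_wv"].data,
                                  params["pbca_g_wo"].data)
            ol = oracle_attention(l[b], g[b], params["pbca_l_wq"].data,
                                  params["pbca_l_wk"].data, params["pbca_l_wv"].data,
                                  params["pbca_l_wo"].data)
            assert np.allclose(z_g.data[b], og, atol=1e-5)
            assert np.allclose(z_l.data[b], ol, atol=1e-5)
        assert np.allclose(aux["attn_global"].sum(axis=-1), 1.0, atol=1e-6)


class TestMultiscalePool:
    def test_scale_one_identity(self):
        x = np.random.default_rng(0).normal(size=(2, 4, 3))
        out, pos, tags = multiscale_pool(Tensor(x), np.arange(4.0), (1,))
        assert np.allclose(out.data, x)
        assert np.allclose(pos, np.arange(4.0))
        assert (tags == 1).all()

    def test_constant_tokens_identical_at_every_scale(self):
        x = np.full((1, 8, 3), 0.7)
        out, _, tags = multiscale_pool(Tensor(x), np.arange(8.0), (1, 2, 4))
        assert np.allclose(out.data, 0.7)
        assert sorted(set(tags)) == [1, 2, 4]

    def test_known_pooled_means(self):
        x = np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 4, 1)
        out, pos, tags = multiscale_pool(Tensor(x), np.arange(4.0), (2,))
        assert np.allclose(out.data[0, :, 0], [1.5, 3.5])
        assert np.allclose(pos, [0.5, 2.5])

    def test_oversized_scale_skipped(self):
        x = np.ones((1, 3, 2))
        out, _, tags = multiscale_pool(Tensor(x), np.arange(3.0), (1, 8))
        assert (tags == 1).all()


class TestMsmha:
    @staticmethod
    def _head_params(rng, d, dk, heads=4):
        params = {}
        for h in range(heads):
            params[f"msmha_wq{h}"] = Tensor(rng.normal(size=(d, dk)))
            params[f"msmha_wk{h}"] = Tensor(rng.normal(size=(d, dk)))
            params[f"msmha_wv{h}"] = Tensor(rng.normal(size=(d, dk)))
        params["msmha_wo"] = Tensor(rng.normal(size=(heads * dk, d)))
        return params

    def test_identical_values_affine_average(self):
        d, dk = 4, 4
        rng = np.random.default_rng(0)
        params = self._head_params(rng, d, dk)
        for h in range(4):  # identity V so values pass through
            params[f"msmha_wv{h}"] = Tensor(np.eye(d))
        v = rng.normal(size=d)
        tokens = np.tile(v, (1, 5, 1))
        pos = np.arange(5.0)
        tags = np.array([1, 1, 1, 2, 2])
        z, _ = msmha_fuse(Tensor(tokens), pos, tags, params, head_window=10,
                          residual_layernorm=False)
        expect = np.concatenate([v] * 4) @ params["msmha_wo"].data
        assert np.allclose(z.data[0], expect, atol=1e-9)

    def test_attention_rows_sum_to_one_all_heads(self):
        d, dk = 8, 2
        rng = np.random.default_rng(1)
        params = self._head_params(rng, d, dk)
        tokens = rng.normal(size=(3, 6, d))
        pos = np.arange(6.0)
        tags = np.array([1, 1, 1, 2, 2, 4])
        _, aux = msmha_fuse(Tensor(tokens), pos, tags, params, head_window=10,
                            residual_layernorm=False)
        for attn in aux["head_attn"]:
            assert np.allclose(attn.sum(axis=-1), 1.0, atol=1e-6)

    def test_matches_dense_oracle_with_masks(self):
        d, dk = 4, 2
        rng = np.random.default_rng(2)
        params = self._head_params(rng, d, dk)
        tokens = rng.normal(size=(1, 3, d))
        pos = np.array([0.0, 1.0, 2.0])
        tags = np.array([1, 1, 2])
        z, _ = msmha_fuse(Tensor(tokens), pos, tags, params, head_window=1.5,
                          residual_layernorm=False)
        masks = head_role_masks(pos, tags, head_window=1.5)
        heads = []
        for h in range(4):
            m = masks[h] if masks[h] is not None else np.zeros((3, 3))
            heads.append(
                oracle_attention(tokens[0], tokens[0], params[f"msmha_wq{h}"].data,
                                 params[f"msmha_wk{h}"].data, params[f"msmha_wv{h}"].data,
                                 mask=m)
            )
        fused_tokens = np.concatenate(heads, axis=-1) @ params["msmha_wo"].data
        assert np.allclose(z.data[0], fused_tokens.mean(axis=0), atol=1e-5)

    def test_empty_key_set_raises_named_head(self):
        pos = np.array([0.0, 100.0])
        tags = np.array([1, 1])  # single scale -> head 4 (cross-scale) empty
        with pytest.raises(ValueError, match="head 4"):
            head_role_masks(pos, tags, head_window=1.0)


class TestHcmForward:
    @staticmethod
    def _params(rng, d, nc, nf):
        return {
            "hcm_w_shared": Tensor(rng.normal(size=(d, d))),
            "hcm_b_coarse": Tensor(rng.normal(size=(d,))),
            "hcm_w_coarse_out": Tensor(rng.normal(size=(d, nc))),
            "hcm_b_coarse_out": Tensor(rng.normal(size=(nc,))),
            "hcm_w_fine": Tensor(rng.normal(size=(d, nf))),
            "hcm_b_fine": Tensor(rng.normal(size=(nf,))),
        }

    def test_zero_weights_all_ones_hidden(self):
        rng = np.random.default_rng(0)
        params = self._params(rng, 3, 2, 4)
        params["hcm_w_shared"] = Tensor(np.zeros((3, 3)))
        params["hcm_b_coarse"] = Tensor(np.ones(3))
        z = Tensor(rng.normal(size=(5, 3)))
        coarse, fine = hcm_forward(z, params)
        h = np.ones((5, 3))
        assert np.allclose(fine.data, h @ params["hcm_w_fine"].data + params["hcm_b_fine"].data)

    def test_dead_relu_limit(self):
        rng = np.random.default_rng(1)
        params = self._params(rng, 3, 2, 4)
        params["hcm_w_shared"] = Tensor(1e-6 * np.ones((3, 3)))
        params["hcm_b_coarse"] = Tensor(np.full(3, -100.0))
        coarse, fine = hcm_forward(Tensor(rng.normal(size=(2, 3))), params)
        assert np.allclose(fine.data, params["hcm_b_fine"].data)

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(2)
        params = self._params(rng, 4, 2, 4)
        z = rng.normal(size=(3, 4))
        coarse, fine = hcm_forward(Tensor(z), params)
        h = np.maximum(0, z @ params["hcm_w_shared"].data + params["hcm_b_coarse"].data)
        assert np.allclose(coarse.data, h @ params["hcm_w_coarse_out"].data + params["hcm_b_coarse_out"].data, atol=1e-10)
        assert np.allclose(fine.data, h @ params["hcm_w_fine"].data + params["hcm_b_fine"].data, atol=1e-10)


class TestLossMechanics:
    def test_schedule_endpoints(self):
        assert dynamic_weight(0, 100, 1, 1, mode="schedule") == 1.0
        assert dynamic_weight(100, 100, 1, 1, mode="schedule") == 0.0
        assert dynamic_weight(0, 100, 1, 1, mode="schedule_raw") == 0.0

    def test_loss_ratio_symmetric(self):
        assert dynamic_weight(5, 10, 2.0, 2.0, mode="loss_ratio") == 0.5

    def test_blend_worked_example(self):
        assert dynamic_weight(50, 100, 1.0, 3.0, mode="blend") == pytest.approx(0.375)

    def test_both_zero_losses_ratio(self):
        assert dynamic_weight(3, 10, 0.0, 0.0, mode="loss_ratio") == 0.5

    def test_total_loss_exact_combination(self):
        assert total_loss(2.0, 4.0, 0.5) == pytest.approx(3.0)
        assert total_loss(2.0, 4.0, 1.0) == pytest.approx(2.0)

    def test_total_loss_convexity(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            lc, lf, w = rng.random() * 5, rng.random() * 5, rng.random()
            lt = total_loss(lc, lf, w)
            assert min(lc, lf) - 1e-12 <= lt <= max(lc, lf) + 1e-12

    def test_invalid_weight(self):
        with pytest.raises(ValueError):
            total_loss(1.0, 1.0, 1.5)


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------


def _tiny_model(**overrides):
    kwargs = dict(
        n_bands=40,
        local_indices=(3, 11, 25),
        global_tokens=5,
        d_model=8,
        d_k=2,
        scales=(1, 2),
        head_window=30.0,
        seed=0,
    )
    kwargs.update(overrides)
    return DBHSNet(DBHSNetConfig(**kwargs))


class TestFullForward:
    def test_deterministic(self):
        model = _tiny_model()
        x = np.random.default_rng(0).random((4, 40))
        c1, f1 = model.forward_spectra(x)
        c2, f2 = model.forward_spectra(x)
        assert np.array_equal(f1.data, f2.data)
        assert np.array_equal(c1.data, c2.data)

    def test_local_band_order_invariance(self):
        """Position travels with the band: permuting supply order is a no-op."""
        model = _tiny_model()
        rng = np.random.default_rng(1)
        x = rng.random((3, 40))
        g, l = model.branch_inputs(x)
        positions = np.asarray(model.config.local_indices, dtype=float)
        _, f_sorted = model.forward(g, l, local_positions=sorted(positions))
        perm = np.array([2, 0, 1])
        _, f_perm = model.forward(g, l[:, perm], local_positions=positions[perm])
        assert np.allclose(f_sorted.data, f_perm.data, atol=1e-10)

    def test_band_count_mismatch(self):
        model = _tiny_model()
        with pytest.raises(ValueError, match="bands"):
            model.forward_spectra(np.ones((2, 39)))

    def test_all_off_baseline_path(self):
        model = _tiny_model(use_pbca=False, use_msmha=False, use_hcm=False)
        x = np.random.default_rng(2).random((2, 40))
        coarse, fine = model.forward_spectra(x)
        assert coarse is None
        assert fine.data.shape == (2, 4)

    def test_oracle_equivalence_small_forward(self):
        """Full pipeline vs an independently coded dense oracle."""
        model = _tiny_model(residual_layernorm=False, global_tokens=5,
                            local_indices=(3, 11, 25), scales=(1, 2))
        rng = np.random.default_rng(3)
        x = rng.random((2, 40))
        coarse, fine = model.forward_spectra(x)

        P = {k: v.data for k, v in model.params.items()}
        g, l = model.branch_inputs(x)
        gpos = model._global_positions
        lpos = model._local_positions
        for b in range(2):
            tg = g[b][:, None] @ P["embed_g_w"] + P["embed_g_b"] + positional_encode(gpos, 8)
            tl = l[b][:, None] @ P["embed_l_w"] + P["embed_l_b"] + positional_encode(lpos, 8)
            zg = oracle_attention(tg, tl, P["pbca_g_wq"], P["pbca_g_wk"], P["pbca_g_wv"], P["pbca_g_wo"])
            zl = oracle_attention(tl, tg, P["pbca_l_wq"], P["pbca_l_wk"], P["pbca_l_wv"], P["pbca_l_wo"])

            def pool(tokens, pos, scales):
                toks, ps, tags = [], [], []
                for s in scales:
                    n_out = math.ceil(tokens.shape[0] / s)
                    for r in range(n_out):
                        sl = slice(r * s, min((r + 1) * s, tokens.shape[0]))
                        toks.append(tokens[sl].mean(axis=0))
                        ps.append(pos[sl].mean())
                        tags.append(s)
                return np.array(toks), np.array(ps), np.array(tags)

            pg, posg, tagg = pool(zg, gpos, (1, 2))
            pl, posl, tagl = pool(zl, lpos, (1, 2))
            tokens = np.vstack([pg, pl])
            pos = np.concatenate([posg, posl])
            tags = np.concatenate([tagg, tagl])
            masks = head_role_masks(pos, tags, head_window=30.0)
            heads = []
            for h in range(4):
                m = masks[h] if masks[h] is not None else np.zeros((len(pos), len(pos)))
                heads.append(oracle_attention(tokens, tokens, P[f"msmha_wq{h}"],
                                              P[f"msmha_wk{h}"], P[f"msmha_wv{h}"], mask=m))
            z_fused = (np.concatenate(heads, axis=-1) @ P["msmha_wo"]).mean(axis=0)
            hid = np.maximum(0, z_fused @ P["hcm_w_shared"] + P["hcm_b_coarse"])
            fine_o = hid @ P["hcm_w_fine"] + P["hcm_b_fine"]
            coarse_o = hid @ P["hcm_w_coarse_out"] + P["hcm_b_coarse_out"]
            assert np.allclose(fine.data[b], fine_o, atol=1e-5)
            assert np.allclose(coarse.data[b], coarse_o, atol=1e-5)

    def test_gradient_check_model_slice(self):
        """Finite differences vs backprop on a slice of model parameters."""
        model = _tiny_model()
        rng = np.random.default_rng(4)
        x = rng.random((6, 40))
        fine_labels = rng.integers(0, 4, size=6)
        coarse_labels = rng.integers(0, 2, size=6)

        def loss_value():
            joint, _, _ = model.loss(x, fine_labels, coarse_labels, 0.6)
            return joint

        model.zero_grad()
        loss_value().backward()
        checked = 0
        eps = 1e-6
        for name in ("embed_l_w", "pbca_g_wq", "msmha_wq0", "hcm_w_fine", "msmha_wo"):
            p = model.params[name]
            flat = p.data.ravel()
            for idx in (0, flat.size // 2):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = float(loss_value().data)
                flat[idx] = orig - eps
                down = float(loss_value().data)
                flat[idx] = orig
                fd = (up - down) / (2 * eps)
                bp = p.grad.ravel()[idx]
                assert bp == pytest.approx(fd, rel=1e-4, abs=1e-7)
                checked += 1
        assert checked == 10

    def test_save_load_round_trip(self, tmp_path):
        model = _tiny_model()
        x = np.random.default_rng(5).random((3, 40))
        _, f1 = model.forward_spectra(x)
        path = tmp_path / "model.npz"
        model.save(path)
        back = DBHSNet.load(path)
        _, f2 = back.forward_spectra(x)
        assert np.allclose(f1.data, f2.data)
        assert back.config == model.config
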