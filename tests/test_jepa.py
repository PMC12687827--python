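"""JEPA objective, EMA teacher, training-loop contracts and inference."""

import numpy as np
import pytest

from conftest import make_full_grid
from voljepa.jepa import (EncoderConfig, Predictor, VolJEPA, ema_update,
                          voljepa_loss)
from voljepa.nn import Tensor, smooth_l1
from voljepa.nn.layers import TransformerEncoder
from voljepa.phantom import PhantomSpec, make_phantom_volume, make_study
from voljepa.tokenizer import (assign_configs, pack_batch,
                               sample_mask_multiblock, sample_mask_smallcrop)


def _small_batch(n=2, dims=(4, 4, 4), seed=0):
    samples = []
    for i, cfg in enumerate(assign_configs(n)):
        tg = make_full_grid(dims, seed=seed + i)
        plan = (sample_mask_multiblock(tg, seed=i) if cfg == "multiblock"
                else sample_mask_smallcrop(tg, seed=i))
        samples.append((tg, plan))
    return pack_batch(samples)


@pytest.fixture(scope="module")
def small_model():
    m = VolJEPA(embed_dim=32, depth=2, heads=4, predictor_dim=16,
                predictor_depth=1, predictor_heads=2, steps=5, batch_size=2,
                random_state=0)
    m._build()
    return m


class TestEncode:
    def test_student_sees_context_only(self, small_model):
        batch = _small_batch()
        ctx = small_model.encode_batch(batch, "student_context")
        full = small_model.encode_batch(batch, "teacher_full")
        n_ctx = sum(p.context_ids.size for p in batch.plans)
        assert ctx.vectors.shape[0] == n_ctx
        assert full.vectors.shape[0] == int(batch.lengths.sum())

    def test_unknown_mode_rejected(self, small_model):
        with pytest.raises(ValueError):
            small_model.encode_batch(_small_batch(), "everything")

    def test_token_permutation_equivariance(self, small_model):
        """Permuting tokens (with their position codes) permutes outputs."""
        from voljepa.nn.layers import sincos3d

        rng = np.random.default_rng(0)
        vals = rng.normal(size=(10, 1024))
        coords = rng.integers(0, 5, size=(10, 3))
        enc = small_model.student_
        out = enc(vals, sincos3d(coords, 32), None).data
        perm = rng.permutation(10)
        out_p = enc(vals[perm], sincos3d(coords[perm], 32), None).data
        np.testing.assert_allclose(out_p, out[perm], atol=1e-10)

    def test_single_token_matches_straight_line_oracle(self):
        """With one token there is no cross-token mixing: the encoder must
        equal a hand-rolled layerwise evaluation of its own weights."""
        from scipy.special import erf

        from voljepa.nn.layers import sincos3d

        rng = np.random.default_rng(4)
        enc = TransformerEncoder(6, 8, 1, 2, rng)
        x = rng.normal(size=(1, 6))
        pos = sincos3d(np.array([[1, 2, 3]]), 8)

        def np_ln(v, g, b, eps=1e-6):
            mu = v.mean()
            d = v - mu
            return d / np.sqrt((d * d).mean() + eps) * g + b

        h = x @ enc.embed.weight.data + enc.embed.bias.data + pos
        blk = enc.blocks[0]
        hn = np_ln(h[0], blk.norm1.gamma.data, blk.norm1.beta.data)[None]
        qkv = hn @ blk.attn.qkv.weight.data + blk.attn.qkv.bias.data
        v = qkv[0, 16:24]  # single token: softmax(score)=1, output = value
        attn_out = np.concatenate([v[:4], v[4:]])[None] \
            @ blk.attn.proj.weight.data + blk.attn.proj.bias.data
        h = h + attn_out
        hn = np_ln(h[0], blk.norm2.gamma.data, blk.norm2.beta.data)[None]
        mid = hn @ blk.fc1.weight.data + blk.fc1.bias.data
        gelu = mid * 0.5 * (1 + erf(mid / np.sqrt(2)))
        h = h + gelu @ blk.fc2.weight.data + blk.fc2.bias.data
        expected = np_ln(h[0], enc.norm.gamma.data, enc.norm.beta.data)
        got = enc(x, pos, None).data[0]
        np.testing.assert_allclose(got, expected, atol=1e-10)


class TestPredictor:
    def test_output_count_matches_targets(self, small_model):
        rng = np.random.default_rng(0)
        ctx = Tensor(rng.normal(size=(5, 32)))
        tgt = rng.integers(0, 4, size=(7, 3))
        out = small_model.predictor_(ctx, rng.integers(0, 4, (5, 3)), tgt)
        assert out.shape == (7, 32)

    def test_duplicate_target_positions_identical_predictions(self, small_model):
        rng = np.random.default_rng(1)
        ctx = Tensor(rng.normal(size=(4, 32)))
        ctx_pos = rng.integers(0, 4, (4, 3))
        tgt = np.array([[1, 2, 3], [1, 2, 3]])
        out = small_model.predictor_(ctx, ctx_pos, tgt).data
        np.testing.assert_allclose(out[0], out[1], atol=1e-12)

    def test_empty_targets_rejected(self, small_model):
        with pytest.raises(ValueError):
            small_model.predictor_(Tensor(np.zeros((2, 32))),
                                   np.zeros((2, 3)), np.zeros((0, 3)))

    def test_zero_output_head_pipes_loss_to_teacher_term(self):
        cfg = EncoderConfig(embed_dim=8, depth=1, heads=2, predictor_dim=8,
                            predictor_depth=1, predictor_heads=2)
        pred = Predictor(cfg, np.random.default_rng(0))
        pred.out_proj.weight.data[:] = 0.0
        pred.out_proj.bias.data[:] = 0.0
        ctx = Tensor(np.random.default_rng(1).normal(size=(3, 8)))
        out = pred(ctx, np.zeros((3, 3), int), np.ones((4, 3), int))
        teacher = np.random.default_rng(2).normal(size=(4, 8))
        loss = voljepa_loss(out, Tensor(teacher))
        hand = np.where(np.abs(teacher) < 1, 0.5 * teacher**2,
                        np.abs(teacher) - 0.5).mean()
        assert float(loss.data) == pytest.approx(hand)


class TestEmaUpdate:
    def _pair(self):
        rng = np.random.default_rng(0)
        s = TransformerEncoder(4, 8, 1, 2, rng)
        t = TransformerEncoder(4, 8, 1, 2, np.random.default_rng(1))
        return s, t

    def test_momentum_one_freezes_teacher(self):
        s, t = self._pair()
        before = t.state_arrays()
        ema_update(s, t, 1.0)
        for k, v in t.state_arrays().items():
            np.testing.assert_array_equal(v, before[k])

    def test_momentum_zero_copies_student(self):
        s, t = self._pair()
        ema_update(s, t, 0.0)
        for k, v in t.state_arrays().items():
            np.testing.assert_array_equal(v, s.state_arrays()[k])

    def test_scalar_convex_combination(self):
        s, t = self._pair()
        sp = s.named_params()
        tp = t.named_params()
        key = next(iter(sp))
        sp[key].data[:] = 1.0
        tp[key].data[:] = 0.0
        ema_update(s, t, 0.9)
        np.testing.assert_allclose(t.named_params()[key].data, 0.1)

    def test_invalid_momentum_rejected(self):
        s, t = self._pair()
        with pytest.raises(ValueError):
            ema_update(s, t, 1.5)


class TestTrainingLoop:
    def _vols(self, n=6):
        from voljepa.jepa import prepare_volume

        out = []
        for i in range(n):
            vol, _ = make_phantom_volume(PhantomSpec(seed=400 + i))
            out.append(prepare_volume(vol))
        return out

    def test_teacher_gets_no_gradient(self, small_model):
        batch = _small_batch()
        loss = small_model._loss_on_batch(batch)
        small_model.optimizer_.zero_grad()
        loss.backward()
        assert all(p.grad is None for p in small_model.teacher_.params())
        assert any(p.grad is not None and np.any(p.grad)
                   for p in small_model.student_.params())
        assert any(p.grad is not None and np.any(p.grad)
                   for p in small_model.predictor_.params())

    def test_loss_invariant_to_sample_order(self, small_model):
        samples = []
        for i, cfg in enumerate(assign_configs(4)):
            tg = make_full_grid((4, 4, 4), seed=3 + i)
            plan = (sample_mask_multiblock(tg, seed=i) if cfg == "multiblock"
                    else sample_mask_smallcrop(tg, seed=i))
            samples.append((tg, plan))
        l1 = float(small_model._loss_on_batch(pack_batch(samples)).data)
        l2 = float(small_model._loss_on_batch(pack_batch(samples[::-1])).data)
        assert l1 == pytest.approx(l2, rel=1e-6)

    def test_frozen_teacher_limit(self):
        m = VolJEPA(embed_dim=32, depth=1, heads=2, predictor_dim=16,
                    predictor_depth=1, predictor_heads=2, steps=3,
                    batch_size=2, ema_start=1.0, ema_end=1.0, random_state=0)
        m._build()
        init = m.teacher_.state_arrays()
        m.fit(self._vols(4))
        for k, v in m.teacher_.state_arrays().items():
            np.testing.assert_array_equal(v, init[k])

    def test_resume_reproduces_loss_trajectory(self, tmp_path):
        kw = dict(embed_dim=32, depth=1, heads=2, predictor_dim=16,
                  predictor_depth=1, predictor_heads=2, steps=10,
                  batch_size=2, random_state=5)
        vols = self._vols(4)
        full = VolJEPA(**kw).fit(vols)
        part = VolJEPA(**kw).fit(vols, steps=5)
        part.save(str(tmp_path / "ckpt.npz"))
        resumed = VolJEPA.load(str(tmp_path / "ckpt.npz"))
        resumed.fit(vols, steps=5)
        a = [r["loss"] for r in full.loss_curve_]
        b = [r["loss"] for r in resumed.loss_curve_]
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_nan_loss_aborts(self):
        m = VolJEPA(embed_dim=32, depth=1, heads=2, predictor_dim=16,
                    predictor_depth=1, predictor_heads=2, steps=2,
                    batch_size=2, random_state=0)
        vols = self._vols(4)
        m.fit(vols, steps=1)
        m.predictor_.out_proj.weight.data[:] = np.nan  # poisoned weights
        with pytest.raises(RuntimeError, match="non-finite"):
            m.fit(vols, steps=1)


class TestEmbedStudy:
    def test_mri_study_yields_one_latent_set_per_series(self, tiny_model):
        study = make_study(PhantomSpec(seed=9))
        study.series.append(study.series[0])
        study.region_maps.append(study.region_maps[0])
        sets = tiny_model.embed_study(study)
        assert len(sets) == 2

    def test_ct_embeds_all_three_windows(self, tiny_model):
        from voljepa.jepa import prepare_volume
        from voljepa.tokenizer import tokenize

        vol, _ = make_phantom_volume(PhantomSpec(seed=9, modality="CT"))
        group = prepare_volume(vol)
        n_fg = tokenize(group["brain"]).n_tokens
        ls = tiny_model.embed_volume(group)
        assert ls.vectors.shape[0] == 3 * n_fg

    def test_deterministic_across_calls(self, tiny_model, mri_processed):
        a = tiny_model.embed_volume(mri_processed).vectors
        b = tiny_model.embed_volume(mri_processed).vectors
        np.testing.assert_array_equal(a, b)

    def test_empty_study_rejected(self, tiny_model):
        study = make_study(PhantomSpec(seed=9))
        study.series = [study.series[0]]
        study.series.clear()
        with pytest.raises(ValueError):
            tiny_model.embed_study(study)


def test_voljepa_loss_examples():
    t = Tensor(np.zeros((2, 3)))
    assert float(voljepa_loss(Tensor(np.zeros((2, 3))), t).data) == 0.0
    assert float(voljepa_loss(Tensor(np.full((2, 3), 1.0)), t).data) == 0.5
    assert float(voljepa_loss(Tensor(np.full((2, 3), 2.0)), t).data) == 1.5


def test_sklearn_param_round_trip():
    m = VolJEPA(embed_dim=32)
    params = m.get_params()
    assert params["embed_dim"] == 32
    m.set_params(embed_dim=64, lr=1e-4)
    assert m.get_params()["embed_dim"] == 64
    with pytest.raises(ValueError):
        m.set_params(nonsense=1)
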