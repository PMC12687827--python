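"""Attentive probe, AB-MIL grounding, pointing game, laterality flip."""

import numpy as np
import pytest

from voljepa.nn import Tensor
from voljepa.probes import (ABMILClassifier, ABMILHead, AttentiveProbeClassifier,
                            attention_map, abmil_forward, laterality_flip_test,
                            pointing_game, youden_thresholds)
from voljepa.scalelaws import auroc
from conftest import make_full_grid


def _bag_features(n, d=6, seed=0):
    return np.random.default_rng(seed).normal(size=(n, d))


class TestABMILForward:
    def _head(self, d=6, k=3, seed=0):
        return ABMILHead(d, k, np.random.default_rng(seed))

    def test_singleton_bag_passthrough(self):
        head = self._head()
        f = _bag_features(1)
        bp = abmil_forward(head, f)
        np.testing.assert_allclose(bp.attention, 1.0)
        np.testing.assert_allclose(bp.bag_logits, bp.instance_logits[0])

    def test_identical_instances_split_attention(self):
        head = self._head()
        f = np.tile(_bag_features(1), (2, 1))
        bp = abmil_forward(head, f)
        np.testing.assert_allclose(bp.attention, 0.5, atol=1e-12)
        np.testing.assert_allclose(bp.bag_logits, bp.instance_logits[0],
                                   atol=1e-12)

    def test_hand_enumerated_two_by_two_oracle(self):
        """ψp = [[1,0],[3,2]], ψm = [[0,0],[ln3,0]] -> α_1 = (0.25, 0.75),
        p(x) = (0.25·1 + 0.75·3, 0.5·0 + 0.5·2) = (2.5, 1.0)."""
        head = self._head(k=2)
        head.psi_p = lambda x: Tensor(np.array([[1.0, 0.0], [3.0, 2.0]]))
        head.psi_m = lambda x: Tensor(np.array([[0.0, 0.0], [np.log(3), 0.0]]))
        bp = abmil_forward(head, _bag_features(2))
        np.testing.assert_allclose(bp.attention[:, 0], [0.25, 0.75])
        np.testing.assert_allclose(bp.attention[:, 1], [0.5, 0.5])
        np.testing.assert_allclose(bp.bag_logits, [2.5, 1.0])

    def test_matches_bruteforce_on_random_bags(self):
        """Classify-then-aggregate equals the per-class weighted sum
        computed by explicit loops, to 1e-6."""
        rng = np.random.default_rng(42)
        for trial in range(10):
            n, k, d = rng.integers(1, 7), rng.integers(1, 5), 5
            head = self._head(d=d, k=int(k), seed=trial)
            f = rng.normal(size=(n, d))
            bp = abmil_forward(head, f)
            logits = head.psi_p(Tensor(f)).data
            scores = head.psi_m(Tensor(f)).data
            for c in range(k):
                e = np.exp(scores[:, c] - scores[:, c].max())
                alpha = e / e.sum()
                expected = float((alpha * logits[:, c]).sum())
                assert bp.bag_logits[c] == pytest.approx(expected, abs=1e-6)
                assert bp.attention[:, c].sum() == pytest.approx(1.0)
                assert (logits[:, c].min() - 1e-9 <= bp.bag_logits[c]
                        <= logits[:, c].max() + 1e-9)  # convex hull

    def test_empty_bag_rejected(self):
        with pytest.raises(ValueError):
            abmil_forward(self._head(), np.zeros((0, 6)))


class TestAttentionMapAndPointing:
    def test_uniform_attention_uniform_heatmap(self):
        tg = make_full_grid((2, 2, 2))
        head = ABMILHead(tg.patch_values.shape[1], 2, np.random.default_rng(0))
        bp = abmil_forward(head, tg.patch_values)
        bp.attention[:, 0] = 1.0 / tg.n_tokens
        amap = attention_map(bp, tg, 0)
        assert amap.heatmap.sum() == pytest.approx(1.0)
        assert np.unique(amap.heatmap.round(12)).size == 1

    def test_concentrated_attention_supports_one_patch(self):
        tg = make_full_grid((2, 2, 2))
        head = ABMILHead(tg.patch_values.shape[1], 1, np.random.default_rng(0))
        bp = abmil_forward(head, tg.patch_values)
        bp.attention[:, 0] = 0.0
        bp.attention[3, 0] = 1.0
        amap = attention_map(bp, tg, 0)
        support = amap.heatmap > 0
        assert support.sum() == np.prod(tg.patch_shape)
        assert amap.heatmap.sum() == pytest.approx(1.0)

    def test_class_index_out_of_range(self):
        tg = make_full_grid((2, 2, 2))
        head = ABMILHead(tg.patch_values.shape[1], 1, np.random.default_rng(0))
        bp = abmil_forward(head, tg.patch_values)
        with pytest.raises(IndexError):
            attention_map(bp, tg, 5)

    def test_pointing_game_hit_and_miss(self):
        tg = make_full_grid((2, 2, 2))
        head = ABMILHead(tg.patch_values.shape[1], 1, np.random.default_rng(0))
        bp = abmil_forward(head, tg.patch_values)
        bp.attention[:, 0] = 0.0
        bp.attention[0, 0] = 1.0  # peak in patch (0,0,0)
        amap = attention_map(bp, tg, 0)
        lesion = np.zeros((8, 32, 32), bool)
        lesion[:4, :16, :16] = True
        assert pointing_game(amap, lesion)
        assert not pointing_game(amap, ~lesion)
        with pytest.raises(ValueError):
            pointing_game(amap, np.zeros((8, 32, 32), bool))

    def test_trained_abmil_points_above_chance(self):
        """On easy lesion phantoms a trained grounding head localizes the
        lesion more often than the lesion volume fraction (chance).

        The lesion spans whole patches (radius 12-14 in-plane) and sits
        below the scalp intensity so the per-volume percentile clip does
        not leak its presence into the global intensity scale; features are
        coarse pooled patch intensities (a frozen, backbone-free feature
        map), which isolates the grounding behaviour of the MIL head.
        """
        from voljepa.jepa import prepare_volume
        from voljepa.phantom import PhantomSpec, make_phantom_volume
        from voljepa.tokenizer import tokenize

        def pooled(vals):
            b = vals.reshape(-1, 4, 16, 16)
            return b.reshape(-1, 2, 2, 4, 4, 4, 4).mean(
                axis=(2, 4, 6)).reshape(len(b), -1)

        menu = (("tumor", (12, 14), 60.0),)
        bags, labels, geoms = [], [], []
        for i in range(50):
            has = i % 2
            vol, rmap = make_phantom_volume(
                PhantomSpec(seed=4000 + i, lesion_menu=menu if has else ()))
            tg = tokenize(prepare_volume(vol)["none"])
            bags.append(pooled(tg.patch_values))
            labels.append([has])
            geoms.append((tg, rmap))
        clf = ABMILClassifier(steps=500, lr=1e-2, random_state=0)
        clf.fit(bags[:30], labels[:30])
        hits, frac = [], []
        for i in range(30, 50):
            if not labels[i][0]:
                continue
            tg, rmap = geoms[i]
            bp = clf.forward_bag(bags[i])
            amap = attention_map(bp, tg, 0)
            lesion = rmap.lesion_mask()
            pad = [(0, a - b) for a, b in zip(amap.heatmap.shape, lesion.shape)]
            lesion = np.pad(lesion, pad)
            hits.append(pointing_game(amap, lesion))
            frac.append(lesion.mean())
        assert np.mean(hits) > np.mean(frac)


class TestAttentiveProbe:
    def test_separable_embeddings_reach_perfect_training_auroc(self):
        rng = np.random.default_rng(0)
        X, y = [], []
        for i in range(30):
            label = i % 2
            X.append(rng.normal(size=(12, 8)) + np.eye(8)[0] * 5 * label)
            y.append([label])
        clf = AttentiveProbeClassifier(steps=300, random_state=0).fit(X, y)
        s = clf.decision_function(X)[:, 0]
        assert auroc(np.array(y)[:, 0], s) == pytest.approx(1.0)

    def test_shuffled_labels_near_chance_on_validation(self):
        rng = np.random.default_rng(1)
        X = [rng.normal(size=(10, 8)) for _ in range(60)]
        y = rng.integers(0, 2, size=(60, 1))
        clf = AttentiveProbeClassifier(steps=200, random_state=0)
        clf.fit(X[:40], y[:40])
        s = clf.decision_function(X[40:])[:, 0]
        assert abs(auroc(y[40:, 0], s) - 0.5) < 0.35  # binomial noise at n=20

    def test_constant_features_recover_prevalence(self):
        """Unweighted BCE on constant inputs has its optimum at the class
        prevalence."""
        X = [np.ones((5, 4)) for _ in range(40)]
        y = np.array([[1 if i < 12 else 0] for i in range(40)])  # 30% positive
        clf = AttentiveProbeClassifier(steps=2000, lr=0.05, weight_decay=0.0,
                                       class_weighted=False, standardize=False,
                                       random_state=0).fit(X, y)
        p = clf.predict_proba(X)[:, 0]
        assert np.allclose(p, 0.3, atol=0.02)

    def test_zero_positive_class_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        X = [rng.normal(size=(6, 4)) for _ in range(10)]
        y = np.zeros((10, 2), int)
        y[::2, 0] = 1
        with pytest.warns(UserWarning, match="excluding"):
            clf = AttentiveProbeClassifier(steps=20, random_state=0).fit(X, y)
        assert list(clf.classes_kept_) == [0]

    def test_runs_on_slicewise_token_sets(self):
        """Backbone-agnostic: variable token counts per study are fine."""
        rng = np.random.default_rng(3)
        X = [rng.normal(size=(rng.integers(3, 40), 8)) for _ in range(20)]
        y = rng.integers(0, 2, size=(20, 1))
        y[0, 0], y[1, 0] = 0, 1
        clf = AttentiveProbeClassifier(steps=20, random_state=0).fit(X, y)
        assert clf.predict_proba(X).shape == (20, 1)


def test_youden_thresholds_maximize_j():
    p = np.array([[0.1], [0.2], [0.6], [0.9]])
    y = np.array([[0], [0], [1], [1]])
    thr = youden_thresholds(p, y)
    assert 0.2 < thr[0] <= 0.6


class TestLateralityFlip:
    def test_double_flip_zero_deltas(self):
        def score(vox):
            return float(vox[:, :, :vox.shape[2] // 2].mean()), \
                float(vox[:, :, vox.shape[2] // 2:].mean())

        rng = np.random.default_rng(0)
        vols = [rng.normal(size=(4, 8, 8)) for _ in range(5)]
        flipped_back = [np.flip(np.flip(v, axis=2), axis=2) for v in vols]
        for v, fb in zip(vols, flipped_back):
            np.testing.assert_array_equal(v, fb)

    def test_side_equivariant_model_perfect_auroc(self):
        # "left" = high intensity in the left half; score = half means
        def score(vox):
            h = vox.shape[2] // 2
            return float(vox[..., :h].mean()), float(vox[..., h:].mean())

        rng = np.random.default_rng(1)
        vols, sides = [], []
        for i in range(20):
            v = rng.normal(size=(4, 8, 8)) * 0.01
            side = "left" if i % 2 else "right"
            if side == "left":
                v[..., :4] += 1.0
            else:
                v[..., 4:] += 1.0
            vols.append(v)
            sides.append(side)
        res = laterality_flip_test(score, vols, sides)
        assert res["auroc"] == pytest.approx(1.0)

    def test_flip_invariant_model_chance_auroc(self):
        def score(vox):
            return float(np.abs(vox).mean()), float((vox ** 2).mean())

        rng = np.random.default_rng(2)
        vols = [rng.normal(size=(4, 8, 8)) for _ in range(30)]
        sides = ["left" if i % 2 else "right" for i in range(30)]
        res = laterality_flip_test(score, vols, sides)
        assert abs(res["auroc"] - 0.5) < 0.2
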