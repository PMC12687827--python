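"""Frozen-feature evaluation heads.

``AttentiveProbeClassifier`` is the unified study-level attentive probe: a
single cross-attention block with one learnable query per head pools *all*
tokens of a study into one vector, followed by a linear multi-label head
trained with class-weighted binary cross-entropy (weight_k = N_neg/N_pos).
Class-specific decision thresholds maximize Youden's J on a validation
split. The protocol is backbone-agnostic — any collection of per-study
token matrices works.

``ABMILClassifier`` is the classify-then-aggregate multiple-instance head
for diagnostic grounding: an instance MLP ψp produces K logits per
instance, a separate attention MLP ψm produces K class-specific scores that
are softmax-normalized across instances, and the bag logits are

    p(x) = Σ_i α_i ∘ ψp(f(x_i)).

Because attention is applied to *logits*, the attention weights are
class-specific and sign-aware, which is what makes the per-class attention
maps interpretable (pointing game, laterality analyses).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nn import AdamW, Module, Tensor, concatenate, weighted_bce_logits
from .nn.layers import Linear
from .jepa import LatentSet
from .phantom import RegionLabelMap
from .tokenizer import TokenGrid

__all__ = ["AttentiveProbeClassifier", "ABMILClassifier", "BagPrediction",
           "AttentionMap", "abmil_forward", "attention_map", "pointing_game",
           "laterality_flip_test", "fit_attentive_probe", "youden_thresholds"]


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, LatentSet):
        return x.vectors
    return np.asarray(x, dtype=np.float64)


# --------------------------------------------------------------- attentive

class _AttentivePool(Module):
    """One cross-attention block: a single learnable query per head attends
    over all tokens; head outputs are concatenated into one pooled vector."""

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError("feature dim must be divisible by heads")
        self.heads = heads
        self.query = Tensor(rng.normal(0.0, 0.02, size=(heads, dim // heads)),
                            requires_grad=True)
        self.key = Linear(dim, dim, rng)
        self.value = Linear(dim, dim, rng)

    def __call__(self, tokens: Tensor) -> Tensor:
        n, d = tokens.shape
        h, dh = self.heads, d // self.heads
        k = self.key(tokens).reshape(n, h, dh).transpose(1, 0, 2)
        v = self.value(tokens).reshape(n, h, dh).transpose(1, 0, 2)
        q = self.query.reshape(h, 1, dh)
        attn = ((q @ k.transpose(0, 2, 1)) * (dh ** -0.5)).softmax(axis=-1)
        return (attn @ v).reshape(1, d)  # (1, dim)


class _ProbeNet(Module):
    def __init__(self, dim: int, n_classes: int, heads: int,
                 rng: np.random.Generator):
        self.pool = _AttentivePool(dim, heads, rng)
        self.head = Linear(dim, n_classes, rng)

    def __call__(self, tokens: Tensor) -> Tensor:
        return self.head(self.pool(tokens))


def youden_thresholds(probs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-class probability threshold maximizing J = TPR − FPR."""
    probs, labels = np.atleast_2d(probs), np.atleast_2d(labels)
    out = np.full(probs.shape[1], 0.5)
    for k in range(probs.shape[1]):
        y, p = labels[:, k], probs[:, k]
        if y.min() == y.max():
            continue
        cand = np.unique(p)
        tpr = (p[y == 1][None, :] >= cand[:, None]).mean(axis=1)
        fpr = (p[y == 0][None, :] >= cand[:, None]).mean(axis=1)
        out[k] = cand[np.argmax(tpr - fpr)]
    return out


class AttentiveProbeClassifier:
    """Multi-label attentive probe over frozen study tokens (sklearn-style)."""

    def __init__(self, heads: int = 4, steps: int = 300, batch_size: int = 32,
                 lr: float = 3e-3, weight_decay: float = 1e-4,
                 class_weighted: bool = True, standardize: bool = True,
                 random_state: int = 0):
        self.heads = heads
        self.steps = steps
        self.batch_size = batch_size
        self.lr = lr
        self.weight_decay = weight_decay
        self.class_weighted = class_weighted
        self.standardize = standardize
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return dict(heads=self.heads, steps=self.steps,
                    batch_size=self.batch_size, lr=self.lr,
                    weight_decay=self.weight_decay,
                    class_weighted=self.class_weighted,
                    standardize=self.standardize,
                    random_state=self.random_state)

    def set_params(self, **p) -> "AttentiveProbeClassifier":
        for k, v in p.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y, X_val=None, y_val=None) -> "AttentiveProbeClassifier":
        """X: list of per-study token matrices (or LatentSets); y: (n, K)
        binary label matrix. Classes without positives are excluded with a
        warning. Thresholds come from the validation split when given,
        otherwise from the training data."""
        mats = [_as_matrix(x) for x in X]
        y = np.atleast_2d(np.asarray(y, dtype=np.float64))
        if y.shape[0] != len(mats):
            raise ValueError("label/study count mismatch")
        if self.standardize:
            allt = np.concatenate(mats)
            self.feat_mean_ = allt.mean(axis=0)
            self.feat_std_ = allt.std(axis=0) + 1e-8
        else:
            self.feat_mean_, self.feat_std_ = 0.0, 1.0
        mats = [(m - self.feat_mean_) / self.feat_std_ for m in mats]
        n_pos = y.sum(axis=0)
        keep = n_pos > 0
        if not keep.all():
            warnings.warn(f"excluding {int((~keep).sum())} class(es) with no "
                          "positives", stacklevel=2)
        if keep.sum() == 0:
            raise ValueError("no class has positive examples")
        self.classes_kept_ = np.flatnonzero(keep)
        yk = y[:, keep]
        n, k = yk.shape
        pos = yk.sum(axis=0)
        pos_weight = np.where(pos > 0, (n - pos) / np.maximum(pos, 1), 1.0) \
            if self.class_weighted else np.ones(k)
        dim = mats[0].shape[1]
        rng = np.random.default_rng(self.random_state)
        self.net_ = _ProbeNet(dim, k, self.heads, rng)
        opt = AdamW(self.net_.params(), lr=self.lr,
                    weight_decay=self.weight_decay)
        for _ in range(self.steps):
            idx = rng.choice(n, size=min(self.batch_size, n), replace=False)
            logits = concatenate([self.net_(Tensor(mats[i])) for i in idx])
            loss = weighted_bce_logits(logits, yk[idx], pos_weight)
            opt.zero_grad()
            loss.backward()
            opt.step()
        pv = self.predict_proba(X_val if X_val is not None else X)
        yv = np.atleast_2d(y_val)[:, keep] if y_val is not None else yk
        self.thresholds_ = youden_thresholds(pv, yv)
        return self

    def decision_function(self, X) -> np.ndarray:
        return np.vstack(
            [self.net_(Tensor((_as_matrix(x) - self.feat_mean_)
                              / self.feat_std_)).data for x in X])

    def predict_proba(self, X) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision_function(X)))

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) >= self.thresholds_).astype(int)


def fit_attentive_probe(latents_per_study, labels, config: dict | None = None,
                        val_latents=None, val_labels=None):
    """Functional wrapper: returns (fitted probe, per-class thresholds)."""
    probe = AttentiveProbeClassifier(**(config or {}))
    probe.fit(latents_per_study, labels, val_latents, val_labels)
    return probe, probe.thresholds_


# ------------------------------------------------------------------ AB-MIL

@dataclass
class BagPrediction:
    instance_logits: np.ndarray  # (N, K) ψp(f(x_i))
    attention: np.ndarray  # (N, K) α, softmax across instances per class
    bag_logits: np.ndarray  # (K,) Σ_i α_i ∘ ψp(f(x_i))

    def __post_init__(self):
        if not np.allclose(self.attention.sum(axis=0), 1.0, atol=1e-8):
            raise ValueError("attention must normalize to 1 per class")


class _MLP(Module):
    def __init__(self, d_in: int, hidden: int, d_out: int,
                 rng: np.random.Generator):
        self.fc1 = Linear(d_in, hidden, rng)
        self.fc2 = Linear(hidden, d_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class ABMILHead(Module):
    """ψp (instance classifier) and ψm (attention scorer), both 2-layer MLPs
    with hidden width equal to the feature dim."""

    def __init__(self, dim: int, n_classes: int, rng: np.random.Generator,
                 hidden: int | None = None):
        h = hidden or dim
        self.psi_p = _MLP(dim, h, n_classes, rng)
        self.psi_m = _MLP(dim, h, n_classes, rng)

    def __call__(self, feats: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        logits = self.psi_p(feats)  # (N, K)
        alpha = self.psi_m(feats).softmax(axis=0)  # softmax across instances
        bag = (alpha * logits).sum(axis=0)  # (K,)
        return logits, alpha, bag


def abmil_forward(head: ABMILHead, instance_features) -> BagPrediction:
    """Classify-then-aggregate pooling: p(x) = Σ_i α_i ∘ ψp(f(x_i))."""
    f = _as_matrix(instance_features)
    if f.ndim != 2 or f.shape[0] < 1:
        raise ValueError("bag must contain at least one instance")
    logits, alpha, bag = head(Tensor(f))
    return BagPrediction(instance_logits=logits.data.copy(),
                         attention=alpha.data.copy(),
                         bag_logits=bag.data.copy())


class ABMILClassifier:
    """Bag-level multi-label classifier with sklearn-style fit/predict."""

    def __init__(self, steps: int = 300, batch_size: int = 32, lr: float = 3e-3,
                 weight_decay: float = 1e-4, class_weighted: bool = True,
                 random_state: int = 0):
        self.steps = steps
        self.batch_size = batch_size
        self.lr = lr
        self.weight_decay = weight_decay
        self.class_weighted = class_weighted
        self.random_state = random_state

    def fit(self, bags, y) -> "ABMILClassifier":
        mats = [_as_matrix(b) for b in bags]
        y = np.atleast_2d(np.asarray(y, dtype=np.float64))
        n, k = y.shape
        pos = y.sum(axis=0)
        pos_weight = np.where(pos > 0, (n - pos) / np.maximum(pos, 1), 1.0) \
            if self.class_weighted else np.ones(k)
        rng = np.random.default_rng(self.random_state)
        self.head_ = ABMILHead(mats[0].shape[1], k, rng)
        opt = AdamW(self.head_.params(), lr=self.lr,
                    weight_decay=self.weight_decay)
        for _ in range(self.steps):
            idx = rng.choice(n, size=min(self.batch_size, n), replace=False)
            logits = concatenate(
                [self.head_(Tensor(mats[i]))[2].reshape(1, k) for i in idx])
            loss = weighted_bce_logits(logits, y[idx], pos_weight)
            opt.zero_grad()
            loss.backward()
            opt.step()
        return self

    def forward_bag(self, bag) -> BagPrediction:
        return abmil_forward(self.head_, bag)

    def decision_function(self, bags) -> np.ndarray:
        return np.vstack([self.forward_bag(b).bag_logits for b in bags])

    def predict_proba(self, bags) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision_function(bags)))


# ------------------------------------------------------------- localization

@dataclass
class AttentionMap:
    heatmap: np.ndarray  # voxel-space, nonnegative, sums to 1
    argmax_voxel: tuple[int, int, int]


def attention_map(bp: BagPrediction, tg: TokenGrid, class_k: int) -> AttentionMap:
    """Broadcast per-token attention uniformly over each token's voxels and
    normalize over the (foreground) support."""
    if not 0 <= class_k < bp.attention.shape[1]:
        raise IndexError(f"class index {class_k} out of range")
    if bp.attention.shape[0] != tg.n_tokens:
        raise ValueError("bag size does not match token grid")
    shape = tuple(d * p for d, p in zip(tg.grid_dims, tg.patch_shape))
    heat = np.zeros(shape)
    pvox = int(np.prod(tg.patch_shape))
    for i, (c0, c1, c2) in enumerate(tg.token_coords):
        sl = (slice(c0 * tg.patch_shape[0], (c0 + 1) * tg.patch_shape[0]),
              slice(c1 * tg.patch_shape[1], (c1 + 1) * tg.patch_shape[1]),
              slice(c2 * tg.patch_shape[2], (c2 + 1) * tg.patch_shape[2]))
        heat[sl] = bp.attention[i, class_k] / pvox
    total = heat.sum()
    if total > 0:
        heat /= total
    flat_arg = int(np.argmax(heat.reshape(-1)))  # ties -> lowest linear index
    return AttentionMap(heatmap=heat,
                        argmax_voxel=np.unravel_index(flat_arg, shape))


def pointing_game(amap: AttentionMap, seg: RegionLabelMap | np.ndarray,
                  lesion_id: int | None = None) -> bool:
    """Hit iff the attention-argmax voxel lies inside the lesion mask."""
    if isinstance(seg, RegionLabelMap):
        mask = seg.labels == lesion_id if lesion_id is not None \
            else seg.lesion_mask()
    else:
        mask = np.asarray(seg, dtype=bool)
    if not mask.any():
        raise ValueError("empty lesion mask")
    v = amap.argmax_voxel
    if any(c >= s for c, s in zip(v, mask.shape)):
        return False  # argmax fell in the zero-padding beyond the volume
    return bool(mask[v])


def laterality_flip_test(score_fn, volumes, sides, flip_axis: int = 2) -> dict:
    """Horizontal-flip laterality check.

    ``score_fn(voxels) -> (logit_left, logit_right)``; for each volume the
    left-right axis (``flip_axis``) is mirrored and the logit changes
    ΔL = logitL(flipped) − logitL, ΔR likewise are computed. A side-aware
    model moves mass from the true side to its mirror, so the score
    ΔR − ΔL separates left- from right-sided findings; AUROC of that score
    against ground-truth side (left = positive) is returned.
    """
    from .scalelaws import auroc

    if flip_axis is None:
        raise ValueError("left-right axis orientation unknown")
    deltas = []
    for vox in volumes:
        l0, r0 = score_fn(vox)
        l1, r1 = score_fn(np.flip(vox, axis=flip_axis).copy())
        deltas.append((l1 - l0, r1 - r0))
    deltas = np.array(deltas)
    y = np.array([1 if s == "left" else 0 for s in sides])
    return dict(delta_left=deltas[:, 0], delta_right=deltas[:, 1],
                auroc=auroc(y, deltas[:, 1] - deltas[:, 0]))
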