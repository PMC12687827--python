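"""Vol-JEPA: joint-embedding predictive pretraining for 3D volumes.

A student vision transformer encodes the visible context tokens; a narrow
predictor, queried by a shared learnable mask token combined with the target
positions' codes, predicts the latent representation of every masked target
token; a teacher encoder — an exponential moving average of the student that
receives no gradients — encodes the full volume to supply the prediction
targets. The objective is the elementwise smooth-L1 distance between
predicted and (stop-gradient) teacher target latents, averaged over
elements:

    minimize_{θ, φ, Δy}  || P_φ(Δy, E_θ(x)) − sg(E_θ̄(y)) ||_smoothL1

Only the student θ, predictor φ and mask token Δy receive gradients; the
teacher θ̄ is updated after every optimizer step as θ̄ ← m·θ̄ + (1−m)·θ with a
linearly increasing momentum schedule.

Default sizes here are desk-scale (embed_dim 192, depth 6) and deliberately
far below production scale for this family of models; they exist so the full
objective and training loop run on a single CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .nn import (AdamW, Module, Tensor, TransformerBlock, TransformerEncoder,
                 block_mask, concatenate, cosine_lr, sincos3d, smooth_l1)
from .phantom import StudyRecord
from .preprocess import (CT_WINDOWS, ProcessedVolume, clip_quantize_mri,
                         compute_foreground, resample_volume, window_ct)
from .tokenizer import (MaskPlan, PackedBatch, TokenGrid, AugmentTransform,
                        apply_dropout, assign_configs, augment, draw_ct_window,
                        pack_batch, sample_mask_multiblock,
                        sample_mask_smallcrop, tokenize, truncate_for_training)

__all__ = ["EncoderConfig", "LatentSet", "Predictor", "VolJEPA",
           "voljepa_loss", "ema_update", "train", "prepare_volume"]


@dataclass(frozen=True)
class EncoderConfig:
    embed_dim: int = 192
    depth: int = 6
    heads: int = 6
    predictor_dim: int = 96
    predictor_depth: int = 4
    predictor_heads: int = 4
    patch_shape: tuple[int, int, int] = (4, 16, 16)
    position_code: str = "sincos3d"
    seed: int = 0

    def __post_init__(self):
        if self.embed_dim % self.heads or self.predictor_dim % self.predictor_heads:
            raise ValueError("dims must be divisible by head counts")
        if self.position_code != "sincos3d":
            raise ValueError("only sincos3d position codes are supported")


@dataclass
class LatentSet:
    """Per-token embeddings with their position codes and sample membership."""

    vectors: np.ndarray  # (N, D)
    coords: np.ndarray  # (N, 3) patch indices
    sample_ids: np.ndarray  # (N,) int membership

    def __post_init__(self):
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("latents must be finite")
        if len(self.vectors) != len(self.coords):
            raise ValueError("vectors/coords length mismatch")


class Predictor(Module):
    """Narrow transformer mapping context latents + mask-token queries to
    predicted target latents. The mask token Δy is shared across target
    positions and combined with each position's code."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        from .nn.layers import LayerNorm, Linear

        self.in_proj = Linear(cfg.embed_dim, cfg.predictor_dim, rng)
        self.mask_token = Tensor(rng.normal(0.0, 0.02, size=cfg.predictor_dim),
                                 requires_grad=True)
        self.blocks = [TransformerBlock(cfg.predictor_dim, cfg.predictor_heads, rng)
                       for _ in range(cfg.predictor_depth)]
        self.norm = LayerNorm(cfg.predictor_dim)
        self.out_proj = Linear(cfg.predictor_dim, cfg.embed_dim, rng)
        self._dim = cfg.predictor_dim

    def __call__(self, ctx_latents: Tensor, ctx_coords: np.ndarray,
                 tgt_coords: np.ndarray) -> Tensor:
        """One sample: returns (|targets|, embed_dim) predictions."""
        if len(tgt_coords) == 0:
            raise ValueError("empty target set")
        ctx = self.in_proj(ctx_latents) + Tensor(sincos3d(ctx_coords, self._dim))
        queries = self.mask_token + Tensor(sincos3d(tgt_coords, self._dim))
        x = concatenate([ctx, queries], axis=0)
        for blk in self.blocks:
            x = blk(x)
        x = self.norm(x)
        return self.out_proj(x[len(ctx_coords):])


def voljepa_loss(pred: LatentSet | Tensor, teacher_targets: LatentSet | Tensor,
                 beta: float = 1.0) -> Tensor:
    """Smooth-L1 objective between predicted and teacher target latents,
    averaged over all elements. The teacher side is detached (stop-gradient)."""
    p = pred if isinstance(pred, Tensor) else Tensor(pred.vectors)
    t = teacher_targets if isinstance(teacher_targets, Tensor) \
        else Tensor(teacher_targets.vectors)
    return smooth_l1(p, t.detach(), beta=beta)


def ema_update(student: Module, teacher: Module, momentum: float):
    """θ̄ ← m·θ̄ + (1−m)·θ, parameter-wise; the teacher is never optimized."""
    if not 0.0 <= momentum <= 1.0:
        raise ValueError("EMA momentum must lie in [0, 1]")
    s, t = student.named_params(), teacher.named_params()
    for k in t:
        t[k].data = momentum * t[k].data + (1.0 - momentum) * s[k].data


def prepare_volume(raw, norm_stats=None) -> dict[str, ProcessedVolume]:
    """Full preprocessing of one raw volume: resample to the pipeline grid,
    compute the air-removing foreground mask and quantize — one windowed
    volume per CT window, a single 8-bit volume for MRI. Returns a mapping
    window_tag -> ProcessedVolume."""
    vol = resample_volume(raw)
    fg = compute_foreground(vol)
    out = {}
    if vol.modality == "CT":
        for name, w in CT_WINDOWS.items():
            pv = window_ct(vol, w)
            pv.foreground = fg
            out[name] = pv
    else:
        pv = clip_quantize_mri(vol)
        pv.foreground = fg
        out["none"] = pv
    return out


class VolJEPA:
    """Vol-JEPA pretrainer with a sklearn-style ``fit`` / ``transform`` API.

    Parameters mirror :class:`EncoderConfig` plus the optimization settings;
    all randomness flows through one generator seeded by ``random_state`` so
    runs (and checkpoint resumes) are bit-reproducible.
    """

    def __init__(self, embed_dim: int = 192, depth: int = 6, heads: int = 6,
                 predictor_dim: int | None = None, predictor_depth: int = 4,
                 predictor_heads: int = 4, beta: float = 1.0,
                 steps: int = 200, batch_size: int = 8, lr: float = 1e-3,
                 weight_decay: float = 0.05, warmup_frac: float = 0.1,
                 ema_start: float = 0.996, ema_end: float = 1.0,
                 target_frac: float = 0.85, dropout_rate: float = 0.2,
                 max_patches_per_axis: int = 20, augment_prob: float = 0.5,
                 random_state: int = 0):
        self.embed_dim = embed_dim
        self.depth = depth
        self.heads = heads
        self.predictor_dim = predictor_dim
        self.predictor_depth = predictor_depth
        self.predictor_heads = predictor_heads
        self.beta = beta
        self.steps = steps
        self.batch_size = batch_size
        self.lr = lr
        self.weight_decay = weight_decay
        self.warmup_frac = warmup_frac
        self.ema_start = ema_start
        self.ema_end = ema_end
        self.target_frac = target_frac
        self.dropout_rate = dropout_rate
        self.max_patches_per_axis = max_patches_per_axis
        self.augment_prob = augment_prob
        self.random_state = random_state

    # -- sklearn plumbing --------------------------------------------------
    _param_names = ("embed_dim depth heads predictor_dim predictor_depth "
                    "predictor_heads beta steps batch_size lr weight_decay "
                    "warmup_frac ema_start ema_end target_frac dropout_rate "
                    "max_patches_per_axis augment_prob random_state").split()

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params) -> "VolJEPA":
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- model construction ------------------------------------------------
    def _config(self) -> EncoderConfig:
        pdim = self.predictor_dim
        if pdim is None:
            pdim = self.embed_dim // 2
        return EncoderConfig(embed_dim=self.embed_dim, depth=self.depth,
                             heads=self.heads, predictor_dim=pdim,
                             predictor_depth=self.predictor_depth,
                             predictor_heads=self.predictor_heads,
                             seed=self.random_state)

    def _build(self):
        cfg = self._config()
        patch_dim = int(np.prod(cfg.patch_shape))
        rng = np.random.default_rng(cfg.seed)
        self.student_ = TransformerEncoder(patch_dim, cfg.embed_dim, cfg.depth,
                                           cfg.heads, rng)
        self.predictor_ = Predictor(cfg, rng)
        # teacher starts as an exact copy of the student
        self.teacher_ = TransformerEncoder(patch_dim, cfg.embed_dim, cfg.depth,
                                           cfg.heads, np.random.default_rng(0))
        self.teacher_.load_state_arrays(self.student_.state_arrays())
        for p in self.teacher_.params():
            p.requires_grad = False
        self.config_ = cfg
        self._rng = np.random.default_rng(self.random_state)
        self.step_ = 0
        self.loss_curve_ = []
        self.optimizer_ = AdamW(self.student_.params() + self.predictor_.params(),
                                lr=self.lr, weight_decay=self.weight_decay)

    # -- encoding ----------------------------------------------------------
    def _encode_packed(self, encoder: Module, values, coords, lengths) -> Tensor:
        pos = sincos3d(coords, self.config_.embed_dim)
        return encoder(values, pos, lengths)

    def encode_batch(self, batch: PackedBatch, which: str) -> LatentSet:
        """Encode a packed batch with ``which`` in {"student_context",
        "teacher_full"}. The student sees context tokens only; the teacher
        sees every token and its output carries no gradient."""
        if which == "student_context":
            vals, crds, lens, sids = _gather_context(batch)
            lat = self._encode_packed(self.student_, vals, crds, lens)
            return LatentSet(vectors=lat.data.copy(), coords=crds, sample_ids=sids)
        if which == "teacher_full":
            lat = self._encode_packed(self.teacher_, batch.values, batch.coords,
                                      batch.lengths)
            sids = np.repeat(np.arange(len(batch.lengths)), batch.lengths)
            return LatentSet(vectors=lat.data.copy(), coords=batch.coords.copy(),
                             sample_ids=sids)
        raise ValueError(f"unknown encoding mode {which!r}")

    # -- training ----------------------------------------------------------
    def _ema_momentum(self, step: int) -> float:
        t = min(step / max(self.steps - 1, 1), 1.0)
        return self.ema_start + (self.ema_end - self.ema_start) * t

    def _make_sample(self, tg: TokenGrid, config: str) -> tuple[TokenGrid, MaskPlan]:
        rng = self._rng
        if rng.random() < self.augment_prob:
            tg = augment(tg, AugmentTransform.random(int(rng.integers(2**31 - 1))))
        tg = truncate_for_training(tg, self.max_patches_per_axis,
                                   seed=int(rng.integers(2**31 - 1)))
        seed = int(rng.integers(2**31 - 1))
        if config == "multiblock":
            plan = sample_mask_multiblock(tg, self.target_frac, seed=seed)
        else:
            plan = sample_mask_smallcrop(tg, seed=seed)
        plan = apply_dropout(plan, self.dropout_rate,
                             seed=int(rng.integers(2**31 - 1)))
        return tg, plan

    def _loss_on_batch(self, batch: PackedBatch) -> Tensor:
        ctx_vals, ctx_crds, ctx_lens, _ = _gather_context(batch)
        student_lat = self._encode_packed(self.student_, ctx_vals, ctx_crds,
                                          ctx_lens)
        teacher_lat = self._encode_packed(self.teacher_, batch.values,
                                          batch.coords, batch.lengths).detach()
        preds, targets = [], []
        ctx_off = 0
        for i, plan in enumerate(batch.plans):
            sl = batch.sample_slice(i)
            coords = batch.coords[sl]
            n_ctx = plan.context_ids.size
            ctx_lat_i = student_lat[np.arange(ctx_off, ctx_off + n_ctx)]
            ctx_off += n_ctx
            preds.append(self.predictor_(ctx_lat_i, coords[plan.context_ids],
                                         coords[plan.target_ids]))
            targets.append(teacher_lat[np.asarray(sl.start + plan.target_ids)])
        pred = concatenate(preds, axis=0)
        tgt = concatenate(targets, axis=0).detach()
        return smooth_l1(pred, tgt, beta=self.beta)

    def fit(self, volume_groups, steps: int | None = None,
            norm_stats: dict | None = None) -> "VolJEPA":
        """Pretrain on a list of volume groups (window_tag -> ProcessedVolume,
        as produced by :func:`prepare_volume`); plain ProcessedVolumes are
        accepted and treated as single-entry groups."""
        if not hasattr(self, "student_"):
            self._build()
        total = self.steps if steps is None else steps
        groups = [g if isinstance(g, dict) else {g.window_tag: g}
                  for g in volume_groups]
        if not groups:
            raise ValueError("empty training set")
        token_cache: dict[tuple[int, str], TokenGrid] = {}

        def grid_for(gi: int, tag: str) -> TokenGrid:
            key = (gi, tag)
            if key not in token_cache:
                token_cache[key] = tokenize(groups[gi][tag],
                                            norm_stats=norm_stats)
            return token_cache[key]

        end = self.step_ + total
        while self.step_ < end:
            rng = self._rng
            idx = rng.integers(0, len(groups), size=self.batch_size)
            configs = list(rng.permutation(assign_configs(self.batch_size)))
            samples = []
            for gi, config in zip(idx, configs):
                group = groups[gi]
                if "none" in group:
                    tag = "none"
                else:
                    tag = draw_ct_window(rng)
                samples.append(self._make_sample(grid_for(int(gi), tag), config))
            batch = pack_batch(samples)
            loss = self._loss_on_batch(batch)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at step {self.step_}: {loss.data!r}")
            self.optimizer_.zero_grad()
            loss.backward()
            lr = cosine_lr(self.step_, self.steps, self.lr,
                           warmup=int(self.warmup_frac * self.steps))
            self.optimizer_.step(lr=lr)
            m = self._ema_momentum(self.step_)
            ema_update(self.student_, self.teacher_, m)
            self.loss_curve_.append(dict(step=self.step_, loss=float(loss.data),
                                         lr=lr, ema_momentum=m))
            self.step_ += 1
        return self

    # -- inference ---------------------------------------------------------
    def embed_volume(self, pv_or_group, use_teacher: bool = True,
                     norm_stats: dict | None = None) -> LatentSet:
        """Embed one volume with the EMA teacher, no truncation. A CT group
        is embedded once per window and the token sets concatenated."""
        group = pv_or_group if isinstance(pv_or_group, dict) \
            else {pv_or_group.window_tag: pv_or_group}
        encoder = self.teacher_ if use_teacher else self.student_
        vecs, crds, sids = [], [], []
        for j, tag in enumerate(group):
            tg = tokenize(group[tag], norm_stats=norm_stats)
            lat = self._encode_packed(encoder, tg.patch_values, tg.token_coords,
                                      np.array([tg.n_tokens]))
            vecs.append(lat.data.copy())
            crds.append(tg.token_coords)
            sids.append(np.full(tg.n_tokens, j))
        return LatentSet(vectors=np.concatenate(vecs),
                         coords=np.concatenate(crds),
                         sample_ids=np.concatenate(sids))

    def embed_study(self, study: StudyRecord, norm_stats=None) -> list[LatentSet]:
        """Preprocess and embed every series of a raw study."""
        if not study.series:
            raise ValueError("empty study")
        return [self.embed_volume(prepare_volume(vol), norm_stats=norm_stats)
                for vol in study.series]

    def transform(self, volume_groups) -> list[LatentSet]:
        return [self.embed_volume(g) for g in volume_groups]

    # -- checkpointing -----------------------------------------------------
    def save(self, path: str):
        arrays = {}
        for prefix, mod in (("student", self.student_), ("teacher", self.teacher_),
                            ("predictor", self.predictor_)):
            for k, v in mod.state_arrays().items():
                arrays[f"{prefix}/{k}"] = v
        opt = self.optimizer_.state()
        for i, (m, v) in enumerate(zip(opt["m"], opt["v"])):
            arrays[f"opt/m/{i}"] = m
            arrays[f"opt/v/{i}"] = v
        meta = dict(params=self.get_params(), step=self.step_,
                    opt_t=opt["t"], loss_curve=self.loss_curve_,
                    rng_state=_rng_state_to_json(self._rng))
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "VolJEPA":
        with np.load(path if str(path).endswith(".npz") else f"{path}.npz") as z:
            meta = json.loads(bytes(z["meta_json"]).decode())
            model = cls(**meta["params"])
            model._build()
            for prefix, mod in (("student", model.student_),
                                ("teacher", model.teacher_),
                                ("predictor", model.predictor_)):
                mod.load_state_arrays(
                    {k[len(prefix) + 1:]: z[k] for k in z.files
                     if k.startswith(prefix + "/")})
            n = len(model.optimizer_.params)
            model.optimizer_.load_state(dict(
                t=meta["opt_t"], m=[z[f"opt/m/{i}"] for i in range(n)],
                v=[z[f"opt/v/{i}"] for i in range(n)]))
        model.step_ = meta["step"]
        model.loss_curve_ = meta["loss_curve"]
        model._rng = _rng_state_from_json(meta["rng_state"])
        return model


def _gather_context(batch: PackedBatch):
    vals, crds, lens, sids = [], [], [], []
    for i, plan in enumerate(batch.plans):
        sl = batch.sample_slice(i)
        vals.append(batch.values[sl][plan.context_ids])
        crds.append(batch.coords[sl][plan.context_ids])
        lens.append(plan.context_ids.size)
        sids.append(np.full(plan.context_ids.size, i))
    return (np.concatenate(vals), np.concatenate(crds), np.array(lens),
            np.concatenate(sids))


def _rng_state_to_json(rng: np.random.Generator) -> dict:
    st = rng.bit_generator.state
    return json.loads(json.dumps(st, default=int))


def _rng_state_from_json(state: dict) -> np.random.Generator:
    rng = np.random.default_rng(0)
    st = rng.bit_generator.state
    st["state"]["state"] = int(state["state"]["state"])
    st["state"]["inc"] = int(state["state"]["inc"])
    st["has_uint32"] = int(state["has_uint32"])
    st["uinteger"] = int(state["uinteger"])
    rng.bit_generator.state = st
    return rng


def train(volume_groups, config: dict | None = None) -> VolJEPA:
    """Functional wrapper: build a :class:`VolJEPA` from a config mapping and
    fit it on the given volumes."""
    model = VolJEPA(**(config or {}))
    model.fit(volume_groups)
    return model
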