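"""Foreground tokenization and Vol-JEPA mask-plan sampling.

Volumes are split into non-overlapping 3D patches of 4×16×16 voxels; only
patches containing foreground voxels become tokens, so context/target
sampling operates exclusively on the head. Two masking configurations are
produced in an equal per-batch mix:

* **multiblock** — large blocks are sampled around foreground centroids and
  their union forms the masked target; centroids are added until at least
  ~85% of tokens are masked. The visible context is the complement.
* **smallcrop** — a small contiguous crop is sampled and a fixed fraction of
  its tokens (25% for MRI, 20% for CT) become the visible context; every
  other token of the grid is target.

A context-dropout step then moves a random 20% of context tokens into the
target set. During training, token grids are truncated to at most 20 patches
per axis (never at inference). CT samples draw one of the three windows per
step with probabilities 0.7 (brain), 0.15 (blood), 0.15 (bone).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import ProcessedVolume

__all__ = [
    "PATCH_SHAPE",
    "TokenGrid",
    "MaskPlan",
    "AugmentTransform",
    "PackedBatch",
    "tokenize",
    "truncate_for_training",
    "sample_mask_multiblock",
    "sample_mask_smallcrop",
    "apply_dropout",
    "augment",
    "augment_volume",
    "draw_ct_window",
    "assign_configs",
    "pack_batch",
    "default_context_ratio",
]

PATCH_SHAPE = (4, 16, 16)
CT_WINDOW_PROBS = {"brain": 0.70, "blood": 0.15, "bone": 0.15}
CONTEXT_RATIO = {"MRI": 0.25, "CT": 0.20}
DROPOUT_RATE = 0.20
TARGET_FRAC = 0.85
MAX_PATCHES_PER_AXIS = 20
BLOCK_HALF_EXTENT = (0.15, 0.45)  # fraction of grid extent, per axis
CROP_SPAN = (0.4, 1.0)  # smallcrop per-axis span fraction


def default_context_ratio(modality: str) -> float:
    return CONTEXT_RATIO[modality]


@dataclass
class TokenGrid:
    """Foreground tokens of one volume in patch space.

    ``token_coords`` are absolute (pre-truncation) patch indices; they double
    as the position codes, so truncation does not re-center positions.
    """

    token_coords: np.ndarray  # (T,3) int
    patch_values: np.ndarray  # (T, prod(patch_shape)) float
    grid_dims: tuple[int, int, int]  # padded full-volume extent in patches
    patch_shape: tuple[int, int, int]
    modality: str
    window_tag: str = "none"

    def __post_init__(self):
        if len(self.token_coords) != len(self.patch_values):
            raise ValueError("coords/values length mismatch")
        if len(np.unique(self.token_coords, axis=0)) != len(self.token_coords):
            raise ValueError("duplicate tokens")

    @property
    def n_tokens(self) -> int:
        return len(self.token_coords)

    @property
    def coord_bounds(self) -> np.ndarray:
        """(2,3) array: per-axis [min, max+1] over token coords."""
        return np.stack([self.token_coords.min(axis=0),
                         self.token_coords.max(axis=0) + 1])


@dataclass
class MaskPlan:
    """Disjoint context (x) / target (y) partition of a token grid."""

    context_ids: np.ndarray  # sorted int token indices
    target_ids: np.ndarray
    n_tokens: int
    config: str  # "multiblock" | "smallcrop"
    seed: int
    dropped_ids: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64))
    crop_size: int | None = None  # smallcrop only: token count of the crop

    def __post_init__(self):
        x, y = np.asarray(self.context_ids), np.asarray(self.target_ids)
        if x.size == 0 or y.size == 0:
            raise ValueError("context and target must both be nonempty")
        if np.intersect1d(x, y).size:
            raise ValueError("context and target overlap")
        if x.size + y.size != self.n_tokens:
            raise ValueError("context/target do not partition the grid")
        if self.dropped_ids.size and not np.isin(self.dropped_ids, y).all():
            raise ValueError("dropped ids must lie in the target set")

    @property
    def masked_fraction(self) -> float:
        return self.target_ids.size / self.n_tokens


@dataclass(frozen=True)
class AugmentTransform:
    """Axis permutation + flips, applied identically to both model views."""

    axis_permutation: tuple[int, int, int] = (0, 1, 2)
    flips: tuple[bool, bool, bool] = (False, False, False)

    def __post_init__(self):
        if sorted(self.axis_permutation) != [0, 1, 2]:
            raise ValueError("axis_permutation must be a permutation of (0,1,2)")

    @classmethod
    def random(cls, seed: int) -> "AugmentTransform":
        rng = np.random.default_rng(seed)
        return cls(axis_permutation=tuple(rng.permutation(3).tolist()),
                   flips=tuple(bool(b) for b in rng.integers(0, 2, 3)))


@dataclass
class PackedBatch:
    """Concatenated variable-length token sequences.

    The layout contract: tokens of different samples never attend to each
    other; ``lengths`` delimit the per-sample spans inside the flat arrays.
    """

    values: np.ndarray  # (sum T_i, patch_dim)
    coords: np.ndarray  # (sum T_i, 3)
    lengths: np.ndarray  # (B,)
    plans: list[MaskPlan]  # token ids local to each sample
    tags: list[tuple[str, str, str]]  # (modality, window, config)
    patch_shape: tuple[int, int, int]

    def sample_slice(self, i: int) -> slice:
        off = int(self.lengths[:i].sum())
        return slice(off, off + int(self.lengths[i]))

    def unpack(self) -> list[tuple[np.ndarray, np.ndarray, MaskPlan]]:
        return [(self.values[self.sample_slice(i)],
                 self.coords[self.sample_slice(i)], self.plans[i])
                for i in range(len(self.lengths))]


def tokenize(pv: ProcessedVolume, min_fg_voxels: int = 1,
             patch_shape: tuple[int, int, int] = PATCH_SHAPE,
             norm_stats: dict | None = None) -> TokenGrid:
    """Zero-pad to patch multiples and keep foreground patches.

    Patch values are the model-ready intensities: scaled to [0,1] and, when
    ``norm_stats`` is given, mean-normalized with background zeroed.
    """
    if pv.foreground is None or not pv.foreground.mask.any():
        raise ValueError("volume has no foreground; cannot tokenize")
    top = (1 << pv.bit_depth) - 1
    vals = pv.quantized.astype(np.float64) / top
    mask = pv.foreground.mask
    if norm_stats is not None:
        vals = vals - float(norm_stats[f"{pv.modality}/{pv.window_tag}"])
    vals = np.where(mask, vals, 0.0)

    dims = tuple(-(-s // p) for s, p in zip(vals.shape, patch_shape))
    pad = [(0, d * p - s) for d, p, s in zip(dims, patch_shape, vals.shape)]
    vals = np.pad(vals, pad)
    mask = np.pad(mask, pad)
    d0, d1, d2 = dims
    p0, p1, p2 = patch_shape
    blocks = vals.reshape(d0, p0, d1, p1, d2, p2).transpose(0, 2, 4, 1, 3, 5)
    fg_counts = (mask.reshape(d0, p0, d1, p1, d2, p2)
                 .transpose(0, 2, 4, 1, 3, 5).sum(axis=(3, 4, 5)))
    keep = fg_counts >= min_fg_voxels
    coords = np.argwhere(keep)
    if coords.size == 0:
        raise ValueError("no token meets the foreground-voxel minimum")
    values = blocks[keep].reshape(len(coords), -1)
    return TokenGrid(token_coords=coords, patch_values=values, grid_dims=dims,
                     patch_shape=patch_shape, modality=pv.modality,
                     window_tag=pv.window_tag)


def truncate_for_training(tg: TokenGrid, max_per_axis: int = MAX_PATCHES_PER_AXIS,
                          seed: int = 0, inference: bool = False) -> TokenGrid:
    """Crop each over-long axis to a uniform-random contiguous span of
    ``max_per_axis`` patches. Inference never truncates."""
    if inference:
        return tg
    rng = np.random.default_rng(seed)
    lo, hi = tg.coord_bounds
    keep = np.ones(tg.n_tokens, dtype=bool)
    for ax in range(3):
        extent = hi[ax] - lo[ax]
        if extent > max_per_axis:
            start = lo[ax] + rng.integers(0, extent - max_per_axis + 1)
            c = tg.token_coords[:, ax]
            keep &= (c >= start) & (c < start + max_per_axis)
    if keep.all():
        return tg
    if not keep.any():
        raise ValueError("truncation removed every token")
    return replace(tg, token_coords=tg.token_coords[keep],
                   patch_values=tg.patch_values[keep])


def sample_mask_multiblock(tg: TokenGrid, target_frac: float = TARGET_FRAC,
                           seed: int = 0) -> MaskPlan:
    """Union-of-large-blocks target: sample centroids over foreground tokens
    and per-axis half-extents uniform in [0.15, 0.45]·extent until the target
    covers at least ``target_frac`` of the tokens."""
    if target_frac >= 1.0:
        raise ValueError("target_frac >= 1 would leave an empty context")
    if tg.n_tokens < 8:
        raise ValueError("need at least 8 tokens for multiblock masking")
    rng = np.random.default_rng(seed)
    lo, hi = tg.coord_bounds
    extent = (hi - lo).astype(float)
    in_target = np.zeros(tg.n_tokens, dtype=bool)
    last_block: np.ndarray | None = None
    while in_target.sum() / tg.n_tokens < target_frac:
        centroid = tg.token_coords[rng.integers(tg.n_tokens)]
        half = rng.uniform(*BLOCK_HALF_EXTENT, size=3) * extent
        inside = np.all(np.abs(tg.token_coords - centroid) <= half, axis=1)
        newly = inside & ~in_target
        if newly.any():
            last_block = np.flatnonzero(newly)
        in_target |= inside
    if in_target.all():
        # shrink the last block until the context is nonempty
        for tid in last_block[::-1]:
            in_target[tid] = False
            if not in_target.all():
                break
    ids = np.arange(tg.n_tokens)
    return MaskPlan(context_ids=ids[~in_target], target_ids=ids[in_target],
                    n_tokens=tg.n_tokens, config="multiblock", seed=seed)


def sample_mask_smallcrop(tg: TokenGrid, context_ratio: float | None = None,
                          seed: int = 0) -> MaskPlan:
    """Small-crop context: sample a contiguous sub-block, keep
    round(ratio · crop tokens) of its tokens as context; everything else in
    the grid is target."""
    if context_ratio is None:
        context_ratio = default_context_ratio(tg.modality)
    if not 0.0 < context_ratio < 1.0:
        raise ValueError("context_ratio must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    lo, hi = tg.coord_bounds
    extent = (hi - lo).astype(float)
    for _ in range(200):
        span = np.maximum(1, np.ceil(rng.uniform(*CROP_SPAN, size=3) * extent))
        start = np.array([lo[a] + rng.integers(0, int(extent[a] - span[a]) + 1)
                          for a in range(3)])
        inside = np.all((tg.token_coords >= start)
                        & (tg.token_coords < start + span), axis=1)
        n_crop = int(inside.sum())
        if n_crop < 2:
            continue
        n_ctx = int(np.floor(context_ratio * n_crop + 0.5))
        n_ctx = max(1, min(n_ctx, n_crop - 1 if n_crop == tg.n_tokens else n_crop))
        crop_ids = np.flatnonzero(inside)
        ctx = rng.choice(crop_ids, size=n_ctx, replace=False)
        if n_ctx >= tg.n_tokens:  # target would be empty
            continue
        ids = np.arange(tg.n_tokens)
        return MaskPlan(context_ids=np.sort(ctx),
                        target_ids=np.setdiff1d(ids, ctx),
                        n_tokens=tg.n_tokens, config="smallcrop", seed=seed,
                        crop_size=n_crop)
    raise ValueError("could not sample a valid small-crop plan")


def apply_dropout(plan: MaskPlan, rate: float = DROPOUT_RATE,
                  seed: int = 0) -> MaskPlan:
    """Independently move each context token to the target with probability
    ``rate``; if that empties the context, the dropped token with the lowest
    index is restored."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("dropout rate must lie in [0, 1)")
    if rate == 0.0:
        return plan
    rng = np.random.default_rng(seed)
    drop = rng.random(plan.context_ids.size) < rate
    dropped = plan.context_ids[drop]
    kept = plan.context_ids[~drop]
    if kept.size == 0:
        kept = dropped[:1]
        dropped = dropped[1:]
    return MaskPlan(context_ids=kept,
                    target_ids=np.sort(np.concatenate([plan.target_ids, dropped])),
                    n_tokens=plan.n_tokens, config=plan.config, seed=plan.seed,
                    dropped_ids=np.sort(dropped), crop_size=plan.crop_size)


def augment_volume(voxels: np.ndarray, t: AugmentTransform) -> np.ndarray:
    out = np.transpose(voxels, t.axis_permutation)
    for ax, f in enumerate(t.flips):
        if f:
            out = np.flip(out, axis=ax)
    return np.ascontiguousarray(out)


def augment(tg: TokenGrid, t: AugmentTransform) -> TokenGrid:
    """Permute/flip a token grid; equivariant with volume-space transforms.

    Note the patch shape permutes too: tokenizing the transformed volume
    with the permuted patch shape yields the same tokens up to ordering.
    """
    perm = t.axis_permutation
    coords = tg.token_coords[:, perm].copy()
    dims = tuple(tg.grid_dims[a] for a in perm)
    pshape = tuple(tg.patch_shape[a] for a in perm)
    blocks = tg.patch_values.reshape((-1,) + tg.patch_shape)
    blocks = np.transpose(blocks, (0,) + tuple(a + 1 for a in perm))
    for ax, f in enumerate(t.flips):
        if f:
            coords[:, ax] = dims[ax] - 1 - coords[:, ax]
            blocks = np.flip(blocks, axis=ax + 1)
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0]))
    return TokenGrid(token_coords=coords[order],
                     patch_values=blocks.reshape(len(coords), -1)[order],
                     grid_dims=dims, patch_shape=pshape, modality=tg.modality,
                     window_tag=tg.window_tag)


def draw_ct_window(rng: np.random.Generator,
                   probs: dict[str, float] = CT_WINDOW_PROBS) -> str:
    names = list(probs)
    return names[rng.choice(len(names), p=[probs[n] for n in names])]


def assign_configs(batch_size: int) -> list[str]:
    """Equal multiblock/smallcrop mix; an odd batch gets the extra multiblock."""
    n_small = batch_size // 2
    return ["multiblock"] * (batch_size - n_small) + ["smallcrop"] * n_small


def pack_batch(samples: list[tuple[TokenGrid, MaskPlan]]) -> PackedBatch:
    if not samples:
        raise ValueError("empty batch")
    pshape = samples[0][0].patch_shape
    # axis-permuted variants of one patch shape share a token dimensionality
    # and are packable; genuinely different patch sizes are not
    if any(sorted(tg.patch_shape) != sorted(pshape) for tg, _ in samples):
        raise ValueError("mixed patch shapes in one batch")
    configs = [plan.config for _, plan in samples]
    n_mb, n_sc = configs.count("multiblock"), configs.count("smallcrop")
    expected = assign_configs(len(samples))
    if sorted(configs) != sorted(expected):
        raise ValueError(
            f"batch must mix configurations equally (odd batch → extra "
            f"multiblock); got {n_mb} multiblock / {n_sc} smallcrop")
    values = np.concatenate([tg.patch_values for tg, _ in samples])
    coords = np.concatenate([tg.token_coords for tg, _ in samples])
    lengths = np.array([tg.n_tokens for tg, _ in samples])
    tags = [(tg.modality, tg.window_tag, plan.config) for tg, plan in samples]
    return PackedBatch(values=values, coords=coords, lengths=lengths,
                       plans=[p for _, p in samples], tags=tags,
                       patch_shape=pshape)
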