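"""Emergent-ability evaluations on frozen features.

Zero-shot anatomical patch matching (cosine nearest neighbour on
L2-normalized features, scored by region agreement), unsupervised
parenchyma clustering (k-means on dense sliding-window embeddings with
voxel-wise majority vote and max-IoU cluster selection), kNN latent
pseudo-reconstruction from a patch databank, and zero-shot cross-modal
transfer deltas with bootstrap CIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scalelaws import auroc
from .tokenizer import TokenGrid

__all__ = ["MatchResult", "patch_match", "ClusterMap", "cluster_parenchyma",
           "LatentBank", "build_latent_bank", "knn_reconstruct",
           "assemble_patches", "cross_modal_transfer"]


def _l2_normalize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    norms = np.linalg.norm(x, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero feature vectors cannot be L2-normalized")
    return x / norms[:, None]


@dataclass
class MatchResult:
    query_index: int
    match_index: int
    similarity: float
    query_region: object
    match_region: object

    @property
    def hit(self) -> bool:
        return self.query_region == self.match_region


def patch_match(query_latents, query_regions, ref_latents, ref_regions,
                ) -> tuple[list[MatchResult], float]:
    """Exhaustive cosine nearest neighbour; ties break to the lowest index.
    Accuracy is the fraction of queries whose match shares the region id."""
    if len(np.atleast_2d(ref_latents)) == 0:
        raise ValueError("empty reference set")
    q = _l2_normalize(query_latents)
    r = _l2_normalize(ref_latents)
    sims = q @ r.T
    best = sims.argmax(axis=1)  # argmax returns the first (lowest) max index
    results = [MatchResult(query_index=i, match_index=int(b),
                           similarity=float(sims[i, b]),
                           query_region=query_regions[i],
                           match_region=ref_regions[int(b)])
               for i, b in enumerate(best)]
    acc = float(np.mean([m.hit for m in results])) if results else 0.0
    return results, acc


# ------------------------------------------------------------- clustering

@dataclass
class ClusterMap:
    voxel_labels: np.ndarray  # cluster id per voxel, -1 outside foreground
    selected_cluster: int
    iou: float  # IoU of the selected cluster vs the reference brain mask
    k: int


def cluster_parenchyma(embed_fn, tg: TokenGrid, brain_mask: np.ndarray,
                       k: int = 3, window_span: tuple | None = None,
                       stride: tuple | None = None, seed: int = 0,
                       max_iter: int = 50, test_mode: bool = False,
                       foreground: np.ndarray | None = None) -> ClusterMap:
    """Dense sliding-window embedding + k-means parenchyma discovery.

    ``embed_fn(values, coords) -> (N, D)`` embeds a token subset (one
    window). Windows slide in patch space with stride = window/2 by
    default; a k-means model (k-means++ init, fixed seed, <= ``max_iter``
    iterations) is fit on the first window's embeddings, all windows are
    assigned to the nearest centroid, and each token takes the majority
    vote across the windows covering it (ties -> lowest cluster id). The
    parenchyma cluster is the one with the highest voxel IoU against the
    reference brain mask.
    """
    from sklearn.cluster import KMeans

    if k < 2 and not test_mode:
        raise ValueError("k < 2 is degenerate (k=1 allowed only in test mode)")
    lo, hi = tg.coord_bounds
    extent = hi - lo
    span = np.minimum(extent, window_span if window_span is not None
                      else np.maximum(1, extent // 2))
    step = np.asarray(stride if stride is not None
                      else np.maximum(1, span // 2))
    starts = [np.arange(lo[a], max(hi[a] - span[a], lo[a]) + 1, step[a])
              for a in range(3)]
    windows = [(d, h, w) for d in starts[0] for h in starts[1] for w in starts[2]]

    km = None
    votes = np.zeros((tg.n_tokens, max(k, 1)), dtype=np.int64)
    for wi, start in enumerate(windows):
        start = np.asarray(start)
        inside = np.all((tg.token_coords >= start)
                        & (tg.token_coords < start + span), axis=1)
        ids = np.flatnonzero(inside)
        if ids.size == 0:
            continue
        emb = embed_fn(tg.patch_values[ids], tg.token_coords[ids])
        if km is None:
            km = KMeans(n_clusters=k, init="k-means++", n_init=1,
                        max_iter=max_iter, random_state=seed).fit(emb)
        assign = km.predict(emb)
        np.add.at(votes, (ids, assign), 1)
    covered = votes.sum(axis=1) > 0
    token_label = np.where(covered, votes.argmax(axis=1), 0)  # ties -> lowest

    shape = brain_mask.shape
    vox = np.full(shape, -1, dtype=np.int32)
    p = tg.patch_shape
    for i, (c0, c1, c2) in enumerate(tg.token_coords):
        sl = (slice(c0 * p[0], min((c0 + 1) * p[0], shape[0])),
              slice(c1 * p[1], min((c1 + 1) * p[1], shape[1])),
              slice(c2 * p[2], min((c2 + 1) * p[2], shape[2])))
        vox[sl] = token_label[i]
    if foreground is not None:
        vox[~foreground] = -1

    brain = np.asarray(brain_mask, dtype=bool)
    best_c, best_iou = 0, -1.0
    for c in range(k):
        cm = vox == c
        union = (cm | brain).sum()
        iou = (cm & brain).sum() / union if union else 0.0
        if iou > best_iou:
            best_c, best_iou = c, float(iou)
    return ClusterMap(voxel_labels=vox, selected_cluster=best_c,
                      iou=best_iou, k=k)


# ---------------------------------------------------------------- kNN bank

@dataclass
class LatentBank:
    keys: np.ndarray  # (M, D) teacher latents of reference patches
    patches: np.ndarray  # (M, P) stored image patches
    meta: list  # per-key provenance (volume id, coords, ...)

    def __post_init__(self):
        if len(self.keys) != len(self.patches):
            raise ValueError("key/patch count mismatch")
        if not np.all(np.isfinite(self.keys)):
            raise ValueError("latent keys must be finite")


def build_latent_bank(embed_fn, token_grids: list[TokenGrid]) -> LatentBank:
    """Encode reference patches (EMA teacher) into latent keys; store the
    corresponding image patches for retrieval."""
    if not token_grids:
        raise ValueError("empty reference set")
    keys, patches, meta = [], [], []
    for vi, tg in enumerate(token_grids):
        emb = embed_fn(tg.patch_values, tg.token_coords)
        keys.append(np.asarray(emb))
        patches.append(tg.patch_values)
        meta.extend({"volume": vi, "coord": tuple(c)} for c in tg.token_coords)
    return LatentBank(keys=np.concatenate(keys),
                      patches=np.concatenate(patches), meta=meta)


def knn_reconstruct(pred_latents, bank: LatentBank, k: int) -> np.ndarray:
    """Pseudo-reconstruction x̃_j = (1/k) Σ_{i∈N_k(ẑ_j)} x_i, neighbours by
    cosine similarity (ties -> lowest index)."""
    if len(bank.keys) == 0:
        raise ValueError("empty bank")
    if not 1 <= k <= len(bank.keys):
        raise ValueError("k must lie in [1, bank size]")
    q = _l2_normalize(pred_latents)
    r = _l2_normalize(bank.keys)
    sims = q @ r.T
    # stable sort on -sims keeps the lowest index first among ties
    top = np.argsort(-sims, axis=1, kind="stable")[:, :k]
    return bank.patches[top].mean(axis=1)


def assemble_patches(patches: np.ndarray, coords: np.ndarray,
                     grid_dims, patch_shape) -> np.ndarray:
    """Place flat patches back into a voxel volume at their positions."""
    shape = tuple(d * p for d, p in zip(grid_dims, patch_shape))
    out = np.zeros(shape)
    for patch, (c0, c1, c2) in zip(patches, coords):
        out[c0 * patch_shape[0]:(c0 + 1) * patch_shape[0],
            c1 * patch_shape[1]:(c1 + 1) * patch_shape[1],
            c2 * patch_shape[2]:(c2 + 1) * patch_shape[2]] = \
            patch.reshape(patch_shape)
    return out


# ----------------------------------------------------------- cross-modal

def cross_modal_transfer(cross_scores, within_scores, labels,
                         n_boot: int = 10_000, seed: int = 0,
                         band: float = 0.05) -> dict:
    """Zero-shot transfer delta ΔAUROC = AUC(cross) − AUC(within) per class
    on the same target-modality studies, with paired study-level bootstrap
    percentile CIs and a ±``band`` equivalence verdict. Classes missing a
    positive or negative example are excluded."""
    zc = np.atleast_2d(np.asarray(cross_scores, dtype=np.float64))
    zw = np.atleast_2d(np.asarray(within_scores, dtype=np.float64))
    y = np.atleast_2d(np.asarray(labels).astype(int))
    n, kcls = y.shape
    rng = np.random.default_rng(seed)
    boot_idx = rng.integers(0, n, size=(n_boot, n))
    out = {}
    for c in range(kcls):
        if y[:, c].min() == y[:, c].max():
            out[c] = dict(excluded=True, reason="label absent in one class arm")
            continue
        delta = auroc(y[:, c], zc[:, c]) - auroc(y[:, c], zw[:, c])
        reps = []
        for b in range(n_boot):
            idx = boot_idx[b]
            yb = y[idx, c]
            if yb.min() == yb.max():
                continue
            reps.append(auroc(yb, zc[idx, c]) - auroc(yb, zw[idx, c]))
        lo, hi = (np.percentile(reps, [2.5, 97.5]) if reps
                  else (delta, delta))
        out[c] = dict(excluded=False, delta=float(delta),
                      ci=(float(lo), float(hi)),
                      within_band=bool(-band <= lo and hi <= band))
    return out
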