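"""Shard storage for processed volumes: flat binary shards plus a JSON
manifest giving per-volume byte offsets for zero-copy random access.

8-bit volumes are stored one byte per voxel; 4-bit volumes are packed two
voxels per byte, little-voxel-first (voxel 2i in the low nibble, voxel 2i+1
in the high nibble). Foreground masks are bit-packed. Round trips are
byte-exact and guarded by CRC32 checksums.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass

import numpy as np

from .preprocess import CT_WINDOWS, ForegroundMask, ProcessedVolume, WindowSpec

__all__ = ["ShardManifest", "write_shards", "read_volume", "compute_norm_stats"]

_MAX_SHARD_BYTES = 64 * 1024 * 1024


@dataclass
class ShardManifest:
    root: str
    entries: dict  # id -> record (shard, offsets, shape, bit depth, ...)
    stats: dict  # "modality/window" -> mean of scaled foreground voxels

    def save(self) -> str:
        path = os.path.join(self.root, "manifest.json")
        with open(path, "w") as fh:
            json.dump(dict(entries=self.entries, stats=self.stats), fh, indent=1)
        return path

    @classmethod
    def load(cls, root: str) -> "ShardManifest":
        with open(os.path.join(root, "manifest.json")) as fh:
            d = json.load(fh)
        return cls(root=root, entries=d["entries"], stats=d["stats"])


def _pack_nibbles(flat: np.ndarray) -> bytes:
    if flat.size % 2:
        flat = np.concatenate([flat, np.zeros(1, dtype=np.uint8)])
    pairs = flat.reshape(-1, 2)
    return ((pairs[:, 0] & 0x0F) | (pairs[:, 1] << 4)).astype(np.uint8).tobytes()


def _unpack_nibbles(buf: bytes, n: int) -> np.ndarray:
    raw = np.frombuffer(buf, dtype=np.uint8)
    out = np.empty(raw.size * 2, dtype=np.uint8)
    out[0::2] = raw & 0x0F
    out[1::2] = raw >> 4
    return out[:n]


def _payload(pv: ProcessedVolume) -> bytes:
    flat = pv.quantized.reshape(-1).astype(np.uint8)
    return _pack_nibbles(flat) if pv.bit_depth == 4 else flat.tobytes()


def write_shards(volumes: dict[str, ProcessedVolume], out_dir: str) -> ShardManifest:
    """Write volumes into ``shard_XXX.bin`` files under ``out_dir``.

    Also computes the per-(modality, window) mean of scaled foreground
    voxels used by :func:`voljepa.preprocess.normalize_for_model`.
    """
    if not volumes:
        raise ValueError("no volumes to write")
    os.makedirs(out_dir, exist_ok=True)
    entries: dict = {}
    shard_idx, offset = 0, 0
    fh = open(os.path.join(out_dir, f"shard_{shard_idx:03d}.bin"), "wb")
    sums: dict[str, list[float]] = {}
    try:
        for vid, pv in volumes.items():
            payload = _payload(pv)
            mask_bytes = b""
            if pv.foreground is not None:
                mask_bytes = np.packbits(
                    pv.foreground.mask.reshape(-1).astype(np.uint8)).tobytes()
            if offset and offset + len(payload) + len(mask_bytes) > _MAX_SHARD_BYTES:
                fh.close()
                shard_idx += 1
                offset = 0
                fh = open(os.path.join(out_dir, f"shard_{shard_idx:03d}.bin"), "wb")
            fh.write(payload)
            fh.write(mask_bytes)
            rec = dict(
                shard=f"shard_{shard_idx:03d}.bin", offset=offset,
                nbytes=len(payload), mask_nbytes=len(mask_bytes),
                shape=list(pv.quantized.shape), bit_depth=pv.bit_depth,
                modality=pv.modality, window=pv.window_tag,
                spacing_mm=list(pv.spacing_mm),
                clip_percentiles=list(pv.clip_percentiles)
                if pv.clip_percentiles else None,
                fg_method=pv.foreground.method if pv.foreground else None,
                fg_threshold=pv.foreground.threshold_value
                if pv.foreground else None,
                provenance=list(pv.provenance),
                crc32=zlib.crc32(payload + mask_bytes) & 0xFFFFFFFF)
            entries[vid] = rec
            offset += len(payload) + len(mask_bytes)
            # accumulate normalization statistic on scaled foreground voxels
            key = f"{pv.modality}/{pv.window_tag}"
            top = (1 << pv.bit_depth) - 1
            scaled = pv.quantized.astype(np.float64) / top
            if pv.foreground is not None:
                scaled = scaled[pv.foreground.mask]
            s = sums.setdefault(key, [0.0, 0.0])
            s[0] += float(scaled.sum())
            s[1] += float(scaled.size)
    finally:
        fh.close()
    stats = {k: s[0] / s[1] for k, (s) in sums.items() if s[1] > 0}
    man = ShardManifest(root=out_dir, entries=entries, stats=stats)
    man.save()
    return man


def read_volume(manifest: ShardManifest, vid: str) -> ProcessedVolume:
    if vid not in manifest.entries:
        raise KeyError(f"unknown volume id {vid!r}")
    rec = manifest.entries[vid]
    with open(os.path.join(manifest.root, rec["shard"]), "rb") as fh:
        fh.seek(rec["offset"])
        buf = fh.read(rec["nbytes"] + rec["mask_nbytes"])
    if (zlib.crc32(buf) & 0xFFFFFFFF) != rec["crc32"]:
        raise IOError(f"checksum mismatch for {vid!r} — corrupted offsets?")
    payload, mask_buf = buf[:rec["nbytes"]], buf[rec["nbytes"]:]
    shape = tuple(rec["shape"])
    n = int(np.prod(shape))
    if rec["bit_depth"] == 4:
        flat = _unpack_nibbles(payload, n)
    else:
        flat = np.frombuffer(payload, dtype=np.uint8)[:n].copy()
    fg = None
    if rec["mask_nbytes"]:
        bits = np.unpackbits(np.frombuffer(mask_buf, dtype=np.uint8))[:n]
        fg = ForegroundMask(mask=bits.astype(bool).reshape(shape),
                            method=rec["fg_method"],
                            threshold_value=rec["fg_threshold"])
    window = CT_WINDOWS.get(rec["window"]) if rec["window"] != "none" else None
    return ProcessedVolume(
        quantized=flat.reshape(shape), bit_depth=rec["bit_depth"],
        spacing_mm=tuple(rec["spacing_mm"]), modality=rec["modality"],
        foreground=fg, window=window,
        clip_percentiles=tuple(rec["clip_percentiles"])
        if rec["clip_percentiles"] else None,
        provenance=list(rec["provenance"]))


def compute_norm_stats(manifest: ShardManifest) -> dict[str, float]:
    """Recompute the normalization means by streaming the shards (the
    manifest already caches them at write time)."""
    sums: dict[str, list[float]] = {}
    for vid in manifest.entries:
        pv = read_volume(manifest, vid)
        key = f"{pv.modality}/{pv.window_tag}"
        top = (1 << pv.bit_depth) - 1
        scaled = pv.quantized.astype(np.float64) / top
        if pv.foreground is not None:
            scaled = scaled[pv.foreground.mask]
        s = sums.setdefault(key, [0.0, 0.0])
        s[0] += float(scaled.sum())
        s[1] += float(scaled.size)
    return {k: v[0] / v[1] for k, v in sums.items() if v[1] > 0}
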