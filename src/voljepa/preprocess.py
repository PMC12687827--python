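"""Series preprocessing: resampling, clipping, windowing, quantization,
foreground masking and normalization.

The pipeline mirrors routine clinical intensity handling: volumes are
resampled to 1×1 mm in-plane with 4 mm along the acquisition axis, MRI
intensities are clipped to the 0.5–99.5th percentile and quantized to 8 bits,
and CT volumes are rendered through three standard Hounsfield windows —
brain (width 80, level 40; 8-bit), subdural/blood (width 200, level 80;
4-bit) and bone (width 2800, level 600; 4-bit). Foreground masks remove air
only (no skull stripping): Otsu thresholding for MRI, a fixed −500 HU
threshold for CT, both with slice-wise hole filling. For model input,
quantized values are scaled to [0, 1] and mean-normalized with a statistic
computed over the training shards.

Rounding is nearest-integer with ties away from zero everywhere, so outputs
are reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantom import RawVolume

__all__ = [
    "WindowSpec",
    "CT_WINDOWS",
    "ProcessedVolume",
    "ForegroundMask",
    "resample_volume",
    "resample_labels",
    "clip_quantize_mri",
    "window_ct",
    "compute_foreground",
    "normalize_for_model",
]

TARGET_SPACING = (4.0, 1.0, 1.0)  # acquisition axis first
CT_FOREGROUND_HU = -500.0


@dataclass(frozen=True)
class WindowSpec:
    name: str
    width_hu: float
    level_hu: float
    bit_depth: int

    def __post_init__(self):
        if self.width_hu <= 0:
            raise ValueError("window width must be positive")
        if self.bit_depth not in (4, 8):
            raise ValueError("bit depth must be 4 or 8")

    @property
    def lo(self) -> float:
        return self.level_hu - self.width_hu / 2.0

    @property
    def hi(self) -> float:
        return self.level_hu + self.width_hu / 2.0


CT_WINDOWS = {
    "brain": WindowSpec("brain", 80.0, 40.0, 8),
    "blood": WindowSpec("blood", 200.0, 80.0, 4),
    "bone": WindowSpec("bone", 2800.0, 600.0, 4),
}


@dataclass
class ForegroundMask:
    mask: np.ndarray  # bool
    method: str  # "otsu" | "hounsfield_threshold"
    threshold_value: float


@dataclass
class ProcessedVolume:
    """Quantized volume ready for tokenization; provenance lists every step."""

    quantized: np.ndarray  # uint8 even at 4-bit depth (values 0..15)
    bit_depth: int
    spacing_mm: tuple[float, float, float]
    modality: str
    foreground: ForegroundMask | None = None
    window: WindowSpec | None = None
    clip_percentiles: tuple[float, float] | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        top = (1 << self.bit_depth) - 1
        if self.quantized.min() < 0 or self.quantized.max() > top:
            raise ValueError(f"quantized values outside [0, {top}]")
        if self.foreground is not None and \
                self.foreground.mask.shape != self.quantized.shape:
            raise ValueError("foreground shape mismatch")

    @property
    def window_tag(self) -> str:
        return self.window.name if self.window is not None else "none"


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Nearest integer, ties away from zero (np.round rounds half-to-even)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def resample_volume(vol: RawVolume,
                    target_spacing: tuple[float, float, float] = TARGET_SPACING,
                    ) -> RawVolume:
    """Trilinear resample onto the pipeline grid.

    ``target_spacing`` is given acquisition-axis-first and is reordered so
    the 4 mm step lands on ``vol.acquisition_axis``. Output shape is
    round(extent_mm / target_spacing) per axis, at least 1.
    """
    if any(s <= 0 for s in vol.spacing_mm):
        raise ValueError("spacing must be strictly positive")
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target spacing must be strictly positive")
    tgt = list(target_spacing[1:])
    tgt.insert(vol.acquisition_axis, target_spacing[0])
    src = vol.spacing_mm
    if tuple(src) == tuple(tgt):
        return RawVolume(voxels=vol.voxels.copy(), spacing_mm=tuple(tgt),
                         modality=vol.modality,
                         intensity_units=vol.intensity_units,
                         acquisition_axis=vol.acquisition_axis)
    out_shape = tuple(
        max(1, int(_round_half_away(np.array(n * src[i] / tgt[i]))))
        for i, n in enumerate(vol.voxels.shape))
    out = _grid_interp(vol.voxels, out_shape, src, tgt, order=1)
    return RawVolume(voxels=out, spacing_mm=tuple(tgt), modality=vol.modality,
                     intensity_units=vol.intensity_units,
                     acquisition_axis=vol.acquisition_axis)


def resample_labels(labels: np.ndarray, spacing, target_spacing=TARGET_SPACING,
                    acquisition_axis: int = 0) -> np.ndarray:
    """Nearest-neighbour resample for label/mask grids (same grid geometry
    as :func:`resample_volume`)."""
    tgt = list(target_spacing[1:])
    tgt.insert(acquisition_axis, target_spacing[0])
    if tuple(spacing) == tuple(tgt):
        return labels.copy()
    out_shape = tuple(
        max(1, int(_round_half_away(np.array(n * spacing[i] / tgt[i]))))
        for i, n in enumerate(labels.shape))
    return _grid_interp(labels.astype(np.float64), out_shape, spacing, tgt,
                        order=0).astype(labels.dtype)


def _grid_interp(data, out_shape, src_spacing, tgt_spacing, order):
    """Sample the source on the voxel-centre grid of the target spacing."""
    coords = np.meshgrid(*[
        (np.arange(n) + 0.5) * tgt_spacing[i] / src_spacing[i] - 0.5
        for i, n in enumerate(out_shape)], indexing="ij")
    return ndimage.map_coordinates(data, coords, order=order, mode="nearest")


def clip_quantize_mri(vol: RawVolume, p_low: float = 0.5,
                      p_high: float = 99.5) -> ProcessedVolume:
    """Percentile clip and 8-bit quantization for MRI.

    Percentiles are computed over all voxels of the volume. A constant
    volume (degenerate percentile range) quantizes to all zeros and is
    flagged in provenance.
    """
    if vol.modality != "MRI":
        raise ValueError("clip_quantize_mri expects an MRI volume")
    lo, hi = np.percentile(vol.voxels, [p_low, p_high])
    prov = [f"resampled@{vol.spacing_mm}", f"clip[{p_low},{p_high}]pct"]
    if hi == lo:
        q = np.zeros(vol.voxels.shape, dtype=np.uint8)
        prov.append("degenerate-range")
    else:
        x = np.clip(vol.voxels, lo, hi)
        q = _round_half_away((x - lo) / (hi - lo) * 255.0).astype(np.uint8)
        prov.append("quantize8")
    return ProcessedVolume(quantized=q, bit_depth=8, spacing_mm=vol.spacing_mm,
                           modality="MRI", clip_percentiles=(p_low, p_high),
                           provenance=prov)


def window_ct(vol: RawVolume, w: WindowSpec) -> ProcessedVolume:
    """Clip HU to [level − width/2, level + width/2] and quantize."""
    if vol.modality != "CT" or vol.intensity_units != "HU":
        raise ValueError("window_ct expects a CT volume in HU")
    top = (1 << w.bit_depth) - 1
    x = np.clip(vol.voxels, w.lo, w.hi)
    q = _round_half_away((x - w.lo) / w.width_hu * top).astype(np.uint8)
    return ProcessedVolume(quantized=q, bit_depth=w.bit_depth,
                           spacing_mm=vol.spacing_mm, modality="CT", window=w,
                           provenance=[f"resampled@{vol.spacing_mm}",
                                       f"window:{w.name}",
                                       f"quantize{w.bit_depth}"])


def _fill_holes_slicewise(mask: np.ndarray, axis: int = 0) -> np.ndarray:
    out = np.empty_like(mask)
    sl = [slice(None)] * mask.ndim
    for i in range(mask.shape[axis]):
        sl[axis] = i
        out[tuple(sl)] = ndimage.binary_fill_holes(mask[tuple(sl)])
    return out


def compute_foreground(vol: RawVolume) -> ForegroundMask:
    """Air-removing foreground mask.

    MRI: Otsu threshold on a 256-bin histogram, foreground above threshold.
    CT: foreground where HU > −500. Both filled slice-wise along the
    acquisition axis. An all-background result signals a misconfigured
    pipeline and raises.
    """
    if vol.modality == "CT":
        thr = CT_FOREGROUND_HU
        mask = vol.voxels > thr
        method = "hounsfield_threshold"
    else:
        from skimage.filters import threshold_otsu

        thr = float(threshold_otsu(vol.voxels, nbins=256))
        mask = vol.voxels > thr
        method = "otsu"
    mask = _fill_holes_slicewise(mask, axis=vol.acquisition_axis)
    if not mask.any():
        raise ValueError("foreground mask is empty — pipeline misconfiguration")
    return ForegroundMask(mask=mask, method=method, threshold_value=float(thr))


def normalize_for_model(pv: ProcessedVolume, manifest_stats: dict) -> np.ndarray:
    """Scale to [0,1], subtract the (modality, window) training mean, and
    zero the background. ``manifest_stats`` maps "modality/window_tag" to
    the mean of scaled foreground voxels on the training shards."""
    key = f"{pv.modality}/{pv.window_tag}"
    if key not in manifest_stats:
        raise KeyError(f"no normalization statistic for {key}")
    top = (1 << pv.bit_depth) - 1
    out = pv.quantized.astype(np.float64) / top - float(manifest_stats[key])
    if pv.foreground is not None:
        out[~pv.foreground.mask] = 0.0
    return out
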