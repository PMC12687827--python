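"""Synthetic volumetric head phantoms.

Generates nested-ellipsoid head/skull/brain/ventricle geometry with optional
lesions, rendered either as CT (Hounsfield units) or MRI (arbitrary intensity
scale with a smooth multiplicative bias field). Every downstream stage of the
package — preprocessing, tokenization, Vol-JEPA pretraining, probing and the
emergent-ability evaluations — is exercised on these phantoms, so the module
also produces paired CT/MRI studies sharing one geometry and long-tailed
multi-label cohorts.

Axis convention throughout the package: arrays are indexed (slice, row, col)
with the acquisition axis = axis 0; spacing_mm is given in the same order.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PhantomSpec",
    "RawVolume",
    "RegionLabelMap",
    "StudyRecord",
    "DEFAULT_ONTOLOGY",
    "LESION_TABLE",
    "make_phantom_volume",
    "make_study",
    "make_paired_study",
    "make_cohort",
    "resample_by_rarity",
    "write_study_nifti",
    "read_volume_nifti",
]

# region ids in every RegionLabelMap
AIR, SCALP, SKULL, BRAIN, VENTRICLE = 0, 1, 2, 3, 4
LESION_BASE = 5  # lesion k occupies id LESION_BASE + k

BASE_LEGEND = {AIR: "air", SCALP: "scalp", SKULL: "skull",
               BRAIN: "brain", VENTRICLE: "ventricle"}

# CT rendering in HU: air -1000, soft tissue ~40, bone ~1000, brain ~35,
# CSF ~10; lesion HU set per kind (blood ~65).
CT_HU = {AIR: -1000.0, SCALP: 40.0, SKULL: 1000.0, BRAIN: 35.0, VENTRICLE: 10.0}
# MRI arbitrary scale (T1-like: CSF dark, bone dark, scalp fat bright).
MRI_INTENSITY = {AIR: 5.0, SCALP: 160.0, SKULL: 60.0, BRAIN: 100.0, VENTRICLE: 40.0}

DEFAULT_ONTOLOGY = ("hemorrhage", "tumor", "infarct", "edema",
                    "bleed_left", "bleed_right")

# Declarative lesion->label mapping: kind -> (label, triage, radius range in
# voxels, CT HU, MRI intensity offset vs brain, lateral constraint).
# The clinical 74/82-label ontology this stands in for is private; six toy
# labels cover the behaviours the evaluations need (co-occurrence, rarity,
# urgency, sidedness).
LESION_TABLE = {
    "hemorrhage": dict(label="hemorrhage", triage="urgent", radius=(3, 6),
                       ct_hu=65.0, mri_offset=80.0, side=None),
    "tumor": dict(label="tumor", triage="routine", radius=(4, 7),
                  ct_hu=45.0, mri_offset=60.0, side=None),
    "infarct": dict(label="infarct", triage="urgent", radius=(3, 6),
                    ct_hu=20.0, mri_offset=-40.0, side=None),
    "edema": dict(label="edema", triage="routine", radius=(4, 7),
                  ct_hu=25.0, mri_offset=45.0, side=None),
    "bleed_left": dict(label="bleed_left", triage="urgent", radius=(3, 6),
                       ct_hu=65.0, mri_offset=80.0, side="left"),
    "bleed_right": dict(label="bleed_right", triage="urgent", radius=(3, 6),
                        ct_hu=65.0, mri_offset=80.0, side="right"),
}

TRIAGE_ORDER = ("unremarkable", "routine", "urgent")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom draw; seed determines output bits."""

    grid_shape: tuple[int, int, int] = (16, 64, 64)
    spacing_mm: tuple[float, float, float] = (4.0, 1.0, 1.0)
    modality: str = "MRI"  # "MRI" | "CT"
    # list of (lesion_kind, (r_lo, r_hi) voxel radius range, intensity offset
    # override or None to use the table default)
    lesion_menu: tuple = ()
    noise_sd: float = 2.0
    bias_field_amplitude: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.modality not in ("MRI", "CT"):
            raise ValueError(f"modality must be MRI or CT, got {self.modality}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")
        if self.noise_sd < 0 or self.bias_field_amplitude < 0:
            raise ValueError("noise_sd and bias_field_amplitude must be >= 0")


@dataclass
class RawVolume:
    """Voxel grid plus the metadata every pipeline stage needs."""

    voxels: np.ndarray  # float, (slice,row,col)
    spacing_mm: tuple[float, float, float]
    modality: str
    intensity_units: str  # "HU" | "arbitrary"
    acquisition_axis: int = 0

    def __post_init__(self):
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels must be finite")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")
        if self.intensity_units == "HU":
            lo, hi = float(self.voxels.min()), float(self.voxels.max())
            if lo < -1024 or hi > 3071:
                raise ValueError(f"CT volume outside [-1024, 3071] HU: [{lo}, {hi}]")


@dataclass
class RegionLabelMap:
    labels: np.ndarray  # int, same shape as voxels
    legend: dict[int, str]

    def region_mask(self, name: str) -> np.ndarray:
        ids = [k for k, v in self.legend.items() if v == name]
        if not ids:
            raise KeyError(f"region {name!r} not in legend")
        return np.isin(self.labels, ids)

    def lesion_mask(self) -> np.ndarray:
        return self.labels >= LESION_BASE


@dataclass
class StudyRecord:
    study_id: str
    series: list[RawVolume]
    region_maps: list[RegionLabelMap]
    diagnosis_labels: np.ndarray  # binary vector over ontology
    ontology: tuple[str, ...]
    triage_class: str

    def __post_init__(self):
        if len(self.series) < 1:
            raise ValueError("study needs at least one series")


def _ellipsoid_mask(shape, center, semi_axes):
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return q <= 1.0


def _build_geometry(spec: PhantomSpec, rng: np.random.Generator):
    """Nested ellipsoids + lesions. Returns labels + legend."""
    shape = tuple(spec.grid_shape)
    labels = np.zeros(shape, dtype=np.int16)
    center = tuple((s - 1) / 2.0 for s in shape)
    # semi-axes as fractions of the grid; head fills most of the FOV
    head_ax = tuple(0.46 * s for s in shape)
    skull_ax = tuple(0.42 * s for s in shape)
    brain_ax = tuple(0.36 * s for s in shape)
    labels[_ellipsoid_mask(shape, center, head_ax)] = SCALP
    labels[_ellipsoid_mask(shape, center, skull_ax)] = SKULL
    brain = _ellipsoid_mask(shape, center, brain_ax)
    labels[brain] = BRAIN
    # two lateral ventricles: small ellipsoids offset left/right of midline
    v_ax = tuple(max(1.2, 0.08 * s) for s in shape)
    for off in (-0.10, 0.10):
        vc = (center[0], center[1], center[2] + off * shape[2])
        labels[_ellipsoid_mask(shape, vc, v_ax) & brain] = VENTRICLE

    legend = dict(BASE_LEGEND)
    lesion_info = []
    for k, entry in enumerate(spec.lesion_menu):
        kind, size_range, offset = entry
        table = LESION_TABLE[kind]
        r_lo, r_hi = size_range if size_range is not None else table["radius"]
        if r_lo <= 0 or r_hi < r_lo:
            raise ValueError("lesion size range must be positive")
        radius = rng.uniform(r_lo, r_hi)
        # anisotropic voxel radius: radius is in in-plane voxels; along the
        # coarse acquisition axis scale by the spacing ratio
        ax = (max(1.0, radius * spec.spacing_mm[1] / spec.spacing_mm[0]),
              radius, radius)
        if any(a >= b for a, b in zip(ax, brain_ax)):
            raise ValueError(
                f"lesion semi-axes {ax} do not fit inside the brain "
                f"(semi-axes {tuple(round(b, 1) for b in brain_ax)})")
        # sample a centre inside the brain honouring the side constraint
        for _ in range(200):
            u = rng.uniform(-0.6, 0.6, size=3)
            c = tuple(center[i] + u[i] * brain_ax[i] for i in range(3))
            if table["side"] == "left" and c[2] >= center[2]:
                continue
            if table["side"] == "right" and c[2] <= center[2]:
                continue
            m = _ellipsoid_mask(shape, c, ax)
            if m.sum() and (labels[m] >= BRAIN).all():
                labels[m] = LESION_BASE + k
                break
        else:
            raise ValueError(f"could not place lesion {kind!r} inside the brain")
        legend[LESION_BASE + k] = f"lesion-{kind}"
        lesion_info.append(dict(kind=kind, id=LESION_BASE + k, offset=offset))
    return labels, legend, lesion_info


def _bias_field(shape, amplitude, rng):
    """Low-order smooth multiplicative field in [1-a, 1+a]."""
    if amplitude == 0:
        return np.ones(shape)
    grids = np.meshgrid(*[np.linspace(0, np.pi, s) for s in shape],
                        indexing="ij", sparse=True)
    phase = rng.uniform(0, 2 * np.pi, size=3)
    f = sum(np.cos(g + p) for g, p in zip(grids, phase)) / 3.0
    return 1.0 + amplitude * f


def _render(labels, legend, lesion_info, spec, rng):
    if spec.modality == "CT":
        base = CT_HU
        img = np.empty(labels.shape, dtype=np.float64)
        for rid in BASE_LEGEND:
            img[labels == rid] = base[rid]
        for info in lesion_info:
            table = LESION_TABLE[info["kind"]]
            hu = table["ct_hu"] if info["offset"] is None else 35.0 + info["offset"]
            img[labels == info["id"]] = hu
        img += rng.normal(0.0, spec.noise_sd, size=labels.shape)
        np.clip(img, -1024, 3071, out=img)
        units = "HU"
    else:
        img = np.empty(labels.shape, dtype=np.float64)
        for rid in BASE_LEGEND:
            img[labels == rid] = MRI_INTENSITY[rid]
        for info in lesion_info:
            table = LESION_TABLE[info["kind"]]
            off = table["mri_offset"] if info["offset"] is None else info["offset"]
            img[labels == info["id"]] = MRI_INTENSITY[BRAIN] + off
        img *= _bias_field(labels.shape, spec.bias_field_amplitude, rng)
        img += rng.normal(0.0, spec.noise_sd, size=labels.shape)
        np.clip(img, 0.0, None, out=img)
        units = "arbitrary"
    return img, units


def make_phantom_volume(spec: PhantomSpec) -> tuple[RawVolume, RegionLabelMap]:
    """Render one phantom volume; deterministic given ``spec`` (incl. seed)."""
    if any(s < p for s, p in zip(spec.grid_shape, (4, 16, 16))):
        raise ValueError("grid smaller than one 4x16x16 patch")
    rng = np.random.default_rng(spec.seed)
    labels, legend, lesion_info = _build_geometry(spec, rng)
    img, units = _render(labels, legend, lesion_info, spec, rng)
    vol = RawVolume(voxels=img, spacing_mm=spec.spacing_mm,
                    modality=spec.modality, intensity_units=units)
    return vol, RegionLabelMap(labels=labels, legend=legend)


def _labels_from_menu(menu, ontology) -> np.ndarray:
    vec = np.zeros(len(ontology), dtype=np.int8)
    for kind, _, _ in menu:
        vec[ontology.index(LESION_TABLE[kind]["label"])] = 1
    return vec


def _triage_from_menu(menu) -> str:
    t = "unremarkable"
    for kind, _, _ in menu:
        cand = LESION_TABLE[kind]["triage"]
        if TRIAGE_ORDER.index(cand) > TRIAGE_ORDER.index(t):
            t = cand
    return t


def make_study(spec: PhantomSpec, study_id: str = "study-0",
               ontology=DEFAULT_ONTOLOGY) -> StudyRecord:
    vol, rmap = make_phantom_volume(spec)
    return StudyRecord(
        study_id=study_id, series=[vol], region_maps=[rmap],
        diagnosis_labels=_labels_from_menu(spec.lesion_menu, list(ontology)),
        ontology=tuple(ontology),
        triage_class=_triage_from_menu(spec.lesion_menu))


def make_paired_study(spec: PhantomSpec,
                      ontology=DEFAULT_ONTOLOGY) -> tuple[StudyRecord, StudyRecord]:
    """CT and MRI studies sharing one geometry and one label vector.

    The geometry stage consumes an identical RNG stream for both renderings,
    so the two RegionLabelMaps are voxelwise equal.
    """
    ct = make_study(replace(spec, modality="CT"), study_id="paired-ct",
                    ontology=ontology)
    mri = make_study(replace(spec, modality="MRI"), study_id="paired-mri",
                     ontology=ontology)
    return ct, mri


def make_cohort(n: int, prevalences: dict[str, float],
                spec_template: PhantomSpec, seed: int = 0,
                ontology=DEFAULT_ONTOLOGY) -> list[StudyRecord]:
    """Draw ``n`` studies with independent Bernoulli labels.

    Long-tailed multi-label cohorts arise from unequal prevalences; labels
    may co-occur. A study with no drawn label is "unremarkable".
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for k, p in prevalences.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"prevalence for {k} outside [0,1]")
        if k not in LESION_TABLE:
            raise KeyError(f"unknown label {k!r}")
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n):
        menu = tuple((k, None, None) for k, p in prevalences.items()
                     if rng.random() < p)
        spec = replace(spec_template, lesion_menu=menu,
                       seed=int(rng.integers(0, 2**31 - 1)))
        cohort.append(make_study(spec, study_id=f"study-{i}", ontology=ontology))
    return cohort


def resample_by_rarity(cohort: list[StudyRecord], m: int,
                       seed: int = 0) -> list[StudyRecord]:
    """Weighted resampling with replacement, weight ∝ 1/prevalence of the
    study's rarest label; label-free studies use the prevalence of the
    "unremarkable" pseudo-label."""
    if not cohort:
        raise ValueError("empty cohort")
    n = len(cohort)
    labmat = np.stack([s.diagnosis_labels for s in cohort])
    prev = labmat.mean(axis=0)
    p_unrem = float((labmat.sum(axis=1) == 0).mean())
    weights = np.empty(n)
    for i, s in enumerate(cohort):
        idx = np.flatnonzero(s.diagnosis_labels)
        if idx.size:
            weights[i] = 1.0 / prev[idx].min()
        else:
            weights[i] = 1.0 / p_unrem
    weights /= weights.sum()
    rng = np.random.default_rng(seed)
    picks = rng.choice(n, size=m, replace=True, p=weights)
    return [cohort[i] for i in picks]


# ---------------------------------------------------------------- NIfTI IO

def write_study_nifti(study: StudyRecord, out_dir: str) -> str:
    """One .nii.gz per series (+ labels) and a JSON metadata record.

    The array's (slice,row,col) axes map directly onto the NIfTI i,j,k axes,
    with spacing carried in the affine diagonal.
    """
    import nibabel as nib

    os.makedirs(out_dir, exist_ok=True)
    meta = dict(study_id=study.study_id, ontology=list(study.ontology),
                diagnosis_labels=[int(v) for v in study.diagnosis_labels],
                triage_class=study.triage_class, series=[])
    for i, (vol, rmap) in enumerate(zip(study.series, study.region_maps)):
        affine = np.diag(list(vol.spacing_mm) + [1.0])
        img_path = os.path.join(out_dir, f"{study.study_id}_series{i}.nii.gz")
        lab_path = os.path.join(out_dir, f"{study.study_id}_series{i}_labels.nii.gz")
        nib.save(nib.Nifti1Image(vol.voxels.astype(np.float32), affine), img_path)
        nib.save(nib.Nifti1Image(rmap.labels.astype(np.int16), affine), lab_path)
        meta["series"].append(dict(image=os.path.basename(img_path),
                                   labels=os.path.basename(lab_path),
                                   modality=vol.modality,
                                   intensity_units=vol.intensity_units,
                                   spacing_mm=list(vol.spacing_mm),
                                   legend={str(k): v for k, v in rmap.legend.items()}))
    meta_path = os.path.join(out_dir, f"{study.study_id}.json")
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1)
    return meta_path


def read_volume_nifti(path: str, modality: str,
                      intensity_units: str | None = None) -> RawVolume:
    import nibabel as nib

    img = nib.load(path)
    data = np.asanyarray(img.dataobj).astype(np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if intensity_units is None:
        intensity_units = "HU" if modality == "CT" else "arbitrary"
    return RawVolume(voxels=data, spacing_mm=spacing, modality=modality,
                     intensity_units=intensity_units)
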