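"""Synthetic multimodal brain phantoms with graded edema texture.

Each phantom subject is a skull-stripped head ellipsoid containing a
nested tumor: an ellipsoidal necrotic core (label 1) inside an enhancing
shell (label 4) inside a peritumoral-edema shell (label 2).  Edema-voxel
intensities are drawn from a grade-dependent stationary Gaussian random
field (Gaussian-kernel-smoothed white noise, correlation length = kernel
sigma) so that low- and high-grade subjects differ in edema texture, the
signal the downstream radiomics/classification chain is meant to detect.

Cohorts reproduce the class imbalance of a typical preoperative glioma
series: ~81% high-grade, ~19% low-grade.
"""

from __future__ import annotations


from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import (
    LABEL_EDEMA,
    LABEL_ENHANCING,
    LABEL_NECROTIC,
    MODALITIES,
    SegMask,
    SubjectRecord,
    VolumeImage,
)

__all__ = [
    "EdemaTexture",
    "PhantomParams",
    "generate_subject",
    "generate_cohort",
    "write_cohort",
    "load_cohort",
]


@dataclass(frozen=True)
class EdemaTexture:
    """Stationary Gaussian-random-field descriptor for edema intensities.

    corr_len_vox
        correlation length of the field in voxels (sigma of the Gaussian
        smoothing kernel applied to white noise).
    mean_offset
        mean edema intensity in working units (~[0, 255] scale).
    variance
        marginal variance of the field.
    """

    corr_len_vox: float
    mean_offset: float
    variance: float

    def __post_init__(self) -> None:
        if self.corr_len_vox < 0 or self.variance < 0:
            raise ValueError("corr_len_vox and variance must be nonnegative")


# Defaults plant a strong, detectable grade effect: high-grade edema is
# brighter, more variable and more spatially coherent than low-grade.
DEFAULT_LGG_TEXTURE = EdemaTexture(corr_len_vox=1.0, mean_offset=110.0, variance=144.0)
DEFAULT_HGG_TEXTURE = EdemaTexture(corr_len_vox=2.5, mean_offset=140.0, variance=484.0)

# Fixed per-modality affine intensity remaps (scale, offset) plus shell
# contrasts, so the four weights are co-registered but non-identical.
# Edema is brightest in the FLAIR-like channel; the enhancing shell is
# brightest in the T1Gd-like channel, mimicking gadolinium uptake.
MODALITY_PROFILES: dict[str, dict[str, float]] = {
    "T1": {"scale": 0.9, "offset": 5.0, "core": 40.0, "enh": 90.0, "edema_gain": 0.55, "tissue": 120.0},
    "T1Gd": {"scale": 1.0, "offset": 0.0, "core": 45.0, "enh": 210.0, "edema_gain": 0.60, "tissue": 125.0},
    "T2": {"scale": 1.1, "offset": 8.0, "core": 150.0, "enh": 110.0, "edema_gain": 0.85, "tissue": 100.0},
    "FLAIR": {"scale": 1.0, "offset": 12.0, "core": 120.0, "enh": 100.0, "edema_gain": 1.0, "tissue": 95.0},
}


@dataclass(frozen=True)
class PhantomParams:
    """Generation parameters for a synthetic graded cohort."""

    volume_shape: tuple[int, int, int] = (48, 48, 48)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_subjects: int = 100
    hgg_fraction: float = 0.81
    edema_texture_lgg: EdemaTexture = DEFAULT_LGG_TEXTURE
    edema_texture_hgg: EdemaTexture = DEFAULT_HGG_TEXTURE
    noise_sd: float = 4.0
    subject_jitter_sd: float = 5.0  # per-subject jitter on edema mean intensity
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.volume_shape) != 3 or any(int(d) < 16 for d in self.volume_shape):
            raise ValueError(f"volume_shape dims must all be >= 16, got {self.volume_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be positive")
        if not (0.0 < self.hgg_fraction < 1.0):
            raise ValueError("hgg_fraction must lie in (0, 1)")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def texture_for(self, grade: str) -> EdemaTexture:
        return self.edema_texture_hgg if grade == "HGG" else self.edema_texture_lgg


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def gaussian_random_field(shape, corr_len_vox: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-variance stationary GRF via smoothed white noise."""
    white = rng.standard_normal(shape)
    if corr_len_vox <= 0:
        return white
    smooth = ndimage.gaussian_filter(white, sigma=corr_len_vox, mode="reflect")
    sd = smooth.std()
    if sd == 0:  # pragma: no cover - only for degenerate tiny shapes
        return smooth
    return smooth / sd


def generate_subject(
    params: PhantomParams,
    grade: str,
    rng: np.random.Generator,
    subject_id: str = "sub-000",
) -> SubjectRecord:
    """Generate one phantom subject of the requested grade.

    The mask nests core (1) inside enhancing shell (4) inside edema (2);
    edema intensities follow the grade's texture descriptor plus additive
    Gaussian noise; the four modalities differ by fixed intensity remaps.
    """
    if grade not in ("LGG", "HGG"):
        raise ValueError(f"grade must be LGG or HGG, got {grade!r}")
    shape = tuple(int(d) for d in params.volume_shape)
    if any(d < 16 for d in shape):
        raise ValueError(f"volume_shape dims must all be >= 16, got {shape}")

    center = np.array(shape) / 2.0
    head_radii = np.array(shape) * 0.46
    head = _ellipsoid(shape, center, head_radii)

    # Tumor geometry: randomized center (within the head) and shell radii.
    max_edema_r = min(shape) * 0.27
    r_edema = rng.uniform(0.75, 1.0) * max_edema_r
    r_enh = r_edema * rng.uniform(0.52, 0.62)
    r_core = r_edema * rng.uniform(0.28, 0.38)
    offset = rng.uniform(-0.08, 0.08, size=3) * np.array(shape)
    t_center = center + offset

    edema_ball = _ellipsoid(shape, t_center, [r_edema] * 3) & head
    enh_ball = _ellipsoid(shape, t_center, [r_enh] * 3) & head
    core_ball = _ellipsoid(shape, t_center, [r_core] * 3) & head

    mask = np.zeros(shape, dtype=np.int16)
    mask[edema_ball] = LABEL_EDEMA
    mask[enh_ball] = LABEL_ENHANCING
    mask[core_ball] = LABEL_NECROTIC

    n_edema = int((mask == LABEL_EDEMA).sum())
    if n_edema < 64:
        raise RuntimeError(f"degenerate phantom: only {n_edema} edema voxels")

    tex = params.texture_for(grade)
    subject_mean = tex.mean_offset + rng.normal(0.0, params.subject_jitter_sd)

    # Shared anatomy + texture fields; modality transforms are deterministic.
    tissue_field = gaussian_random_field(shape, 3.0, rng)  # smooth parenchyma pattern
    edema_field = gaussian_random_field(shape, tex.corr_len_vox, rng)
    noise = {m: rng.standard_normal(shape) * params.noise_sd for m in MODALITIES}

    spacing = params.spacing_mm
    modalities: dict[str, VolumeImage] = {}
    edema_only = mask == LABEL_EDEMA
    for m in MODALITIES:
        prof = MODALITY_PROFILES[m]
        vol = np.zeros(shape, dtype=np.float64)
        vol[head] = prof["tissue"] + 12.0 * tissue_field[head]
        vol[edema_only] = prof["edema_gain"] * (
            subject_mean + np.sqrt(tex.variance) * edema_field[edema_only]
        )
        vol[mask == LABEL_ENHANCING] = prof["enh"]
        vol[mask == LABEL_NECROTIC] = prof["core"]
        vol = prof["scale"] * vol + prof["offset"]
        vol[head] += noise[m][head]
        vol[~head] = 0.0  # skull-stripped background is exactly zero
        np.clip(vol, 0.0, None, out=vol)
        modalities[m] = VolumeImage(vol, spacing)

    return SubjectRecord(
        subject_id=subject_id,
        modalities=modalities,
        mask=SegMask(mask, spacing),
        grade=grade,
    )


def _grade_sequence(params: PhantomParams) -> list[str]:
    n_hgg = int(round(params.hgg_fraction * params.n_subjects))
    n_lgg = params.n_subjects - n_hgg
    if n_hgg == 0 or n_lgg == 0:
        raise ValueError(
            f"hgg_fraction={params.hgg_fraction} yields an empty class "
            f"for n_subjects={params.n_subjects}"
        )
    return ["HGG"] * n_hgg + ["LGG"] * n_lgg


def generate_cohort(params: PhantomParams) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Generate a reproducible graded cohort and its manifest.

    HGG count = round(hgg_fraction * n_subjects); subjects are generated
    from independent child RNG streams of the master seed, so the cohort
    is bit-reproducible.
    """
    if params.n_subjects < 10:
        raise ValueError("n_subjects must be >= 10 for a cohort")
    grades = _grade_sequence(params)
    seq = np.random.SeedSequence(params.seed)
    children = seq.spawn(len(grades))
    records = []
    rows = []
    for i, (grade, child) in enumerate(zip(grades, children)):
        sid = f"sub-{i:03d}"
        rec = generate_subject(params, grade, np.random.default_rng(child), subject_id=sid)
        records.append(rec)
        row = {"subject_id": sid, "grade": grade, "excluded": False}
        for m in MODALITIES:
            row[f"path_{m}"] = f"{sid}/{sid}_{m}.nii.gz"
        row["path_mask"] = f"{sid}/{sid}_mask.nii.gz"
        rows.append(row)
    manifest = pd.DataFrame(rows)
    return records, manifest


def write_cohort(records: list[SubjectRecord], manifest: pd.DataFrame, out_dir) -> Path:
    """Write a cohort as per-subject NIfTI files plus a manifest CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in records:
        sub_dir = out / rec.subject_id
        sub_dir.mkdir(exist_ok=True)
        for m, vol in rec.modalities.items():
            vol.to_nifti().to_filename(str(sub_dir / f"{rec.subject_id}_{m}.nii.gz"))
        rec.mask.to_nifti().to_filename(str(sub_dir / f"{rec.subject_id}_mask.nii.gz"))
    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def load_cohort(cohort_dir) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Load a cohort previously written by :func:`write_cohort`."""
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.csv")
    records = []
    for _, row in manifest.iterrows():
        if row.get("excluded", False):
            continue
        modalities = {
            m: VolumeImage.from_nifti(cohort_dir / row[f"path_{m}"]) for m in MODALITIES
        }
        mask = SegMask.from_nifti(cohort_dir / row["path_mask"])
        records.append(
            SubjectRecord(row["subject_id"], modalities, mask, row["grade"])
        )
    return records, manifest
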