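"""Reduce MNI-space brain volumes to per-subject VOI uptake vectors.

Chain per subject: optional Gaussian smoothing (world-space FWHM) →
intensity normalization by whole-brain mean → mean uptake within each VOI
mask.  A pre-extracted cohort table (TSV) can bypass the imaging stage
entirely; see :func:`read_cohort_tsv` / :func:`write_cohort_tsv`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas import VOIDefinition, VOIMaskSet, build_sphere_masks

__all__ = [
    "BrainVolume",
    "SubjectUptake",
    "gaussian_smooth",
    "normalize_by_brain_mean",
    "auto_brain_mask",
    "extract_voi_means",
    "build_cohort_table",
    "read_volume",
    "cohort_to_frame",
    "frame_to_cohort",
    "write_cohort_tsv",
    "read_cohort_tsv",
    "FWHM_TO_SIGMA",
]

# sigma = FWHM / (2 * sqrt(2 * ln 2))
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class BrainVolume:
    """A 3-D scalar image with its voxel-to-world affine and subject metadata."""

    data: np.ndarray
    affine: np.ndarray
    subject_id: str
    group: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D volume, got {self.data.ndim}-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"subject {self.subject_id}: non-finite voxel values")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class SubjectUptake:
    """One subject's mean normalized uptake per VOI, in atlas order."""

    subject_id: str
    group: str
    values: np.ndarray
    voi_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.voi_names = tuple(self.voi_names)
        if self.values.ndim != 1 or len(self.values) != len(self.voi_names):
            raise ValueError("uptake vector length must match VOI name list")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"subject {self.subject_id}: non-finite uptake values")


def read_volume(path, subject_id: str, group: str) -> BrainVolume:
    """Read a NIfTI-1 or Analyze 7.5 volume from disk.

    Analyze inputs are taken in the reader's default orientation; callers
    that know the image is flipped must reorient before extraction.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return BrainVolume(data=data, affine=img.affine, subject_id=subject_id, group=group)


def gaussian_smooth(volume: BrainVolume, fwhm_mm: float) -> BrainVolume:
    """Isotropic world-space Gaussian smoothing; ``fwhm_mm = 0`` is identity.

    Per-axis sigma in voxels is ``fwhm_mm * FWHM_TO_SIGMA / voxel_size``.
    Boundaries use nearest-edge replication so brain-edge voxels are not
    dimmed by zero padding.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return replace(volume, data=volume.data.copy())
    if abs(np.linalg.det(volume.affine)) < 1e-12:
        raise ValueError("affine is not invertible; cannot derive voxel sizes")
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / volume.voxel_sizes()
    smoothed = ndimage.gaussian_filter(volume.data, sigma=sigma_vox, mode="nearest")
    return replace(volume, data=smoothed)


def auto_brain_mask(data: np.ndarray) -> np.ndarray:
    """Threshold mask: voxels above 12.5% of the 99th-percentile intensity."""
    robust_max = np.percentile(data, 99)
    return data > 0.125 * robust_max


def normalize_by_brain_mean(volume: BrainVolume, brain_mask="auto") -> BrainVolume:
    """Divide every voxel by the mean intensity within the brain mask.

    After normalization the masked mean is exactly 1.  ``brain_mask`` may be
    a boolean volume or ``"auto"`` (see :func:`auto_brain_mask`).
    """
    if isinstance(brain_mask, str):
        if brain_mask != "auto":
            raise ValueError(f"unknown mask mode {brain_mask!r}")
        mask = auto_brain_mask(volume.data)
    else:
        mask = np.asarray(brain_mask, dtype=bool)
        if mask.shape != volume.data.shape:
            raise ValueError("brain mask shape mismatch")
    if not mask.any():
        raise ValueError(f"subject {volume.subject_id}: empty brain mask")
    mean = volume.data[mask].mean()
    if mean <= 0:
        raise ValueError(
            f"subject {volume.subject_id}: non-positive masked mean {mean}"
        )
    return replace(volume, data=volume.data / mean)


def extract_voi_means(volume: BrainVolume, masks: VOIMaskSet) -> SubjectUptake:
    """Mean voxel value inside each VOI mask, in atlas order."""
    if tuple(volume.data.shape) != tuple(masks.shape):
        raise ValueError(
            f"subject {volume.subject_id}: volume shape {volume.data.shape} "
            f"!= mask grid {masks.shape}"
        )
    if not np.allclose(volume.affine, masks.affine, atol=1e-6):
        raise ValueError(f"subject {volume.subject_id}: volume/mask affine mismatch")
    values = []
    for abbr, m in masks.masks.items():
        if not m.any():
            raise ValueError(f"empty mask for VOI {abbr}")
        values.append(volume.data[m].mean())
    return SubjectUptake(
        subject_id=volume.subject_id,
        group=volume.group,
        values=np.array(values),
        voi_names=tuple(masks.masks),
    )


def build_cohort_table(
    volumes: list[BrainVolume],
    atlas: list[VOIDefinition],
    smooth_fwhm_mm: float = 0.0,
    normalize: bool = True,
    brain_mask="auto",
    radius_mm: float = 6.0,
    masks: VOIMaskSet | None = None,
) -> list[SubjectUptake]:
    """Apply smooth → normalize → extract to every subject.

    Sphere masks are built once from the first subject's grid unless a
    ``masks`` set is supplied.  Failures are re-raised with the subject id
    attached.
    """
    if not volumes:
        raise ValueError("no volumes supplied")
    if masks is None:
        masks = build_sphere_masks(
            atlas, volumes[0].affine, volumes[0].data.shape, radius_mm=radius_mm
        )
    cohort = []
    for vol in volumes:
        try:
            if smooth_fwhm_mm > 0:
                vol = gaussian_smooth(vol, smooth_fwhm_mm)
            if normalize:
                vol = normalize_by_brain_mean(vol, brain_mask)
            cohort.append(extract_voi_means(vol, masks))
        except ValueError as exc:
            raise ValueError(f"subject {vol.subject_id}: {exc}") from exc
    return cohort


def cohort_to_frame(cohort: list[SubjectUptake]) -> pd.DataFrame:
    """Cohort as a DataFrame: subject_id, group, then one column per VOI."""
    if not cohort:
        raise ValueError("empty cohort")
    names = cohort[0].voi_names
    for s in cohort:
        if s.voi_names != names:
            raise ValueError("inconsistent VOI order across subjects")
    rows = [{"subject_id": s.subject_id, "group": s.group, **dict(zip(names, s.values))} for s in cohort]
    return pd.DataFrame(rows, columns=["subject_id", "group", *names])


def frame_to_cohort(frame: pd.DataFrame) -> list[SubjectUptake]:
    meta = {"subject_id", "group"}
    if not meta.issubset(frame.columns):
        raise ValueError("cohort table needs subject_id and group columns")
    voi_cols = [c for c in frame.columns if c not in meta and np.issubdtype(frame[c].dtype, np.number)]
    if not voi_cols:
        raise ValueError("cohort table has no numeric VOI columns")
    return [
        SubjectUptake(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            values=row[voi_cols].to_numpy(dtype=float),
            voi_names=tuple(voi_cols),
        )
        for _, row in frame.iterrows()
    ]


def write_cohort_tsv(cohort: list[SubjectUptake], path) -> None:
    cohort_to_frame(cohort).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_cohort_tsv(path) -> list[SubjectUptake]:
    return frame_to_cohort(pd.read_csv(path, sep="\t"))
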