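"""Default-mode-network volume-of-interest atlas and voxel mask construction.

The packaged atlas lists 14 DMN regions with their MNI-space center
coordinates (millimetres).  Masks are built on an arbitrary image grid
either as fixed-radius spheres around those centers or from a user-supplied
integer parcellation image.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "VOIDefinition",
    "VOIMaskSet",
    "load_default_atlas",
    "build_sphere_masks",
    "load_label_masks",
    "DEFAULT_SPHERE_RADIUS_MM",
]

DEFAULT_SPHERE_RADIUS_MM = 6.0


@dataclass(frozen=True)
class VOIDefinition:
    """One volume of interest: a named region with an MNI center."""

    index: int
    name: str
    abbreviation: str
    hemisphere: str
    center_mni: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be left/right, got {self.hemisphere!r}")
        if len(self.center_mni) != 3:
            raise ValueError("center_mni must be an (x, y, z) triple")


@dataclass
class VOIMaskSet:
    """Per-VOI boolean voxel masks sharing one grid and affine.

    ``masks`` preserves atlas order (dicts are ordered).  All masks have
    shape ``shape``; ``affine`` maps 0-based voxel indices to world mm.
    """

    masks: dict[str, np.ndarray]
    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        for abbr, m in self.masks.items():
            if m.shape != tuple(self.shape):
                raise ValueError(f"mask {abbr} shape {m.shape} != grid {self.shape}")
            if m.dtype != bool:
                raise ValueError(f"mask {abbr} must be boolean")

    @property
    def abbreviations(self) -> list[str]:
        return list(self.masks)

    def voxel_counts(self) -> dict[str, int]:
        return {k: int(m.sum()) for k, m in self.masks.items()}

    def overlap_count(self) -> int:
        """Number of voxels belonging to more than one VOI."""
        total = np.zeros(self.shape, dtype=np.int32)
        for m in self.masks.values():
            total += m
        return int((total > 1).sum())


def load_default_atlas() -> list[VOIDefinition]:
    """Load the packaged 14-region DMN atlas, in index order."""
    path = resources.files("dmnconn").joinpath("data/dmn_voi_atlas.tsv")
    rows = path.read_text().strip().splitlines()
    header = rows[0].split("\t")
    expected = ["index", "name", "abbreviation", "hemisphere", "x", "y", "z"]
    if header != expected:
        raise RuntimeError(f"packaged atlas header malformed: {header}")
    atlas = []
    for line in rows[1:]:
        idx, name, abbr, hemi, x, y, z = line.split("\t")
        atlas.append(
            VOIDefinition(
                index=int(idx),
                name=name,
                abbreviation=abbr,
                hemisphere=hemi,
                center_mni=(float(x), float(y), float(z)),
            )
        )
    abbrs = [v.abbreviation for v in atlas]
    if len(set(abbrs)) != len(abbrs):
        raise RuntimeError("packaged atlas has duplicate abbreviations")
    return atlas


def _world_to_voxel(affine: np.ndarray, world: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    w = np.append(np.asarray(world, dtype=float), 1.0)
    return (inv @ w)[:3]


def build_sphere_masks(
    atlas: list[VOIDefinition],
    affine: np.ndarray,
    shape: tuple[int, int, int],
    radius_mm: float = DEFAULT_SPHERE_RADIUS_MM,
) -> VOIMaskSet:
    """Build spherical voxel masks of ``radius_mm`` around each VOI center.

    A voxel belongs to a mask when its world-space center lies within
    ``radius_mm`` of the VOI center.  Masks may overlap.  If a sphere
    captures no voxel center (very coarse grids) the single nearest voxel
    is included instead, so no VOI is ever silently empty.

    Raises
    ------
    ValueError
        If ``radius_mm`` is not positive, the affine is singular, or a VOI
        center maps outside the grid (usually a wrong-space input).
    """
    affine = np.asarray(affine, dtype=float)
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    if abs(np.linalg.det(affine)) < 1e-12:
        raise ValueError("affine is not invertible")
    shape = tuple(int(s) for s in shape)

    # voxel edge lengths along each array axis
    voxel_sizes = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))

    masks: dict[str, np.ndarray] = {}
    for voi in atlas:
        center_vox = _world_to_voxel(affine, np.array(voi.center_mni))
        if np.any(center_vox < -0.5) or np.any(center_vox > np.array(shape) - 0.5):
            raise ValueError(
                f"VOI {voi.abbreviation} center {voi.center_mni} maps to voxel "
                f"{center_vox} outside grid {shape}; check image space/orientation"
            )
        # bounding box in voxel space, generous by one voxel
        half = np.ceil(radius_mm / voxel_sizes).astype(int) + 1
        lo = np.maximum(np.floor(center_vox).astype(int) - half, 0)
        hi = np.minimum(np.floor(center_vox).astype(int) + half + 1, shape)
        ii, jj, kk = np.meshgrid(
            np.arange(lo[0], hi[0]),
            np.arange(lo[1], hi[1]),
            np.arange(lo[2], hi[2]),
            indexing="ij",
        )
        vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1).reshape(-1, 4)
        world = (affine @ vox.T).T[:, :3]
        dist = np.linalg.norm(world - np.array(voi.center_mni), axis=1)
        inside = dist <= radius_mm

        mask = np.zeros(shape, dtype=bool)
        if inside.any():
            sel = vox[inside, :3]
            mask[sel[:, 0], sel[:, 1], sel[:, 2]] = True
        else:
            nearest = vox[np.argmin(dist), :3]
            mask[nearest[0], nearest[1], nearest[2]] = True
        masks[voi.abbreviation] = mask
    return VOIMaskSet(masks=masks, shape=shape, affine=affine)


def load_label_masks(
    label_image: np.ndarray,
    affine: np.ndarray,
    label_map: dict[str, int],
) -> VOIMaskSet:
    """Build masks from an integer parcellation volume.

    ``label_map`` maps VOI abbreviation to the integer label carried by the
    parcellation image.  Masks are disjoint by construction.

    Raises
    ------
    ValueError
        If a mapped label value is absent from the image.
    """
    label_image = np.asarray(label_image)
    if label_image.ndim != 3:
        raise ValueError("label image must be 3-D")
    present = set(np.unique(label_image).tolist())
    masks: dict[str, np.ndarray] = {}
    for abbr, value in label_map.items():
        if value not in present:
            raise ValueError(f"label value {value} for {abbr} absent from label image")
        masks[abbr] = label_image == value
    return VOIMaskSet(masks=masks, shape=tuple(label_image.shape), affine=np.asarray(affine, float))
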