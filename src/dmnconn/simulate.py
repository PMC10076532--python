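"""Synthetic cohorts with controlled covariance structure.

Two groups of VOI uptake vectors are drawn from multivariate normals
whose correlation matrices differ on a planted edge set; edited matrices
are repaired to the nearest valid correlation matrix before sampling.
Cohorts can optionally be rendered into voxel volumes with spherical VOI
signals for round-trip testing of the extraction stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import VOIDefinition, build_sphere_masks, load_default_atlas
from .extraction import BrainVolume, SubjectUptake

__all__ = [
    "SimulationSpec",
    "generate_cohorts",
    "render_volumes",
    "default_base_correlation",
    "nearest_correlation",
    "default_grid_affine",
    "DEFAULT_GRID_SHAPE",
    "DEFAULT_VOXEL_SIZE_MM",
]

# grid defaults mirror the scanner reconstruction matrix
DEFAULT_GRID_SHAPE = (128, 128, 35)
DEFAULT_VOXEL_SIZE_MM = (1.95, 1.95, 4.25)


def default_base_correlation(n_vois: int = 14, n_per_hemisphere: int = 7) -> np.ndarray:
    """Exchangeable 0.5 off-diagonal plus +0.2 within-hemisphere bonus.

    Positive definite by construction for the two-block layout (checked).
    """
    R = np.full((n_vois, n_vois), 0.5)
    for start in range(0, n_vois, n_per_hemisphere):
        block = slice(start, min(start + n_per_hemisphere, n_vois))
        R[block, block] += 0.2
    np.fill_diagonal(R, 1.0)
    if np.linalg.eigvalsh(R).min() <= 0:
        raise RuntimeError("default base correlation is not positive definite")
    return R


def nearest_correlation(
    A: np.ndarray, tol: float = 1e-8, max_iter: int = 200
) -> tuple[np.ndarray, float]:
    """Nearest correlation matrix by Higham alternating projections.

    Projects alternately onto the PSD cone and the unit-diagonal affine
    set with Dykstra's correction.  Returns (repaired matrix, Frobenius
    distance from the input).
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("input must be square")
    A = (A + A.T) / 2.0
    Y = A.copy()
    dS = np.zeros_like(A)
    for _ in range(max_iter):
        Rk = Y - dS
        vals, vecs = np.linalg.eigh(Rk)
        X = (vecs * np.maximum(vals, 0)) @ vecs.T
        dS = X - Rk
        Y_new = X.copy()
        np.fill_diagonal(Y_new, 1.0)
        if np.linalg.norm(Y_new - Y, "fro") < tol * max(1.0, np.linalg.norm(Y, "fro")):
            Y = Y_new
            break
        Y = Y_new
    Y = (Y + Y.T) / 2.0
    np.fill_diagonal(Y, 1.0)
    if np.linalg.eigvalsh(Y).min() < -1e-6:
        raise ValueError("nearest-correlation repair failed to reach the PSD cone")
    return Y, float(np.linalg.norm(Y - A, "fro"))


@dataclass
class SimulationSpec:
    """Parameters of a two-group cohort simulation.

    Group A is the patient-like group: ``planted_edges`` lists
    (voi_i, voi_j, delta_r) edits applied to ITS correlation matrix
    relative to the shared base; group B samples from the base.  VOIs may
    be given by abbreviation or 0-based index.
    """

    n_a: int = 40
    n_b: int = 41
    base_correlation: np.ndarray | None = None
    planted_edges: list[tuple] = field(default_factory=list)
    uptake_mean: np.ndarray | float = 1.0
    uptake_sd: np.ndarray | float = 0.1
    noise_sd: float = 0.0
    seed: int = 0
    group_a: str = "patient"
    group_b: str = "control"

    def __post_init__(self) -> None:
        if self.n_a < 3 or self.n_b < 3:
            raise ValueError("group sizes must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _resolve_node(key, names: list[str]) -> int:
    if isinstance(key, str):
        if key not in names:
            raise ValueError(f"unknown VOI {key!r}")
        return names.index(key)
    idx = int(key)
    if not 0 <= idx < len(names):
        raise ValueError(f"VOI index {idx} out of range")
    return idx


def _apply_edges(R: np.ndarray, edges: list[tuple], names: list[str]) -> np.ndarray:
    out = R.copy()
    for voi_i, voi_j, delta in edges:
        i, j = _resolve_node(voi_i, names), _resolve_node(voi_j, names)
        if i == j:
            raise ValueError("planted edge endpoints must differ")
        new = out[i, j] + float(delta)
        if not -1.0 < new < 1.0:
            raise ValueError(
                f"planted edge ({voi_i}, {voi_j}, {delta}) leaves correlation "
                f"{new} outside (-1, 1)"
            )
        out[i, j] = out[j, i] = new
    return out


def _sample_mvn(
    rng: np.random.Generator, corr: np.ndarray, n: int
) -> np.ndarray:
    """Draw n rows from N(0, corr) via an eigh factor (tolerates PSD edge)."""
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() < -1e-6:  # repair tolerance; residual negatives are clipped
        raise ValueError("correlation matrix is not positive semidefinite")
    factor = vecs * np.sqrt(np.maximum(vals, 0.0))
    return rng.standard_normal((n, corr.shape[0])) @ factor.T


def generate_cohorts(
    spec: SimulationSpec, atlas: list[VOIDefinition] | None = None
) -> tuple[list[SubjectUptake], list[SubjectUptake], dict]:
    """Simulate the two cohorts; returns (cohort_a, cohort_b, ground_truth).

    Group B samples from the (repaired) base correlation; group A from the
    base with planted edge edits, repaired to the nearest valid
    correlation matrix.  Each draw is scaled by ``uptake_sd``, shifted by
    ``uptake_mean``, and perturbed by independent Gaussian noise.
    """
    if atlas is None:
        atlas = load_default_atlas()
    names = [v.abbreviation for v in atlas]
    k = len(names)

    base = spec.base_correlation
    base = default_base_correlation(k) if base is None else np.asarray(base, float)
    if base.shape != (k, k):
        raise ValueError(f"base correlation must be {k}x{k}")
    R_b, repair_b = nearest_correlation(base)
    R_a_raw = _apply_edges(R_b, spec.planted_edges, names)
    R_a, repair_a = nearest_correlation(R_a_raw)

    mean = np.broadcast_to(np.asarray(spec.uptake_mean, float), (k,))
    sd = np.broadcast_to(np.asarray(spec.uptake_sd, float), (k,))
    if np.any(sd <= 0):
        raise ValueError("uptake_sd must be positive")

    rng = np.random.default_rng(spec.seed)

    def draw(corr, n, group, prefix):
        Z = _sample_mvn(rng, corr, n)
        X = Z * sd + mean
        if spec.noise_sd > 0:
            X = X + rng.normal(0.0, spec.noise_sd, X.shape)
        return [
            SubjectUptake(
                subject_id=f"{prefix}{i + 1:03d}",
                group=group,
                values=X[i],
                voi_names=tuple(names),
            )
            for i in range(n)
        ]

    cohort_a = draw(R_a, spec.n_a, spec.group_a, "A")
    cohort_b = draw(R_b, spec.n_b, spec.group_b, "B")
    ground_truth = {
        "voi_names": names,
        "correlation_a": R_a,
        "correlation_b": R_b,
        "repair_distance_a": repair_a,
        "repair_distance_b": repair_b,
        "planted_edges": [
            (str(i), str(j), float(d)) for i, j, d in spec.planted_edges
        ],
        "seed": spec.seed,
        "n_a": spec.n_a,
        "n_b": spec.n_b,
    }
    return cohort_a, cohort_b, ground_truth


def default_grid_affine(
    shape=DEFAULT_GRID_SHAPE, voxel_size=DEFAULT_VOXEL_SIZE_MM
) -> np.ndarray:
    """Grid-centered affine: voxel indices to MNI-style world millimetres."""
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = voxel_size
    affine[:3, 3] = -(np.array(shape) - 1) / 2.0 * np.array(voxel_size)
    return affine


def render_volumes(
    cohort: list[SubjectUptake],
    atlas: list[VOIDefinition] | None = None,
    shape=DEFAULT_GRID_SHAPE,
    voxel_size=DEFAULT_VOXEL_SIZE_MM,
    radius_mm: float = 6.0,
    background: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[BrainVolume]:
    """Paint each subject's uptake into spherical VOIs on a brain ellipsoid.

    Spheres must not overlap on the chosen grid (checked) so that the
    painting/extraction round trip is exact at zero noise.
    """
    if atlas is None:
        atlas = load_default_atlas()
    affine = default_grid_affine(shape, voxel_size)
    masks = build_sphere_masks(atlas, affine, shape, radius_mm=radius_mm)
    if masks.overlap_count() > 0:
        raise ValueError(
            f"VOI spheres overlap on this grid ({masks.overlap_count()} voxels); "
            "reduce radius_mm"
        )

    # brain ellipsoid: centered, semi-axes at 90% of the half field of view
    idx = np.indices(shape, dtype=float)
    center = (np.array(shape) - 1) / 2.0
    semi = 0.9 * center * np.array(voxel_size)
    world_offsets = (idx - center.reshape(3, 1, 1, 1)) * np.array(voxel_size).reshape(
        3, 1, 1, 1
    )
    brain = (world_offsets / semi.reshape(3, 1, 1, 1)) ** 2
    brain_mask = brain.sum(axis=0) <= 1.0

    rng = np.random.default_rng(seed)
    volumes = []
    for subject in cohort:
        data = np.zeros(shape)
        data[brain_mask] = background
        for abbr, value in zip(subject.voi_names, subject.values):
            data[masks.masks[abbr]] = value
        if noise_sd > 0:
            data = data + rng.normal(0.0, noise_sd, shape)
        volumes.append(
            BrainVolume(
                data=data,
                affine=affine,
                subject_id=subject.subject_id,
                group=subject.group,
            )
        )
    return volumes
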