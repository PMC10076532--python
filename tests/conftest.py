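import numpy as np
import pytest

from dmnconn.atlas import build_sphere_masks, load_default_atlas
from dmnconn.extraction import SubjectUptake


@pytest.fixture(scope="session")
def atlas():
    return load_default_atlas()


@pytest.fixture(scope="session")
def voi_names(atlas):
    return tuple(v.abbreviation for v in atlas)


@pytest.fixture(scope="session")
def mni_2mm_grid():
    """2 mm isotropic grid covering standard MNI brain extents."""
    affine = np.array(
        [
            [2.0, 0, 0, -90.0],
            [0, 2.0, 0, -126.0],
            [0, 0, 2.0, -72.0],
            [0, 0, 0, 1.0],
        ]
    )
    return affine, (91, 109, 91)


@pytest.fixture(scope="session")
def sphere_masks(atlas, mni_2mm_grid):
    affine, shape = mni_2mm_grid
    return build_sphere_masks(atlas, affine, shape, radius_mm=6.0)


def make_cohort(X, group="control", voi_names=None, prefix="s"):
    """Wrap an (n_subjects, n_vois) array as a cohort of SubjectUptake."""
    X = np.asarray(X, dtype=float)
    if voi_names is None:
        voi_names = tuple(f"V{i + 1}" for i in range(X.shape[1]))
    return [
        SubjectUptake(
            subject_id=f"{prefix}{i + 1:03d}",
            group=group,
            values=X[i],
            voi_names=tuple(voi_names),
        )
        for i in range(X.shape[0])
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
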