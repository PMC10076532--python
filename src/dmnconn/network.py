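"""Group-level inter-subject correlation networks.

One network per group: the Pearson correlation of VOI uptake ACROSS
subjects gives a 14x14 weighted undirected matrix R, its Fisher-z
transform Z (used for edgewise statistics), and a non-negative weight
matrix W (used for graph analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .extraction import SubjectUptake

__all__ = [
    "GroupNetwork",
    "intersubject_correlation",
    "fisher_z",
    "threshold_weights",
    "cohort_matrix",
]

WEIGHT_MODES = ("positive", "absolute")


@dataclass
class GroupNetwork:
    """A group's correlation network and derived matrices.

    R: Pearson correlations, symmetric, unit diagonal.
    Z: Fisher z = atanh(r) off-diagonal; diagonal is NaN (undefined).
    W: non-negative weights for graph analysis, zero diagonal.
    """

    group: str
    n_subjects: int
    voi_names: tuple[str, ...]
    R: np.ndarray
    Z: np.ndarray
    W: np.ndarray
    weight_mode: str

    @property
    def n_nodes(self) -> int:
        return len(self.voi_names)

    def to_frame(self, which: str = "R") -> pd.DataFrame:
        mat = getattr(self, which)
        return pd.DataFrame(mat, index=self.voi_names, columns=self.voi_names)

    def edge_list(self) -> pd.DataFrame:
        """Upper-triangle edges as rows: voi_a, voi_b, r, z, w."""
        rows = []
        k = self.n_nodes
        for i in range(k):
            for j in range(i + 1, k):
                rows.append(
                    {
                        "voi_a": self.voi_names[i],
                        "voi_b": self.voi_names[j],
                        "r": self.R[i, j],
                        "z": self.Z[i, j],
                        "w": self.W[i, j],
                    }
                )
        return pd.DataFrame(rows)


def cohort_matrix(cohort: list[SubjectUptake]) -> tuple[np.ndarray, tuple[str, ...]]:
    """Stack a cohort into an (n_subjects, n_vois) array; checks VOI order."""
    if not cohort:
        raise ValueError("empty cohort")
    names = cohort[0].voi_names
    for s in cohort:
        if s.voi_names != names:
            raise ValueError("inconsistent VOI order across subjects")
    return np.vstack([s.values for s in cohort]), names


def intersubject_correlation(
    cohort: list[SubjectUptake], weight_mode: str = "positive"
) -> GroupNetwork:
    """Pearson correlation between every VOI pair across one group's subjects.

    Requires at least 3 subjects, a single group label, and no
    zero-variance VOI column (correlation is undefined there).
    """
    X, names = cohort_matrix(cohort)
    groups = {s.group for s in cohort}
    if len(groups) != 1:
        raise ValueError(f"cohort mixes groups {sorted(groups)}; one group per network")
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 subjects, got {n}")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        dead = [names[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance VOI column(s): {dead}")
    R = np.corrcoef(X, rowvar=False)
    # guard fp roundoff without masking genuine |r|=1 duplicates
    np.clip(R, -1.0, 1.0, out=R)
    np.fill_diagonal(R, 1.0)
    Z = fisher_z(R, on_degenerate="inf")
    W = threshold_weights(R, mode=weight_mode)
    return GroupNetwork(
        group=groups.pop(),
        n_subjects=n,
        voi_names=names,
        R=R,
        Z=Z,
        W=W,
        weight_mode=weight_mode,
    )


def fisher_z(R: np.ndarray, on_degenerate: str = "raise") -> np.ndarray:
    """Fisher transform z = atanh(r) off-diagonal; diagonal set to NaN.

    ``on_degenerate`` controls off-diagonal |r| >= 1 (duplicated columns):
    ``"raise"`` errors — required wherever z enters a statistic — while
    ``"inf"`` propagates the +/-inf limit so a degenerate network can
    still be inspected.
    """
    R = np.asarray(R, dtype=float)
    off = ~np.eye(R.shape[0], dtype=bool)
    if np.any(np.abs(R[off]) >= 1.0):
        if on_degenerate == "raise":
            raise ValueError("off-diagonal |r| >= 1: Fisher transform undefined")
        if on_degenerate != "inf":
            raise ValueError("on_degenerate must be 'raise' or 'inf'")
    with np.errstate(divide="ignore"):
        Z = np.arctanh(np.where(off, np.clip(R, -1.0, 1.0), 0.0))
    Z[~off] = np.nan
    return Z


def threshold_weights(R: np.ndarray, mode: str = "positive") -> np.ndarray:
    """Map correlations to non-negative graph weights.

    ``positive`` clamps negative r to 0; ``absolute`` takes |r|.  The
    diagonal is structurally zero.
    """
    if mode not in WEIGHT_MODES:
        raise ValueError(f"weight mode must be one of {WEIGHT_MODES}, got {mode!r}")
    R = np.asarray(R, dtype=float)
    W = np.abs(R) if mode == "absolute" else np.maximum(R, 0.0)
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    return W
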