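"""Group-comparison statistics.

Edgewise test: observed difference of Fisher-z correlation matrices,
null distribution from random reassignment of subjects to pseudo-groups
of the original sizes, Monte-Carlo p with the add-one convention,
Benjamini-Hochberg FDR across the edge family.

Metric test: same permutation scheme with a graph metric as the
statistic; per-node metrics are BH-corrected across nodes, global
metrics are tested uncorrected.

Also houses the demographic-table tests (pooled-variance two-sample t
from summary statistics; Pearson chi-square without continuity
correction on a 2x2 table).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .extraction import SubjectUptake
from .metrics import (
    degree_centrality,
    nodal_efficiency,
    shortest_path_distances,
    weight_to_length,
)
from .metrics import (
    characteristic_path_length as _cpl,
)
from .metrics import (
    global_efficiency as _geff,
)
from .network import cohort_matrix, threshold_weights

__all__ = [
    "PermutationConfig",
    "PermutationResult",
    "edgewise_permutation_test",
    "metric_permutation_test",
    "bh_fdr",
    "two_sample_t_from_summary",
    "chi_square_2x2",
    "METRICS",
]

METRICS = (
    "global_efficiency",
    "characteristic_path_length",
    "nodal_efficiency",
    "degree_centrality",
)

_SIDEDNESS = ("two_sided", "less", "greater")
_MAX_REDRAWS = 100


@dataclass(frozen=True)
class PermutationConfig:
    n_permutations: int = 10_000
    seed: int = 0
    sidedness: str = "two_sided"
    fdr_q: float = 0.05

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.sidedness not in _SIDEDNESS:
            raise ValueError(f"sidedness must be one of {_SIDEDNESS}")


@dataclass
class PermutationResult:
    """Observed differences, permutation p-values, and BH q-values."""

    labels: list[str]
    observed: np.ndarray
    pvalues: np.ndarray
    qvalues: np.ndarray
    significant: np.ndarray
    direction: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    null_quantiles: dict[str, np.ndarray]
    config: PermutationConfig
    statistic: str = "fisher_z_difference"
    fdr_family_size: int = 0
    n_redraws: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "observed": self.observed,
                "p": self.pvalues,
                "q": self.qvalues,
                "significant": self.significant,
                "direction": self.direction,
                "null_mean": self.null_mean,
                "null_sd": self.null_sd,
            }
        )

    def significant_labels(self) -> list[str]:
        return [l for l, s in zip(self.labels, self.significant) if s]

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "config": {
                "n_permutations": self.config.n_permutations,
                "seed": self.config.seed,
                "sidedness": self.config.sidedness,
                "fdr_q": self.config.fdr_q,
            },
            "fdr_family_size": self.fdr_family_size,
            "n_redraws": self.n_redraws,
            "results": self.to_frame().to_dict(orient="records"),
        }


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: q_i = min_{k>=i} (m * p_(k) / k).

    Returns (qvalues, significance flags); flags are q <= threshold.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    qsorted = np.minimum.accumulate(ranked[::-1])[::-1]
    qsorted = np.minimum(qsorted, 1.0)
    qvalues = np.empty(m)
    qvalues[order] = qsorted
    return qvalues, qvalues <= q


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------


def _batch_pearson(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Correlation matrices for a (P, n, k) batch; returns (C, bad_rows).

    bad_rows flags permutations containing a zero-variance column.
    """
    Xc = X - X.mean(axis=1, keepdims=True)
    ss = np.einsum("pik,pik->pk", Xc, Xc)
    bad = np.any(ss <= 0, axis=1)
    denom = np.sqrt(np.where(ss > 0, ss, 1.0))
    C = np.einsum("pik,pil->pkl", Xc, Xc)
    C /= denom[:, :, None] * denom[:, None, :]
    np.clip(C, -1.0, 1.0, out=C)
    return C, bad


def _null_atanh_clip(C: np.ndarray) -> np.ndarray:
    # under permutation exact |r|=1 is possible with degenerate data; keep
    # the null finite rather than aborting the whole test
    return np.arctanh(np.clip(C, -1.0 + 1e-15, 1.0 - 1e-15))


def _permutation_indices(
    rng: np.random.Generator, n_total: int, n_perm: int
) -> np.ndarray:
    idx = np.tile(np.arange(n_total), (n_perm, 1))
    return rng.permuted(idx, axis=1)


def _stack_groups(
    cohort_a: list[SubjectUptake], cohort_b: list[SubjectUptake]
) -> tuple[np.ndarray, int, int, tuple[str, ...]]:
    Xa, names_a = cohort_matrix(cohort_a)
    Xb, names_b = cohort_matrix(cohort_b)
    if names_a != names_b:
        raise ValueError("cohorts disagree on VOI order")
    if len(cohort_a) < 3 or len(cohort_b) < 3:
        raise ValueError("each group needs >= 3 subjects")
    return np.vstack([Xa, Xb]), Xa.shape[0], Xb.shape[0], names_a


def _pvalues(observed: np.ndarray, null: np.ndarray, sidedness: str) -> np.ndarray:
    """Add-one Monte-Carlo p: (1 + #as-or-more-extreme) / (1 + P)."""
    P = null.shape[0]
    if sidedness == "two_sided":
        b = (np.abs(null) >= np.abs(observed)).sum(axis=0)
    elif sidedness == "greater":
        b = (null >= observed).sum(axis=0)
    else:
        b = (null <= observed).sum(axis=0)
    return (1.0 + b) / (1.0 + P)


def edgewise_permutation_test(
    cohort_a: list[SubjectUptake],
    cohort_b: list[SubjectUptake],
    config: PermutationConfig = PermutationConfig(),
) -> PermutationResult:
    """Permutation test on every edge's Fisher-z correlation difference.

    The observed statistic per edge is z_a - z_b on the unthresholded
    Fisher-z matrices.  Each permutation reassigns all subjects to
    pseudo-groups of the original sizes and recomputes both matrices.
    Permutations yielding a zero-variance column are redrawn (bounded,
    counted, warned).  BH-FDR is applied across the edge family.
    """
    X, n_a, n_b, names = _stack_groups(cohort_a, cohort_b)
    k = X.shape[1]
    iu = np.triu_indices(k, 1)
    labels = [f"{names[i]} - {names[j]}" for i, j in zip(*iu)]

    Ca, bad_a = _batch_pearson(X[None, :n_a])
    Cb, bad_b = _batch_pearson(X[None, n_a:])
    if bad_a[0] or bad_b[0]:
        raise ValueError("zero-variance VOI column in an observed group")
    # strict transform on the observed matrices: degenerate data must error
    from .network import fisher_z

    observed = (fisher_z(Ca[0]) - fisher_z(Cb[0]))[iu]

    rng = np.random.default_rng(config.seed)
    P = config.n_permutations
    null = np.empty((P, len(labels)))
    n_redraws = 0
    chunk = max(1, min(P, 20_000_000 // (X.size + 1)))  # bound memory
    done = 0
    while done < P:
        want = min(chunk, P - done)
        idx = _permutation_indices(rng, n_a + n_b, want)
        Xp = X[idx]
        Ca, bad_a = _batch_pearson(Xp[:, :n_a])
        Cb, bad_b = _batch_pearson(Xp[:, n_a:])
        bad = bad_a | bad_b
        retries = 0
        while bad.any():
            n_redraws += int(bad.sum())
            retries += 1
            if retries > _MAX_REDRAWS:
                raise ValueError("could not draw permutations without zero-variance columns")
            idx_new = _permutation_indices(rng, n_a + n_b, int(bad.sum()))
            Xp_new = X[idx_new]
            Ca_new, bad_a = _batch_pearson(Xp_new[:, :n_a])
            Cb_new, bad_b = _batch_pearson(Xp_new[:, n_a:])
            Ca[bad], Cb[bad] = Ca_new, Cb_new
            sub = np.flatnonzero(bad)
            bad = np.zeros_like(bad)
            bad[sub] = bad_a | bad_b
        diff = _null_atanh_clip(Ca) - _null_atanh_clip(Cb)
        null[done : done + want] = diff[:, iu[0], iu[1]]
        done += want
    if n_redraws:
        warnings.warn(
            f"redrew {n_redraws} permutation(s) with zero-variance columns",
            stacklevel=2,
        )

    pvals = _pvalues(observed, null, config.sidedness)
    qvals, sig = bh_fdr(pvals, q=config.fdr_q)
    return PermutationResult(
        labels=labels,
        observed=observed,
        pvalues=pvals,
        qvalues=qvals,
        significant=sig,
        direction=np.sign(observed),
        null_mean=null.mean(axis=0),
        null_sd=null.std(axis=0, ddof=1),
        null_quantiles={
            "q025": np.quantile(null, 0.025, axis=0),
            "q975": np.quantile(null, 0.975, axis=0),
        },
        config=config,
        statistic="fisher_z_difference",
        fdr_family_size=len(labels),
        n_redraws=n_redraws,
    )


def _metric_statistic(C: np.ndarray, metric: str, weight_mode: str) -> np.ndarray:
    """Graph metric(s) from one correlation matrix (scalar as length-1)."""
    W = threshold_weights(C, mode=weight_mode)
    if metric == "degree_centrality":
        return degree_centrality(W)
    dist = shortest_path_distances(weight_to_length(W))
    if metric == "global_efficiency":
        return np.array([_geff(dist)])
    if metric == "characteristic_path_length":
        return np.array([_cpl(dist)])
    if metric == "nodal_efficiency":
        return nodal_efficiency(dist)
    raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")


def metric_permutation_test(
    cohort_a: list[SubjectUptake],
    cohort_b: list[SubjectUptake],
    metric: str,
    config: PermutationConfig = PermutationConfig(),
    weight_mode: str = "positive",
) -> PermutationResult:
    """Permutation test on a graph metric of the thresholded weight matrix.

    Per-node metrics (nodal efficiency, degree centrality) are BH-FDR
    corrected across nodes; global metrics are reported uncorrected
    (q-values equal p-values, family size 1 per statistic).
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    X, n_a, n_b, names = _stack_groups(cohort_a, cohort_b)

    Ca, bad_a = _batch_pearson(X[None, :n_a])
    Cb, bad_b = _batch_pearson(X[None, n_a:])
    if bad_a[0] or bad_b[0]:
        raise ValueError("zero-variance VOI column in an observed group")
    observed = _metric_statistic(Ca[0], metric, weight_mode) - _metric_statistic(
        Cb[0], metric, weight_mode
    )
    per_node = observed.size > 1
    labels = list(names) if per_node else [metric]

    rng = np.random.default_rng(config.seed)
    P = config.n_permutations
    null = np.empty((P, observed.size))
    n_redraws = 0
    for p in range(P):
        for _ in range(_MAX_REDRAWS + 1):
            idx = _permutation_indices(rng, n_a + n_b, 1)[0]
            Xp = X[idx]
            Ca, bad_a = _batch_pearson(Xp[None, :n_a])
            Cb, bad_b = _batch_pearson(Xp[None, n_a:])
            if not (bad_a[0] or bad_b[0]):
                break
            n_redraws += 1
        else:
            raise ValueError("could not draw a permutation without zero-variance columns")
        null[p] = _metric_statistic(Ca[0], metric, weight_mode) - _metric_statistic(
            Cb[0], metric, weight_mode
        )
    if n_redraws:
        warnings.warn(
            f"redrew {n_redraws} permutation(s) with zero-variance columns",
            stacklevel=2,
        )

    pvals = _pvalues(observed, null, config.sidedness)
    if per_node:
        qvals, sig = bh_fdr(pvals, q=config.fdr_q)
        family = observed.size
    else:
        qvals, sig = pvals.copy(), pvals <= 0.05
        family = 1
    return PermutationResult(
        labels=labels,
        observed=observed,
        pvalues=pvals,
        qvalues=qvals,
        significant=sig,
        direction=np.sign(observed),
        null_mean=null.mean(axis=0),
        null_sd=null.std(axis=0, ddof=1),
        null_quantiles={
            "q025": np.quantile(null, 0.025, axis=0),
            "q975": np.quantile(null, 0.975, axis=0),
        },
        config=config,
        statistic=metric,
        fdr_family_size=family,
        n_redraws=n_redraws,
    )


# ---------------------------------------------------------------------------
# demographic-table tests
# ---------------------------------------------------------------------------


def two_sample_t_from_summary(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    equal_var: bool = True,
) -> tuple[float, float]:
    """Independent two-sample t-test from per-group mean, SD, and n.

    Pooled-variance Student t by default (df = n_a + n_b - 2); set
    ``equal_var=False`` for Welch.  Returns (t, two-sided p).
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=equal_var
    )
    return float(res.statistic), float(res.pvalue)


def chi_square_2x2(counts) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction.

    Returns (statistic, upper-tail p).  Errors on zero marginals (expected
    counts undefined).
    """
    obs = np.asarray(counts, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero marginal: expected counts undefined")
    stat, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return float(stat), float(p)
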