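"""Compositional dissimilarity and permutation tests for trap communities.

Implements the distance-based statistics used to compare communities of
dispersing microbes between ecosystems:

* Bray-Curtis dissimilarity between sample compositions,
* principal coordinates analysis (classical MDS by Gower centering),
* PERMANOVA — a pseudo-F computed directly from within/between sums of
  squared dissimilarities, with a label-permutation null,
* PERMDISP — homogeneity of multivariate dispersions, comparing per-sample
  distances to the group centroid in principal-coordinate space.

The pseudo-F statistics are computed from the distance matrix itself (not
via a feature-space ANOVA), so they are valid for arbitrary, possibly
non-metric, dissimilarities.  Permutation p-values use the add-one rule
``(1 + #exceedances) / (1 + n_perm)`` and are therefore never exactly zero.
For tiny designs ``permutations="exhaustive"`` enumerates every distinct
label arrangement instead.

Distance matrices are scikit-bio :class:`~skbio.DistanceMatrix` objects
(symmetric, hollow, with unique sample ids).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

__all__ = [
    "CommunityError",
    "PermTestResult",
    "PCoAResult",
    "validate_count_table",
    "relative_abundance",
    "rarefy",
    "bray_curtis",
    "pcoa",
    "permanova",
    "permdisp",
]

_EXHAUSTIVE_LIMIT = 9  # n! enumeration guard


class CommunityError(ValueError):
    """Raised for invalid count tables, groupings, or degenerate designs."""


# ---------------------------------------------------------------------------
# count tables


def validate_count_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a samples x taxa table (non-negative, unique sample ids)."""
    if table.index.has_duplicates:
        dupes = table.index[table.index.duplicated()].unique().tolist()
        raise CommunityError(f"duplicate sample ids: {dupes}")
    if (table.to_numpy() < 0).any():
        raise CommunityError("negative counts present")
    return table


def relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Convert counts to per-sample proportions (rows sum to 1)."""
    validate_count_table(table)
    totals = table.sum(axis=1)
    empty = totals.index[totals <= 0].tolist()
    if empty:
        raise CommunityError(f"samples with zero total count: {empty}")
    return table.div(totals, axis=0)


def rarefy(table: pd.DataFrame, depth: int, seed: int | None = None) -> pd.DataFrame:
    """Subsample each sample to ``depth`` counts without replacement.

    Samples with fewer than ``depth`` counts are rejected rather than
    silently dropped.
    """
    validate_count_table(table)
    totals = table.sum(axis=1)
    shallow = totals.index[totals < depth].tolist()
    if shallow:
        raise CommunityError(f"samples below rarefaction depth {depth}: {shallow}")
    rng = np.random.default_rng(seed)
    out = np.zeros(table.shape, dtype=int)
    counts = table.to_numpy(dtype=int)
    for i in range(counts.shape[0]):
        pool = np.repeat(np.arange(counts.shape[1]), counts[i])
        picked = rng.choice(pool, size=depth, replace=False)
        out[i] = np.bincount(picked, minlength=counts.shape[1])
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between table rows.

    ``BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i)``; rows may be counts or
    proportions.  All-zero rows are rejected (the dissimilarity between two
    empty samples is undefined).
    """
    validate_count_table(table)
    X = table.to_numpy(dtype=float)
    zero = table.index[X.sum(axis=1) == 0].tolist()
    if zero:
        raise CommunityError(f"all-zero samples make Bray-Curtis undefined: {zero}")
    condensed = pdist(X, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=[str(i) for i in table.index])


# ---------------------------------------------------------------------------
# principal coordinates


@dataclass(frozen=True)
class PCoAResult:
    """Classical-MDS embedding of a distance matrix.

    ``coordinates`` has one column per retained (positive-eigenvalue) axis,
    scaled so Euclidean distances between rows reproduce the input for
    Euclidean-embeddable matrices.  All eigenvalues, including negative ones
    arising from semimetric dissimilarities, are reported in ``eigenvalues``.
    """

    ids: tuple[str, ...]
    coordinates: np.ndarray
    eigenvalues: np.ndarray

    @property
    def negative_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.eigenvalues < 0]


def pcoa(dm: DistanceMatrix) -> PCoAResult:
    """Principal coordinates analysis by double-centering -D^2/2."""
    D = np.asarray(dm.data, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), abs(eigvals[-1]), 1.0) * 1e-12
    keep = eigvals > tol
    coords = eigvecs[:, keep] * np.sqrt(eigvals[keep])
    return PCoAResult(ids=tuple(dm.ids), coordinates=coords, eigenvalues=eigvals)


# ---------------------------------------------------------------------------
# permutation tests


@dataclass(frozen=True)
class PermTestResult:
    """Outcome of a distance-based permutation test."""

    method: str
    statistic: float
    p_value: float
    n_permutations: int
    variance_explained: float | None = None
    seed: int | None = None

    def summary(self) -> str:
        lines = [
            f"{self.method}: pseudo-F = {self.statistic:.4f}, "
            f"p = {self.p_value:.4g} ({self.n_permutations} permutations)"
        ]
        if self.variance_explained is not None:
            lines.append(f"  variance explained (R2): {self.variance_explained:.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "variance_explained": self.variance_explained,
            "seed": self.seed,
        }


def _align_grouping(dm: DistanceMatrix, grouping) -> np.ndarray:
    if isinstance(grouping, pd.Series):
        missing = [i for i in dm.ids if i not in grouping.index]
        if missing:
            raise CommunityError(f"grouping lacks samples: {missing}")
        labels = grouping.loc[list(dm.ids)].to_numpy()
    else:
        labels = np.asarray(list(grouping))
        if len(labels) != len(dm.ids):
            raise CommunityError(
                f"grouping length {len(labels)} != number of samples {len(dm.ids)}"
            )
    return labels


def _group_codes(labels: np.ndarray, min_size: int = 2) -> np.ndarray:
    codes, counts = np.unique(labels, return_counts=True)
    if len(codes) < 2:
        raise CommunityError("need at least 2 groups")
    small = [str(c) for c, k in zip(codes, counts) if k < min_size]
    if small:
        raise CommunityError(f"groups with fewer than {min_size} samples: {small}")
    lookup = {c: i for i, c in enumerate(codes)}
    return np.array([lookup[v] for v in labels], dtype=int)


def _distinct_label_permutations(codes: np.ndarray) -> np.ndarray:
    n = len(codes)
    if n > _EXHAUSTIVE_LIMIT:
        raise CommunityError(
            f"exhaustive enumeration limited to n <= {_EXHAUSTIVE_LIMIT}, got {n}"
        )
    perms = sorted(set(itertools.permutations(codes.tolist())))
    return np.array(perms, dtype=int)


def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int, sst: float):
    """Pseudo-F and R^2 from squared dissimilarities and integer labels."""
    n = d2.shape[0]
    ssw = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        sub = d2[np.ix_(idx, idx)]
        ssw += sub.sum() / (2.0 * len(idx))
    ssa = sst - ssw
    df_a = n_groups - 1
    df_w = n - n_groups
    denom = ssw / df_w
    if denom <= 0:
        f = math.inf if ssa > 0 else 0.0
    else:
        f = (ssa / df_a) / denom
    return f, ssa / sst if sst > 0 else 0.0


def permanova(
    dm: DistanceMatrix,
    grouping,
    permutations: int | str = 999,
    seed: int | None = None,
) -> PermTestResult:
    """Permutational multivariate ANOVA on a distance matrix.

    The pseudo-F compares between-group to within-group sums of squared
    dissimilarities, computed directly from the matrix; significance comes
    from permuting group labels.  ``variance_explained`` is the partial R^2
    of the grouping, SS_between / SS_total.

    ``permutations`` may be ``"exhaustive"`` for small n, in which case the
    p-value is the exact fraction of distinct label arrangements (the
    observed one included) whose pseudo-F is at least the observed value.
    """
    labels = _align_grouping(dm, grouping)
    codes = _group_codes(labels)
    n_groups = int(codes.max()) + 1
    D = np.asarray(dm.data, dtype=float)
    d2 = D**2
    n = D.shape[0]
    sst = d2.sum() / (2.0 * n)

    f_obs, r2 = _permanova_f(d2, codes, n_groups, sst)

    if permutations == "exhaustive":
        perms = _distinct_label_permutations(codes)
        f_perm = np.array(
            [_permanova_f(d2, p, n_groups, sst)[0] for p in perms]
        )
        p_value = float(np.mean(f_perm >= f_obs))
        n_perm = len(perms)
    else:
        n_perm = int(permutations)
        if n_perm < 1:
            raise CommunityError(f"permutations must be >= 1, got {permutations}")
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            f_p, _ = _permanova_f(d2, rng.permutation(codes), n_groups, sst)
            if f_p >= f_obs:
                exceed += 1
        p_value = (1.0 + exceed) / (1.0 + n_perm)

    return PermTestResult(
        method="PERMANOVA",
        statistic=float(f_obs),
        p_value=p_value,
        n_permutations=n_perm,
        variance_explained=float(r2),
        seed=seed,
    )


def _anova_f(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """One-way ANOVA F on scalar values; inf when SSW == 0 < SSB."""
    n = len(values)
    grand = values.mean()
    ssb = 0.0
    ssw = 0.0
    for g in range(n_groups):
        v = values[codes == g]
        ssb += len(v) * (v.mean() - grand) ** 2
        ssw += ((v - v.mean()) ** 2).sum()
    df_b = n_groups - 1
    df_w = n - n_groups
    if ssw <= 0:
        return math.inf if ssb > 0 else 0.0
    return (ssb / df_b) / (ssw / df_w)


def centroid_distances(dm: DistanceMatrix, grouping) -> pd.Series:
    """Per-sample Euclidean distance to its group centroid in PCoA space.

    Only positive-eigenvalue axes enter the embedding; negative eigenvalues
    (semimetric input) are reported by :func:`pcoa` but excluded here.
    """
    labels = _align_grouping(dm, grouping)
    codes = _group_codes(labels, min_size=1)
    coords = pcoa(dm).coordinates
    dists = np.empty(len(labels))
    for g in range(int(codes.max()) + 1):
        idx = np.flatnonzero(codes == g)
        centroid = coords[idx].mean(axis=0)
        dists[idx] = np.linalg.norm(coords[idx] - centroid, axis=1)
    return pd.Series(dists, index=list(dm.ids), name="distance_to_centroid")


def permdisp(
    dm: DistanceMatrix,
    grouping,
    permutations: int | str = 999,
    seed: int | None = None,
) -> PermTestResult:
    """Permutation test for homogeneity of multivariate dispersions.

    Embeds the samples by PCoA, measures each sample's distance to its own
    group centroid, and F-tests the group effect on those distances.  The
    null distribution permutes group labels over the fixed distances.
    """
    labels = _align_grouping(dm, grouping)
    codes = _group_codes(labels)
    n_groups = int(codes.max()) + 1
    dists = centroid_distances(dm, grouping).to_numpy()

    f_obs = _anova_f(dists, codes, n_groups)

    if permutations == "exhaustive":
        perms = _distinct_label_permutations(codes)
        f_perm = np.array([_anova_f(dists, p, n_groups) for p in perms])
        p_value = float(np.mean(f_perm >= f_obs))
        n_perm = len(perms)
    else:
        n_perm = int(permutations)
        if n_perm < 1:
            raise CommunityError(f"permutations must be >= 1, got {permutations}")
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            if _anova_f(dists, rng.permutation(codes), n_groups) >= f_obs:
                exceed += 1
        p_value = (1.0 + exceed) / (1.0 + n_perm)

    return PermTestResult(
        method="PERMDISP",
        statistic=float(f_obs),
        p_value=p_value,
        n_permutations=n_perm,
        variance_explained=None,
        seed=seed,
    )
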