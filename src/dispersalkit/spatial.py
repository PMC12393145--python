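"""Spatial scale of dispersal limitation: Mantel tests and the radius scan.

The question: at what distance does the surrounding vegetation best predict
the composition of microbes landing in a trap?  For each radius in a grid
(default 11 log-spaced values from 0.1 to 4 m) the scan

1. measures plant composition within that radius of every trap
   (:func:`dispersalkit.landscape.plant_composition_at_radius`),
2. turns those compositions into a Bray-Curtis plant distance matrix,
3. runs a partial Mantel test of the microbial distance matrix against the
   plant matrix, controlling for geographic distance between traps.

The radius with the largest partial Mantel r localises the spatial scale at
which plant composition shapes the identity of immigrating taxa.

Mantel correlations are Pearson correlations of the strictly-lower-triangle
entries of two aligned distance matrices; the partial variant correlates the
residuals of each triangle after OLS regression on the control (geographic)
triangle.  P-values permute the rows and columns of the focal (microbial)
matrix jointly, one-sided for positive association, with the add-one rule.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .community import CommunityError, bray_curtis
from .landscape import (
    CompositionError,
    PlantComposition,
    PlantPolygonMap,
    SampleLocation,
    plant_composition_at_radius,
)

__all__ = [
    "MantelError",
    "MantelResult",
    "ScanResult",
    "default_radii",
    "geographic_distance_matrix",
    "mantel",
    "partial_mantel",
    "radius_scan",
    "holm_adjust",
]

_EXHAUSTIVE_LIMIT = 8
_VAR_TOL = 1e-12


class MantelError(ValueError):
    """Raised for misaligned or degenerate distance matrices."""


def default_radii(
    r_min: float = 0.1, r_max: float = 4.0, n: int = 11
) -> np.ndarray:
    """Log-spaced radius grid (meters); 11 values spanning 0.1-4 m."""
    return np.geomspace(r_min, r_max, n)


def geographic_distance_matrix(locations: Sequence[SampleLocation]) -> DistanceMatrix:
    """Pairwise planar Euclidean distances (meters) between sample locations."""
    if len(locations) < 2:
        raise MantelError("need at least 2 locations")
    ids = [loc.sample_id for loc in locations]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise MantelError(f"duplicated sample ids: {dupes}")
    xy = np.array([[loc.x, loc.y] for loc in locations], dtype=float)
    return DistanceMatrix(squareform(pdist(xy)), ids=ids)


@dataclass(frozen=True)
class MantelResult:
    """Simple or partial Mantel correlation with its permutation p-value."""

    r: float
    p_value: float | None
    n_permutations: int
    partial: bool
    radius_m: float | None = None
    seed: int | None = None
    degenerate: bool = False
    note: str = ""

    def summary(self) -> str:
        kind = "partial Mantel" if self.partial else "Mantel"
        rad = f" @ {self.radius_m:.3g} m" if self.radius_m is not None else ""
        p = "n/a" if self.p_value is None else f"{self.p_value:.4g}"
        return f"{kind}{rad}: r = {self.r:.4f}, p = {p} ({self.n_permutations} perms)"

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "partial": self.partial,
            "radius_m": self.radius_m,
            "seed": self.seed,
            "degenerate": self.degenerate,
            "note": self.note,
        }


@dataclass(frozen=True)
class ScanResult:
    """Per-radius partial Mantel results and the best-supported radius."""

    results: tuple[MantelResult, ...]
    radii_m: tuple[float, ...]

    def __post_init__(self) -> None:
        radii = np.asarray(self.radii_m)
        if len(radii) == 0:
            raise MantelError("empty radius grid")
        if np.any(np.diff(radii) <= 0):
            raise MantelError("radii must be strictly increasing")

    @property
    def argmax_radius_m(self) -> float | None:
        """Radius with the largest partial r among non-degenerate radii."""
        best_r, best_rad = -np.inf, None
        for res in self.results:
            if not res.degenerate and res.r > best_r:
                best_r, best_rad = res.r, res.radius_m
        return best_rad

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "radius_m": [res.radius_m for res in self.results],
                "r": [res.r for res in self.results],
                "p_value": [res.p_value for res in self.results],
                "n_permutations": [res.n_permutations for res in self.results],
                "degenerate": [res.degenerate for res in self.results],
            }
        )


# ---------------------------------------------------------------------------
# triangle helpers


def _check_aligned(*dms: DistanceMatrix, min_n: int) -> int:
    n = len(dms[0].ids)
    for dm in dms[1:]:
        if len(dm.ids) != n:
            raise MantelError(
                f"distance matrices differ in size: {n} vs {len(dm.ids)}"
            )
        if tuple(dm.ids) != tuple(dms[0].ids):
            raise MantelError("distance matrices have mismatched sample orderings")
    if n < min_n:
        raise MantelError(f"need at least {min_n} samples, got {n}")
    return n


def _tri(D: np.ndarray, idx: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    return D[idx]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return 0.0
    return float((xc @ yc) / denom)


def _residualize(v: np.ndarray, z: np.ndarray) -> np.ndarray:
    """OLS residuals of v on [1, z]; rank-deficient designs fall back to
    mean-centering, so a constant control matrix controls for nothing."""
    X = np.column_stack([np.ones_like(z), z])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def _require_variance(v: np.ndarray, name: str) -> None:
    if np.ptp(v) == 0:
        raise MantelError(f"zero variance in the {name} distance triangle")


def _perm_iter(n: int, n_perm: int | str, rng: np.random.Generator):
    if n_perm == "exhaustive":
        if n > _EXHAUSTIVE_LIMIT:
            raise MantelError(
                f"exhaustive enumeration limited to n <= {_EXHAUSTIVE_LIMIT}"
            )
        return [np.array(p) for p in itertools.permutations(range(n))]
    n_perm = int(n_perm)
    if n_perm < 0:
        raise MantelError(f"permutations must be >= 0, got {n_perm}")
    return [rng.permutation(n) for _ in range(n_perm)]


def mantel(
    da: DistanceMatrix,
    db: DistanceMatrix,
    permutations: int | str = 999,
    seed: int | None = None,
) -> MantelResult:
    """Mantel test: Pearson r of the lower triangles of two distance matrices.

    The permutation null shuffles the rows and columns of ``da`` jointly;
    the p-value is one-sided for positive association with the add-one rule.
    ``permutations="exhaustive"`` enumerates all n! relabelings (identity
    included, so p >= 1/n!); ``permutations=0`` skips the null and reports
    only r.
    """
    n = _check_aligned(da, db, min_n=4)
    idx = np.tril_indices(n, k=-1)
    A = np.asarray(da.data, dtype=float)
    x = _tri(A, idx)
    y = _tri(np.asarray(db.data, dtype=float), idx)
    _require_variance(x, "first")
    _require_variance(y, "second")
    r_obs = _pearson(x, y)

    rng = np.random.default_rng(seed)
    perms = _perm_iter(n, permutations, rng)
    if not perms:
        return MantelResult(r=r_obs, p_value=None, n_permutations=0, partial=False,
                            seed=seed)
    exceed = sum(
        1 for p in perms if _pearson(_tri(A[np.ix_(p, p)], idx), y) >= r_obs
    )
    if permutations == "exhaustive":
        p_value = exceed / len(perms)
    else:
        p_value = (1.0 + exceed) / (1.0 + len(perms))
    return MantelResult(
        r=r_obs, p_value=p_value, n_permutations=len(perms), partial=False, seed=seed
    )


def partial_mantel(
    da: DistanceMatrix,
    db: DistanceMatrix,
    dc: DistanceMatrix,
    permutations: int | str = 999,
    seed: int | None = None,
    radius_m: float | None = None,
) -> MantelResult:
    """Partial Mantel test of ``da`` vs ``db`` controlling for ``dc``.

    r is the Pearson correlation of the OLS residuals of each lower triangle
    on the control triangle (the residual method).  The null permutes the
    focal matrix ``da``'s rows/columns and re-residualises.  If either
    residual vector is numerically constant — e.g. when ``da`` coincides
    with ``dc`` — the partial correlation is reported as 0.
    """
    n = _check_aligned(da, db, dc, min_n=5)
    idx = np.tril_indices(n, k=-1)
    A = np.asarray(da.data, dtype=float)
    x = _tri(A, idx)
    y = _tri(np.asarray(db.data, dtype=float), idx)
    z = _tri(np.asarray(dc.data, dtype=float), idx)
    _require_variance(x, "focal")
    _require_variance(y, "second")

    ry = _residualize(y, z)
    rx = _residualize(x, z)

    def _partial_r(res_x: np.ndarray) -> float:
        if np.std(res_x) < _VAR_TOL * max(np.std(x), 1.0) or np.std(ry) < _VAR_TOL * max(
            np.std(y), 1.0
        ):
            return 0.0
        return _pearson(res_x, ry)

    r_obs = _partial_r(rx)

    rng = np.random.default_rng(seed)
    perms = _perm_iter(n, permutations, rng)
    if not perms:
        return MantelResult(
            r=r_obs, p_value=None, n_permutations=0, partial=True,
            radius_m=radius_m, seed=seed,
        )
    exceed = 0
    for p in perms:
        xp = _tri(A[np.ix_(p, p)], idx)
        if _partial_r(_residualize(xp, z)) >= r_obs:
            exceed += 1
    if permutations == "exhaustive":
        p_value = exceed / len(perms)
    else:
        p_value = (1.0 + exceed) / (1.0 + len(perms))
    return MantelResult(
        r=r_obs,
        p_value=p_value,
        n_permutations=len(perms),
        partial=True,
        radius_m=radius_m,
        seed=seed,
    )


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment of a family of p-values."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adjusted[i] = min(running, 1.0)
    return adjusted.tolist()


def radius_scan(
    pmap: PlantPolygonMap,
    samples: Sequence[SampleLocation],
    microbial_dm: DistanceMatrix,
    radii: Sequence[float] | None = None,
    avg_grass: PlantComposition | None = None,
    permutations: int | str = 999,
    seed: int | None = None,
) -> ScanResult:
    """Scan radii for the scale at which plant composition predicts microbes.

    For each radius, plant composition around every sample is turned into a
    Bray-Curtis distance matrix and tested against ``microbial_dm`` with a
    partial Mantel test controlling geographic distance.  Radii where all
    samples share an identical plant composition are flagged degenerate and
    excluded from the argmax, not fatal.  Per-radius permutations use
    independent substreams spawned from ``seed``.
    """
    if radii is None:
        radii = default_radii()
    radii = np.asarray(list(radii), dtype=float)
    if len(radii) == 0 or np.any(np.diff(radii) <= 0):
        raise MantelError("radii must be a non-empty strictly increasing grid")
    ids = [s.sample_id for s in samples]
    if list(microbial_dm.ids) != ids:
        raise MantelError("microbial distance matrix is not aligned with samples")
    if avg_grass is None:
        avg_grass = pmap.grass_background

    geo = geographic_distance_matrix(samples)
    child_seeds = np.random.SeedSequence(seed).generate_state(len(radii)) % (2**31)

    results = []
    for radius, sub_seed in zip(radii, child_seeds):
        comps = [
            plant_composition_at_radius(pmap, s, radius, avg_grass=avg_grass)
            for s in samples
        ]
        cats = sorted({c for comp in comps for c in comp.categories})
        mat = pd.DataFrame(
            [comp.as_vector(cats) for comp in comps], index=ids, columns=cats
        )
        if np.allclose(mat.to_numpy(), mat.to_numpy()[0], atol=1e-12):
            results.append(
                MantelResult(
                    r=float("nan"), p_value=None, n_permutations=0, partial=True,
                    radius_m=float(radius), seed=int(sub_seed), degenerate=True,
                    note="all samples share one plant composition at this radius",
                )
            )
            continue
        plant_dm = bray_curtis(mat)
        results.append(
            partial_mantel(
                microbial_dm,
                plant_dm,
                geo,
                permutations=permutations,
                seed=int(sub_seed),
                radius_m=float(radius),
            )
        )
    return ScanResult(results=tuple(results), radii_m=tuple(float(r) for r in radii))
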