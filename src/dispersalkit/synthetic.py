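"""Synthetic landscapes, trap communities, and cell-count series.

Emulates the field design used to measure microbial dispersal into surface
soil: two adjacent ecosystems (shrubland west of a linear boundary,
grassland east of it), three transects crossing the boundary, and traps at
1, 3, 7 and 15 m into each ecosystem.  Every generator takes an explicit
seed and is bit-reproducible.

Three generators with known ground truth:

* :func:`generate_landscape` — labelled plant patches (discs clipped to
  their ecosystem half and against earlier patches) plus trap locations.
  Grass is the implicit background of unmapped ground, described by an
  average grass composition.
* :func:`simulate_trap_communities` — taxon counts per trap.  The expected
  profile mixes per-plant-category source profiles by the plant cover
  within a *true influence radius* around the trap, plus an ambient
  (background) component; counts are multinomial at a fixed read depth,
  optionally Dirichlet-overdispersed.
* :func:`simulate_cell_counts` — cell densities over time.  Closed slides
  decay from an inoculum, ``N(t) = N0 exp(-delta t)``; open slides fill
  toward the immigration-death plateau, ``N(t) = (I/delta)(1 - e^{-delta
  t})``.  Measurements carry unit-median lognormal noise of a stated CV.

Default parameter values reflect the field study being emulated: a 40 x 30
m domain, 3 transects, 4 collection days across a two-month deployment,
96 open slides (24 traps x 4 days), death-rate slides at +/-7 m, an
immigration rate near 1060 cells/cm2/day and a death rate near 0.028/day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, box
from shapely.ops import unary_union

from .landscape import (
    GeometryError,
    PlantComposition,
    PlantPolygonMap,
    SampleLocation,
    plant_composition_at_radius,
)

__all__ = [
    "SyntheticError",
    "LandscapeConfig",
    "SourceProfiles",
    "TrapSimConfig",
    "KineticsSimConfig",
    "generate_landscape",
    "default_source_profiles",
    "simulate_trap_communities",
    "simulate_cell_counts",
]

_MIN_PATCH_AREA = 1e-9


class SyntheticError(ValueError):
    """Raised for invalid simulation configurations."""


def _default_grass() -> PlantComposition:
    return PlantComposition({"grass_avena": 0.6, "grass_bromus": 0.4})


@dataclass(frozen=True)
class LandscapeConfig:
    """Geometry and patch intensities of a synthetic two-ecosystem landscape.

    The shrubland occupies ``x < boundary_x_m``, the grassland the rest.
    Patch centers follow independent Poisson processes; patch radii are
    gamma-distributed around the category's mean.  Shrubs occur only in the
    shrubland; forbs and bare-soil patches occur in both halves.  Negative
    trap offsets point into the shrubland.
    """

    domain_width_m: float = 40.0
    domain_height_m: float = 30.0
    boundary_x_m: float = 20.0
    n_transects: int = 3
    trap_offsets_m: tuple[float, ...] = (-15.0, -7.0, -3.0, -1.0, 1.0, 3.0, 7.0, 15.0)
    shrub_density_per_m2: float = 0.12
    forb_density_per_m2: float = 0.10
    bare_density_per_m2: float = 0.05
    patch_radius_mean_m: float = 1.0
    avg_grass_composition: PlantComposition = field(default_factory=_default_grass)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("shrub_density_per_m2", "forb_density_per_m2", "bare_density_per_m2"):
            if getattr(self, name) < 0:
                raise SyntheticError(f"{name} must be >= 0")
        if any(off == 0 for off in self.trap_offsets_m):
            raise SyntheticError("trap offsets must be nonzero")
        if not 0 < self.boundary_x_m < self.domain_width_m:
            raise SyntheticError("ecosystem boundary must lie inside the domain")
        if self.n_transects < 1:
            raise SyntheticError("need at least one transect")
        lo = self.boundary_x_m + min(self.trap_offsets_m)
        hi = self.boundary_x_m + max(self.trap_offsets_m)
        if lo < 0 or hi > self.domain_width_m:
            raise SyntheticError(
                "domain too small to place all traps: offsets reach "
                f"x in [{lo}, {hi}] outside [0, {self.domain_width_m}]"
            )


# (category, which halves, density attr, radius scale relative to mean)
_PATCH_SPECS = (
    ("shrub", ("shrubland",), "shrub_density_per_m2", 1.0),
    ("forb", ("shrubland", "grassland"), "forb_density_per_m2", 0.3),
    ("bare", ("shrubland", "grassland"), "bare_density_per_m2", 0.5),
)
_RADIUS_GAMMA_SHAPE = 6.0  # CV ~ 0.41 around the category mean


def generate_landscape(
    config: LandscapeConfig,
) -> tuple[PlantPolygonMap, list[SampleLocation]]:
    """Generate a labelled patch map and the transect trap locations.

    Later-drawn patches are clipped against earlier ones, so the returned
    patches never overlap; each is also clipped to its ecosystem half.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    W, H, bx = config.domain_width_m, config.domain_height_m, config.boundary_x_m
    domain = box(0.0, 0.0, W, H)
    halves = {
        "shrubland": box(0.0, 0.0, bx, H),
        "grassland": box(bx, 0.0, W, H),
    }

    patches: list[tuple[str, object]] = []
    for category, half_names, density_attr, rscale in _PATCH_SPECS:
        density = getattr(config, density_attr)
        for half_name in half_names:
            half = halves[half_name]
            n = rng.poisson(density * half.area)
            minx, miny, maxx, maxy = half.bounds
            xs = rng.uniform(minx, maxx, size=n)
            ys = rng.uniform(miny, maxy, size=n)
            mean_r = config.patch_radius_mean_m * rscale
            radii = rng.gamma(
                _RADIUS_GAMMA_SHAPE, mean_r / _RADIUS_GAMMA_SHAPE, size=n
            )
            for x, y, r in zip(xs, ys, radii):
                disc = Point(x, y).buffer(max(r, 1e-3), quad_segs=16)
                geom = disc.intersection(half)
                # clip against earlier patches; bbox prefilter keeps this near-linear
                gb = geom.bounds
                blockers = [
                    g for _, g in patches
                    if not (
                        g.bounds[2] < gb[0] or g.bounds[0] > gb[2]
                        or g.bounds[3] < gb[1] or g.bounds[1] > gb[3]
                    )
                ]
                if blockers:
                    geom = geom.difference(unary_union(blockers))
                if geom.is_empty or geom.area < _MIN_PATCH_AREA:
                    continue
                patches.append((category, geom))

    pmap = PlantPolygonMap(
        patches=patches,
        domain=domain,
        boundary_x_m=bx,
        grass_background=config.avg_grass_composition,
    )

    locations: list[SampleLocation] = []
    for t in range(1, config.n_transects + 1):
        y = H * (t - 0.5) / config.n_transects
        for off in config.trap_offsets_m:
            x = bx + off
            ecosystem = "shrubland" if off < 0 else "grassland"
            locations.append(
                SampleLocation(
                    sample_id=f"T{t}_{off:+g}m",
                    x=x,
                    y=y,
                    ecosystem=ecosystem,
                    transect=t,
                    offset_m=off,
                )
            )
    return pmap, locations


@dataclass(frozen=True)
class SourceProfiles:
    """Per-plant-category taxon source profiles plus an ambient background."""

    categories: tuple[str, ...]
    profiles: np.ndarray  # shape (n_categories, n_taxa), rows sum to 1
    background_profile: np.ndarray  # shape (n_taxa,), sums to 1
    background_weight: float = 0.3

    def __post_init__(self) -> None:
        profiles = np.asarray(self.profiles, dtype=float)
        background = np.asarray(self.background_profile, dtype=float)
        if profiles.ndim != 2 or profiles.shape[0] != len(self.categories):
            raise SyntheticError("profiles must be (n_categories, n_taxa)")
        if (profiles < 0).any() or (background < 0).any():
            raise SyntheticError("profiles must be non-negative")
        if not np.allclose(profiles.sum(axis=1), 1.0, atol=1e-9):
            raise SyntheticError("each category profile must sum to 1")
        if not math.isclose(background.sum(), 1.0, abs_tol=1e-9):
            raise SyntheticError("background profile must sum to 1")
        if not 0 <= self.background_weight <= 1:
            raise SyntheticError("background_weight must be in [0, 1]")
        object.__setattr__(self, "profiles", profiles)
        object.__setattr__(self, "background_profile", background)

    @property
    def n_taxa(self) -> int:
        return self.profiles.shape[1]

    def profile_for(self, category: str) -> np.ndarray:
        try:
            i = self.categories.index(category)
        except ValueError:
            raise SyntheticError(
                f"plant category {category!r} has no source profile; "
                f"known: {list(self.categories)}"
            ) from None
        return self.profiles[i]


def default_source_profiles(
    categories: Sequence[str],
    n_taxa: int = 60,
    background_weight: float = 0.3,
    concentration: float = 0.3,
    seed: int = 12345,
) -> SourceProfiles:
    """Sparse, mutually distinct Dirichlet source profiles per category.

    A small Dirichlet concentration (default 0.3) yields the skewed,
    low-overlap taxon profiles typical of distinct environmental sources.
    """
    rng = np.random.default_rng(seed)
    profiles = rng.dirichlet(np.full(n_taxa, concentration), size=len(categories))
    background = rng.dirichlet(np.full(n_taxa, concentration))
    return SourceProfiles(
        categories=tuple(categories),
        profiles=profiles,
        background_profile=background,
        background_weight=background_weight,
    )


@dataclass(frozen=True)
class TrapSimConfig:
    """Ground-truth settings for trap community simulation.

    ``influence_radius_m`` is the true radius at which surrounding
    vegetation determines what lands in a trap — the quantity the radius
    scan should recover.  ``overdispersion`` is a Dirichlet concentration
    scalar (None or inf for pure multinomial sampling).
    """

    influence_radius_m: float = 1.0
    reads_per_sample: int = 10000
    overdispersion: float | None = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.influence_radius_m <= 0:
            raise SyntheticError("influence_radius_m must be > 0")
        if self.reads_per_sample < 1:
            raise SyntheticError("reads_per_sample must be >= 1")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise SyntheticError("overdispersion concentration must be > 0")


def expected_trap_profile(
    pmap: PlantPolygonMap,
    location: SampleLocation,
    profiles: SourceProfiles,
    influence_radius_m: float,
) -> np.ndarray:
    """Expected taxon profile of a trap: cover-weighted source mixture.

    ``p = (1 - w_bg) * sum_c cover_c(rho*) * profile_c + w_bg * background``.
    """
    comp = plant_composition_at_radius(pmap, location, influence_radius_m)
    mix = np.zeros(profiles.n_taxa)
    for cat, frac in comp.items():
        if frac > 0:
            mix += frac * profiles.profile_for(cat)
    p = (1.0 - profiles.background_weight) * mix + (
        profiles.background_weight * profiles.background_profile
    )
    return p / p.sum()


def simulate_trap_communities(
    pmap: PlantPolygonMap,
    locations: Sequence[SampleLocation],
    profiles: SourceProfiles,
    cfg: TrapSimConfig,
) -> pd.DataFrame:
    """Simulate taxon counts (samples x taxa) for every trap location.

    Counts per trap are multinomial at ``reads_per_sample`` around the
    expected cover-weighted profile; finite ``overdispersion`` first draws
    the multinomial probabilities from a Dirichlet with that concentration,
    adding realistic sample-to-sample compositional noise.  Rows sum
    exactly to the read depth.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for loc in locations:
        if not pmap.domain.buffer(1e-9).contains(Point(loc.x, loc.y)):
            raise SyntheticError(f"location {loc.sample_id!r} lies outside the domain")
        p = expected_trap_profile(pmap, loc, profiles, cfg.influence_radius_m)
        if cfg.overdispersion is not None and math.isfinite(cfg.overdispersion):
            q = np.zeros_like(p)
            pos = p > 0
            q[pos] = rng.dirichlet(cfg.overdispersion * p[pos])
        else:
            q = p
        rows.append(rng.multinomial(cfg.reads_per_sample, q))
    table = pd.DataFrame(
        np.array(rows, dtype=int),
        index=[loc.sample_id for loc in locations],
        columns=[f"taxon_{i:03d}" for i in range(profiles.n_taxa)],
    )
    table.index.name = "sample_id"
    return table


@dataclass(frozen=True)
class KineticsSimConfig:
    """Ground-truth kinetics for simulated slide series.

    Defaults mirror the emulated deployment: collections at days 7, 14, 28
    and 56 within a two-month window; 24 open slides per collection day
    (96 total); immigration near 1060 cells/cm2/day and death rate
    0.02799/day (2.76% of cells dying per day); lognormal measurement
    noise with a 0.5 coefficient of variation and unit median.
    """

    immigration_rate_I: float = 1060.0
    death_rate_delta: float = 0.02799
    initial_density_N0: float = 50000.0
    sample_days: tuple[float, ...] = (7.0, 14.0, 28.0, 56.0)
    slides_per_timepoint: int = 24
    noise_cv: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.immigration_rate_I < 0:
            raise SyntheticError("immigration_rate_I must be >= 0")
        if self.death_rate_delta < 0:
            raise SyntheticError("death_rate_delta must be >= 0")
        days = np.asarray(self.sample_days, dtype=float)
        if len(days) == 0 or (days <= 0).any() or (np.diff(days) <= 0).any():
            raise SyntheticError("sample_days must be strictly positive and increasing")
        if self.slides_per_timepoint < 1:
            raise SyntheticError("slides_per_timepoint must be >= 1")
        if self.noise_cv < 0:
            raise SyntheticError("noise_cv must be >= 0")


def _mean_density(cfg: KineticsSimConfig, slide_type: str, day: np.ndarray) -> np.ndarray:
    if slide_type == "closed":
        return cfg.initial_density_N0 * np.exp(-cfg.death_rate_delta * day)
    if cfg.death_rate_delta > 0:
        return (cfg.immigration_rate_I / cfg.death_rate_delta) * (
            -np.expm1(-cfg.death_rate_delta * day)
        )
    return cfg.immigration_rate_I * day


# open slides sit at every offset; death-rate slides at 7 m into each ecosystem
_OPEN_OFFSETS = (-15.0, -7.0, -3.0, -1.0, 1.0, 3.0, 7.0, 15.0)
_CLOSED_OFFSETS = (-7.0, 7.0)


def simulate_cell_counts(cfg: KineticsSimConfig, slide_type: str) -> pd.DataFrame:
    """Simulate a cell-count series for open or closed slides.

    Mean dynamics follow the immigration-death model (open) or exponential
    decay (closed); each measurement is the mean times a unit-median
    lognormal factor with coefficient of variation ``noise_cv``.  Slides at
    each collection day are assigned round-robin to transects and offsets.
    Deterministic given ``cfg.seed``.
    """
    if slide_type not in ("open", "closed"):
        raise SyntheticError(f"slide_type must be 'open' or 'closed', got {slide_type!r}")
    if slide_type == "closed" and cfg.initial_density_N0 <= 0:
        raise SyntheticError(
            "closed slides need a positive inoculum density N0 "
            "(decay from zero is degenerate)"
        )
    if (
        slide_type == "open"
        and cfg.immigration_rate_I == 0
    ):
        raise SyntheticError("open slides with zero immigration yield no counts")

    rng = np.random.default_rng(cfg.seed)
    sigma = math.sqrt(math.log1p(cfg.noise_cv**2))
    offsets = _OPEN_OFFSETS if slide_type == "open" else _CLOSED_OFFSETS

    records = []
    counter = 0
    for day in cfg.sample_days:
        means = _mean_density(cfg, slide_type, np.full(cfg.slides_per_timepoint, day))
        factors = (
            np.exp(rng.normal(0.0, sigma, size=cfg.slides_per_timepoint))
            if sigma > 0
            else np.ones(cfg.slides_per_timepoint)
        )
        for s in range(cfg.slides_per_timepoint):
            off = offsets[counter % len(offsets)]
            transect = (counter // len(offsets)) % 3 + 1
            records.append(
                {
                    "slide_id": f"{slide_type}_{counter:04d}",
                    "slide_type": slide_type,
                    "ecosystem": "shrubland" if off < 0 else "grassland",
                    "transect": transect,
                    "offset_m": off,
                    "day": float(day),
                    "cells_per_cm2": float(means[s] * factors[s]),
                }
            )
            counter += 1
    return pd.DataFrame.from_records(records)
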