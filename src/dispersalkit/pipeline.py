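"""End-to-end pipeline: simulate -> kinetics -> community tests -> radius scan.

A :class:`RunConfig` captures every seed and parameter; :func:`run_pipeline`
executes the stages, writes their artifacts into an output directory and a
``manifest.json`` sufficient to reproduce the run.  A single top-level seed
deterministically derives independent per-stage substreams.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .community import bray_curtis, permanova, permdisp, relative_abundance
from .kinetics import (
    fit_death_rate,
    fit_immigration_rate,
    test_slope_homogeneity,
)
from .landscape import PlantPolygonMap
from .spatial import radius_scan, default_radii
from .synthetic import (
    KineticsSimConfig,
    LandscapeConfig,
    TrapSimConfig,
    default_source_profiles,
    generate_landscape,
    simulate_cell_counts,
    simulate_trap_communities,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("dispersalkit")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Parameters of a full pipeline run."""

    outdir: str = "dispersalkit_run"
    seed: int = 0
    n_perm: int = 999
    radii: list[float] = field(default_factory=lambda: [float(r) for r in default_radii()])
    group_field: str = "ecosystem"
    simulate: bool = True
    # paths used when simulate is False
    counts_path: str | None = None
    table_path: str | None = None
    map_path: str | None = None
    influence_radius_m: float = 1.0
    noise_cv: float = 0.5

    def __post_init__(self) -> None:
        if not isinstance(self.seed, int) or self.seed < 0:
            raise PipelineError("seed must be a non-negative integer")
        if self.n_perm < 1:
            raise PipelineError("n_perm must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    return [int(s % (2**31)) for s in np.random.SeedSequence(seed).generate_state(n)]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "stages": [],
    }

    def record(stage: str, t0: float, **info) -> None:
        manifest["stages"].append(
            {"stage": stage, "elapsed_s": round(time.perf_counter() - t0, 3), **info}
        )

    # pre-flight: inputs must exist before any stage runs
    if not config.simulate:
        for label, p in (
            ("counts", config.counts_path),
            ("table", config.table_path),
            ("map", config.map_path),
        ):
            if p is None or not Path(p).exists():
                raise PipelineError(f"pre-flight: missing {label} input file: {p}")

    # -- stage 1: simulate ---------------------------------------------------
    t0 = time.perf_counter()
    try:
        if config.simulate:
            land_cfg = LandscapeConfig(seed=seeds[0])
            pmap, locations = generate_landscape(land_cfg)
            profiles = default_source_profiles(
                pmap.categories + land_cfg.avg_grass_composition.categories,
                seed=seeds[1],
            )
            trap_cfg = TrapSimConfig(
                influence_radius_m=config.influence_radius_m, seed=seeds[2]
            )
            table = simulate_trap_communities(pmap, locations, profiles, trap_cfg)
            open_cfg = KineticsSimConfig(noise_cv=config.noise_cv, seed=seeds[3])
            closed_cfg = KineticsSimConfig(
                noise_cv=config.noise_cv, slides_per_timepoint=9, seed=seeds[4]
            )
            counts = pd.concat(
                [
                    simulate_cell_counts(open_cfg, "open"),
                    simulate_cell_counts(closed_cfg, "closed"),
                ],
                ignore_index=True,
            )
            pmap.write_geojson(outdir / "landscape.geojson")
            dio.write_count_table(table, outdir / "trap_taxa.tsv")
            dio.write_cell_counts(counts, outdir / "cell_counts.tsv")
            dio.write_json(
                {
                    "immigration_rate_I": open_cfg.immigration_rate_I,
                    "death_rate_delta": open_cfg.death_rate_delta,
                    "influence_radius_m": trap_cfg.influence_radius_m,
                },
                outdir / "ground_truth.json",
            )
            meta = {loc.sample_id: loc for loc in locations}
        else:
            counts = dio.read_cell_counts(config.counts_path)
            table = dio.read_count_table(config.table_path)
            pmap = PlantPolygonMap.from_geojson(config.map_path)
            _, locations = generate_landscape(LandscapeConfig(seed=seeds[0]))
            meta = {loc.sample_id: loc for loc in locations}
        logger.info("simulate: %d slides, %d trap samples", len(counts), len(table))
        record("simulate", t0, n_slides=len(counts), n_samples=len(table),
               seeds=seeds[:5])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'simulate' failed: {exc}") from exc

    # -- stage 2: kinetics ---------------------------------------------------
    t0 = time.perf_counter()
    try:
        death = fit_death_rate(counts)
        homogeneity = test_slope_homogeneity(counts, config.group_field)
        immigration = fit_immigration_rate(counts, delta=death.delta_per_day)
        dio.write_json(
            {
                "death_rate": death.to_dict(),
                "slope_homogeneity": homogeneity.to_dict(),
                "immigration": immigration.to_dict(),
            },
            outdir / "kinetics.json",
        )
        record("fit-kinetics", t0, n_points=death.n_points + immigration.n_points)
    except Exception as exc:
        raise PipelineError(f"stage 'fit-kinetics' failed: {exc}") from exc

    # -- stage 3: community --------------------------------------------------
    t0 = time.perf_counter()
    try:
        dm = bray_curtis(relative_abundance(table))
        groups = [meta[s].ecosystem for s in dm.ids]
        pa = permanova(dm, groups, permutations=config.n_perm, seed=seeds[5])
        pdp = permdisp(dm, groups, permutations=config.n_perm, seed=seeds[6])
        dio.write_distance_matrix(dm, outdir / "bray_curtis.tsv")
        dio.write_json(
            {"permanova": pa.to_dict(), "permdisp": pdp.to_dict()},
            outdir / "community_tests.json",
        )
        record("community", t0, n_samples=len(dm.ids))
    except Exception as exc:
        raise PipelineError(f"stage 'community' failed: {exc}") from exc

    # -- stage 4: scale scan -------------------------------------------------
    t0 = time.perf_counter()
    try:
        samples = [meta[s] for s in dm.ids]
        scan = radius_scan(
            pmap,
            samples,
            dm,
            radii=config.radii,
            permutations=config.n_perm,
            seed=seeds[7],
        )
        scan.to_frame().to_csv(outdir / "radius_scan.tsv", sep="\t", index=False)
        dio.write_json(
            {
                "argmax_radius_m": scan.argmax_radius_m,
                "results": [r.to_dict() for r in scan.results],
            },
            outdir / "radius_scan.json",
        )
        record("scale-scan", t0, n_radii=len(config.radii),
               argmax_radius_m=scan.argmax_radius_m)
    except Exception as exc:
        raise PipelineError(f"stage 'scale-scan' failed: {exc}") from exc

    dio.write_json(manifest, outdir / "manifest.json")
    return manifest
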