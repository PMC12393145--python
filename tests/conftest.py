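"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pandas as pd
import pytest

from dispersalkit import (
    LandscapeConfig,
    TrapSimConfig,
    default_source_profiles,
    generate_landscape,
    simulate_trap_communities,
)


def make_cell_series(
    slide_type: str,
    days,
    values,
    ecosystem: str = "grassland",
    prefix: str = "s",
) -> pd.DataFrame:
    """Build a cell-count series DataFrame from parallel day/value lists."""
    return pd.DataFrame(
        {
            "slide_id": [f"{prefix}{i}" for i in range(len(days))],
            "slide_type": slide_type,
            "ecosystem": ecosystem,
            "transect": 1,
            "offset_m": 1.0,
            "day": np.asarray(days, dtype=float),
            "cells_per_cm2": np.asarray(values, dtype=float),
        }
    )


@pytest.fixture(scope="session")
def landscape():
    """One default landscape with its 24 trap locations (seed-fixed)."""
    return generate_landscape(LandscapeConfig(seed=20240))


@pytest.fixture(scope="session")
def trap_table(landscape):
    """Trap taxon counts simulated on the session landscape."""
    pmap, locs = landscape
    profiles = default_source_profiles(
        pmap.categories + pmap.grass_background.categories, seed=7
    )
    table = simulate_trap_communities(
        pmap, locs, profiles, TrapSimConfig(seed=11)
    )
    return table, locs
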