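"""Plant-composition buffers, Mantel tests, and the radius scan."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from shapely import affinity
from shapely.geometry import box
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel

from dispersalkit import (
    PlantComposition,
    PlantPolygonMap,
    SampleLocation,
    bray_curtis,
    default_radii,
    geographic_distance_matrix,
    mantel,
    partial_mantel,
    plant_composition_at_radius,
    radius_scan,
)
from dispersalkit.landscape import CompositionError, GeometryError
from dispersalkit.spatial import MantelError, holm_adjust

from test_community import random_dm, table_from


GRASS = PlantComposition({"grass_a": 0.6, "grass_b": 0.4})


def shrub_half_map(width=20.0):
    """Left half of the domain is one shrub polygon; right half is grass."""
    domain = box(0, 0, width, 10)
    return PlantPolygonMap(
        patches=[("shrub", box(0, 0, width / 2, 10))],
        domain=domain,
        grass_background=GRASS,
    )


class TestPlantComposition:
    def test_circle_inside_one_polygon(self):
        pmap = shrub_half_map()
        comp = plant_composition_at_radius(pmap, (5.0, 5.0), 1.0)
        assert comp["shrub"] == pytest.approx(1.0, abs=1e-12)

    def test_circle_on_unmapped_grass_returns_average_grass(self):
        pmap = shrub_half_map()
        comp = plant_composition_at_radius(pmap, (15.0, 5.0), 1.0)
        assert comp["grass_a"] == pytest.approx(0.6, abs=1e-12)
        assert comp["grass_b"] == pytest.approx(0.4, abs=1e-12)
        assert comp["shrub"] == 0.0

    def test_half_disc_on_straight_edge(self):
        """Centred on the shrub boundary: analytic half-disc split."""
        comp = plant_composition_at_radius(shrub_half_map(), (10.0, 5.0), 1.0)
        assert comp["shrub"] == pytest.approx(0.5, abs=1e-9)
        assert comp["grass_a"] == pytest.approx(0.3, abs=1e-9)
        assert comp["grass_b"] == pytest.approx(0.2, abs=1e-9)

    def test_circle_clipped_to_domain(self):
        # circle hangs off the domain edge: fractions are over circle-within-domain
        comp = plant_composition_at_radius(shrub_half_map(), (15.0, 0.0), 1.0)
        assert comp["grass_a"] == pytest.approx(0.6, abs=1e-9)

    def test_circle_outside_domain_errors(self):
        with pytest.raises(GeometryError):
            plant_composition_at_radius(shrub_half_map(), (50.0, 50.0), 1.0)
        with pytest.raises(GeometryError):
            plant_composition_at_radius(shrub_half_map(), (5.0, 5.0), -1.0)

    def test_unmapped_area_without_grass_profile_errors(self):
        pmap = shrub_half_map()
        pmap.grass_background = None
        with pytest.raises(CompositionError):
            plant_composition_at_radius(pmap, (15.0, 5.0), 1.0)

    def test_translation_invariance(self):
        """Rigidly translating map and point leaves fractions unchanged."""
        pmap = shrub_half_map()
        dx, dy = 13.7, -4.2
        moved = PlantPolygonMap(
            patches=[(c, affinity.translate(g, dx, dy)) for c, g in pmap.patches],
            domain=affinity.translate(pmap.domain, dx, dy),
            grass_background=GRASS,
        )
        a = plant_composition_at_radius(pmap, (9.3, 5.1), 1.3)
        b = plant_composition_at_radius(moved, (9.3 + dx, 5.1 + dy), 1.3)
        for cat in a.categories:
            assert a[cat] == pytest.approx(b[cat], abs=1e-9)

    def test_rotation_invariance_within_circle_discretisation(self):
        """Rotation agrees at the circle-approximation accuracy (256-gon)."""
        pmap = shrub_half_map()
        angle = 33.0
        rot = lambda g: affinity.rotate(g, angle, origin=(0, 0))
        moved = PlantPolygonMap(
            patches=[(c, rot(g)) for c, g in pmap.patches],
            domain=rot(pmap.domain),
            grass_background=GRASS,
        )
        from shapely.geometry import Point

        p = Point(9.3, 5.1)
        q = rot(p)
        a = plant_composition_at_radius(pmap, (p.x, p.y), 1.3)
        b = plant_composition_at_radius(moved, (q.x, q.y), 1.3)
        for cat in a.categories:
            assert a[cat] == pytest.approx(b[cat], abs=1e-3)

    def test_monotone_in_coverage(self):
        """Growing a polygon that contains the circle cannot lower its share."""
        domain = box(0, 0, 20, 20)
        small = PlantPolygonMap(
            patches=[("shrub", box(4, 4, 8, 8))], domain=domain, grass_background=GRASS
        )
        big = PlantPolygonMap(
            patches=[("shrub", box(2, 2, 10, 10))], domain=domain, grass_background=GRASS
        )
        a = plant_composition_at_radius(small, (6.0, 6.0), 1.0)
        b = plant_composition_at_radius(big, (6.0, 6.0), 1.0)
        assert b["shrub"] >= a["shrub"]


class TestGeographicDistance:
    def test_examples(self):
        locs = [
            SampleLocation("a", 0, 0),
            SampleLocation("b", 3, 4),
            SampleLocation("c", 0, 0),
        ]
        dm = geographic_distance_matrix(locs)
        assert dm["a", "b"] == pytest.approx(5.0)
        assert dm["a", "c"] == pytest.approx(0.0)

    def test_collinear_points(self):
        locs = [SampleLocation(s, x, 0) for s, x in zip("abc", (0.0, 1.0, 3.0))]
        dm = geographic_distance_matrix(locs)
        assert dm["a", "b"] == pytest.approx(1.0)
        assert dm["b", "c"] == pytest.approx(2.0)
        assert dm["a", "c"] == pytest.approx(3.0)

    def test_duplicate_ids_rejected(self):
        locs = [SampleLocation("a", 0, 0), SampleLocation("a", 1, 1)]
        with pytest.raises(MantelError, match="duplicated"):
            geographic_distance_matrix(locs)


def brute_force_mantel_p(da, db):
    """Exhaustive Mantel oracle over all n! relabelings of the first matrix."""
    n = da.shape[0]
    idx = np.tril_indices(n, k=-1)
    y = db[idx]

    def corr(mat):
        x = mat[idx]
        return np.corrcoef(x, y)[0, 1]

    r_obs = corr(da)
    rs = [
        corr(da[np.ix_(p, p)]) for p in itertools.permutations(range(n))
    ]
    return r_obs, sum(r >= r_obs for r in rs) / len(rs)


class TestMantel:
    def test_identical_matrices_give_r_one(self):
        dm = random_dm(6, np.random.default_rng(0))
        res = mantel(dm, dm, permutations=99, seed=1)
        assert res.r == pytest.approx(1.0, abs=1e-12)

    def test_exhaustive_p_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        da, db = random_dm(5, rng), random_dm(5, rng)
        r_oracle, p_oracle = brute_force_mantel_p(da.data, db.data)
        res = mantel(da, db, permutations="exhaustive")
        assert res.n_permutations == 120
        assert res.r == pytest.approx(r_oracle, abs=1e-12)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_matches_skbio(self):
        """r and p cross-checked against scikit-bio's Mantel implementation."""
        rng = np.random.default_rng(2)
        da, db = random_dm(10, rng), random_dm(10, rng)
        ours = mantel(da, db, permutations=999, seed=0)
        r_skbio, p_skbio, _ = skbio_mantel(
            da, db, method="pearson", permutations=999, alternative="greater"
        )
        assert ours.r == pytest.approx(float(r_skbio), abs=1e-12)
        assert ours.p_value == pytest.approx(float(p_skbio), abs=0.05)

    def test_invariant_to_positive_affine_rescaling(self):
        rng = np.random.default_rng(3)
        da, db = random_dm(7, rng), random_dm(7, rng)
        scaled = 3.0 * db.data + 2.0
        np.fill_diagonal(scaled, 0.0)
        db2 = DistanceMatrix(scaled, ids=db.ids)
        assert mantel(da, db, permutations=0).r == pytest.approx(
            mantel(da, db2, permutations=0).r, abs=1e-12
        )

    def test_degenerate_inputs_rejected(self):
        dm = random_dm(6, np.random.default_rng(4))
        flat = DistanceMatrix(
            np.ones((6, 6)) - np.eye(6), ids=dm.ids
        )
        with pytest.raises(MantelError, match="zero variance"):
            mantel(dm, flat, permutations=9)
        small = random_dm(3, np.random.default_rng(5))
        with pytest.raises(MantelError, match="at least 4"):
            mantel(small, small, permutations=9)


class TestPartialMantel:
    def test_matches_closed_form_partial_correlation(self):
        """r_ab.c = (r_ab - r_ac r_bc) / sqrt((1-r_ac^2)(1-r_bc^2))."""
        rng = np.random.default_rng(6)
        for _ in range(50):
            da, db, dc = (random_dm(7, rng) for _ in range(3))
            idx = np.tril_indices(7, k=-1)
            x, y, z = da.data[idx], db.data[idx], dc.data[idx]
            r_ab = np.corrcoef(x, y)[0, 1]
            r_ac = np.corrcoef(x, z)[0, 1]
            r_bc = np.corrcoef(y, z)[0, 1]
            expected = (r_ab - r_ac * r_bc) / math.sqrt(
                (1 - r_ac**2) * (1 - r_bc**2)
            )
            res = partial_mantel(da, db, dc, permutations=0)
            assert res.r == pytest.approx(expected, abs=1e-10)

    def test_constant_control_reduces_to_simple_mantel(self):
        rng = np.random.default_rng(7)
        da, db = random_dm(8, rng), random_dm(8, rng)
        const = DistanceMatrix(np.ones((8, 8)) - np.eye(8), ids=da.ids)
        partial = partial_mantel(da, db, const, permutations=0).r
        simple = mantel(da, db, permutations=0).r
        assert partial == pytest.approx(simple, abs=1e-10)

    def test_controlling_for_itself_gives_zero(self):
        rng = np.random.default_rng(8)
        da, db = random_dm(8, rng), random_dm(8, rng)
        assert partial_mantel(da, db, da, permutations=0).r == 0.0

    def test_seeded_determinism(self):
        rng = np.random.default_rng(9)
        da, db, dc = (random_dm(8, rng) for _ in range(3))
        p1 = partial_mantel(da, db, dc, permutations=99, seed=5).p_value
        p2 = partial_mantel(da, db, dc, permutations=99, seed=5).p_value
        assert p1 == p2


class TestRadiusScan:
    def test_default_grid_shape(self):
        radii = default_radii()
        assert len(radii) == 11
        assert radii[0] == pytest.approx(0.1)
        assert radii[-1] == pytest.approx(4.0)
        assert (np.diff(radii) > 0).all()

    def test_single_radius_reduces_to_partial_mantel(self, trap_table, landscape):
        pmap, locs = landscape
        table, _ = trap_table
        from dispersalkit import relative_abundance

        dm = bray_curtis(relative_abundance(table))
        scan = radius_scan(pmap, locs, dm, radii=[1.0], permutations=0, seed=0)
        assert len(scan.results) == 1
        direct = partial_mantel(
            dm,
            bray_curtis(_plant_table(pmap, locs, 1.0)),
            geographic_distance_matrix(locs),
            permutations=0,
        )
        assert scan.results[0].r == pytest.approx(direct.r, abs=1e-12)
        assert scan.argmax_radius_m == 1.0

    def test_scan_deterministic_under_fixed_seed(self, trap_table, landscape):
        pmap, locs = landscape
        table, _ = trap_table
        from dispersalkit import relative_abundance

        dm = bray_curtis(relative_abundance(table))
        s1 = radius_scan(pmap, locs, dm, radii=[0.5, 1.0], permutations=49, seed=3)
        s2 = radius_scan(pmap, locs, dm, radii=[0.5, 1.0], permutations=49, seed=3)
        assert [r.p_value for r in s1.results] == [r.p_value for r in s2.results]

    def test_degenerate_radius_flagged_not_fatal(self):
        """A featureless landscape yields identical compositions everywhere."""
        domain = box(0, 0, 30, 10)
        pmap = PlantPolygonMap(patches=[], domain=domain, grass_background=GRASS)
        locs = [SampleLocation(f"s{i}", 2.0 + 3 * i, 5.0) for i in range(8)]
        dm = random_dm(8, np.random.default_rng(10), ids=[l.sample_id for l in locs])
        scan = radius_scan(pmap, locs, dm, radii=[0.5, 1.0], permutations=9, seed=0)
        assert all(r.degenerate for r in scan.results)
        assert scan.argmax_radius_m is None

    def test_misaligned_matrix_rejected(self, landscape):
        pmap, locs = landscape
        dm = random_dm(5, np.random.default_rng(11))
        with pytest.raises(MantelError, match="aligned"):
            radius_scan(pmap, locs, dm, radii=[1.0], permutations=9)


def _plant_table(pmap, locs, radius):
    comps = [plant_composition_at_radius(pmap, l, radius) for l in locs]
    cats = sorted({c for comp in comps for c in comp.categories})
    return pd.DataFrame(
        [comp.as_vector(cats) for comp in comps],
        index=[l.sample_id for l in locs],
        columns=cats,
    )


class TestHolm:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        p = [0.01, 0.04, 0.03, 0.2, 0.9]
        ours = holm_adjust(p)
        theirs = multipletests(p, method="holm")[1]
        assert np.allclose(ours, theirs, atol=1e-12)
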