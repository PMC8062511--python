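"""Performance metrics: definition checks, inscribed-circle oracle,
prolapse fixtures, invariances."""

import dataclasses
import math

import numpy as np
import pytest
from shapely.geometry import Polygon

from conftest import make_free_state
from stentmech.lattice import DESIGN_CATALOG, strut_outer_surface_area
from stentmech.metrics import (MetricsReport, circular_cell_diameter,
                               deployed_hoop_force, inscribed_circle_diameter,
                               mean_stent_diameter, normalized_hoop_force,
                               percentage_difference, radial_strength,
                               stent_artery_ratio, vessel_prolapse)
from stentmech.solver import CrimpResult


class TestMSD:
    def test_uniform_cylinder(self, m12):
        st = make_free_state(m12, 4.5)
        assert mean_stent_diameter(st) == pytest.approx(4.5, abs=1e-12)

    def test_arithmetic_mean_of_stations(self, m12):
        half = m12.rings // 2
        diams = np.array([4.0] * half + [5.0] * (m12.rings - half))
        st = make_free_state(m12, diams)
        assert mean_stent_diameter(st) == pytest.approx(diams.mean(),
                                                        abs=1e-12)

    def test_percentage_difference_formula(self):
        # the printed design-comparison form: (12pk - 9pk)/9pk x 100
        assert percentage_difference(4.2, 4.0) == pytest.approx(5.0,
                                                                abs=1e-12)
        assert percentage_difference(4.0, 4.0) == 0.0


def _grid_oracle(points, spacing_frac=1e-3):
    """Brute-force inscribed circle: densely sample interior points and
    take twice the maximal distance to the boundary."""
    poly = Polygon(points)
    minx, miny, maxx, maxy = poly.bounds
    size = max(maxx - minx, maxy - miny)
    step = max(size * spacing_frac, size / 400)  # capped for runtime
    xs = np.arange(minx, maxx + step, step)
    ys = np.arange(miny, maxy + step, step)
    gx, gy = np.meshgrid(xs, ys)
    from shapely import contains_xy, distance, points as mk_points
    pts = mk_points(gx.ravel(), gy.ravel())
    inside = contains_xy(poly, gx.ravel(), gy.ravel())
    if not inside.any():
        return 0.0
    d = distance(poly.exterior, pts[inside])
    return 2.0 * float(d.max())


def _random_convex(rng, n=8):
    ang = np.sort(rng.uniform(0, 2 * math.pi, n))
    rad = rng.uniform(0.5, 1.5)
    return np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])


def _random_star(rng, n=7):
    ang = np.sort(rng.uniform(0, 2 * math.pi, n))
    rad = rng.uniform(0.4, 1.4, n)
    return np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])


class TestInscribedCircle:
    def test_square_cell_equals_side(self):
        s = 1.37
        square = np.array([[0, 0], [s, 0], [s, s], [0, s]])
        assert inscribed_circle_diameter(square, tolerance=1e-8) \
            == pytest.approx(s, abs=1e-6)

    def test_matches_grid_oracle_on_random_cells(self):
        rng = np.random.default_rng(42)
        for k in range(100):
            pts = (_random_convex(rng) if k % 2 == 0
                   else _random_star(rng))
            poly = Polygon(pts)
            if not poly.is_valid or poly.area < 0.05:
                continue
            exact = inscribed_circle_diameter(pts, tolerance=1e-5)
            oracle = _grid_oracle(pts)
            assert exact == pytest.approx(oracle, rel=0.01, abs=5e-3)

    def test_degenerate_polygon_rejected(self):
        bow_tie = np.array([[0, 0], [1, 1], [1, 0], [0, 1]])
        with pytest.raises(ValueError, match="degenerate"):
            inscribed_circle_diameter(bow_tie)


class TestCCD:
    def test_ccd_increases_with_expansion_diameter(self, m12):
        ccd = {d: circular_cell_diameter(make_free_state(m12, d))
               for d in (3.5, 5.0)}
        assert ccd[5.0] > ccd[3.5]

    def test_ccd_positive_and_smaller_than_cell_pitch(self, m12):
        st = make_free_state(m12, 4.5)
        ccd = circular_cell_diameter(st)
        assert 0.0 < ccd < 2 * math.pi * 2.25 / m12.peaks * 2

    def test_more_peaks_scaffold_better(self):
        ccd = {}
        for name in ("MEGATRON_9", "MEGATRON_10", "MEGATRON_12"):
            d = DESIGN_CATALOG[name]
            ccd[name] = circular_cell_diameter(make_free_state(d, 4.5))
        assert ccd["MEGATRON_12"] < ccd["MEGATRON_10"] < ccd["MEGATRON_9"]


class TestProlapse:
    def test_zero_sag_gives_zero(self, m12):
        st = make_free_state(m12, 4.5)
        st.wall_sag_override = lambda cell: 0.0
        assert vessel_prolapse(st) == 0.0

    def test_hemispherical_sag_fixture(self, m12):
        """A single cell sagging as a spherical cap of depth d must report
        a prolapse of d (up to the axial section sampling)."""
        st = make_free_state(m12, 4.5)
        depth = 0.123
        cells_seen = []

        def override(cell):
            cells_seen.append(cell["z_center"])
            return depth if len(cells_seen) == 1 else 0.0

        st.wall_sag_override = override
        got = vessel_prolapse(st, aggregate="max", n_sections=400)
        assert got == pytest.approx(depth, rel=0.02)

    def test_sag_law_orders_designs_by_peaks(self):
        """Under one shared sag law (depth proportional to cell opening
        area) denser patterns protrude less."""
        prol = {}
        for name in ("MEGATRON_9", "MEGATRON_12"):
            d = DESIGN_CATALOG[name]
            st = make_free_state(d, 4.5)
            st.wall_sag_override = lambda cell: 0.1 * cell["ccd"] ** 2
            prol[name] = vessel_prolapse(st)
        assert prol["MEGATRON_12"] < prol["MEGATRON_9"]

    def test_missing_wall_field_rejected(self, m12):
        st = make_free_state(m12, 4.5)
        with pytest.raises(ValueError, match="wall"):
            vessel_prolapse(st)


class TestSAR:
    def test_matches_analytic_cylinder_ratio(self, m12):
        st = make_free_state(m12, 4.5)
        strut_area = strut_outer_surface_area(st.lattice, m12)
        lumen = 2 * math.pi * st.r_outer[0] * st.deployed_length
        assert stent_artery_ratio(st) == pytest.approx(
            100 * strut_area / lumen, rel=1e-6)

    def test_doubling_strut_width_doubles_sar(self, m12):
        st = make_free_state(m12, 4.5)
        wide = dataclasses.replace(m12, strut_width_um=2 * m12.strut_width_um)
        st_w = dataclasses.replace(st, design=wide)
        assert stent_artery_ratio(st_w) == pytest.approx(
            2 * stent_artery_ratio(st), rel=1e-9)

    def test_sar_decreases_with_diameter(self, m12):
        sar = {d: stent_artery_ratio(make_free_state(m12, d))
               for d in (3.5, 5.0)}
        assert sar[5.0] < sar[3.5]


class TestHoopForceDefinitions:
    def test_definition_arithmetic(self):
        # radial force 2 pi N over a 1 mm nominal length -> 1 N/mm
        cr = CrimpResult(curve=np.array([[4.0, 2 * math.pi]]),
                         reduction=0.15)
        assert normalized_hoop_force(cr, 1.0) == pytest.approx(1.0,
                                                               abs=1e-12)

    def test_bench_scale_pairing(self):
        # a 7.6 N maximum hoop force over a 20 mm nominal length is
        # 0.38 N/mm (the hoop force is radial force / 2 pi)
        cr = CrimpResult(curve=np.array([[4.0, 7.6 * 2 * math.pi]]),
                         reduction=0.15)
        assert cr.max_hoop_force == pytest.approx(7.6, rel=1e-12)
        assert normalized_hoop_force(cr, 20.0) == pytest.approx(0.38,
                                                                rel=1e-12)

    def test_linearity_in_force(self):
        base = np.array([[4.0, 5.0], [3.9, 8.0]])
        a = normalized_hoop_force(CrimpResult(curve=base, reduction=0.15),
                                  10.0)
        b = normalized_hoop_force(CrimpResult(curve=base * [1.0, 3.0],
                                              reduction=0.15), 10.0)
        assert b == pytest.approx(3 * a, rel=1e-12)

    def test_nonpositive_length_rejected(self):
        cr = CrimpResult(curve=np.array([[4.0, 5.0]]), reduction=0.15)
        with pytest.raises(ValueError):
            normalized_hoop_force(cr, 0.0)


class TestRadialStrength:
    def test_force_over_area(self, m12):
        st = make_free_state(m12, 4.5, radial_force=10.0 / m12.rings)
        area = strut_outer_surface_area(st.lattice, m12)
        assert radial_strength(st) == pytest.approx(10.0 / area, rel=1e-9)

    def test_free_expansion_has_zero_strength(self, m12):
        st = make_free_state(m12, 4.5)
        assert radial_strength(st) == 0.0
        assert deployed_hoop_force(st) == 0.0


class TestInvariances:
    def test_metrics_invariant_under_axial_rotation(self, m12):
        st = make_free_state(m12, 4.5)
        st.wall_sag_override = lambda cell: 0.05 * cell["ccd"]
        ref = (mean_stent_diameter(st), circular_cell_diameter(st),
               stent_artery_ratio(st), vessel_prolapse(st))
        st.lattice.theta = (st.lattice.theta + 2.0) % (2 * math.pi)
        rot = (mean_stent_diameter(st), circular_cell_diameter(st),
               stent_artery_ratio(st), vessel_prolapse(st))
        assert rot[0] == pytest.approx(ref[0], abs=1e-12)
        assert rot[1] == pytest.approx(ref[1], abs=1e-3)
        assert rot[2] == pytest.approx(ref[2], rel=1e-9)
        assert rot[3] == pytest.approx(ref[3], abs=1e-3)


class TestReportValidation:
    def test_invalid_values_rejected(self):
        good = dict(design="X", diameter=4.5, plaque_mode="soft",
                    geometry_seed=0, msd=4.2, ccd=1.0, prolapse=0.05,
                    prolapse_mean=0.02, sar=12.0,
                    normalized_hoop_force=0.1, radial_strength=0.3)
        MetricsReport(**good)
        with pytest.raises(ValueError):
            MetricsReport(**{**good, "msd": 0.0})
        with pytest.raises(ValueError):
            MetricsReport(**{**good, "sar": 120.0})
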