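"""Deployment solver: hinge mechanics oracles, limit cases, recoil, crimp."""

import math

import numpy as np
import pytest

from stentmech.lattice import max_expansion_diameter
from stentmech.materials import AlloyMaterial, material_catalog
from stentmech.solver import (_HingeRings, SolverConfig, expand_stent,
                              free_expand, radial_crimp, recoil,
                              rigid_response, stent_hoop_resistance)
from stentmech.vessel import assign_homogeneous_plaque

ELASTIC_ALLOY = AlloyMaterial(elastic_modulus=203000.0, yield_stress=1e9,
                              hardening=((0.0, 1e9), (1.0, 1e9)))


class TestHoopResistance:
    def test_zero_at_crimped_diameter(self, m12):
        p = stent_hoop_resistance(
            m12, inner_diameter=m12.crimped_inner_diameter)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_increases_with_peaks_at_equal_strut_dims(self, designs):
        ps = {n: stent_hoop_resistance(designs[n], inner_diameter=4.5)
              for n in ("MEGATRON_9", "MEGATRON_10", "MEGATRON_12")}
        assert ps["MEGATRON_12"] > ps["MEGATRON_10"] > ps["MEGATRON_9"]

    def test_out_of_range_diameter_rejected(self, m12):
        with pytest.raises(ValueError, match="kinematic range"):
            stent_hoop_resistance(m12, inner_diameter=0.5)
        with pytest.raises(ValueError, match="kinematic range"):
            stent_hoop_resistance(
                m12, inner_diameter=max_expansion_diameter(m12) + 0.1)

    def test_elastic_reversibility(self, m12):
        rings = _HingeRings(m12, ELASTIC_ALLOY)
        r_hi = np.full(rings.n, 2.0)
        r_back = np.full(rings.n, rings.r0)
        for r in np.linspace(rings.r0, 2.0, 50):
            rings.commit(np.full(rings.n, r))
        for r in np.linspace(2.0, rings.r0, 50):
            rings.commit(np.full(rings.n, r))
        assert np.allclose(rings.theta_pl, 0.0, atol=1e-15)
        assert np.allclose(rings.pressure(r_back), 0.0, atol=1e-12)

    def test_work_balance_closes(self, m12):
        """Pressure work along the virgin expansion path equals the total
        hinge work (midpoint quadrature on both sides)."""
        alloy = material_catalog("pt_cr")
        rings = _HingeRings(m12, alloy)
        r_path = np.linspace(rings.r0, 2.1, 8000)
        w_pressure = 0.0
        w_hinge = 0.0
        for r_a, r_b in zip(r_path[:-1], r_path[1:]):
            r_mid = np.full(rings.n, 0.5 * (r_a + r_b))
            p_mid = rings.pressure(r_mid)[0]
            w_pressure += (p_mid * 2 * math.pi * 0.5 * (r_a + r_b)
                           * rings.s0 * (r_b - r_a))
            m_mid, _, _ = rings.trial_moment(r_mid)
            dth = (rings.dtheta(np.full(rings.n, r_b))
                   - rings.dtheta(np.full(rings.n, r_a)))[0]
            w_hinge += 2 * rings.p * m_mid[0] * dth
            rings.commit(np.full(rings.n, r_b))
        assert w_pressure == pytest.approx(w_hinge, rel=1e-6)


class TestExpansion:
    def test_free_expansion_is_uniform(self, m12):
        st = free_expand(m12, 4.5, deflate=False)
        assert np.ptp(st.r_center) <= 1e-9
        assert st.contact_pressure.max() == 0.0

    def test_free_expansion_reaches_balloon_target(self, m12):
        st = free_expand(m12, 4.5, deflate=False)
        assert 2 * st.r_inner.mean() == pytest.approx(4.5, abs=1e-6)

    def test_rigid_vessel_limit(self, m12, neutral_vessel):
        pos = (neutral_vessel.params.stenosis_center_z
               - m12.crimped_length / 2)
        resp = rigid_response(neutral_vessel, m12, pos, stiffness=1e6)
        st = expand_stent(m12, neutral_vessel, target_inner_diameter=6.0,
                          position_z=pos, response=resp, deflate=False)
        r_nat = neutral_vessel.lumen_radius[st.vessel_station].mean(axis=1)
        assert np.abs(st.r_outer - r_nat).max() < 1e-4

    def test_soft_expands_more_than_stiff(self, m12, base_vessel):
        msd = {}
        for cat in ("soft", "stiff"):
            v = assign_homogeneous_plaque(base_vessel, cat)
            st = expand_stent(m12, v, target_inner_diameter=4.5)
            msd[cat] = 2 * st.r_inner.mean()
        assert msd["soft"] > msd["stiff"]

    def test_equilibrium_residual_within_tolerance(self, m12,
                                                   neutral_vessel):
        cfg = SolverConfig()
        st = expand_stent(m12, neutral_vessel, cfg,
                          target_inner_diameter=4.5)
        assert st.residual.max() <= cfg.tolerance

    def test_stent_must_fit_vessel(self, m12, neutral_vessel):
        with pytest.raises(ValueError, match="fit"):
            expand_stent(m12, neutral_vessel, target_inner_diameter=4.5,
                         position_z=30.0)


class TestRecoil:
    def test_radii_non_increasing_and_contact_non_negative(
            self, m12, neutral_vessel):
        peak = expand_stent(m12, neutral_vessel, target_inner_diameter=4.5,
                            deflate=False)
        final = recoil(peak)
        assert np.all(final.r_center <= peak.r_center + 1e-12)
        assert np.all(final.contact_pressure >= 0.0)
        assert np.all(final.radial_force >= 0.0)
        assert final.deflated

    def test_recoil_grows_with_vessel_stiffness(self, m12, base_vessel):
        rec = {}
        for cat in ("soft", "very_stiff"):
            v = assign_homogeneous_plaque(base_vessel, cat)
            peak = expand_stent(m12, v, target_inner_diameter=4.5,
                                deflate=False)
            final = recoil(peak)
            rec[cat] = float((peak.r_center - final.r_center).mean())
        assert rec["very_stiff"] > rec["soft"]

    def test_stiffer_alloy_recoils_less(self, m12, neutral_vessel):
        rec = {}
        for scale in (1.0, 10.0):
            alloy = AlloyMaterial(203000.0 * scale, 480.0 * scale,
                                  tuple((e, s * scale) for e, s in
                                        material_catalog("pt_cr").hardening))
            peak = expand_stent(m12, neutral_vessel,
                                target_inner_diameter=4.5, deflate=False,
                                alloy=alloy)
            final = recoil(peak)
            rec[scale] = float((peak.r_center - final.r_center).mean())
        assert rec[10.0] < rec[1.0]

    def test_double_deflation_rejected(self, m12, neutral_vessel):
        st = expand_stent(m12, neutral_vessel, target_inner_diameter=4.5)
        with pytest.raises(ValueError, match="deflated"):
            recoil(st)


class TestCrimp:
    def test_target_diameter_arithmetic(self, m12):
        st = free_expand(m12, 4.5)
        cr = radial_crimp(st, reduction=0.15)
        d0 = cr.curve[0, 0]
        assert cr.curve[-1, 0] == pytest.approx(0.85 * d0, abs=1e-9)
        assert cr.reduction == 0.15

    def test_diameters_strictly_decreasing(self, m12):
        cr = radial_crimp(free_expand(m12, 4.5))
        assert np.all(np.diff(cr.curve[:, 0]) < 0)

    def test_invalid_reduction_rejected(self, m12):
        st = free_expand(m12, 4.5)
        with pytest.raises(ValueError):
            radial_crimp(st, reduction=0.6)
        with pytest.raises(ValueError):
            radial_crimp(st, reduction=0.0)

    def test_force_rises_to_maximum_then_plateaus(self, m12):
        """Monotone rise to the force maximum; the post-peak tail is a
        plateau (bounded geometric softening, < 10% below the max)."""
        cr = radial_crimp(free_expand(m12, 4.5))
        f = cr.curve[:, 1]
        k = int(np.argmax(f))
        assert np.all(np.diff(f[:k + 1]) >= -1e-9)
        assert f[k:].min() >= 0.9 * f.max()

    def test_elastic_alloy_retraces_without_hysteresis(self, m12):
        """With a purely elastic alloy the crimp force at a radius equals
        the virgin loading curve at that radius (path independence)."""
        st = free_expand(m12, 3.0, deflate=False)
        st_el = expand_stent(m12, None, target_inner_diameter=3.0,
                             deflate=False, alloy=ELASTIC_ALLOY)
        cr = radial_crimp(st_el, reduction=0.2)
        fresh = _HingeRings(m12, ELASTIC_ALLOY)
        for d_out, force in cr.curve[1:]:
            r = np.full(fresh.n, (d_out - m12.strut_thickness) / 2)
            q = max(-fresh.pressure(r)[0], 0.0)
            expect = q * math.pi * d_out * fresh.s0 * fresh.n
            assert force == pytest.approx(expect, abs=1e-9 + 1e-6 * expect)

    def test_hoop_force_grows_with_expansion_diameter(self, m12):
        forces = [radial_crimp(free_expand(m12, d)).max_hoop_force
                  for d in (3.5, 4.5, 5.0)]
        assert forces[0] < forces[1] < forces[2]

    def test_hoop_force_ordering_across_designs(self, designs):
        hf = {n: radial_crimp(free_expand(designs[n], 4.5)).max_hoop_force
              for n in designs}
        assert hf["MEGATRON_12"] > hf["MEGATRON_10"] > hf["MEGATRON_9"]
        # SYNERGY's hoop force tracks the 9-peak design, not the 10-peak
        assert (abs(hf["SYNERGY"] - hf["MEGATRON_9"])
                < abs(hf["SYNERGY"] - hf["MEGATRON_10"]))
        assert hf["SYNERGY"] < hf["MEGATRON_10"]
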