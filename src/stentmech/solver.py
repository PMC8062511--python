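"""Reduced-order quasi-static stent deployment mechanics.

The full 3-D explicit-dynamics contact problem is replaced by a per-station
(axisymmetric) equilibrium model.  This is the central fidelity trade-off of
the package: it reproduces the *definitions* of the performance metrics and
the *orderings* between designs, diameters and plaque classes, not absolute
newton/millimetre values of any commercial finite-element analysis.

Model
-----
Each stent ring is a closed zigzag of 2p rigid legs of length L joined by
elastoplastic hinges at the crowns.  At centerline radius r the chord
between adjacent crowns is c = 2 r sin(pi/2p), the crown half-angle is
beta = asin(c / L), and each crown has opened by dtheta = 2 (beta - beta0)
since crimp.  The hinge moment follows a 1-D elastoplastic law: elastic
stiffness k = E I / l_h with I = w t^3 / 12 and an effective hinge length
l_h = 2 t; yield at M_y = Z_p sigma_flow with the plastic section modulus
Z_p = w t^2 / 4 and isotropic hardening on the accumulated hinge rotation
(the hinge-strain mapping is eps_pl = kappa t / (2 l_h)).  Equating hinge
work to pressure work on the ring's tributary shell (area 2 pi r s0, with
s0 the crimped crown pitch) gives the equivalent expansion pressure

    p_s(r) = 2p * M * (dtheta/dr) / (2 pi r s0),   dtheta/dr = 4 sin(pi/2p)/h

with h = sqrt(L^2 - c^2) the current axial crown height.  The balloon is an
internal pressure source capped by a semi-compliant membrane limit (900 MPa
modulus); the vessel reacts with the per-station pressure-displacement law
of :mod:`stentmech.vessel`.  Equilibrium at every pressure increment is
solved per station by bisection to the configured force tolerance.

The recorded friction coefficient (0.2) plays no role: the reduced model
has no axial contact sliding.  It is kept in the configuration for
provenance only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .lattice import (StentDesign, StentLattice, build_design,
                      expand_kinematics, max_expansion_diameter)
from .materials import AlloyMaterial, BalloonMaterial, material_catalog
from .vessel import RadialResponse, VesselGeometry

__all__ = [
    "SolverConfig",
    "DeployedState",
    "CrimpResult",
    "stent_hoop_resistance",
    "expand_stent",
    "recoil",
    "radial_crimp",
    "free_expand",
    "rigid_response",
    "ATM",
]

ATM = 0.101325  # MPa per atmosphere


@dataclass(frozen=True)
class SolverConfig:
    """Quasi-static solver settings.

    ``tolerance`` is the per-station net radial force residual in newtons.
    ``friction`` is recorded for provenance and unused (no axial sliding in
    the reduced model).
    """

    inflation_pressure_atm: float = 18.0
    n_inflation_steps: int = 50
    n_deflation_steps: int = 25
    tolerance: float = 1e-6          # N
    friction: float = 0.2            # recorded, unused
    max_iterations: int = 48
    balloon: BalloonMaterial = field(
        default_factory=lambda: material_catalog("balloon"))

    def __post_init__(self):
        if self.inflation_pressure_atm <= 0:
            raise ValueError("pressure must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


# ---------------------------------------------------------------------------
# hinge ring array
# ---------------------------------------------------------------------------

class _HingeRings:
    """Vectorized elastoplastic crown hinges for all rings of one stent."""

    def __init__(self, design: StentDesign, alloy: AlloyMaterial):
        self.design = design
        self.alloy = alloy
        p = design.peaks
        t, w = design.strut_thickness, design.strut_width
        self.n = design.rings
        self.p = p
        self.L = design.leg_length
        self.sinp = math.sin(math.pi / (2 * p))
        self.s0 = design.crown_height + design.link_gap  # tributary length
        self.hinge_len = 2.0 * t
        self.k_el = alloy.elastic_modulus * w * t**3 / 12.0 / self.hinge_len
        self.z_pl = w * t**2 / 4.0
        self.eps_per_rot = t / (2.0 * self.hinge_len)
        self.r0 = design.crimped_node_radius
        self.beta0 = math.asin(self._chord(self.r0) / self.L)
        # hardening lookup cached as plain arrays (hot path)
        self._hx = np.array([e for e, _ in alloy.hardening])
        self._hy = np.array([s for _, s in alloy.hardening])
        # state
        self.theta_pl = np.zeros(self.n)
        self.kappa = np.zeros(self.n)

    def _chord(self, r):
        return 2.0 * np.asarray(r) * self.sinp

    def h(self, r):
        c = self._chord(r)
        return np.sqrt(np.maximum(self.L**2 - c**2, 1e-12))

    def dtheta(self, r):
        """Crown opening rotation since crimp, per hinge (rad)."""
        c = np.minimum(self._chord(r), self.L * (1 - 1e-12))
        return 2.0 * (np.arcsin(c / self.L) - self.beta0)

    def _yield_moment(self, kappa):
        eps = kappa * self.eps_per_rot
        return self.z_pl * np.interp(eps, self._hx, self._hy)

    def trial_moment(self, r):
        """Return-mapped hinge moment at radius r (no state commit)."""
        dth = self.dtheta(r)
        m_tr = self.k_el * (dth - self.theta_pl)
        m_y = self._yield_moment(self.kappa)
        plastic = np.abs(m_tr) - m_y > 0
        if not np.any(plastic):
            return m_tr, np.zeros(self.n), np.zeros(self.n)
        # Newton on the consistency condition
        #   |m_tr| - k dpl = M_y(kappa + dpl)
        # (exact within two steps per piecewise-linear hardening segment)
        dpl = np.zeros(self.n)
        for _ in range(8):
            kap = self.kappa + dpl
            hard = (self._yield_moment(kap + 1e-9)
                    - self._yield_moment(kap)) / 1e-9
            res = np.abs(m_tr) - self.k_el * dpl - self._yield_moment(kap)
            dpl = np.where(plastic,
                           np.maximum(dpl + res / (self.k_el
                                                   + np.maximum(hard, 0.0)),
                                      0.0),
                           0.0)
            if np.max(np.abs(np.where(plastic, res, 0.0))) < 1e-12:
                break
        m = np.where(plastic,
                     np.sign(m_tr) * (np.abs(m_tr) - self.k_el * dpl),
                     m_tr)
        return m, np.sign(m_tr) * dpl, dpl

    def pressure(self, r):
        """Equivalent internal pressure (MPa) needed to hold radius r."""
        m, _, _ = self.trial_moment(r)
        dth_dr = 4.0 * self.sinp / self.h(r)
        return 2 * self.p * m * dth_dr / (2 * math.pi * np.asarray(r)
                                          * self.s0)

    def commit(self, r):
        _, signed_dpl, dpl = self.trial_moment(r)
        self.theta_pl = self.theta_pl + signed_dpl
        self.kappa = self.kappa + dpl

    def hinge_energy_increment(self, r_a, r_b):
        """Trapezoid increment of total hinge work between two radii."""
        m_a, _, _ = self.trial_moment(r_a)
        m_b, _, _ = self.trial_moment(r_b)
        return float(np.sum(2 * self.p * 0.5 * (m_a + m_b)
                            * (self.dtheta(r_b) - self.dtheta(r_a))))


# ---------------------------------------------------------------------------
# public hoop resistance
# ---------------------------------------------------------------------------

def stent_hoop_resistance(design: StentDesign,
                          alloy: AlloyMaterial | None = None,
                          inner_diameter: float | None = None,
                          n_steps: int = 200):
    """Equivalent external pressure (MPa) holding a stent at a diameter.

    Follows the virgin elastoplastic loading path from the crimped state to
    ``inner_diameter``, committing hinge plasticity along the way.  Zero at
    the crimped diameter; increases with crown count at equal strut
    dimensions (denser hinge pattern).
    """
    alloy = alloy or material_catalog("pt_cr")
    if inner_diameter is None:
        raise ValueError("inner_diameter is required")
    d_max = max_expansion_diameter(design)
    if not (design.crimped_inner_diameter - 1e-9 <= inner_diameter
            <= d_max - 1e-6):
        raise ValueError(
            f"diameter outside the kinematic range "
            f"[{design.crimped_inner_diameter}, {d_max:.3f}] mm")
    rings = _HingeRings(design, alloy)
    r_target = (inner_diameter + design.strut_thickness) / 2
    path = np.linspace(rings.r0, r_target, n_steps + 1)
    for r in path[1:]:
        rings.commit(np.full(rings.n, r))
    return float(rings.pressure(np.full(rings.n, r_target))[0])


# ---------------------------------------------------------------------------
# deployed state
# ---------------------------------------------------------------------------

@dataclass
class DeployedState:
    """Equilibrium configuration of a stent (free, in-vessel, or crimped)."""

    design: StentDesign
    config: SolverConfig
    lattice: StentLattice
    ring_z: np.ndarray               # deployed ring axial centers (mm)
    vessel_station: np.ndarray       # vessel station index per ring (or -1)
    r_center: np.ndarray             # strut centerline radius per ring (mm)
    contact_pressure: np.ndarray     # MPa per ring
    radial_force: np.ndarray         # N per ring (outward, on the wall)
    lumen_radius: np.ndarray         # wall position per ring (mm)
    theta_plastic: np.ndarray        # residual plastic hinge rotation (rad)
    kappa: np.ndarray
    residual: np.ndarray             # per-station net force residual (N)
    balloon_pressure: float          # MPa still applied (0 after recoil)
    vessel: VesselGeometry | None = None
    position_z: float = 0.0          # vessel z of the proximal stent edge
    deflated: bool = False

    @property
    def r_inner(self) -> np.ndarray:
        return self.r_center - self.design.strut_thickness / 2

    @property
    def r_outer(self) -> np.ndarray:
        return self.r_center + self.design.strut_thickness / 2

    @property
    def nominal_length(self) -> float:
        return self.design.crimped_length

    @property
    def deployed_length(self) -> float:
        return self.lattice.length

    def total_radial_force(self) -> float:
        return float(self.radial_force.sum())


def _ring_stations(vessel, design, position_z):
    lat0 = build_design(design)
    zc = lat0.ring_z() + position_z
    dz = vessel.z[1] - vessel.z[0]
    return np.clip(np.round(zc / dz).astype(int), 0, vessel.n_stations - 1)


class _WallResponse:
    """Per-ring wall reaction p(r_outer) of the pseudo-elastic wall.

    The curve of :class:`RadialResponse` (plaque plateau included) is
    followed in both loading and unloading — the diseased wall is treated
    as a nonlinearly elastic, plateau-softened medium, a standard
    simplification for plaque in deployment models.  The curve is
    state-independent, so it is precomputed on a radius grid per ring and
    solver iterations reduce to interpolation.
    """

    def __init__(self, vessel, design, position_z):
        self.stations = _ring_stations(vessel, design, position_z)
        rr = RadialResponse(vessel)
        grid_lo = design.crimped_inner_diameter / 2 * 0.8
        grid_hi = max_expansion_diameter(design) / 2 + 0.5
        self.rgrid = np.linspace(grid_lo, grid_hi, 400)
        r0grid = vessel.lumen_radius[self.stations]     # (n_rings, nt)
        n = len(self.stations)
        self.table = np.empty((n, len(self.rgrid)))
        for j, rg in enumerate(self.rgrid):
            u = np.maximum(rg - r0grid, 0.0)
            self.table[:, j] = rr._pressure(self.stations, u).mean(axis=1)

    def __call__(self, ring_idx, r_out):
        ring_idx = np.asarray(ring_idx, dtype=int)
        r_out = np.asarray(r_out, dtype=float)
        j = np.clip(np.searchsorted(self.rgrid, r_out) - 1, 0,
                    len(self.rgrid) - 2)
        w = (r_out - self.rgrid[j]) / (self.rgrid[j + 1] - self.rgrid[j])
        return self.table[ring_idx, j] * (1 - w) \
            + self.table[ring_idx, j + 1] * w


def _make_response(vessel, response, position_z, design):
    """Resolve the per-station wall reaction p(r_outer) and station map."""
    n_rings = design.rings
    if vessel is None:
        stations = np.full(n_rings, -1, dtype=int)
        if response is None:
            return (lambda st, r_out: np.zeros(len(st))), stations, None
        return response, stations, None
    if response is not None:
        return response, _ring_stations(vessel, design, position_z), None
    wall = _WallResponse(vessel, design, position_z)
    return wall, wall.stations, wall


def rigid_response(vessel: VesselGeometry, design: StentDesign,
                   position_z: float, stiffness: float = 1e6):
    """Wall reaction of a rigid vessel (infinite-stiffness limit)."""
    lat0 = build_design(design)
    zc = lat0.ring_z() + position_z
    dz = vessel.z[1] - vessel.z[0]
    stations = np.clip(np.round(zc / dz).astype(int), 0,
                       vessel.n_stations - 1)
    r_nat = vessel.lumen_radius[stations].mean(axis=1)

    def fn(ring_idx, r_out):
        ring_idx = np.asarray(ring_idx, dtype=int)
        return stiffness * np.maximum(
            np.asarray(r_out) - r_nat[ring_idx], 0.0)
    return fn


def _balloon_cap_radius(pressure, p_full, target_inner_diameter, balloon):
    """Balloon radius limit at a given pressure (semi-compliant membrane).

    The unpressurized balloon radius is chosen so that the membrane reaches
    the target radius exactly at full inflation pressure.
    """
    te = balloon.thickness * balloon.elastic_modulus
    r_t = target_inner_diameter / 2
    r_n = r_t / (1 + r_t * p_full / te)
    denom = 1.0 - r_n * pressure / te
    return r_n / max(denom, 1e-6)


def _solve_stations(hinges, response_ring, r_prev, p_balloon, r_cap,
                    tol_force, max_iter):
    """Per-station bisection for f(r) = P - p_v(r_out) - p_s(r) = 0.

    The root is capped at the balloon radius; the residual at capped
    stations is carried by the balloon membrane and reported as zero.
    """
    t_half = hinges.design.strut_thickness / 2
    ring_idx = np.arange(hinges.n)

    def f(r):
        return (p_balloon - response_ring(ring_idx, r + t_half)
                - hinges.pressure(r))

    lo = np.full(hinges.n, hinges.r0 * 0.999)
    hi = np.full(hinges.n, min(r_cap, (max_expansion_diameter(hinges.design)
                                       + hinges.design.strut_thickness) / 2
                               - 1e-4))
    hi = np.maximum(hi, lo + 1e-12)
    f_hi = f(hi)
    capped = f_hi >= 0.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        pos = f(mid) > 0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    r = np.where(capped, hi, 0.5 * (lo + hi))
    area = 2 * math.pi * r * hinges.s0
    resid = np.where(capped, 0.0, np.abs(f(r)) * area)
    return r, resid


def _deploy(design, vessel, config, target_inner_diameter, position_z,
            response, deflate, alloy=None):
    alloy = alloy or material_catalog("pt_cr")
    hinges = _HingeRings(design, alloy)
    resp, stations, _ = _make_response(vessel, response, position_z, design)

    p_full = config.inflation_pressure_atm * ATM
    r = np.full(hinges.n, hinges.r0)
    resid = np.zeros(hinges.n)
    for p_b in np.linspace(0.0, p_full, config.n_inflation_steps + 1)[1:]:
        r_cap = (_balloon_cap_radius(p_b, p_full, target_inner_diameter,
                                     config.balloon)
                 + design.strut_thickness / 2)
        r, resid = _solve_stations(hinges, resp, r, p_b, r_cap,
                                   config.tolerance, config.max_iterations)
        hinges.commit(r)
    p_final = p_full
    if deflate:
        # the deflating balloon only releases pressure: no radius cap, and
        # no station may expand during deflation
        for p_b in np.linspace(p_full, 0.0,
                               config.n_deflation_steps + 1)[1:]:
            r_new, resid = _solve_stations(hinges, resp, r, p_b, np.inf,
                                           config.tolerance,
                                           config.max_iterations)
            r = np.minimum(r_new, r)
            hinges.commit(r)
        p_final = 0.0

    return _finalize(design, config, hinges, resp, stations, vessel, r,
                     resid, p_final, position_z, deflated=deflate)


def _finalize(design, config, hinges, resp, stations, vessel, r, resid,
              p_balloon, position_z, deflated):
    ring_idx = np.arange(hinges.n)
    r_out = r + design.strut_thickness / 2
    p_c = resp(ring_idx, r_out)
    force = p_c * 2 * math.pi * r_out * hinges.s0
    if vessel is not None:
        r_nat = vessel.lumen_radius[stations].mean(axis=1)
        lumen = np.where(p_c > 0, r_out, r_nat)
    else:
        lumen = r_out.copy()
    target = np.maximum(2 * r - design.strut_thickness,
                        design.crimped_inner_diameter)
    lat = expand_kinematics(build_design(design), design, target)
    state = DeployedState(
        design=design, config=config, lattice=lat, ring_z=lat.ring_z(),
        vessel_station=stations, r_center=r.copy(),
        contact_pressure=p_c, radial_force=force, lumen_radius=lumen,
        theta_plastic=hinges.theta_pl.copy(), kappa=hinges.kappa.copy(),
        residual=resid, balloon_pressure=float(p_balloon), vessel=vessel,
        position_z=position_z, deflated=deflated)
    state._hinges = hinges  # carried for recoil / crimp continuation
    state._response = resp
    return state


def expand_stent(design: StentDesign,
                 vessel: VesselGeometry | None,
                 config: SolverConfig | None = None,
                 target_inner_diameter: float = 4.5,
                 position_z: float | None = None,
                 response=None,
                 deflate: bool = True,
                 alloy: AlloyMaterial | None = None) -> DeployedState:
    """Balloon-driven expansion (and, by default, deflation/recoil).

    The stent is centered on the stenosis unless ``position_z`` (vessel z of
    the proximal stent edge) is given.  ``response`` overrides the wall law
    (callable ``(ring_indices, r_outer) -> MPa``), e.g. for rigid-vessel
    limit studies.  With ``deflate=False`` the returned state is the peak
    (pre-deflation) configuration suitable for :func:`recoil`.
    """
    config = config or SolverConfig()
    if position_z is None:
        if vessel is not None:
            position_z = (vessel.params.stenosis_center_z
                          - design.crimped_length / 2)
        else:
            position_z = 0.0
    if vessel is not None:
        if position_z < 0 or (position_z + design.crimped_length
                              > vessel.params.length):
            raise ValueError("stent does not fit inside the vessel")
    return _deploy(design, vessel, config, target_inner_diameter,
                   position_z, response, deflate, alloy)


def free_expand(design: StentDesign, target_inner_diameter: float,
                config: SolverConfig | None = None,
                deflate: bool = True) -> DeployedState:
    """Expansion without a vessel (bench free expansion)."""
    return expand_stent(design, None, config,
                        target_inner_diameter=target_inner_diameter,
                        deflate=deflate)


def recoil(state: DeployedState,
           vessel: VesselGeometry | None = None) -> DeployedState:
    """Deflate the balloon from a peak-pressure state and re-equilibrate.

    Radii are non-increasing at every station and contact forces stay
    non-negative (no adhesion).
    """
    if state.deflated:
        raise ValueError("state is already deflated")
    hinges = state._hinges
    resp = state._response
    config = state.config
    p_full = state.balloon_pressure
    r = state.r_center.copy()
    resid = state.residual
    for p_b in np.linspace(p_full, 0.0, config.n_deflation_steps + 1)[1:]:
        r_new, resid = _solve_stations(hinges, resp, r, p_b, np.inf,
                                       config.tolerance,
                                       config.max_iterations)
        r = np.minimum(r_new, r)  # deflation cannot expand a station
        hinges.commit(r)
    return _finalize(state.design, config, hinges, resp,
                     state.vessel_station, vessel or state.vessel, r, resid,
                     0.0, state.position_z, deflated=True)


# ---------------------------------------------------------------------------
# radial crimp
# ---------------------------------------------------------------------------

@dataclass
class CrimpResult:
    """Force-diameter record of a radial crimp (bench hoop-force protocol).

    ``curve`` rows are (outer diameter mm, total radial force N) with
    strictly decreasing diameters; ``max_hoop_force`` is max force / 2 pi.
    """

    curve: np.ndarray
    reduction: float
    design_name: str = ""

    @property
    def max_radial_force(self) -> float:
        return float(self.curve[:, 1].max())

    @property
    def max_hoop_force(self) -> float:
        return self.max_radial_force / (2 * math.pi)


def radial_crimp(state: DeployedState, reduction: float = 0.15,
                 n_steps: int = 60) -> CrimpResult:
    """Uniform radial compression of an expanded stent.

    Displacement-controlled: the outer diameter is stepped down to
    ``(1 - reduction)`` of its starting value; at each step the recorded
    total radial force is the external holding pressure times the lateral
    stent surface.  The hoop force is total radial force / 2 pi, per the
    radial-force-gauge convention.
    """
    if not (0.0 < reduction <= 0.5):
        raise ValueError("reduction fraction must be in (0, 0.5]")
    hinges = state._hinges
    t = state.design.strut_thickness
    r_start = float(state.r_center.mean())
    d0_outer = 2 * r_start + t
    d_target = (1.0 - reduction) * d0_outer
    rows = []
    length = state.deployed_length
    for d_out in np.linspace(d0_outer, d_target, n_steps + 1):
        r = np.full(hinges.n, (d_out - t) / 2)
        q = np.maximum(-hinges.pressure(r), 0.0)  # holding pressure
        force = float(np.sum(q * math.pi * d_out * hinges.s0))
        rows.append((d_out, force))
        hinges.commit(r)
    curve = np.array(rows)
    return CrimpResult(curve=curve, reduction=reduction,
                       design_name=state.design.name)
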