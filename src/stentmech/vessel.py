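"""Seeded generator of left-main-bifurcation-like vessel geometries.

This module stands in for imaging-derived patient anatomies: it generates a
bifurcating tube (main branch = LM into LAD, side branch = LCX-like) with a
tapering lumen, a mid-segment stenosis of prescribed area reduction, a
normal-wall layer 0.1-0.25 mm thick, and a plaque layer whose thickness is
the gap between the stenosed lumen and the healthy reference profile.
Plaque stiffness can be assigned homogeneously (one of the five catalog
categories over the whole diseased extent) or heterogeneously: per-station
plaque morphometrics in the style of intracoronary OCT (lipid / calcium /
fibrosis arcs, cap thickness, eccentricity, necrotic core) are sampled on a
coarse grid, interpolated to the fine station grid, segmented into
contiguous zones of similar morphometry, and each zone is mapped to a
stiffness category by compositional dominance (lipid-dominant -> soft side,
calcium-dominant -> stiff side, shifted by plaque thickness).

Stations are axial samples every 0.2 mm (OCT-like frame spacing);
morphometrics are sampled every 10th station and interpolated, mimicking
frame-subsampled image analysis.  All sampling is driven by a single seed
and is bitwise reproducible.

The solver-facing quantity is :func:`radial_response`: the quasi-static
pressure with which the composite wall resists an outward radial
displacement of the lumen at one station.  Each circumferential sector is a
thin-walled layered shell: every layer contributes its nominal hoop stress
(at the local circumferential stretch) times thickness over the current
radius (Laplace), plaque with its plastic plateau, the normal layer
hyperelastically; sectors without wall (side-branch ostium) contribute
nothing.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .materials import (PLAQUE_CATEGORIES, HyperelasticModel,
                        PlaqueMaterial, material_catalog)

__all__ = [
    "VesselParams",
    "PlaqueZone",
    "VesselGeometry",
    "generate_bifurcation",
    "assign_homogeneous_plaque",
    "assign_heterogeneous_plaque",
    "radial_response",
    "zone_map_csv",
    "vessel_to_mesh",
]

STATION_SPACING = 0.2   # mm, OCT-like frame spacing
N_THETA = 64            # circumferential sectors


@dataclass(frozen=True)
class VesselParams:
    """Generator parameters; defaults emulate a diseased LM/LAD crossover.

    Diameters in mm.  ``stenosis_severity`` is the fractional area reduction
    of the minimal lumen relative to the local healthy reference (0-0.9).
    """

    proximal_diameter: float = 4.6
    distal_diameter: float = 3.6
    side_branch_diameter: float = 3.0
    length: float = 36.0
    bifurcation_z: float = 12.0
    side_branch_angle_deg: float = 60.0
    stenosis_severity: float = 0.55
    stenosis_center_z: float = 18.0
    stenosis_width: float = 4.0
    eccentricity: float = 0.5           # plaque eccentricity (0 concentric)
    wall_thickness_mean: float = 0.18   # normal layer, mm
    wall_thickness_ripple: float = 0.03
    curvature_amplitude: float = 1.0    # centerline bow, mm

    def __post_init__(self):
        if not (0.0 <= self.stenosis_severity <= 0.9):
            raise ValueError("stenosis severity must be in [0, 0.9]")
        if self.proximal_diameter < self.distal_diameter:
            raise ValueError("proximal diameter must be >= distal diameter")
        lo = self.wall_thickness_mean - self.wall_thickness_ripple
        hi = self.wall_thickness_mean + self.wall_thickness_ripple
        if lo < 0.1 or hi > 0.25:
            raise ValueError(
                "normal wall thickness must stay within [0.1, 0.25] mm")


@dataclass
class PlaqueZone:
    """A contiguous axial/circumferential plaque zone with morphometrics."""

    zone_id: int
    station_range: tuple[int, int]        # [start, stop) station indices
    theta_arc: tuple[float, float] = (0.0, 360.0)  # degrees
    plaque_thickness: float = 0.0         # mm, zone mean
    eccentricity: float = 0.0
    lipid_arc: float = 0.0                # degrees
    calcium_arc: float = 0.0
    fibrosis_arc: float = 0.0
    cap_thickness: float = 0.0            # mm
    necrotic_core: bool = False
    category: str = "neutral"

    def __post_init__(self):
        for arc in (self.lipid_arc, self.calcium_arc, self.fibrosis_arc):
            if not (0.0 <= arc <= 360.0):
                raise ValueError("arcs must be within [0, 360] degrees")
        if self.plaque_thickness < 0:
            raise ValueError("plaque thickness must be non-negative")
        if self.category not in PLAQUE_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class VesselGeometry:
    """Synthetic bifurcation lumen/wall on a station x theta grid."""

    params: VesselParams
    seed: int
    z: np.ndarray                   # (nz,) station axial positions
    theta: np.ndarray               # (nt,) sector centers, radians
    lumen_radius: np.ndarray        # (nz, nt) mm
    reference_radius: np.ndarray    # (nz,) healthy taper profile, mm
    wall_thickness: np.ndarray      # (nz,) normal layer, mm
    plaque_thickness: np.ndarray    # (nz, nt) mm
    ostium_mask: np.ndarray         # (nz, nt) True where wall is absent
    main_centerline: np.ndarray     # (nz, 3)
    side_centerline: np.ndarray     # (ns, 3)
    zones: list[PlaqueZone] = field(default_factory=list)
    zone_id: np.ndarray | None = None   # (nz, nt) int, -1 = no plaque zone

    @property
    def n_stations(self) -> int:
        return len(self.z)

    @property
    def proximal_reference_diameter(self) -> float:
        """Mean lumen diameter of the proximal (pre-bifurcation) segment."""
        prox = self.z < self.params.bifurcation_z
        return float(2.0 * self.lumen_radius[prox].mean())

    def mean_lumen_radius(self) -> np.ndarray:
        return self.lumen_radius.mean(axis=1)

    def lumen_area(self) -> np.ndarray:
        """Cross-sectional lumen area per station (polar integral)."""
        return 0.5 * np.trapezoid(
            np.column_stack([self.lumen_radius, self.lumen_radius[:, :1]])**2,
            np.append(self.theta, self.theta[0] + 2 * math.pi), axis=1)

    def diseased(self) -> np.ndarray:
        """Stations carrying a plaque layer thicker than 0.05 mm."""
        return self.plaque_thickness.max(axis=1) > 0.05


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_bifurcation(params: VesselParams | None = None,
                         seed: int = 0) -> VesselGeometry:
    """Generate a seeded LM-like bifurcation geometry.

    The healthy reference is a linear taper from the proximal to the distal
    radius; the stenosis multiplies the lumen area by a Gaussian dip whose
    trough equals ``1 - severity`` exactly.  Plaque thickness is the radial
    gap between reference and stenosed lumen, distributed eccentrically
    around the circumference; the side-branch ostium removes the wall over
    the branch arc at the bifurcation stations.
    """
    p = params or VesselParams()
    rng = np.random.default_rng(seed)

    nz = int(round(p.length / STATION_SPACING)) + 1
    z = np.linspace(0.0, p.length, nz)
    theta = (np.arange(N_THETA) + 0.5) * (2 * math.pi / N_THETA)

    r_prox, r_dist = p.proximal_diameter / 2, p.distal_diameter / 2
    ref = r_prox + (r_dist - r_prox) * z / p.length

    dip = p.stenosis_severity * np.exp(
        -((z - p.stenosis_center_z) / p.stenosis_width) ** 2)
    area_scale = 1.0 - dip
    r_mean = ref * np.sqrt(area_scale)

    # eccentric lumen: stenosed lumen center shifts toward theta = 0, which
    # piles the plaque on one side; the radius function keeps the prescribed
    # cross-sectional area (offset circle in polar form, first order).
    gap = ref - r_mean
    offset = p.eccentricity * gap
    # r(theta) = R + e cos(theta) has area pi (R^2 + e^2/2); shrink R so the
    # prescribed stenosed area is met exactly despite the eccentric offset
    r_base = np.sqrt(np.maximum(r_mean**2 - offset**2 / 2.0, 1e-6))
    lumen = r_base[:, None] + offset[:, None] * np.cos(theta)[None, :]

    plaque = np.maximum(ref[:, None] - lumen, 0.0)
    plaque[plaque < 1e-9] = 0.0

    wall = (p.wall_thickness_mean
            + p.wall_thickness_ripple
            * np.sin(2 * math.pi * z / p.length * (1 + rng.uniform(0, 2))
                     + rng.uniform(0, 2 * math.pi)))
    if wall.min() < 0.1 - 1e-12 or wall.max() > 0.25 + 1e-12:
        raise ValueError("generated wall thickness left the [0.1, 0.25] mm "
                         "normal-layer band")

    # side-branch ostium: wall absent over the branch arc near the carina
    ost = np.zeros((nz, N_THETA), dtype=bool)
    half_arc = math.asin(min(0.95, (p.side_branch_diameter / 2)
                             / np.interp(p.bifurcation_z, z, ref)))
    z_half = p.side_branch_diameter / 2
    sel_z = np.abs(z - p.bifurcation_z) < z_half
    sel_t = np.abs((theta - math.pi + math.pi) % (2 * math.pi)
                   - math.pi - 0.0) < half_arc  # arc centered at theta = pi
    sel_t = np.abs(theta - math.pi) < half_arc
    ost[np.ix_(sel_z, sel_t)] = True

    # centerlines: gentle in-plane bow for the main branch; straight side
    bow = p.curvature_amplitude * np.sin(math.pi * z / p.length)
    main_cl = np.column_stack([bow, np.zeros_like(z), z])
    ang = math.radians(p.side_branch_angle_deg)
    s = np.linspace(0.0, 8.0, 41)
    origin = main_cl[np.argmin(np.abs(z - p.bifurcation_z))]
    side_cl = origin + np.column_stack([
        -np.sin(ang) * s, np.zeros_like(s), np.cos(ang) * s])

    return VesselGeometry(params=p, seed=seed, z=z, theta=theta,
                          lumen_radius=lumen, reference_radius=ref,
                          wall_thickness=wall, plaque_thickness=plaque,
                          ostium_mask=ost, main_centerline=main_cl,
                          side_centerline=side_cl)


# ---------------------------------------------------------------------------
# plaque material assignment
# ---------------------------------------------------------------------------

def _diseased_runs(vessel: VesselGeometry) -> list[tuple[int, int]]:
    """Contiguous [start, stop) station runs of the diseased extent."""
    mask = vessel.diseased()
    runs, start = [], None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def assign_homogeneous_plaque(vessel: VesselGeometry,
                              category: str) -> VesselGeometry:
    """One plaque zone of a single stiffness category over the whole
    diseased extent; the normal layer keeps the normal-wall material."""
    if category not in PLAQUE_CATEGORIES:
        raise ValueError(f"unknown plaque category {category!r}")
    out = replace(vessel, zones=[], zone_id=np.full(
        vessel.plaque_thickness.shape, -1, dtype=int))
    zid = 0
    for start, stop in _diseased_runs(vessel):
        thick = vessel.plaque_thickness[start:stop]
        zone = PlaqueZone(
            zone_id=zid, station_range=(start, stop),
            plaque_thickness=float(thick[thick > 0].mean()),
            eccentricity=vessel.params.eccentricity, category=category)
        out.zones.append(zone)
        sel = vessel.plaque_thickness[start:stop] > 0
        out.zone_id[start:stop][sel] = zid
        zid += 1
    return out


# morphometric-distance weights (thickness mm, lipid arc deg, calcium arc
# deg); arcs are scaled to the unit interval before weighting
_SIM_WEIGHTS = np.array([2.0, 1.0, 1.0])
_SIM_THRESHOLD = 0.35


def assign_heterogeneous_plaque(vessel: VesselGeometry,
                                seed: int | None = None,
                                n_categories: int = 5,
                                coarse_every: int = 10) -> VesselGeometry:
    """OCT-style heterogeneous plaque zoning.

    Morphometrics are sampled on every ``coarse_every``-th diseased station
    (lipid/fibrosis/calcium arc fractions from a Dirichlet draw whose
    concentration leans lipid/fibrous, as is typical of LM disease;
    cap thickness and necrotic-core flags alongside), linearly interpolated
    to all stations, then greedily segmented into contiguous zones: a
    station opens a new zone when its weighted morphometric distance to the
    running zone mean exceeds a documented threshold.  Each zone's category
    is the compositional dominance (calcium vs lipid arc) shifted by plaque
    thickness, mapped onto the ``n_categories``-step stiffness scale.
    """
    rng = np.random.default_rng(vessel.seed + 1 if seed is None else seed)
    out = replace(vessel, zones=[], zone_id=np.full(
        vessel.plaque_thickness.shape, -1, dtype=int))
    zid = 0
    for start, stop in _diseased_runs(vessel):
        idx = np.arange(start, stop)
        thick = vessel.plaque_thickness[start:stop].max(axis=1)
        total_arc = 360.0 * (vessel.plaque_thickness[start:stop] > 0
                             ).mean(axis=1)
        coarse = idx[::coarse_every]
        if coarse[-1] != idx[-1]:
            coarse = np.append(coarse, idx[-1])
        fracs = rng.dirichlet((4.0, 4.0, 1.5), size=len(coarse))  # L, F, Ca
        caps = rng.uniform(0.05, 0.25, size=len(coarse))
        cores = rng.random(len(coarse)) < 0.3
        lipid = np.interp(idx, coarse, fracs[:, 0]) * total_arc
        fibro = np.interp(idx, coarse, fracs[:, 1]) * total_arc
        calc = np.interp(idx, coarse, fracs[:, 2]) * total_arc
        cap = np.interp(idx, coarse, caps)

        feats = np.column_stack([thick, lipid / 360.0, calc / 360.0])
        breaks = [0]
        acc, n_acc = feats[0].copy(), 1
        for i in range(1, len(idx)):
            d = np.abs(feats[i] - acc / n_acc) @ _SIM_WEIGHTS
            if d > _SIM_THRESHOLD:
                breaks.append(i)
                acc, n_acc = feats[i].copy(), 1
            else:
                acc += feats[i]
                n_acc += 1
        breaks.append(len(idx))

        for a, b in zip(breaks, breaks[1:]):
            seg = slice(a, b)
            cat = _dominance_category(
                lipid[seg].mean(), calc[seg].mean(), fibro[seg].mean(),
                thick[seg].mean(), n_categories)
            zone = PlaqueZone(
                zone_id=zid, station_range=(start + a, start + b),
                plaque_thickness=float(thick[seg].mean()),
                eccentricity=vessel.params.eccentricity,
                lipid_arc=float(lipid[seg].mean()),
                calcium_arc=float(calc[seg].mean()),
                fibrosis_arc=float(fibro[seg].mean()),
                cap_thickness=float(cap[seg].mean()),
                necrotic_core=bool(cores[min(a // coarse_every,
                                             len(cores) - 1)]),
                category=cat)
            out.zones.append(zone)
            sel = vessel.plaque_thickness[start + a:start + b] > 0
            out.zone_id[start + a:start + b][sel] = zid
            zid += 1
    return out


def _dominance_category(lipid: float, calc: float, fibro: float,
                        thick: float, n_categories: int = 5) -> str:
    """Map zone composition to a stiffness category.

    Score in [-1, 1]: calcium-dominant positive, lipid-dominant negative,
    fibrosis neutral; thick soft plaque shifts down, thick calcific up.
    """
    total = max(lipid + calc + fibro, 1e-9)
    score = (calc - lipid) / total
    score += 0.2 * math.copysign(min(thick / 1.0, 1.0), score)
    score = min(max(score, -1.0), 1.0)
    scale = [PLAQUE_CATEGORIES[round(k * (len(PLAQUE_CATEGORIES) - 1)
                                     / (n_categories - 1))]
             for k in range(n_categories)]
    k = round((score + 1.0) / 2.0 * (n_categories - 1))
    return scale[k]


# ---------------------------------------------------------------------------
# radial response
# ---------------------------------------------------------------------------

def _category_grid(vessel: VesselGeometry) -> np.ndarray:
    """Per-(station, theta) plaque category index, -1 where no plaque."""
    grid = np.full(vessel.plaque_thickness.shape, -1, dtype=int)
    if vessel.zone_id is None:
        return grid
    cat_of_zone = {z.zone_id: PLAQUE_CATEGORIES.index(z.category)
                   for z in vessel.zones}
    for zid, ci in cat_of_zone.items():
        grid[vessel.zone_id == zid] = ci
    return grid


class RadialResponse:
    """Vectorized per-station pressure-displacement law of the wall.

    Precomputes the layer stack per (station, sector); calling the object
    with per-station outward displacements returns the mean resisting
    pressure per station in MPa.  Sectors under the side-branch ostium have
    no wall and contribute zero.
    """

    def __init__(self, vessel: VesselGeometry):
        self.vessel = vessel
        self.r0 = vessel.lumen_radius            # (nz, nt)
        self.t_wall = np.broadcast_to(
            vessel.wall_thickness[:, None], self.r0.shape)
        self.t_plaque = vessel.plaque_thickness
        self.has_wall = ~vessel.ostium_mask
        self.cat = _category_grid(vessel)
        self.wall_model: HyperelasticModel = material_catalog("normal_wall")
        self.plaques = [material_catalog(c) for c in PLAQUE_CATEGORIES]
        # plaque with no zone assignment defaults to neutral
        self.cat = np.where((self.t_plaque > 0) & (self.cat < 0),
                            PLAQUE_CATEGORIES.index("neutral"), self.cat)

    def __call__(self, stations: np.ndarray, u: np.ndarray) -> np.ndarray:
        """Mean resisting pressure (MPa) at ``stations`` for a uniform
        outward sector displacement ``u`` (mm per station, clipped at 0)."""
        stations = np.asarray(stations, dtype=int)
        u = np.maximum(np.asarray(u, dtype=float), 0.0)[:, None]
        grid = np.broadcast_to(u, (len(stations), len(self.vessel.theta)))
        return self._pressure(stations, grid).mean(axis=1)

    def at_radius(self, stations: np.ndarray, r_out: np.ndarray
                  ) -> np.ndarray:
        """Mean pressure when the wall is pushed to radius ``r_out``:
        each sector is displaced by max(0, r_out - natural radius)."""
        stations = np.asarray(stations, dtype=int)
        r_out = np.asarray(r_out, dtype=float)[:, None]
        u = np.maximum(r_out - self.r0[stations], 0.0)
        return self._pressure(stations, u).mean(axis=1)

    def _pressure(self, stations: np.ndarray, u: np.ndarray) -> np.ndarray:
        """Per-sector resisting pressure (MPa); ``u`` is (ns, nt) >= 0."""
        u = np.maximum(u, 0.0)
        r0 = self.r0[stations]
        lam = (r0 + u) / r0
        strain = np.maximum(lam - 1.0, 0.0)
        r_cur = r0 + u
        press = np.zeros_like(r0)

        sw = self.wall_model.uniaxial_stress(np.maximum(lam, 1.0))
        press += sw * self.t_wall[stations] / r_cur

        tp = self.t_plaque[stations]
        cat = self.cat[stations]
        for ci, mat in enumerate(self.plaques):
            sel = cat == ci
            if not sel.any():
                continue
            sp = mat.stress(strain * sel)
            press += np.where(sel, sp * tp / r_cur, 0.0)

        press = np.where(self.has_wall[stations], press, 0.0)
        press = np.where(u > 0, press, 0.0)
        return press

    def tangent(self, stations, u, h: float = 1e-5) -> np.ndarray:
        up = self(stations, np.asarray(u) + h)
        dn = self(stations, np.maximum(np.asarray(u) - h, 0.0))
        return (up - dn) / (h + np.minimum(np.asarray(u), h))


def radial_response(vessel: VesselGeometry, station: int,
                    displacement: float) -> float:
    """Resisting pressure (MPa) of the wall at one station for an outward
    lumen displacement (mm).  Monotone non-decreasing, zero at zero."""
    if displacement < 0:
        raise ValueError("displacement must be outward (>= 0)")
    if not (0 <= station < vessel.n_stations):
        raise IndexError(f"station {station} outside vessel")
    rr = RadialResponse(vessel)
    return float(rr(np.array([station]), np.array([displacement]))[0])


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def zone_map_csv(vessel: VesselGeometry) -> str:
    """Zone table as CSV (station range, arc, category, morphometrics)."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["zone_id", "station_start", "station_stop", "theta_start_deg",
                "theta_end_deg", "category", "plaque_thickness_mm",
                "eccentricity", "lipid_arc_deg", "calcium_arc_deg",
                "fibrosis_arc_deg", "cap_thickness_mm", "necrotic_core"])
    for zn in vessel.zones:
        w.writerow([zn.zone_id, zn.station_range[0], zn.station_range[1],
                    f"{zn.theta_arc[0]:.1f}", f"{zn.theta_arc[1]:.1f}",
                    zn.category, f"{zn.plaque_thickness:.4f}",
                    f"{zn.eccentricity:.3f}", f"{zn.lipid_arc:.1f}",
                    f"{zn.calcium_arc:.1f}", f"{zn.fibrosis_arc:.1f}",
                    f"{zn.cap_thickness:.4f}", int(zn.necrotic_core)])
    return buf.getvalue()


def vessel_to_mesh(vessel: VesselGeometry):
    """Lumen surface as a trimesh mesh (stations x sectors grid)."""
    import trimesh
    nz, nt = vessel.lumen_radius.shape
    th = vessel.theta
    verts = np.empty((nz * nt, 3))
    for i in range(nz):
        r = vessel.lumen_radius[i]
        verts[i * nt:(i + 1) * nt] = np.column_stack([
            r * np.cos(th), r * np.sin(th),
            np.full(nt, vessel.z[i])])
    faces = []
    for i in range(nz - 1):
        for j in range(nt):
            a = i * nt + j
            b = i * nt + (j + 1) % nt
            faces.append([a, b, a + nt])
            faces.append([b, b + nt, a + nt])
    return trimesh.Trimesh(vertices=verts, faces=np.array(faces),
                           process=False)
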