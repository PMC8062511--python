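"""Stent performance metrics computed from a deployed state.

The five comparison metrics:

* **MSD** — mean inner stent diameter over stations (mm).
* **CCD** (circular cell diameter) — mean over stent cells of the largest
  circle inscribable in the deployed cell; smaller CCD means denser strut
  coverage (better vessel scaffolding).  Each cell is unrolled onto the
  plane of its mean-radius cylinder (cells are shallow relative to the
  cylinder at 3.5-5.0 mm), and the inscribed circle is found against the
  strut *edges*: pole-of-inaccessibility distance to the centerline loop
  minus half the strut width.
* **Prolapse** — per cross-section, the radial distance from the lumen
  centroid to the maximum inward wall protrusion minus the mean radial
  distance to the strut outer surfaces; the state-level value defaults to
  the maximum over sections (clinically conservative), with the mean also
  reported.  Tissue sag between struts follows a membrane law: a cell in
  contact at pressure p_c with wall Laplace tension T sags by
  d = p_c a^2 / (2 max(T, T0)), a the inscribed radius, T = p_c r, and T0
  a physiologic baseline tension (mean arterial pressure times the natural
  radius) that governs when contact is light.
* **SAR** — strut outer surface area as a percentage of the lumen surface
  over the stented segment.
* **Hoop force / radial strength** — hoop force is total outward radial
  force / 2 pi; normalized hoop force divides by the nominal stent length
  (N/mm); radial strength divides the total radial force by the strut
  outer surface area (N/mm^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon
from shapely.ops import polylabel

from .lattice import cell_polygons, strut_outer_surface_area, unroll_loop
from .solver import CrimpResult, DeployedState

__all__ = [
    "MetricsReport",
    "mean_stent_diameter",
    "circular_cell_diameter",
    "vessel_prolapse",
    "stent_artery_ratio",
    "normalized_hoop_force",
    "radial_strength",
    "compute_metrics",
    "percentage_difference",
    "inscribed_circle_diameter",
    "cell_details",
]

PHYSIO_PRESSURE = 0.0133  # MPa, ~100 mmHg mean arterial pressure


# ---------------------------------------------------------------------------
# expansion
# ---------------------------------------------------------------------------

def mean_stent_diameter(state: DeployedState) -> float:
    """MSD: mean over stations of twice the inner stent radius (mm)."""
    if len(state.r_center) == 0:
        raise ValueError("empty deployed state")
    return float(2.0 * state.r_inner.mean())


def percentage_difference(value: float, reference: float) -> float:
    """(value - reference) / reference x 100, the design-comparison form."""
    return (value - reference) / reference * 100.0


# ---------------------------------------------------------------------------
# scaffolding
# ---------------------------------------------------------------------------

def inscribed_circle_diameter(points: np.ndarray,
                              tolerance: float = 1e-4) -> float:
    """Largest inscribed circle diameter of a planar polygon.

    Uses the pole of inaccessibility (the interior point maximizing the
    distance to the boundary) at the given tolerance in mm.
    """
    poly = Polygon(points)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("degenerate cell polygon")
    pole = polylabel(poly, tolerance=tolerance)
    return 2.0 * poly.exterior.distance(pole)


def cell_details(state: DeployedState, include_ostium: bool = False):
    """Per-cell geometry of a deployed lattice.

    Returns a list of dicts with the unrolled polygon, inscribed-circle
    diameter against the strut edges, mean radius, axial span and the
    adjacent ring indices.  Degenerate (self-intersecting) cells are
    excluded and counted in the companion integer.
    """
    lat = state.lattice
    loops = cell_polygons(lat)
    w = state.design.strut_width
    out, degenerate = [], 0
    for loop in loops:
        pts = unroll_loop(lat, loop)
        try:
            d_center = inscribed_circle_diameter(pts)
        except ValueError:
            degenerate += 1
            continue
        d_open = max(d_center - w, 0.0)
        rings = np.unique(lat.ring[list(loop)])
        zc = float(lat.z[list(loop)].mean())
        if not include_ostium and _over_ostium(state, zc):
            continue
        out.append({"loop": loop, "points": pts, "ccd": d_open,
                    "r_mean": float(lat.r[list(loop)].mean()),
                    "z_center": zc,
                    "z_min": float(lat.z[list(loop)].min()),
                    "z_max": float(lat.z[list(loop)].max()),
                    "rings": rings})
    return out, degenerate


def _over_ostium(state: DeployedState, z_local: float) -> bool:
    v = state.vessel
    if v is None:
        return False
    z_vessel = state.position_z + z_local
    half = v.params.side_branch_diameter / 2
    return abs(z_vessel - v.params.bifurcation_z) < half


def circular_cell_diameter(state: DeployedState,
                           include_ostium: bool = False) -> float:
    """CCD: mean largest-inscribed-circle diameter over deployed cells."""
    cells, _ = cell_details(state, include_ostium=include_ostium)
    if not cells:
        raise ValueError("deployed state has no cells")
    return float(np.mean([c["ccd"] for c in cells]))


# ---------------------------------------------------------------------------
# prolapse
# ---------------------------------------------------------------------------

def _cell_sag(state: DeployedState, cell) -> float:
    """Membrane sag depth of the wall into one cell (mm)."""
    v = state.vessel
    rings = cell["rings"]
    p_c = float(state.contact_pressure[rings].mean())
    if p_c <= 0 or v is None:
        return 0.0
    a = cell["ccd"] / 2.0
    r_out = float(state.r_outer[rings].mean())
    stations = state.vessel_station[rings]
    r_nat = float(v.lumen_radius[stations].mean())
    t_laplace = p_c * r_out
    t0 = PHYSIO_PRESSURE * r_nat
    sag = p_c * a**2 / (2.0 * max(t_laplace, t0))
    # the wall cannot relax past its natural position
    return float(min(sag, max(r_out - r_nat, 0.0)))


def vessel_prolapse(state: DeployedState, aggregate: str = "max",
                    n_sections: int = 80) -> float:
    """Tissue protrusion between struts (mm).

    Per section: (mean strut outer radius deficit from the lumen centroid)
    minus (minimum wall radius), i.e. the deepest local sag of the wall
    into the stent cells, sampled on ``n_sections`` cross-sections along
    the stented segment; sag follows a spherical-cap profile across each
    cell.  ``aggregate`` selects the per-state reduction: "max" (default,
    clinically conservative) or "mean".
    """
    if state.vessel is None and getattr(state, "wall_sag_override",
                                        None) is None:
        raise ValueError("state has no vessel wall to sag (missing "
                         "wall-sag field)")
    override = getattr(state, "wall_sag_override", None)
    cells, _ = cell_details(state)
    lat = state.lattice
    z_lo, z_hi = lat.z.min(), lat.z.max()
    zs = np.linspace(z_lo, z_hi, n_sections)
    prol = np.zeros(n_sections)
    for cell in cells:
        sag = (_cell_sag(state, cell) if override is None
               else override(cell))
        if sag <= 0:
            continue
        zc = cell["z_center"]
        half = max((cell["z_max"] - cell["z_min"]) / 2.0, 1e-9)
        sel = np.abs(zs - zc) < half
        profile = sag * np.sqrt(np.maximum(
            1.0 - ((zs[sel] - zc) / half) ** 2, 0.0))
        prol[sel] = np.maximum(prol[sel], profile)
    if aggregate == "max":
        return float(prol.max())
    if aggregate == "mean":
        return float(prol.mean())
    raise ValueError("aggregate must be 'max' or 'mean'")


# ---------------------------------------------------------------------------
# stent-artery ratio
# ---------------------------------------------------------------------------

def stent_artery_ratio(state: DeployedState) -> float:
    """SAR (%): strut outer surface area / lumen surface in the stented
    segment x 100."""
    strut_area = strut_outer_surface_area(state.lattice, state.design)
    # lumen surface integrated over per-ring tributary spans, rescaled so
    # the covered extent equals the deployed length exactly
    seg = np.abs(np.gradient(state.ring_z))
    lumen_area = float(np.sum(2 * math.pi * state.lumen_radius * seg))
    covered = seg.sum()
    if covered > 0:
        lumen_area *= state.deployed_length / covered
    if lumen_area <= 0:
        raise ValueError("zero lumen area")
    return 100.0 * strut_area / lumen_area


# ---------------------------------------------------------------------------
# hoop force and radial strength
# ---------------------------------------------------------------------------

def normalized_hoop_force(crimp: CrimpResult, nominal_length: float) -> float:
    """Max crimp hoop force per unit nominal stent length (N/mm)."""
    if nominal_length <= 0:
        raise ValueError("nominal length must be positive")
    if len(crimp.curve) == 0:
        raise ValueError("empty crimp curve")
    return crimp.max_hoop_force / nominal_length


def deployed_hoop_force(state: DeployedState) -> float:
    """Hoop force of a deployed stent: total outward radial force / 2 pi."""
    return state.total_radial_force() / (2 * math.pi)


def radial_strength(state: DeployedState) -> float:
    """Total outward radial contact force / strut outer surface area
    (N/mm^2)."""
    area = strut_outer_surface_area(state.lattice, state.design)
    if area <= 0:
        raise ValueError("zero stent area")
    return state.total_radial_force() / area


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """All metrics for one simulation cell of the factorial design."""

    design: str
    diameter: float                 # target expansion diameter, mm
    plaque_mode: str                # category label or "heterogeneous"
    geometry_seed: int
    msd: float                      # mm
    ccd: float                      # mm
    prolapse: float                 # mm (max over sections)
    prolapse_mean: float            # mm (mean over sections)
    sar: float                      # %
    normalized_hoop_force: float    # N/mm (deployed radial force / 2pi / L)
    radial_strength: float          # N/mm^2
    degenerate_cells: int = 0

    def __post_init__(self):
        if self.msd <= 0:
            raise ValueError("MSD must be positive")
        if self.ccd < 0 or self.prolapse < 0:
            raise ValueError("CCD and prolapse must be non-negative")
        if not (0.0 <= self.sar <= 100.0):
            raise ValueError("SAR must be a percentage in [0, 100]")

    FIELDS = ("design", "diameter", "plaque_mode", "geometry_seed", "msd",
              "ccd", "prolapse", "prolapse_mean", "sar",
              "normalized_hoop_force", "radial_strength",
              "degenerate_cells")

    def row(self) -> dict:
        return {k: getattr(self, k) for k in self.FIELDS}


def compute_metrics(state: DeployedState,
                    prolapse_state: DeployedState | None = None,
                    plaque_mode: str = "",
                    target_diameter: float = 0.0,
                    geometry_seed: int = 0) -> MetricsReport:
    """Assemble the full metrics report for one deployed state.

    ``prolapse_state`` is the companion deployment against the bare normal
    wall (the prolapse protocol assigns no plaque material); when omitted,
    prolapse is computed on ``state`` itself.
    """
    cells, degen = cell_details(state)
    ps = prolapse_state or state
    return MetricsReport(
        design=state.design.name,
        diameter=target_diameter,
        plaque_mode=plaque_mode,
        geometry_seed=geometry_seed,
        msd=mean_stent_diameter(state),
        ccd=circular_cell_diameter(state),
        prolapse=vessel_prolapse(ps, "max"),
        prolapse_mean=vessel_prolapse(ps, "mean"),
        sar=stent_artery_ratio(state),
        normalized_hoop_force=deployed_hoop_force(state)
        / state.nominal_length,
        radial_strength=radial_strength(state),
        degenerate_cells=degen)
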