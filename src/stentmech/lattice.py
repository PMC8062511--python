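"""Parametric ring-and-link stent lattices on a cylinder.

A stent is a stack of zigzag rings (alternating peaks and valleys, ``p``
peaks per ring, hence ``2p`` strut legs per ring) joined by straight axial
links.  The catalog reproduces the printed characteristics of the four
everolimus-eluting designs compared in this package: the 9-, 10- and 12-peak
MEGATRON prototypes and SYNERGY.

Geometric conventions
---------------------
* Cylindrical frame: theta in [0, 2pi) right-handed, z along the stent axis
  in mm with z = 0 at the proximal edge, r in mm (node radius = strut
  centerline radius).
* Each crown (peak or valley node) is shared by two legs; adjacent rings are
  phase-shifted by half a crown pitch so that ring-k peaks are theta-aligned
  with ring-(k+1) valleys, and links connect exactly those aligned pairs.
* Leg length is common to all crowns of a design.  Its nominal value comes
  from a shared fully-open geometric ceiling (all four designs overexpand to
  the same maximum diameter), and is then adjusted by at most a few percent
  so that ``rings`` crowns plus ``rings - 1`` link gaps reproduce the printed
  crimped length exactly.  Ring count is the derived integer closest to that
  length budget.

Cell extraction builds the rotation system (combinatorial embedding) of the
lattice graph on the cylinder and traces faces; the two faces that wind
around the axis are the open stent ends and are discarded, every other face
is an interior cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "StentDesign",
    "StentLattice",
    "DESIGN_CATALOG",
    "build_design",
    "cell_polygons",
    "strut_outer_surface_area",
    "expand_kinematics",
    "max_expansion_diameter",
    "lattice_to_mesh",
    "design_catalog_yaml",
]


# ---------------------------------------------------------------------------
# design description
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StentDesign:
    """Parametric description of a ring-and-link stent design.

    Lengths in mm, strut dimensions in micrometres.  ``strut_width_um``
    defaults to the thickness (square cross-section) when not given.
    """

    name: str
    peaks: int
    links_total: int
    strut_thickness_um: float
    crimped_inner_diameter: float
    crimped_length: float
    strut_width_um: float | None = None
    link_gap: float = 0.30              # axial link length between rings, mm
    fully_open_diameter: float = 7.0    # shared geometric ceiling, mm
    nominal_crown_height: float | None = None

    def __post_init__(self):
        if self.peaks < 3:
            raise ValueError("need at least 3 peaks per ring")
        if self.strut_width_um is None:
            object.__setattr__(self, "strut_width_um", self.strut_thickness_um)

    # -- derived quantities -------------------------------------------------

    @property
    def strut_thickness(self) -> float:
        """Strut (radial) thickness in mm."""
        return self.strut_thickness_um * 1e-3

    @property
    def strut_width(self) -> float:
        """Strut (surface) width in mm."""
        return self.strut_width_um * 1e-3

    @property
    def crimped_outer_diameter(self) -> float:
        return self.crimped_inner_diameter + 2 * self.strut_thickness

    @property
    def crimped_node_radius(self) -> float:
        """Strut centerline radius at crimp."""
        return (self.crimped_inner_diameter + self.strut_thickness) / 2

    def _chord(self, radius: float) -> float:
        """Chord between adjacent crown nodes at a given centerline radius."""
        return 2.0 * radius * math.sin(math.pi / (2 * self.peaks))

    @property
    def rings(self) -> int:
        """Ring count derived from the crimped length budget."""
        h_nom = (self.nominal_crown_height
                 if self.nominal_crown_height is not None
                 else self.fully_open_diameter
                 * math.sin(math.pi / (2 * self.peaks)))
        n = round((self.crimped_length + self.link_gap)
                  / (h_nom + self.link_gap))
        return max(2, int(n))

    @property
    def crown_height(self) -> float:
        """Axial crown extent at crimp; absorbs the length residual."""
        n = self.rings
        return (self.crimped_length - (n - 1) * self.link_gap) / n

    @property
    def leg_length(self) -> float:
        """Strut leg length (constant under expansion)."""
        return math.hypot(self.crown_height,
                          self._chord(self.crimped_node_radius))

    @property
    def links_per_pair(self) -> tuple[int, ...]:
        """Per-ring-pair link counts, distributed as evenly as possible."""
        pairs = self.rings - 1
        base, extra = divmod(self.links_total, pairs)
        counts = tuple(base + (1 if k < extra else 0) for k in range(pairs))
        if max(counts) > self.peaks:
            raise ValueError("more links per ring pair than peaks")
        return counts


def _design(name, peaks, length, links, thick_um, width_um=None):
    return StentDesign(name=name, peaks=peaks, links_total=links,
                       strut_thickness_um=thick_um, strut_width_um=width_um,
                       crimped_inner_diameter=0.84, crimped_length=length)


#: Catalog of the four compared designs (printed characteristics: peaks,
#: crimped length, total links, strut thickness; crimped ID 0.84 mm).
DESIGN_CATALOG: dict[str, StentDesign] = {
    "MEGATRON_9": _design("MEGATRON_9", 9, 19.74, 36, 89.0),
    "MEGATRON_10": _design("MEGATRON_10", 10, 20.62, 28, 89.0),
    "MEGATRON_12": _design("MEGATRON_12", 12, 20.05, 50, 89.0),
    "SYNERGY": _design("SYNERGY", 10, 20.33, 36, 81.0),
}


def design_catalog_yaml() -> str:
    """Structured-text dump of the design catalog."""
    import yaml
    out = {}
    for name, d in DESIGN_CATALOG.items():
        out[name] = {
            "peaks": d.peaks, "rings": d.rings,
            "links_total": d.links_total,
            "strut_thickness_um": d.strut_thickness_um,
            "strut_width_um": d.strut_width_um,
            "crimped_inner_diameter_mm": d.crimped_inner_diameter,
            "crimped_outer_diameter_mm": d.crimped_outer_diameter,
            "crimped_length_mm": d.crimped_length,
        }
    return yaml.safe_dump(out, sort_keys=True)


# ---------------------------------------------------------------------------
# lattice realization
# ---------------------------------------------------------------------------

@dataclass
class StentLattice:
    """Geometric realization of a stent design.

    ``theta``, ``z``, ``r`` are per-node cylindrical coordinates; ``struts``
    is an (n, 2) int array of node pairs; ``kind`` marks each strut as a ring
    leg (0) or a link (1); ``ring`` is the ring index of each node.
    """

    theta: np.ndarray
    z: np.ndarray
    r: np.ndarray
    struts: np.ndarray
    kind: np.ndarray
    ring: np.ndarray
    design_name: str = ""

    @property
    def n_nodes(self) -> int:
        return len(self.theta)

    @property
    def length(self) -> float:
        return float(self.z.max() - self.z.min())

    def node_xyz(self) -> np.ndarray:
        return np.column_stack([self.r * np.cos(self.theta),
                                self.r * np.sin(self.theta), self.z])

    def strut_lengths(self) -> np.ndarray:
        """True 3-D chord length of every strut segment."""
        xyz = self.node_xyz()
        d = xyz[self.struts[:, 0]] - xyz[self.struts[:, 1]]
        return np.linalg.norm(d, axis=1)

    def ring_radii(self) -> np.ndarray:
        """Mean node radius per ring (stations of the reduced solver)."""
        n = self.ring.max() + 1
        return np.array([self.r[self.ring == k].mean() for k in range(n)])

    def ring_z(self) -> np.ndarray:
        """Mean axial position per ring."""
        n = self.ring.max() + 1
        return np.array([self.z[self.ring == k].mean() for k in range(n)])


def build_design(design: StentDesign) -> StentLattice:
    """Realize a design as a crimped-state lattice.

    Ring k occupies z in [z_k, z_k + h]; even nodes are valleys (z_k), odd
    nodes are peaks (z_k + h).  Ring k+1 is phase-shifted by one node pitch
    so its valleys are theta-aligned with ring-k peaks; links are straight
    axial connectors between those aligned pairs, spread evenly around the
    circumference with a rotating per-pair offset.
    """
    p, n_r = design.peaks, design.rings
    if n_r < 2:
        raise ValueError("need at least 2 rings")
    h, g = design.crown_height, design.link_gap
    r0 = design.crimped_node_radius
    pitch = math.pi / p  # node angular pitch (half crown pitch)

    theta, z, ring = [], [], []
    for k in range(n_r):
        z0 = k * (h + g)
        for j in range(2 * p):
            theta.append(((j + k) * pitch) % (2 * math.pi))
            z.append(z0 + (h if j % 2 else 0.0))
            ring.append(k)
    theta = np.array(theta)
    z = np.array(z)
    ring = np.array(ring, dtype=int)
    r = np.full(theta.shape, r0)

    struts, kind = [], []
    for k in range(n_r):
        base = 2 * p * k
        for j in range(2 * p):
            struts.append((base + j, base + (j + 1) % (2 * p)))
            kind.append(0)

    # links: peak j (odd) of ring k aligns with node j-1 of ring k+1
    counts = design.links_per_pair
    for k in range(n_r - 1):
        m = counts[k]
        base, nxt = 2 * p * k, 2 * p * (k + 1)
        offset = k % p  # rotational offset pattern
        for s in range(m):
            peak_idx = (2 * ((offset + round(s * p / m)) % p) + 1)
            a = base + peak_idx
            b = nxt + (peak_idx - 1) % (2 * p)
            if abs((theta[a] - theta[b] + math.pi) % (2 * math.pi)
                   - math.pi) > 1e-9:
                raise RuntimeError("link endpoints not theta-aligned")
            struts.append((a, b))
            kind.append(1)

    lat = StentLattice(theta=theta, z=z, r=r,
                       struts=np.array(struts, dtype=int),
                       kind=np.array(kind, dtype=int),
                       ring=ring, design_name=design.name)
    assert abs(lat.length - design.crimped_length) < 1e-6
    return lat


# ---------------------------------------------------------------------------
# cells (faces of the cylinder-embedded graph)
# ---------------------------------------------------------------------------

def _adjacency(lat: StentLattice) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in range(lat.n_nodes)]
    for a, b in lat.struts:
        adj[a].append(b)
        adj[b].append(a)
    return adj


def _connected(lat: StentLattice) -> bool:
    adj = _adjacency(lat)
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == lat.n_nodes


def _dtheta(lat: StentLattice, a: int, b: int) -> float:
    """Signed angular step a -> b on the shortest arc (seam-safe)."""
    d = lat.theta[b] - lat.theta[a]
    return (d + math.pi) % (2 * math.pi) - math.pi


def cell_polygons(lat: StentLattice):
    """Interior cells of the lattice as ordered node loops.

    Returns a list of loops; each loop is a list of node indices.  The loops
    are traced from the rotation system of the graph embedded on the
    cylinder: at every node the incident edges are sorted by direction in
    the locally-unrolled (r*theta, z) plane, and faces are walked with the
    standard next-edge rule.  Faces with a nonzero winding number around the
    axis (the two open stent ends) are dropped, so each interior face is
    returned exactly once and no loop is split at the theta = 0 seam.
    """
    if not _connected(lat):
        raise ValueError("lattice graph is disconnected")
    r_mean = float(lat.r.mean())
    adj = _adjacency(lat)

    def edge_angle(a: int, b: int) -> float:
        return math.atan2(lat.z[b] - lat.z[a],
                          r_mean * _dtheta(lat, a, b))

    rotation: list[list[int]] = []
    for u in range(lat.n_nodes):
        rotation.append(sorted(set(adj[u]), key=lambda v: edge_angle(u, v)))

    nxt: dict[tuple[int, int], tuple[int, int]] = {}
    for u in range(lat.n_nodes):
        ring_u = rotation[u]
        for v in ring_u:
            # face-tracing successor of directed edge (v, u): the edge after
            # (u, v) in counterclockwise rotation at u
            i = ring_u.index(v)
            w = ring_u[(i + 1) % len(ring_u)]
            nxt[(v, u)] = (u, w)

    faces, visited = [], set()
    for e0 in list(nxt):
        if e0 in visited:
            continue
        loop, e = [], e0
        while e not in visited:
            visited.add(e)
            loop.append(e[0])
            e = nxt[e]
        winding = sum(_dtheta(lat, loop[i], loop[(i + 1) % len(loop)])
                      for i in range(len(loop))) / (2 * math.pi)
        if abs(winding) < 0.5:
            faces.append(loop)
    return faces


def unroll_loop(lat: StentLattice, loop) -> np.ndarray:
    """Unroll a cell loop onto the plane of its mean-radius cylinder.

    Returns (n, 2) coordinates (arc length, z) with cumulative seam-safe
    angular unwrapping; cells are shallow relative to the cylinder at
    deployment radii, so this local development is accurate.
    """
    r_loc = float(lat.r[list(loop)].mean())
    th = 0.0
    pts = [(0.0, lat.z[loop[0]])]
    for a, b in zip(loop, loop[1:]):
        th += _dtheta(lat, a, b)
        pts.append((r_loc * th, lat.z[b]))
    return np.array(pts)


# ---------------------------------------------------------------------------
# areas and kinematics
# ---------------------------------------------------------------------------

def strut_outer_surface_area(lat: StentLattice, design: StentDesign) -> float:
    """Outer (abluminal) strut surface area: sum of length x width, mm^2."""
    return float(lat.strut_lengths().sum() * design.strut_width)


def max_expansion_diameter(design: StentDesign) -> float:
    """Inner diameter at which the zigzag is fully straightened.

    At full opening the leg is purely circumferential, so the chord between
    adjacent nodes equals the leg length: 2 r sin(pi / 2p) = L.
    """
    r = design.leg_length / (2 * math.sin(math.pi / (2 * design.peaks)))
    return 2 * r - design.strut_thickness


def expand_kinematics(lat: StentLattice, design: StentDesign,
                      target_inner_diameter: float | np.ndarray
                      ) -> StentLattice:
    """Map the lattice to a target diameter with inextensible legs.

    ``target_inner_diameter`` may be a scalar or a per-ring array.  Crown
    opening increases with radius while the axial crown height shrinks
    (foreshortening); leg lengths are preserved exactly and total length is
    non-increasing in diameter.
    """
    n_r = int(lat.ring.max()) + 1
    target = np.broadcast_to(np.asarray(target_inner_diameter, dtype=float),
                             (n_r,))
    if np.any(target < design.crimped_inner_diameter - 1e-12):
        raise ValueError("target below the crimped diameter")
    d_max = max_expansion_diameter(design)
    if np.any(target > d_max + 1e-12):
        raise ValueError(
            f"target diameter unreachable with inextensible struts; "
            f"maximum reachable inner diameter is {d_max:.4f} mm")

    radii = (target + design.strut_thickness) / 2.0
    L = design.leg_length
    chord = 2.0 * radii * np.sin(math.pi / (2 * design.peaks))
    h = np.sqrt(np.maximum(L**2 - chord**2, 0.0))

    z = lat.z.copy()
    r = lat.r.copy()
    z0 = 0.0
    for k in range(n_r):
        mask = lat.ring == k
        odd = mask & (np.arange(lat.n_nodes) % 2 == 1)
        even = mask & ~odd
        z[even] = z0
        z[odd] = z0 + h[k]
        r[mask] = radii[k]
        z0 += h[k] + design.link_gap
    return replace(lat, z=z, r=r)


# ---------------------------------------------------------------------------
# mesh export
# ---------------------------------------------------------------------------

def lattice_to_mesh(lat: StentLattice, design: StentDesign):
    """Sweep struts as square tubes and return a trimesh surface mesh."""
    import trimesh
    xyz = lat.node_xyz()
    half = design.strut_width / 2.0
    meshes = []
    for a, b in lat.struts:
        seg = xyz[b] - xyz[a]
        length = np.linalg.norm(seg)
        if length < 1e-12:
            continue
        box = trimesh.creation.box((2 * half, 2 * half, length))
        align = trimesh.geometry.align_vectors([0, 0, 1], seg / length)
        box.apply_transform(align)
        box.apply_translation((xyz[a] + xyz[b]) / 2.0)
        meshes.append(box)
    return trimesh.util.concatenate(meshes)
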