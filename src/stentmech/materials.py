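"""Constitutive models for vessel wall, plaque, stent alloy and balloon.

The soft tissues (normal arterial wall and the five atherosclerotic plaque
classes) are modeled as incompressible isotropic hyperelastic solids with a
polynomial strain-energy density

    U = sum_{i+j=1..N} C_ij (I1 - 3)^i (I2 - 3)^j      [MPa]

where I1 = l1^2 + l2^2 + l3^2 and I2 = l1^-2 + l2^-2 + l3^-2 are the
invariants of the Cauchy-Green tensor in terms of principal stretches.  The
"reduced" polynomial keeps only the first-invariant terms (j = 0), which is
the form used for every shipped catalog material.  Plaque additionally yields
at 34% engineering strain and is extended past the onset with a
perfectly-plastic plateau.  The platinum-chromium stent alloy is reduced to a
one-dimensional elastoplastic hardening law (the hinge solver only ever sees
uniaxial fiber strain), and the semi-compliant balloon is a linear-elastic
membrane with a 900 MPa modulus.

All stresses are nominal (force per undeformed area), all strains are
engineering strains eps = lambda - 1, and incompressibility is exact.

The numeric values in :data:`CATALOG` are documented package defaults shaped
to the published character of each tissue class (lipid pools in the tens of
kPa, calcific plaque in the MPa-to-tens-of-MPa range); they are *defaults*,
not reproductions of any proprietary data set.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass

import numpy as np
import yaml

__all__ = [
    "HyperelasticModel",
    "PlaqueMaterial",
    "AlloyMaterial",
    "BalloonMaterial",
    "strain_energy",
    "uniaxial_stress",
    "plaque_stress",
    "fit_reduced_polynomial",
    "material_catalog",
    "catalog_to_yaml",
    "catalog_from_yaml",
    "stress_curve_csv",
    "CATALOG",
    "PLAQUE_CATEGORIES",
]

PLAQUE_CATEGORIES = ("very_soft", "soft", "neutral", "stiff", "very_stiff")


# ---------------------------------------------------------------------------
# hyperelastic core
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HyperelasticModel:
    """Incompressible polynomial hyperelastic model.

    Parameters
    ----------
    coefficients
        Mapping ``(i, j) -> C_ij`` in MPa with ``1 <= i + j <= N``.
        Reduced-polynomial materials only carry ``(i, 0)`` keys.
    """

    coefficients: dict[tuple[int, int], float]
    incompressible: bool = True

    def __post_init__(self):
        if not self.coefficients:
            raise ValueError("model needs at least one coefficient")
        for (i, j) in self.coefficients:
            if i < 0 or j < 0 or i + j < 1:
                raise ValueError(f"invalid coefficient index ({i}, {j})")

    @property
    def order(self) -> int:
        """Polynomial order N = max(i + j)."""
        return max(i + j for (i, j) in self.coefficients)

    # -- energy and stress --------------------------------------------------

    def energy(self, stretches) -> np.ndarray | float:
        """Strain-energy density U at principal stretches (l1, l2, l3)."""
        l1, l2, l3 = (np.asarray(s, dtype=float) for s in stretches)
        if np.any(l1 <= 0) or np.any(l2 <= 0) or np.any(l3 <= 0):
            raise ValueError("principal stretches must be positive")
        i1 = l1**2 + l2**2 + l3**2 - 3.0
        i2 = l1**-2 + l2**-2 + l3**-2 - 3.0
        u = np.zeros(np.broadcast(l1, l2, l3).shape)
        for (i, j), c in self.coefficients.items():
            u = u + c * i1**i * i2**j
        return u if u.shape else float(u)

    def uniaxial_stress(self, stretch) -> np.ndarray | float:
        """Nominal uniaxial stress dU/dl on the incompressible path.

        The lateral stretches are l2 = l3 = l^(-1/2); the derivative is
        analytic (chain rule on the invariants), not a finite difference.
        """
        lam = np.asarray(stretch, dtype=float)
        if np.any(lam <= 0):
            raise ValueError("stretch must be positive")
        i1 = lam**2 + 2.0 / lam - 3.0
        i2 = lam**-2 + 2.0 * lam - 3.0
        di1 = 2.0 * lam - 2.0 * lam**-2
        di2 = -2.0 * lam**-3 + 2.0
        s = np.zeros(lam.shape)
        for (i, j), c in self.coefficients.items():
            if i >= 1:
                s = s + c * i * _safe_pow(i1, i - 1) * _safe_pow(i2, j) * di1
            if j >= 1:
                s = s + c * j * _safe_pow(i1, i) * _safe_pow(i2, j - 1) * di2
        return s if s.shape else float(s)

    def tangent_stiffness(self, stretch, h: float = 1e-6) -> float:
        """Numerical slope of the uniaxial stress-stretch curve."""
        return (self.uniaxial_stress(stretch + h)
                - self.uniaxial_stress(stretch - h)) / (2 * h)


def _safe_pow(base, exp):
    """base**exp with the convention 0**0 == 1 (and exp always >= 0 here)."""
    if exp == 0:
        return np.ones_like(base)
    return base**exp


def strain_energy(model: HyperelasticModel, stretches):
    """U(l1, l2, l3) in MPa; see :meth:`HyperelasticModel.energy`."""
    return model.energy(stretches)


def uniaxial_stress(model: HyperelasticModel, stretch):
    """Nominal uniaxial stress in MPa on the incompressible path."""
    return model.uniaxial_stress(stretch)


# ---------------------------------------------------------------------------
# plaque with plastic plateau
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlaqueMaterial:
    """Hyperelastic plaque with a perfectly-plastic plateau past yield.

    Yield onset is at 34% engineering strain; beyond it the nominal stress
    holds the value reached at onset, which is the simplest continuous
    extension of the hyperelastic branch.
    """

    base: HyperelasticModel
    plastic_onset_strain: float = 0.34
    category: str = "neutral"

    def stress(self, strain) -> np.ndarray | float:
        eps = np.asarray(strain, dtype=float)
        if np.any(eps < 0):
            raise ValueError("engineering strain must be non-negative")
        capped = np.minimum(eps, self.plastic_onset_strain)
        s = self.base.uniaxial_stress(1.0 + capped)
        return s if np.shape(eps) else float(s)


def plaque_stress(material: PlaqueMaterial, strain):
    """Nominal stress of a plaque category at engineering strain >= 0."""
    return material.stress(strain)


# ---------------------------------------------------------------------------
# alloy and balloon
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlloyMaterial:
    """1-D elastoplastic hardening law for the Pt-Cr stent alloy.

    ``hardening`` is a list of (plastic strain, flow stress MPa) pairs
    starting at (0, yield_stress); flow stress is piecewise-linear and held
    constant beyond the last point.
    """

    elastic_modulus: float
    yield_stress: float
    hardening: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if self.elastic_modulus <= 0:
            raise ValueError("elastic modulus must be positive")
        stresses = [s for _, s in self.hardening]
        if any(b < a for a, b in zip(stresses, stresses[1:])):
            raise ValueError("hardening stresses must be non-decreasing")

    def flow_stress(self, plastic_strain) -> np.ndarray | float:
        eps = np.asarray(plastic_strain, dtype=float)
        xs = np.array([e for e, _ in self.hardening])
        ys = np.array([s for _, s in self.hardening])
        return np.interp(eps, xs, ys)


@dataclass(frozen=True)
class BalloonMaterial:
    """Semi-compliant balloon membrane: linear stress-strain response."""

    elastic_modulus: float = 900.0  # MPa
    thickness: float = 0.05         # mm


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_reduced_polynomial(data, order: int,
                           include_second_invariant: bool = False
                           ) -> HyperelasticModel:
    """Least-squares fit of polynomial coefficients to uniaxial data.

    Parameters
    ----------
    data
        Sequence of ``(stretch, nominal_stress_MPa)`` pairs with stretch > 1.
    order
        Polynomial order N; the fitted terms are C_10..C_N0 (plus the
        second-invariant terms when ``include_second_invariant``).

    Returns
    -------
    HyperelasticModel with the fitted coefficients; the residual 2-norm of
    the stress misfit is stored on the ``fit_residual_`` attribute.

    The stress is linear in the coefficients, so this is a plain linear
    least-squares problem on the analytic per-term uniaxial stresses.
    """
    pts = np.asarray(list(data), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("data must be (stretch, stress) pairs")
    terms: list[tuple[int, int]] = [(i, 0) for i in range(1, order + 1)]
    if include_second_invariant:
        terms += [(i, j) for j in range(1, order + 1)
                  for i in range(0, order - j + 1)]
    if len(pts) < len(terms):
        raise ValueError(
            f"need at least {len(terms)} data points for order {order}")
    lam = pts[:, 0]
    if np.any(lam <= 0):
        raise ValueError("stretches must be positive")
    design = np.column_stack([
        HyperelasticModel({t: 1.0}).uniaxial_stress(lam) for t in terms])
    rank = np.linalg.matrix_rank(design)
    if rank < len(terms):
        raise ValueError(
            "rank-deficient fit: too few distinct stretches for the order")
    coef, *_ = np.linalg.lstsq(design, pts[:, 1], rcond=None)
    model = HyperelasticModel({t: float(c) for t, c in zip(terms, coef)})
    resid = float(np.linalg.norm(design @ coef - pts[:, 1]))
    object.__setattr__(model, "fit_residual_", resid)
    return model


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------

def _plaque(cat: str, coeffs: dict[tuple[int, int], float]) -> PlaqueMaterial:
    return PlaqueMaterial(HyperelasticModel(coeffs), 0.34, cat)


#: Default material catalog.  Plaque coefficients increase elementwise from
#: very_soft to very_stiff, which guarantees the tangent-stiffness ordering
#: at every strain (each basis term has positive, increasing stress slope for
#: stretch > 1).  Values are package defaults in the literature-shaped range.
CATALOG: dict[str, object] = {
    "very_soft": _plaque("very_soft", {(1, 0): 0.005, (2, 0): 0.010}),
    "soft": _plaque("soft", {(1, 0): 0.020, (2, 0): 0.060}),
    "neutral": _plaque("neutral", {(1, 0): 0.080, (2, 0): 0.500}),
    "stiff": _plaque("stiff", {(1, 0): 0.400, (2, 0): 3.000}),
    "very_stiff": _plaque("very_stiff", {(1, 0): 2.000, (2, 0): 15.000}),
    # 6th-order reduced polynomial, positive coefficients -> monotone,
    # strongly strain-stiffening normal arterial wall.
    "normal_wall": HyperelasticModel({
        (1, 0): 0.0065, (2, 0): 0.049, (3, 0): 0.0086,
        (4, 0): 0.0, (5, 0): 0.0, (6, 0): 0.45,
    }),
    "pt_cr": AlloyMaterial(
        elastic_modulus=203000.0, yield_stress=480.0,
        hardening=((0.0, 480.0), (0.05, 560.0), (0.15, 680.0),
                   (0.30, 780.0), (0.45, 834.0)),
    ),
    "balloon": BalloonMaterial(elastic_modulus=900.0, thickness=0.05),
}


def material_catalog(category: str):
    """Look up a catalog material by label.

    Valid labels: the five plaque categories, ``normal_wall``, ``pt_cr``
    and ``balloon``.
    """
    try:
        return CATALOG[category]
    except KeyError:
        raise KeyError(
            f"unknown material category {category!r}; "
            f"valid: {sorted(CATALOG)}") from None


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _model_to_dict(m: HyperelasticModel) -> dict:
    return {"order": m.order,
            "coefficients": [[i, j, c] for (i, j), c in
                             sorted(m.coefficients.items())]}


def _model_from_dict(d: dict) -> HyperelasticModel:
    return HyperelasticModel({(int(i), int(j)): float(c)
                              for i, j, c in d["coefficients"]})


def catalog_to_yaml(catalog: dict[str, object] | None = None) -> str:
    """Serialize a material catalog to a structured-text (YAML) config."""
    catalog = CATALOG if catalog is None else catalog
    out: dict[str, dict] = {}
    for name, mat in catalog.items():
        if isinstance(mat, PlaqueMaterial):
            out[name] = {"kind": "plaque",
                         "plastic_onset_strain": mat.plastic_onset_strain,
                         **_model_to_dict(mat.base)}
        elif isinstance(mat, HyperelasticModel):
            out[name] = {"kind": "hyperelastic", **_model_to_dict(mat)}
        elif isinstance(mat, AlloyMaterial):
            out[name] = {"kind": "alloy",
                         "elastic_modulus": mat.elastic_modulus,
                         "yield_stress": mat.yield_stress,
                         "hardening": [list(p) for p in mat.hardening]}
        elif isinstance(mat, BalloonMaterial):
            out[name] = {"kind": "balloon",
                         "elastic_modulus": mat.elastic_modulus,
                         "thickness": mat.thickness}
    return yaml.safe_dump(out, sort_keys=True)


def catalog_from_yaml(text: str) -> dict[str, object]:
    """Inverse of :func:`catalog_to_yaml`."""
    raw = yaml.safe_load(text)
    out: dict[str, object] = {}
    for name, d in raw.items():
        kind = d["kind"]
        if kind == "plaque":
            out[name] = PlaqueMaterial(_model_from_dict(d),
                                       float(d["plastic_onset_strain"]), name)
        elif kind == "hyperelastic":
            out[name] = _model_from_dict(d)
        elif kind == "alloy":
            out[name] = AlloyMaterial(float(d["elastic_modulus"]),
                                      float(d["yield_stress"]),
                                      tuple((float(a), float(b))
                                            for a, b in d["hardening"]))
        elif kind == "balloon":
            out[name] = BalloonMaterial(float(d["elastic_modulus"]),
                                        float(d["thickness"]))
        else:
            raise ValueError(f"unknown material kind {kind!r}")
    return out


def stress_curve_csv(material, stretches) -> str:
    """CSV export (stretch, nominal_stress_MPa) of a uniaxial curve."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["stretch", "nominal_stress_MPa"])
    for lam in stretches:
        if isinstance(material, PlaqueMaterial):
            s = material.stress(lam - 1.0)
        else:
            s = material.uniaxial_stress(lam)
        w.writerow([f"{lam:.6f}", f"{s:.8g}"])
    return buf.getvalue()
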