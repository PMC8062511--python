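"""Shared fixtures: catalog designs, synthetic vessels, fabricated states."""

import numpy as np
import pytest

from stentmech.lattice import (DESIGN_CATALOG, StentDesign, build_design,
                               expand_kinematics)
from stentmech.solver import DeployedState, SolverConfig
from stentmech.vessel import (VesselParams, assign_homogeneous_plaque,
                              generate_bifurcation)


@pytest.fixture(scope="session")
def designs():
    return DESIGN_CATALOG


@pytest.fixture(scope="session")
def m12():
    return DESIGN_CATALOG["MEGATRON_12"]


@pytest.fixture(scope="session")
def m9():
    return DESIGN_CATALOG["MEGATRON_9"]


@pytest.fixture(scope="session")
def base_vessel():
    """One bare (no plaque assignment) synthetic bifurcation."""
    return generate_bifurcation(VesselParams(), seed=1)


@pytest.fixture(scope="session")
def neutral_vessel(base_vessel):
    return assign_homogeneous_plaque(base_vessel, "neutral")


def make_free_state(design: StentDesign, inner_diameter,
                    radial_force=None) -> DeployedState:
    """Fabricate an equilibrium-free deployed state at prescribed radii
    (scalar or per-ring inner diameters) for metric unit tests."""
    diam = np.broadcast_to(np.asarray(inner_diameter, dtype=float),
                           (design.rings,))
    lat = expand_kinematics(build_design(design), design, diam)
    n = design.rings
    r_center = (diam + design.strut_thickness) / 2
    force = (np.zeros(n) if radial_force is None
             else np.broadcast_to(np.asarray(radial_force, float), (n,)))
    return DeployedState(
        design=design, config=SolverConfig(), lattice=lat,
        ring_z=lat.ring_z(), vessel_station=np.zeros(n, dtype=int),
        r_center=r_center.copy(), contact_pressure=np.zeros(n),
        radial_force=force.copy(),
        lumen_radius=r_center + design.strut_thickness / 2,
        theta_plastic=np.zeros(n), kappa=np.zeros(n),
        residual=np.zeros(n), balloon_pressure=0.0, vessel=None,
        deflated=True)
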