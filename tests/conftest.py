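"""Shared fixtures: small filter banks, model-derived tuning, sessions.

Expensive model simulations are session-scoped and run at reduced
resolution (128 px, 4 carrier phases) to keep the suite fast; the
acceptance tests re-run the headline quantities at full scale.
"""

from __future__ import annotations

import numpy as np
import pytest

from vignetta.pyramid import PyramidConfig, build_filter_bank
from vignetta.simulation import PRF, predict_prf_tuning, simulate_orientation_maps
from vignetta.stimuli import AnnulusSpec, CarrierSpec, ModulatorSpec, simulation_geometry
from vignetta.synth import (
    GroundTruthVoxel,
    NoiseModel,
    SessionDesign,
    cosine_tuning_truths,
    generate_session,
    make_prf_grid,
)

SIM_ANNULUS = AnnulusSpec(inner_deg=0.75, outer_deg=9.0, transition_deg=1.0)
SIM_CARRIER = CarrierSpec(sf_cpd=1.4)
SIM_RADIAL = ModulatorSpec("radial", "sine", "cosine", 1.0, log_scaled=True)
SIM_ANGULAR = ModulatorSpec("angular", "sine", "cosine", 12)
MID_ECC = 0.5 * (SIM_ANNULUS.inner_deg + SIM_ANNULUS.outer_deg)


@pytest.fixture(scope="session")
def bank64():
    return build_filter_bank(PyramidConfig(image_shape=(64, 64)))


@pytest.fixture(scope="session")
def sim_geometry():
    return simulation_geometry(128, 24.0)


@pytest.fixture(scope="session")
def model_maps(sim_geometry):
    """Energy-model orientation maps for both sinusoidal modulators."""
    phases = np.arange(4) / 4 * 2 * np.pi
    maps = {}
    for axis, mod in (("radial", SIM_RADIAL), ("angular", SIM_ANGULAR)):
        maps[axis], _ = simulate_orientation_maps(
            sim_geometry, mod, SIM_ANNULUS, SIM_CARRIER, carrier_phases=phases
        )
    return maps


@pytest.fixture(scope="session")
def model_truths(model_maps, sim_geometry):
    """Ground-truth voxels whose tuning comes from the energy model,
    pRFs on the mid-annulus ring (16 polar angles, sigma 1 deg)."""
    prfs = make_prf_grid((MID_ECC - 0.4, MID_ECC + 0.4), 2, 16,
                         sigma_rule=lambda e: 1.0)
    truths = []
    for prf in prfs:
        tuning = {
            axis: predict_prf_tuning(model_maps[axis], prf, sim_geometry)
            for axis in ("radial", "angular")
        }
        truths.append(GroundTruthVoxel(prf=prf, tuning=tuning))
    return truths


@pytest.fixture(scope="session")
def session_design():
    return SessionDesign(radial=SIM_RADIAL, angular=SIM_ANGULAR)


@pytest.fixture(scope="session")
def faithful_session(session_design, model_truths):
    """One model-faithful synthetic session at moderate noise."""
    return generate_session(
        session_design, model_truths, NoiseModel(white_sd=1.0, drift_linear=1.0),
        seed=11,
    )


@pytest.fixture()
def analytic_truths():
    rng = np.random.default_rng(42)
    prfs = make_prf_grid((3.0, 7.0), 3, 12, sigma_rule=lambda e: 1.0)
    return cosine_tuning_truths(prfs, rng)
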