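"""Shared fixtures: phantoms and end-to-end study results reused across tests.

The default study (256^2 grid, 360 projections, 1e5 blank counts/ray,
thresholds 30/51/62/72/81 keV, seed 0) is expensive, so it is computed
once per session and shared; the same goes for the noiseless water-disc
run and the full 2400-projection acquisition.
"""

from __future__ import annotations

import numpy as np
import pytest

import kneespec as ks
from kneespec.phantom import WaterCylinderConfig
from kneespec.pipeline import DEFAULT_THRESHOLDS


@pytest.fixture(scope="session")
def spectrum():
    return ks.make_spectrum_120kvp(total_fluence=1e5)


@pytest.fixture(scope="session")
def knee_phantom():
    return ks.make_knee_phantom(seed=0)


@pytest.fixture(scope="session")
def knee_study():
    """Default Poisson knee study at the desk-scale acquisition."""
    return ks.run_knee_study(seed=0)


@pytest.fixture(scope="session")
def full_acquisition_study():
    """Knee study at the scanner's 2400 projections per rotation."""
    return ks.run_knee_study(seed=0, n_angles=2400)


@pytest.fixture(scope="session")
def water_noiseless(spectrum):
    """Noiseless end-to-end water-disc run: scan, decomposition, basis maps."""
    ph = ks.make_water_cylinder(WaterCylinderConfig(grid_size=256, voxel_size=0.25))
    geom = ks.ScanGeometry(n_angles=360, n_detectors=256, detector_pitch=0.25)
    scan = ks.simulate_counts(ph, spectrum, DEFAULT_THRESHOLDS, geom, noiseless=True)
    bs = ks.decompose_sinogram(scan)
    basis = ks.reconstruct_basis(bs, ph.voxel_size)
    return {"phantom": ph, "scan": scan, "basis_sinogram": bs, "basis": basis}
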