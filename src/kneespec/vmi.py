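"""Virtual monoenergetic image synthesis and the conventional HU image.

A VMI at energy ``E`` is the linear combination of the reconstructed
basis maps, ``mu(x; E) = a_pe(x) f_pe(E) + a_c(x) f_KN(E)``, converted to
Hounsfield units with the water material's attenuation at the same
energy: ``HU = 1000 (mu - mu_water) / mu_water``.  The conventional image
merges all energy bins into a single transmission measurement,
reconstructs the effective attenuation by FBP, and maps it to HU with a
water-cylinder calibration acquired at identical settings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import BinnedSinogram, simulate_counts
from .materials import MATERIALS, klein_nishina_factor, photoelectric_factor
from .phantom import WaterCylinderConfig, make_water_cylinder
from .recon import BasisImageStack, fbp_reconstruct
from .spectrum import SourceSpectrum

__all__ = [
    "VmiStack",
    "DEFAULT_VMI_ENERGIES",
    "synthesize_vmi",
    "conventional_attenuation",
    "conventional_image",
    "water_calibration_factor",
]

#: default VMI energy grid (keV): 40 to 110 in 10 keV steps
DEFAULT_VMI_ENERGIES = tuple(range(40, 120, 10))

#: zero-count floor for merged-bin log transforms
COUNT_FLOOR = 0.5


@dataclass
class VmiStack:
    """HU images indexed by synthesis energy."""

    energies: np.ndarray   # keV
    images: np.ndarray     # (n_energies, ny, nx), HU
    water_mu: np.ndarray   # mu_water(E) in 1/cm per energy

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        if self.images.shape[0] != self.energies.size:
            raise ValueError("one image per energy required")
        if np.any(self.water_mu <= 0):
            raise ValueError("water attenuation must be positive at all energies")

    def at(self, energy_kev: float) -> np.ndarray:
        i = int(np.flatnonzero(np.isclose(self.energies, energy_kev))[0])
        return self.images[i]


def synthesize_vmi(
    basis: BasisImageStack,
    energies=DEFAULT_VMI_ENERGIES,
    e_bounds: tuple[float, float] = (30.0, 120.0),
) -> VmiStack:
    """Synthesize HU images at the requested energies from basis maps."""
    energies = np.asarray(energies, dtype=float)
    if np.any(energies < e_bounds[0]) or np.any(energies > e_bounds[1]):
        raise ValueError(f"VMI energies must lie within {e_bounds} keV")
    water = MATERIALS["water"]
    f_pe = photoelectric_factor(energies)
    f_kn = klein_nishina_factor(energies)
    mu_w = water.a_pe * f_pe + water.a_c * f_kn
    mu = (
        basis.a_pe_map[None, ...] * f_pe[:, None, None]
        + basis.a_c_map[None, ...] * f_kn[:, None, None]
    )
    hu = 1000.0 * (mu - mu_w[:, None, None]) / mu_w[:, None, None]
    return VmiStack(energies=energies, images=hu, water_mu=mu_w)


def conventional_attenuation(scan: BinnedSinogram, filter_name: str = "ramp") -> np.ndarray:
    """Effective attenuation map (1/cm) from the merged-bin transmission.

    Sums counts over bins, forms ``-ln(n_total / blank_total)`` line
    integrals (zero-count rays floored at 0.5 counts) and reconstructs by
    FBP.
    """
    total = scan.counts.sum(axis=0).astype(float)
    blank_total = float(np.asarray(scan.blank).sum())
    total = np.maximum(total, COUNT_FLOOR)
    L = -np.log(total / blank_total)
    return fbp_reconstruct(L, scan.geometry, scan.geometry.detector_pitch, filter_name)


def water_calibration_factor(
    spectrum: SourceSpectrum,
    thresholds,
    geometry,
    voxel_size_mm: float,
    filter_name: str = "ramp",
) -> float:
    """Effective water attenuation (1/cm) of the merged-bin image.

    Simulates a noiseless water cylinder at identical acquisition settings
    and returns the mean reconstructed value over its interior.
    """
    ph = make_water_cylinder(
        WaterCylinderConfig(grid_size=geometry.n_detectors, voxel_size=voxel_size_mm)
    )
    scan = simulate_counts(ph, spectrum, thresholds, geometry, noiseless=True)
    mu_eff = conventional_attenuation(scan, filter_name)
    return float(mu_eff[ph.rois["interior"]].mean())


def conventional_image(
    scan: BinnedSinogram,
    mu_water_eff: float | None = None,
    filter_name: str = "ramp",
) -> np.ndarray:
    """Conventional merged-bin image in HU.

    ``mu_water_eff`` is the water calibration factor from
    :func:`water_calibration_factor`; if omitted it is computed from the
    scan's own spectrum and geometry.
    """
    if mu_water_eff is None:
        if scan.spectrum is None:
            raise ValueError("scan carries no spectrum; pass mu_water_eff explicitly")
        mu_water_eff = water_calibration_factor(
            scan.spectrum, scan.thresholds, scan.geometry, scan.geometry.detector_pitch,
            filter_name,
        )
    mu_eff = conventional_attenuation(scan, filter_name)
    return 1000.0 * (mu_eff - mu_water_eff) / mu_water_eff
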