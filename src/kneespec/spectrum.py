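"""Polychromatic X-ray source model and energy binning.

The tube spectrum is a Kramers bremsstrahlung shape ``S(E) ~ (kVp - E)``
hardened by an aluminium-equivalent filtration and truncated to the
detector's spectral support [30, 120] keV, then scaled to a configured
total fluence per detector element per projection.  Energies are tabulated
on a 1 keV grid; all spectral sums are quadratures on that grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import ENERGY_MAX_KEV, ENERGY_MIN_KEV

__all__ = ["SourceSpectrum", "make_spectrum_120kvp", "blank_scan", "bin_edges"]

# aluminium linear attenuation (1/cm): mass attenuation x density 2.699 g/cm^3,
# representative values on a coarse grid, log-interpolated between
_AL_E = np.array([30.0, 40.0, 50.0, 60.0, 80.0, 100.0, 120.0])
_AL_MU = 2.699 * np.array([1.128, 0.5685, 0.3681, 0.2778, 0.2018, 0.1704, 0.1536])


def _al_mu(E: np.ndarray) -> np.ndarray:
    return np.exp(np.interp(E, _AL_E, np.log(_AL_MU)))


@dataclass(frozen=True)
class SourceSpectrum:
    """Expected photon fluence per energy per detector element per view."""

    energies: np.ndarray  # keV, ascending, 1 keV steps
    fluence: np.ndarray   # expected photons at each energy

    def __post_init__(self):
        if np.any(self.fluence < 0):
            raise ValueError("fluence must be non-negative")
        if self.fluence.sum() <= 0:
            raise ValueError("total fluence must be positive")

    @property
    def total_fluence(self) -> float:
        return float(self.fluence.sum())

    def fluence_at(self, E):
        """Fluence at arbitrary energies; zero outside the tabulated support."""
        return np.interp(np.asarray(E, dtype=float), self.energies, self.fluence,
                         left=0.0, right=0.0)


def make_spectrum_120kvp(
    kvp: float = 120.0,
    filtration_mm_al: float = 2.5,
    total_fluence: float = 1e5,
    e_min: float = ENERGY_MIN_KEV,
    e_max: float = ENERGY_MAX_KEV,
) -> SourceSpectrum:
    """Filtered 120 kVp bremsstrahlung spectrum on a 1 keV grid.

    ``total_fluence`` is the expected photon count per ray with no object
    (the blank).  Fluence is identically zero outside [e_min, e_max].
    """
    if kvp <= 0 or filtration_mm_al < 0:
        raise ValueError("kvp must be positive and filtration non-negative")
    if total_fluence <= 0:
        raise ValueError("total fluence must be positive")
    E = np.arange(e_min, min(e_max, kvp) + 0.5, 1.0)
    shape = np.clip(kvp - E, 0.0, None)
    shape *= np.exp(-_al_mu(E) * filtration_mm_al / 10.0)
    if shape.sum() <= 0:
        raise ValueError("spectrum has no fluence in the supported range")
    return SourceSpectrum(energies=E, fluence=shape * (total_fluence / shape.sum()))


def bin_edges(thresholds, e_max: float = ENERGY_MAX_KEV) -> np.ndarray:
    """Bin edges from ascending thresholds; the last bin extends to e_max."""
    t = np.asarray(thresholds, dtype=float)
    if t.ndim != 1 or t.size < 1 or np.any(np.diff(t) <= 0):
        raise ValueError("thresholds must be strictly ascending")
    return np.append(t, e_max)


def bin_index(spectrum: SourceSpectrum, thresholds, e_max: float = ENERGY_MAX_KEV):
    """Assign each spectrum energy to a bin; -1 for energies below the first
    threshold.  Bin b spans [T_b, T_{b+1}), the last bin up to e_max inclusive."""
    edges = bin_edges(thresholds, e_max)
    idx = np.searchsorted(edges, spectrum.energies, side="right") - 1
    idx[spectrum.energies > e_max] = -1
    idx[idx == len(edges) - 1] = len(edges) - 2  # E == e_max into last bin
    return idx, edges


def blank_scan(spectrum: SourceSpectrum, thresholds) -> np.ndarray:
    """Expected per-bin counts with no object in the beam.

    Raises if any bin contains no spectral energy (empty bin).
    """
    idx, edges = bin_index(spectrum, thresholds)
    n_bins = len(edges) - 1
    lam = np.zeros(n_bins)
    for b in range(n_bins):
        sel = idx == b
        if not sel.any():
            raise ValueError(f"energy bin {b} [{edges[b]}, {edges[b + 1]}) contains no spectrum energy")
        lam[b] = spectrum.fluence[sel].sum()
    if np.any(lam <= 0):
        raise ValueError("every bin must have positive expected blank counts")
    return lam
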