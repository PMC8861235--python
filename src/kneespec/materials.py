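"""Two-material attenuation basis and the tissue material library.

The energy dependence of the linear attenuation coefficient in the
diagnostic range is modelled as a linear combination of two basis
functions: a photoelectric term falling as ``E**-3`` and a Compton term
following the Klein-Nishina total cross-section.  Both are normalized to
1 at the 60 keV reference energy, so material coefficients ``(a_pe, a_c)``
are read directly as the photoelectric and Compton contributions to
``mu`` (1/cm) at 60 keV:

    mu(E) = a_pe * f_pe(E) + a_c * f_KN(E)

Material coefficients are fitted once, at import, from the small bundled
reference attenuation table below (representative linear attenuation
values assembled from published mass-attenuation data and nominal tissue
densities; they are generic tissue surrogates, not specimen-matched).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

E_REF_KEV = 60.0
ELECTRON_REST_KEV = 510.975
ENERGY_MIN_KEV = 30.0
ENERGY_MAX_KEV = 120.0

__all__ = [
    "MaterialSpec",
    "photoelectric_factor",
    "klein_nishina_factor",
    "material_mu",
    "fit_basis_coefficients",
    "MATERIALS",
    "REFERENCE_ATTENUATION",
    "E_REF_KEV",
    "ENERGY_MIN_KEV",
    "ENERGY_MAX_KEV",
]


def _check_energy(E, lo: float = 1.0, hi: float = 200.0) -> np.ndarray:
    E = np.asarray(E, dtype=float)
    if np.any(E <= 0):
        raise ValueError("photon energy must be positive (keV)")
    if np.any(E < lo) or np.any(E > hi):
        raise ValueError(f"photon energy outside supported range [{lo}, {hi}] keV")
    return E


def photoelectric_factor(E):
    """Photoelectric basis function ``(60/E)**3``, dimensionless.

    Normalized so ``photoelectric_factor(60) == 1``.  Accepts scalars or
    arrays of energies in keV; strictly decreasing with energy.
    """
    E = _check_energy(E)
    out = (E_REF_KEV / E) ** 3
    return out if out.ndim else float(out)


def _kn_sigma(alpha: np.ndarray) -> np.ndarray:
    # Klein-Nishina total cross-section in units of 2*pi*r_e^2
    a = alpha
    t = np.log1p(2 * a)
    return (
        (1 + a) / a**2 * (2 * (1 + a) / (1 + 2 * a) - t / a)
        + t / (2 * a)
        - (1 + 3 * a) / (1 + 2 * a) ** 2
    )


def klein_nishina_factor(E):
    """Compton basis function: Klein-Nishina total cross-section vs energy.

    Evaluated at ``alpha = E / 510.975`` and normalized so the value at
    60 keV is exactly 1.  Strictly decreasing over the diagnostic range.
    """
    E = _check_energy(E)
    out = _kn_sigma(E / ELECTRON_REST_KEV) / _kn_sigma(
        np.asarray(E_REF_KEV / ELECTRON_REST_KEV)
    )
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class MaterialSpec:
    """A material expressed in the photoelectric/Compton basis.

    ``a_pe`` and ``a_c`` are the basis coefficients in 1/cm at the 60 keV
    reference energy; both must be non-negative.
    """

    name: str
    a_pe: float
    a_c: float

    def __post_init__(self):
        if self.a_pe < 0 or self.a_c < 0:
            raise ValueError(f"material {self.name!r}: basis coefficients must be >= 0")

    def mu(self, E):
        return material_mu(self, E)


def material_mu(m: MaterialSpec, E):
    """Linear attenuation (1/cm) of material ``m`` at energy ``E`` (keV).

    ``E`` must lie within the spectral support [30, 120] keV.
    """
    E = _check_energy(E, ENERGY_MIN_KEV, ENERGY_MAX_KEV)
    out = m.a_pe * (E_REF_KEV / E) ** 3 + m.a_c * (
        _kn_sigma(E / ELECTRON_REST_KEV) / _kn_sigma(np.asarray(E_REF_KEV / ELECTRON_REST_KEV))
    )
    return out if np.ndim(out) else float(out)


def fit_basis_coefficients(samples) -> tuple[float, float]:
    """Least-squares fit of ``(a_pe, a_c)`` to (energy keV, mu 1/cm) samples.

    Coefficients are constrained non-negative (NNLS).  With two samples at
    distinct energies and a non-negative solution the fit is exact.
    Raises if fewer than two distinct energies are supplied.
    """
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError("need at least two (energy, attenuation) samples")
    E = np.array([s[0] for s in samples], dtype=float)
    mu = np.array([s[1] for s in samples], dtype=float)
    if np.unique(E).size < 2:
        raise ValueError("samples must cover at least two distinct energies (singular system)")
    A = np.column_stack([photoelectric_factor(E), klein_nishina_factor(E)])
    coef, _ = nnls(A, mu)
    return float(coef[0]), float(coef[1])


# ---------------------------------------------------------------------------
# Bundled reference attenuation table: linear attenuation in 1/cm at the
# listed energies (keV).  Representative values for generic tissue
# surrogates; cartilage is set slightly more attenuating than soft tissue
# (denser, proteoglycan-rich matrix) so the two tissues remain separable.
# ---------------------------------------------------------------------------
_REF_ENERGIES = np.array([30.0, 40.0, 50.0, 60.0, 80.0, 100.0, 120.0])

_WATER_MU = np.array([0.3756, 0.2683, 0.2269, 0.2059, 0.1837, 0.1707, 0.1614])
_CORTICAL_MU = np.array([1.847, 0.983, 0.670, 0.526, 0.401, 0.346, 0.315])

REFERENCE_ATTENUATION: dict[str, list[tuple[float, float]]] = {
    "water": list(zip(_REF_ENERGIES, _WATER_MU)),
    # soft tissue and cartilage are water-dominated but slightly
    # photoelectric-enriched (protein matrix; sulfated GAGs and trace
    # mineral in cartilage), modelled as water + a small bone-curve share
    "soft_tissue": list(zip(_REF_ENERGIES, 1.005 * _WATER_MU + 0.005 * _CORTICAL_MU)),
    "cartilage": list(zip(_REF_ENERGIES, 1.06 * _WATER_MU + 0.015 * _CORTICAL_MU)),
    # synovial / cyst fluid: water-like
    "joint_fluid": list(zip(_REF_ENERGIES, 1.005 * _WATER_MU)),
    "cyst_fluid": list(zip(_REF_ENERGIES, 1.005 * _WATER_MU)),
    "cortical_bone": list(zip(_REF_ENERGIES, _CORTICAL_MU)),
    # homogeneous trabecular-bone + marrow mixture
    "trabecular_bone": list(zip(_REF_ENERGIES, 0.35 * _CORTICAL_MU + 0.65 * _WATER_MU)),
    # hydroxyapatite-like calcification
    "calcification": list(zip(_REF_ENERGIES, np.array([3.20, 1.65, 1.05, 0.78, 0.55, 0.46, 0.41]))),
}


def _build_library() -> dict[str, MaterialSpec]:
    lib = {"air": MaterialSpec("air", 0.0, 0.0)}
    for name, table in REFERENCE_ATTENUATION.items():
        a_pe, a_c = fit_basis_coefficients(table)
        lib[name] = MaterialSpec(name, a_pe, a_c)
    return lib


#: Material library fitted from :data:`REFERENCE_ATTENUATION` at import.
MATERIALS: dict[str, MaterialSpec] = _build_library()
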