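"""End-to-end study driver: phantom -> scan -> decomposition -> VMI -> metrics.

``run_knee_study`` reproduces the full analysis chain on the synthetic
knee phantom at desk scale: simulate the five-threshold photon-counting
acquisition, decompose every ray by Poisson maximum likelihood,
reconstruct the basis maps by FBP, synthesize the VMI ladder and the
conventional merged-bin image, and evaluate noise/CNR and tissue
fingerprints.  ``run_cyst_analysis`` quantifies planted subchondral
cysts on a selected image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cysts as cq
from .decompose import BasisSinogram, decompose_sinogram
from .forward import BinnedSinogram, ScanGeometry, simulate_counts
from .phantom import KneePhantomConfig, LabeledPhantom, LABELS, make_knee_phantom
from .quality import energy_fingerprint, quality_table, select_optimal_energy
from .recon import BasisImageStack, reconstruct_basis
from .spectrum import SourceSpectrum, make_spectrum_120kvp
from .vmi import (
    DEFAULT_VMI_ENERGIES,
    VmiStack,
    conventional_image,
    synthesize_vmi,
    water_calibration_factor,
)

__all__ = ["StudyResult", "run_knee_study", "run_cyst_analysis", "DEFAULT_THRESHOLDS"]

#: detector thresholds (keV) of the five-bin acquisition
DEFAULT_THRESHOLDS = (30.0, 51.0, 62.0, 72.0, 81.0)


@dataclass
class StudyResult:
    phantom: LabeledPhantom
    scan: BinnedSinogram
    basis_sinogram: BasisSinogram
    basis: BasisImageStack
    vmi: VmiStack
    conventional: np.ndarray
    quality: pd.DataFrame
    fingerprints: pd.DataFrame
    optimal: dict
    spectrum: SourceSpectrum = None
    extras: dict = field(default_factory=dict)


def run_knee_study(
    seed: int = 0,
    phantom_config: KneePhantomConfig | None = None,
    thresholds=DEFAULT_THRESHOLDS,
    n_angles: int = 360,
    blank_fluence: float = 1e5,
    vmi_energies=DEFAULT_VMI_ENERGIES,
    noiseless: bool = False,
    filter_name: str = "ramp",
) -> StudyResult:
    """Run the complete spectral analysis on one knee-phantom slice."""
    cfg = phantom_config or KneePhantomConfig()
    phantom = make_knee_phantom(cfg, seed=seed)
    if phantom.labels.ndim != 2:
        raise ValueError("run_knee_study operates on a single-slice phantom")

    spectrum = make_spectrum_120kvp(total_fluence=blank_fluence)
    geometry = ScanGeometry(
        n_angles=n_angles, n_detectors=cfg.grid_size, detector_pitch=cfg.voxel_size
    )
    scan = simulate_counts(
        phantom, spectrum, thresholds, geometry, seed=seed + 1, noiseless=noiseless
    )
    bs = decompose_sinogram(scan)
    basis = reconstruct_basis(bs, cfg.voxel_size, filter_name)
    vmi = synthesize_vmi(basis, vmi_energies)

    mu_w_eff = water_calibration_factor(
        spectrum, thresholds, geometry, cfg.voxel_size, filter_name
    )
    conventional = conventional_image(scan, mu_w_eff, filter_name)

    quality = quality_table(vmi, phantom.rois, conventional)
    tissue_rois = {
        "cartilage": phantom.rois["roi_cartilage"],
        "soft_tissue": phantom.rois["roi_soft_tissue"],
        "cortical_bone": phantom.rois["roi_cortical_bone"],
        "subchondral_bone": phantom.rois["roi_trabecular_bone"],
    }
    fingerprints = energy_fingerprint(vmi, tissue_rois)
    optimal = select_optimal_energy(quality)

    return StudyResult(
        phantom=phantom,
        scan=scan,
        basis_sinogram=bs,
        basis=basis,
        vmi=vmi,
        conventional=conventional,
        quality=quality,
        fingerprints=fingerprints,
        optimal=optimal,
        spectrum=spectrum,
        extras={"mu_water_effective": mu_w_eff},
    )


def ideal_vmi(phantom: LabeledPhantom, energy_kev: float = 60.0,
              noise_sd_hu: float = 0.0, seed: int = 0) -> np.ndarray:
    """Noise-controlled HU image straight from the phantom's ground truth.

    Maps each voxel's material attenuation at ``energy_kev`` to HU and
    optionally adds white Gaussian noise — a fast stand-in for a full
    reconstruction when only segmentation behaviour is under study.
    """
    from .materials import MATERIALS

    mu = phantom.mu_map(energy_kev)
    mu_w = MATERIALS["water"].mu(energy_kev)
    hu = 1000.0 * (mu - mu_w) / mu_w
    if noise_sd_hu > 0:
        hu = hu + np.random.default_rng(seed).normal(0.0, noise_sd_hu, hu.shape)
    return hu


def run_cyst_analysis(
    phantom: LabeledPhantom,
    image: np.ndarray,
    tolerance: float | None = None,
    min_voxels: int = cq.MIN_CYST_VOXELS,
    depth_mm: float = 10.0,
    site: str = "femoral",
) -> tuple[cq.CystReport, cq.SubchondralBand, np.ndarray]:
    """Quantify cysts on an HU image using the phantom's geometry masks.

    Seeds are taken at the centroids of the ground-truth cyst components
    (mirroring the operator's seed clicks); the growth tolerance defaults
    to half the HU gap between cyst fluid and trabecular bone.
    """
    from scipy import ndimage

    bone = phantom.rois["bone_mask"] | (phantom.truth_masks["cysts"] > 0)
    band = cq.subchondral_band(
        bone, phantom.rois["articular_surface"], depth_mm, phantom.voxel_size
    )

    truth = phantom.truth_masks["cysts"]
    seeds = [
        tuple(int(round(c)) for c in ndimage.center_of_mass(truth == lab))
        for lab in np.unique(truth)[1:]
    ]
    if tolerance is None:
        # half the cyst-fluid vs trabecular-bone HU gap on the ideal image
        hu_cyst = float(np.median(image[truth > 0])) if (truth > 0).any() else 0.0
        trab = phantom.labels == LABELS["trabecular_bone"]
        hu_bone = float(np.median(image[trab]))
        tolerance = abs(hu_bone - hu_cyst) / 2.0
    components = cq.segment_cysts(image, band, seeds, tolerance, min_voxels)
    rows, records = cq.compartment_stats(
        components,
        {
            "medial": phantom.rois["compartment_medial"],
            "lateral": phantom.rois["compartment_lateral"],
        },
        phantom.voxel_size,
        site=site,
    )
    report = cq.aggregate_report(rows)
    report.records = records
    report.density_per_mm3 = cq.cyst_density(report, band)
    return report, band, components
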