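"""Image-quality metrics: ROI noise, CNR, energy fingerprints, energy selection.

Noise is the sample standard deviation inside a small circular ROI placed
in a homogeneous part of the cartilage (radius 4 pixels).  CNR is the
absolute difference of mean grey level along a line inside the cartilage
and a parallel line in the joint space, divided by that noise.  The
energy fingerprint of a tissue is its ROI mean (and SD) attenuation as a
function of VMI energy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .vmi import VmiStack

__all__ = [
    "roi_noise",
    "cnr",
    "energy_fingerprint",
    "quality_table",
    "select_optimal_energy",
]

#: label used for the merged-bin image in quality tables
CONVENTIONAL = "conventional"


def roi_noise(image: np.ndarray, disc: np.ndarray) -> float:
    """Sample standard deviation of the image under a mask (ddof=1)."""
    vals = image[disc]
    if vals.size == 0:
        raise ValueError("noise ROI is empty")
    if vals.size < 2:
        raise ValueError("noise ROI must contain at least two pixels")
    return float(np.std(vals, ddof=1))


def cnr(image: np.ndarray, line1: np.ndarray, line2: np.ndarray, noise: float) -> float:
    """|mean(line1) - mean(line2)| / noise."""
    if noise <= 0:
        raise ValueError("CNR undefined for non-positive noise")
    v1 = image[line1]
    v2 = image[line2]
    if v1.size == 0 or v2.size == 0:
        raise ValueError("both measurement lines must be non-empty")
    return float(abs(v1.mean() - v2.mean()) / noise)


def energy_fingerprint(stack: VmiStack, tissue_rois: dict[str, np.ndarray],
                       hu_offset: float = 0.0) -> pd.DataFrame:
    """Per-tissue mean and SD attenuation (HU) versus VMI energy.

    Empty ROIs are skipped with a warning row omitted.  ``hu_offset`` is
    added to reported means for comparability with offset HU conventions;
    it never enters any internal computation.
    """
    rows = []
    for tissue, mask in tissue_rois.items():
        if not mask.any():
            continue
        for i, E in enumerate(stack.energies):
            vals = stack.images[i][mask]
            rows.append(
                {
                    "tissue": tissue,
                    "energy_kev": float(E),
                    "mean_hu": float(vals.mean()) + hu_offset,
                    "sd_hu": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def quality_table(
    stack: VmiStack,
    rois: dict[str, np.ndarray],
    conventional: np.ndarray | None = None,
) -> pd.DataFrame:
    """Noise SD and CNR per VMI energy (and the conventional image).

    ``rois`` must provide ``noise_disc``, ``line_cartilage`` and
    ``line_background`` masks on the image grid.
    """
    disc = rois["noise_disc"]
    l1 = rois["line_cartilage"]
    l2 = rois["line_background"]
    rows = []
    for i, E in enumerate(stack.energies):
        img = stack.images[i]
        sd = roi_noise(img, disc)
        rows.append({"image": float(E), "noise_sd_hu": sd, "cnr": cnr(img, l1, l2, sd)})
    if conventional is not None:
        sd = roi_noise(conventional, disc)
        rows.append({"image": CONVENTIONAL, "noise_sd_hu": sd, "cnr": cnr(conventional, l1, l2, sd)})
    return pd.DataFrame(rows)


def select_optimal_energy(quality: pd.DataFrame) -> dict:
    """Pick the max-CNR and min-noise VMI energies from a quality table.

    Only numeric (monoenergetic) rows participate.  Ties break toward the
    lower energy and are flagged in the result.
    """
    mono = quality[quality["image"].apply(lambda v: isinstance(v, (int, float)))]
    mono = mono.sort_values("image").reset_index(drop=True)
    if len(mono) < 2:
        raise ValueError("need at least two energies to select an optimum")
    cnr_vals = mono["cnr"].to_numpy()
    noise_vals = mono["noise_sd_hu"].to_numpy()
    e = mono["image"].to_numpy(dtype=float)
    i_cnr = int(np.argmax(cnr_vals))          # argmax returns first (lowest-E) tie
    i_noise = int(np.argmin(noise_vals))
    return {
        "energy_max_cnr": float(e[i_cnr]),
        "energy_min_noise": float(e[i_noise]),
        "cnr_tie": bool(np.sum(cnr_vals == cnr_vals[i_cnr]) > 1),
        "noise_tie": bool(np.sum(noise_vals == noise_vals[i_noise]) > 1),
    }
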