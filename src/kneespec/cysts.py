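"""Subchondral bone cyst segmentation and quantification.

Cysts are fluid-filled, low-attenuation cavities in the bone just below
the articular cartilage.  The analysis restricts attention to a
subchondral band (bone within a fixed depth, default 10 mm, of the
articular surface), grows each operator-supplied seed into the connected
set of voxels whose HU lies within a tolerance half-width of the seed
value, removes objects smaller than 20 voxels as noise, and reports
per-compartment (medial/lateral) and aggregated statistics: number of
cysts, total volume, maximum single-cyst volume (mm^3) and cyst density
per mm^3 of band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SubchondralBand",
    "CystRecord",
    "CystReport",
    "subchondral_band",
    "region_grow",
    "label_components",
    "filter_min_volume",
    "compartment_stats",
    "aggregate_report",
    "cyst_density",
    "MIN_CYST_VOXELS",
]

#: objects below this voxel count are treated as noise and removed
MIN_CYST_VOXELS = 20


def _full_connectivity(ndim: int) -> np.ndarray:
    # 8-connectivity in 2D, 26-connectivity in 3D
    return np.ones((3,) * ndim, dtype=bool)


@dataclass
class SubchondralBand:
    """Bone voxels within ``depth`` mm of the articular surface."""

    mask: np.ndarray
    depth: float
    reference_surface: np.ndarray
    voxel_size: float

    @property
    def band_volume(self) -> float:
        """Band volume in mm^3."""
        return float(self.mask.sum()) * self.voxel_size**self.mask.ndim


def subchondral_band(
    bone_mask: np.ndarray,
    surface_mask: np.ndarray,
    depth_mm: float = 10.0,
    voxel_size: float = 0.25,
) -> SubchondralBand:
    """Bone within a Euclidean distance ``depth_mm`` of the articular surface.

    The surface mask is the interface layer adjacent to the bone (the
    first non-bone layer on the articular side); distances are computed by
    Euclidean distance transform with physical voxel sampling.
    """
    if depth_mm < 0:
        raise ValueError("depth must be >= 0")
    if not surface_mask.any():
        raise ValueError("articular surface mask is empty")
    if surface_mask.shape != bone_mask.shape:
        raise ValueError("bone and surface masks must share a shape")
    dist = ndimage.distance_transform_edt(~surface_mask, sampling=voxel_size)
    band = bone_mask & (dist <= depth_mm)
    return SubchondralBand(
        mask=band, depth=depth_mm, reference_surface=surface_mask, voxel_size=voxel_size
    )


def region_grow(
    image: np.ndarray,
    seed: tuple[int, ...],
    tolerance: float,
    domain: np.ndarray | None = None,
    connectivity: np.ndarray | None = None,
) -> np.ndarray:
    """Seeded region growing: the connected component of
    ``|HU(v) - HU(seed)| <= tolerance`` containing the seed.

    ``domain`` restricts growth (e.g. to the subchondral band); growth is
    8-connected in 2D and 26-connected in 3D by default.  Deterministic.
    """
    seed = tuple(int(s) for s in seed)
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if domain is None:
        domain = np.ones(image.shape, dtype=bool)
    if not domain[seed]:
        raise ValueError(f"seed {seed} lies outside the growth domain")
    structure = connectivity if connectivity is not None else _full_connectivity(image.ndim)
    candidate = domain & (np.abs(image - image[seed]) <= tolerance)
    labeled, _ = ndimage.label(candidate, structure=structure)
    return labeled == labeled[seed]


def label_components(mask: np.ndarray, connectivity: np.ndarray | None = None) -> np.ndarray:
    """Connected-component labeling (26-connectivity in 3D, 8 in 2D).

    Labels are contiguous positive integers in first-voxel scan order.
    """
    structure = connectivity if connectivity is not None else _full_connectivity(mask.ndim)
    labeled, _ = ndimage.label(mask.astype(bool), structure=structure)
    return labeled


def filter_min_volume(
    components: np.ndarray,
    min_voxels: int = MIN_CYST_VOXELS,
    voxel_size: float | None = None,
) -> np.ndarray:
    """Remove components with fewer than ``min_voxels`` voxels (strict `<`).

    Survivors keep their original labels.  The physical threshold this
    implies for a given voxel size is :func:`min_volume_mm3`.
    """
    out = components.copy()
    if components.max() == 0:
        return out
    sizes = np.bincount(components.ravel())
    kill = np.flatnonzero(sizes < min_voxels)
    out[np.isin(components, kill[kill > 0])] = 0
    return out


def min_volume_mm3(min_voxels: int = MIN_CYST_VOXELS, voxel_size: float = 0.25, ndim: int = 3) -> float:
    """Physical volume (mm^3) of the minimum-size filter."""
    return min_voxels * voxel_size**ndim


@dataclass
class CystRecord:
    """One segmented cyst after the minimum-size filter."""

    id: int
    voxel_count: int
    volume: float          # mm^3
    centroid: tuple[float, ...]
    compartment: str       # 'medial' | 'lateral'
    site: str = "femoral"  # 'femoral' | 'patellar'
    flagged: bool = False  # centroid fell in no compartment; nearest assigned


@dataclass
class CystReport:
    """Per-compartment rows plus per-site totals (Table-style semantics)."""

    rows: pd.DataFrame
    records: list[CystRecord] = field(default_factory=list)
    density_per_mm3: float | None = None


def compartment_stats(
    components: np.ndarray,
    compartment_masks: dict[str, np.ndarray],
    voxel_size: float,
    site: str = "femoral",
) -> tuple[list[dict], list[CystRecord]]:
    """Assign each cyst to the compartment containing its centroid and
    report per-compartment (number, total volume, maximum volume) rows.

    A centroid falling in no compartment is assigned to the nearest one
    and the record flagged.
    """
    ndim = components.ndim
    vox_vol = voxel_size**ndim
    labels = np.unique(components)
    labels = labels[labels > 0]
    records: list[CystRecord] = []

    # distance maps for nearest-compartment fallback
    nearest = {
        name: ndimage.distance_transform_edt(~mask) for name, mask in compartment_masks.items()
    }

    for lab in labels:
        mask = components == lab
        nvox = int(mask.sum())
        centroid = ndimage.center_of_mass(mask)
        at = tuple(int(round(c)) for c in centroid)
        comp = None
        for name, cmask in compartment_masks.items():
            if cmask[at]:
                comp = name
                break
        flagged = comp is None
        if flagged:
            comp = min(nearest, key=lambda nm: nearest[nm][at])
        records.append(
            CystRecord(
                id=int(lab),
                voxel_count=nvox,
                volume=nvox * vox_vol,
                centroid=centroid,
                compartment=comp,
                site=site,
                flagged=flagged,
            )
        )

    rows = []
    for name in compartment_masks:
        sel = [r for r in records if r.compartment == name]
        rows.append(
            {
                "site": site,
                "compartment": name,
                "number": len(sel),
                "total_volume_mm3": sum(r.volume for r in sel),
                "max_volume_mm3": max((r.volume for r in sel), default=0.0),
            }
        )
    return rows, records


def aggregate_report(rows) -> CystReport:
    """Aggregate per-compartment rows into per-site totals.

    Per site: number and total volume are sums over compartments, maximum
    volume is the max over compartments.  Volumes are reported at one
    decimal.
    """
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("aggregate_report needs at least one row")
    out = []
    for site, grp in df.groupby("site", sort=False):
        for _, r in grp.iterrows():
            out.append(
                {
                    "site": site,
                    "compartment": r["compartment"],
                    "number": int(r["number"]),
                    "total_volume_mm3": round(float(r["total_volume_mm3"]), 1),
                    "max_volume_mm3": round(float(r["max_volume_mm3"]), 1),
                }
            )
        out.append(
            {
                "site": site,
                "compartment": "total",
                "number": int(grp["number"].sum()),
                "total_volume_mm3": round(float(grp["total_volume_mm3"].sum()), 1),
                "max_volume_mm3": round(float(grp["max_volume_mm3"].max()), 1),
            }
        )
    return CystReport(rows=pd.DataFrame(out))


def cyst_density(report: CystReport, band: SubchondralBand) -> float:
    """Total cyst number divided by band volume (cysts per mm^3)."""
    vol = band.band_volume
    if vol <= 0:
        raise ValueError("cyst density undefined for zero band volume")
    totals = report.rows[report.rows["compartment"] == "total"]
    n = int(totals["number"].sum()) if not totals.empty else int(report.rows["number"].sum())
    return n / vol


def segment_cysts(
    image: np.ndarray,
    band: SubchondralBand,
    seeds,
    tolerance: float,
    min_voxels: int = MIN_CYST_VOXELS,
) -> np.ndarray:
    """Grow every seed inside the band, merge, label and size-filter.

    Returns the labeled cyst components after the minimum-size filter.
    """
    mask = np.zeros(image.shape, dtype=bool)
    for seed in seeds:
        mask |= region_grow(image, seed, tolerance, domain=band.mask)
    return filter_min_volume(label_components(mask), min_voxels)
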