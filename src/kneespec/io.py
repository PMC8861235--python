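"""Persistence: NIfTI volumes, HDF5 scan containers, YAML sidecars, CSV tables.

Layout conventions
------------------
* A phantom directory holds ``labels.nii`` plus ``phantom.yaml`` (voxel
  size and material coefficients) and one ``roi_<name>.nii`` /
  ``truth_<name>.nii`` mask per ROI and truth mask.
* A scan container (``.h5``) holds ``counts[bins, angles, detectors]``,
  ``thresholds``, ``blank``, the spectrum tables and geometry attributes.
  Basis sinograms and basis image stacks live in groups of the same file
  or their own files with the same schema.
* VMI stacks are written as one NIfTI per energy plus an ``index.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .decompose import BasisSinogram
from .forward import BinnedSinogram, ScanGeometry
from .materials import MaterialSpec
from .phantom import LabeledPhantom
from .recon import BasisImageStack
from .spectrum import SourceSpectrum
from .vmi import VmiStack

__all__ = [
    "save_phantom", "load_phantom",
    "save_sinogram", "load_sinogram",
    "save_basis_sinogram", "load_basis_sinogram",
    "save_basis_images", "load_basis_images",
    "save_vmi_stack", "load_vmi_stack",
]


def _affine(voxel_size: float, ndim: int) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size
    return aff


def _save_nii(path: Path, arr: np.ndarray, voxel_size: float):
    nib.save(nib.Nifti1Image(np.asarray(arr), _affine(voxel_size, arr.ndim)), str(path))


def _load_nii(path: Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def save_phantom(phantom: LabeledPhantom, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _save_nii(out / "labels.nii", phantom.labels.astype(np.int16), phantom.voxel_size)
    for name, mask in phantom.rois.items():
        _save_nii(out / f"roi_{name}.nii", mask.astype(np.uint8), phantom.voxel_size)
    for name, mask in phantom.truth_masks.items():
        _save_nii(out / f"truth_{name}.nii", np.asarray(mask, dtype=np.int32), phantom.voxel_size)
    sidecar = {
        "voxel_size_mm": float(phantom.voxel_size),
        "materials": {
            int(lab): {"name": m.name, "a_pe": float(m.a_pe), "a_c": float(m.a_c)}
            for lab, m in phantom.label_to_material.items()
        },
        "rois": sorted(phantom.rois),
        "truth_masks": sorted(phantom.truth_masks),
    }
    (out / "phantom.yaml").write_text(yaml.safe_dump(sidecar, sort_keys=True))
    return out


def load_phantom(in_dir) -> LabeledPhantom:
    src = Path(in_dir)
    meta = yaml.safe_load((src / "phantom.yaml").read_text())
    labels = _load_nii(src / "labels.nii").astype(np.int16)
    materials = {
        int(lab): MaterialSpec(d["name"], d["a_pe"], d["a_c"])
        for lab, d in meta["materials"].items()
    }
    rois = {n: _load_nii(src / f"roi_{n}.nii").astype(bool) for n in meta["rois"]}
    truth = {n: _load_nii(src / f"truth_{n}.nii") for n in meta["truth_masks"]}
    truth = {n: (v.astype(np.int32) if n == "cysts" else v.astype(bool)) for n, v in truth.items()}
    return LabeledPhantom(
        labels=labels,
        label_to_material=materials,
        voxel_size=meta["voxel_size_mm"],
        rois=rois,
        truth_masks=truth,
    )


def _write_geometry(grp, geom: ScanGeometry):
    grp.attrs["n_angles"] = geom.n_angles
    grp.attrs["n_detectors"] = geom.n_detectors
    grp.attrs["detector_pitch_mm"] = geom.detector_pitch
    grp.attrs["beam"] = geom.beam


def _read_geometry(grp) -> ScanGeometry:
    return ScanGeometry(
        n_angles=int(grp.attrs["n_angles"]),
        n_detectors=int(grp.attrs["n_detectors"]),
        detector_pitch=float(grp.attrs["detector_pitch_mm"]),
        beam=str(grp.attrs["beam"]),
    )


def save_sinogram(scan: BinnedSinogram, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=scan.counts)
        f.create_dataset("thresholds", data=scan.thresholds)
        f.create_dataset("blank", data=scan.blank)
        if scan.spectrum is not None:
            f.create_dataset("spectrum/energies", data=scan.spectrum.energies)
            f.create_dataset("spectrum/fluence", data=scan.spectrum.fluence)
        _write_geometry(f, scan.geometry)
    return path


def load_sinogram(path) -> BinnedSinogram:
    with h5py.File(Path(path), "r") as f:
        spectrum = None
        if "spectrum" in f:
            spectrum = SourceSpectrum(
                energies=f["spectrum/energies"][()], fluence=f["spectrum/fluence"][()]
            )
        return BinnedSinogram(
            counts=f["counts"][()],
            thresholds=f["thresholds"][()],
            geometry=_read_geometry(f),
            blank=f["blank"][()],
            spectrum=spectrum,
        )


def save_basis_sinogram(bs: BasisSinogram, path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("A_pe", data=bs.A_pe)
        f.create_dataset("A_c", data=bs.A_c)
        if bs.status is not None:
            f.create_dataset("status", data=bs.status)
        _write_geometry(f, bs.geometry)
    return path


def load_basis_sinogram(path) -> BasisSinogram:
    with h5py.File(Path(path), "r") as f:
        return BasisSinogram(
            A_pe=f["A_pe"][()],
            A_c=f["A_c"][()],
            geometry=_read_geometry(f),
            status=f["status"][()] if "status" in f else None,
        )


def save_basis_images(basis: BasisImageStack, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _save_nii(out / "a_pe.nii", basis.a_pe_map, basis.voxel_size)
    _save_nii(out / "a_c.nii", basis.a_c_map, basis.voxel_size)
    (out / "basis.json").write_text(json.dumps({"voxel_size_mm": basis.voxel_size}))
    return out


def load_basis_images(in_dir) -> BasisImageStack:
    src = Path(in_dir)
    meta = json.loads((src / "basis.json").read_text())
    return BasisImageStack(
        a_pe_map=_load_nii(src / "a_pe.nii").astype(float),
        a_c_map=_load_nii(src / "a_c.nii").astype(float),
        voxel_size=meta["voxel_size_mm"],
    )


def save_vmi_stack(stack: VmiStack, out_dir, voxel_size: float = 0.25) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index = []
    for i, E in enumerate(stack.energies):
        name = f"vmi_{int(round(E))}keV.nii"
        _save_nii(out / name, stack.images[i], voxel_size)
        index.append({"energy_kev": float(E), "file": name, "water_mu": float(stack.water_mu[i])})
    (out / "index.json").write_text(json.dumps(index, indent=1))
    return out


def load_vmi_stack(in_dir) -> VmiStack:
    src = Path(in_dir)
    index = json.loads((src / "index.json").read_text())
    energies = [e["energy_kev"] for e in index]
    images = np.stack([_load_nii(src / e["file"]).astype(float) for e in index])
    water_mu = np.array([e["water_mu"] for e in index])
    return VmiStack(energies=np.asarray(energies), images=images, water_mu=water_mu)
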