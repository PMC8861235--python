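"""Digital knee-joint and calibration phantoms with ground truth.

The knee phantom is a stylized axial section through the femoro-patellar
joint: two bone bodies (cortical rim around homogeneous trabecular
interior) facing each other across a fluid-filled joint space, articular
cartilage lining both articular surfaces, soft tissue around the joint
and air outside.  Optional spherical subchondral cysts (fluid-filled,
within 10 mm of the articular bone surface) and calcification specks
inside the cartilage carry ground-truth masks for validating
segmentation.  The phantom also provides the measurement geometry used
for image-quality analysis: a circular noise ROI of radius 4 pixels
inside the cartilage, a measurement line inside the cartilage, a
parallel background line in the joint space, per-tissue fingerprint ROIs
and a medial/lateral split.

Phantoms are generated per axial slice; a 3D phantom is a stack of
identical anatomical slices in which cysts and calcifications are true
3D spheres.  Generation is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .materials import MATERIALS, MaterialSpec

__all__ = [
    "LabeledPhantom",
    "KneePhantomConfig",
    "WaterCylinderConfig",
    "make_knee_phantom",
    "make_water_cylinder",
    "LABELS",
]

#: Integer label conventions for the knee phantom.
LABELS = {
    "air": 0,
    "soft_tissue": 1,
    "joint_fluid": 2,
    "cartilage": 3,
    "cortical_bone": 4,
    "trabecular_bone": 5,
    "cyst_fluid": 6,
    "calcification": 7,
}


@dataclass
class LabeledPhantom:
    """Voxel grid of tissue labels plus material map, ROIs and truth masks.

    ``labels`` is 2D ``(ny, nx)`` or 3D ``(nz, ny, nx)``.  ``rois`` and
    ``truth_masks`` are boolean arrays with the same shape as ``labels``
    (``truth_masks['cysts']`` is an integer component-labelled array).
    ``voxel_size`` is the isotropic voxel edge in mm.
    """

    labels: np.ndarray
    label_to_material: dict[int, MaterialSpec]
    voxel_size: float = 0.25
    rois: dict[str, np.ndarray] = field(default_factory=dict)
    truth_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        present = np.unique(self.labels)
        missing = [int(v) for v in present if int(v) not in self.label_to_material]
        if missing:
            raise ValueError(f"labels without material mapping: {missing}")
        for d in (self.rois, self.truth_masks):
            for name, mask in d.items():
                if mask.shape != self.labels.shape:
                    raise ValueError(f"mask {name!r} shape {mask.shape} != grid {self.labels.shape}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def coefficient_maps(self) -> tuple[np.ndarray, np.ndarray]:
        """Ground-truth (a_pe, a_c) maps (1/cm at 60 keV) from the labels."""
        max_label = int(self.labels.max())
        lut_pe = np.zeros(max_label + 1)
        lut_c = np.zeros(max_label + 1)
        for lab, mat in self.label_to_material.items():
            if lab <= max_label:
                lut_pe[lab] = mat.a_pe
                lut_c[lab] = mat.a_c
        return lut_pe[self.labels], lut_c[self.labels]

    def mu_map(self, energy_kev: float) -> np.ndarray:
        """Ground-truth linear attenuation map (1/cm) at one energy."""
        from .materials import klein_nishina_factor, photoelectric_factor

        a_pe, a_c = self.coefficient_maps()
        return a_pe * photoelectric_factor(energy_kev) + a_c * klein_nishina_factor(energy_kev)


@dataclass(frozen=True)
class KneePhantomConfig:
    grid_size: int = 256
    voxel_size: float = 0.25          # mm, isotropic
    n_slices: int = 1                 # 1 -> 2D phantom
    cortical_thickness_mm: float = 1.0
    cartilage_thickness_mm: float = 2.5
    n_cysts: int = 3
    cyst_radius_mm: tuple[float, float] = (0.75, 1.5)
    n_calcifications: int = 2
    calcification_radius_mm: float = 0.4
    subchondral_depth_mm: float = 10.0


@dataclass(frozen=True)
class WaterCylinderConfig:
    grid_size: int = 256
    voxel_size: float = 0.25
    radius_mm: float | None = None    # default: 1/3 of the field of view
    n_slices: int = 1


def _disc(shape, center, radius) -> np.ndarray:
    yy, xx = np.indices(shape)
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _ellipse(shape, center, semi_y, semi_x) -> np.ndarray:
    yy, xx = np.indices(shape)
    return ((yy - center[0]) / semi_y) ** 2 + ((xx - center[1]) / semi_x) ** 2 <= 1.0


def _sphere_mask(shape3d, center, radius_vox) -> np.ndarray:
    zz, yy, xx = np.indices(shape3d)
    return (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2 <= radius_vox**2


def _material_map() -> dict[int, MaterialSpec]:
    return {lab: MATERIALS[name] for name, lab in LABELS.items()}


def make_knee_phantom(config: KneePhantomConfig | None = None, seed: int = 0) -> LabeledPhantom:
    """Build the labeled knee phantom (deterministic for a given seed).

    Raises a configuration error if a requested cyst cannot be placed in
    the subchondral band without touching cortical bone or cartilage.
    """
    cfg = config or KneePhantomConfig()
    n = cfg.grid_size
    if n < 64:
        raise ValueError("grid_size must be >= 64")
    vx = cfg.voxel_size
    px = lambda mm: mm / vx  # mm -> pixels

    shape = (n, n)
    c = n / 2.0 - 0.5
    scale = n / 256.0  # anatomy scales with the grid

    labels = np.zeros(shape, dtype=np.int16)

    # surrounding soft tissue body
    body = _ellipse(shape, (c, c), 0.46 * n, 0.47 * n)
    labels[body] = LABELS["soft_tissue"]

    # femoral condyle (upper) and patella (lower)
    femur_center = (c - 0.195 * n, c)
    femur = _ellipse(shape, femur_center, 0.205 * n, 0.31 * n)
    patella_center = (c + 0.27 * n, c)
    patella = _ellipse(shape, patella_center, 0.155 * n, 0.25 * n)
    bones = femur | patella

    cortical_px = max(1, int(round(px(cfg.cortical_thickness_mm))))
    cart_px = max(2, int(round(px(cfg.cartilage_thickness_mm))))

    for bone in (femur, patella):
        interior = ndimage.binary_erosion(bone, iterations=cortical_px)
        labels[bone] = LABELS["cortical_bone"]
        labels[interior] = LABELS["trabecular_bone"]

    # articular cartilage: layers on the facing surfaces of both bones
    yy, _ = np.indices(shape)
    femur_cart = (
        ndimage.binary_dilation(femur, iterations=cart_px)
        & ~bones & body & (yy > femur_center[0])
    )
    patella_cart = (
        ndimage.binary_dilation(patella, iterations=cart_px)
        & ~bones & body & (yy < patella_center[0])
    )
    cartilage = femur_cart | patella_cart
    labels[cartilage] = LABELS["cartilage"]

    # joint space: fluid between the cartilage layers
    gap = body & ~bones & ~cartilage
    joint_band = (
        gap
        & (yy > femur_center[0] + 0.12 * n)
        & (yy < patella_center[0] - 0.08 * n)
        & (np.abs(np.indices(shape)[1] - c) < 0.26 * n)
    )
    labels[joint_band] = LABELS["joint_fluid"]

    # ---- measurement geometry -------------------------------------------
    rois: dict[str, np.ndarray] = {}
    # noise disc: radius 4 px, centred in the femoral cartilage layer
    col = int(round(c))
    cart_rows = np.flatnonzero(femur_cart[:, col])
    if cart_rows.size == 0:
        raise ValueError("cartilage layer not found at the central column")
    disc_row = int(round(cart_rows.mean()))
    noise_disc = _disc(shape, (disc_row, col), 4) & femur_cart
    rois["noise_disc"] = noise_disc

    half = int(0.12 * n)
    line_cart = np.zeros(shape, dtype=bool)
    for cc in range(col - half, col + half):
        rr = np.flatnonzero(femur_cart[:, cc])
        if rr.size:
            line_cart[int(round(rr.mean())), cc] = True
    bg_row = int(round(0.5 * (femur_center[0] + 0.12 * n + patella_center[0] - 0.08 * n)))
    line_bg = np.zeros(shape, dtype=bool)
    line_bg[bg_row, col - half:col + half] = joint_band[bg_row, col - half:col + half]
    rois["line_cartilage"] = line_cart
    rois["line_background"] = line_bg & ~line_cart

    # per-tissue fingerprint ROIs (eroded so they avoid partial-volume rims)
    rois["roi_cartilage"] = ndimage.binary_erosion(femur_cart, iterations=2)
    soft = labels == LABELS["soft_tissue"]
    rois["roi_soft_tissue"] = ndimage.binary_erosion(soft, iterations=4) & (yy < 0.3 * n)
    rois["roi_cortical_bone"] = labels == LABELS["cortical_bone"]
    rois["roi_trabecular_bone"] = ndimage.binary_erosion(
        labels == LABELS["trabecular_bone"], iterations=2
    )

    xx = np.indices(shape)[1]
    rois["compartment_medial"] = xx < c
    rois["compartment_lateral"] = xx >= c

    # articular bone surface: first non-bone layer in contact with bone,
    # restricted to the cartilage side (reference for subchondral depth)
    surface = ndimage.binary_dilation(bones) & ~bones & ndimage.binary_dilation(cartilage, iterations=2)
    rois["articular_surface"] = surface
    rois["bone_mask"] = bones

    # ---- stack to 3D and plant cysts / calcifications -------------------
    nz = cfg.n_slices
    labels3 = np.broadcast_to(labels, (nz, n, n)).copy()
    rois3 = {k: np.broadcast_to(v, (nz, n, n)).copy() for k, v in rois.items()}

    rng = np.random.default_rng(seed)
    trabecular3 = labels3 == LABELS["trabecular_bone"]

    # subchondral candidate region: trabecular bone within depth of surface
    dist = ndimage.distance_transform_edt(~rois3["articular_surface"], sampling=vx)
    band = trabecular3 & (dist <= cfg.subchondral_depth_mm)

    cyst_truth = np.zeros((nz, n, n), dtype=np.int32)
    for i in range(cfg.n_cysts):
        r_mm = float(rng.uniform(*cfg.cyst_radius_mm)) if cfg.cyst_radius_mm[0] != cfg.cyst_radius_mm[1] else cfg.cyst_radius_mm[0]
        r_vox = r_mm / vx
        margin = int(np.ceil(r_vox)) + 1
        # candidate centres: deep enough inside the trabecular band and
        # clear of the slice-stack boundaries
        ok = band & (ndimage.distance_transform_edt(trabecular3) > margin)
        if nz > 1:
            ok[:margin] = False
            ok[nz - margin:] = False
        idx = np.flatnonzero(ok)
        placed = False
        order = rng.permutation(idx.size)
        for j in order[: min(idx.size, 200)]:
            center = np.unravel_index(idx[j], ok.shape)
            sph = (
                _sphere_mask((nz, n, n), center, r_vox)
                if nz > 1
                else _disc((n, n), center[1:], r_vox)[None]
            )
            if not (sph & ~trabecular3).any() and not (sph & (cyst_truth > 0)).any():
                labels3[sph] = LABELS["cyst_fluid"]
                cyst_truth[sph] = i + 1
                placed = True
                break
        if not placed:
            raise ValueError(
                f"cyst {i} (radius {r_mm} mm) does not fit in the subchondral band"
            )

    cart3 = labels3 == LABELS["cartilage"]
    calc_truth = np.zeros((nz, n, n), dtype=bool)
    r_calc = cfg.calcification_radius_mm / vx
    ok = cart3 & (ndimage.distance_transform_edt(cart3) > r_calc)
    idx = np.flatnonzero(ok)
    for i in range(cfg.n_calcifications):
        if idx.size == 0:
            raise ValueError("no room for calcification inside cartilage")
        center = np.unravel_index(idx[rng.integers(idx.size)], ok.shape)
        sph = (
            _sphere_mask((nz, n, n), center, r_calc)
            if nz > 1
            else _disc((n, n), center[1:], r_calc)[None]
        )
        sph &= cart3
        labels3[sph] = LABELS["calcification"]
        calc_truth |= sph

    if nz == 1:
        labels3 = labels3[0]
        rois3 = {k: v[0] for k, v in rois3.items()}
        cyst_truth = cyst_truth[0]
        calc_truth = calc_truth[0]

    return LabeledPhantom(
        labels=labels3,
        label_to_material=_material_map(),
        voxel_size=vx,
        rois=rois3,
        truth_masks={"cysts": cyst_truth, "calcifications": calc_truth},
    )


def make_water_cylinder(config: WaterCylinderConfig | None = None) -> LabeledPhantom:
    """Uniform water disc in air, used to calibrate and verify the HU scale."""
    cfg = config or WaterCylinderConfig()
    n = cfg.grid_size
    vx = cfg.voxel_size
    fov = n * vx
    r_mm = cfg.radius_mm if cfg.radius_mm is not None else fov / 3.0
    r_vox = r_mm / vx
    if r_vox >= n / 2:
        raise ValueError("cylinder radius does not fit the grid")
    c = n / 2.0 - 0.5
    labels = np.where(_disc((n, n), (c, c), r_vox), 1, 0).astype(np.int16)
    interior = _disc((n, n), (c, c), r_vox / 2.0)
    if cfg.n_slices > 1:
        labels = np.broadcast_to(labels, (cfg.n_slices, n, n)).copy()
        interior = np.broadcast_to(interior, (cfg.n_slices, n, n)).copy()
    return LabeledPhantom(
        labels=labels,
        label_to_material={0: MATERIALS["air"], 1: MATERIALS["water"]},
        voxel_size=vx,
        rois={"interior": interior},
    )
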