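"""Synthetic MT-prepared GRE phantoms with known SNc ground truth.

The phantom emulates the geometry of a neuromelanin-sensitive acquisition:
an axial slab of 16 contiguous 2-mm slices at 0.5 x 0.5 mm in-plane
resolution, repeated 5 or 10 times. The scene is a uniform background with a
bilateral crescent-shaped hyperintense SNc (fractional contrast
``snc_contrast``) and a disjoint cerebral-peduncle reference region at
background intensity. Each measurement may be moved by a known rigid-body
transform and is corrupted by Rician noise, the magnitude-MRI convention
(Gaussian noise is available via ``noise_model``).

Ground-truth masks are voxel-aligned, so a noise-free, motion-free phantom
admits exact segmentation recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import ImageVolume, RoiMask
from .spatial import AffineTransform, rigid_matrix, resample_to_grid
from ._registration import world_center

__all__ = [
    "PhantomSpec",
    "default_affine",
    "default_masks",
    "make_atlas",
    "make_phantom",
    "rician_noise",
]

DEFAULT_VOXEL_DIMS = (0.5, 0.5, 2.0)
DEFAULT_GRID_SHAPE = (96, 96, 16)


def default_affine(voxel_dims=DEFAULT_VOXEL_DIMS, grid_shape=DEFAULT_GRID_SHAPE) -> np.ndarray:
    """RAS+ affine with the grid centre at the world origin."""
    aff = np.diag([*voxel_dims, 1.0]).astype(float)
    aff[:3, 3] = -(np.asarray(grid_shape, dtype=float) - 1.0) / 2.0 * voxel_dims
    return aff


def _mm_coords(grid_shape, affine):
    idx = np.indices(grid_shape).astype(float)
    lin, trans = affine[:3, :3], affine[:3, 3]
    return np.stack([lin[i, 0] * idx[0] + lin[i, 1] * idx[1] + lin[i, 2] * idx[2] + trans[i]
                     for i in range(3)])


def _ellipsoid(coords, center, radii) -> np.ndarray:
    d = sum(((coords[i] - center[i]) / radii[i]) ** 2 for i in range(3))
    return d <= 1.0


def default_masks(grid_shape=DEFAULT_GRID_SHAPE, affine=None, snc_voxels: int | None = None,
                  space: str = "gre") -> tuple[RoiMask, RoiMask]:
    """Bilateral crescent SNc mask and a disjoint cerebral-peduncle reference ROI.

    ``snc_voxels`` forces an exact ground-truth voxel count by deterministically
    trimming (or growing) the crescents from the outside in.
    """
    if affine is None:
        affine = default_affine(grid_shape=grid_shape)
    coords = _mm_coords(grid_shape, affine)
    snc = np.zeros(grid_shape, dtype=bool)
    cp = np.zeros(grid_shape, dtype=bool)
    for s in (-1.0, 1.0):
        # Crescent: outer ellipsoid minus a laterally/anteriorly shifted one.
        # Radii give a bilateral truth of ~380 mm^3, a realistic SNc; the small
        # opposite through-plane offsets break the z-mirror symmetry so rigid
        # registration has first-order sensitivity to out-of-plane rotations.
        outer = _ellipsoid(coords, (s * 7.0, 0.0, s * 1.0), (3.0, 5.5, 4.0))
        inner = _ellipsoid(coords, (s * 9.0, 1.5, s * 1.0), (2.5, 5.0, 3.5))
        snc |= outer & ~inner
        cp |= _ellipsoid(coords, (s * 9.0, -11.0, 0.0), (3.0, 4.0, 6.0))
    if snc.any() and cp.any() and (snc & cp).any():  # pragma: no cover - geometry guard
        raise RuntimeError("default geometry produced overlapping SNc and reference masks")

    if snc_voxels is not None:
        if snc_voxels < 1:
            raise ValueError("snc_voxels must be >= 1")
        # Signed distance to the crescent boundary: interior voxels first.
        inside = ndimage.distance_transform_edt(snc)
        outside = ndimage.distance_transform_edt(~snc)
        key = np.where(snc, -inside, outside).ravel()
        order = np.lexsort((np.arange(key.size), key))
        chosen = order[:snc_voxels]
        snc = np.zeros(np.prod(grid_shape), dtype=bool)
        snc[chosen] = True
        snc = snc.reshape(grid_shape)
        snc &= ~cp
        if int(snc.sum()) != snc_voxels:
            raise ValueError("could not realise the requested SNc voxel count disjointly")
    return RoiMask(snc, affine, space), RoiMask(cp, affine, space)


@dataclass
class PhantomSpec:
    """Parameters of one synthetic subject.

    ``motion_params`` holds one (tx, ty, tz [mm], rx, ry, rz [deg]) tuple per
    measurement; the first measurement must be motion-free (it defines the
    native frame the others are registered to).
    """

    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE
    voxel_dims: tuple[float, float, float] = DEFAULT_VOXEL_DIMS
    snc_true_mask: RoiMask | None = None
    cp_true_mask: RoiMask | None = None
    background_intensity: float = 100.0
    snc_contrast: float = 0.3
    noise_sigma: float = 0.0
    noise_model: str = "rician"
    n_measurements: int = 5
    motion_params: list | None = None
    template_to_native: AffineTransform | None = None
    rng_seed: int = 0
    snc_voxels: int | None = None

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_dims):
            raise ValueError("voxel_dims must be strictly positive")
        if self.n_measurements < 1:
            raise ValueError("n_measurements must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_model not in ("rician", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.snc_true_mask is None or self.cp_true_mask is None:
            snc, cp = default_masks(self.grid_shape, self.affine, self.snc_voxels)
            self.snc_true_mask = self.snc_true_mask or snc
            self.cp_true_mask = self.cp_true_mask or cp
        if (self.snc_true_mask.data & self.cp_true_mask.data).any():
            raise ValueError("snc_true_mask and cp_true_mask must be disjoint")
        if self.motion_params is not None:
            if len(self.motion_params) != self.n_measurements:
                raise ValueError("motion_params must have one entry per measurement")
            if np.any(np.abs(np.asarray(self.motion_params[0], dtype=float)) > 1e-12):
                raise ValueError("the first measurement must be motion-free")
        if self.template_to_native is None:
            self.template_to_native = AffineTransform.identity("template", "gre")
        if abs(np.linalg.det(self.template_to_native.matrix[:3, :3])) < 1e-12:
            raise ValueError("template_to_native must be invertible")

    @property
    def affine(self) -> np.ndarray:
        return default_affine(self.voxel_dims, self.grid_shape)


def rician_noise(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of a complex signal with i.i.d. Gaussian channel noise."""
    if sigma == 0:
        return np.asarray(signal, dtype=float).copy()
    re = signal + rng.normal(0.0, sigma, size=np.shape(signal))
    im = rng.normal(0.0, sigma, size=np.shape(signal))
    return np.hypot(re, im)


def _dilated_fits(mask: np.ndarray, margin: int = 2) -> bool:
    grown = ndimage.binary_dilation(mask, ndimage.generate_binary_structure(3, 1),
                                    iterations=margin)
    edge = np.zeros_like(grown)
    edge[0], edge[-1] = True, True
    edge[:, 0], edge[:, -1] = True, True
    edge[:, :, 0], edge[:, :, -1] = True, True
    return not (grown & edge).any()


def _t1_anatomy(grid_shape, affine) -> np.ndarray:
    """Smooth anatomical-like volume: brainstem ellipsoid plus internal blobs.

    Feature sizes scale with the field of view so the anatomy stays interior
    to the grid — content touching the volume edge would bias intensity-based
    registration of this image.
    """
    coords = _mm_coords(grid_shape, affine)
    fov = np.asarray(grid_shape, dtype=float) * np.linalg.norm(affine[:3, :3], axis=0)
    radii = 0.36 * fov
    base = 300.0 + 500.0 * _ellipsoid(coords, (0.0, -0.04 * fov[1], 0.0), radii)
    r_blob = 0.10 * fov.min()
    for (fx, fy, fz), amp in (((0.0, 0.12, 0.10), 180.0),
                              ((-0.16, -0.12, -0.18), -120.0),
                              ((0.18, 0.06, 0.22), 140.0)):
        cx, cy, cz = fx * fov[0], fy * fov[1], fz * fov[2]
        d2 = ((coords[0] - cx) ** 2 + (coords[1] - cy) ** 2
              + (coords[2] - cz) ** 2) / r_blob**2
        base = base + amp * np.exp(-d2)
    sigma_vox = 1.5 / np.linalg.norm(affine[:3, :3], axis=0)
    return ndimage.gaussian_filter(base, sigma_vox)


def make_atlas(snc_template_mask: RoiMask, sigma_mm: float = 2.0) -> ImageVolume:
    """Probabilistic SNc atlas: the template-space truth smoothed to [0, 1]."""
    sigma_vox = sigma_mm / snc_template_mask.voxel_dims
    prob = ndimage.gaussian_filter(snc_template_mask.data.astype(float), sigma_vox)
    peak = prob.max()
    if peak > 0:
        prob = prob / peak
    return ImageVolume(prob, snc_template_mask.affine, snc_template_mask.space)


def make_phantom(spec: PhantomSpec):
    """Simulate one subject: measurement stack, T1 image and ground truth.

    Returns ``(measurements, t1_image, truth)`` where ``truth`` carries
    ``snc_true_mask``, ``cp_true_mask`` and ``template_to_native``. Identical
    seeds give bit-identical output.
    """
    affine = spec.affine
    if not _dilated_fits(spec.snc_true_mask.data):
        raise ValueError("dilated SNc search region would exceed the grid; "
                         "use a larger grid or a smaller ground-truth mask")
    scene = np.full(spec.grid_shape, float(spec.background_intensity))
    scene[spec.snc_true_mask.data] = spec.background_intensity * (1.0 + spec.snc_contrast)
    scene_vol = ImageVolume(scene, affine, "gre")
    center = world_center(scene_vol)

    rng = np.random.default_rng(spec.rng_seed)
    measurements: list[ImageVolume] = []
    for m in range(spec.n_measurements):
        params = None if spec.motion_params is None else np.asarray(
            spec.motion_params[m], dtype=float)
        if m == 0 or params is None or not np.any(np.abs(params) > 1e-12):
            moved = scene.copy()
        else:
            motion = AffineTransform(rigid_matrix(params, center), "gre", "gre")
            moved = resample_to_grid(scene_vol, motion, spec.grid_shape, affine).data
        if spec.noise_model == "rician":
            noisy = rician_noise(moved, spec.noise_sigma, rng)
        else:
            noisy = moved + rng.normal(0.0, spec.noise_sigma, size=moved.shape) \
                if spec.noise_sigma > 0 else moved
        measurements.append(ImageVolume(noisy, affine, "gre"))

    t1 = ImageVolume(_t1_anatomy(spec.grid_shape, affine), affine, "t1")
    truth = {
        "snc_true_mask": spec.snc_true_mask,
        "cp_true_mask": spec.cp_true_mask,
        "template_to_native": spec.template_to_native,
    }
    return measurements, t1, truth
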