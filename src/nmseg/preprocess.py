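"""Per-subject preprocessing of an MT-GRE measurement stack.

The stages run in the fixed order denoise -> motion-correct -> average: each
repeated measurement is denoised, rigidly registered to the first measurement,
and the aligned stack is averaged voxel-wise into the image that is
segmented. The order is enforced by the pipeline driver; the individual
operations are exposed for testing and reuse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import ImageVolume, grids_match
from .spatial import AffineTransform, resample_to_grid
from ._registration import RegistrationError, register

__all__ = ["MeasurementStack", "denoise_stack", "motion_correct", "average_stack"]

logger = logging.getLogger(__name__)

GAUSSIAN_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class MeasurementStack:
    """Ordered repeated measurements on a common grid plus acquisition metadata."""

    measurements: list[ImageVolume]
    metadata: dict = field(default_factory=dict)  # TE, TR, flip angle: carried, unused

    def __post_init__(self) -> None:
        if not self.measurements:
            raise ValueError("a stack needs at least one measurement")
        first = self.measurements[0]
        for m in self.measurements[1:]:
            if not grids_match(first, m):
                raise ValueError("all measurements must share grid shape and affine")

    def __len__(self) -> int:
        return len(self.measurements)

    @property
    def grid_shape(self):
        return self.measurements[0].shape

    @property
    def affine(self):
        return self.measurements[0].affine


def _mppca_patch(patch_stack: np.ndarray) -> np.ndarray:
    """Shrink one (n_voxels, n_measurements) patch matrix by PCA.

    The per-voxel mean across measurements (the repeated signal) is always
    kept; PCA shrinkage acts only on the across-measurement residual. Rank
    selection follows the Marchenko-Pastur idea: trailing eigenvalues are
    attributed to noise when they fall below the bulk edge a pure-noise
    spectrum of that size would have, and those components are discarded.
    For an already-aligned stack the residual is pure noise, so the output
    reduces to the per-voxel measurement mean; inter-measurement structure
    (e.g. residual motion) survives as above-edge components.
    """
    X = patch_stack
    n, m = X.shape
    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    lam = s**2 / n  # eigenvalues of the m x m residual covariance
    if lam[0] <= 0:
        return X.copy()
    r = len(lam)
    for k in range(len(lam)):
        tail = lam[k:]
        sigma2 = tail.mean()
        # MP bulk edge for an (n x (m - k)) pure-noise matrix.
        gamma = len(tail) / n
        edge = sigma2 * (1.0 + np.sqrt(gamma)) ** 2
        if lam[k] <= edge:
            r = k
            break
    if r >= len(lam):
        return X.copy()
    s_shrunk = s.copy()
    s_shrunk[r:] = 0.0
    return (U * s_shrunk) @ Vt + mean


def denoise_stack(stack: MeasurementStack, method: str = "patch_pca",
                  params: dict | None = None) -> MeasurementStack:
    """Denoise a stack; output lives on the same grid.

    Methods: ``patch_pca`` (local patch principal-component shrinkage across
    measurements), ``gaussian`` (isotropic smoothing of stated ``fwhm_mm``),
    ``none`` (pass-through).
    """
    params = dict(params or {})
    if method == "none":
        return stack
    if method == "gaussian":
        fwhm = float(params.get("fwhm_mm", 1.0))
        out = []
        for m in stack.measurements:
            sigma_vox = fwhm * GAUSSIAN_FWHM_TO_SIGMA / m.voxel_dims
            out.append(m.with_data(ndimage.gaussian_filter(m.data.astype(float), sigma_vox)))
        return MeasurementStack(out, dict(stack.metadata))
    if method == "patch_pca":
        if len(stack) == 1:
            return stack
        patch = int(params.get("patch_size", 4))
        data = np.stack([m.data.astype(float) for m in stack.measurements], axis=-1)
        out = np.empty_like(data)
        nx, ny, nz, _ = data.shape
        for i0 in range(0, nx, patch):
            for j0 in range(0, ny, patch):
                for k0 in range(0, nz, patch):
                    sl = (slice(i0, min(i0 + patch, nx)),
                          slice(j0, min(j0 + patch, ny)),
                          slice(k0, min(k0 + patch, nz)))
                    block = data[sl]
                    flat = block.reshape(-1, block.shape[-1])
                    out[sl] = _mppca_patch(flat).reshape(block.shape)
        vols = [stack.measurements[i].with_data(out[..., i]) for i in range(len(stack))]
        return MeasurementStack(vols, dict(stack.metadata))
    raise ValueError(f"unknown denoising method {method!r}")


def motion_correct(stack: MeasurementStack):
    """Rigidly register every measurement to the first one.

    Returns ``(corrected_stack, transforms)`` where ``transforms[i]`` maps
    measurement ``i`` into measurement-1 space (the first entry is the
    identity). A measurement whose registration fails to improve on identity
    falls back to the identity transform with a logged warning.
    """
    first = stack.measurements[0]
    corrected = [first]
    transforms = [AffineTransform.identity(first.space, first.space)]
    from .spatial import rigid_params
    from ._registration import world_center

    center = world_center(first)
    for i, meas in enumerate(stack.measurements[1:], start=2):
        try:
            t = register(meas, first, dof=6)
        except RegistrationError as exc:
            logger.warning("measurement %d: registration failed (%s); keeping identity",
                           i, exc)
            t = AffineTransform.identity(first.space, first.space)
        # Snap numerically-negligible estimates to the exact identity so an
        # already-aligned measurement is passed through without resampling.
        p = rigid_params(t.matrix, center)
        if np.all(np.abs(p[:3]) < 5e-3) and np.all(np.abs(p[3:]) < 5e-3):
            t = AffineTransform.identity(first.space, first.space)
        transforms.append(t)
        if np.allclose(t.matrix, np.eye(4)):
            corrected.append(meas)
        else:
            corrected.append(resample_to_grid(meas, t, first.shape, first.affine))
    return MeasurementStack(corrected, dict(stack.metadata)), transforms


def average_stack(stack: MeasurementStack) -> ImageVolume:
    """Voxel-wise arithmetic mean of the measurements."""
    data = np.mean([m.data.astype(float) for m in stack.measurements], axis=0)
    return stack.measurements[0].with_data(data)
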