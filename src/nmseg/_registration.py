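"""Intensity-based affine registration: NCC metric, Powell optimiser.

Mono-modal registration for same-contrast volumes (repeated MT-GRE
measurements, synthetic T1 pairs). The similarity is the normalised
cross-correlation of the fixed image with the moving image resampled through
the candidate transform (trilinear, constant padding at the border median),
optimised by Powell's method after a multi-start search over coarse
translations. Rotations are parameterised about the fixed image's world
centre so translation and rotation parameters are well scaled.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, optimize

from .image import ImageVolume
from .spatial import AffineTransform, resample_to_grid, rigid_matrix

__all__ = ["RegistrationError", "register", "world_center"]


class RegistrationError(RuntimeError):
    """The optimiser failed to improve on the identity transform."""


def world_center(image: ImageVolume) -> np.ndarray:
    """World coordinates of the grid centre."""
    c_vox = (np.asarray(image.shape, dtype=float) - 1.0) / 2.0
    return image.affine[:3, :3] @ c_vox + image.affine[:3, 3]


def _affine_matrix(params, center) -> np.ndarray:
    """12-dof matrix: rigid params + log-scales + shears, about ``center``."""
    p = np.asarray(params, dtype=float)
    m = rigid_matrix(p[:6], center)
    if p.size == 6:
        return m
    sx, sy, sz = np.exp(p[6:9])
    hxy, hxz, hyz = p[9:12]
    S = np.diag([sx, sy, sz])
    H = np.array([[1.0, hxy, hxz], [0.0, 1.0, hyz], [0.0, 0.0, 1.0]])
    c = np.asarray(center, dtype=float)
    A = m[:3, :3] @ H @ S
    out = np.eye(4)
    out[:3, :3] = A
    out[:3, 3] = m[:3, 3] + (m[:3, :3] - A) @ c
    return out


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


def _params_to_transform(params, center, moving, fixed) -> AffineTransform:
    return AffineTransform(_affine_matrix(params, center), moving.space, fixed.space)


def register(moving: ImageVolume, fixed: ImageVolume, dof: int = 6,
             initial_params=None, coarse_search: bool = True,
             smooth_sigma_vox: float = 3.0, decimate: bool = True) -> AffineTransform:
    """Estimate the transform maximising NCC(fixed, moving ∘ T⁻¹).

    Returns the world transform T such that resampling ``moving`` through T
    onto the fixed grid aligns it with ``fixed``. The metric is evaluated on
    smoothed, in-plane 2x-decimated copies (the transform itself is expressed
    in world mm, so the result is resolution independent); set
    ``decimate=False`` to optimise at full resolution.
    """
    if dof not in (6, 12):
        raise ValueError("dof must be 6 or 12")
    center = world_center(fixed)

    # Smooth both images a little so the NCC surface is smooth in subvoxel
    # shifts; the kernel is specified in mm so anisotropic slabs (thin
    # in-plane voxels, thick slices) are not over-blurred through-plane.
    vx = np.linalg.norm(fixed.affine[:3, :3], axis=0)
    sigma = smooth_sigma_vox * np.min(vx) / vx
    fdat = ndimage.gaussian_filter(fixed.data.astype(float), sigma)
    mdat = ndimage.gaussian_filter(moving.data.astype(float), sigma)
    f_aff, m_aff = fixed.affine, moving.affine
    if decimate and min(fixed.shape[0], fixed.shape[1]) >= 48:
        scale = np.diag([2.0, 2.0, 1.0, 1.0])
        fdat, mdat = fdat[::2, ::2, :], mdat[::2, ::2, :]
        f_aff, m_aff = f_aff @ scale, m_aff @ scale
    mov_s = ImageVolume(mdat, m_aff, moving.space)

    def objective(params) -> float:
        t = _params_to_transform(params, center, moving, fixed)
        res = resample_to_grid(mov_s, t, fdat.shape, f_aff)
        return -_ncc(fdat, res.data)

    n_par = 6 if dof == 6 else 12
    x0 = np.zeros(n_par)
    if initial_params is not None:
        x0[: len(initial_params)] = initial_params

    f_identity = objective(np.zeros(n_par))
    best_x, best_f = x0.copy(), objective(x0)

    if coarse_search:
        # Multi-start over coarse in-plane/through-plane translations (mm).
        steps = np.array([0.0, -2.0, 2.0, -4.0, 4.0])
        vx = np.linalg.norm(fixed.affine[:3, :3], axis=0)
        for dx in steps * vx[0] / 2.0:
            for dy in steps * vx[1] / 2.0:
                for dz in (0.0, -vx[2], vx[2]):
                    cand = x0.copy()
                    cand[:3] = x0[:3] + [dx, dy, dz]
                    f = objective(cand)
                    if f < best_f:
                        best_x, best_f = cand, f

    res = optimize.minimize(objective, best_x, method="Powell",
                            options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 50})
    x_opt, f_opt = (res.x, res.fun) if res.fun <= best_f else (best_x, best_f)

    if not np.isfinite(f_opt) or f_opt > f_identity + 1e-12:
        raise RegistrationError(
            f"registration did not improve on identity (NCC {-f_opt:.6f} "
            f"vs {-f_identity:.6f})")
    return _params_to_transform(x_opt, center, moving, fixed)
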