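"""World-space affine transforms, transform chains and single-step resampling.

The pipeline moves ROIs between three coordinate frames — template space, T1
space and native MT-GRE space. Every mapping is an invertible affine on RAS+
world coordinates (mm). When an object must cross several frames the chain is
composed into a single matrix and exactly one resampling is performed, which
avoids compounding interpolation error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import ImageVolume, RoiMask

__all__ = [
    "AffineTransform",
    "TransformChain",
    "compose",
    "invert",
    "rigid_matrix",
    "rigid_params",
    "resample_to_grid",
    "compose_and_resample",
    "estimate_affine",
]


@dataclass
class AffineTransform:
    """Invertible affine mapping world coordinates of ``source`` into ``target``.

    ``matrix`` is a 4x4 homogeneous matrix acting on RAS+ mm coordinates:
    ``w_target = matrix @ w_source``.
    """

    matrix: np.ndarray
    source: str = "source"
    target: str = "target"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("transform has a singular linear part")

    @classmethod
    def identity(cls, source: str = "source", target: str = "target") -> "AffineTransform":
        return cls(np.eye(4), source, target)

    @classmethod
    def translation(cls, t, source: str = "source", target: str = "target") -> "AffineTransform":
        m = np.eye(4)
        m[:3, 3] = np.asarray(t, dtype=float)
        return cls(m, source, target)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array of world points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]
        return out if np.asarray(points).ndim == 2 else out[0]

    def save(self, path) -> None:
        """Plain-text 4x4 matrix with a JSON sidecar for the space labels."""
        np.savetxt(str(path), self.matrix, fmt="%.17g")
        with open(str(path) + ".json", "w") as fh:
            json.dump({"source": self.source, "target": self.target}, fh)

    @classmethod
    def load(cls, path) -> "AffineTransform":
        matrix = np.loadtxt(str(path))
        source, target = "source", "target"
        try:
            with open(str(path) + ".json") as fh:
                labels = json.load(fh)
            source, target = labels["source"], labels["target"]
        except FileNotFoundError:
            pass
        return cls(matrix, source, target)


def compose(*transforms: AffineTransform) -> AffineTransform:
    """Compose transforms in application order: the first is applied first."""
    if not transforms:
        raise ValueError("compose requires at least one transform")
    matrix = np.eye(4)
    for t in transforms:
        matrix = t.matrix @ matrix
    return AffineTransform(matrix, transforms[0].source, transforms[-1].target)


def invert(transform: AffineTransform) -> AffineTransform:
    """Matrix inverse with the space labels swapped."""
    return AffineTransform(np.linalg.inv(transform.matrix), transform.target, transform.source)


@dataclass
class TransformChain:
    """An ordered list of affine steps composing to one invertible mapping."""

    transforms: list[AffineTransform] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in zip(self.transforms, self.transforms[1:]):
            if a.target != b.source:
                raise ValueError(f"chain breaks: {a.target!r} -> {b.source!r}")

    @property
    def source(self) -> str:
        return self.transforms[0].source if self.transforms else "any"

    @property
    def target(self) -> str:
        return self.transforms[-1].target if self.transforms else "any"

    def composed(self) -> AffineTransform:
        if not self.transforms:
            return AffineTransform.identity("any", "any")
        return compose(*self.transforms)

    @classmethod
    def identity(cls) -> "TransformChain":
        return cls([])


# -- rigid-body parameterisation ------------------------------------------------

def rigid_matrix(params, center=(0.0, 0.0, 0.0)) -> np.ndarray:
    """4x4 rigid-body matrix from (tx, ty, tz [mm], rx, ry, rz [deg]).

    Rotation is ``Rz @ Ry @ Rx`` about the world point ``center``.
    """
    tx, ty, tz, rx, ry, rz = np.asarray(params, dtype=float)
    ax, ay, az = np.deg2rad([rx, ry, rz])
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    R = Rz @ Ry @ Rx
    c = np.asarray(center, dtype=float)
    m = np.eye(4)
    m[:3, :3] = R
    m[:3, 3] = c + np.array([tx, ty, tz]) - R @ c
    return m


def rigid_params(matrix: np.ndarray, center=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Inverse of :func:`rigid_matrix` for proper rigid matrices."""
    matrix = np.asarray(matrix, dtype=float)
    R = matrix[:3, :3]
    ry = np.arcsin(np.clip(-R[2, 0], -1.0, 1.0))
    rx = np.arctan2(R[2, 1], R[2, 2])
    rz = np.arctan2(R[1, 0], R[0, 0])
    c = np.asarray(center, dtype=float)
    t = matrix[:3, 3] - c + R @ c
    return np.array([t[0], t[1], t[2], np.rad2deg(rx), np.rad2deg(ry), np.rad2deg(rz)])


# -- resampling -----------------------------------------------------------------

def _voxel_map(src_affine, transform_matrix, tgt_affine) -> tuple[np.ndarray, np.ndarray]:
    """Target-voxel -> source-voxel mapping for scipy.ndimage.affine_transform."""
    m = np.linalg.inv(src_affine) @ np.linalg.inv(transform_matrix) @ tgt_affine
    return m[:3, :3], m[:3, 3]


def resample_to_grid(obj, transform: AffineTransform, target_shape, target_affine,
                     order: int | None = None, cval: float | None = None,
                     target_space: str | None = None):
    """Resample an image or mask through a world transform onto a target grid.

    Masks default to nearest-neighbour (order 0) and stay strictly binary;
    scalar images default to trilinear (order 1) with constant padding at the
    border median (``cval`` overrides).
    """
    is_mask = isinstance(obj, RoiMask)
    if order is None:
        order = 0 if is_mask else 1
    data = obj.data.astype(float)
    if cval is None:
        if is_mask:
            cval = 0.0
        else:
            border = np.concatenate([
                data[0].ravel(), data[-1].ravel(),
                data[:, 0].ravel(), data[:, -1].ravel(),
                data[:, :, 0].ravel(), data[:, :, -1].ravel(),
            ])
            cval = float(np.median(border))
    mat, off = _voxel_map(obj.affine, transform.matrix, np.asarray(target_affine, dtype=float))
    out = ndimage.affine_transform(data, mat, offset=off, output_shape=tuple(target_shape),
                                   order=order, mode="constant", cval=cval)
    space = target_space if target_space is not None else transform.target
    if is_mask:
        return RoiMask(out > 0.5 if order > 0 else out.astype(bool),
                       np.asarray(target_affine, dtype=float), space)
    return ImageVolume(out, np.asarray(target_affine, dtype=float), space)


def compose_and_resample(obj, chain: TransformChain, target, order: int | None = None,
                         cval: float | None = None):
    """Warp an image or ROI through a whole chain with a single resampling.

    ``target`` is an ImageVolume/RoiMask defining the output grid. The chain is
    composed into one matrix so exactly one interpolation is performed.
    """
    composed = chain.composed()
    if chain.transforms:
        if obj.space not in (composed.source, "any"):
            raise ValueError(
                f"object lives in space {obj.space!r} but chain starts at {composed.source!r}")
        if target.space not in (composed.target, "any"):
            raise ValueError(
                f"target grid is in space {target.space!r} but chain ends at {composed.target!r}")
        composed = AffineTransform(composed.matrix, obj.space, target.space)
    else:
        composed = AffineTransform.identity(obj.space, target.space)
    return resample_to_grid(obj, composed, target.shape, target.affine, order=order,
                            cval=cval, target_space=target.space)


# -- registration ---------------------------------------------------------------

def estimate_affine(moving: ImageVolume, fixed: ImageVolume, dof: int = 6,
                    initial_params=None, coarse_search: bool = True) -> AffineTransform:
    """Estimate the world transform aligning ``moving`` to ``fixed``.

    Maximises normalised cross-correlation with trilinear interpolation.
    ``dof=6`` estimates a rigid-body transform, ``dof=12`` a full affine
    (rigid + anisotropic scales + shears). Raises ``RegistrationError`` when
    the optimum does not improve on the identity.
    """
    from ._registration import register

    return register(moving, fixed, dof=dof, initial_params=initial_params,
                    coarse_search=coarse_search)
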