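"""Group-level population maps in template space.

Individual SNc masks (or contrast images) are warped to the template grid —
one composed resampling each — and averaged voxel-wise. Warped masks are
treated as fractional occupancies (trilinear interpolation), so a mask-derived
population map is the per-voxel proportion of subjects whose SNc covers that
voxel; a nearest-neighbour dialect is available. The companion statistic is
the mean of that proportion over a template-space sub-ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import ImageVolume, RoiMask, grids_match
from .spatial import TransformChain, compose_and_resample

__all__ = ["PopulationMap", "population_mean", "proportion_in_roi"]


@dataclass
class PopulationMap:
    mean_map: ImageVolume
    n_subjects: int
    group_label: str = ""
    kind: str = "mask"  # "mask" (values are proportions) or "image"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.kind == "mask":
            v = self.mean_map.data
            if v.min() < -1e-9 or v.max() > 1 + 1e-9:
                raise ValueError("mask-derived population map must lie in [0, 1]")


def population_mean(items, template_grid: ImageVolume, group_label: str = "",
                    mask_interpolation: str = "trilinear") -> PopulationMap:
    """Average subject masks or images on the template grid.

    ``items`` is a sequence of ``(mask_or_image, chain_to_template)`` pairs.
    Masks become fractional occupancy maps; scalar images are averaged in
    signal units.
    """
    items = list(items)
    if not items:
        raise ValueError("population_mean needs at least one subject")
    if mask_interpolation not in ("trilinear", "nearest"):
        raise ValueError(f"unknown mask interpolation {mask_interpolation!r}")
    accum = np.zeros(template_grid.shape, dtype=float)
    kind = "mask"
    for obj, chain in items:
        if isinstance(obj, RoiMask):
            if mask_interpolation == "nearest":
                warped = compose_and_resample(obj, chain, template_grid, order=0)
                data = warped.data.astype(float)
            else:
                as_img = ImageVolume(obj.data.astype(float), obj.affine, obj.space)
                warped = compose_and_resample(as_img, chain, template_grid, order=1, cval=0.0)
                data = np.clip(warped.data, 0.0, 1.0)
        else:
            kind = "image"
            warped = compose_and_resample(obj, chain, template_grid, order=1)
            data = warped.data
        if data.shape != tuple(template_grid.shape):
            raise ValueError("warped subject does not match the template grid")
        accum += data
    mean = accum / len(items)
    return PopulationMap(ImageVolume(mean, template_grid.affine, template_grid.space),
                         n_subjects=len(items), group_label=group_label, kind=kind)


def proportion_in_roi(pop_map: PopulationMap, sub_roi: RoiMask) -> float:
    """Mean population-map value over a template-space sub-ROI.

    For mask-derived maps this is the expected proportion of subjects sharing
    a voxel of the sub-ROI.
    """
    if not grids_match(pop_map.mean_map, sub_roi):
        raise ValueError("sub-ROI must live on the population-map grid")
    if not sub_roi.data.any():
        raise ValueError("sub-ROI is empty")
    return float(pop_map.mean_map.data[sub_roi.data].mean())
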