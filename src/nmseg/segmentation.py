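"""Reference-ROI statistics and atlas-constrained SNc threshold segmentation.

The core rule: a voxel inside the atlas-derived search region belongs to SNc
when its intensity strictly exceeds mu_ref + k * sigma_ref, where mu_ref and
sigma_ref are the mean and standard deviation of the averaged MT-GRE signal
inside a cerebral-peduncle reference ROI and k defaults to 2.8. The search
region is the probabilistic SNc atlas thresholded (strictly) at 5%, dilated,
and warped from template space to the native GRE grid in a single composed
resampling. Nigral volume is the suprathreshold voxel count times the voxel
volume.

sigma_ref uses the population convention (divide by n); the ROI voxel count
is large enough that the distinction is immaterial, and the choice is
configurable via ``ddof``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import ImageVolume, RoiMask, grids_match
from .spatial import TransformChain, compose_and_resample

__all__ = [
    "ReferenceStats",
    "SegmentationResult",
    "reference_stats",
    "build_search_roi",
    "segment_snc",
    "mtc_map",
]

DEFAULT_K = 2.8
DEFAULT_PROB_THRESHOLD = 0.05


@dataclass
class ReferenceStats:
    mu_ref: float
    sigma_ref: float
    n_voxels: int

    def __post_init__(self) -> None:
        if self.sigma_ref < 0:
            raise ValueError("sigma_ref must be >= 0")
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")


@dataclass
class SegmentationResult:
    snc_mask: RoiMask
    reference: ReferenceStats
    k: float
    threshold: float
    voxel_count: int
    volume_mm3: float
    search_roi: RoiMask


def reference_stats(image: ImageVolume, cp_mask: RoiMask, ddof: int = 0) -> ReferenceStats:
    """Mean and standard deviation of the signal inside the reference ROI."""
    if not grids_match(image, cp_mask):
        raise ValueError("reference mask must live on the image grid")
    values = image.data[cp_mask.data]
    if values.size == 0:
        raise ValueError("reference ROI is empty (failed ROI transfer?)")
    return ReferenceStats(float(values.mean()), float(values.std(ddof=ddof)),
                          int(values.size))


def build_search_roi(atlas: ImageVolume, chain: TransformChain, target: ImageVolume,
                     prob_threshold: float = DEFAULT_PROB_THRESHOLD,
                     dilation_radius_voxels: int = 1) -> RoiMask:
    """Threshold and dilate the probabilistic atlas, then warp to the GRE grid.

    The atlas is binarised at ``prob_threshold`` (strict >), dilated with a
    city-block ball of the given radius (6-connected structuring element,
    iterated), and transformed to the native grid with a single composed
    nearest-neighbour resampling.
    """
    prob = np.asarray(atlas.data, dtype=float)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("atlas values must lie in [0, 1]")
    binary = prob > prob_threshold
    if not binary.any():
        raise ValueError("atlas threshold produced an empty mask")
    if dilation_radius_voxels > 0:
        struct = ndimage.generate_binary_structure(3, 1)
        binary = ndimage.binary_dilation(binary, struct,
                                         iterations=int(dilation_radius_voxels))
    mask = RoiMask(binary, atlas.affine, atlas.space)
    warped = compose_and_resample(mask, chain, target, order=0)
    if not warped.data.any():
        raise ValueError("search ROI is empty after warping to the native grid")
    return warped


def segment_snc(image: ImageVolume, search_roi: RoiMask, reference: ReferenceStats,
                k: float = DEFAULT_K) -> SegmentationResult:
    """Apply the strict intensity rule I > mu_ref + k*sigma_ref inside the ROI."""
    if not grids_match(image, search_roi):
        raise ValueError("search ROI must live on the image grid")
    if not search_roi.data.any():
        raise ValueError("search ROI is empty")
    roi_values = image.data[search_roi.data]
    if np.isnan(roi_values).any():
        raise ValueError("NaN intensities inside the search ROI")
    threshold = reference.mu_ref + k * reference.sigma_ref
    mask_data = search_roi.data & (image.data > threshold)
    mask = RoiMask(mask_data, image.affine, image.space)
    count = int(mask_data.sum())
    return SegmentationResult(
        snc_mask=mask,
        reference=reference,
        k=float(k),
        threshold=float(threshold),
        voxel_count=count,
        volume_mm3=count * image.voxel_volume_mm3,
        search_roi=search_roi,
    )


def largest_components(mask: RoiMask, n_keep: int = 2) -> RoiMask:
    """Optional post-filter keeping the ``n_keep`` largest connected components."""
    labels, n = ndimage.label(mask.data)
    if n <= n_keep:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.argsort(sizes)[::-1][:n_keep] + 1
    return RoiMask(np.isin(labels, keep), mask.affine, mask.space)


def mtc_map(image: ImageVolume, reference: ReferenceStats) -> ImageVolume:
    """Reference-normalised contrast image: (I - mu_ref) / mu_ref."""
    if reference.mu_ref <= 0:
        raise ValueError("mu_ref must be positive for contrast normalisation")
    return image.with_data((image.data - reference.mu_ref) / reference.mu_ref)
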