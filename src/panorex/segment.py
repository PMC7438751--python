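"""Dental-arch segmentation on the reference axial slice.

The arch mask is produced by the classical chain for CBCT dental data:
global thresholding at the enamel level (1500 HU), selection of the axial
slice with the most segmented voxels (the tips of the teeth), a 20x20
morphological dilation to bridge gaps left by missing teeth, Gaussian
smoothing of the binary mask, and retention of the largest 8-connected
component.  All defaults follow that recipe and are exposed through
:class:`SegmentationConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .errors import ConfigError, SegmentationEmptyError
from .volume import CTVolume

__all__ = [
    "SegmentationConfig",
    "threshold_volume",
    "select_reference_slice",
    "connect_regions",
    "smooth_mask",
    "largest_component",
    "segment_arch",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters of the segmentation chain (defaults: enamel threshold
    1500 HU, 20x20 dilation, Gaussian sigma 4 px, re-binarization at 0.5)."""

    threshold_hu: float = 1500.0
    dilation_size: tuple[int, int] = (20, 20)
    gaussian_sigma: float = 4.0
    rebinarize_level: float = 0.5

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold_hu):
            raise ConfigError("threshold_hu must be finite")
        if len(self.dilation_size) != 2 or any(int(s) < 1 for s in self.dilation_size):
            raise ConfigError(f"dilation_size components must be >= 1, got {self.dilation_size}")
        if not (self.gaussian_sigma > 0):
            raise ConfigError(f"gaussian_sigma must be > 0, got {self.gaussian_sigma}")
        if not (0.0 < self.rebinarize_level < 1.0):
            raise ConfigError(
                f"rebinarize_level must be in (0, 1), got {self.rebinarize_level}"
            )


def threshold_volume(volume: CTVolume, threshold_hu: float) -> np.ndarray:
    """Binary volume of voxels at or above ``threshold_hu`` (inclusive)."""
    return volume.voxels >= threshold_hu


def select_reference_slice(binary_volume: np.ndarray) -> int:
    """Index of the axial slice with the most segmented voxels.

    Ties break toward the smallest index (numpy argmax convention).
    """
    counts = binary_volume.reshape(binary_volume.shape[0], -1).sum(axis=1)
    if counts.sum() == 0:
        raise SegmentationEmptyError(
            "no enamel-range voxels; check threshold/units"
        )
    return int(np.argmax(counts))


def _dilation_origin(size: tuple[int, int]) -> tuple[int, int]:
    # place the structuring-element origin at the floor-center index
    # floor((s-1)/2); for even sizes this shifts scipy's default by -1
    return tuple((int(s) - 1) // 2 - int(s) // 2 for s in size)


def connect_regions(mask: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Bridge disjoint tooth regions with a rectangular all-ones dilation."""
    structure = np.ones(tuple(int(s) for s in cfg.dilation_size), dtype=bool)
    return ndi.binary_dilation(mask, structure=structure, origin=_dilation_origin(cfg.dilation_size))


def smooth_mask(mask: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Gaussian-smooth the {0,1} cast of the mask and re-binarize.

    A pixel survives when the blurred value exceeds ``rebinarize_level``
    (strictly), so an isolated pixel vanishes at sigma=4 while a filled
    region keeps its symmetric 0.5 level set.
    """
    blurred = ndi.gaussian_filter(mask.astype(np.float64), sigma=cfg.gaussian_sigma)
    return blurred > cfg.rebinarize_level


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected component.

    Size ties break toward the component containing the smallest pixel in
    raster order.
    """
    if not mask.any():
        raise SegmentationEmptyError("mask is empty; nothing to segment")
    labels = measure.label(mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = counts.max()
    tied = np.flatnonzero(counts == best)
    if len(tied) > 1:
        # raster-order scan: first tied label encountered wins
        flat = labels.ravel()
        first = {lab: np.argmax(flat == lab) for lab in tied}
        winner = min(tied, key=lambda lab: first[lab])
    else:
        winner = tied[0]
    return labels == winner


def segment_arch(
    volume: CTVolume, cfg: SegmentationConfig | None = None
) -> tuple[int, np.ndarray]:
    """Run the full chain and return ``(reference_slice_index, arch_mask)``.

    The mask is a single 8-connected component on the reference slice.
    """
    cfg = cfg or SegmentationConfig()
    row_mm, col_mm = volume.spacing[1], volume.spacing[2]
    if abs(row_mm - col_mm) > 0.1 * max(row_mm, col_mm):
        log.warning(
            "in-plane anisotropy %.3g vs %.3g mm exceeds 10%%; the 2D arch "
            "curve is fitted in pixel units and will be distorted",
            row_mm,
            col_mm,
        )
    binary = threshold_volume(volume, cfg.threshold_hu)
    index = select_reference_slice(binary)
    mask = binary[index]
    mask = connect_regions(mask, cfg)
    mask = smooth_mask(mask, cfg)
    if not mask.any():
        raise SegmentationEmptyError(
            "segmentation vanished after smoothing; structure too thin for "
            f"sigma={cfg.gaussian_sigma}"
        )
    return index, largest_component(mask)
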