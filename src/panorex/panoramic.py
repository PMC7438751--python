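"""Offset-curve families and average-intensity-projection panoramic synthesis.

The fitted arch curve B(t) is swept across the arch thickness by parallel
offset curves: at each sample the derivative B'(t) is rotated 90 degrees
counterclockwise, normalized, and the point displaced by k*q along that
normal for offset indices k = -K..+K (k = 0 is the arch curve itself).
Every axial slice is sampled along every offset curve and the panoramic
image assigns pixel (z, i) the mean across offsets — an average intensity
projection through the arch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage as ndi

from .bezier import BezierCurve, FitConfig, bezier_derivative, bezier_eval, fit_bezier
from .errors import DegenerateCurveError, InputError
from .segment import SegmentationConfig, segment_arch
from .skeleton import medial_axis, prune_and_order
from .volume import CTVolume

__all__ = [
    "OffsetFamily",
    "PanoramicImage",
    "offset_curves",
    "sample_slice",
    "reconstruct_panoramic",
    "run_pipeline",
]

log = logging.getLogger(__name__)

AIR_HU = -1000.0


@dataclass
class OffsetFamily:
    """Sampled parallel curves: ``curves[j]`` is polyline ``(m+1, 2)`` for
    offset index ``offset_indices[j]``; the central curve (k = 0) is the
    sampled arch curve itself."""

    curves: np.ndarray  # (2K+1, m+1, 2)
    t: np.ndarray  # (m+1,)
    q: float
    central_index: int

    @property
    def offset_indices(self) -> np.ndarray:
        return np.arange(len(self.curves)) - self.central_index

    @property
    def n_samples(self) -> int:
        return self.curves.shape[1]


@dataclass
class PanoramicImage:
    """The synthesized panoramic: rows = axial slices (in volume order),
    columns = arc samples, values = mean HU across the offset family."""

    pixels: np.ndarray
    provenance: dict = field(default_factory=dict)


def offset_curves(
    curve: BezierCurve, q: float, n_offsets_per_side: int, m_samples: int
) -> OffsetFamily:
    """Build 2K+1 parallel sampled curves spaced ``q`` pixels apart.

    Normals are the unit 90-degree-CCW rotations of B'(t); samples where the
    derivative vanishes borrow the nearest non-degenerate normal.
    """
    if q <= 0:
        raise InputError("offset spacing q must be > 0")
    if n_offsets_per_side < 0:
        raise InputError("n_offsets_per_side must be >= 0")
    m = int(m_samples)
    t = np.arange(m + 1) / m
    base = bezier_eval(curve, t)
    vel = bezier_derivative(curve, t)
    speed = np.hypot(vel[:, 0], vel[:, 1])
    ok = speed > 1e-12
    if not ok.any():
        raise DegenerateCurveError("curve derivative vanishes everywhere; no normals")
    if not ok.all():
        # borrow the nearest well-defined tangent for cusp samples
        good = np.flatnonzero(ok)
        idx = np.arange(m + 1)
        pos = np.searchsorted(good, idx)
        right = good[np.clip(pos, 0, len(good) - 1)]
        left = good[np.clip(pos - 1, 0, len(good) - 1)]
        use = np.where(np.abs(right - idx) < np.abs(idx - left), right, left)
        vel = vel[use]
        speed = speed[use]
    normals = np.column_stack((-vel[:, 1], vel[:, 0])) / speed[:, None]
    ks = np.arange(-n_offsets_per_side, n_offsets_per_side + 1)
    curves = base[None, :, :] + ks[:, None, None] * q * normals[None, :, :]
    return OffsetFamily(curves=curves, t=t, q=float(q), central_index=int(n_offsets_per_side))


def sample_slice(
    slice_image: np.ndarray,
    polyline: np.ndarray,
    interpolation: Literal["bilinear", "nearest"] = "bilinear",
    fill_value: float = AIR_HU,
) -> np.ndarray:
    """Sample a 2D slice along an ``(m+1, 2)`` polyline of (x, y) points.

    Bilinear by default; out-of-bounds samples read as air (-1000 HU).
    """
    polyline = np.asarray(polyline, dtype=np.float64)
    coords = np.stack((polyline[:, 1], polyline[:, 0]))  # (row, col) order
    order = 1 if interpolation == "bilinear" else 0
    return ndi.map_coordinates(
        np.asarray(slice_image, dtype=np.float64),
        coords,
        order=order,
        mode="constant",
        cval=fill_value,
    )


def reconstruct_panoramic(
    volume: CTVolume,
    family: OffsetFamily,
    interpolation: Literal["bilinear", "nearest"] = "bilinear",
) -> PanoramicImage:
    """Average-intensity projection across the offset family.

    pixel(z, i) = mean over k of slice_z sampled along curve_k at sample i.
    Rows follow the volume's slice order (no flipping).
    """
    n_curves, n_samples, _ = family.curves.shape
    flat = family.curves.reshape(-1, 2)
    pano = np.empty((volume.n_slices, n_samples), dtype=np.float64)
    for z in range(volume.n_slices):
        profiles = sample_slice(volume.voxels[z], flat, interpolation=interpolation)
        pano[z] = profiles.reshape(n_curves, n_samples).mean(axis=0)
    return PanoramicImage(
        pixels=pano,
        provenance={
            "n_offset_curves": int(n_curves),
            "offset_spacing_px": family.q,
            "interpolation": interpolation,
            "row_order": "volume slice order (ascending acquisition index)",
        },
    )


def _stage(name):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except Exception as exc:  # attach the stage for pipeline users
                exc.add_note(f"pipeline stage: {name}")
                raise

        return wrapped

    return deco


def run_pipeline(
    volume: CTVolume,
    seg_cfg: SegmentationConfig | None = None,
    fit_cfg: FitConfig | None = None,
    offset_q: float = 2.0,
    offsets_per_side: int = 5,
    interpolation: Literal["bilinear", "nearest"] = "bilinear",
):
    """End-to-end reconstruction: segmentation -> skeleton -> Bezier fit ->
    offset curves -> AIP panoramic.

    Returns ``(PanoramicImage, FitResult, diagnostics)``; diagnostics carries
    the per-stage intermediates (reference slice, arch mask, skeleton image,
    ordered skeleton curve, offset family).  Deterministic for a fixed
    configuration and seed.
    """
    seg_cfg = seg_cfg or SegmentationConfig()
    fit_cfg = fit_cfg or FitConfig()

    index, arch_mask = _stage("segment_arch")(segment_arch)(volume, seg_cfg)
    skel_img = _stage("medial_axis")(medial_axis)(arch_mask)
    skel = _stage("prune_and_order")(prune_and_order)(skel_img)
    fit = _stage("fit_bezier")(fit_bezier)(skel, fit_cfg)
    if not fit.converged:
        log.warning("optimizer did not report convergence; using best curve found")
    family = _stage("offset_curves")(offset_curves)(
        fit.curve, offset_q, offsets_per_side, fit_cfg.m_samples
    )
    pano = _stage("reconstruct_panoramic")(reconstruct_panoramic)(
        volume, family, interpolation
    )
    pano.provenance.update(
        {
            "reference_slice": int(index),
            "f_initial_px": fit.f_initial,
            "f_final_px": fit.f_final,
        }
    )
    diagnostics = {
        "reference_slice": index,
        "arch_mask": arch_mask,
        "skeleton_image": skel_img,
        "skeleton_curve": skel,
        "offset_family": family,
    }
    return pano, fit, diagnostics
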