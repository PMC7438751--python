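"""Reading DICOM series and packed volumes; writing images and curve artifacts.

A DICOM series is read into a :class:`~panorex.volume.CTVolume` with stored
values converted to Hounsfield units through the rescale slope/intercept tags.
Slices are ordered by the projection of ``ImagePositionPatient`` onto the
slice normal (cross product of the row/column direction cosines), falling back
to ``InstanceNumber`` — file names are never trusted.

The "packed volume" format is a NumPy ``.npz`` container holding the voxel
array and the spacing vector; it round-trips bit-exactly and is the fixture
format used by the phantom generator and the CLI.
"""

from __future__ import annotations

import csv
import json
import logging
import zipfile
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pydicom
from pydicom.errors import InvalidDicomError

from .errors import AmbiguousSeriesError, FormatError, InputError
from .volume import CTVolume

__all__ = [
    "load_dicom_series",
    "load_volume_file",
    "save_volume_file",
    "write_image",
    "export_curves_csv",
    "export_fit_json",
]

log = logging.getLogger(__name__)


def _slice_normal(ds: pydicom.Dataset) -> np.ndarray | None:
    iop = getattr(ds, "ImageOrientationPatient", None)
    if iop is None or len(iop) != 6:
        return None
    row = np.asarray(iop[:3], dtype=float)
    col = np.asarray(iop[3:], dtype=float)
    return np.cross(row, col)


def _sort_key(ds: pydicom.Dataset) -> tuple[float, float]:
    """Primary: position along the slice normal; secondary: instance number."""
    instance = float(getattr(ds, "InstanceNumber", 0) or 0)
    pos = getattr(ds, "ImagePositionPatient", None)
    normal = _slice_normal(ds)
    if pos is not None and len(pos) == 3 and normal is not None:
        proj = float(np.dot(np.asarray(pos, dtype=float), normal))
        return (proj, instance)
    return (0.0, instance)


def load_dicom_series(directory_path: str | Path) -> CTVolume:
    """Read one single-frame axial DICOM series into a HU volume.

    Raises
    ------
    InputError
        Empty directory, no readable DICOM files, or a multi-frame file.
    AmbiguousSeriesError
        Files from more than one series (lists the offending UIDs).
    """
    directory = Path(directory_path)
    if not directory.is_dir():
        raise InputError(f"not a directory: {directory}")
    datasets = []
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        try:
            ds = pydicom.dcmread(path)
        except (InvalidDicomError, OSError, ValueError):
            continue
        if "PixelData" not in ds:
            continue
        if int(getattr(ds, "NumberOfFrames", 1) or 1) > 1:
            raise InputError(
                f"multi-frame DICOM not supported: {path.name}; "
                "expected a single-frame axial series"
            )
        datasets.append(ds)
    if not datasets:
        raise InputError(f"no readable single-frame DICOM files in {directory}")

    uids = {str(getattr(ds, "SeriesInstanceUID", "<missing>")) for ds in datasets}
    if len(uids) > 1:
        raise AmbiguousSeriesError(
            "directory mixes multiple DICOM series: " + ", ".join(sorted(uids))
        )

    datasets.sort(key=_sort_key)

    slices = []
    for ds in datasets:
        slope = getattr(ds, "RescaleSlope", None)
        intercept = getattr(ds, "RescaleIntercept", None)
        if slope is None or intercept is None:
            log.warning(
                "missing rescale tags; assuming slope=1, intercept=0 "
                "(stored values treated as HU)"
            )
            slope = 1.0 if slope is None else slope
            intercept = 0.0 if intercept is None else intercept
        slices.append(ds.pixel_array.astype(np.float64) * float(slope) + float(intercept))
    voxels = np.stack(slices, axis=0)

    ref = datasets[0]
    pixel_spacing = getattr(ref, "PixelSpacing", None)
    if pixel_spacing is not None and len(pixel_spacing) == 2:
        row_mm, col_mm = float(pixel_spacing[0]), float(pixel_spacing[1])
    else:
        log.warning("missing PixelSpacing; assuming 1 mm pixels")
        row_mm = col_mm = 1.0

    positions = [_sort_key(ds)[0] for ds in datasets]
    steps = np.diff(positions)
    if len(steps) and np.all(steps > 0):
        slice_mm = float(np.median(steps))
    else:
        slice_mm = float(
            getattr(ref, "SpacingBetweenSlices", None)
            or getattr(ref, "SliceThickness", None)
            or 1.0
        )
    return CTVolume(voxels=voxels, spacing=(slice_mm, row_mm, col_mm))


def save_volume_file(volume: CTVolume, path: str | Path) -> None:
    """Write a packed volume (``.npz`` with ``voxels`` and ``spacing``)."""
    np.savez(path, voxels=volume.voxels, spacing=np.asarray(volume.spacing, dtype=np.float64))


def load_volume_file(path: str | Path) -> CTVolume:
    """Load a packed volume written by :func:`save_volume_file`.

    Round-trips voxels and spacing bit-exactly.
    """
    try:
        with np.load(path) as data:
            if "voxels" not in data or "spacing" not in data:
                raise FormatError(f"not a packed volume (missing arrays): {path}")
            voxels = data["voxels"]
            spacing = tuple(data["spacing"].tolist())
    except FormatError:
        raise
    except (OSError, ValueError, zipfile.BadZipFile, KeyError, EOFError) as exc:
        raise FormatError(f"malformed packed volume file {path}: {exc}") from exc
    return CTVolume(voxels=voxels, spacing=spacing)


def write_image(
    image: np.ndarray,
    path: str | Path,
    window: tuple[float, float] | None = None,
) -> None:
    """Write a 2D scalar image as 16-bit grayscale PNG/TIFF.

    ``window=(lo, hi)`` maps lo -> 0 and hi -> 65535 linearly, clipping
    outside; ``None`` uses the image min/max.  Rounding is half-away-from-zero.
    A constant image under an auto window is written as all zeros.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or not np.all(np.isfinite(image)):
        raise InputError("image must be a finite 2D array")
    if window is None:
        window = (float(image.min()), float(image.max()))
    lo, hi = float(window[0]), float(window[1])
    if hi <= lo:
        log.warning("degenerate window (%g, %g); writing all-zero image", lo, hi)
        scaled = np.zeros_like(image)
    else:
        scaled = np.clip((image - lo) / (hi - lo), 0.0, 1.0) * 65535.0
    # values are non-negative, so floor(x + 0.5) is round-half-away-from-zero
    pixels = np.floor(scaled + 0.5).astype(np.uint16)
    iio.imwrite(Path(path), pixels)


def export_curves_csv(family, path: str | Path) -> None:
    """Write an offset-curve family as CSV: curve_id, sample_index, t, x, y.

    ``curve_id`` is the signed offset index k (0 = the fitted arch curve).
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["curve_id", "sample_index", "t", "x", "y"])
        for k, polyline in zip(family.offset_indices, family.curves):
            for i, (t, (x, y)) in enumerate(zip(family.t, polyline)):
                writer.writerow([k, i, repr(float(t)), repr(float(x)), repr(float(y))])


def export_fit_json(fit_result, path: str | Path, extra: dict | None = None) -> None:
    """Serialize a FitResult (control points, costs, convergence) to JSON."""
    payload = fit_result.to_dict()
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
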