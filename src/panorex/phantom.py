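"""Synthetic CBCT phantoms with a known dental-arch geometry.

The phantom emulates the axial anatomy the pipeline targets: an air
background, a soft-tissue ellipse (the head outline), a bone band following a
ground-truth Bezier arch (mandible/maxilla), and bright tooth cylinders
centered at equally spaced arc-length fractions of the arch.  Teeth sit above
the enamel threshold (default 2200 HU), bone below it (900 HU), so every
segmentation stage behaves as on patient data while the true arch curve and
tooth positions stay known.  Gaussian HU noise is clipped at ten standard
deviations, which guarantees no background voxel ever crosses the 1500 HU
threshold and no tooth voxel ever drops below it — segmentation outcomes on
phantoms are therefore deterministic, not merely probable.

The default phantom is 60 slices of 256 x 256 (desk scale); the
``full-scale`` preset matches clinical CBCT dimensions (200 slices of
512 x 512) for manual runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .bezier import BezierCurve, bezier_eval
from .errors import InputError
from .volume import CTVolume

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "arch_distance",
    "preset_spec",
    "write_synthetic_dicom_series",
]

_DENSE = 4001  # samples for arc-length tables and distance oracles


def _default_arch(rows: int, cols: int) -> np.ndarray:
    """U-shaped cubic arch control points, scaled to the slice size.

    Chosen so the default 14-tooth layout has inter-tooth gaps small enough
    that a 20 x 20 dilation bridges a single missing tooth (edge gap below
    ~18 px at desk scale).
    """
    w, h = float(cols), float(rows)
    return np.array(
        [
            [0.32 * w, 0.34 * h],
            [0.32 * w, 0.72 * h],
            [0.68 * w, 0.72 * h],
            [0.68 * w, 0.34 * h],
        ]
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity parameters of the synthetic volume."""

    n_slices: int = 60
    rows: int = 256
    cols: int = 256
    arch_control_points: np.ndarray | None = None
    n_teeth: int = 14
    tooth_radius_px: float = 5.0
    bone_radius_px: float = 7.0
    tooth_hu: float = 2200.0
    bone_hu: float = 900.0
    soft_tissue_hu: float = 40.0
    air_hu: float = -1000.0
    missing_teeth: frozenset[int] = field(default_factory=frozenset)
    noise_sigma_hu: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_teeth < 1:
            raise InputError("n_teeth must be >= 1")
        if not (self.tooth_hu >= 1500.0 > self.bone_hu):
            raise InputError(
                "tooth_hu must be >= 1500 HU and bone_hu < 1500 HU so that "
                "only enamel survives the threshold"
            )
        for name in ("tooth_hu", "bone_hu", "soft_tissue_hu", "air_hu", "noise_sigma_hu"):
            if not np.isfinite(getattr(self, name)):
                raise InputError(f"{name} must be finite")

    def arch(self) -> BezierCurve:
        pts = self.arch_control_points
        if pts is None:
            pts = _default_arch(self.rows, self.cols)
        return BezierCurve(control_points=np.asarray(pts, dtype=np.float64))


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    arch_curve: BezierCurve
    tooth_arc_fractions: np.ndarray  # fractions of present teeth
    tooth_centers: np.ndarray  # (n_present, 2) (x, y)
    all_tooth_indices: np.ndarray
    present_tooth_indices: np.ndarray
    arc_length_px: float
    tooth_slab: tuple[int, int]  # [z0, z1) slice range containing teeth


def _arc_table(curve: BezierCurve, n: int = _DENSE):
    t = np.linspace(0.0, 1.0, n)
    pts = bezier_eval(curve, t)
    seg = np.hypot(*np.diff(pts, axis=0).T)
    cum = np.concatenate(([0.0], np.cumsum(seg)))
    return t, pts, cum


def _points_at_arc_fractions(curve: BezierCurve, fractions: np.ndarray) -> np.ndarray:
    t, pts, cum = _arc_table(curve)
    targets = np.asarray(fractions) * cum[-1]
    ts = np.interp(targets, cum, t)
    return bezier_eval(curve, ts)


def generate_phantom(spec: PhantomSpec | None = None) -> tuple[CTVolume, GroundTruth]:
    """Build the synthetic volume and its ground truth.

    Teeth occupy the central half of the slice stack, bone a wider slab, soft
    tissue every slice; seeded noise makes volumes reproducible.
    """
    spec = spec or PhantomSpec()
    curve = spec.arch()
    _, dense_pts, cum = _arc_table(curve)
    arc_length = float(cum[-1])

    all_idx = np.arange(spec.n_teeth)
    fractions_all = (all_idx + 0.5) / spec.n_teeth
    present = np.array([i for i in all_idx if i not in spec.missing_teeth], dtype=int)
    if len(present) == 0:
        centers = np.empty((0, 2))
    else:
        centers = _points_at_arc_fractions(curve, fractions_all[present])
        r = spec.tooth_radius_px
        if (
            (centers[:, 0] - r < 0).any()
            or (centers[:, 0] + r >= spec.cols).any()
            or (centers[:, 1] - r < 0).any()
            or (centers[:, 1] + r >= spec.rows).any()
        ):
            raise InputError("tooth overlaps the image border; shrink the arch or teeth")

    yy, xx = np.mgrid[0 : spec.rows, 0 : spec.cols]

    # head outline: soft-tissue ellipse around the arch
    cy, cx = 0.55 * spec.rows, 0.5 * spec.cols
    ellipse = ((xx - cx) / (0.45 * spec.cols)) ** 2 + ((yy - cy) / (0.42 * spec.rows)) ** 2 <= 1.0

    # bone band: pixels within bone_radius of the arch polyline
    tree = cKDTree(dense_pts)
    d_arch, _ = tree.query(np.column_stack((xx.ravel(), yy.ravel())))
    bone2d = (d_arch.reshape(spec.rows, spec.cols) <= spec.bone_radius_px) & ellipse

    teeth2d = np.zeros((spec.rows, spec.cols), dtype=bool)
    for x0, y0 in centers:
        teeth2d |= (xx - x0) ** 2 + (yy - y0) ** 2 <= spec.tooth_radius_px**2

    vol = np.full((spec.n_slices, spec.rows, spec.cols), spec.air_hu, dtype=np.float64)
    vol[:, ellipse] = spec.soft_tissue_hu
    bone_slab = (int(0.15 * spec.n_slices), int(np.ceil(0.85 * spec.n_slices)))
    tooth_slab = (int(0.25 * spec.n_slices), int(np.ceil(0.75 * spec.n_slices)))
    vol[bone_slab[0] : bone_slab[1], bone2d] = spec.bone_hu
    vol[tooth_slab[0] : tooth_slab[1], teeth2d] = spec.tooth_hu

    if spec.noise_sigma_hu > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_sigma_hu, size=vol.shape)
        bound = 10.0 * spec.noise_sigma_hu  # keeps every tissue on its side of 1500 HU
        vol += np.clip(noise, -bound, bound)

    truth = GroundTruth(
        arch_curve=curve,
        tooth_arc_fractions=fractions_all[present],
        tooth_centers=centers,
        all_tooth_indices=all_idx,
        present_tooth_indices=present,
        arc_length_px=arc_length,
        tooth_slab=tooth_slab,
    )
    return CTVolume(voxels=vol, spacing=(0.5, 0.5, 0.5)), truth


def arch_distance(curve: BezierCurve, truth: GroundTruth, n_eval: int = 200) -> float:
    """Mean distance (px) from ``n_eval`` uniform-t samples of ``curve`` to
    the ground-truth arch.

    A dense sample grid seeds the nearest point on the truth curve; Newton
    projection on the squared distance then refines it to machine precision
    rather than polyline-chord precision.
    """
    from .bezier import bernstein_matrix, bezier_derivative

    target = truth.arch_curve
    tgrid, dense_pts, _ = _arc_table(target)
    tree = cKDTree(dense_pts)
    samples = bezier_eval(curve, np.linspace(0.0, 1.0, n_eval))
    _, idx = tree.query(samples)

    n = target.degree
    d2_ctrl = None
    if n >= 2:
        d2_ctrl = n * (n - 1) * np.diff(target.control_points, n=2, axis=0)

    def second_derivative(t: float) -> np.ndarray:
        if d2_ctrl is None:
            return np.zeros(2)
        return (bernstein_matrix(n - 2, np.array([t])) @ d2_ctrl)[0]

    dists = np.empty(len(samples))
    for j, (p, i) in enumerate(zip(samples, idx)):
        t = float(tgrid[i])
        for _ in range(50):
            r = bezier_eval(target, t) - p
            d1 = bezier_derivative(target, t)
            g = float(r @ d1)
            gp = float(d1 @ d1 + r @ second_derivative(t))
            if gp <= 0:
                break
            t_new = min(1.0, max(0.0, t - g / gp))
            if abs(t_new - t) < 1e-15:
                t = t_new
                break
            t = t_new
        candidates = [t, 0.0, 1.0]
        dists[j] = min(
            float(np.hypot(*(bezier_eval(target, tc) - p))) for tc in candidates
        )
    return float(dists.mean())


def random_spec(seed: int, missing_prob: float = 0.2) -> PhantomSpec:
    """A seeded "virtual patient": the default spec with the arch control
    points jittered (uniform +-5 px) and, with probability ``missing_prob``,
    one missing tooth.  Used to emulate inter-patient anatomical variation
    in trend studies."""
    rng = np.random.default_rng(seed)
    spec = PhantomSpec()
    pts = _default_arch(spec.rows, spec.cols) + rng.uniform(-5.0, 5.0, size=(4, 2))
    missing = frozenset()
    if rng.random() < missing_prob:
        missing = frozenset({int(rng.integers(2, spec.n_teeth - 2))})
    return PhantomSpec(arch_control_points=pts, missing_teeth=missing, seed=seed)


def virtual_patient_spec(seed: int) -> PhantomSpec:
    """A seeded clinical-scale "virtual patient" for trend studies.

    512 x 512 in-plane (clinical CBCT resolution) with a thin slice stack, a
    deep horseshoe arch — the mandibular shape a parabola cannot represent —
    16 teeth, and per-seed jitter of the arch control points.  At this scale
    anatomy is larger than the 20 px morphology kernel, so the skeleton
    retains the arch's shape detail the way patient skeletons do.
    """
    rng = np.random.default_rng(seed)
    w = h = 512.0
    base = np.array(
        [
            [0.38 * w, 0.26 * h],
            [0.09 * w, 0.88 * h],
            [0.50 * w, 1.08 * h],
            [0.91 * w, 0.88 * h],
            [0.62 * w, 0.26 * h],
        ]
    )
    pts = base + rng.uniform(-10.0, 10.0, size=(5, 2))
    return PhantomSpec(
        n_slices=12,
        rows=512,
        cols=512,
        arch_control_points=pts,
        n_teeth=16,
        tooth_radius_px=16.0,
        bone_radius_px=18.0,
        seed=seed,
    )


def preset_spec(name: str, seed: int = 0) -> PhantomSpec:
    """Named phantom presets: ``default``, ``missing-teeth`` (two single-tooth
    gaps, as in partially edentulous patients), ``full-scale`` (clinical
    CBCT dimensions)."""
    if name == "default":
        return PhantomSpec(seed=seed)
    if name == "missing-teeth":
        return PhantomSpec(missing_teeth=frozenset({4, 8}), seed=seed)
    if name == "full-scale":
        return PhantomSpec(
            n_slices=200,
            rows=512,
            cols=512,
            tooth_radius_px=10.0,
            bone_radius_px=14.0,
            seed=seed,
        )
    raise InputError(f"unknown phantom preset {name!r}")


def write_synthetic_dicom_series(
    volume: CTVolume, directory: str | Path, seed: int = 0
) -> list[Path]:
    """Emit the volume as a synthetic single-frame axial DICOM series.

    Exists to exercise DICOM ingestion without patient data: stored values
    are HU + 1024 with rescale slope 1 / intercept -1024.  File names are
    deliberately unordered (hash-like) so readers must sort by position tags.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entropy = f"panorex-synth-{seed}"
    series_uid = generate_uid(entropy_srcs=[entropy, "series"])
    slice_mm, row_mm, col_mm = volume.spacing
    paths = []
    n = volume.n_slices
    for i in range(n):
        stored = np.clip(np.round(volume.voxels[i] + 1024.0), 0, 65535).astype(np.uint16)
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=[entropy, f"sop{i}"])
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = generate_uid(entropy_srcs=[entropy, "study"])
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(i) * slice_mm]
        ds.ImageOrientationPatient = [1.0, 0.0, 0.0, 0.0, 1.0, 0.0]
        ds.PixelSpacing = [row_mm, col_mm]
        ds.SliceThickness = slice_mm
        ds.Rows, ds.Columns = stored.shape
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.PixelData = stored.tobytes()
        # scrambled name: readers must not rely on lexicographic order
        name = f"img_{(i * 2654435761) % 10**8:08d}.dcm"
        path = directory / name
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths
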