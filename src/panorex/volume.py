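"""The in-memory CT/CBCT volume container.

Axial slice stacks are kept as a ``(n_slices, rows, cols)`` array of
Hounsfield units together with the physical voxel spacing.  The slice axis is
always axis 0; the pipeline never reorients data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

__all__ = ["CTVolume"]


@dataclass
class CTVolume:
    """A HU-calibrated axial volume.

    Parameters
    ----------
    voxels
        3D scalar array of Hounsfield units, shape ``(n_slices, rows, cols)``.
    spacing
        ``(slice_mm, row_mm, col_mm)`` physical voxel spacing, all positive.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    axial_axis: int = field(default=0, init=False)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise InputError(f"volume must be 3D, got shape {self.voxels.shape}")
        n_slices, rows, cols = self.voxels.shape
        if n_slices < 1 or rows < 16 or cols < 16:
            raise InputError(
                f"volume too small: {self.voxels.shape} (need >=1 slice of >=16x16)"
            )
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 or not np.isfinite(s) for s in spacing):
            raise InputError(f"spacing must be 3 positive reals, got {self.spacing}")
        self.spacing = spacing
        if not np.all(np.isfinite(self.voxels)):
            raise InputError("volume contains non-finite voxel values")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1], self.voxels.shape[2]
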