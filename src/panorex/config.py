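"""Flat pipeline configuration with file/CLI/default precedence.

The configuration is a flat key-value mapping (YAML on disk) mirroring the
segmentation, fit, and offset parameters.  Precedence is CLI override > file
value > default; defaults are the method's published operating point
(1500 HU threshold, 20x20 dilation, sigma = 4, m = 1000, 11 control points).
Unknown keys are rejected rather than ignored so typos cannot silently fall
back to defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Any

import yaml

from .bezier import FitConfig
from .errors import ConfigError
from .segment import SegmentationConfig

__all__ = ["PipelineConfig", "parse_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Union of all stage parameters, flat for serialization."""

    threshold_hu: float = 1500.0
    dilation_size: tuple[int, int] = (20, 20)
    gaussian_sigma: float = 4.0
    rebinarize_level: float = 0.5
    n_control_points: int = 11
    m_samples: int = 1000
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0
    init_mode: str = "skeleton_uniform"
    offset_q: float = 2.0
    offsets_per_side: int = 5
    interpolation: str = "bilinear"

    def __post_init__(self) -> None:
        # delegate validation to the stage configs, then the extras
        self.segmentation()
        self.fit()
        if not (self.offset_q > 0):
            raise ConfigError(f"offset_q must be > 0, got {self.offset_q}")
        if self.offsets_per_side < 0:
            raise ConfigError("offsets_per_side must be >= 0")
        if self.interpolation not in ("bilinear", "nearest"):
            raise ConfigError(f"interpolation must be bilinear|nearest, got {self.interpolation!r}")

    def segmentation(self) -> SegmentationConfig:
        return SegmentationConfig(
            threshold_hu=self.threshold_hu,
            dilation_size=tuple(self.dilation_size),
            gaussian_sigma=self.gaussian_sigma,
            rebinarize_level=self.rebinarize_level,
        )

    def fit(self) -> FitConfig:
        return FitConfig(
            n_control_points=self.n_control_points,
            m_samples=self.m_samples,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=self.seed,
            init_mode=self.init_mode,  # type: ignore[arg-type]
        )

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["dilation_size"] = list(self.dilation_size)
        return d


def parse_config(
    file_path: str | Path | None = None, overrides: dict[str, Any] | None = None
) -> PipelineConfig:
    """Resolve a :class:`PipelineConfig` from a YAML file plus overrides.

    Raises :class:`ConfigError` for unknown keys (listing the valid ones) or
    invalid values.
    """
    valid = {f.name for f in fields(PipelineConfig)}
    merged: dict[str, Any] = {}
    if file_path is not None:
        with open(file_path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file must be a flat mapping: {file_path}")
        merged.update(loaded)
    if overrides:
        merged.update({k: v for k, v in overrides.items() if v is not None})
    unknown = sorted(set(merged) - valid)
    if unknown:
        raise ConfigError(
            f"unknown config keys {unknown}; valid keys: {sorted(valid)}"
        )
    if "dilation_size" in merged:
        ds = merged["dilation_size"]
        if isinstance(ds, int):
            ds = (ds, ds)
        merged["dilation_size"] = tuple(int(s) for s in ds)
    try:
        return PipelineConfig(**merged)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
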