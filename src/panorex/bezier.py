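"""Bezier arch curves: evaluation, derivative, distance cost, and fitting.

A degree-n Bezier curve is B(t) = sum_i C(n,i) (1-t)^(n-i) t^i P_i for
t in [0, 1], with control points P_0..P_n.  The dental-arch curve is obtained
by minimizing the mean distance between m+1 uniformly sampled curve points
b_i = B(i/m) and their nearest skeleton points e_i,

    f(P) = (1/m) * sum_{i=0}^{m} |e_i - b_i|,

over all 2(n+1) control-point coordinates with SLSQP.  The divisor is m while
the sum has m+1 terms; the formula is implemented literally as stated so that
reported costs are reproducible.  Distances (and hence f) are in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .errors import ConfigError, InputError
from .skeleton import SkeletonCurve

__all__ = [
    "BezierCurve",
    "FitConfig",
    "FitResult",
    "bezier_eval",
    "bezier_derivative",
    "bernstein_matrix",
    "cost_function",
    "initialize_control_points",
    "fit_bezier",
]


@dataclass
class BezierCurve:
    """Control points ``(n+1, 2)`` of a degree-n Bezier curve, n >= 1."""

    control_points: np.ndarray

    def __post_init__(self) -> None:
        self.control_points = np.asarray(self.control_points, dtype=np.float64)
        if (
            self.control_points.ndim != 2
            or self.control_points.shape[1] != 2
            or len(self.control_points) < 2
        ):
            raise InputError("a Bezier curve needs >= 2 (x, y) control points")
        if not np.all(np.isfinite(self.control_points)):
            raise InputError("control points must be finite")

    @property
    def degree(self) -> int:
        return len(self.control_points) - 1


@dataclass(frozen=True)
class FitConfig:
    """Fit settings: number of control points (3/7/11/15 are the usual
    sweep), sample count m (default 1000, i.e. m+1 curve samples),
    optimizer budget and initialization mode."""

    n_control_points: int = 11
    m_samples: int = 1000
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0
    init_mode: Literal["skeleton_uniform", "random_in_bbox"] = "skeleton_uniform"

    def __post_init__(self) -> None:
        if self.n_control_points < 2:
            raise ConfigError("n_control_points must be >= 2")
        if self.n_control_points > self.m_samples:
            raise ConfigError("n_control_points must be <= m_samples")
        if self.init_mode not in ("skeleton_uniform", "random_in_bbox"):
            raise ConfigError(f"unknown init_mode {self.init_mode!r}")


@dataclass
class FitResult:
    """Outcome of a curve fit; ``f_final <= f_initial`` always holds and
    both costs are in pixels."""

    curve: BezierCurve
    f_initial: float
    f_final: float
    n_iterations: int
    converged: bool
    config: FitConfig | None = field(default=None)

    def __post_init__(self) -> None:
        if self.f_final < 0 or self.f_final > self.f_initial + 1e-12:
            raise InputError(
                f"invalid fit costs: f_initial={self.f_initial}, f_final={self.f_final}"
            )

    def to_dict(self) -> dict:
        d = {
            "control_points": self.curve.control_points.tolist(),
            "f_initial": float(self.f_initial),
            "f_final": float(self.f_final),
            "n_iterations": int(self.n_iterations),
            "converged": bool(self.converged),
            "cost_units": "pixels",
        }
        if self.config is not None:
            d["config"] = {
                "n_control_points": self.config.n_control_points,
                "m_samples": self.config.m_samples,
                "max_iter": self.config.max_iter,
                "tol": self.config.tol,
                "seed": self.config.seed,
                "init_mode": self.config.init_mode,
            }
        return d


def _check_t(t) -> np.ndarray:
    t = np.asarray(t, dtype=np.float64)
    if np.any(t < 0.0) or np.any(t > 1.0):
        raise ValueError("curve parameter t must lie in [0, 1]")
    return t


def bernstein_matrix(degree: int, t: np.ndarray) -> np.ndarray:
    """Bernstein basis values, shape ``(len(t), degree+1)``.

    Binomial coefficients are built multiplicatively, which is stable well
    past degree 20.
    """
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    n = int(degree)
    binom = np.ones(n + 1)
    for i in range(1, n + 1):
        binom[i] = binom[i - 1] * (n - i + 1) / i
    i = np.arange(n + 1)
    tt = t[:, None]
    return binom * (1.0 - tt) ** (n - i) * tt**i


def bezier_eval(curve: BezierCurve, t) -> np.ndarray:
    """Evaluate B(t); ``t`` scalar or array in [0, 1], result ``(..., 2)``."""
    t_arr = _check_t(t)
    pts = bernstein_matrix(curve.degree, np.atleast_1d(t_arr)) @ curve.control_points
    return pts[0] if np.isscalar(t) or t_arr.ndim == 0 else pts


def bezier_derivative(curve: BezierCurve, t) -> np.ndarray:
    """Evaluate B'(t) = n * sum_i b_{i,n-1}(t) (P_{i+1} - P_i)."""
    t_arr = _check_t(t)
    n = curve.degree
    diffs = np.diff(curve.control_points, axis=0)
    vel = n * (bernstein_matrix(n - 1, np.atleast_1d(t_arr)) @ diffs)
    return vel[0] if np.isscalar(t) or t_arr.ndim == 0 else vel


def _skeleton_points(skeleton) -> np.ndarray:
    pts = skeleton.points if isinstance(skeleton, SkeletonCurve) else np.asarray(skeleton, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise InputError("skeleton must be a nonempty (N, 2) point set")
    return pts


def cost_function(curve: BezierCurve, skeleton, m_samples: int) -> float:
    """Mean curve-to-skeleton distance f(P) (pixels).

    Samples b_i = B(i/m) for i = 0..m; each b_i is paired with its exact
    nearest skeleton point via a k-d tree (ties resolve to the lowest
    skeleton index); returns sum(|e_i - b_i|) / m.
    """
    if m_samples < 1:
        raise InputError("m_samples must be >= 1")
    pts = _skeleton_points(skeleton)
    tree = cKDTree(pts)
    t = np.arange(m_samples + 1) / m_samples
    b = bezier_eval(curve, t)
    dists, _ = tree.query(b)
    return float(dists.sum() / m_samples)


def initialize_control_points(
    skeleton, n_points: int, init_mode: str = "skeleton_uniform", seed: int = 0
) -> BezierCurve:
    """Initial control polygon for the fit.

    ``skeleton_uniform`` picks skeleton points at uniformly spaced indices
    (deterministic); ``random_in_bbox`` draws uniformly inside the skeleton
    bounding box from a seeded generator.
    """
    pts = _skeleton_points(skeleton)
    if n_points > len(pts):
        raise InputError(f"n_points={n_points} exceeds skeleton length {len(pts)}")
    if init_mode == "skeleton_uniform":
        idx = np.round(np.linspace(0, len(pts) - 1, n_points)).astype(int)
        return BezierCurve(control_points=pts[idx].copy())
    if init_mode == "random_in_bbox":
        rng = np.random.default_rng(seed)
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        return BezierCurve(control_points=rng.uniform(lo, hi, size=(n_points, 2)))
    raise ConfigError(f"unknown init_mode {init_mode!r}")


def _cost_and_grad(flat: np.ndarray, basis: np.ndarray, tree: cKDTree, m: int):
    P = flat.reshape(-1, 2)
    b = basis @ P
    dists, idx = tree.query(b)
    diff = b - tree.data[idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(dists[:, None] > 0, diff / np.maximum(dists, 1e-300)[:, None], 0.0)
    grad = (basis.T @ unit) / m
    return dists.sum() / m, grad.ravel()


def fit_bezier(skeleton, cfg: FitConfig | None = None) -> FitResult:
    """Fit the arch curve by SLSQP minimization of :func:`cost_function`.

    The objective gradient is analytic under the current nearest-neighbor
    assignment (a subgradient of the piecewise-smooth cost); the optimizer is
    unconstrained, so control points may leave the image.  Non-convergence is
    reported through ``converged=False`` with the best curve seen, never an
    exception.
    """
    cfg = cfg or FitConfig()
    pts = _skeleton_points(skeleton)
    tree = cKDTree(pts)
    m = cfg.m_samples
    t = np.arange(m + 1) / m
    init = initialize_control_points(skeleton, cfg.n_control_points, cfg.init_mode, cfg.seed)
    basis = bernstein_matrix(init.degree, t)

    best = {"f": np.inf, "x": init.control_points.ravel().copy()}

    def fun(x):
        f, g = _cost_and_grad(x, basis, tree, m)
        if f < best["f"]:
            best["f"] = f
            best["x"] = x.copy()
        return f, g

    f_initial, _ = _cost_and_grad(init.control_points.ravel(), basis, tree, m)
    res = minimize(
        fun,
        init.control_points.ravel(),
        jac=True,
        method="SLSQP",
        options={"maxiter": cfg.max_iter, "ftol": cfg.tol},
    )
    f_final = min(best["f"], f_initial)
    curve = BezierCurve(control_points=best["x"].reshape(-1, 2))
    return FitResult(
        curve=curve,
        f_initial=float(f_initial),
        f_final=float(f_final),
        n_iterations=int(getattr(res, "nit", 0)),
        converged=bool(res.success),
        config=cfg,
    )
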