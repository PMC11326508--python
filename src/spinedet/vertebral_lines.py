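"""Sparse-to-dense vertebral line interpolation.

A scoliotic spine's vertebral borders follow a smooth, step-off-free
curve.  Three such lines are derived from the 68 corner annotations: the
left line through the 34 left-border corners (top-left and bottom-left of
each vertebra), the right line through the 34 right-border corners, and
the middle line through the 17 vertebral centroids.  Each point set is
interpolated with a chord-length-parameterised B-spline and resampled at
``n_samples`` arc-length-equidistant points (endpoints included), turning
the sparse corner annotation into a dense curve description.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_interp_spline

from .annotations import SpineAnnotation

__all__ = [
    "SplineConfig",
    "VertebralLineSet",
    "ParametricCurve",
    "collect_line_points",
    "fit_interpolating_spline",
    "sample_equidistant",
    "encode_vertebral_lines",
]

SIDES = ("left", "middle", "right")


@dataclass(frozen=True)
class SplineConfig:
    """Spline fitting and resampling parameters.

    ``degree``: spline degree (cubic by default); ``n_samples``: number of
    equidistant output points per line; ``arc_resolution``: dense
    piecewise-linear subdivisions used to compute and invert arc length;
    ``lines_enabled``: which of left/middle/right to produce (middle only
    by default — in practice the middle line alone captures the spine
    morphology at a third of the head parameters).
    """

    degree: int = 3
    n_samples: int = 100
    arc_resolution: int = 10_000
    lines_enabled: frozenset = frozenset({"middle"})

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if self.arc_resolution < 10 * self.n_samples:
            raise ValueError("arc_resolution must be >= 10 * n_samples")
        unknown = set(self.lines_enabled) - set(SIDES)
        if unknown:
            raise ValueError(f"unknown line sides: {sorted(unknown)}")


@dataclass
class VertebralLineSet:
    """The sampled vertebral lines; disabled sides are ``None``."""

    left: np.ndarray | None = None
    middle: np.ndarray | None = None
    right: np.ndarray | None = None

    def enabled(self) -> dict[str, np.ndarray]:
        return {
            side: getattr(self, side)
            for side in SIDES
            if getattr(self, side) is not None
        }


@dataclass
class ParametricCurve:
    """A chord-length-parameterised interpolating spline in the plane."""

    spline: object
    t_min: float
    t_max: float

    def __call__(self, t) -> np.ndarray:
        return np.asarray(self.spline(t), dtype=float)


def collect_line_points(ann: SpineAnnotation, side: str) -> np.ndarray:
    """Ordered control points for one vertebral line.

    left: per vertebra the top-left then bottom-left corner (34 points);
    right: top-right then bottom-right (34 points); middle: the 17
    centroids.  All ordered superior to inferior.
    """
    corners = ann.corner_array()
    if side == "left":
        pts = corners[:, (0, 2), :].reshape(-1, 2)
    elif side == "right":
        pts = corners[:, (1, 3), :].reshape(-1, 2)
    elif side == "middle":
        pts = corners.mean(axis=1)
    else:
        raise ValueError(f"unknown side {side!r}; expected one of {SIDES}")
    return pts


def fit_interpolating_spline(
    points: np.ndarray, config: SplineConfig = SplineConfig()
) -> ParametricCurve:
    """Interpolating B-spline through ``points`` with chord parameters.

    The parameter of point ``i`` is the cumulative chord (straight-line)
    length up to it, so the curve passes through every control point
    exactly.  The degree drops automatically for very short point lists
    (a spline of degree d needs d+1 points).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError(f"need an (n>=2, 2) point array; got {pts.shape}")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0):
        dup = int(np.argmin(seg)) + 1
        raise ValueError(f"duplicate consecutive control points at index {dup}")
    t = np.concatenate([[0.0], np.cumsum(seg)])
    degree = min(config.degree, pts.shape[0] - 1)
    spline = make_interp_spline(t, pts, k=degree)
    return ParametricCurve(spline=spline, t_min=0.0, t_max=float(t[-1]))


def sample_equidistant(
    curve: ParametricCurve,
    config: SplineConfig = SplineConfig(),
    return_params: bool = False,
):
    """``n_samples`` points at equal arc-length spacing along the curve.

    Arc length is accumulated over ``arc_resolution`` piecewise-linear
    subdivisions and inverted by linear interpolation; both endpoints are
    included.  Returns an (n_samples, 2) array, or ``(points, params)``
    with the curve parameters of the samples when ``return_params`` is
    set.
    """
    ts = np.linspace(curve.t_min, curve.t_max, config.arc_resolution + 1)
    pts = curve(ts)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    if total <= 0:
        raise ValueError("zero-length curve")
    targets = np.linspace(0.0, total, config.n_samples)
    t_at = np.interp(targets, arclen, ts)
    if return_params:
        return curve(t_at), t_at
    return curve(t_at)


def encode_vertebral_lines(
    ann: SpineAnnotation, config: SplineConfig = SplineConfig()
) -> VertebralLineSet:
    """Fit and resample every enabled vertebral line of an annotation."""
    out = VertebralLineSet()
    for side in config.lines_enabled:
        pts = collect_line_points(ann, side)
        curve = fit_interpolating_spline(pts, config)
        setattr(out, side, sample_equidistant(curve, config))
    return out
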