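"""Parametric scoliotic-spine simulator with analytic Cobb ground truth.

The generator emulates the statistical structure of anterior-posterior
spinal radiograph annotations: 17 vertebral bodies sit on a smooth curved
centerline, each drawn as a rectangle aligned with the local tangent,
with vertebra size growing from the thoracic to the lumbar region and a
configurable inter-vertebral gap.  The centerline is a sum of sinusoids
in the lateral (x) direction, so the tangent -- and hence every
vertebra's tilt -- has a closed form, which gives every simulated case an
analytic true Cobb angle triple.

Rendering produces a pseudo-radiograph: bright blurred vertebral bodies
over a darker background, additive Gaussian noise, and a clutter texture
whose strength ramps toward the bottom of the image, mimicking the
heavier soft-tissue interference over the lower spine seen in real AP
scans.  The renderer is deliberately not a physical X-ray model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .annotations import (
    SpineAnnotation,
    validate_annotation,
    write_annotation,
)
from .evaluation import CobbAngles, _is_s_curve, cobb_from_slope_vectors

__all__ = [
    "SpineSimParams",
    "SimulatedCase",
    "generate_case",
    "render_xray",
    "generate_dataset",
    "toy_params",
]


@dataclass(frozen=True)
class SpineSimParams:
    """Geometry, appearance and randomness of a simulated spine.

    ``curve_amplitudes``/``curve_frequencies`` describe the lateral
    sinusoids (pixels / cycles over the spine length); each case draws
    its actual amplitudes uniformly from [0.3, 1] x amplitude and a
    random phase, so a fixed parameter set spans a family of curvatures.
    ``gap_fraction`` is the inter-vertebral spacing as a fraction of the
    local vertebra height.  ``lower_region_clutter`` in [0, 1] scales the
    extra texture toward the bottom row.
    """

    n_vertebrae: int = 17
    image_height: int = 1024
    image_width: int = 512
    curve_amplitudes: tuple = (40.0,)
    curve_frequencies: tuple = (1.0,)
    vertebra_width_range: tuple = (80.0, 120.0)
    vertebra_height_range: tuple = (34.0, 44.0)
    gap_fraction: float = 0.25
    noise_sd: float = 0.03
    lower_region_clutter: float = 0.5
    top_margin: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vertebrae < 2:
            raise ValueError("n_vertebrae must be >= 2")
        if len(self.curve_amplitudes) != len(self.curve_frequencies):
            raise ValueError("amplitudes and frequencies must pair up")
        if not (0 < self.gap_fraction < 1):
            raise ValueError("gap_fraction must be in (0, 1)")
        if not (0 <= self.lower_region_clutter <= 1):
            raise ValueError("lower_region_clutter must be in [0, 1]")


@dataclass
class SimulatedCase:
    """A generated annotation, its rendered image and analytic truth."""

    annotation: SpineAnnotation
    image: np.ndarray | None
    true_cobb: CobbAngles
    tilt_per_vertebra: np.ndarray
    params: SpineSimParams


def _centerline(params: SpineSimParams, amplitudes, frequencies, phases):
    """Closed-form centerline x(t), y(t) and derivatives, t in [0, 1]."""
    h = params.image_height
    y0 = params.top_margin
    y1 = h - params.top_margin

    def position(t):
        t = np.asarray(t, dtype=float)
        x = params.image_width / 2.0 + sum(
            a * np.sin(2 * np.pi * f * t + p)
            for a, f, p in zip(amplitudes, frequencies, phases)
        )
        y = y0 + t * (y1 - y0)
        return np.stack([x, y], axis=-1)

    def derivative(t):
        t = np.asarray(t, dtype=float)
        dx = sum(
            a * 2 * np.pi * f * np.cos(2 * np.pi * f * t + p)
            for a, f, p in zip(amplitudes, frequencies, phases)
        )
        dy = np.full_like(np.asarray(dx, dtype=float), y1 - y0)
        return np.stack([np.broadcast_to(dx, dy.shape), dy], axis=-1)

    return position, derivative


def generate_case(params: SpineSimParams, render: bool = True) -> SimulatedCase:
    """Generate one annotated case; identical seeds repeat exactly.

    Vertebra centers are placed along the centerline at arc spacings of
    (1 + gap_fraction) times the local vertebra height, the chain
    centered within the curve's arc length.  Each vertebra is a rectangle
    of linearly interpolated size rotated to the local tangent.  The true
    Cobb triple comes from the closed-form tangent directions (not from
    the emitted corners), run through the same regional partition rule as
    :func:`spinedet.evaluation.cobb_from_landmarks`, so landmark-based
    estimates can be checked against an independent analytic truth.
    ``render=False`` skips the image (``case.image`` is ``None``).
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_vertebrae

    amplitudes = [a * rng.uniform(0.3, 1.0) for a in params.curve_amplitudes]
    phases = [rng.uniform(0, 2 * np.pi) for _ in params.curve_amplitudes]
    frequencies = list(params.curve_frequencies)
    position, derivative = _centerline(params, amplitudes, frequencies, phases)

    # dense arc-length table for equal-arc center placement
    ts = np.linspace(0.0, 1.0, 4001)
    pts = position(ts)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]

    frac = np.linspace(0.0, 1.0, n)
    heights = np.interp(frac, [0, 1], params.vertebra_height_range)
    widths = np.interp(frac, [0, 1], params.vertebra_width_range)
    pitch = heights * (1.0 + params.gap_fraction)
    # center i sits half a pitch below center i-1's slot
    rel = np.concatenate([[0.0], np.cumsum((pitch[:-1] + pitch[1:]) / 2.0)])
    chain = rel[-1] + pitch[0] / 2.0 + pitch[-1] / 2.0
    if chain > total:
        raise ValueError(
            f"vertebra chain ({chain:.0f} px along arc) exceeds the "
            f"centerline length ({total:.0f} px); enlarge the image or "
            "shrink the vertebrae"
        )
    start = (total - chain) / 2.0 + pitch[0] / 2.0
    t_centers = np.interp(start + rel, arclen, ts)

    centers = position(t_centers)
    tangents = derivative(t_centers)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    # left-to-right vertebra axis: tangent rotated 90 deg counter to y-down
    normals = np.stack([tangents[:, 1], -tangents[:, 0]], axis=1)
    flip = normals[:, 0] < 0
    normals[flip] *= -1
    tilts = np.degrees(np.arctan2(normals[:, 1], normals[:, 0]))

    corners = np.empty((n, 4, 2))
    for i in range(n):
        half_w = widths[i] / 2.0 * normals[i]
        half_h = heights[i] / 2.0 * tangents[i]
        corners[i, 0] = centers[i] - half_w - half_h   # top-left
        corners[i, 1] = centers[i] + half_w - half_h   # top-right
        corners[i, 2] = centers[i] - half_w + half_h   # bottom-left
        corners[i, 3] = centers[i] + half_w + half_h   # bottom-right

    if (
        corners[..., 0].min() < 0
        or corners[..., 0].max() >= params.image_width
        or corners[..., 1].min() < 0
        or corners[..., 1].max() >= params.image_height
    ):
        raise ValueError(
            "generated landmarks leave the canvas; reduce curve_amplitudes "
            "or vertebra sizes"
        )

    ann = SpineAnnotation.from_corner_array(
        corners, params.image_height, params.image_width
    )
    report = validate_annotation(ann, n_vertebrae=n)
    if not report.passed:
        raise ValueError("generator invariant violated: " + "; ".join(report.violations))

    # analytic truth: slope vectors are the exact tangent normals; the
    # S-shape test runs on the analytic endplate midpoints (identical to
    # the landmark-derived ones for exact rectangles), so both routes use
    # the same partition rule
    mids = np.empty((2 * n, 2))
    mids[0::2] = centers - (heights[:, None] / 2.0) * tangents
    mids[1::2] = centers + (heights[:, None] / 2.0) * tangents
    true_cobb = cobb_from_slope_vectors(normals, s_curve=_is_s_curve(mids))
    image = render_xray(ann, params) if render else None
    return SimulatedCase(
        annotation=ann,
        image=image,
        true_cobb=true_cobb,
        tilt_per_vertebra=tilts,
        params=params,
    )


def render_xray(ann: SpineAnnotation, params: SpineSimParams) -> np.ndarray:
    """Render an 8-bit pseudo-radiograph of the annotation.

    Vertebral bodies are filled bright quadrilaterals, blurred at the
    edges; the background carries a clutter texture ramping from zero at
    the top row to ``lower_region_clutter`` at the bottom, plus additive
    Gaussian noise of ``noise_sd`` (intensities on the [0, 1] scale
    before quantisation to uint8).
    """
    from scipy.ndimage import gaussian_filter
    from skimage.draw import polygon

    rng = np.random.default_rng(params.seed + 1_000_003)
    h, w = ann.image_height, ann.image_width
    canvas = np.full((h, w), 0.2)

    body = np.zeros((h, w))
    for quad in ann.corner_array():
        # draw order TL, TR, BR, BL for a simple polygon
        ys = quad[(0, 1, 3, 2), 1]
        xs = quad[(0, 1, 3, 2), 0]
        rr, cc = polygon(ys, xs, shape=(h, w))
        body[rr, cc] = 0.55
    body = gaussian_filter(body, sigma=1.5)
    canvas += body

    if params.lower_region_clutter > 0:
        texture = gaussian_filter(rng.standard_normal((h, w)), sigma=6.0)
        texture /= max(np.abs(texture).max(), 1e-9)
        ramp = np.linspace(0.0, 1.0, h)[:, None]
        canvas += 0.25 * params.lower_region_clutter * ramp * np.abs(texture)

    if params.noise_sd > 0:
        canvas += rng.normal(0.0, params.noise_sd, size=(h, w))

    return (np.clip(canvas, 0.0, 1.0) * 255).astype(np.uint8)


def toy_params(seed: int = 0, amplitude: float = 9.0) -> SpineSimParams:
    """A 192x96 desk-scale parameter set for CPU training experiments.

    Sized so that adjacent vertebra centers stay at least two grid cells
    apart on the downsample-4 decoding grid (the 3x3 peak suppression
    needs that separation to resolve all 17 centers).
    """
    return SpineSimParams(
        image_height=192,
        image_width=96,
        curve_amplitudes=(amplitude,),
        curve_frequencies=(1.0,),
        vertebra_width_range=(20.0, 30.0),
        vertebra_height_range=(6.5, 8.0),
        top_margin=12.0,
        noise_sd=0.02,
        lower_region_clutter=0.3,
        seed=seed,
    )


def generate_dataset(
    n_cases: int,
    params: SpineSimParams,
    seed: int,
    out_dir: str | Path | None = None,
    render: bool = True,
) -> list[SimulatedCase]:
    """Generate ``n_cases`` cases with per-case seeds ``seed + index``.

    With ``out_dir`` set, writes ``case_XXX.png`` images, CSV and JSON
    annotations, and a ``manifest.csv`` listing each case's files and
    true Cobb angles.
    """
    import pandas as pd

    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    cases = [
        generate_case(replace(params, seed=seed + i), render=render or out_dir is not None)
        for i in range(n_cases)
    ]
    if out_dir is not None:
        from PIL import Image

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, case in enumerate(cases):
            stem = f"case_{i:03d}"
            Image.fromarray(case.image).save(out / f"{stem}.png")
            write_annotation(case.annotation, out / f"{stem}.csv")
            write_annotation(case.annotation, out / f"{stem}.json")
            rows.append(
                {
                    "case": stem,
                    "seed": seed + i,
                    "cobb_pt": case.true_cobb.PT,
                    "cobb_mt": case.true_cobb.MT,
                    "cobb_tl": case.true_cobb.TL,
                }
            )
        pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    return cases
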