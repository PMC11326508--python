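"""Encoding annotations into supervision grids and decoding them back.

The detector is supervised through six pathways, all defined on a grid
downsampled by a factor ``k`` from the input image:

* **heatmap** — one unnormalised 2-D Gaussian disc per vertebra center,
  peak value 1 at the quantised center pixel, overlapping discs merged by
  element-wise maximum;
* **center offset** — the sub-pixel remainder ``(x/k - floor(x/k),
  y/k - floor(y/k))`` lost to quantisation, stored at the center pixel;
* **corner polar offsets** — each corner expressed in polar coordinates
  about its vertebra center (polar axis along +x, angle measured toward
  +y in the image frame), 8 channels: r then theta for corners 1..4;
* **CPIE** (center point interval estimator) — the vector from each
  center to the next vertebra's center, anchored at the upper vertebra;
* **AVIE** (adjacent vertebra interval estimator) — the offsets from a
  vertebra's bottom corners to the next vertebra's top corners, anchored
  at the lower vertebra;
* **vertebral lines** — dense equidistant curve samples (see
  :mod:`spinedet.vertebral_lines`).

All offsets and radii are stored in full-resolution pixels, which makes
encode -> decode an exact inverse (up to floating point) as long as no
two centers share a grid pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import maximum_filter

from .annotations import CenterPoint, SpineAnnotation, VertebraQuad
from .vertebral_lines import SplineConfig, VertebralLineSet, encode_vertebral_lines

__all__ = [
    "CodecConfig",
    "PolarCorner",
    "EncodedTargets",
    "encode_heatmap",
    "encode_center_offset",
    "corners_to_polar",
    "polar_to_cartesian",
    "encode_cpie",
    "encode_avie",
    "encode_all",
    "nms",
    "topk_centers",
    "adaptive_centers",
    "decode_landmarks",
    "gaussian_radius",
]


@dataclass(frozen=True)
class CodecConfig:
    """Grid geometry and Gaussian policy for target encoding.

    ``sigma_policy`` is either ``("fixed", value)`` for a constant
    Gaussian width or ``("iou_radius", overlap)`` (the default, overlap
    0.7) which derives a per-vertebra radius from its bounding box such
    that a box shifted by the radius still overlaps the original by at
    least ``overlap``, and sets sigma = radius / 3.
    """

    downsample_k: int = 4
    input_height: int = 1024
    input_width: int = 512
    sigma_policy: tuple = ("iou_radius", 0.7)
    heatmap_peak: float = 1.0
    spline: SplineConfig = field(default_factory=SplineConfig)

    def __post_init__(self) -> None:
        if self.input_height % self.downsample_k or self.input_width % self.downsample_k:
            raise ValueError("input dims must be divisible by downsample_k")
        kind, value = self.sigma_policy
        if kind not in ("fixed", "iou_radius"):
            raise ValueError(f"unknown sigma policy {kind!r}")
        if kind == "fixed" and value <= 0:
            raise ValueError("fixed sigma must be > 0")
        if kind == "iou_radius" and not (0 < value < 1):
            raise ValueError("iou_radius overlap must be in (0, 1)")

    @property
    def grid_height(self) -> int:
        return self.input_height // self.downsample_k

    @property
    def grid_width(self) -> int:
        return self.input_width // self.downsample_k


@dataclass(frozen=True)
class PolarCorner:
    """A corner in polar coordinates about its vertebra center."""

    r: float
    theta: float


@dataclass
class EncodedTargets:
    """The six supervision tensors plus their masks for one image."""

    heatmap: np.ndarray          # (H/k, W/k)
    center_offset: np.ndarray    # (2, H/k, W/k)
    corner_polar: np.ndarray     # (8, H/k, W/k): r1..r4 then theta1..theta4
    cpie: np.ndarray             # (2, H/k, W/k)
    avie: np.ndarray             # (4, H/k, W/k)
    vertebral_lines: VertebralLineSet
    center_mask: np.ndarray      # bool (H/k, W/k)
    cpie_mask: np.ndarray        # bool
    avie_mask: np.ndarray        # bool

    def save_npz(self, path: str | Path) -> None:
        arrays = {
            "heatmap": self.heatmap,
            "center_offset": self.center_offset,
            "corner_polar": self.corner_polar,
            "cpie": self.cpie,
            "avie": self.avie,
            "center_mask": self.center_mask,
            "cpie_mask": self.cpie_mask,
            "avie_mask": self.avie_mask,
        }
        for side, pts in self.vertebral_lines.enabled().items():
            arrays[f"line_{side}"] = pts
        np.savez(str(path), **arrays)

    @classmethod
    def load_npz(cls, path: str | Path) -> "EncodedTargets":
        data = np.load(str(path))
        lines = VertebralLineSet()
        for side in ("left", "middle", "right"):
            key = f"line_{side}"
            if key in data:
                setattr(lines, side, data[key])
        return cls(
            heatmap=data["heatmap"],
            center_offset=data["center_offset"],
            corner_polar=data["corner_polar"],
            cpie=data["cpie"],
            avie=data["avie"],
            vertebral_lines=lines,
            center_mask=data["center_mask"],
            cpie_mask=data["cpie_mask"],
            avie_mask=data["avie_mask"],
        )


def _centers_array(centers) -> np.ndarray:
    if isinstance(centers, np.ndarray):
        return np.atleast_2d(np.asarray(centers, dtype=float))
    return np.array(
        [
            c.as_array() if isinstance(c, CenterPoint) else np.asarray(c, float)
            for c in centers
        ]
    )


def _check_inside(centers: np.ndarray, config: CodecConfig) -> None:
    if np.any(
        (centers[:, 0] < 0)
        | (centers[:, 0] >= config.input_width)
        | (centers[:, 1] < 0)
        | (centers[:, 1] >= config.input_height)
    ):
        raise ValueError("center outside the image bounds")


def gaussian_radius(box_height: float, box_width: float, min_overlap: float = 0.7) -> float:
    """Largest displacement radius keeping box IoU >= ``min_overlap``.

    Solves the three quadratic cases (both corners inward, outward, one
    each) and returns the most conservative root; used to size the
    Gaussian disc from the vertebra's bounding box on the grid.
    """
    h, w = box_height, box_width

    a1 = 1.0
    b1 = h + w
    c1 = w * h * (1 - min_overlap) / (1 + min_overlap)
    r1 = (b1 - np.sqrt(b1**2 - 4 * a1 * c1)) / (2 * a1)

    a2 = 4.0
    b2 = 2 * (h + w)
    c2 = (1 - min_overlap) * w * h
    r2 = (b2 - np.sqrt(b2**2 - 4 * a2 * c2)) / (2 * a2)

    a3 = 4.0 * min_overlap
    b3 = -2 * min_overlap * (h + w)
    c3 = (min_overlap - 1) * w * h
    r3 = (-b3 + np.sqrt(b3**2 - 4 * a3 * c3)) / (2 * a3)
    return float(min(r1, r2, r3))


def _sigmas(centers: np.ndarray, config: CodecConfig, boxes=None) -> np.ndarray:
    kind, value = config.sigma_policy
    n = centers.shape[0]
    if kind == "fixed" or boxes is None:
        sigma = value if kind == "fixed" else 2.0
        return np.full(n, float(sigma))
    sigmas = np.empty(n)
    for i, (bh, bw) in enumerate(boxes):
        r = gaussian_radius(bh / config.downsample_k, bw / config.downsample_k, value)
        sigmas[i] = max(r, 1.0) / 3.0
    return sigmas


def encode_heatmap(centers, config: CodecConfig, boxes=None) -> np.ndarray:
    """Gaussian-disc heatmap on the downsampled grid.

    ``boxes`` optionally gives per-vertebra (height, width) in input
    pixels for the IoU-radius sigma policy; without boxes a fixed default
    width is used.  Discs are merged by element-wise maximum, so every
    quantised center pixel keeps the exact peak value 1.
    """
    centers = _centers_array(centers)
    _check_inside(centers, config)
    k = config.downsample_k
    hm = np.zeros((config.grid_height, config.grid_width))
    sigmas = _sigmas(centers, config, boxes)
    ys, xs = np.arange(config.grid_height), np.arange(config.grid_width)
    for (cx, cy), sigma in zip(centers, sigmas):
        gx, gy = int(np.floor(cx / k)), int(np.floor(cy / k))
        extent = max(int(np.ceil(4 * sigma)), 1)
        x0, x1 = max(gx - extent, 0), min(gx + extent + 1, config.grid_width)
        y0, y1 = max(gy - extent, 0), min(gy + extent + 1, config.grid_height)
        dy = ys[y0:y1, None] - gy
        dx = xs[None, x0:x1] - gx
        disc = np.exp(-(dx**2 + dy**2) / (2 * sigma**2)) * config.heatmap_peak
        hm[y0:y1, x0:x1] = np.maximum(hm[y0:y1, x0:x1], disc)
    return hm


def encode_center_offset(centers, config: CodecConfig) -> tuple[np.ndarray, np.ndarray]:
    """Sub-pixel quantisation remainders at each quantised center pixel."""
    centers = _centers_array(centers)
    _check_inside(centers, config)
    k = config.downsample_k
    offset = np.zeros((2, config.grid_height, config.grid_width))
    mask = np.zeros((config.grid_height, config.grid_width), dtype=bool)
    for cx, cy in centers:
        gx, gy = int(np.floor(cx / k)), int(np.floor(cy / k))
        offset[0, gy, gx] = cx / k - gx
        offset[1, gy, gx] = cy / k - gy
        mask[gy, gx] = True
    return offset, mask


def corners_to_polar(quad: VertebraQuad, center: CenterPoint) -> list[PolarCorner]:
    """Polar coordinates (r, theta) of the 4 corners about the center.

    r is the Euclidean center-to-corner distance; theta the two-argument
    arctangent of (dy, dx) in (-pi, pi], so the polar axis points along
    +x and angles grow toward +y (downward in the image frame).  A corner
    coincident with the center maps to (0, 0).
    """
    c = center.as_array()
    out = []
    for corner in quad.corner_array():
        dx, dy = corner - c
        r = float(np.hypot(dx, dy))
        theta = float(np.arctan2(dy, dx)) if r > 0 else 0.0
        out.append(PolarCorner(r=r, theta=theta))
    return out


def polar_to_cartesian(center: CenterPoint, pc: PolarCorner):
    """Cartesian corner position: center + r (cos theta, sin theta)."""
    from .annotations import Landmark

    return Landmark(
        x=center.x_ct + pc.r * np.cos(pc.theta),
        y=center.y_ct + pc.r * np.sin(pc.theta),
    )


def _encode_corner_polar(ann: SpineAnnotation, config: CodecConfig) -> np.ndarray:
    k = config.downsample_k
    grid = np.zeros((8, config.grid_height, config.grid_width))
    centers = ann.center_array()
    for quad, (cx, cy) in zip(ann.vertebrae, centers):
        gx, gy = int(np.floor(cx / k)), int(np.floor(cy / k))
        polar = corners_to_polar(quad, CenterPoint(float(cx), float(cy)))
        for m, pc in enumerate(polar):
            grid[m, gy, gx] = pc.r
            grid[4 + m, gy, gx] = pc.theta
    return grid


def encode_cpie(centers, config: CodecConfig) -> tuple[np.ndarray, np.ndarray]:
    """Adjacent center intervals, anchored at the upper vertebra's pixel.

    For vertebra i (i = 1..n-1) the vector center(i+1) - center(i) in
    full-resolution pixels is stored at vertebra i's quantised center
    pixel; the last vertebra has no successor and stays unsupervised.
    """
    centers = _centers_array(centers)
    _check_inside(centers, config)
    k = config.downsample_k
    cpie = np.zeros((2, config.grid_height, config.grid_width))
    mask = np.zeros((config.grid_height, config.grid_width), dtype=bool)
    for i in range(centers.shape[0] - 1):
        cx, cy = centers[i]
        gx, gy = int(np.floor(cx / k)), int(np.floor(cy / k))
        cpie[:, gy, gx] = centers[i + 1] - centers[i]
        mask[gy, gx] = True
    return cpie, mask


def encode_avie(ann: SpineAnnotation, config: CodecConfig) -> tuple[np.ndarray, np.ndarray]:
    """Adjacent vertebra interval offsets, anchored at the lower vertebra.

    For vertebra i (i = 2..n) the 4-vector of offsets from the upper
    vertebra's bottom corners to this vertebra's top corners,
    (x1_i - x3_{i-1}, y1_i - y3_{i-1}, x2_i - x4_{i-1}, y2_i - y4_{i-1}),
    is stored at vertebra i's quantised center pixel; the first vertebra
    has no predecessor and stays unsupervised.
    """
    k = config.downsample_k
    corners = ann.corner_array()
    centers = ann.center_array()
    avie = np.zeros((4, config.grid_height, config.grid_width))
    mask = np.zeros((config.grid_height, config.grid_width), dtype=bool)
    for i in range(1, corners.shape[0]):
        cx, cy = centers[i]
        gx, gy = int(np.floor(cx / k)), int(np.floor(cy / k))
        tl = corners[i, 0] - corners[i - 1, 2]   # top-left from bottom-left
        tr = corners[i, 1] - corners[i - 1, 3]   # top-right from bottom-right
        avie[:, gy, gx] = np.concatenate([tl, tr])
        mask[gy, gx] = True
    return avie, mask


def encode_all(ann: SpineAnnotation, config: CodecConfig = CodecConfig()) -> EncodedTargets:
    """Full deterministic target encoding for one annotation."""
    centers = ann.center_array()
    corners = ann.corner_array()
    boxes = [
        (quad[:, 1].max() - quad[:, 1].min(), quad[:, 0].max() - quad[:, 0].min())
        for quad in corners
    ]
    heatmap = encode_heatmap(centers, config, boxes=boxes)
    center_offset, center_mask = encode_center_offset(centers, config)
    corner_polar = _encode_corner_polar(ann, config)
    cpie, cpie_mask = encode_cpie(centers, config)
    avie, avie_mask = encode_avie(ann, config)
    lines = encode_vertebral_lines(ann, config.spline)
    return EncodedTargets(
        heatmap=heatmap,
        center_offset=center_offset,
        corner_polar=corner_polar,
        cpie=cpie,
        avie=avie,
        vertebral_lines=lines,
        center_mask=center_mask,
        cpie_mask=cpie_mask,
        avie_mask=avie_mask,
    )


def nms(heatmap: np.ndarray) -> np.ndarray:
    """3x3 non-maximum suppression; plateau ties are all retained."""
    hm = np.asarray(heatmap, dtype=float)
    local_max = maximum_filter(hm, size=3, mode="constant", cval=-np.inf)
    return np.where(hm == local_max, hm, 0.0)


def _refine(
    pixels: np.ndarray, center_offset: np.ndarray, config: CodecConfig
) -> np.ndarray:
    """Turn (row, col) grid pixels into full-resolution centers."""
    k = config.downsample_k
    gy, gx = pixels[:, 0], pixels[:, 1]
    x = (gx + center_offset[0, gy, gx]) * k
    y = (gy + center_offset[1, gy, gx]) * k
    centers = np.stack([x, y], axis=1)
    order = np.argsort(centers[:, 1], kind="stable")
    return centers[order]


def topk_centers(
    heatmap: np.ndarray,
    center_offset: np.ndarray,
    config: CodecConfig,
    k_points: int = 17,
) -> np.ndarray:
    """The ``k_points`` strongest suppressed peaks as refined centers.

    Ties break by row-major pixel index; the offset channel restores the
    sub-pixel position and the result is scaled to input resolution and
    sorted by y (superior to inferior).  Returns a (k_points, 2) array.
    """
    suppressed = nms(heatmap)
    flat = suppressed.ravel()
    nonzero = int(np.count_nonzero(flat))
    if nonzero < k_points:
        raise ValueError(
            f"only {nonzero} nonzero peaks after suppression, need {k_points}"
        )
    order = np.lexsort((np.arange(flat.size), -flat))[:k_points]
    pixels = np.stack(np.unravel_index(order, suppressed.shape), axis=1)
    return _refine(pixels, center_offset, config)


def adaptive_centers(
    heatmap: np.ndarray,
    center_offset: np.ndarray,
    config: CodecConfig,
    threshold: float = 0.05,
) -> np.ndarray:
    """All suppressed peaks strictly above ``threshold``, refined.

    The count adapts to the heatmap content, so an image may yield more
    (or fewer) than 17 centers.  Returns an (n, 2) array sorted by y.
    """
    suppressed = nms(heatmap)
    rows, cols = np.nonzero(suppressed > threshold)
    if rows.size == 0:
        return np.empty((0, 2))
    pixels = np.stack([rows, cols], axis=1)
    return _refine(pixels, center_offset, config)


def decode_landmarks(
    centers: np.ndarray, corner_polar: np.ndarray, config: CodecConfig
) -> np.ndarray:
    """Corner landmarks from centers plus the polar offset grid.

    For each center, (r, theta) for corners 1..4 are read at its
    quantised grid pixel and converted back to Cartesian coordinates.
    Returns an (n, 4, 2) array.
    """
    centers = _centers_array(centers)
    k = config.downsample_k
    gx = np.floor(centers[:, 0] / k).astype(int)
    gy = np.floor(centers[:, 1] / k).astype(int)
    if np.any((gx < 0) | (gx >= config.grid_width) | (gy < 0) | (gy >= config.grid_height)):
        raise ValueError("center outside the decoding grid")
    rs = corner_polar[0:4, gy, gx].T        # (n, 4)
    thetas = corner_polar[4:8, gy, gx].T    # (n, 4)
    dx = rs * np.cos(thetas)
    dy = rs * np.sin(thetas)
    out = np.empty((centers.shape[0], 4, 2))
    out[:, :, 0] = centers[:, 0:1] + dx
    out[:, :, 1] = centers[:, 1:2] + dy
    return out
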