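"""The six supervision losses and their weighted composition.

All functions here are pure: they map prediction/target grids (plus
masks) to scalars, so they are testable with no network attached.  The
total training objective is

    L = a1*L_hm + a2*L_center + a3*L_corner + a4*L_CPIE + a5*L_AVIE + a6*L_VIL

with default weights a1..a5 = 1 and a6 = 0.05 (the vertebral-line term
runs over 100 dense points and is scaled down to keep the terms of
similar magnitude).  The vertebral-line loss itself decomposes per line:
L_VIL = L_vil_l + L_vil_m + L_vil_r, disabled lines contributing zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vertebral_lines import VertebralLineSet

__all__ = [
    "LossWeights",
    "LossTerms",
    "focal_loss",
    "masked_l1",
    "corner_polar_loss",
    "vil_loss",
    "total_loss",
    "FOCAL_ALPHA",
    "FOCAL_BETA",
    "EPS",
]

FOCAL_ALPHA = 2.0
FOCAL_BETA = 4.0
EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    """Per-term weights of the composite objective."""

    alpha1: float = 1.0
    alpha2: float = 1.0
    alpha3: float = 1.0
    alpha4: float = 1.0
    alpha5: float = 1.0
    alpha6: float = 0.05

    def __post_init__(self) -> None:
        if any(
            a < 0
            for a in (self.alpha1, self.alpha2, self.alpha3, self.alpha4, self.alpha5, self.alpha6)
        ):
            raise ValueError("loss weights must be >= 0")


@dataclass
class LossTerms:
    """The six named loss values plus the per-line VIL components."""

    L_hm: float = 0.0
    L_center: float = 0.0
    L_corner: float = 0.0
    L_CPIE: float = 0.0
    L_AVIE: float = 0.0
    L_VIL: float = 0.0
    L_vil_l: float = 0.0
    L_vil_m: float = 0.0
    L_vil_r: float = 0.0


def focal_loss(pred_heatmap: np.ndarray, gt_heatmap: np.ndarray) -> float:
    """Penalty-reduced pixel-wise focal loss for the center heatmap.

    At peak pixels (gt == 1): -(1 - p)^alpha log p; elsewhere
    -(1 - gt)^beta p^alpha log(1 - p), with alpha = 2, beta = 4.  The
    (1 - gt)^beta factor down-weights the pixels near (but not at) a
    Gaussian peak.  Summed and normalised by the number of peak pixels;
    predictions are clamped to [eps, 1 - eps].
    """
    pred = np.asarray(pred_heatmap, dtype=float)
    gt = np.asarray(gt_heatmap, dtype=float)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    p = np.clip(pred, EPS, 1.0 - EPS)
    pos = gt >= 1.0
    pos_loss = -((1.0 - p) ** FOCAL_ALPHA) * np.log(p)
    neg_loss = -((1.0 - gt) ** FOCAL_BETA) * (p**FOCAL_ALPHA) * np.log(1.0 - p)
    n_peaks = max(int(pos.sum()), 1)
    return float((pos_loss[pos].sum() + neg_loss[~pos].sum()) / n_peaks)


def masked_l1(pred_grid: np.ndarray, gt_grid: np.ndarray, mask: np.ndarray) -> float:
    """Mean absolute difference over masked positions; 0 on an empty mask.

    ``mask`` is broadcast over leading channel axes, so a (H, W) mask
    supervises every channel of a (C, H, W) grid at the same pixels.
    """
    pred = np.asarray(pred_grid, dtype=float)
    gt = np.asarray(gt_grid, dtype=float)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    mask = np.broadcast_to(np.asarray(mask, dtype=bool), pred.shape)
    if not mask.any():
        return 0.0
    return float(np.abs(pred - gt)[mask].mean())


def corner_polar_loss(
    pred_polar: np.ndarray, gt_polar: np.ndarray, mask: np.ndarray
) -> float:
    """Masked L1 on the polar corner grids, angle-aware.

    Channels 0..3 are radii (plain L1); channels 4..7 are angles, whose
    difference is wrapped to [0, pi] before the L1 so that the +/-pi
    branch cut does not produce spurious 2*pi-sized errors.
    """
    pred = np.asarray(pred_polar, dtype=float)
    gt = np.asarray(gt_polar, dtype=float)
    if pred.shape != gt.shape or pred.shape[0] != 8:
        raise ValueError(f"expected matching 8-channel grids; got {pred.shape} vs {gt.shape}")
    r_term = masked_l1(pred[0:4], gt[0:4], mask)
    dtheta = np.mod(np.abs(pred[4:8] - gt[4:8]), 2.0 * np.pi)
    wrapped = np.minimum(dtheta, 2.0 * np.pi - dtheta)
    theta_term = masked_l1(wrapped, np.zeros_like(wrapped), mask)
    return r_term + theta_term


def vil_loss(
    pred_lines: VertebralLineSet, gt_lines: VertebralLineSet
) -> tuple[float, float, float, float]:
    """Per-line mean absolute coordinate error and their sum.

    Returns (L_vil_l, L_vil_m, L_vil_r, L_VIL); lines disabled on both
    sides contribute zero.
    """
    terms = {}
    for side in ("left", "middle", "right"):
        pred = getattr(pred_lines, side)
        gt = getattr(gt_lines, side)
        if (pred is None) != (gt is None):
            raise ValueError(f"line {side!r} enabled on one side only")
        if pred is None:
            terms[side] = 0.0
            continue
        pred = np.asarray(pred, dtype=float)
        gt = np.asarray(gt, dtype=float)
        if pred.shape != gt.shape:
            raise ValueError(
                f"line {side!r} point-count mismatch: {pred.shape} vs {gt.shape}"
            )
        terms[side] = float(np.abs(pred - gt).mean())
    total = terms["left"] + terms["middle"] + terms["right"]
    return terms["left"], terms["middle"], terms["right"], total


def total_loss(terms: LossTerms, weights: LossWeights = LossWeights()) -> float:
    """Weighted sum of the six loss terms."""
    values = (
        terms.L_hm,
        terms.L_center,
        terms.L_corner,
        terms.L_CPIE,
        terms.L_AVIE,
        terms.L_VIL,
    )
    if not all(np.isfinite(v) for v in values):
        raise ValueError(f"non-finite loss term: {values}")
    alphas = (
        weights.alpha1,
        weights.alpha2,
        weights.alpha3,
        weights.alpha4,
        weights.alpha5,
        weights.alpha6,
    )
    return float(sum(a * v for a, v in zip(alphas, values)))
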