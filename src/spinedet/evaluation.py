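"""Cobb angle estimation and the landmark-detection metric suite.

The Cobb angle is the gold-standard scoliosis severity measure: the angle
between the endplate directions of the two most-tilted vertebrae of a
curve.  From 68 corner landmarks (17 vertebrae x 4 corners) we form one
slope vector per vertebra (left-edge midpoint to right-edge midpoint),
build the 17x17 matrix of pairwise angles, and read off the three regional
angles reported clinically:

* MT (main thoracic)       -- the maximum pairwise angle,
* PT (proximal thoracic)   -- the secondary angle above the MT pair,
* TL (thoracolumbar)       -- the secondary angle below the MT pair.

Metrics: MDE (mean Euclidean landmark error in pixels, poolable over a
dataset and splittable into the upper-10 / lower-7 vertebra regions),
SMAPE over the three Cobb angles (percent, symmetric in prediction and
ground truth), and the self-adaptive MDE, which replaces fixed top-k
center decoding with an intensity threshold and optimally re-orders the
detected vertebrae with the Hungarian algorithm before measuring the
landmark error, isolating localisation error from ordering error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .annotations import N_CORNERS, N_VERTEBRAE, SpineAnnotation

UPPER_VERTEBRAE = 10  # top-10 / bottom-7 region split
ADAPTIVE_THRESHOLD = 0.05

__all__ = [
    "CobbAngles",
    "MatchResult",
    "MetricReport",
    "cobb_from_landmarks",
    "cobb_from_slope_vectors",
    "mde",
    "smape",
    "hungarian_match",
    "self_adaptive_mde",
    "evaluate_case",
    "evaluate_dataset",
    "UPPER_VERTEBRAE",
    "ADAPTIVE_THRESHOLD",
]


@dataclass(frozen=True)
class CobbAngles:
    """The (PT, MT, TL) Cobb angle triple, in degrees."""

    PT: float
    MT: float
    TL: float

    def as_array(self) -> np.ndarray:
        return np.array([self.PT, self.MT, self.TL], dtype=float)


@dataclass
class MatchResult:
    """A predicted-to-ground-truth vertebra assignment."""

    pairs: list[tuple[int, int]]
    total_cost: float
    unmatched_pred: list[int] = field(default_factory=list)


@dataclass
class MetricReport:
    """Aggregated landmark and Cobb angle metrics for a case or dataset."""

    mde: float
    mde_upper: float
    mde_lower: float
    smape: float
    smape_pt: float
    smape_mt: float
    smape_tl: float
    self_adaptive_mde: float = float("nan")


def _as_landmark_array(landmarks) -> np.ndarray:
    if isinstance(landmarks, SpineAnnotation):
        arr = landmarks.landmark_array()
    else:
        arr = np.asarray(landmarks, dtype=float)
    if arr.ndim == 3:
        arr = arr.reshape(-1, 2)
    return arr


def cobb_from_slope_vectors(
    slope_vectors: np.ndarray,
    s_curve: bool,
) -> CobbAngles:
    """Regional Cobb angles from per-vertebra slope vectors.

    ``slope_vectors`` is (n, 2), one left-to-right endplate direction per
    vertebra ordered superior to inferior.  Pairwise angles are
    ``arccos`` of the normalised dot products, clipped to [0, 90] degrees
    so that parallel and anti-parallel vertebrae both read as aligned.

    MT is the global maximum, attained between vertebrae p1 < p2.  For a
    single (C-shaped) curve, PT is the angle between the first vertebra
    and p1 and TL the angle between the last vertebra and p2.  For an
    S-shaped spine (``s_curve=True``) the secondary angles are instead
    the maxima over the sub-ranges above p1 and below p2, which tracks
    the additional curve's own most-tilted pair.
    """
    vec = np.asarray(slope_vectors, dtype=float)
    n = vec.shape[0]
    norms = np.linalg.norm(vec, axis=1)
    if np.any(norms <= 0):
        bad = int(np.argmin(norms)) + 1
        raise ValueError(f"degenerate vertebra {bad}: zero-length slope vector")
    cosines = (vec @ vec.T) / np.outer(norms, norms)
    angles = np.degrees(np.arccos(np.clip(cosines, 0.0, 1.0)))

    flat = int(np.argmax(angles))
    p1, p2 = sorted(divmod(flat, n))
    mt = float(angles[p1, p2])
    if s_curve:
        pt = float(np.max(angles[p1, : p1 + 1]))
        tl = float(np.max(angles[p2, p2:]))
    else:
        pt = float(angles[0, p1])
        tl = float(angles[n - 1, p2])
    return CobbAngles(PT=pt, MT=mt, TL=tl)


def _is_s_curve(mid_points: np.ndarray) -> bool:
    """Sign test of lateral displacement residuals about the chord.

    Each interior midpoint's x displacement is compared with the straight
    chord between the first and last midpoints; mixed residual signs mean
    the spine bends both ways (an S curve).
    """
    p = np.asarray(mid_points, dtype=float)
    first, last = p[0], p[-1]
    dy = first[1] - last[1]
    dx = first[0] - last[0]
    if dy == 0 or dx == 0:
        return False
    interior = p[:-1]
    residual = (interior[:, 1] - last[1]) / dy - (interior[:, 0] - last[0]) / dx
    outer = np.outer(residual, residual)
    return bool(abs(outer.sum() - np.abs(outer).sum()) > 1e-4)


def cobb_from_landmarks(
    landmarks_68,
    s_curve_handling: bool = True,
) -> CobbAngles:
    """PT/MT/TL Cobb angles from 68 corner landmarks.

    Landmarks are ordered vertebra-major (superior to inferior), corners
    (top-left, top-right, bottom-left, bottom-right) per vertebra.  The
    per-vertebra slope vector runs from the left-edge midpoint (mean of
    corners 1 and 3) to the right-edge midpoint (mean of corners 2 and 4).
    With ``s_curve_handling`` the S-shape test selects the sub-range rule
    for the secondary angles (see :func:`cobb_from_slope_vectors`).
    """
    pts = _as_landmark_array(landmarks_68).reshape(-1, N_CORNERS, 2)
    left_mid = (pts[:, 0] + pts[:, 2]) / 2.0
    right_mid = (pts[:, 1] + pts[:, 3]) / 2.0
    slope = right_mid - left_mid
    # endplate midpoints, interleaved top/bottom, for the S-shape test
    top_mid = (pts[:, 0] + pts[:, 1]) / 2.0
    bottom_mid = (pts[:, 2] + pts[:, 3]) / 2.0
    mids = np.empty((2 * pts.shape[0], 2))
    mids[0::2] = top_mid
    mids[1::2] = bottom_mid
    s_curve = s_curve_handling and _is_s_curve(mids)
    return cobb_from_slope_vectors(slope, s_curve=s_curve)


def mde(pred_landmarks, gt_landmarks) -> float:
    """Mean Euclidean distance (pixels) between index-aligned landmarks."""
    pred = _as_landmark_array(pred_landmarks)
    gt = _as_landmark_array(gt_landmarks)
    if pred.shape != gt.shape:
        raise ValueError(
            f"landmark count mismatch: {pred.shape} vs {gt.shape}"
        )
    if pred.shape[0] == 0:
        raise ValueError("empty landmark set")
    return float(np.mean(np.linalg.norm(pred - gt, axis=1)))


def smape(
    pred_angles: Sequence[CobbAngles], gt_angles: Sequence[CobbAngles]
) -> tuple[float, float, float, float]:
    """SMAPE over the Cobb angle triples, in percent.

    Per case the ratio of summed absolute angle errors to the summed
    (pred + gt) angles is taken over the three regional angles, averaged
    over cases and scaled by 100.  The per-angle variants restrict both
    numerator and denominator to one angle; cases where both prediction
    and truth are exactly zero for that angle carry no information and
    are skipped (the variant is NaN when every case is skipped).  A zero
    three-angle denominator is an error naming the case.  Returns
    ``(smape, smape_pt, smape_mt, smape_tl)``.
    """
    if len(pred_angles) != len(gt_angles):
        raise ValueError("pred/gt case counts differ")
    if not pred_angles:
        raise ValueError("no cases")
    pred = np.stack([a.as_array() for a in pred_angles])
    gt = np.stack([a.as_array() for a in gt_angles])

    num = np.abs(pred - gt)
    den = pred + gt
    den_all = den.sum(axis=1)
    if np.any(den_all <= 0):
        bad = int(np.argmax(den_all <= 0))
        raise ValueError(f"zero angle-sum denominator for case {bad}")
    overall = float(np.mean(num.sum(axis=1) / den_all) * 100.0)

    per_angle = []
    for i in range(3):
        valid = den[:, i] > 0
        if not valid.any():
            per_angle.append(float("nan"))
            continue
        per_angle.append(
            float(np.mean(num[valid, i] / den[valid, i]) * 100.0)
        )
    return (overall, *per_angle)


def hungarian_match(pred_centers, gt_centers) -> MatchResult:
    """Minimum-total-distance assignment of predicted to true vertebrae.

    The cost matrix holds Euclidean center-to-center distances; with more
    predictions than ground-truth vertebrae the surplus predictions stay
    unmatched (rectangular assignment).
    """
    pred = np.atleast_2d(np.asarray(pred_centers, dtype=float))
    gt = np.atleast_2d(np.asarray(gt_centers, dtype=float))
    if pred.shape[0] == 0:
        raise ValueError("empty prediction set")
    cost = np.linalg.norm(pred[:, None, :] - gt[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    pairs = [(int(r), int(c)) for r, c in zip(rows, cols)]
    total = float(cost[rows, cols].sum())
    matched = set(rows.tolist())
    unmatched = [i for i in range(pred.shape[0]) if i not in matched]
    return MatchResult(pairs=pairs, total_cost=total, unmatched_pred=unmatched)


def self_adaptive_mde(
    heatmap,
    center_offset,
    corner_polar,
    gt_ann: SpineAnnotation,
    config,
    threshold: float = ADAPTIVE_THRESHOLD,
) -> float:
    """MDE after thresholded detection and optimal vertebra matching.

    Centers are decoded adaptively (all suppressed-heatmap peaks above
    ``threshold``, so possibly more or fewer than 17), their corner
    landmarks decoded from the polar grids, predicted and true vertebrae
    matched by center distance, and the landmark error averaged over the
    matched vertebrae's corners only.
    """
    from .label_codec import adaptive_centers, decode_landmarks

    centers = adaptive_centers(heatmap, center_offset, config, threshold)
    if centers.shape[0] == 0:
        raise ValueError(f"no center above threshold {threshold}")
    pred_corners = decode_landmarks(centers, corner_polar, config)
    match = hungarian_match(centers, gt_ann.center_array())
    gt_corners = gt_ann.corner_array()
    pred_sel = np.concatenate([pred_corners[r] for r, _ in match.pairs])
    gt_sel = np.concatenate([gt_corners[c] for _, c in match.pairs])
    return mde(pred_sel, gt_sel)


def _region_mde(pred: np.ndarray, gt: np.ndarray) -> tuple[float, float, float]:
    pred = pred.reshape(-1, N_CORNERS, 2)
    gt = gt.reshape(-1, N_CORNERS, 2)
    return (
        mde(pred, gt),
        mde(pred[:UPPER_VERTEBRAE], gt[:UPPER_VERTEBRAE]),
        mde(pred[UPPER_VERTEBRAE:], gt[UPPER_VERTEBRAE:]),
    )


def evaluate_case(pred, gt) -> MetricReport:
    """Per-case metrics from index-aligned 68-landmark sets."""
    pred = _as_landmark_array(pred)
    gt = _as_landmark_array(gt)
    overall, upper, lower = _region_mde(pred, gt)
    sm = smape([cobb_from_landmarks(pred)], [cobb_from_landmarks(gt)])
    return MetricReport(
        mde=overall,
        mde_upper=upper,
        mde_lower=lower,
        smape=sm[0],
        smape_pt=sm[1],
        smape_mt=sm[2],
        smape_tl=sm[3],
    )


def evaluate_dataset(cases: Sequence[tuple]) -> MetricReport:
    """Aggregate metrics over (pred, gt) pairs.

    MDE is landmark-pooled (the mean runs over every landmark in the
    dataset); SMAPE is case-averaged.
    """
    if not cases:
        raise ValueError("no cases")
    preds = [_as_landmark_array(p) for p, _ in cases]
    gts = [_as_landmark_array(g) for _, g in cases]
    pred_all = np.concatenate(preds)
    gt_all = np.concatenate(gts)
    overall, upper_, lower_ = (
        mde(pred_all, gt_all),
        mde(
            np.concatenate([p.reshape(-1, N_CORNERS, 2)[:UPPER_VERTEBRAE] for p in preds]),
            np.concatenate([g.reshape(-1, N_CORNERS, 2)[:UPPER_VERTEBRAE] for g in gts]),
        ),
        mde(
            np.concatenate([p.reshape(-1, N_CORNERS, 2)[UPPER_VERTEBRAE:] for p in preds]),
            np.concatenate([g.reshape(-1, N_CORNERS, 2)[UPPER_VERTEBRAE:] for g in gts]),
        ),
    )
    sm = smape(
        [cobb_from_landmarks(p) for p in preds],
        [cobb_from_landmarks(g) for g in gts],
    )
    return MetricReport(
        mde=overall,
        mde_upper=upper_,
        mde_lower=lower_,
        smape=sm[0],
        smape_pt=sm[1],
        smape_mt=sm[2],
        smape_tl=sm[3],
    )
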