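"""Domain types, validation and file I/O for spine landmark annotations.

Coordinate conventions
----------------------
All coordinates live in the standard image frame: origin at the top-left
pixel, ``x`` along image width (columns), ``y`` along image height (rows,
increasing downward), 0-based and real-valued (sub-pixel positions are
allowed).

An anterior-posterior spinal radiograph is annotated with 17 vertebrae
(thoracic + lumbar), each described by its 4 body corners.  Corners are
indexed 1..4 with the fixed semantics

    1 = top-left, 2 = top-right, 3 = bottom-left, 4 = bottom-right,

so the left vertebral border is the {1, 3} pair, the right border is
{2, 4}, the superior endplate is {1, 2} and the inferior endplate {3, 4}.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

N_VERTEBRAE = 17
N_CORNERS = 4
N_LANDMARKS = N_VERTEBRAE * N_CORNERS

__all__ = [
    "Landmark",
    "VertebraQuad",
    "SpineAnnotation",
    "CenterPoint",
    "ValidationReport",
    "AnnotationError",
    "centers_from_corners",
    "validate_annotation",
    "read_annotation",
    "write_annotation",
    "N_VERTEBRAE",
    "N_CORNERS",
    "N_LANDMARKS",
]


class AnnotationError(ValueError):
    """Raised for malformed annotation files or invalid annotations."""


@dataclass(frozen=True)
class Landmark:
    """A single annotated point in image coordinates (pixels)."""

    x: float
    y: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class CenterPoint:
    """Centroid of a vertebra's four corners (pixels)."""

    x_ct: float
    y_ct: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x_ct, self.y_ct], dtype=float)


@dataclass(frozen=True)
class VertebraQuad:
    """One vertebra: index 1..17 (superior to inferior) and 4 corners.

    ``corners`` is ordered (top-left, top-right, bottom-left, bottom-right).
    """

    index: int
    corners: tuple[Landmark, Landmark, Landmark, Landmark]

    def __post_init__(self) -> None:
        if len(self.corners) != N_CORNERS:
            raise AnnotationError(
                f"vertebra {self.index}: expected {N_CORNERS} corners, "
                f"got {len(self.corners)}"
            )

    def corner_array(self) -> np.ndarray:
        """Corners as a (4, 2) array in index order 1..4."""
        return np.array([[c.x, c.y] for c in self.corners], dtype=float)

    def center(self) -> CenterPoint:
        cx, cy = self.corner_array().mean(axis=0)
        return CenterPoint(float(cx), float(cy))


@dataclass
class SpineAnnotation:
    """Ordered list of 17 vertebral quadrilaterals plus the image size."""

    vertebrae: list[VertebraQuad]
    image_height: int
    image_width: int

    def corner_array(self) -> np.ndarray:
        """All corners as a (17, 4, 2) array (vertebra-major, corner-minor)."""
        return np.stack([v.corner_array() for v in self.vertebrae])

    def landmark_array(self) -> np.ndarray:
        """All 68 landmarks as a (68, 2) array, vertebra-major."""
        return self.corner_array().reshape(-1, 2)

    def center_array(self) -> np.ndarray:
        """Vertebra centroids as a (17, 2) array."""
        return self.corner_array().mean(axis=1)

    @classmethod
    def from_corner_array(
        cls, corners: np.ndarray, image_height: int, image_width: int
    ) -> "SpineAnnotation":
        """Build from a (n, 4, 2) or (4n, 2) corner array."""
        corners = np.asarray(corners, dtype=float)
        if corners.ndim == 2:
            if corners.shape[0] % N_CORNERS != 0 or corners.shape[1] != 2:
                raise AnnotationError(
                    f"landmark array must be (4n, 2); got {corners.shape}"
                )
            corners = corners.reshape(-1, N_CORNERS, 2)
        vertebrae = [
            VertebraQuad(
                index=i + 1,
                corners=tuple(Landmark(float(x), float(y)) for x, y in quad),
            )
            for i, quad in enumerate(corners)
        ]
        return cls(vertebrae, image_height=image_height, image_width=image_width)


@dataclass
class ValidationReport:
    """Pass/fail per invariant; report-style, never raises."""

    passed: bool = True
    violations: list[str] = field(default_factory=list)

    def record(self, message: str) -> None:
        self.passed = False
        self.violations.append(message)


def centers_from_corners(ann: SpineAnnotation) -> list[CenterPoint]:
    """Vertebral centers as component-wise means of the 4 corners.

    Output is ordered by vertebra index (superior to inferior).
    """
    report = validate_annotation(ann)
    if not report.passed:
        raise AnnotationError(
            "invalid annotation: " + "; ".join(report.violations)
        )
    return [CenterPoint(float(x), float(y)) for x, y in ann.center_array()]


def validate_annotation(
    ann: SpineAnnotation, n_vertebrae: int = N_VERTEBRAE
) -> ValidationReport:
    """Check the annotation invariants and return a report.

    Checked invariants: vertebra count, finite coordinates, corner order
    (x1 < x2, x3 < x4, top edge above bottom edge), and strictly
    increasing center y down the spine.
    """
    report = ValidationReport()
    if len(ann.vertebrae) != n_vertebrae:
        report.record(
            f"vertebra count: expected {n_vertebrae}, got {len(ann.vertebrae)}"
        )
        return report

    corners = ann.corner_array()
    if not np.all(np.isfinite(corners)):
        report.record("non-finite coordinates present")
        return report

    for i, quad in enumerate(corners, start=1):
        (x1, y1), (x2, y2), (x3, y3), (x4, y4) = quad
        if not (x1 < x2 and x3 < x4):
            report.record(
                f"corner order: vertebra {i} violates x1<x2 and x3<x4"
            )
        if not ((y1 + y2) / 2.0 < (y3 + y4) / 2.0):
            report.record(
                f"corner order: vertebra {i} top edge not above bottom edge"
            )

    center_y = corners.mean(axis=1)[:, 1]
    if not np.all(np.diff(center_y) > 0):
        report.record("vertebra centers not strictly increasing in y")
    return report


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

CSV_HEADER = ["vertebra", "corner", "x", "y"]


def _ann_to_json_obj(ann: SpineAnnotation) -> dict:
    return {
        "image_height": ann.image_height,
        "image_width": ann.image_width,
        "vertebrae": [
            {
                "index": v.index,
                "corners": [{"x": c.x, "y": c.y} for c in v.corners],
            }
            for v in ann.vertebrae
        ],
    }


def _ann_from_json_obj(obj: dict) -> SpineAnnotation:
    try:
        vertebrae = [
            VertebraQuad(
                index=int(v["index"]),
                corners=tuple(
                    Landmark(float(c["x"]), float(c["y"])) for c in v["corners"]
                ),
            )
            for v in obj["vertebrae"]
        ]
        return SpineAnnotation(
            vertebrae,
            image_height=int(obj["image_height"]),
            image_width=int(obj["image_width"]),
        )
    except (KeyError, TypeError) as exc:
        raise AnnotationError(f"malformed JSON annotation: {exc}") from exc


def write_annotation(
    ann: SpineAnnotation, path: str | Path, format: str | None = None
) -> None:
    """Write an annotation to ``path`` as csv, json or mat.

    ``format`` defaults to the file suffix.  CSV uses the dialect
    ``vertebra,corner,x,y`` (one row per landmark, UTF-8); JSON nests
    vertebrae and corners; MAT stores the 68x2 ``p2`` landmark array
    (vertebra-major, corner-minor).
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "json":
        path.write_text(json.dumps(_ann_to_json_obj(ann), indent=1))
    elif fmt == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(CSV_HEADER)
        for v in ann.vertebrae:
            for m, c in enumerate(v.corners, start=1):
                writer.writerow([v.index, m, repr(c.x), repr(c.y)])
        path.write_text(buf.getvalue(), encoding="utf-8")
    elif fmt == "mat":
        from scipy.io import savemat

        savemat(str(path), {"p2": ann.landmark_array()})
    else:
        raise AnnotationError(f"unknown annotation format: {fmt!r}")


def read_annotation(
    path: str | Path,
    format: str | None = None,
    image_height: int = 0,
    image_width: int = 0,
) -> SpineAnnotation:
    """Read an annotation from csv/json/mat.

    CSV and MAT files do not carry the image size; pass ``image_height``
    and ``image_width`` when known (they default to 0, meaning unknown).
    MAT reading accepts a 68x2 landmark array under the key ``p2``
    (falling back to the first 68x2 numeric array found), ordered
    vertebra-major, corner-minor.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "json":
        try:
            obj = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise AnnotationError(f"{path}: invalid JSON: {exc}") from exc
        return _ann_from_json_obj(obj)
    if fmt == "csv":
        return _read_csv(path, image_height, image_width)
    if fmt == "mat":
        return _read_mat(path, image_height, image_width)
    raise AnnotationError(f"unknown annotation format: {fmt!r}")


def _read_csv(path: Path, image_height: int, image_width: int) -> SpineAnnotation:
    rows: dict[tuple[int, int], tuple[float, float]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != CSV_HEADER:
            raise AnnotationError(f"{path}: bad or missing CSV header {header}")
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                vi, m = int(row[0]), int(row[1])
                x, y = float(row[2]), float(row[3])
            except (ValueError, IndexError) as exc:
                raise AnnotationError(
                    f"{path}: unparsable row {line_no}: {row}"
                ) from exc
            if (vi, m) in rows:
                raise AnnotationError(
                    f"{path}: duplicate landmark at row {line_no} "
                    f"(vertebra {vi}, corner {m})"
                )
            rows[(vi, m)] = (x, y)
    if len(rows) != N_LANDMARKS:
        raise AnnotationError(
            f"{path}: expected {N_LANDMARKS} landmark rows, got {len(rows)}"
        )
    corners = np.empty((N_VERTEBRAE, N_CORNERS, 2), dtype=float)
    for (vi, m), (x, y) in rows.items():
        if not (1 <= vi <= N_VERTEBRAE and 1 <= m <= N_CORNERS):
            raise AnnotationError(
                f"{path}: out-of-range indices vertebra={vi} corner={m}"
            )
        corners[vi - 1, m - 1] = (x, y)
    return SpineAnnotation.from_corner_array(corners, image_height, image_width)


def _read_mat(path: Path, image_height: int, image_width: int) -> SpineAnnotation:
    from scipy.io import loadmat

    data = loadmat(str(path))
    arr = data.get("p2")
    if arr is None:
        for key, value in data.items():
            if key.startswith("__"):
                continue
            value = np.asarray(value)
            if value.ndim == 2 and value.shape == (N_LANDMARKS, 2):
                arr = value
                break
    if arr is None:
        raise AnnotationError(
            f"{path}: no {N_LANDMARKS}x2 landmark array found"
        )
    arr = np.asarray(arr, dtype=float)
    if arr.shape != (N_LANDMARKS, 2):
        raise AnnotationError(
            f"{path}: landmark array has shape {arr.shape}, "
            f"expected ({N_LANDMARKS}, 2)"
        )
    return SpineAnnotation.from_corner_array(arr, image_height, image_width)
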