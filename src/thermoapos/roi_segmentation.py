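"""Anchor-driven segmentation of a filtered thermogram into 18 ROIs.

Segmentation is semi-automatic: an operator marks 12 named landmark pixels
(``Pur_1`` ... ``Pur_12``, right wrist through crotch), and each of the 18
regions of interest is then derived from its governing anchors plus row/column
traversal of the zero-background silhouette. The body is split into
left/right mirror pairs about the vertical midline through the head-trunk
anchors.

The exact per-ROI vertex construction is a configurable rule table
(:data:`DEFAULT_GEOMETRY`): every ROI maps to a function producing one simple
quadrilateral. The defaults build axis-aligned rectangles from anchor rows,
silhouette scan runs and a fixed same-size scale for the elbow patch; any
rule can be overridden without touching the rest of the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import AnchorValidationError, EmptyROIError, SegmentationError
from .thermal_io import TemperatureField

__all__ = [
    "ANCHOR_NAMES",
    "ANCHOR_LANDMARKS",
    "ROI_TABLE",
    "ROI_MIRROR_PAIRS",
    "AnchorSet",
    "ROIQuad",
    "ROISet",
    "GeometryParams",
    "validate_anchors",
    "body_boundary",
    "compute_roi_quads",
    "extract_roi",
    "points_in_polygon",
    "segment",
]

ANCHOR_NAMES = tuple(f"Pur_{i}" for i in range(1, 13))

#: Body-surface landmark bound to each anchor name.
ANCHOR_LANDMARKS = {
    "Pur_1": "right wrist",
    "Pur_2": "medial right elbow",
    "Pur_3": "right armpit",
    "Pur_4": "right shoulder",
    "Pur_5": "left wrist",
    "Pur_6": "medial left elbow",
    "Pur_7": "left armpit",
    "Pur_8": "left shoulder",
    "Pur_9": "forehead",
    "Pur_10": "chin",
    "Pur_11": "belly-button",
    "Pur_12": "crotch",
}

#: ROI label -> (body part, governing anchors).
ROI_TABLE = {
    "ROI1": ("right palm", ("Pur_1",)),
    "ROI2": ("right forearm", ("Pur_1", "Pur_2")),
    "ROI3": ("right anterior elbow", ("Pur_2",)),
    "ROI4": ("right upper arm", ("Pur_2", "Pur_3", "Pur_4")),
    "ROI5": ("left palm", ("Pur_5",)),
    "ROI6": ("left forearm", ("Pur_5", "Pur_6")),
    "ROI7": ("left anterior elbow", ("Pur_6",)),
    "ROI8": ("left upper arm", ("Pur_6", "Pur_7", "Pur_8")),
    "ROI9": ("right face", ("Pur_9", "Pur_10")),
    "ROI10": ("left face", ("Pur_9", "Pur_10")),
    "ROI11": ("right clavicle fossa", ("Pur_4", "Pur_8", "Pur_10")),
    "ROI12": ("left clavicle fossa", ("Pur_4", "Pur_8", "Pur_10")),
    "ROI13": ("right chest", ("Pur_3", "Pur_4", "Pur_7", "Pur_8", "Pur_11")),
    "ROI14": ("left chest", ("Pur_3", "Pur_4", "Pur_7", "Pur_8", "Pur_11")),
    "ROI15": ("right upper abdomen", ("Pur_4", "Pur_8", "Pur_11")),
    "ROI16": ("left upper abdomen", ("Pur_4", "Pur_8", "Pur_11")),
    "ROI17": ("right lower abdomen", ("Pur_11", "Pur_12")),
    "ROI18": ("left lower abdomen", ("Pur_11", "Pur_12")),
}

#: Left/right mirror pairing of ROI labels (right label first).
ROI_MIRROR_PAIRS = (
    ("ROI1", "ROI5"),
    ("ROI2", "ROI6"),
    ("ROI3", "ROI7"),
    ("ROI4", "ROI8"),
    ("ROI9", "ROI10"),
    ("ROI11", "ROI12"),
    ("ROI13", "ROI14"),
    ("ROI15", "ROI16"),
    ("ROI17", "ROI18"),
)


@dataclass
class AnchorSet:
    """The 12 named landmark pixels, each a 0-based (row, col) pair."""

    points: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        self.points = {k: (int(v[0]), int(v[1])) for k, v in self.points.items()}

    def __getitem__(self, name: str) -> tuple[int, int]:
        return self.points[name]

    def row(self, name: str) -> int:
        return self.points[name][0]

    def col(self, name: str) -> int:
        return self.points[name][1]

    def midline_col(self) -> float:
        """Vertical midline: mean column of the four head-trunk anchors."""
        return float(np.mean([self.col(n) for n in ("Pur_9", "Pur_10", "Pur_11", "Pur_12")]))

    def right_side_is_low_cols(self) -> bool:
        """Whether the subject's right-side anchors sit at lower column indices."""
        right = np.mean([self.col(n) for n in ("Pur_1", "Pur_2", "Pur_3", "Pur_4")])
        return bool(right < self.midline_col())

    def mirrored(self, cols: int) -> "AnchorSet":
        """Anchor set for the horizontally mirrored image, with left/right
        names swapped so each name still labels the same body side."""
        swap = {
            "Pur_1": "Pur_5", "Pur_2": "Pur_6", "Pur_3": "Pur_7", "Pur_4": "Pur_8",
            "Pur_5": "Pur_1", "Pur_6": "Pur_2", "Pur_7": "Pur_3", "Pur_8": "Pur_4",
        }
        return AnchorSet({
            swap.get(name, name): (r, cols - 1 - c)
            for name, (r, c) in self.points.items()
        })


@dataclass
class ROIQuad:
    """One labeled quadrilateral region: 4 (row, col) vertices in order."""

    label: str
    body_part: str
    vertices: np.ndarray  # shape (4, 2), float (row, col)
    anchors: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.shape != (4, 2):
            raise SegmentationError(f"{self.label}: quad needs exactly 4 vertices, got {v.shape}")
        self.vertices = v


@dataclass
class ROISet:
    """All 18 quads plus each region's rasterized temperature multiset
    (background zeros retained; granulation deals with them)."""

    quads: dict[str, ROIQuad]
    temperatures: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if set(self.quads) != set(ROI_TABLE):
            missing = sorted(set(ROI_TABLE) - set(self.quads))
            raise SegmentationError(f"ROISet must contain all 18 ROIs; missing {missing}")

    def __getitem__(self, label: str) -> np.ndarray:
        return self.temperatures[label]


def validate_anchors(anchors: AnchorSet, fld: TemperatureField) -> AnchorSet:
    """Check completeness, bounds, distinctness, and vertical ordering.

    Vertical ordering: forehead above chin above belly-button above crotch.
    Anchors sitting on background (zero) cells only warn — an operator may
    legitimately click just off the silhouette edge.
    """
    missing = [n for n in ANCHOR_NAMES if n not in anchors.points]
    if missing:
        raise AnchorValidationError(f"missing anchors: {missing}")
    for name in ANCHOR_NAMES:
        r, c = anchors[name]
        if not (0 <= r < fld.rows and 0 <= c < fld.cols):
            raise AnchorValidationError(
                f"{name} at ({r}, {c}) outside {fld.rows}x{fld.cols} image"
            )
    coords = [anchors[n] for n in ANCHOR_NAMES]
    if len(set(coords)) != len(coords):
        raise AnchorValidationError("anchor positions must be pairwise distinct")
    r9, r10, r11, r12 = (anchors.row(n) for n in ("Pur_9", "Pur_10", "Pur_11", "Pur_12"))
    if not (r9 < r10 < r11 < r12):
        raise AnchorValidationError(
            f"vertical ordering violated: forehead {r9}, chin {r10}, "
            f"belly-button {r11}, crotch {r12} must be strictly descending on the body"
        )
    on_background = [n for n in ANCHOR_NAMES if fld.values[anchors[n]] == 0.0]
    if on_background:
        warnings.warn(f"anchors on background cells: {on_background}", stacklevel=2)
    return anchors


def body_boundary(fld: TemperatureField, axis: str, index: int) -> tuple[int, int] | None:
    """First and last nonzero positions along one row or column scanline.

    ``axis='row'`` scans row ``index`` across columns; ``axis='col'`` scans
    column ``index`` across rows. Returns ``None`` for an all-zero scanline.
    """
    if axis == "row":
        line = fld.values[index, :]
    elif axis == "col":
        line = fld.values[:, index]
    else:
        raise SegmentationError(f"axis must be 'row' or 'col', got {axis!r}")
    nz = np.flatnonzero(line)
    if nz.size == 0:
        return None
    return int(nz[0]), int(nz[-1])


@dataclass(frozen=True)
class GeometryParams:
    """Tunable constants of the default geometry rules."""

    #: Anterior-elbow patch side as a fraction of the wrist-elbow distance
    #: (the same-size scale).
    elbow_scale: float = 0.5


# ---------------------------------------------------------------------------
# default geometry rules
# ---------------------------------------------------------------------------


def _rect(r0: float, r1: float, c0: float, c1: float) -> np.ndarray:
    return np.array([[r0, c0], [r0, c1], [r1, c1], [r1, c0]], dtype=np.float64)


#: How far (pixels) a silhouette scan may snap to the nearest nonzero run
#: when the requested column itself is background (an operator clicking just
#: off the silhouette edge). Beyond this the body part is considered absent.
SNAP_TOLERANCE = 10.0


def _run_containing(fld: TemperatureField, row: int, col: float, label: str) -> tuple[int, int]:
    """Contiguous nonzero column run in ``row`` containing (or within
    :data:`SNAP_TOLERANCE` of) the given column."""
    row = int(np.clip(row, 0, fld.rows - 1))
    line = fld.values[row, :] != 0.0
    if not line.any():
        raise SegmentationError(f"{label}: scanline row {row} is entirely background")
    nz = np.flatnonzero(line)
    # split into runs
    breaks = np.flatnonzero(np.diff(nz) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [nz.size - 1]))
    runs = [(int(nz[s]), int(nz[e])) for s, e in zip(starts, ends)]
    c = float(col)
    for c0, c1 in runs:
        if c0 <= c <= c1:
            return c0, c1
    dist, nearest = min(
        (min(abs(c - r[0]), abs(c - r[1])), r) for r in runs
    )
    if dist > SNAP_TOLERANCE:
        raise SegmentationError(
            f"{label}: no silhouette within {SNAP_TOLERANCE:g} px of column {col:g} in row {row}"
        )
    return nearest


def _last_body_row(fld: TemperatureField, from_row: int, c0: int, c1: int, label: str) -> int:
    band = fld.values[from_row:, c0 : c1 + 1] != 0.0
    rows_any = np.flatnonzero(band.any(axis=1))
    if rows_any.size == 0:
        raise SegmentationError(f"{label}: no body pixels below row {from_row} in band [{c0},{c1}]")
    return from_row + int(rows_any[-1])


def _side_cols(anchors: AnchorSet, side: str, c0: float, c1: float) -> tuple[float, float]:
    """Restrict a column interval to the subject's right or left half."""
    mid = anchors.midline_col()
    right_low = anchors.right_side_is_low_cols()
    take_low = (side == "right") == right_low
    if take_low:
        return min(c0, mid), mid
    return mid, max(c1, mid)


def _palm(anchors, fld, params, wrist):
    rw, cw = anchors[wrist]
    c0, c1 = _run_containing(fld, rw, cw, "palm")
    r1 = _last_body_row(fld, rw, c0, c1, "palm")
    return _rect(rw, r1, c0, c1)


def _forearm(anchors, fld, params, wrist, elbow):
    rw, cw = anchors[wrist]
    re_, ce = anchors[elbow]
    if re_ >= rw:
        raise SegmentationError("forearm: elbow anchor must lie above the wrist anchor")
    rm = (re_ + rw) // 2
    c0, c1 = _run_containing(fld, rm, (cw + ce) / 2.0, "forearm")
    return _rect(re_, rw, c0, c1)


def _anterior_elbow(anchors, fld, params, wrist, elbow):
    rw, cw = anchors[wrist]
    re_, ce = anchors[elbow]
    d = float(np.hypot(rw - re_, cw - ce))
    if d == 0.0:
        raise SegmentationError("anterior elbow: wrist and elbow anchors coincide")
    half = params.elbow_scale * d / 2.0
    return _rect(re_ - half, re_ + half, ce - half, ce + half)


def _upper_arm(anchors, fld, params, elbow, armpit, shoulder):
    re_, ce = anchors[elbow]
    ra, _ = anchors[armpit]
    rs, _ = anchors[shoulder]
    if not (rs < re_):
        raise SegmentationError("upper arm: shoulder anchor must lie above the elbow anchor")
    rm = (ra + re_) // 2
    c0, c1 = _run_containing(fld, rm, ce, "upper arm")
    return _rect(rs, re_, c0, c1)


def _face(anchors, fld, params, side):
    rf, cf = anchors["Pur_9"]
    rc, cc = anchors["Pur_10"]
    rm = (rf + rc) // 2
    c0, c1 = _run_containing(fld, rm, (cf + cc) / 2.0, "face")
    c0f, c1f = _side_cols(anchors, side, c0, c1)
    return _rect(rf, rc, c0f, c1f)


def _clavicle(anchors, fld, params, side):
    r_chin = anchors.row("Pur_10")
    shoulder = "Pur_4" if side == "right" else "Pur_8"
    rs, cs = anchors[shoulder]
    if not (r_chin < rs):
        raise SegmentationError("clavicle fossa: chin anchor must lie above the shoulders")
    mid = anchors.midline_col()
    c0, c1 = sorted((float(cs), mid))
    return _rect(r_chin, rs, c0, c1)


def _chest_rows(anchors) -> tuple[float, float]:
    ra = (anchors.row("Pur_3") + anchors.row("Pur_7")) / 2.0
    top = ra
    bottom = (ra + anchors.row("Pur_11")) / 2.0
    return top, bottom


def _chest(anchors, fld, params, side):
    top, bottom = _chest_rows(anchors)
    armpit = "Pur_3" if side == "right" else "Pur_7"
    mid = anchors.midline_col()
    c0, c1 = sorted((float(anchors.col(armpit)), mid))
    return _rect(top, bottom, c0, c1)


def _upper_abdomen(anchors, fld, params, side):
    _, chest_bottom = _chest_rows(anchors)
    r_belly = anchors.row("Pur_11")
    rm = int(round((chest_bottom + r_belly) / 2.0))
    c0, c1 = _run_containing(fld, rm, anchors.midline_col(), "upper abdomen")
    c0f, c1f = _side_cols(anchors, side, c0, c1)
    return _rect(chest_bottom, r_belly, c0f, c1f)


def _lower_abdomen(anchors, fld, params, side):
    r_belly = anchors.row("Pur_11")
    r_crotch = anchors.row("Pur_12")
    rm = (r_belly + r_crotch) // 2
    c0, c1 = _run_containing(fld, rm, anchors.midline_col(), "lower abdomen")
    c0f, c1f = _side_cols(anchors, side, c0, c1)
    return _rect(r_belly, r_crotch, c0f, c1f)


#: label -> rule(anchors, field, params) -> (4, 2) vertex array.
DEFAULT_GEOMETRY = {
    "ROI1": lambda a, f, p: _palm(a, f, p, "Pur_1"),
    "ROI2": lambda a, f, p: _forearm(a, f, p, "Pur_1", "Pur_2"),
    "ROI3": lambda a, f, p: _anterior_elbow(a, f, p, "Pur_1", "Pur_2"),
    "ROI4": lambda a, f, p: _upper_arm(a, f, p, "Pur_2", "Pur_3", "Pur_4"),
    "ROI5": lambda a, f, p: _palm(a, f, p, "Pur_5"),
    "ROI6": lambda a, f, p: _forearm(a, f, p, "Pur_5", "Pur_6"),
    "ROI7": lambda a, f, p: _anterior_elbow(a, f, p, "Pur_5", "Pur_6"),
    "ROI8": lambda a, f, p: _upper_arm(a, f, p, "Pur_6", "Pur_7", "Pur_8"),
    "ROI9": lambda a, f, p: _face(a, f, p, "right"),
    "ROI10": lambda a, f, p: _face(a, f, p, "left"),
    "ROI11": lambda a, f, p: _clavicle(a, f, p, "right"),
    "ROI12": lambda a, f, p: _clavicle(a, f, p, "left"),
    "ROI13": lambda a, f, p: _chest(a, f, p, "right"),
    "ROI14": lambda a, f, p: _chest(a, f, p, "left"),
    "ROI15": lambda a, f, p: _upper_abdomen(a, f, p, "right"),
    "ROI16": lambda a, f, p: _upper_abdomen(a, f, p, "left"),
    "ROI17": lambda a, f, p: _lower_abdomen(a, f, p, "right"),
    "ROI18": lambda a, f, p: _lower_abdomen(a, f, p, "left"),
}


def compute_roi_quads(
    anchors: AnchorSet,
    fld: TemperatureField,
    params: GeometryParams = GeometryParams(),
    geometry=None,
) -> dict[str, ROIQuad]:
    """Apply the (possibly overridden) rule table; always emits 18 quads.

    Vertices are clipped to the image bounds. Any failing rule raises a
    :class:`SegmentationError` naming the ROI.
    """
    geometry = dict(DEFAULT_GEOMETRY, **(geometry or {}))
    quads: dict[str, ROIQuad] = {}
    for label, (body_part, govern) in ROI_TABLE.items():
        try:
            verts = np.asarray(geometry[label](anchors, fld, params), dtype=np.float64)
        except SegmentationError as exc:
            raise SegmentationError(f"{label} ({body_part}): {exc}") from exc
        verts[:, 0] = np.clip(verts[:, 0], 0, fld.rows - 1)
        verts[:, 1] = np.clip(verts[:, 1], 0, fld.cols - 1)
        quads[label] = ROIQuad(label, body_part, verts, govern)
    return quads


def points_in_polygon(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Boundary-inclusive even-odd membership test, vectorized.

    ``points`` is (N, 2) of (row, col) cell centers; ``vertices`` is (M, 2).
    A point exactly on an edge counts as inside.
    """
    pts = np.asarray(points, dtype=np.float64)
    verts = np.asarray(vertices, dtype=np.float64)
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    on_edge = np.zeros(len(pts), dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        # on-segment test: collinear and within the bounding box
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        within = (
            (np.minimum(x1, x2) - 1e-12 <= x) & (x <= np.maximum(x1, x2) + 1e-12)
            & (np.minimum(y1, y2) - 1e-12 <= y) & (y <= np.maximum(y1, y2) + 1e-12)
        )
        on_edge |= (np.abs(cross) < 1e-9) & within
        # even-odd ray crossing (ray along +col from the point)
        cond = (x1 > x) != (x2 > x)
        with np.errstate(divide="ignore", invalid="ignore"):
            y_int = y1 + (x - x1) / (x2 - x1) * (y2 - y1)
        inside ^= cond & (y < y_int)
    return inside | on_edge


def extract_roi(fld: TemperatureField, quad: ROIQuad) -> np.ndarray:
    """Temperatures of all cells whose centers fall inside the quad.

    Zeros (filtered background) are retained; granulation decides what to do
    with them. Raises :class:`EmptyROIError` when no cell center is enclosed.
    """
    verts = quad.vertices
    r0 = max(0, int(np.floor(verts[:, 0].min())))
    r1 = min(fld.rows - 1, int(np.ceil(verts[:, 0].max())))
    c0 = max(0, int(np.floor(verts[:, 1].min())))
    c1 = min(fld.cols - 1, int(np.ceil(verts[:, 1].max())))
    if r1 < r0 or c1 < c0:
        raise EmptyROIError(f"{quad.label}: polygon lies outside the image")
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)
    mask = points_in_polygon(pts, verts)
    if not mask.any():
        raise EmptyROIError(f"{quad.label}: polygon encloses no grid-cell centers")
    return fld.values[r0 : r1 + 1, c0 : c1 + 1].ravel()[mask]


def segment(
    fld: TemperatureField,
    anchors: AnchorSet,
    params: GeometryParams = GeometryParams(),
    geometry=None,
) -> ROISet:
    """Full segmentation: validate anchors, build 18 quads, rasterize each."""
    validate_anchors(anchors, fld)
    quads = compute_roi_quads(anchors, fld, params, geometry)
    temps = {label: extract_roi(fld, quad) for label, quad in quads.items()}
    return ROISet(quads, temps)
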