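"""Contour primitives and planar geometry for short-axis cardiac MR analysis.

All coordinates live in physical patient space, in millimetres, using a
right-handed coordinate system.  A segmented study is represented as a
:class:`ContourStack`: an ordered list of short-axis :class:`Slice` objects
(slice 0 most basal, increasing toward the apex), each carrying epicardial
and (optionally) endocardial :class:`PlanarContour` objects at end diastole
(ED) and end systole (ES), plus the two right-ventricular insertion points
that delimit the interventricular septum on that slice.  Six labelled
atrioventricular-plane landmarks per phase (from the 2-, 3- and 4-chamber
long-axis views) and an apical reference point define the ventricular long
axis.

Conventions
-----------
* Contours are simple closed polygons; the closing edge from the last to the
  first vertex is implicit.
* Orientation is normalised so that the signed area in the slice's canonical
  in-plane basis (see :func:`plane_basis`) is positive; with the slice normal
  pointing base-to-apex this corresponds to counterclockwise as viewed from
  the apex toward the base.
* The septal arc between the two RV insertion points is, by default, the
  shorter of the two arcs; a per-slice ``septal_hint`` point can override
  this for pathological shapes, and is required to break an exact tie
  (antipodal insertion points).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon as _ShPolygon

__all__ = [
    "GeometryError",
    "InputError",
    "ED",
    "ES",
    "EPICARDIAL",
    "ENDOCARDIAL",
    "LANDMARK_LABELS",
    "PLANARITY_TOL_MM",
    "PlanarContour",
    "SlicePhase",
    "Slice",
    "LandmarkSet",
    "ContourStack",
    "as_point",
    "plane_basis",
    "project_to_plane",
    "signed_area_2d",
    "polygon_area",
    "orient_positive",
    "long_axis",
    "split_at_insertions",
    "split_arcs",
    "ArcSplit",
]

ED = "ED"
ES = "ES"
EPICARDIAL = "epicardial"
ENDOCARDIAL = "endocardial"

#: The six standardized atrioventricular-plane landmarks: inferoseptal and
#: anterolateral from the 4-chamber view, anteroseptal and inferolateral from
#: the 3-chamber view, anterior and inferior from the 2-chamber view.
LANDMARK_LABELS = (
    "inferoseptal",
    "anterolateral",
    "anteroseptal",
    "inferolateral",
    "anterior",
    "inferior",
)

#: Maximum allowed out-of-plane deviation of a contour vertex (sub-voxel).
PLANARITY_TOL_MM = 0.5


class GeometryError(ValueError):
    """A geometric precondition is violated (degenerate or invalid shape)."""


class InputError(ValueError):
    """Required input data are missing or malformed."""


def as_point(p) -> np.ndarray:
    """Coerce to a finite 3-vector of millimetre coordinates."""
    arr = np.asarray(p, dtype=float)
    if arr.shape != (3,):
        raise InputError(f"expected a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InputError(f"non-finite coordinates: {arr}")
    return arr


def plane_basis(normal) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic right-handed in-plane basis ``(u, v)`` with ``u x v = n``.

    The basis depends only on the normal direction, so every contour of a
    slice is expressed in the same 2-D frame and signed areas are mutually
    consistent.
    """
    n = as_point(normal)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise GeometryError("zero-length plane normal")
    n = n / norm
    ref = np.zeros(3)
    ref[int(np.argmin(np.abs(n)))] = 1.0
    u = np.cross(n, ref)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def project_to_plane(points, origin, normal) -> np.ndarray:
    """Project 3-D points onto the plane (origin, normal); returns (N, 2)."""
    u, v = plane_basis(normal)
    rel = np.atleast_2d(np.asarray(points, dtype=float)) - as_point(origin)
    return np.column_stack([rel @ u, rel @ v])


def signed_area_2d(xy: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon given as (N, 2) vertices."""
    xy = np.asarray(xy, dtype=float)
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


@dataclass
class PlanarContour:
    """Closed planar polygon on one short-axis slice.

    Parameters
    ----------
    vertices : (N, 3) array
        Ordered vertex list in mm; the first vertex is implicitly joined to
        the last.  N >= 3.
    surface : {"epicardial", "endocardial"}
    phase : {"ED", "ES"}
    """

    vertices: np.ndarray
    surface: str = EPICARDIAL
    phase: str = ED

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise InputError(
                f"contour vertices must be (N, 3), got {self.vertices.shape}"
            )
        if len(self.vertices) < 3:
            raise GeometryError("contour needs at least 3 vertices")
        if not np.all(np.isfinite(self.vertices)):
            raise InputError("non-finite contour vertex")
        if self.surface not in (EPICARDIAL, ENDOCARDIAL):
            raise InputError(f"unknown surface tag {self.surface!r}")
        if self.phase not in (ED, ES):
            raise InputError(f"unknown phase tag {self.phase!r}")

    def __len__(self) -> int:
        return len(self.vertices)

    def newell_normal(self) -> np.ndarray:
        """Robust polygon normal (Newell's method), unit length."""
        v = self.vertices
        w = np.roll(v, -1, axis=0)
        n = np.array(
            [
                np.sum((v[:, 1] - w[:, 1]) * (v[:, 2] + w[:, 2])),
                np.sum((v[:, 2] - w[:, 2]) * (v[:, 0] + w[:, 0])),
                np.sum((v[:, 0] - w[:, 0]) * (v[:, 1] + w[:, 1])),
            ]
        )
        norm = np.linalg.norm(n)
        if norm == 0:
            raise GeometryError("degenerate contour: zero normal")
        return n / norm

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def reversed(self) -> "PlanarContour":
        return PlanarContour(self.vertices[::-1].copy(), self.surface, self.phase)


def _as_xy(contour: PlanarContour, normal=None) -> np.ndarray:
    if normal is None:
        normal = contour.newell_normal()
    return project_to_plane(contour.vertices, contour.centroid(), normal)


def polygon_area(contour: PlanarContour, normal=None, context: str = "") -> float:
    """Area (mm^2) of a simple closed planar contour.

    Independent of the vertex ordering direction.  ``normal`` fixes the
    projection plane; when omitted it is estimated from the contour itself.

    Raises
    ------
    GeometryError
        If the polygon self-intersects or has zero area.  ``context`` (for
        example a slice description) is included in the message.
    """
    xy = _as_xy(contour, normal)
    where = f" ({context})" if context else ""
    if not _ShPolygon(xy).is_valid:
        raise GeometryError(f"self-intersecting {contour.surface} contour{where}")
    area = abs(signed_area_2d(xy))
    if area <= 0.0:
        raise GeometryError(f"zero-area contour{where}")
    return area


def orient_positive(contour: PlanarContour, normal) -> PlanarContour:
    """Return the contour ordered with positive signed area in the canonical
    in-plane basis of ``normal`` (counterclockwise viewed along the normal)."""
    xy = project_to_plane(contour.vertices, contour.centroid(), normal)
    if signed_area_2d(xy) < 0:
        return contour.reversed()
    return contour


@dataclass
class SlicePhase:
    """Per-phase content of one short-axis slice."""

    epicardial: PlanarContour | None = None
    endocardial: PlanarContour | None = None
    insertion_anterior: np.ndarray | None = None
    insertion_inferior: np.ndarray | None = None

    def __post_init__(self):
        if self.insertion_anterior is not None:
            self.insertion_anterior = as_point(self.insertion_anterior)
        if self.insertion_inferior is not None:
            self.insertion_inferior = as_point(self.insertion_inferior)

    def has_insertions(self) -> bool:
        return self.insertion_anterior is not None and self.insertion_inferior is not None


@dataclass
class Slice:
    """One short-axis imaging plane with its segmented content.

    ``index`` 0 is the most basal slice; indices increase toward the apex.
    ``origin``/``normal`` define the slice plane; the normal is unit length
    and, by convention, points from base toward apex.
    """

    index: int
    origin: np.ndarray
    normal: np.ndarray
    ed: SlicePhase = field(default_factory=SlicePhase)
    es: SlicePhase = field(default_factory=SlicePhase)
    septal_hint: np.ndarray | None = None

    def __post_init__(self):
        self.origin = as_point(self.origin)
        n = as_point(self.normal)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise GeometryError(f"slice {self.index}: zero-length normal")
        self.normal = n / norm
        if self.septal_hint is not None:
            self.septal_hint = as_point(self.septal_hint)
        for phase_name, phase in (("ED", self.ed), ("ES", self.es)):
            for c in (phase.epicardial, phase.endocardial):
                if c is None:
                    continue
                off = np.abs((c.vertices - self.origin) @ self.normal)
                if off.max() > PLANARITY_TOL_MM:
                    raise GeometryError(
                        f"slice {self.index} {phase_name} {c.surface} contour is "
                        f"{off.max():.2f} mm out of plane (tolerance "
                        f"{PLANARITY_TOL_MM} mm)"
                    )

    def phase(self, name: str) -> SlicePhase:
        if name == ED:
            return self.ed
        if name == ES:
            return self.es
        raise InputError(f"unknown phase {name!r}")


@dataclass
class LandmarkSet:
    """Six labelled atrioventricular-plane landmarks per phase, plus the ED
    apical reference point used to orient the long axis."""

    ed: dict[str, np.ndarray]
    es: dict[str, np.ndarray]
    apex_ed: np.ndarray

    def __post_init__(self):
        for phase_name, pts in (("ED", self.ed), ("ES", self.es)):
            missing = [lbl for lbl in LANDMARK_LABELS if lbl not in pts]
            if missing:
                raise InputError(
                    f"missing {phase_name} landmark(s): {', '.join(missing)}"
                )
            for lbl in LANDMARK_LABELS:
                pts[lbl] = as_point(pts[lbl])
        self.apex_ed = as_point(self.apex_ed)

    def array(self, phase: str) -> np.ndarray:
        pts = self.ed if phase == ED else self.es
        return np.array([pts[lbl] for lbl in LANDMARK_LABELS])


@dataclass
class ContourStack:
    """Full segmented geometry of one subject at ED and ES."""

    subject_id: str
    slices: list[Slice]
    slice_thickness_mm: float
    slice_gap_mm: float
    landmarks: LandmarkSet | None = None
    heart_rate_bpm: float | None = None

    def __post_init__(self):
        if self.slice_thickness_mm + self.slice_gap_mm <= 0:
            raise InputError("slice spacing (thickness + gap) must be positive")
        idx = [s.index for s in self.slices]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise InputError("slice indices must be unique and increasing")
        if self.landmarks is not None and len(self.slices) >= 2:
            axis, base = long_axis(self)
            pos = [float((s.origin - base) @ axis) for s in self.slices]
            if not np.all(np.diff(pos) > 0):
                raise InputError(
                    "slice ordering is not monotone along the long axis"
                )

    @property
    def spacing_mm(self) -> float:
        """Centre-to-centre slice spacing: thickness + gap."""
        return self.slice_thickness_mm + self.slice_gap_mm


def long_axis(stack: ContourStack) -> tuple[np.ndarray, np.ndarray]:
    """Ventricular long axis of a stack.

    Returns the unit direction from the centroid of the six ED landmarks
    toward the ED apical reference (i.e. pointing base-to-apex) and that
    centroid as the base reference point.
    """
    if stack.landmarks is None:
        raise InputError("stack has no landmark set")
    base = stack.landmarks.array(ED).mean(axis=0)
    vec = stack.landmarks.apex_ed - base
    norm = np.linalg.norm(vec)
    if norm < 1e-6:
        raise GeometryError("degenerate long axis: apex coincides with base centroid")
    return vec / norm, base


def _snap_index(contour: PlanarContour, point) -> int:
    d = np.linalg.norm(contour.vertices - as_point(point), axis=1)
    return int(np.argmin(d))


def _arc_indices(n: int, start: int, end: int) -> np.ndarray:
    """Vertex indices from start to end inclusive, following contour order."""
    if end >= start:
        return np.arange(start, end + 1)
    return np.concatenate([np.arange(start, n), np.arange(0, end + 1)])


def _path_length(vertices: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(vertices, axis=0), axis=1).sum())


@dataclass
class ArcSplit:
    """Result of splitting a contour at the two RV insertion points.

    ``septal_indices`` runs in contour order and includes both snapped
    insertion vertices; ``free_indices`` is the complementary open arc,
    excluding them, so the concatenation covers every vertex exactly once.
    ``septal_start`` names the insertion point ("anterior" or "inferior") at
    which the septal arc begins.
    """

    septal_indices: np.ndarray
    free_indices: np.ndarray
    septal_start: str
    anterior_index: int
    inferior_index: int


_TIE_RTOL = 1e-9


def split_arcs(
    contour: PlanarContour,
    anterior,
    inferior,
    septal_hint=None,
) -> ArcSplit:
    """Partition a closed contour at the RV insertion points into septal and
    free-wall arcs.

    The insertion points are snapped to the nearest contour vertex.  The
    septal arc is the shorter of the two arcs by path length unless a
    ``septal_hint`` point is given, in which case the arc whose midpoint lies
    nearer the hint is chosen.  An exact length tie without a hint is an
    error.
    """
    n = len(contour)
    ia = _snap_index(contour, anterior)
    ii = _snap_index(contour, inferior)
    if ia == ii:
        raise GeometryError(
            "both insertion points snap to the same contour vertex"
        )
    arc_a = _arc_indices(n, ia, ii)  # starts at anterior
    arc_b = _arc_indices(n, ii, ia)  # starts at inferior
    len_a = _path_length(contour.vertices[arc_a])
    len_b = _path_length(contour.vertices[arc_b])
    if septal_hint is not None:
        hint = as_point(septal_hint)
        mid_a = contour.vertices[arc_a[len(arc_a) // 2]]
        mid_b = contour.vertices[arc_b[len(arc_b) // 2]]
        use_a = np.linalg.norm(mid_a - hint) <= np.linalg.norm(mid_b - hint)
    else:
        if np.isclose(len_a, len_b, rtol=_TIE_RTOL, atol=0.0):
            raise GeometryError(
                "insertion points are antipodal: a septal-side hint is "
                "required to identify the septal arc"
            )
        use_a = len_a < len_b
    septal = arc_a if use_a else arc_b
    free_full = arc_b if use_a else arc_a
    free = free_full[1:-1]  # interior only: endpoints belong to the septal arc
    return ArcSplit(
        septal_indices=septal,
        free_indices=free,
        septal_start="anterior" if use_a else "inferior",
        anterior_index=ia,
        inferior_index=ii,
    )


def split_at_insertions(
    contour: PlanarContour,
    anterior,
    inferior,
    septal_hint=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Split a contour at the RV insertion points.

    Returns ``(septal_vertices, free_wall_vertices)`` as open polylines in
    contour order.  The septal arc includes the two snapped insertion
    vertices; the free-wall arc is the complement (their concatenation
    reproduces the full vertex set exactly once).
    """
    split = split_arcs(contour, anterior, inferior, septal_hint)
    return (
        contour.vertices[split.septal_indices].copy(),
        contour.vertices[split.free_indices].copy(),
    )
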