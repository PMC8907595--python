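"""Landmark geometry: the four facial parameters S, Le, H1, H2.

A photograph of a rodent face is reduced to a small set of 2D landmarks
annotated in image coordinates (origin top-left, y increasing downward,
units pixels, sub-pixel values permitted):

* the two outer canthi (lateral eye corners),
* the nose tip,
* an ordered simple polygon tracing the outer edge of the face.

From these the module computes

=====  ==============================================================
S      facial area: exact (shoelace) area of the outline polygon, px²
Le     interocular distance between the outer canthi, px
H1     perpendicular distance from the nose tip to the line through
       both canthi, px
H2     distance from the nose tip to the canthus midpoint, px
=====  ==============================================================

Le proxies camera-to-head distance (the interocular width is anatomically
fixed), H1 proxies head pitch (lift/lower) and the H2:H1 ratio signals
head rotation: a frontal face has H1 = H2, a turned head has H2 > H1.
H1 is taken perpendicular to the canthus line rather than parallel to the
image's vertical axis; the two coincide for a level eye line.

Since the canthus midpoint lies on the canthus line and H1 is the
shortest distance to that line, H2 >= H1 holds for every annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import shapely

from .errors import InvalidAnnotationError

__all__ = [
    "Landmark2D",
    "FaceAnnotation",
    "FaceMeasurement",
    "polygon_area",
    "interocular_distance",
    "nose_heights",
    "measure",
]

GROUPS = ("control", "model", "positive")


class Landmark2D(NamedTuple):
    """One annotated point, image convention (x right, y down), pixels."""

    x: float
    y: float


def _as_landmark(p) -> Landmark2D:
    x, y = float(p[0]), float(p[1])
    return Landmark2D(x, y)


@dataclass
class FaceAnnotation:
    """Landmarks of one photograph plus study metadata.

    ``outline`` is an (n, 2) float array of ordered vertices forming a
    simple polygon; the closing edge is implicit.  Construction is cheap;
    call :meth:`validate` to enforce the geometric invariants (the
    library does so inside :func:`measure` by default).
    """

    rat_id: str
    group: str
    day: int
    left_canthus: Landmark2D
    right_canthus: Landmark2D
    nose_tip: Landmark2D
    outline: np.ndarray
    image_size: tuple[int, int] = (3000, 4000)

    def __post_init__(self):
        self.left_canthus = _as_landmark(self.left_canthus)
        self.right_canthus = _as_landmark(self.right_canthus)
        self.nose_tip = _as_landmark(self.nose_tip)
        self.outline = np.asarray(self.outline, dtype=float)

    # -- invariants ------------------------------------------------------

    def validate(self) -> "FaceAnnotation":
        """Check all annotation invariants; raise InvalidAnnotationError.

        Returns self so it can be chained.
        """
        pts = self.outline
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidAnnotationError(
                f"{self._ctx()}: outline must be an (n, 2) array of vertices"
            )
        coords = np.concatenate(
            [
                pts.ravel(),
                np.array(self.left_canthus + self.right_canthus + self.nose_tip),
            ]
        )
        if not np.isfinite(coords).all():
            raise InvalidAnnotationError(f"{self._ctx()}: non-finite coordinate")
        if pts.shape[0] < 3:
            raise InvalidAnnotationError(
                f"{self._ctx()}: outline needs at least 3 vertices, got {pts.shape[0]}"
            )
        if _canthus_span(self) <= 0.0:
            raise InvalidAnnotationError(f"{self._ctx()}: coincident canthi")
        poly = shapely.Polygon(pts)
        if not poly.is_valid or poly.area <= 0.0:
            raise InvalidAnnotationError(
                f"{self._ctx()}: outline polygon is self-intersecting or degenerate"
            )
        nose = shapely.Point(self.nose_tip)
        # boundary tolerance: an annotated nose exactly on the outline is legal
        if not poly.covers(nose) and poly.exterior.distance(nose) > 1e-9 * np.sqrt(poly.area):
            raise InvalidAnnotationError(
                f"{self._ctx()}: nose tip lies outside the face outline"
            )
        return self

    def _ctx(self) -> str:
        return f"rat {self.rat_id!r} day {self.day}"

    # -- transforms (used by tests and tooling) --------------------------

    def translated(self, dx: float, dy: float) -> "FaceAnnotation":
        shift = np.array([dx, dy], dtype=float)
        return replace(
            self,
            left_canthus=Landmark2D(*(np.add(self.left_canthus, shift))),
            right_canthus=Landmark2D(*(np.add(self.right_canthus, shift))),
            nose_tip=Landmark2D(*(np.add(self.nose_tip, shift))),
            outline=self.outline + shift,
        )


@dataclass(frozen=True)
class FaceMeasurement:
    """Raw S, Le, H1, H2 of one photograph, all in pixel units."""

    rat_id: str
    group: str
    day: int
    S: float
    Le: float
    H1: float
    H2: float


def _canthus_span(a: FaceAnnotation) -> float:
    dx = a.right_canthus.x - a.left_canthus.x
    dy = a.right_canthus.y - a.left_canthus.y
    return float(np.hypot(dx, dy))


def polygon_area(outline: Sequence | np.ndarray, *, check: bool = True) -> float:
    """Exact absolute area of a simple polygon from its ordered vertices.

    Shoelace formula; independent of vertex orientation and starting
    vertex.  With ``check=True`` (default) the polygon is verified to be
    simple (non-self-intersecting) and non-degenerate.
    """
    pts = np.asarray(outline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise InvalidAnnotationError(
            "polygon needs an (n>=3, 2) vertex array, got shape "
            f"{getattr(pts, 'shape', None)}"
        )
    if not np.isfinite(pts).all():
        raise InvalidAnnotationError("polygon has non-finite vertices")
    if check:
        poly = shapely.Polygon(pts)
        if not poly.is_valid or poly.area <= 0.0:
            raise InvalidAnnotationError(
                "polygon is self-intersecting or degenerate"
            )
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def interocular_distance(a: FaceAnnotation) -> float:
    """Le: Euclidean distance between the outer canthi (symmetric in L/R)."""
    le = _canthus_span(a)
    if le <= 0.0:
        raise InvalidAnnotationError(f"{a._ctx()}: coincident canthi")
    return le


def nose_heights(a: FaceAnnotation) -> tuple[float, float]:
    """(H1, H2): perpendicular and midpoint distances from the nose tip.

    H1 is the point-to-line distance from the nose tip to the infinite
    line through both canthi; H2 the distance to the canthus midpoint.
    H2 >= H1 is guaranteed (enforced against floating-point noise).
    """
    c1 = np.array(a.left_canthus, dtype=float)
    c2 = np.array(a.right_canthus, dtype=float)
    d = c2 - c1
    le = float(np.hypot(*d))
    if le <= 0.0:
        raise InvalidAnnotationError(f"{a._ctx()}: coincident canthi")
    n = np.array(a.nose_tip, dtype=float) - c1
    h1 = abs(float(d[0] * n[1] - d[1] * n[0])) / le
    mid = 0.5 * (c1 + c2)
    h2 = float(np.hypot(*(np.array(a.nose_tip, dtype=float) - mid)))
    return h1, max(h2, h1)


def measure(a: FaceAnnotation, *, validate: bool = True) -> FaceMeasurement:
    """Bundle S, Le, H1, H2 for one annotation.

    Deterministic; with ``validate=True`` the annotation invariants are
    checked first and violations are reported with rat/day context.
    """
    if validate:
        a.validate()
    s = polygon_area(a.outline, check=validate)
    le = interocular_distance(a)
    h1, h2 = nose_heights(a)
    return FaceMeasurement(
        rat_id=a.rat_id, group=a.group, day=a.day, S=s, Le=le, H1=h1, H2=h2
    )
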