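"""Synthetic ground truth: a 3D rodent head projected by a pinhole camera.

The calibration stages can only be validated against known ground truth,
and no annotated photographs are available, so this module generates
them.  The head is a rigid landmark model, not a rendered image — the
measurement pipeline consumes landmarks, so rasterization is out of
scope:

* two eyes (outer canthi) at (±w/2, 0, 0), interocular width w;
* a nose tip at (0, d, -p): d mm below the eye line in-plane and
  protruding p mm toward the camera (p = 0 gives a fully planar head);
* an elliptical face outline with semi-axes (a, b) sampled at n
  vertices in the eye plane z = 0, centred on the eye midpoint.  A
  dimensionless swelling factor s multiplies the outline *area*
  (semi-axes scale by sqrt(s)), leaving w, d, p untouched.

Head frame: x to the animal's image-left, y downward, z into the scene
(negative z toward the camera).  A pose is a yaw rotation about the
vertical axis through the eye midpoint, then a pitch rotation about the
eye line (positive pitch = head lifted, nose rising toward the eye line
in the image), then translation to distance Z.  The ideal pinhole maps
(X, Y, Z') to (f*X/Z' + cx, f*Y/Z' + cy) with Z' the point's depth.

Default geometry approximates an adult rat (w = 30 mm, d = 35 mm,
p = 10 mm, a = 30 mm, b = 40 mm) — plausibility placeholders, not
measured values.  The default camera pairs the 3000 x 4000 px frame
with a long focal length (15000 px) at Z ≈ 1.5 m, i.e. a telephoto,
weak-perspective capture at 10 px/mm.  The linear H1 tilt correction is
exact only in the orthographic limit; its perspective bias ~ d*sin(φ)/Z
is below 1% in this regime but grows to several percent at arm's-length
distances (see docs/methods.md).

With zero landmark jitter the generator is a deterministic function of
its parameters; jitter is i.i.d. Gaussian per coordinate driven by an
explicit seed/Generator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .errors import GenerationError
from .geometry import FaceAnnotation, polygon_area

__all__ = [
    "HeadModel3D",
    "Pose",
    "CameraModel",
    "build_head",
    "project",
    "frontal_reference",
    "rotation_bundle",
]


@dataclass(frozen=True)
class HeadModel3D:
    """Rigid landmark head model; lengths in millimetres."""

    interocular_w: float = 30.0
    nose_drop: float = 35.0
    nose_protrusion: float = 10.0
    outline_semiaxes: tuple[float, float] = (30.0, 40.0)
    outline_vertices: int = 36
    swelling: float = 1.0

    def with_swelling(self, s: float) -> "HeadModel3D":
        return replace(self, swelling=float(s))

    # -- landmark construction ------------------------------------------

    def eye_points(self) -> np.ndarray:
        w = self.interocular_w
        return np.array([[-w / 2, 0.0, 0.0], [w / 2, 0.0, 0.0]])

    def nose_point(self) -> np.ndarray:
        return np.array([0.0, self.nose_drop, -self.nose_protrusion])

    def outline_points(self) -> np.ndarray:
        a, b = self.outline_semiaxes
        k = np.sqrt(self.swelling)
        t = 2.0 * np.pi * np.arange(self.outline_vertices) / self.outline_vertices
        return np.column_stack(
            [a * k * np.cos(t), b * k * np.sin(t), np.zeros_like(t)]
        )

    @property
    def true_area_mm2(self) -> float:
        """Frontal-view outline area in mm² (n-gon discretization of
        pi*a*b*s; approaches the ellipse area as n grows)."""
        return polygon_area(self.outline_points()[:, :2], check=False)


def build_head(
    interocular_w: float = 30.0,
    nose_drop: float = 35.0,
    nose_protrusion: float = 10.0,
    outline_semiaxes: tuple[float, float] = (30.0, 40.0),
    outline_vertices: int = 36,
    swelling: float = 1.0,
) -> HeadModel3D:
    """Validated constructor for :class:`HeadModel3D`."""
    a, b = outline_semiaxes
    if not (interocular_w > 0 and a > 0 and b > 0):
        raise GenerationError("interocular width and outline semi-axes must be > 0")
    if nose_protrusion < 0:
        raise GenerationError("nose protrusion must be >= 0")
    if not swelling > 0:
        raise GenerationError("swelling factor must be > 0")
    if outline_vertices < 12:
        raise GenerationError("outline needs at least 12 vertices")
    return HeadModel3D(
        interocular_w=float(interocular_w),
        nose_drop=float(nose_drop),
        nose_protrusion=float(nose_protrusion),
        outline_semiaxes=(float(a), float(b)),
        outline_vertices=int(outline_vertices),
        swelling=float(swelling),
    )


@dataclass(frozen=True)
class Pose:
    """Camera distance (mm, to the eye plane) and head yaw/pitch (deg)."""

    distance: float
    yaw_deg: float = 0.0
    pitch_deg: float = 0.0

    def __post_init__(self):
        if not self.distance > 0:
            raise GenerationError(f"distance must be > 0, got {self.distance}")
        if abs(self.yaw_deg) >= 60 or abs(self.pitch_deg) >= 60:
            raise GenerationError("|yaw| and |pitch| must be < 60 degrees")


@dataclass(frozen=True)
class CameraModel:
    """Ideal pinhole: focal length and principal point in pixels."""

    focal_px: float = 15000.0
    cx: float = 1500.0
    cy: float = 2000.0
    image_size: tuple[int, int] = (3000, 4000)

    def __post_init__(self):
        if not self.focal_px > 0:
            raise GenerationError("focal length must be > 0")


def _rotation(yaw_deg: float, pitch_deg: float) -> np.ndarray:
    """Yaw about the vertical (y) axis, then pitch about the eye line (x).

    Positive pitch lifts the head: face points (y > 0) rotate toward
    the camera and the nose rises in the image.  Both rotations are
    about the eye midpoint / eye line, so the eyes are fixed points of
    the pitch rotation.
    """
    ty, tp = np.deg2rad(yaw_deg), np.deg2rad(pitch_deg)
    ry = np.array(
        [
            [np.cos(ty), 0.0, np.sin(ty)],
            [0.0, 1.0, 0.0],
            [-np.sin(ty), 0.0, np.cos(ty)],
        ]
    )
    rx = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, np.cos(tp), np.sin(tp)],
            [0.0, -np.sin(tp), np.cos(tp)],
        ]
    )
    return rx @ ry


def _project_points(
    pts: np.ndarray, pose: Pose, cam: CameraModel
) -> np.ndarray:
    """Rigid pose transform + pinhole projection of (n, 3) head-frame points."""
    q = pts @ _rotation(pose.yaw_deg, pose.pitch_deg).T
    depth = pose.distance + q[:, 2]
    if (depth <= 0).any():
        raise GenerationError("landmark behind the camera after pose transform")
    u = cam.focal_px * q[:, 0] / depth + cam.cx
    v = cam.focal_px * q[:, 1] / depth + cam.cy
    return np.column_stack([u, v])


def project(
    head: HeadModel3D,
    pose: Pose,
    cam: CameraModel = CameraModel(),
    jitter_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    *,
    rat_id: str = "synthetic",
    group: str = "control",
    day: int = 0,
    z_ref: float | None = None,
) -> tuple[FaceAnnotation, dict]:
    """Photograph the head: annotation landmarks plus a truth record.

    jitter_sd adds i.i.d. Gaussian landmark-placement noise (pixels) to
    every coordinate, emulating manual annotation; it is driven by
    ``rng`` (seed or Generator) and the call is bit-reproducible for a
    fixed seed.  The truth record carries the frontal-projection area at
    ``z_ref`` (defaulting to the pose's own distance), which is the
    target every calibration stage aims to recover.

    Raises GenerationError if any landmark falls behind the camera or
    outside the image frame.
    """
    eyes = head.eye_points()
    nose = head.nose_point()
    outline = head.outline_points()
    pts = np.vstack([eyes, nose[None, :], outline])
    uv = _project_points(pts, pose, cam)
    if jitter_sd > 0.0:
        gen = np.random.default_rng(rng)
        uv = uv + gen.normal(0.0, jitter_sd, size=uv.shape)
    w, h = cam.image_size
    if (uv[:, 0] < 0).any() or (uv[:, 0] > w).any() or (uv[:, 1] < 0).any() or (
        uv[:, 1] > h
    ).any():
        raise GenerationError(
            f"rat {rat_id!r} day {day}: projected landmark outside the "
            f"{w}x{h} image (distance too small?)"
        )
    ann = FaceAnnotation(
        rat_id=rat_id,
        group=group,
        day=day,
        left_canthus=tuple(uv[0]),
        right_canthus=tuple(uv[1]),
        nose_tip=tuple(uv[2]),
        outline=uv[3:],
        image_size=cam.image_size,
    )
    truth = {
        "A_true_mm2": head.true_area_mm2,
        "swelling": head.swelling,
        "Z_mm": pose.distance,
        "yaw_deg": pose.yaw_deg,
        "pitch_deg": pose.pitch_deg,
        "frontal_ref_px2": frontal_reference(
            head, cam, pose.distance if z_ref is None else z_ref
        ),
    }
    return ann, truth


def frontal_reference(head: HeadModel3D, cam: CameraModel, z_ref: float) -> float:
    """Projected outline area (px²) at zero yaw/pitch and distance z_ref.

    This is the standardized quantity the full calibration pipeline
    estimates for every photograph.
    """
    uv = _project_points(head.outline_points(), Pose(distance=z_ref), cam)
    return polygon_area(uv, check=False)


def rotation_bundle(
    head: HeadModel3D,
    cam: CameraModel,
    z_ref: float,
    yaws_deg: np.ndarray | list,
    pitch_deg: float = 0.0,
) -> Mapping[str, np.ndarray]:
    """Ground-truth pose sweep for fitting the rotation exponent.

    Generates noise-free captures at the given yaw angles (fixed pitch,
    fixed distance z_ref) and returns the arrays consumed by
    :func:`faceswell.calibration.fit_rotation_exponent`:

    ``S_le``      distance-calibrated area per pose (Le_ref = frontal Le)
    ``H1, H2``    measured nose heights per pose
    ``S_frontal`` frontal reference area (constant)
    ``tilt_factor`` H1_ref / H1_scaled per pose — multiply in for the
                    end-to-end (post-tilt) fit target
    """
    from .geometry import measure  # local import to avoid cycle at module load

    frontal_ann, _ = project(head, Pose(distance=z_ref), cam)
    m0 = measure(frontal_ann, validate=False)
    rows = []
    for yaw in np.asarray(yaws_deg, dtype=float):
        ann, _ = project(head, Pose(distance=z_ref, yaw_deg=float(yaw), pitch_deg=pitch_deg), cam)
        m = measure(ann, validate=False)
        s_le = m.S * (m0.Le / m.Le) ** 2
        h1_scaled = m.H1 * (m0.Le / m.Le)
        rows.append((s_le, m.H1, m.H2, m0.S, m0.H1 / h1_scaled))
    arr = np.array(rows, dtype=float)
    return {
        "S_le": arr[:, 0],
        "H1": arr[:, 1],
        "H2": arr[:, 2],
        "S_frontal": arr[:, 3],
        "tilt_factor": arr[:, 4],
    }
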