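"""Sequential calibration of the facial area S for nuisance pose/distance.

Three multiplicative stages are applied in a fixed order, mirroring the
order in which the nuisance factors are identified from the landmarks:

1. **Distance** (via Le).  The interocular width is anatomically fixed,
   so the projected Le is inversely proportional to camera distance and
   every projected length scales with it.  Area is quadratic in any
   linear magnification, hence

       S_le = S * (Le_ref / Le)**2.

2. **Rotation** (via H2:H1).  A frontal face has H1 = H2; a yawed head
   has H2 > H1.  The correction is the power law

       S_rot = S_le * (H2 / H1)**gamma,

   identity at H1 = H2.  The intuitive reading ("area shrinks when the
   head turns while Le stays constant") suggests gamma > 0, but for a
   rigid planar outline the Le stage already removes the yaw
   foreshortening (over-removes it, in fact), so the exponent that
   actually minimizes deviation from the frontal area on synthetic
   ground truth is small and negative.  gamma is therefore an ordinary
   real-valued tuning parameter, default 1.0, and
   :func:`fit_rotation_exponent` estimates it from synthetic bundles.
   gamma = 0 reproduces the reading in which H1 ~ H2 is only an
   inclusion check and no rotation correction is applied.

3. **Tilt** (via H1).  Pitch compresses the face image vertically while
   Le is unchanged, so area scales linearly with H1:

       S_final = S_rot * (H1_ref / H1_scaled),

   where H1_scaled = H1 * (Le_ref / Le) puts H1 on the reference
   distance scale first — otherwise camera distance would leak back in
   through H1.

The distance and tilt stages are plain multiplicative scalings and
commute; the pipeline nevertheless always applies the fixed order above.
Reference values Le_ref / H1_ref default to cohort-wide medians (robust
to outliers) via :func:`references_from_measurements`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    CalibrationDomainError,
    DegeneratePoseError,
    InvalidMeasurementError,
)
from .geometry import FaceMeasurement

__all__ = [
    "CalibrationConfig",
    "CalibratedMeasurement",
    "calibrate_distance",
    "calibrate_rotation",
    "calibrate_tilt",
    "calibrate",
    "fit_rotation_exponent",
    "references_from_measurements",
]

#: pipeline stage order is fixed; exposed for reporting
STAGE_ORDER = ("distance", "rotation", "tilt")

#: relative slack for the H2 >= H1 contract (floating-point noise only)
_H2_TOL = 1e-9


@dataclass(frozen=True)
class CalibrationConfig:
    """Reference lengths and rotation exponent for the three stages.

    le_ref, h1_ref : float
        Reference interocular distance and (Le-rescaled) nose height in
        pixels; both must be positive.  Typically cohort medians.
    rotation_exponent : float
        Exponent gamma of the (H2/H1) rotation correction.  Any finite
        real; 0 disables the stage, the default 1.0 applies the ratio
        directly.
    """

    le_ref: float
    h1_ref: float
    rotation_exponent: float = 1.0

    def __post_init__(self):
        if not (self.le_ref > 0.0 and np.isfinite(self.le_ref)):
            raise CalibrationDomainError(f"le_ref must be > 0, got {self.le_ref}")
        if not (self.h1_ref > 0.0 and np.isfinite(self.h1_ref)):
            raise CalibrationDomainError(f"h1_ref must be > 0, got {self.h1_ref}")
        if not np.isfinite(self.rotation_exponent):
            raise CalibrationDomainError(
                f"rotation_exponent must be finite, got {self.rotation_exponent}"
            )


@dataclass(frozen=True)
class CalibratedMeasurement:
    """Raw measurement plus the area after each calibration stage."""

    rat_id: str
    group: str
    day: int
    S_raw: float
    Le: float
    H1: float
    H2: float
    H1_scaled: float
    S_le: float
    S_rot: float
    S_final: float


def _require_positive(**values: float) -> None:
    for name, v in values.items():
        if not (v > 0.0 and np.isfinite(v)):
            raise CalibrationDomainError(f"{name} must be positive and finite, got {v}")


def calibrate_distance(S: float, Le: float, le_ref: float) -> float:
    """Stage 1: rescale area to the reference interocular distance.

    Exact inverse exists; identity when Le == le_ref.
    """
    _require_positive(S=S, Le=Le, le_ref=le_ref)
    return S * (le_ref / Le) ** 2


def calibrate_rotation(S_le: float, H1: float, H2: float, gamma: float) -> float:
    """Stage 2: head-rotation correction by the (H2/H1)**gamma power law.

    Identity for a frontal face (H1 == H2) at any gamma.  H1 = 0 means
    the nose was annotated on the eye line: the pose proxy is undefined
    and a DegeneratePoseError is raised rather than silently passing
    through.  H2 < H1 (beyond float noise) cannot arise from real
    landmarks and raises InvalidMeasurementError.
    """
    _require_positive(S_le=S_le)
    if not (H1 > 0.0 and np.isfinite(H1)):
        raise DegeneratePoseError(
            f"H1 = {H1}: nose tip on the canthus line, pose is degenerate"
        )
    if H2 < H1 * (1.0 - _H2_TOL):
        raise InvalidMeasurementError(f"H2 ({H2}) < H1 ({H1}) is geometrically impossible")
    ratio = max(H2 / H1, 1.0)
    return S_le * ratio**gamma


def calibrate_tilt(S_rot: float, H1_scaled: float, h1_ref: float) -> float:
    """Stage 3: head lift/lower correction, linear in the H1 ratio.

    Identity when H1_scaled == h1_ref.
    """
    _require_positive(S_rot=S_rot, H1_scaled=H1_scaled, h1_ref=h1_ref)
    return S_rot * (h1_ref / H1_scaled)


def calibrate(m: FaceMeasurement, config: CalibrationConfig) -> CalibratedMeasurement:
    """Apply distance → rotation → tilt and record every intermediate area."""
    try:
        s_le = calibrate_distance(m.S, m.Le, config.le_ref)
    except CalibrationDomainError as e:
        raise CalibrationDomainError(f"distance stage: {e}") from e
    try:
        s_rot = calibrate_rotation(s_le, m.H1, m.H2, config.rotation_exponent)
    except (CalibrationDomainError, InvalidMeasurementError) as e:
        raise type(e)(f"rotation stage: {e}") from e
    h1_scaled = m.H1 * (config.le_ref / m.Le)
    try:
        s_final = calibrate_tilt(s_rot, h1_scaled, config.h1_ref)
    except CalibrationDomainError as e:
        raise CalibrationDomainError(f"tilt stage: {e}") from e
    return CalibratedMeasurement(
        rat_id=m.rat_id,
        group=m.group,
        day=m.day,
        S_raw=m.S,
        Le=m.Le,
        H1=m.H1,
        H2=m.H2,
        H1_scaled=h1_scaled,
        S_le=s_le,
        S_rot=s_rot,
        S_final=s_final,
    )


def references_from_measurements(
    measurements: Iterable[FaceMeasurement], policy: str = "median"
) -> tuple[float, float]:
    """(le_ref, h1_ref) from a cohort of raw measurements.

    le_ref is the median (or mean) Le; h1_ref is the median (or mean) of
    the Le-rescaled H1 values so that both references live on the same
    distance scale.
    """
    ms = list(measurements)
    if not ms:
        raise CalibrationDomainError("cannot derive references from an empty cohort")
    if policy not in ("median", "mean"):
        raise CalibrationDomainError(
            f"reference policy must be 'median' or 'mean', got {policy!r}"
        )
    agg = np.median if policy == "median" else np.mean
    le = np.array([m.Le for m in ms], dtype=float)
    h1 = np.array([m.H1 for m in ms], dtype=float)
    if not (le > 0).all():
        raise CalibrationDomainError("non-positive Le in cohort")
    le_ref = float(agg(le))
    h1_ref = float(agg(h1 * (le_ref / le)))
    if h1_ref <= 0.0:
        raise CalibrationDomainError("cohort h1 reference is non-positive")
    return le_ref, h1_ref


def fit_rotation_exponent(
    S_le: Sequence[float],
    H1: Sequence[float],
    H2: Sequence[float],
    S_frontal: Sequence[float],
    *,
    tilt_factor: Sequence[float] | None = None,
    default: float = 1.0,
) -> float:
    """Least-squares estimate of the rotation exponent gamma.

    Minimizes the mean squared log-error between S_le * (H2/H1)**gamma
    (optionally further multiplied by the per-sample tilt factor
    H1_ref/H1_scaled, i.e. the end-to-end pipeline output) and the
    frontal ground-truth area S_frontal.  In log space the model is
    linear in gamma, so the estimate is the closed-form regression slope

        gamma_hat = sum(r * x) / sum(x**2),
        x = log(H2/H1),  r = log(S_frontal) - log(S_le [* tilt_factor]).

    A bundle with no rotation signal (all H2 == H1, e.g. generated at
    zero yaw) leaves gamma unidentified; ``default`` is returned as the
    tie-break.  Deterministic given the bundle.
    """
    s_le = np.asarray(S_le, dtype=float)
    h1 = np.asarray(H1, dtype=float)
    h2 = np.asarray(H2, dtype=float)
    s_f = np.asarray(S_frontal, dtype=float)
    if s_le.size == 0:
        raise CalibrationDomainError("empty bundle")
    if not (s_le.shape == h1.shape == h2.shape == s_f.shape):
        raise CalibrationDomainError("bundle arrays must have identical shapes")
    if not ((s_le > 0).all() and (h1 > 0).all() and (s_f > 0).all()):
        raise CalibrationDomainError("bundle requires positive areas and H1")
    x = np.log(np.maximum(h2 / h1, 1.0))
    base = np.log(s_le)
    if tilt_factor is not None:
        tf = np.asarray(tilt_factor, dtype=float)
        if tf.shape != s_le.shape or not (tf > 0).all():
            raise CalibrationDomainError("tilt_factor must be positive, same shape")
        base = base + np.log(tf)
    r = np.log(s_f) - base
    sxx = float(np.dot(x, x))
    if sxx < 1e-24:
        return float(default)
    return float(np.dot(r, x) / sxx)
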