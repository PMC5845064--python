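"""Sensor calibration: tool-tip offsets, grip maps, and the camera cone.

Three independent calibrations connect raw sensor readings to the
quantities the kinematic features need:

* **Tip (pivot) calibration** — the tracking sensor sits on the tool
  shaft, 2-3 cm from the tip.  Rotating the tool about its stationary tip
  makes the sensor positions trace a sphere centred on the tip; solving
  the pivot system jointly for the sensor-frame offset and the fixed tip
  position recovers the displacement from sensor to tip.
* **Grip calibration** — handle-mounted flex-sensor voltages recorded
  while the handle is held at known postures (open / closed, plus the
  ratcheted stop for the needle driver) anchor a piecewise-linear
  voltage-to-angle map.
* **Camera cone** — the endoscope's field of view is modelled as a cone
  (apex, axis, half-angle) in the scope-sensor frame, fitted to boundary
  points traced at two or more distances from the lens.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .trial_io import PoseStream

__all__ = [
    "CalibrationError",
    "DegenerateGeometryError",
    "TipCalibration",
    "GripCalibration",
    "CameraCone",
    "CalibrationSet",
    "fit_tip_offset",
    "fit_grip_map",
    "fit_camera_cone",
]


class CalibrationError(ValueError):
    """A calibration recording is inconsistent (e.g. sensor fault)."""


class DegenerateGeometryError(CalibrationError):
    """The recorded geometry does not constrain the fit."""


@dataclass(frozen=True)
class TipCalibration:
    """Sensor-frame tip offset: tip_world = pos + R(quat) @ offset."""

    offset: np.ndarray          # 3-vector, cm, sensor frame
    rms_residual: float         # cm
    tip_world: np.ndarray = field(default=None)  # pivot point, cm, world frame

    def __post_init__(self):
        object.__setattr__(self, "offset", np.asarray(self.offset, dtype=float))
        if self.tip_world is not None:
            object.__setattr__(self, "tip_world", np.asarray(self.tip_world, dtype=float))
        if self.rms_residual < 0:
            raise CalibrationError("rms_residual must be >= 0")
        if np.linalg.norm(self.offset) >= 10.0:
            raise CalibrationError("tip offset implausibly large (>= 10 cm)")


@dataclass(frozen=True)
class GripCalibration:
    """Piecewise-linear flex-voltage to grip-angle map.

    ``anchors`` are (mean voltage, angle in degrees) pairs in strictly
    monotone voltage order; outside the anchored range the map clips to
    the terminal anchor angles.
    """

    anchors: tuple[tuple[float, float], ...]

    def __post_init__(self):
        v = np.array([a[0] for a in self.anchors])
        ang = np.array([a[1] for a in self.anchors])
        if len(v) < 2:
            raise CalibrationError("need at least two anchors")
        dv = np.diff(v)
        if not (np.all(dv > 0) or np.all(dv < 0)):
            raise CalibrationError("anchor voltages not strictly monotone (sensor fault)")
        da = np.diff(ang)
        if not (np.all(da > 0) or np.all(da < 0)):
            raise CalibrationError("anchor angles not monotone")

    def __call__(self, voltage) -> np.ndarray:
        """Map voltage(s) to grip angle(s), clipping outside the anchors."""
        v = np.array([a[0] for a in self.anchors], dtype=float)
        ang = np.array([a[1] for a in self.anchors], dtype=float)
        if v[0] > v[-1]:
            v, ang = v[::-1], ang[::-1]
        return np.interp(np.asarray(voltage, dtype=float), v, ang)

    def inverse(self, angle) -> np.ndarray:
        """Angle -> voltage (used by the simulator to synthesise voltages)."""
        v = np.array([a[0] for a in self.anchors], dtype=float)
        ang = np.array([a[1] for a in self.anchors], dtype=float)
        if ang[0] > ang[-1]:
            v, ang = v[::-1], ang[::-1]
        return np.interp(np.asarray(angle, dtype=float), ang, v)

    def out_of_range(self, voltage) -> np.ndarray:
        v = np.array([a[0] for a in self.anchors], dtype=float)
        lo, hi = min(v[0], v[-1]), max(v[0], v[-1])
        x = np.asarray(voltage, dtype=float)
        return (x < lo) | (x > hi)


@dataclass(frozen=True)
class CameraCone:
    """Field-of-view cone in the scope-sensor frame."""

    apex: np.ndarray       # cm
    axis: np.ndarray       # unit vector
    half_angle: float      # degrees, in (0, 90)

    def __post_init__(self):
        object.__setattr__(self, "apex", np.asarray(self.apex, dtype=float))
        ax = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(ax)
        if n == 0 or not np.isfinite(n):
            raise CalibrationError("cone axis must be a nonzero finite vector")
        object.__setattr__(self, "axis", ax / n)
        if not (0.0 < self.half_angle < 90.0) or not np.isfinite(self.half_angle):
            raise CalibrationError(f"half_angle {self.half_angle} outside (0, 90)")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean in-view test for (N,3) points in the scope-sensor frame.

        A point is visible iff it lies in the forward half-space of the
        apex and within ``half_angle`` of the axis.  A point coincident
        with the apex is not visible (its direction is undefined).
        """
        p = np.atleast_2d(np.asarray(points, dtype=float)) - self.apex
        d = p @ self.axis
        norm = np.linalg.norm(p, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.where(norm > 0, d / norm, -1.0)
        return (d > 0) & (cosang >= np.cos(np.deg2rad(self.half_angle)))


@dataclass
class CalibrationSet:
    """All per-session calibrations, persisted together as JSON."""

    tips: dict[str, TipCalibration]
    grips: dict[str, GripCalibration]
    cone: CameraCone

    def to_json(self, path: str | Path) -> None:
        d = {
            "tips": {
                k: {"offset": list(v.offset), "rms_residual": v.rms_residual}
                for k, v in self.tips.items()
            },
            "grips": {k: {"anchors": [list(a) for a in v.anchors]} for k, v in self.grips.items()},
            "cone": {
                "apex": list(self.cone.apex),
                "axis": list(self.cone.axis),
                "half_angle": self.cone.half_angle,
            },
        }
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationSet":
        d = json.loads(Path(path).read_text())
        return cls(
            tips={k: TipCalibration(v["offset"], v["rms_residual"]) for k, v in d["tips"].items()},
            grips={
                k: GripCalibration(tuple(tuple(a) for a in v["anchors"]))
                for k, v in d["grips"].items()
            },
            cone=CameraCone(d["cone"]["apex"], d["cone"]["axis"], d["cone"]["half_angle"]),
        )


# ---------------------------------------------------------------------------
# Tip (pivot) calibration

def fit_tip_offset(poses: PoseStream, min_samples: int = 30,
                   sv_tol: float = 1e-3) -> TipCalibration:
    """Estimate the sensor-frame tip offset from a pivot recording.

    With the tip held stationary at unknown world point ``c`` while the
    handle is rotated, each sample satisfies ``pos_i + R_i @ offset = c``.
    Stacking gives the linear system ``[R_i | -I] [offset; c] = -pos_i``,
    solved jointly by least squares.  Equivalently the sensor positions
    lie on a sphere of radius ``|offset|`` about ``c`` (the hemisphere
    picture of pivot calibration).

    Raises :class:`DegenerateGeometryError` when the rotations do not
    span enough of SO(3) to constrain the offset (smallest singular value
    of the stacked system below ``sv_tol``).
    """
    n = len(poses)
    if n < min_samples:
        raise DegenerateGeometryError(f"need >= {min_samples} samples, got {n}")
    R = Rotation.from_quat(poses.quat, scalar_first=True).as_matrix()  # (n,3,3)
    A = np.zeros((3 * n, 6))
    A[:, :3] = R.reshape(3 * n, 3)
    A[:, 3:] = np.tile(-np.eye(3), (n, 1))
    b = -poses.pos.reshape(3 * n)
    sv = np.linalg.svd(A, compute_uv=False)
    if sv[-1] < sv_tol:
        raise DegenerateGeometryError(
            "insufficient rotation diversity in pivot recording "
            f"(smallest singular value {sv[-1]:.2e})"
        )
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    offset, tip = x[:3], x[3:]
    resid = poses.pos + np.einsum("nij,j->ni", R, offset) - tip
    rms = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return TipCalibration(offset=offset, rms_residual=rms, tip_world=tip)


# ---------------------------------------------------------------------------
# Grip calibration

#: Default handle angles for the calibration postures, degrees.  The open
#: jaw is taken as 30 deg; the needle driver has an extra almost-closed
#: anchor just before the ratchet engages.
DEFAULT_ANCHOR_ANGLES = {
    "maryland": (30.0, 0.0),            # open, closed
    "needle": (30.0, 3.0, 0.0),         # open, closed-unratcheted, ratcheted
}


def fit_grip_map(segments: list[tuple[np.ndarray, np.ndarray]],
                 anchor_angles: tuple[float, ...],
                 trim_seconds: float = 0.5) -> GripCalibration:
    """Fit a piecewise-linear voltage-to-angle map from hold segments.

    ``segments`` is one ``(t, voltage)`` pair per anchor posture, in the
    same order as ``anchor_angles``.  Each segment must span at least
    2 s; its first and last ``trim_seconds`` are discarded (transients
    while the experimenter repositions the handle) and the rest averaged.
    """
    if len(segments) != len(anchor_angles):
        raise CalibrationError(
            f"{len(anchor_angles)} anchor angles but {len(segments)} segments"
        )
    anchors = []
    for (t, v), ang in zip(segments, anchor_angles):
        t = np.asarray(t, dtype=float)
        v = np.asarray(v, dtype=float)
        if t[-1] - t[0] < 2.0:
            raise CalibrationError("hold segment shorter than 2 s")
        keep = (t >= t[0] + trim_seconds) & (t <= t[-1] - trim_seconds)
        anchors.append((float(np.mean(v[keep])), float(ang)))
    return GripCalibration(tuple(anchors))


# ---------------------------------------------------------------------------
# Camera cone calibration

def _fit_circle_3d(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Fit a circle to ~coplanar 3-D points: (center, plane normal, radius)."""
    c0 = points.mean(axis=0)
    q = points - c0
    _, s, vt = np.linalg.svd(q, full_matrices=False)
    normal = vt[2]
    # project into the plane, algebraic (Kasa) circle fit
    u, v = vt[0], vt[1]
    x, y = q @ u, q @ v
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x ** 2 + y ** 2
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c2 = sol
    r = float(np.sqrt(c2 + cx ** 2 + cy ** 2))
    center = c0 + cx * u + cy * v
    return center, normal, r


def _cluster_by_axis(points: np.ndarray, axis: np.ndarray) -> list[np.ndarray]:
    """Split traced points into planes by their projection along the axis."""
    proj = points @ axis
    order = np.argsort(proj)
    gaps = np.diff(proj[order])
    if gaps.size == 0:
        return [points]
    split = int(np.argmax(gaps))
    if gaps[split] < 1e-6:
        return [points]
    return [points[order[: split + 1]], points[order[split + 1:]]]


def fit_camera_cone(boundary_points: np.ndarray, axis_hint: np.ndarray,
                    clusters: list[np.ndarray] | None = None,
                    max_iter: int = 200) -> CameraCone:
    """Fit the field-of-view cone to traced boundary points.

    Initialisation follows the two-circle construction: a circle is
    fitted to each traced cluster, the apex extrapolated along the line
    through the circle centres by similar triangles, and the half-angle
    taken as ``atan(dr / dd)``.  The parameters are then refined by
    least squares on the angular residuals (angle between point - apex
    and the axis, minus the half-angle), which is the natural error
    measure for points meant to lie on the cone boundary.
    """
    axis_hint = np.asarray(axis_hint, dtype=float)
    if np.linalg.norm(axis_hint) == 0:
        raise DegenerateGeometryError("axis_hint must be nonzero")
    axis_hint = axis_hint / np.linalg.norm(axis_hint)
    pts = np.asarray(boundary_points, dtype=float)
    if clusters is None:
        clusters = _cluster_by_axis(pts, axis_hint)
    if len(clusters) < 2:
        raise DegenerateGeometryError(
            "boundary points from at least two distinct planes required"
        )
    circles = [_fit_circle_3d(np.asarray(c, dtype=float)) for c in clusters]
    # order circles by distance along the hint axis
    circles.sort(key=lambda c: float(c[0] @ axis_hint))
    (c1, _, r1), (c2, _, r2) = circles[0], circles[-1]
    d = np.linalg.norm(c2 - c1)
    if d < 1e-9 or abs(r2 - r1) < 1e-12:
        raise DegenerateGeometryError("traced circles coincident or equal radius")
    axis0 = (c2 - c1) / d
    if axis0 @ axis_hint < 0:
        axis0, c1, c2, r1, r2 = -axis0, c2, c1, r2, r1
    # similar triangles: radius grows linearly with distance from apex
    apex0 = c1 - axis0 * (r1 * d / (r2 - r1))
    half0 = np.degrees(np.arctan2(r2 - r1, d))
    if not (0 < half0 < 90):
        raise DegenerateGeometryError("initial half-angle outside (0, 90) deg")

    def residuals(p):
        apex, th, phi, half = p[:3], p[3], p[4], p[5]
        ax = np.array([np.sin(th) * np.cos(phi), np.sin(th) * np.sin(phi), np.cos(th)])
        q = pts - apex
        nq = np.linalg.norm(q, axis=1)
        nq = np.where(nq > 1e-12, nq, 1e-12)
        ang = np.arccos(np.clip((q @ ax) / nq, -1.0, 1.0))
        return ang - half

    th0 = float(np.arccos(np.clip(axis0[2], -1, 1)))
    phi0 = float(np.arctan2(axis0[1], axis0[0]))
    p0 = np.concatenate([apex0, [th0, phi0, np.deg2rad(half0)]])
    init_cost = float(np.sum(residuals(p0) ** 2))
    sol = least_squares(residuals, p0, max_nfev=max_iter * len(p0), xtol=1e-12,
                        ftol=1e-14, gtol=1e-14)
    p = sol.x if float(np.sum(sol.fun ** 2)) <= init_cost else p0
    th, phi, half = p[3], p[4], np.degrees(p[5])
    if not (0.0 < half < 90.0):
        raise CalibrationError(f"refined half-angle {half:.2f} deg outside (0, 90)")
    ax = np.array([np.sin(th) * np.cos(phi), np.sin(th) * np.sin(phi), np.cos(th)])
    return CameraCone(apex=p[:3], axis=ax, half_angle=float(half))
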