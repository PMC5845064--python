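"""From raw recordings to uniform, filtered tip kinematics.

The processing order is fixed: each raw channel is low-pass filtered at
its native rate, resampled onto an exact 20 Hz grid, transformed
(sensor pose -> tool-tip pose, voltage -> grip angle), and finally
differentiated.  Euler angles use the Z-Y-X (azimuth, elevation, roll)
convention of the magnetic tracker and are unwrapped over time so that
angular path lengths and rates are well defined.

The low-pass filter is a zero-phase fourth-order Butterworth with a
6 Hz cutoff.  It is realised in the frequency domain with the exact
two-pass (squared) Butterworth magnitude ``|H(f)|^2 = 1/(1 + (f/fc)^8)``
after odd-reflection edge padding; see docs/methods.md for why this
realisation is preferred over a bilinear-transform recursion when the
cutoff sits this close to the Nyquist frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

from .calibration import CalibrationSet, CameraCone, GripCalibration, TipCalibration
from .trial_io import TOOLS, TrialRecording

__all__ = [
    "GRID_STEP",
    "ToolKinematics",
    "TrialKinematics",
    "lowpass_zero_phase",
    "resample_20hz",
    "tip_trajectory",
    "derivatives",
    "grip_series",
    "visibility_series",
    "compute_kinematics",
]

log = logging.getLogger(__name__)

#: Uniform grid step, seconds (exactly 20 Hz).
GRID_STEP = 0.05


def lowpass_zero_phase(series: np.ndarray, fs: float, fc: float = 6.0,
                       order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the first axis.

    The two-pass magnitude response is exactly the squared analog
    Butterworth characteristic ``1/(1 + (f/fc)^(2*order))``; the phase is
    identically zero.  Edges are handled by odd reflection padding of
    length ``3*(order+1)`` samples, so a constant input passes through
    unchanged and short transients do not wrap around.
    """
    x = np.asarray(series, dtype=float)
    pad = 3 * (order + 1)
    if x.shape[0] < pad:
        raise ValueError(
            f"series of length {x.shape[0]} shorter than padding requirement {pad}"
        )
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    top = 2 * x[0] - x[pad:0:-1]
    bot = 2 * x[-1] - x[-2:-pad - 2:-1]
    xp = np.concatenate([top, x, bot], axis=0)
    f = np.fft.rfftfreq(xp.shape[0], d=1.0 / fs)
    H = 1.0 / (1.0 + (f / fc) ** (2 * order))
    yp = np.fft.irfft(np.fft.rfft(xp, axis=0) * H[:, None], n=xp.shape[0], axis=0)
    y = yp[pad:pad + x.shape[0]]
    return y[:, 0] if squeeze else y


def make_grid(t_start: float, t_end: float) -> np.ndarray:
    """The exact-20 Hz grid covering [t_start, t_end] without extrapolation."""
    n = int(np.floor((t_end - t_start) / GRID_STEP + 1e-9)) + 1
    if n < 1:
        raise ValueError("empty time range")
    return t_start + GRID_STEP * np.arange(n)


def resample_20hz(t: np.ndarray, values: np.ndarray,
                  grid: np.ndarray | None = None,
                  kind: str = "linear") -> tuple[np.ndarray, np.ndarray]:
    """Resample a timestamped signal onto the uniform 0.05 s grid.

    ``kind='linear'`` interpolates each column linearly; ``kind='slerp'``
    treats rows as quaternions (w, x, y, z), interpolates on the rotation
    manifold, and returns renormalised, hemisphere-aligned quaternions.
    The grid never extends beyond the recorded range (no extrapolation):
    when ``grid`` is omitted it runs from the first to the last timestamp.
    """
    t = np.asarray(t, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    if grid is None:
        grid = make_grid(t[0], t[-1])
    else:
        grid = np.asarray(grid, dtype=float)
        grid = grid[(grid >= t[0] - 1e-12) & (grid <= t[-1] + 1e-12)]
        grid = np.clip(grid, t[0], t[-1])
    v = np.asarray(values, dtype=float)
    if kind == "slerp":
        q = align_quat_signs(v)
        rot = Rotation.from_quat(q, scalar_first=True)
        out = Slerp(t, rot)(grid).as_quat(scalar_first=True)
        return grid, align_quat_signs(out)
    if v.ndim == 1:
        return grid, np.interp(grid, t, v)
    out = np.column_stack([np.interp(grid, t, v[:, j]) for j in range(v.shape[1])])
    return grid, out


def align_quat_signs(quat: np.ndarray) -> np.ndarray:
    """Flip quaternion signs so consecutive samples stay in one hemisphere."""
    q = np.array(quat, dtype=float)
    d = np.sum(q[1:] * q[:-1], axis=1)
    flips = np.cumprod(np.where(d < 0, -1.0, 1.0))
    q[1:] *= flips[:, None]
    return q


def tip_trajectory(pos: np.ndarray, quat: np.ndarray,
                   tip_cal: TipCalibration) -> tuple[np.ndarray, np.ndarray]:
    """Sensor poses -> tool-tip positions and unwrapped Euler angles.

    ``tip_i = pos_i + R(quat_i) @ offset``.  Euler angles are extracted
    in intrinsic Z-Y-X order — (azimuth, elevation, roll), degrees — and
    unwrapped along time so no step exceeds 180 deg.
    """
    rot = Rotation.from_quat(align_quat_signs(quat), scalar_first=True)
    tip = np.asarray(pos, dtype=float) + rot.apply(tip_cal.offset)
    euler = rot.as_euler("ZYX", degrees=True)  # azimuth, elevation, roll
    euler = np.unwrap(euler, axis=0, period=360.0)
    if np.any(np.abs(((euler[:, 1] + 90) % 360) - 90) > 85.0):
        log.warning("elevation near gimbal lock (|elevation| > 85 deg)")
    return tip, euler


def derivatives(y: np.ndarray, dt: float = GRID_STEP) -> tuple[np.ndarray, np.ndarray]:
    """First and second time derivatives on a uniform grid.

    Central differences in the interior, one-sided at the ends (the
    ``numpy.gradient`` stencil, exact for quadratics in the interior).
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] < 3:
        raise ValueError("need at least 3 samples to differentiate")
    d1 = np.gradient(y, dt, axis=0)
    d2 = np.gradient(d1, dt, axis=0)
    return d1, d2


def grip_series(voltage_on_grid: np.ndarray, grip_cal: GripCalibration,
                dt: float = GRID_STEP) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Grip angle and its derivatives from filtered, resampled voltage."""
    if np.any(grip_cal.out_of_range(voltage_on_grid)):
        log.warning("grip voltage outside calibrated range; clipping to anchors")
    angle = grip_cal(voltage_on_grid)
    vel, acc = derivatives(angle, dt)
    return angle, vel, acc


def visibility_series(tip_pos: np.ndarray, scope_pos: np.ndarray,
                      scope_quat: np.ndarray, cone: CameraCone) -> np.ndarray:
    """Per-sample in-view flags for a tool tip.

    Each world-frame tip position is transformed into the scope-sensor
    frame (``R_scope^T (tip - scope_pos)``) and tested against the cone.
    """
    rot = Rotation.from_quat(align_quat_signs(scope_quat), scalar_first=True)
    local = rot.inv().apply(np.asarray(tip_pos, dtype=float) - np.asarray(scope_pos, dtype=float))
    return cone.contains(local)


@dataclass
class ToolKinematics:
    """Filtered, resampled kinematics of one tool on the common grid."""

    tip_pos: np.ndarray     # (N, 3) cm
    euler: np.ndarray       # (N, 3) degrees, unwrapped (azimuth, elevation, roll)
    lin_vel: np.ndarray     # (N, 3) cm/s
    lin_acc: np.ndarray     # (N, 3) cm/s^2
    ang_vel: np.ndarray     # (N, 3) deg/s
    ang_acc: np.ndarray     # (N, 3) deg/s^2
    grip_angle: np.ndarray  # (N,) degrees
    grip_vel: np.ndarray    # (N,) deg/s
    grip_acc: np.ndarray    # (N,) deg/s^2
    visible: np.ndarray     # (N,) bool


@dataclass
class TrialKinematics:
    t: np.ndarray                     # uniform grid, step exactly 0.05 s
    tools: dict[str, ToolKinematics]  # keys 'maryland', 'needle'

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def n_samples(self) -> int:
        return self.t.size


def compute_kinematics(rec: TrialRecording, calib: CalibrationSet,
                       fc: float = 6.0, order: int = 4) -> TrialKinematics:
    """Run the full pipeline: filter -> resample -> transform -> differentiate."""
    rec.check()

    filtered: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for ch, s in rec.streams.items():
        fs = 1.0 / float(np.median(np.diff(s.t)))
        pos = lowpass_zero_phase(s.pos, fs, fc, order)
        q = lowpass_zero_phase(align_quat_signs(s.quat), fs, fc, order)
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        filtered[ch] = (s.t, pos, q)
    fgrip: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for tool, g in rec.grip.items():
        fs = 1.0 / float(np.median(np.diff(g.t)))
        fgrip[tool] = (g.t, lowpass_zero_phase(g.voltage, fs, fc, order))

    t0 = max([v[0][0] for v in filtered.values()] + [v[0][0] for v in fgrip.values()])
    t1 = min([v[0][-1] for v in filtered.values()] + [v[0][-1] for v in fgrip.values()])
    grid = make_grid(t0, t1)

    scope_t, scope_p, scope_q = filtered["scope_pose"]
    _, scope_pos = resample_20hz(scope_t, scope_p, grid)
    _, scope_quat = resample_20hz(scope_t, scope_q, grid, kind="slerp")

    tools: dict[str, ToolKinematics] = {}
    for tool in TOOLS:
        t_raw, p_raw, q_raw = filtered[f"{tool}_pose"]
        _, pos = resample_20hz(t_raw, p_raw, grid)
        _, quat = resample_20hz(t_raw, q_raw, grid, kind="slerp")
        tip, euler = tip_trajectory(pos, quat, calib.tips[tool])
        lin_vel, lin_acc = derivatives(tip)
        ang_vel, ang_acc = derivatives(euler)
        gt, gv = fgrip[tool]
        _, v_on_grid = resample_20hz(gt, gv, grid)
        angle, gvel, gacc = grip_series(v_on_grid, calib.grips[tool])
        visible = visibility_series(tip, scope_pos, scope_quat, calib.cone)
        tools[tool] = ToolKinematics(
            tip_pos=tip, euler=euler, lin_vel=lin_vel, lin_acc=lin_acc,
            ang_vel=ang_vel, ang_acc=ang_acc, grip_angle=angle,
            grip_vel=gvel, grip_acc=gacc, visible=visible,
        )
    return TrialKinematics(t=grid, tools=tools)


def kinematics_to_frame(kin: TrialKinematics):
    """Flatten to a DataFrame (one row per grid sample) for CSV export."""
    import pandas as pd

    cols = {"t": kin.t}
    for tool, tk in kin.tools.items():
        for name, arr in [("tip", tk.tip_pos), ("euler", tk.euler),
                          ("lin_vel", tk.lin_vel), ("lin_acc", tk.lin_acc),
                          ("ang_vel", tk.ang_vel), ("ang_acc", tk.ang_acc)]:
            for j, ax in enumerate("xyz"):
                cols[f"{tool}_{name}_{ax}"] = arr[:, j]
        cols[f"{tool}_grip_angle"] = tk.grip_angle
        cols[f"{tool}_grip_vel"] = tk.grip_vel
        cols[f"{tool}_grip_acc"] = tk.grip_acc
        cols[f"{tool}_visible"] = tk.visible.astype(int)
    return pd.DataFrame(cols)
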