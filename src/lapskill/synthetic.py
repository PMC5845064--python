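"""Skill-graded synthetic suturing trials with noisy simulated ratings.

No recordings of the motivating study were deposited, so this module
generates cohorts with the statistical structure the pipeline assumes:
tool-tip trajectories built from minimum-jerk sub-movements inside a
14 x 19 x 7 cm box-trainer workspace, tremor and sensor quantisation
noise, jittered ~20 Hz sampling, skill-dependent trial duration, grip
event trains, out-of-view excursions of the needle driver, and an
OSATS-style rater with controllable noise.

Latent skill ``s`` in [1, 5] drives everything monotonically: less
skilled trainees take longer (duration ``T(s) = 480 * exp(-0.45 (s-1))``
seconds, capped at the 600 s acquisition limit), make more and larger
corrective sub-movements, tremble more, let the needle driver drift out
of view more often, and snap the grip more abruptly.  Each modality
(motion, grip, visibility) expresses skill through its own per-trial
perturbation, and the simulated rater scores the realised performance
(the mean of the three modality skills) — so sensor fusion genuinely
carries more information about the rating than any single stream.

All numeric defaults are this package's choices, collected in
:class:`GeneratorConfig` and overridable; trials are deterministic given
a seed and are written through :mod:`lapskill.trial_io` so the format
code is exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .calibration import CalibrationSet, CameraCone, GripCalibration, TipCalibration
from .trial_io import (
    GripStream,
    OSATS_DOMAINS,
    OSATSRating,
    PoseStream,
    TrialMeta,
    TrialRecording,
    write_trial,
)

__all__ = [
    "SkillProfile",
    "GeneratorConfig",
    "true_calibration",
    "simulate_trial",
    "simulate_rater",
    "simulate_cohort",
    "SimulatedCohort",
]

LEVELS = ("student", "resident", "fellow")


@dataclass(frozen=True)
class SkillProfile:
    """Latent skill of one subject."""

    s: float                     # latent skill in [1, 5]
    level: str = "resident"
    learning_gain: float = 0.0   # added to s on the second trial

    def __post_init__(self):
        if not (1.0 <= self.s <= 5.0):
            raise ValueError(f"latent skill {self.s} outside [1, 5]")
        if self.learning_gain < 0:
            raise ValueError("learning gain must be >= 0")
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")


@dataclass(frozen=True)
class GeneratorConfig:
    """All tunable generator parameters (units in comments)."""

    # duration model: T(s) = base * exp(-decay * (s - 1)), seconds
    base_duration: float = 480.0
    duration_decay: float = 0.45
    max_duration: float = 599.0
    duration_jitter_sd: float = 0.06    # lognormal sd of the duration factor

    rate_hz: float = 20.0
    time_jitter_sd: float = 0.004       # s, per-sample timestamp jitter

    # sensor resolution (quantisation steps)
    pos_quant: float = 0.14             # cm
    ang_quant: float = 0.5              # degrees

    # sub-movement structure
    seg_rate_base: float = 0.45         # segments per second at s = 5
    seg_rate_per_skill: float = 0.22    # extra segments/s per point below 5
    via_spread: tuple = (2.5, 3.0, 1.5)  # cm, sd of via-points about the tissue

    # tremor: Gaussian position noise, cm, amplitude grows as skill drops
    tremor_amp_per_skill: float = 0.05
    roll_wiggle_deg: float = 8.0        # sd of slow roll-angle wander

    # needle-driver out-of-view excursions
    outview_rate_per_min: float = 0.9   # episodes/min per point below 5
    outview_duration: float = 2.5       # s

    # grip events
    grip_event_rate: float = 0.06       # events/s base
    grip_event_rate_per_skill: float = 0.07  # extra events/s per point below 5
    grip_rise_base: float = 0.40        # s, rise time at s = 5
    grip_rise_per_skill: float = 0.06   # rise shortens per point below 5
    grip_open_angle: float = 15.0       # deg, resting half-open posture
    voltage_noise_sd: float = 0.001     # V

    # per-trial modality skill perturbations and the rater
    modality_sd: float = 0.5
    rater_sigma: float = 0.4
    rater_rho: float = 0.5              # shared fraction of rater noise variance

    # geometry, cm (workspace 14 wide x 19 deep x 7 tall)
    workspace_half: tuple = (7.0, 9.5, 3.5)
    tissue_center: tuple = (0.0, 0.0, 2.0)
    maryland_trocar: tuple = (-4.0, 0.0, 7.0)
    needle_trocar: tuple = (4.0, 0.0, 7.0)
    scope_pos: tuple = (0.0, -7.0, 9.0)
    cone_half_angle: float = 35.0       # degrees
    tip_offset: tuple = (0.0, 0.0, -2.5)  # cm, sensor frame

    def duration(self, s: float) -> float:
        return min(self.base_duration * np.exp(-self.duration_decay * (s - 1.0)),
                   self.max_duration)


def true_calibration(config: GeneratorConfig | None = None) -> CalibrationSet:
    """The ground-truth calibration of the simulated hardware."""
    config = config or GeneratorConfig()
    tip = TipCalibration(offset=np.array(config.tip_offset), rms_residual=0.0)
    grips = {
        "maryland": GripCalibration(((1.0, 30.0), (2.0, 0.0))),
        "needle": GripCalibration(((1.0, 30.0), (1.8, 3.0), (2.0, 0.0))),
    }
    cone = CameraCone(apex=np.zeros(3), axis=np.array([0.0, 0.0, 1.0]),
                      half_angle=config.cone_half_angle)
    return CalibrationSet(tips={"maryland": tip, "needle": tip},
                          grips=grips, cone=cone)


# ---------------------------------------------------------------------------
# Trajectory building blocks

def _minimum_jerk(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Minimum-jerk normalized profile 0 -> 1 over [t0, t1]."""
    tau = np.clip((t - t0) / max(t1 - t0, 1e-9), 0.0, 1.0)
    return 10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5

def _via_trajectory(t: np.ndarray, times: np.ndarray, vias: np.ndarray) -> np.ndarray:
    """Piecewise minimum-jerk path through via-points at the given times."""
    out = np.empty((t.size, vias.shape[1]))
    idx = np.clip(np.searchsorted(times, t, side="right") - 1, 0, len(times) - 2)
    for k in range(len(times) - 1):
        m = idx == k
        if not np.any(m):
            continue
        prof = _minimum_jerk(t[m], times[k], times[k + 1])[:, None]
        out[m] = vias[k] + (vias[k + 1] - vias[k]) * prof
    return out


def _align_z_to(direction: np.ndarray) -> Rotation:
    """Minimal rotation taking the +z axis onto ``direction`` (rows)."""
    d = direction / np.linalg.norm(direction, axis=1, keepdims=True)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(np.broadcast_to(z, d.shape), d)
    c = d @ z
    angle = np.arccos(np.clip(c, -1.0, 1.0))
    nv = np.linalg.norm(v, axis=1, keepdims=True)
    axis = np.where(nv > 1e-12, v / np.where(nv > 0, nv, 1.0),
                    np.array([1.0, 0.0, 0.0]))
    return Rotation.from_rotvec(axis * angle[:, None])


def _quantize(x: np.ndarray, step: float) -> np.ndarray:
    return np.round(x / step) * step


def _jittered_clock(T: float, config: GeneratorConfig, rng) -> np.ndarray:
    n = int(np.floor(T * config.rate_hz)) + 1
    t = np.arange(n) / config.rate_hz
    t = t + rng.normal(0.0, config.time_jitter_sd, size=n)
    t[0] = 0.0
    t = np.maximum.accumulate(t)
    t += np.arange(n) * 1e-9  # guarantee strictly increasing
    return t


# ---------------------------------------------------------------------------
# Rater

def simulate_rater(s: float, sigma: float, seed, rho: float = 0.5) -> OSATSRating:
    """Noisy five-domain OSATS rating of a performance of quality ``s``.

    Each domain is ``clip(round(s + eps_d), 1, 5)`` where the noise has a
    component shared across domains (a rater's overall impression) and an
    independent per-domain component: ``eps_d = sigma * (sqrt(rho) z0 +
    sqrt(1-rho) z_d)``.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    z0 = rng.normal()
    zd = rng.normal(size=5)
    eps = sigma * (np.sqrt(rho) * z0 + np.sqrt(1.0 - rho) * zd)
    domains = np.clip(np.floor(s + eps + 0.5), 1, 5).astype(int)
    return OSATSRating(tuple(int(d) for d in domains))


# ---------------------------------------------------------------------------
# Trial synthesis

def _tool_stream(t: np.ndarray, tip: np.ndarray, trocar: np.ndarray,
                 roll: np.ndarray, config: GeneratorConfig, rng) -> PoseStream:
    """Sensor pose stream for one tool given its tip trajectory."""
    shaft = tip - trocar
    d = shaft / np.linalg.norm(shaft, axis=1, keepdims=True)
    pos = tip - 2.5 * d  # sensor sits 2.5 cm behind the tip along the shaft
    rot = _align_z_to(-d) * Rotation.from_euler("z", roll[:, None], degrees=True)
    pos = _quantize(pos, config.pos_quant)
    eul = rot.as_euler("ZYX", degrees=True)
    eul = _quantize(eul, config.ang_quant)
    quat = Rotation.from_euler("ZYX", eul, degrees=True).as_quat(scalar_first=True)
    return PoseStream(t, pos, quat)


def simulate_trial(profile: SkillProfile, config: GeneratorConfig | None = None,
                   seed: int | None = None, trial_index: int = 1,
                   subject_id: str = "synthetic",
                   ) -> tuple[TrialRecording, OSATSRating]:
    """Generate one trial recording and its ground-truth rating.

    Deterministic given ``(profile, config, seed)``.  The returned
    rating is produced by :func:`simulate_rater` applied to the trial's
    realised performance quality.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    s = min(5.0, profile.s + (profile.learning_gain if trial_index >= 2 else 0.0))

    # per-trial modality skills: motion, grip, visibility
    s_m, s_g, s_v = np.clip(s + rng.normal(0.0, config.modality_sd, 3), 1.0, 5.0)
    performance = float((s_m + s_g + s_v) / 3.0)

    T = config.duration(s_m) * float(np.exp(rng.normal(0.0, config.duration_jitter_sd)))
    T = min(T, config.max_duration)

    calib = true_calibration(config)
    tissue = np.array(config.tissue_center)
    half = np.array(config.workspace_half)
    center = np.array([0.0, 0.0, half[2]])
    scope_pos0 = np.array(config.scope_pos)

    def via_points(n, spread_scale=1.0):
        # ordinary working via-points stay inside the camera view (a
        # trainee works where they can see); out-of-view episodes are
        # inserted explicitly below
        out = np.empty((n, 3))
        for i in range(n):
            for _try in range(50):
                v = tissue + rng.normal(0.0, spread_scale, 3) * np.array(config.via_spread)
                v = np.clip(v, center - half + 0.2, center + half - 0.2)
                if in_view(v):
                    break
            out[i] = v
        return out

    def segment_times(n_seg):
        w = rng.gamma(2.0, 1.0, size=n_seg)
        edges = np.concatenate([[0.0], np.cumsum(w)])
        return edges / edges[-1] * T

    streams = {}
    grip = {}
    view_dir = tissue - scope_pos0
    view_dir = view_dir / np.linalg.norm(view_dir)

    def in_view(p):
        q = p - scope_pos0
        nq = np.linalg.norm(q)
        return nq > 0 and np.degrees(np.arccos(np.clip(q @ view_dir / nq, -1, 1))) \
            <= config.cone_half_angle

    for tool, trocar in [("maryland", config.maryland_trocar),
                         ("needle", config.needle_trocar)]:
        t = _jittered_clock(T, config, rng)
        seg_rate = config.seg_rate_base + config.seg_rate_per_skill * (5.0 - s_m)
        n_seg = max(3, rng.poisson(T * seg_rate))
        times = segment_times(n_seg)
        vias = via_points(n_seg + 1)
        if tool == "needle":
            # out-of-view excursions, more frequent at low visibility skill
            n_out = rng.poisson(T / 60.0 * config.outview_rate_per_min * (5.0 - s_v))
            for _ in range(int(n_out)):
                for _try in range(50):
                    cand = center + (rng.uniform(-1, 1, 3) * (half - 0.3))
                    cand[2] = half[2] * 2 - 0.5 - rng.uniform(0, 1.5)  # high corner
                    if not in_view(cand):
                        break
                # dwell out of view for a whole segment (two equal vias)
                k = int(rng.integers(1, max(n_seg - 1, 2)))
                vias[k] = cand
                vias[min(k + 1, n_seg)] = cand + rng.normal(0, 0.1, 3)
        tip = _via_trajectory(t, times, vias)
        tremor = rng.normal(0.0, config.tremor_amp_per_skill * (5.0 - s_m),
                            size=tip.shape)
        tip = tip + tremor
        roll_wander = np.cumsum(rng.normal(0, 1, t.size))
        roll_wander *= config.roll_wiggle_deg / max(np.std(roll_wander), 1e-9)
        streams[f"{tool}_pose"] = _tool_stream(t, tip, np.array(trocar),
                                               roll_wander, config, rng)

        # grip: open-close event train through the inverse calibration map
        tg = _jittered_clock(T, config, rng)
        rate = config.grip_event_rate + config.grip_event_rate_per_skill * (5.0 - s_g)
        n_ev = max(1, rng.poisson(T * rate))
        ev_times = np.sort(rng.uniform(0.0, T, size=n_ev))
        rise = max(0.08, config.grip_rise_base - config.grip_rise_per_skill * (5.0 - s_g))
        angle = np.full(tg.size, config.grip_open_angle)
        for te in ev_times:
            hold = rng.uniform(0.3, 1.2)
            closing = _minimum_jerk(tg, te, te + rise)
            opening = _minimum_jerk(tg, te + rise + hold, te + 2 * rise + hold)
            angle = angle - config.grip_open_angle * (closing - opening)
        angle = np.clip(angle, 0.0, 30.0)
        voltage = calib.grips[tool].inverse(angle)
        voltage = voltage + rng.normal(0.0, config.voltage_noise_sd, size=tg.size)
        grip[tool] = GripStream(tg, voltage)

    # scope: slowly swaying sensor whose local +z is the viewing axis
    ts = _jittered_clock(T, config, rng)
    sway = 0.3 * np.column_stack([
        np.sin(2 * np.pi * 0.02 * ts), np.sin(2 * np.pi * 0.013 * ts + 1.0),
        np.sin(2 * np.pi * 0.017 * ts + 2.0)])
    spos = scope_pos0 + sway
    sdir = tissue - spos
    sdir = sdir / np.linalg.norm(sdir, axis=1, keepdims=True)
    srot = _align_z_to(sdir)
    spos = _quantize(spos, config.pos_quant)
    seul = _quantize(srot.as_euler("ZYX", degrees=True), config.ang_quant)
    squat = Rotation.from_euler("ZYX", seul, degrees=True).as_quat(scalar_first=True)
    streams["scope_pose"] = PoseStream(ts, spos, squat)

    rating = simulate_rater(performance, config.rater_sigma,
                            seed=int(rng.integers(2 ** 31 - 1)),
                            rho=config.rater_rho)
    meta = TrialMeta(subject_id=subject_id, trial_index=trial_index,
                     nominal_rate_hz=config.rate_hz, completed=T < config.max_duration,
                     seed=seed, rating=rating)
    rec = TrialRecording(streams=streams, grip=grip, meta=meta)
    rec.check()
    return rec, rating


# ---------------------------------------------------------------------------
# Cohorts

#: Level-specific latent-skill distributions (mean, sd, clip lo, clip hi).
LEVEL_SKILL = {
    "student": (1.35, 0.35, 1.0, 2.2),
    "resident": (2.90, 0.55, 1.3, 4.2),
    "fellow": (3.60, 0.30, 3.0, 4.6),
}


@dataclass
class SimulatedCohort:
    trials: list            # (TrialRecording, OSATSRating)
    profiles: dict          # subject_id -> SkillProfile
    calibration: CalibrationSet
    config: GeneratorConfig = field(default_factory=GeneratorConfig)

    def ratings_frame(self) -> pd.DataFrame:
        rows = []
        for rec, rating in self.trials:
            row = {"trial_id": f"{rec.meta.subject_id}_t{rec.meta.trial_index}",
                   "subject_id": rec.meta.subject_id}
            row.update(dict(zip(OSATS_DOMAINS, rating.domains)))
            row["summed"] = rating.summed
            row["rounded_avg"] = rating.rounded_avg
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for rec, _ in self.trials:
            write_trial(rec, outdir / f"{rec.meta.subject_id}_t{rec.meta.trial_index}.csv")
        self.calibration.to_json(outdir / "calibration.json")
        self.ratings_frame().to_csv(outdir / "ratings.csv", index=False)


def simulate_cohort(n_subjects: int = 32, trials_each: int = 2,
                    level_mix: dict[str, int] | None = None,
                    config: GeneratorConfig | None = None,
                    seed: int | None = None) -> SimulatedCohort:
    """Simulate a training cohort (default: 6 students, 21 residents,
    5 fellows, two trials each).

    Per-subject latent skill is drawn by training level; second trials
    apply the subject's learning gain.
    """
    config = config or GeneratorConfig()
    if level_mix is None:
        level_mix = {"student": 6, "resident": 21, "fellow": 5}
    if sum(level_mix.values()) != n_subjects:
        raise ValueError("level_mix must sum to n_subjects")
    rng = np.random.default_rng(seed)
    profiles: dict[str, SkillProfile] = {}
    trials = []
    i = 0
    for level in LEVELS:
        for _ in range(level_mix.get(level, 0)):
            sid = f"S{i:02d}"
            mu, sd, lo, hi = LEVEL_SKILL[level]
            s = float(np.clip(rng.normal(mu, sd), lo, hi))
            gain = abs(rng.normal(0.25, 0.15))
            profiles[sid] = SkillProfile(s=s, level=level, learning_gain=gain)
            for k in range(1, trials_each + 1):
                trial_seed = int(rng.integers(2 ** 31 - 1))
                rec, rating = simulate_trial(profiles[sid], config, seed=trial_seed,
                                             trial_index=k, subject_id=sid)
                trials.append((rec, rating))
            i += 1
    return SimulatedCohort(trials=trials, profiles=profiles,
                           calibration=true_calibration(config), config=config)
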