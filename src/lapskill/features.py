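"""The 280 motion-analysis features (MAFs) and their normative manifest.

Each trial is summarised by 280 scalar features in four sensor
categories:

* **time** (5): trial duration ``T`` and its square, square root,
  inverse, and squared inverse;
* **visibility** (8): per tool, time in / out of the camera's
  field-of-view cone and the corresponding fractions of ``T``;
* **grip** (20): per tool, peak rates of grip-angle velocity (above
  5/10/20 deg/s) and acceleration (above 100 deg/s^2), and the time the
  handle was moving versus stationary;
* **tip_motion** (247): path lengths, average speeds, and instantaneous
  velocity/acceleration statistics of each tool tip, linear (cm) and
  angular (degrees), plus needle/maryland ratios and cross-tool sums.

The manifest (names, ordering, category tags) is normative and
version-locked: models and persisted feature files reference features by
these names.  Peak counts are reported per second of trial (divided by
``T``); "stationary" on noisy signals means a magnitude at or below a
small configurable threshold (1 deg/s for grip velocity, 10 deg/s^2 for
grip acceleration).  Needle/maryland ratios with a vanishing denominator
are mapped to 0 so every feature is finite (a standardised design
matrix cannot carry infinities).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .kinematics import TrialKinematics

__all__ = [
    "MANIFEST_VERSION",
    "CATEGORIES",
    "SUBSETS",
    "FeatureDescriptor",
    "FeatureVector",
    "maf_manifest",
    "manifest_names",
    "subset_names",
    "count_peaks",
    "extract_mafs",
]

MANIFEST_VERSION = "1.0"

CATEGORIES = ("time", "visibility", "grip", "tip_motion")

#: Sensor subsets used for model comparison (T = time, M = tip motion,
#: V = visibility, G = grip).
SUBSETS = {
    "T": ("time",),
    "TG": ("time", "grip"),
    "TM": ("time", "tip_motion"),
    "TMV": ("time", "tip_motion", "visibility"),
    "TMG": ("time", "tip_motion", "grip"),
    "TMVG": ("time", "tip_motion", "visibility", "grip"),
}

TOOLS = ("maryland", "needle")

#: Peak-count thresholds for instantaneous magnitude series.
LIN_VEL_THRESHOLDS = (2.0, 5.0, 10.0, 100.0)        # cm/s
ANG_VEL_THRESHOLDS = (1.0, 10.0, 20.0, 200.0)       # deg/s
LIN_ACC_THRESHOLDS = (10.0, 100.0, 1000.0, 10000.0)  # cm/s^2
ANG_ACC_THRESHOLDS = (50.0, 100.0, 1000.0, 10000.0)  # deg/s^2
GRIP_VEL_THRESHOLDS = (5.0, 10.0, 20.0)             # deg/s
GRIP_ACC_THRESHOLDS = (100.0,)                      # deg/s^2

#: |velocity| <= EPS_V counts as "stationary" (deg/s); same for accel.
EPS_GRIP_VEL = 1.0
EPS_GRIP_ACC = 10.0

#: Ratio denominators below this magnitude yield a 0 ratio.
RATIO_EPS = 1e-9


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    category: str
    subcategory: str
    tool: str       # 'maryland', 'needle', 'both', or 'none'
    units: str


@dataclass(frozen=True)
class FeatureVector:
    """280 finite feature values in manifest order for one trial."""

    values: np.ndarray
    names: tuple[str, ...]
    trial_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.names),):
            raise ValueError("values/names length mismatch")
        if not np.all(np.isfinite(self.values)):
            bad = [n for n, v in zip(self.names, self.values) if not np.isfinite(v)]
            raise ValueError(f"non-finite feature values: {bad[:5]}")

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names), name=self.trial_id)


# ---------------------------------------------------------------------------
# Manifest construction

_AXES = ("x", "y", "z")
_ANG_AXES = ("elev", "roll", "azim")   # tracker x, y, z rotation axes
_STATS = ("max", "min", "range", "std")

_INST_KINDS = (
    ("inst_lin_vel", "lin_vel", "cm/s", LIN_VEL_THRESHOLDS, _AXES),
    ("inst_ang_vel", "ang_vel", "deg/s", ANG_VEL_THRESHOLDS, _ANG_AXES),
    ("inst_lin_acc", "lin_acc", "cm/s2", LIN_ACC_THRESHOLDS, _AXES),
    ("inst_ang_acc", "ang_acc", "deg/s2", ANG_ACC_THRESHOLDS, _ANG_AXES),
)

_AVG_KINDS = (
    ("avg_lin_speed", "lin_vel", "cm/s", _AXES),
    ("avg_ang_speed", "ang_vel", "deg/s", _ANG_AXES),
    ("avg_lin_acc", "lin_acc", "cm/s2", _AXES),
    ("avg_ang_acc", "ang_acc", "deg/s2", _ANG_AXES),
)


def _build_manifest() -> tuple[FeatureDescriptor, ...]:
    out: list[FeatureDescriptor] = []

    def add(name, category, sub, tool, units):
        out.append(FeatureDescriptor(name, category, sub, tool, units))

    # --- time (5): T, T^2, sqrt(T), 1/T, 1/T^2
    add("trial_time", "time", "time", "none", "s")
    add("trial_time_sq", "time", "time", "none", "s2")
    add("trial_time_sqrt", "time", "time", "none", "s^0.5")
    add("trial_time_inv", "time", "time", "none", "1/s")
    add("trial_time_inv_sq", "time", "time", "none", "1/s2")

    # --- visibility (8)
    for tool in TOOLS:
        add(f"{tool}_time_in_view", "visibility", "visibility", tool, "s")
        add(f"{tool}_time_out_view", "visibility", "visibility", tool, "s")
        add(f"{tool}_frac_in_view", "visibility", "visibility", tool, "")
        add(f"{tool}_frac_out_view", "visibility", "visibility", tool, "")

    # --- grip (20)
    for tool in TOOLS:
        for thr in GRIP_VEL_THRESHOLDS:
            add(f"{tool}_grip_vel_peaks_ge{thr:g}_rate", "grip", "grip_vel", tool, "1/s")
        add(f"{tool}_grip_vel_time_zero", "grip", "grip_vel", tool, "s")
        add(f"{tool}_grip_vel_time_nonzero", "grip", "grip_vel", tool, "s")
        add(f"{tool}_grip_vel_zero_frac", "grip", "grip_vel", tool, "")
        for thr in GRIP_ACC_THRESHOLDS:
            add(f"{tool}_grip_acc_peaks_ge{thr:g}_rate", "grip", "grip_acc", tool, "1/s")
        add(f"{tool}_grip_acc_time_zero", "grip", "grip_acc", tool, "s")
        add(f"{tool}_grip_acc_time_nonzero", "grip", "grip_acc", tool, "s")
        add(f"{tool}_grip_acc_zero_frac", "grip", "grip_acc", tool, "")

    # --- tip motion (247)
    # S1 linear path (16)
    for tool in TOOLS:
        for ax in _AXES:
            add(f"{tool}_path_{ax}", "tip_motion", "linear_path", tool, "cm")
        add(f"{tool}_path_3d", "tip_motion", "linear_path", tool, "cm")
        add(f"{tool}_bbox_diag", "tip_motion", "linear_path", tool, "cm")
    for part in [f"path_{ax}" for ax in _AXES] + ["path_3d", "bbox_diag"]:
        add(f"ratio_{part}", "tip_motion", "linear_path", "both", "")
    add("sum_path_3d", "tip_motion", "linear_path", "both", "cm")

    # S2 angular path (15)
    for tool in TOOLS:
        for ax in _ANG_AXES:
            add(f"{tool}_apath_{ax}", "tip_motion", "angular_path", tool, "deg")
        add(f"{tool}_apath_total", "tip_motion", "angular_path", tool, "deg")
        add(f"{tool}_arange_sum", "tip_motion", "angular_path", tool, "deg")
    for part in [f"apath_{ax}" for ax in _ANG_AXES] + ["apath_total"]:
        add(f"ratio_{part}", "tip_motion", "angular_path", "both", "")
    add("sum_apath_total", "tip_motion", "angular_path", "both", "deg")

    # S3-S6 average speeds/accelerations (12 each)
    for sub, _, units, axes in _AVG_KINDS:
        for tool in TOOLS:
            for ax in axes:
                add(f"{tool}_{sub}_{ax}", "tip_motion", sub, tool, units)
            add(f"{tool}_{sub}_mag", "tip_motion", sub, tool, units)
        for ax in axes:
            add(f"ratio_{sub}_{ax}", "tip_motion", sub, "both", "")
        add(f"ratio_{sub}_mag", "tip_motion", sub, "both", "")

    # S7-S10 instantaneous statistics + peak rates (42 each)
    for sub, _, units, thresholds, axes in _INST_KINDS:
        for tool in TOOLS:
            for ax in axes:
                for stat in _STATS:
                    add(f"{tool}_{sub}_{ax}_{stat}", "tip_motion", sub, tool, units)
        for tool in TOOLS:
            add(f"{tool}_{sub}_mag_max", "tip_motion", sub, tool, units)
            add(f"{tool}_{sub}_mag_std", "tip_motion", sub, tool, units)
        for ax in axes:
            add(f"ratio_{sub}_{ax}_std", "tip_motion", sub, "both", "")
        add(f"ratio_{sub}_mag_max", "tip_motion", sub, "both", "")
        add(f"ratio_{sub}_mag_std", "tip_motion", sub, "both", "")
        for tool in TOOLS:
            for thr in thresholds:
                add(f"{tool}_{sub}_mag_peaks_ge{thr:g}_rate", "tip_motion", sub, tool, "1/s")
        add(f"sum_{sub}_mag_peaks_ge{thresholds[0]:g}_rate", "tip_motion", sub, "both", "1/s")

    names = [d.name for d in out]
    assert len(names) == len(set(names)), "manifest names must be unique"
    counts = {c: sum(d.category == c for d in out) for c in CATEGORIES}
    assert counts == {"time": 5, "visibility": 8, "grip": 20, "tip_motion": 247}, counts
    return tuple(out)


_MANIFEST = _build_manifest()


def maf_manifest() -> tuple[FeatureDescriptor, ...]:
    """The ordered, version-locked manifest of all 280 features."""
    return _MANIFEST


def manifest_names(categories: Iterable[str] | None = None) -> list[str]:
    cats = set(CATEGORIES if categories is None else categories)
    unknown = cats - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories {sorted(unknown)}")
    return [d.name for d in _MANIFEST if d.category in cats]


def subset_names(subset: str) -> list[str]:
    """Feature names available to a sensor subset (T, TG, ... TMVG)."""
    if subset not in SUBSETS:
        raise ValueError(f"unknown subset {subset!r}; choose from {sorted(SUBSETS)}")
    return manifest_names(SUBSETS[subset])


# ---------------------------------------------------------------------------
# Extraction

def count_peaks(series: np.ndarray, threshold: float) -> int:
    """Count local maxima at or above ``threshold``.

    A sample ``i`` (interior) is a peak when ``s[i] > s[i-1]``,
    ``s[i] >= s[i+1]``, and ``s[i] >= threshold``.  Intended for
    nonnegative magnitude series on the uniform grid.  Returns 0 for
    series shorter than 3 samples.
    """
    s = np.asarray(series, dtype=float)
    if s.size < 3:
        return 0
    mid = s[1:-1]
    return int(np.sum((mid > s[:-2]) & (mid >= s[2:]) & (mid >= threshold)))


def _ratio(num: float, den: float) -> float:
    return 0.0 if abs(den) < RATIO_EPS else float(num / den)


def _ang_cols(arr: np.ndarray) -> np.ndarray:
    """Reorder (azimuth, elevation, roll) columns to tracker-axis order.

    The tracker's rotation axes are x = tilting up/down (elevation),
    y = rotation about the shaft (roll), z = bending left/right
    (azimuth); kinematics stores Euler columns as (azimuth, elevation,
    roll), so axis order (elev, roll, azim) is columns (1, 2, 0).
    """
    return arr[:, [1, 2, 0]]


def extract_mafs(kin: TrialKinematics, categories: Iterable[str] | None = None,
                 trial_id: str = "") -> FeatureVector:
    """Compute the features of the requested categories in manifest order."""
    T = kin.duration
    if T <= 0:
        raise ValueError("empty trial (zero duration)")
    N = kin.n_samples
    vals: dict[str, float] = {}

    vals["trial_time"] = T
    vals["trial_time_sq"] = T ** 2
    vals["trial_time_sqrt"] = float(np.sqrt(T))
    vals["trial_time_inv"] = 1.0 / T
    vals["trial_time_inv_sq"] = 1.0 / T ** 2

    for tool in TOOLS:
        tk = kin.tools[tool]
        frac_in = float(np.mean(tk.visible))
        vals[f"{tool}_time_in_view"] = frac_in * T
        vals[f"{tool}_time_out_view"] = (1.0 - frac_in) * T
        vals[f"{tool}_frac_in_view"] = frac_in
        vals[f"{tool}_frac_out_view"] = 1.0 - frac_in

    for tool in TOOLS:
        tk = kin.tools[tool]
        for sig, thresholds, eps, tag in [
            (tk.grip_vel, GRIP_VEL_THRESHOLDS, EPS_GRIP_VEL, "grip_vel"),
            (tk.grip_acc, GRIP_ACC_THRESHOLDS, EPS_GRIP_ACC, "grip_acc"),
        ]:
            mag = np.abs(sig)
            for thr in thresholds:
                vals[f"{tool}_{tag}_peaks_ge{thr:g}_rate"] = count_peaks(mag, thr) / T
            zero_frac = float(np.mean(mag <= eps))
            vals[f"{tool}_{tag}_time_zero"] = zero_frac * T
            vals[f"{tool}_{tag}_time_nonzero"] = (1.0 - zero_frac) * T
            vals[f"{tool}_{tag}_zero_frac"] = zero_frac

    # --- tip motion
    for tool in TOOLS:
        tk = kin.tools[tool]
        dp = np.diff(tk.tip_pos, axis=0)
        for j, ax in enumerate(_AXES):
            vals[f"{tool}_path_{ax}"] = float(np.sum(np.abs(dp[:, j])))
        vals[f"{tool}_path_3d"] = float(np.sum(np.linalg.norm(dp, axis=1)))
        extent = tk.tip_pos.max(axis=0) - tk.tip_pos.min(axis=0)
        vals[f"{tool}_bbox_diag"] = float(np.linalg.norm(extent))

        eul = _ang_cols(tk.euler)  # columns: elev, roll, azim
        de = np.diff(eul, axis=0)
        for j, ax in enumerate(_ANG_AXES):
            vals[f"{tool}_apath_{ax}"] = float(np.sum(np.abs(de[:, j])))
        vals[f"{tool}_apath_total"] = float(np.sum(np.linalg.norm(de, axis=1)))
        vals[f"{tool}_arange_sum"] = float(np.sum(eul.max(axis=0) - eul.min(axis=0)))

        for sub, attr, _, axes in _AVG_KINDS:
            arr = getattr(tk, attr)
            if axes is _ANG_AXES:
                arr = _ang_cols(arr)
            for j, ax in enumerate(axes):
                vals[f"{tool}_{sub}_{ax}"] = float(np.mean(np.abs(arr[:, j])))
            vals[f"{tool}_{sub}_mag"] = float(np.mean(np.linalg.norm(arr, axis=1)))

        for sub, attr, _, thresholds, axes in _INST_KINDS:
            arr = getattr(tk, attr)
            if axes is _ANG_AXES:
                arr = _ang_cols(arr)
            for j, ax in enumerate(axes):
                col = arr[:, j]
                vals[f"{tool}_{sub}_{ax}_max"] = float(col.max())
                vals[f"{tool}_{sub}_{ax}_min"] = float(col.min())
                vals[f"{tool}_{sub}_{ax}_range"] = float(col.max() - col.min())
                vals[f"{tool}_{sub}_{ax}_std"] = float(col.std())
            mag = np.linalg.norm(arr, axis=1)
            vals[f"{tool}_{sub}_mag_max"] = float(mag.max())
            vals[f"{tool}_{sub}_mag_std"] = float(mag.std())
            for thr in thresholds:
                vals[f"{tool}_{sub}_mag_peaks_ge{thr:g}_rate"] = count_peaks(mag, thr) / T

    # cross-tool ratios (needle / maryland) and sums
    for part in [f"path_{ax}" for ax in _AXES] + ["path_3d", "bbox_diag"]:
        vals[f"ratio_{part}"] = _ratio(vals[f"needle_{part}"], vals[f"maryland_{part}"])
    vals["sum_path_3d"] = vals["needle_path_3d"] + vals["maryland_path_3d"]
    for part in [f"apath_{ax}" for ax in _ANG_AXES] + ["apath_total"]:
        vals[f"ratio_{part}"] = _ratio(vals[f"needle_{part}"], vals[f"maryland_{part}"])
    vals["sum_apath_total"] = vals["needle_apath_total"] + vals["maryland_apath_total"]
    for sub, _, _, axes in _AVG_KINDS:
        for ax in axes:
            vals[f"ratio_{sub}_{ax}"] = _ratio(vals[f"needle_{sub}_{ax}"],
                                               vals[f"maryland_{sub}_{ax}"])
        vals[f"ratio_{sub}_mag"] = _ratio(vals[f"needle_{sub}_mag"],
                                          vals[f"maryland_{sub}_mag"])
    for sub, _, _, thresholds, axes in _INST_KINDS:
        for ax in axes:
            vals[f"ratio_{sub}_{ax}_std"] = _ratio(vals[f"needle_{sub}_{ax}_std"],
                                                   vals[f"maryland_{sub}_{ax}_std"])
        vals[f"ratio_{sub}_mag_max"] = _ratio(vals[f"needle_{sub}_mag_max"],
                                              vals[f"maryland_{sub}_mag_max"])
        vals[f"ratio_{sub}_mag_std"] = _ratio(vals[f"needle_{sub}_mag_std"],
                                              vals[f"maryland_{sub}_mag_std"])
        low = thresholds[0]
        vals[f"sum_{sub}_mag_peaks_ge{low:g}_rate"] = (
            vals[f"needle_{sub}_mag_peaks_ge{low:g}_rate"]
            + vals[f"maryland_{sub}_mag_peaks_ge{low:g}_rate"]
        )

    names = manifest_names(categories)
    return FeatureVector(values=np.array([vals[n] for n in names]),
                         names=tuple(names), trial_id=trial_id)
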