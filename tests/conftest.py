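import logging

import numpy as np
import pandas as pd
import pytest

import lapskill as lk

logging.getLogger("lapskill").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def calib():
    return lk.true_calibration()


@pytest.fixture(scope="session")
def small_trial():
    """One mid-skill synthetic trial plus its ground-truth rating."""
    rec, rating = lk.simulate_trial(lk.SkillProfile(s=3.0), seed=7)
    return rec, rating


@pytest.fixture(scope="session")
def small_kin(small_trial, calib):
    rec, _ = small_trial
    return lk.compute_kinematics(rec, calib)


@pytest.fixture(scope="session")
def cohort():
    """Default 32-subject cohort, seed 11 (shared across model tests)."""
    return lk.simulate_cohort(seed=11)


@pytest.fixture(scope="session")
def cohort_features(cohort):
    """(X, domain matrix, subject ids) for the shared cohort."""
    rows, doms, subj = [], [], []
    for rec, rating in cohort.trials:
        kin = lk.compute_kinematics(rec, cohort.calibration)
        rows.append(lk.extract_mafs(kin).to_series())
        doms.append(rating.domains)
        subj.append(rec.meta.subject_id)
    X = pd.DataFrame(rows).reset_index(drop=True)
    return X, np.array(doms), np.array(subj)


def uniform_trial(n: int = 1200, rate: float = 20.0) -> lk.TrialRecording:
    """A perfectly uniform recording with n samples per channel."""
    t = np.arange(n) / rate
    pos = np.column_stack([np.sin(t / 5), np.cos(t / 7), 0.1 * t / t[-1]])
    quat = np.tile([1.0, 0.0, 0.0, 0.0], (n, 1))
    from lapskill.trial_io import GripStream, PoseStream

    streams = {ch: PoseStream(t, pos + i, quat)
               for i, ch in enumerate(["maryland_pose", "needle_pose", "scope_pose"])}
    grip = {tool: GripStream(t, 1.5 + 0.1 * np.sin(t)) for tool in ["maryland", "needle"]}
    return lk.TrialRecording(streams=streams, grip=grip)
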