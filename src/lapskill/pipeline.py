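"""High-level experiment drivers: cohort -> features -> LOSO evaluation."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import extract_mafs
from .kinematics import compute_kinematics
from .modeling import EvalReport, loso_evaluate
from .synthetic import GeneratorConfig, SimulatedCohort, simulate_cohort

__all__ = ["cohort_feature_table", "skill_recovery_experiment"]


def cohort_feature_table(cohort: SimulatedCohort):
    """Run every trial of a cohort through kinematics + feature extraction.

    Returns ``(X, domains, subjects)``: the 280-column feature matrix,
    the (n, 5) OSATS domain matrix, and the subject-id vector.
    """
    rows, doms, subj = [], [], []
    for rec, rating in cohort.trials:
        kin = compute_kinematics(rec, cohort.calibration)
        rows.append(extract_mafs(kin).to_series())
        doms.append(rating.domains)
        subj.append(rec.meta.subject_id)
    X = pd.DataFrame(rows).reset_index(drop=True)
    return X, np.array(doms), np.array(subj)


def skill_recovery_experiment(seeds, subsets=("TMVG", "TM"),
                              config: GeneratorConfig | None = None,
                              ) -> dict[str, dict[str, float]]:
    """LOSO skill recovery on fresh default cohorts, one per seed.

    For each seed a full 32-subject cohort is simulated, featurised, and
    evaluated with leave-one-subject-out CV for each requested sensor
    subset.  Returns per-subset seed-averaged metrics.
    """
    acc: dict[str, dict[str, list[float]]] = {
        s: {"summed_r": [], "summed_within2": [], "summed_within4": [],
            "rounded_exact": [], "rounded_within1": []} for s in subsets}
    for seed in seeds:
        cohort = simulate_cohort(seed=int(seed), config=config)
        X, doms, subj = cohort_feature_table(cohort)
        for subset in subsets:
            rep: EvalReport = loso_evaluate(X, doms, subj, subset=subset,
                                            seed=int(seed))
            for k in acc[subset]:
                acc[subset][k].append(rep.metrics[k])
    return {s: {k: float(np.mean(v)) for k, v in d.items()}
            for s, d in acc.items()}
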