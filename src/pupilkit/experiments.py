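"""Simulation experiments used by the acceptance suite and report.

Each function runs the *full* pipeline (generation -> preprocessing ->
contrast -> statistics) on synthetic cohorts; nothing is cached or
shortcut, so these measure the behaviour of the shipped code paths.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import clusterstat, prediction
from .preprocess import preprocess_run
from .synthcohort import (
    SyntheticCohort,
    SyntheticCohortConfig,
    generate_cohort,
    generate_score_table,
    null_config,
)


def cohort_contrast(cohort: SyntheticCohort) -> clusterstat.ContrastMatrix:
    """Preprocess every run and build the group contrast."""
    epochs = {
        p.participant_id: preprocess_run(p.run, p.events) for p in cohort
    }
    return clusterstat.build_contrast(epochs)


def estimated_pdi(cohort: SyntheticCohort) -> np.ndarray:
    """Fixed-window PDI estimates for each participant, pipeline order."""
    contrast = cohort_contrast(cohort)
    table = clusterstat.compute_pdi(contrast)
    order = {pid: i for i, pid in enumerate(table["participant_id"])}
    assert all(p.participant_id in order for p in cohort)
    return table.set_index("participant_id")["pdi"].loc[
        [p.participant_id for p in cohort]
    ].to_numpy()


def null_cluster_significance_rate(
    n_cohorts: int = 200,
    base_seed: int = 0,
    n_participants: int = 34,
    n_iter: int = 1000,
    alpha: float = 0.05,
    blink_rate_per_min: float = 0.0,
) -> float:
    """Fraction of null cohorts whose largest cluster reaches p <= alpha.

    Cohorts have no regulation effect and default sample noise; blink
    injection is off by default purely for speed (loss interpolation is
    effect-neutral under the null).
    """
    hits = 0
    for i in range(n_cohorts):
        cfg = null_config(
            seed=base_seed + i,
            n_participants=n_participants,
            blink_rate_per_min=blink_rate_per_min,
        )
        contrast = cohort_contrast(generate_cohort(cfg))
        result = clusterstat.run_cluster_test(
            contrast, n_iter=n_iter, seed=base_seed + 10_000 + i, alpha=alpha
        )
        if result.clusters and min(result.p_per_cluster) <= alpha:
            hits += 1
    return hits / n_cohorts


def pdi_recovery_correlations(
    n_cohorts: int = 50,
    base_seed: int = 0,
    pdi_loading: float = 0.3,
    n_participants: int = 34,
) -> np.ndarray:
    """Spearman correlation between true and pipeline-estimated PDI per cohort."""
    rhos = np.empty(n_cohorts)
    for i in range(n_cohorts):
        cfg = SyntheticCohortConfig(
            seed=base_seed + i,
            n_participants=n_participants,
            pdi_loading=pdi_loading,
        )
        cohort = generate_cohort(cfg)
        est = estimated_pdi(cohort)
        true = np.array([p.true_pdi for p in cohort])
        rhos[i] = stats.spearmanr(true, est).statistic
    return rhos


def noiseless_pdi_recovery(seed: int = 0, n_participants: int = 8):
    """(true, estimated) PDI pairs for a zero-noise plateau cohort."""
    cfg = SyntheticCohortConfig(
        seed=seed,
        n_participants=n_participants,
        noise_sd=0.0,
        drift_sd=0.0,
        blink_rate_per_min=0.0,
        pdi_loading=0.3,
    )
    cohort = generate_cohort(cfg)
    est = estimated_pdi(cohort)
    true = np.array([p.true_pdi for p in cohort])
    return true, est


def null_prediction_behaviour(
    n_seeds: int = 50,
    base_seed: int = 0,
    n_participants: int = 24,
    n_iter: int = 1000,
):
    """(accuracies, p_values) of leave-2-out prediction on null score tables."""
    accs = np.empty(n_seeds)
    ps = np.empty(n_seeds)
    for i in range(n_seeds):
        table = generate_score_table(
            n_participants,
            coef=(1.75, 0.0, 0.0, 0.0),
            noise_sd=0.5,
            hcs_coef=(62.0, 0.0),
            seed=base_seed + i,
        )
        res = prediction.accuracy_permutation_null(
            table, n_iter=n_iter, seed=base_seed + 5000 + i
        )
        accs[i] = res.accuracy
        ps[i] = res.p_value
    return accs, ps
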