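"""Cohort-level simulation studies: null calibration and effect recovery.

``null_calibration_study`` measures the empirical type-I rate of the
edge-wise and metric-wise group comparisons on cohorts generated with no
group difference. ``effect_recovery_study`` measures how often cohorts with
the planted task-state effect reproduce the qualitative signature — more
significant findings and a higher classification accuracy in the task state
than at rest.

Both studies run the generator at the HbO stage (the optical forward model
and its inversion are validated separately and are linear, so they do not
change connectivity), and the calibration study restricts the metric-wise
tests to the surrogate-free global metrics (Cp, Lp, Eg, Eloc, r, b) — the
small-world ratios are quotients of two of these and would multiply the run
time a hundredfold for no additional calibration information.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import graphmetrics as gm
from .classify import fit_eval
from .connectivity import SPARSITY_GRID, pearson_fisher, segment_states, threshold_sweep
from .model import AnalysisConfig, CohortNetworkModel
from .stats import compare_connectivity_edges, compare_groups
from .synth import CohortConfig, generate_cohort

CALIBRATION_METRICS = ("Cp", "Lp", "Eloc", "Eg", "r", "b")


def _surrogate_free_global_aucs(z: np.ndarray) -> dict[str, float]:
    """AUCs of the surrogate-free global metrics over the sparsity sweep."""
    thr = np.asarray(SPARSITY_GRID)
    curves = {m: [] for m in CALIBRATION_METRICS}
    for net in threshold_sweep(z):
        a = net.adjacency
        ncp, cp = gm.clustering(a)
        curves["Cp"].append(cp)
        curves["Lp"].append(gm.char_path_length(a))
        eg, _, _, eloc = gm.efficiencies(a)
        curves["Eg"].append(eg)
        curves["Eloc"].append(eloc)
        curves["r"].append(gm.assortativity(a))
        curves["b"].append(gm.hierarchy_slope(ncp, gm.degrees(a)))
    return {m: gm.auc_over_thresholds(np.asarray(v), thr) for m, v in curves.items()}


def _cohort_connectivity(subjects):
    z = {"rest": {"PSD": [], "nonPSD": []}, "task": {"PSD": [], "nonPSD": []}}
    for subj in subjects:
        rest, task = segment_states(subj.recording, subj.schedule)
        z["rest"][subj.group].append(pearson_fisher(rest).z)
        z["task"][subj.group].append(pearson_fisher(task).z)
    return z


def null_calibration_study(
    n_cohorts: int = 200,
    n_psd: int = 19,
    n_nonpsd: int = 18,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical type-I rates on cohorts with no planted group difference.

    Returns one row per cohort with the fraction of significant edge-wise
    tests per state (uncorrected two-tailed, 91 tests each) and the fraction
    of significant surrogate-free global-metric AUC tests in the task state.
    """
    rows = []
    seeds = np.random.SeedSequence(seed).generate_state(n_cohorts)
    for k in range(n_cohorts):
        subjects = generate_cohort(CohortConfig(
            n_psd=n_psd, n_nonpsd=n_nonpsd,
            effect_size_task=0.0, effect_size_rest=0.0,
            emit_stage="hbo", seed=int(seeds[k] % 2**31),
        ))
        z = _cohort_connectivity(subjects)
        row = {}
        for st in ("rest", "task"):
            df = compare_connectivity_edges(
                np.stack(z[st]["PSD"]), np.stack(z[st]["nonPSD"]), alpha=alpha, tails="two"
            )
            row[f"edge_frac_{st}"] = df["significant"].mean()
        aucs = {"PSD": [], "nonPSD": []}
        for g in ("PSD", "nonPSD"):
            for zm in z["task"][g]:
                aucs[g].append(_surrogate_free_global_aucs(zm))
        n_sig = n_tot = 0
        for m in CALIBRATION_METRICS:
            va = np.asarray([a[m] for a in aucs["PSD"]])
            vb = np.asarray([a[m] for a in aucs["nonPSD"]])
            va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
            if len(va) < 3 or len(vb) < 3:
                continue
            rec = compare_groups(va, vb, tails="two", alpha=alpha, name=m)
            n_tot += 1
            n_sig += int(rec.p < alpha)
        row["metric_frac_task"] = n_sig / n_tot if n_tot else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def effect_recovery_study(
    n_cohorts: int = 50,
    effect_size_task: float = 1.0,
    n_rand: int = 6,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Task-vs-rest contrast on cohorts with a task-state-only planted effect.

    Each cohort is analysed end to end (connectivity, metric sweep with
    ``n_rand`` rewired surrogates, group statistics, repeated stratified-CV
    classification in both states). Returns per-cohort counts of significant
    edges and metrics and the mean classification accuracy per state.
    """
    rows = []
    seeds = np.random.SeedSequence(seed).generate_state(n_cohorts)
    for k in range(n_cohorts):
        s = int(seeds[k] % 2**31)
        subjects = generate_cohort(CohortConfig(
            effect_size_task=effect_size_task, effect_size_rest=0.0,
            emit_stage="hbo", seed=s,
        ))
        cfg = AnalysisConfig(n_rand=n_rand, n_repeats=n_repeats, seed=s)
        res = CohortNetworkModel(subjects, config=cfg).fit()
        rows.append({
            "sig_edges_rest": res.n_significant_edges("rest"),
            "sig_edges_task": res.n_significant_edges("task"),
            "sig_metrics_rest": res.n_significant_metrics("rest"),
            "sig_metrics_task": res.n_significant_metrics("task"),
            "acc_rest": res.classification["rest"].mean_accuracy,
            "acc_task": res.classification["task"].mean_accuracy,
        })
    return pd.DataFrame(rows)


def permuted_label_accuracy(
    n_permutations: int = 3, n_repeats: int = 4, seed: int = 0
) -> float:
    """Mean cross-validated accuracy with permuted group labels.

    Uses real pipeline features from one null cohort; the expectation under
    the permutation null is chance-level accuracy.
    """
    rng = np.random.default_rng(seed)
    subjects = generate_cohort(CohortConfig(
        effect_size_task=0.0, effect_size_rest=0.0, emit_stage="hbo",
        seed=int(rng.integers(0, 2**31)),
    ))
    res = CohortNetworkModel(subjects, config=AnalysisConfig(n_rand=4, n_repeats=1, seed=seed)).fit()
    table = res.features["task"]
    y = res.manifest.loc[table.index, "group"].to_numpy()
    accs = [
        fit_eval(table, rng.permutation(y), n_repeats=n_repeats,
                 seed=int(rng.integers(0, 2**31))).mean_accuracy
        for _ in range(n_permutations)
    ]
    return float(np.mean(accs))
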