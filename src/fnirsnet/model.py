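"""Cohort-level model and results objects.

``CohortNetworkModel`` is built from a list of subjects (synthetic or read
from disk); ``fit()`` runs the full analysis — preprocessing, rest/task
connectivity, graph-metric sweep, group statistics, HAMD correlations and
cost-sensitive SVM classification — and returns a ``CohortNetworkResults``
carrying every intermediate product plus a ``summary()`` table contrasting
the task and rest states.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import classify as _classify
from . import connectivity as _conn
from . import graphmetrics as _gm
from . import preprocess as _pre
from . import stats as _stats
from .connectivity import SPARSITY_GRID
from .synth import CohortConfig, SubjectRecord, generate_cohort

STATES = ("rest", "task")


@dataclass
class AnalysisConfig:
    """Tunable parameters of the analysis stages.

    Defaults follow the protocol this pipeline targets: 0.5 s / 6×SD motion
    windows, 0.01–0.2 Hz band, DPF 6, sparsity sweep 0.15–0.50, 100 rewired
    surrogates per network, α = 0.05 uncorrected, 8-fold CV repeated 10×
    with 95% retained PCA variance. ``n_rand`` is the main runtime knob for
    simulation studies.
    """

    window_s: float = _pre.DEFAULT_WINDOW_S
    k_sd: float = _pre.DEFAULT_K_SD
    band_hz: tuple[float, float] = _pre.DEFAULT_BAND_HZ
    dpf: float = _pre.DEFAULT_DPF
    sparsities: tuple[float, ...] = SPARSITY_GRID
    n_rand: int = _gm.DEFAULT_N_RAND
    alpha: float = _stats.DEFAULT_ALPHA
    tails_edges: str = "two"
    tails_metrics: str = "two"
    fdr: bool = False
    n_folds: int = 8
    n_repeats: int = 10
    variance_retained: float = 0.95
    kernel: str = "linear"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


class CohortNetworkModel:
    """Brain-network group analysis of a two-group fNIRS cohort.

    Parameters
    ----------
    subjects : list of SubjectRecord
        Recordings may arrive at the raw ``intensity`` stage (the full
        preprocessing chain is applied) or already as ``hbo``.
    config : AnalysisConfig, optional
    """

    def __init__(self, subjects: list[SubjectRecord], config: AnalysisConfig | None = None):
        if not subjects:
            raise ValueError("empty cohort")
        groups = {s.group for s in subjects}
        if groups != {"PSD", "nonPSD"}:
            raise ValueError(f"expected groups PSD and nonPSD, got {sorted(groups)}")
        self.subjects = subjects
        self.config = config or AnalysisConfig()

    @classmethod
    def from_synthetic(
        cls,
        n_psd: int = 19,
        n_nonpsd: int = 18,
        effect_size_task: float = 1.0,
        effect_size_rest: float = 0.0,
        seed: int = 0,
        config: AnalysisConfig | None = None,
        cohort_config: CohortConfig | None = None,
        **cohort_kw,
    ) -> "CohortNetworkModel":
        """Generate a synthetic cohort and wrap it in a model."""
        if cohort_config is None:
            cohort_config = CohortConfig(
                n_psd=n_psd, n_nonpsd=n_nonpsd,
                effect_size_task=effect_size_task, effect_size_rest=effect_size_rest,
                seed=seed, **cohort_kw,
            )
        return cls(generate_cohort(cohort_config), config=config)

    @classmethod
    def from_manifest(cls, path, config: AnalysisConfig | None = None) -> "CohortNetworkModel":
        """Load a cohort written by :mod:`fnirsnet.io` (CSV manifest)."""
        from .io import read_cohort

        return cls(read_cohort(path), config=config)

    # -- fitting ------------------------------------------------------------

    def fit(self, progress: bool = False) -> "CohortNetworkResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        manifest = pd.DataFrame(
            {"id": [s.id for s in self.subjects],
             "group": [s.group for s in self.subjects],
             "hamd": [s.hamd for s in self.subjects]}
        ).set_index("id")

        connectivity: dict[str, dict[str, np.ndarray]] = {st: {} for st in STATES}
        metric_sets: dict[str, list[_gm.MetricSet]] = {st: [] for st in STATES}
        for subj in self.subjects:
            rec = subj.recording
            if rec.stage == "intensity":
                rec = _pre.run_preprocessing(
                    rec, window_s=cfg.window_s, k_sd=cfg.k_sd, band_hz=cfg.band_hz, dpf=cfg.dpf
                )
            elif rec.stage != "hbo":
                raise ValueError(f"subject {subj.id}: unsupported input stage {rec.stage}")
            rest, task = _conn.segment_states(rec, subj.schedule)
            for st, seg in (("rest", rest), ("task", task)):
                cm = _conn.pearson_fisher(seg, state=st, subject_id=subj.id)
                connectivity[st][subj.id] = cm.z
                metric_sets[st].append(
                    _gm.compute_metric_set(cm, sparsities=cfg.sparsities, n_rand=cfg.n_rand, seed=rng)
                )

        psd_ids = manifest.index[manifest["group"] == "PSD"]
        non_ids = manifest.index[manifest["group"] == "nonPSD"]

        edge_stats, metric_stats, features, reports, spearman = {}, {}, {}, {}, {}
        imputation_log: dict[str, list[str]] = {}
        for st in STATES:
            za = np.stack([connectivity[st][i] for i in psd_ids])
            zb = np.stack([connectivity[st][i] for i in non_ids])
            edge_stats[st] = _stats.compare_connectivity_edges(
                za, zb, alpha=cfg.alpha, tails=cfg.tails_edges, fdr=cfg.fdr
            )
            table, log = _classify.assemble_features(metric_sets[st], st)
            table = table.loc[manifest.index]
            features[st] = table
            imputation_log[st] = log
            metric_stats[st] = _stats.compare_metric_aucs(
                table, manifest["group"], alpha=cfg.alpha, tails=cfg.tails_metrics, fdr=cfg.fdr
            )
            reports[st] = _classify.fit_eval(
                table, manifest["group"].to_numpy(),
                n_folds=cfg.n_folds, n_repeats=cfg.n_repeats,
                variance_retained=cfg.variance_retained, kernel=cfg.kernel,
                seed=int(np.random.default_rng(cfg.seed).integers(0, 2**31 - 1)),
            )
            rows = []
            for col in table.columns:
                rec_ = _stats.spearman_vs_hamd(table[col], manifest["hamd"], name=col)
                rows.append({"metric": col, "rho": rec_.statistic, "p": rec_.p})
            sp = pd.DataFrame(rows)
            sp["significant"] = sp["p"] < cfg.alpha
            spearman[st] = sp

        return CohortNetworkResults(
            model=self,
            manifest=manifest,
            connectivity=connectivity,
            metric_sets=metric_sets,
            features=features,
            edge_stats=edge_stats,
            metric_stats=metric_stats,
            spearman=spearman,
            classification=reports,
            imputation_log=imputation_log,
        )


@dataclass
class CohortNetworkResults:
    """Everything the cohort analysis produced, with a task-vs-rest summary."""

    model: CohortNetworkModel
    manifest: pd.DataFrame
    connectivity: dict                      # state -> {subject_id: z matrix}
    metric_sets: dict                       # state -> [MetricSet]
    features: dict                          # state -> subjects × 79 DataFrame
    edge_stats: dict                        # state -> DataFrame (91 rows)
    metric_stats: dict                      # state -> DataFrame (79 rows)
    spearman: dict                          # state -> DataFrame
    classification: dict                    # state -> ClassificationReport
    imputation_log: dict = field(default_factory=dict)

    def n_significant_edges(self, state: str) -> int:
        return int(self.edge_stats[state]["significant"].sum())

    def n_significant_metrics(self, state: str) -> int:
        return int(self.metric_stats[state]["significant"].sum())

    def state_contrast(self) -> pd.DataFrame:
        """Task-vs-rest counts of significant findings and accuracies."""
        rows = {}
        for st in STATES:
            rep = self.classification[st]
            rows[st] = {
                "significant_edges": self.n_significant_edges(st),
                "significant_metrics": self.n_significant_metrics(st),
                "significant_hamd_correlations": int(self.spearman[st]["significant"].sum()),
                "accuracy_mean": rep.mean_accuracy,
                "accuracy_sd": rep.sd_accuracy,
            }
        return pd.DataFrame(rows).T

    def summary(self) -> str:
        n_psd = int((self.manifest["group"] == "PSD").sum())
        n_non = int((self.manifest["group"] == "nonPSD").sum())
        cfg = self.model.config
        lines = [
            "fNIRS Brain-Network Cohort Analysis",
            "=" * 60,
            f"Subjects: {n_psd} PSD vs {n_non} non-PSD "
            f"({self.features['task'].shape[1]} features/state)",
            f"Sparsity sweep: {cfg.sparsities[0]:.2f}-{cfg.sparsities[-1]:.2f} "
            f"({len(cfg.sparsities)} thresholds), alpha={cfg.alpha}, "
            f"{'FDR' if cfg.fdr else 'uncorrected'}",
            "",
            f"{'state':<8}{'sig.edges':>10}{'sig.metrics':>12}{'sig.HAMD-rho':>13}"
            f"{'accuracy':>20}",
            "-" * 63,
        ]
        for st in STATES:
            rep = self.classification[st]
            lines.append(
                f"{st:<8}{self.n_significant_edges(st):>10d}"
                f"{self.n_significant_metrics(st):>12d}"
                f"{int(self.spearman[st]['significant'].sum()):>13d}"
                f"{100 * rep.mean_accuracy:>13.2f}% ± {100 * rep.sd_accuracy:.2f}%"
            )
        lines += [
            "-" * 63,
            f"CV: {cfg.n_folds}-fold × {cfg.n_repeats} repeats, PCA variance retained "
            f"{cfg.variance_retained:.2f}, {cfg.kernel} SVM with balanced class costs",
        ]
        return "\n".join(lines)

    def plot_connectivity(self, state: str = "task", ax=None):
        """Group-mean Fisher-z connectivity matrices side by side."""
        import matplotlib.pyplot as plt

        psd = self.manifest.index[self.manifest["group"] == "PSD"]
        non = self.manifest.index[self.manifest["group"] == "nonPSD"]
        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(9, 4))
        for a, ids, title in zip(ax, (psd, non), ("PSD", "non-PSD")):
            m = np.mean([self.connectivity[state][i] for i in ids], axis=0)
            im = a.imshow(m, cmap="viridis")
            a.set_title(f"{title} ({state})")
            a.figure.colorbar(im, ax=a, shrink=0.8)
        return ax
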