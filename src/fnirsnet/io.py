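"""File formats, run configuration and the end-to-end pipeline driver.

Subjects round-trip through two containers: a flat CSV (time_s, ch01…ch14
per wavelength for raw intensity, or plain channels for HbO) with a JSON
sidecar for schedule and metadata, and an HDF5 file laid out
SNIRF-compatibly (/nirs/data1 time series, /nirs/stim1 stimulus table,
/nirs/probe optode geometry). Channel indexing is 1-based in every file and
report; µM, seconds and Hz are the units throughout.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .classify import ClassificationReport
from .model import AnalysisConfig, CohortNetworkModel, CohortNetworkResults
from .montage import ChannelMontage, default_montage
from .recording import OpticalRecording
from .synth import ArtifactParams, CohortConfig, NoiseParams, StimulusSchedule, SubjectRecord

# --------------------------------------------------------------------------
# subject CSV (+ JSON sidecar)
# --------------------------------------------------------------------------


def _schedule_to_dict(s: StimulusSchedule) -> dict:
    return {
        "onsets_s": np.asarray(s.onsets_s).tolist(),
        "labels": np.asarray(s.labels).tolist(),
        "stim_duration_s": s.stim_duration_s,
        "rest_end_s": s.rest_end_s,
        "task_end_s": s.task_end_s,
    }


def _schedule_from_dict(d: dict) -> StimulusSchedule:
    return StimulusSchedule(
        onsets_s=np.asarray(d["onsets_s"], dtype=float),
        labels=np.asarray(d["labels"], dtype="U8"),
        stim_duration_s=float(d["stim_duration_s"]),
        rest_end_s=float(d["rest_end_s"]),
        task_end_s=float(d["task_end_s"]),
    )


def write_subject_csv(subject: SubjectRecord, path) -> Path:
    """Flat CSV of the time series plus a ``.json`` sidecar with metadata.

    HbO-stage columns are ``ch01…chNN`` (µM); intensity/OD-stage columns are
    ``ch01_730nm``-style, one per channel per wavelength.
    """
    path = Path(path)
    rec = subject.recording
    t = rec.times_s
    cols = {"time_s": t}
    if rec.stage == "hbo":
        for c in range(rec.n_channels):
            cols[f"ch{c + 1:02d}"] = rec.data[c]
    else:
        for c in range(rec.n_channels):
            for w, wl in enumerate(rec.wavelengths_nm):
                cols[f"ch{c + 1:02d}_{wl:g}nm"] = rec.data[c, w]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")
    meta = {
        "id": subject.id,
        "group": subject.group,
        "hamd": subject.hamd,
        "stage": rec.stage,
        "fs_hz": rec.fs_hz,
        "wavelengths_nm": list(rec.wavelengths_nm) if rec.wavelengths_nm else None,
        "units": {"time": "s", "hbo": "uM", "frequency": "Hz"},
        "schedule": _schedule_to_dict(subject.schedule),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def read_subject_csv(path) -> SubjectRecord:
    path = Path(path)
    side = path.with_suffix(".json")
    if not side.exists():
        raise ValueError(f"CSV subject {path} lacks its JSON sidecar")
    try:
        meta = json.loads(side.read_text())
        df = pd.read_csv(path)
        stage = meta["stage"]
        n_t = len(df)
        ch_cols = [c for c in df.columns if c.startswith("ch")]
        if stage == "hbo":
            data = df[sorted(ch_cols)].to_numpy().T
            wl = None
        else:
            wl = tuple(float(w) for w in meta["wavelengths_nm"])
            n_ch = len({c.split("_")[0] for c in ch_cols})
            data = np.empty((n_ch, len(wl), n_t))
            for c in range(n_ch):
                for w, wnm in enumerate(wl):
                    data[c, w] = df[f"ch{c + 1:02d}_{wnm:g}nm"].to_numpy()
        rec = OpticalRecording(data, stage, fs_hz=float(meta["fs_hz"]), wavelengths_nm=wl,
                               montage=default_montage() if data.shape[0] == 14 else None)
        return SubjectRecord(meta["id"], meta["group"], int(meta["hamd"]), rec,
                             _schedule_from_dict(meta["schedule"]))
    except (KeyError, IndexError, json.JSONDecodeError) as exc:
        raise ValueError(f"malformed CSV subject file {path}: {exc}") from exc


# --------------------------------------------------------------------------
# SNIRF-compatible HDF5
# --------------------------------------------------------------------------


def write_subject_snirf(subject: SubjectRecord, path) -> Path:
    """SNIRF-style HDF5: /nirs/data1 series, /nirs/stim1 schedule, /nirs/probe."""
    path = Path(path)
    rec = subject.recording
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0-fnirsnet")
        nirs = f.create_group("nirs")
        data1 = nirs.create_group("data1")
        if rec.stage == "hbo":
            series = rec.data.T  # (t, measurements)
        else:
            series = rec.data.reshape(rec.n_channels * rec.data.shape[1], -1).T
        data1.create_dataset("dataTimeSeries", data=series)
        data1.create_dataset("time", data=rec.times_s)
        data1.attrs["stage"] = rec.stage
        mont = rec.montage or default_montage()
        for m, (si, di) in enumerate(mont.channels):
            ml = data1.create_group(f"measurementList{m + 1}")
            ml.create_dataset("sourceIndex", data=si + 1)
            ml.create_dataset("detectorIndex", data=di + 1)
        stim = nirs.create_group("stim1")
        sch = subject.schedule
        onsets = np.asarray(sch.onsets_s)
        amp = (np.asarray(sch.labels) == "deviant").astype(float) + 1.0  # 2=deviant, 1=standard
        stim.create_dataset("data", data=np.column_stack([onsets, np.full_like(onsets, sch.stim_duration_s), amp]))
        stim.create_dataset("name", data="oddball")
        stim.attrs["rest_end_s"] = sch.rest_end_s
        stim.attrs["task_end_s"] = sch.task_end_s
        probe = nirs.create_group("probe")
        probe.create_dataset("sourcePos2D", data=mont.sources)
        probe.create_dataset("detectorPos2D", data=mont.detectors)
        if rec.wavelengths_nm:
            probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths_nm))
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=subject.id)
        meta.create_dataset("group", data=subject.group)
        meta.create_dataset("hamd", data=subject.hamd)
        meta.create_dataset("fs_hz", data=rec.fs_hz)
    return path


def read_subject_snirf(path) -> SubjectRecord:
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            nirs = f["nirs"]
            data1 = nirs["data1"]
            series = data1["dataTimeSeries"][()]
            stage = data1.attrs["stage"]
            meta = nirs["metaDataTags"]
            fs = float(meta["fs_hz"][()])
            wl = None
            if "wavelengths" in nirs["probe"]:
                wl = tuple(float(w) for w in nirs["probe"]["wavelengths"][()])
            mont = default_montage()
            if stage == "hbo":
                data = series.T
            else:
                data = series.T.reshape(mont.n_channels, len(wl), -1)
            stim = nirs["stim1"]
            sdata = stim["data"][()]
            labels = np.where(sdata[:, 2] > 1.5, "deviant", "standard").astype("U8")
            sch = StimulusSchedule(
                onsets_s=sdata[:, 0], labels=labels,
                stim_duration_s=float(sdata[0, 1]) if len(sdata) else 0.05,
                rest_end_s=float(stim.attrs["rest_end_s"]),
                task_end_s=float(stim.attrs["task_end_s"]),
            )
            rec = OpticalRecording(data, str(stage), fs_hz=fs, wavelengths_nm=wl, montage=mont)
            sid = meta["SubjectID"][()]
            group = meta["group"][()]
            sid = sid.decode() if isinstance(sid, bytes) else str(sid)
            group = group.decode() if isinstance(group, bytes) else str(group)
            return SubjectRecord(sid, group, int(meta["hamd"][()]), rec, sch)
    except (KeyError, OSError) as exc:
        raise ValueError(f"malformed SNIRF-style file {path}: {exc}") from exc


def write_subject(subject: SubjectRecord, path, format: str = "csv") -> Path:
    if format == "csv":
        return write_subject_csv(subject, path)
    if format in ("hdf5-snirf", "snirf", "h5"):
        return write_subject_snirf(subject, path)
    raise ValueError(f"unknown format {format!r}")


def read_subject(path, format: str | None = None) -> SubjectRecord:
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix == ".csv" else "hdf5-snirf"
    if format == "csv":
        return read_subject_csv(path)
    return read_subject_snirf(path)


# --------------------------------------------------------------------------
# cohort manifest
# --------------------------------------------------------------------------


def write_cohort(subjects: list[SubjectRecord], outdir, format: str = "csv") -> Path:
    """Write per-subject files plus a manifest CSV (id, group, hamd, file)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = ".csv" if format == "csv" else ".h5"
    rows = []
    for s in subjects:
        fname = f"{s.id}{ext}"
        write_subject(s, outdir / fname, format=format)
        rows.append({"id": s.id, "group": s.group, "hamd": s.hamd, "file": fname})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path) -> list[SubjectRecord]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    return [read_subject(manifest_path.parent / row["file"]) for _, row in df.iterrows()]


# --------------------------------------------------------------------------
# analysis-product writers
# --------------------------------------------------------------------------


def write_matrix_csv(z: np.ndarray, path) -> Path:
    """Square connectivity matrix with 1-based channel labels."""
    n = z.shape[0]
    labels = [f"ch{i + 1:02d}" for i in range(n)]
    pd.DataFrame(z, index=labels, columns=labels).to_csv(Path(path), float_format="%.12g")
    return Path(path)


def read_matrix_csv(path) -> np.ndarray:
    return pd.read_csv(Path(path), index_col=0).to_numpy()


def write_edge_tsv(edge_stats: pd.DataFrame, path) -> Path:
    edge_stats.to_csv(Path(path), sep="\t", index=False)
    return Path(path)


def write_metrics_csv(metric_sets, path) -> Path:
    """Long-format metric table: subject, state, metric, channel, threshold, value.

    Nodal metrics carry a 1-based channel label; global metrics use
    ``channel=global``. AUC rows use ``threshold=AUC``.
    """
    from .graphmetrics import GLOBAL_METRICS, NODAL_METRICS

    rows = []
    for ms in metric_sets:
        for thr in ms.thresholds:
            for m in GLOBAL_METRICS:
                rows.append((ms.subject_id, ms.state, m, "global", f"{thr:.2f}",
                             ms.global_curves.loc[thr, m]))
        t_idx = {t: i for i, t in enumerate(ms.thresholds)}
        for m in NODAL_METRICS:
            for thr in ms.thresholds:
                for c in range(ms.nodal_curves[m].shape[1]):
                    rows.append((ms.subject_id, ms.state, m, f"ch{c + 1:02d}", f"{thr:.2f}",
                                 ms.nodal_curves[m][t_idx[thr], c]))
        for m in GLOBAL_METRICS:
            rows.append((ms.subject_id, ms.state, m, "global", "AUC", ms.global_auc[m]))
        for m in NODAL_METRICS:
            for c in range(len(ms.nodal_auc)):
                rows.append((ms.subject_id, ms.state, m, f"ch{c + 1:02d}", "AUC",
                             ms.nodal_auc.loc[c, m]))
    df = pd.DataFrame(rows, columns=["subject", "state", "metric", "channel", "threshold", "value"])
    df.to_csv(Path(path), index=False, float_format="%.12g")
    return Path(path)


def write_classification_json(report: ClassificationReport, path) -> Path:
    Path(path).write_text(json.dumps(report.to_dict(), indent=1))
    return Path(path)


# --------------------------------------------------------------------------
# run configuration and pipeline
# --------------------------------------------------------------------------


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_config_to_yaml(cohort: CohortConfig, analysis: AnalysisConfig, path) -> Path:
    doc = {"cohort": dataclasses.asdict(cohort), "analysis": analysis.to_dict()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
    return Path(path)


def run_config_from_yaml(path) -> tuple[CohortConfig, AnalysisConfig]:
    doc = yaml.safe_load(Path(path).read_text())
    ckw = dict(doc.get("cohort", {}))
    if "noise" in ckw and isinstance(ckw["noise"], dict):
        nkw = dict(ckw["noise"])
        if "background_band_hz" in nkw:
            nkw["background_band_hz"] = tuple(nkw["background_band_hz"])
        ckw["noise"] = NoiseParams(**nkw)
    if "artifacts" in ckw and isinstance(ckw["artifacts"], dict):
        ckw["artifacts"] = ArtifactParams(**ckw["artifacts"])
    akw = dict(doc.get("analysis", {}))
    for key in ("band_hz", "sparsities"):
        if key in akw:
            akw[key] = tuple(akw[key])
    return CohortConfig(**ckw), AnalysisConfig(**akw)


def run_pipeline(
    cohort_config: CohortConfig | None = None,
    analysis_config: AnalysisConfig | None = None,
    outdir="fnirsnet_run",
    subjects: list[SubjectRecord] | None = None,
    write_subjects: bool = False,
) -> CohortNetworkResults:
    """End-to-end run: simulate (or take) a cohort, analyse it, write the bundle.

    Every output file name carries the run's config hash and seed; the full
    configuration is archived beside the outputs.
    """
    cohort_config = cohort_config or CohortConfig()
    analysis_config = analysis_config or AnalysisConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"{config_hash({'c': dataclasses.asdict(cohort_config), 'a': analysis_config.to_dict()})}-seed{cohort_config.seed}"

    if subjects is None:
        from .synth import generate_cohort

        subjects = generate_cohort(cohort_config)
    model = CohortNetworkModel(subjects, config=analysis_config)
    results = model.fit()

    run_config_to_yaml(cohort_config, analysis_config, outdir / f"config-{tag}.yaml")
    if write_subjects:
        write_cohort(subjects, outdir / "subjects")
    results.manifest.to_csv(outdir / f"manifest-{tag}.csv")
    for st in ("rest", "task"):
        mdir = outdir / f"matrices-{st}"
        mdir.mkdir(exist_ok=True)
        for sid, z in results.connectivity[st].items():
            write_matrix_csv(z, mdir / f"{sid}-{tag}.csv")
        write_metrics_csv(results.metric_sets[st], outdir / f"metrics-{st}-{tag}.csv")
        write_edge_tsv(results.edge_stats[st], outdir / f"edges-{st}-{tag}.tsv")
        results.metric_stats[st].to_csv(outdir / f"metricstats-{st}-{tag}.csv", index=False)
        results.spearman[st].to_csv(outdir / f"spearman-{st}-{tag}.csv", index=False)
        write_classification_json(results.classification[st], outdir / f"classification-{st}-{tag}.json")
        results.features[st].to_csv(outdir / f"features-{st}-{tag}.csv")
    contrast = results.state_contrast()
    contrast.to_csv(outdir / f"summary-{tag}.csv")
    (outdir / f"summary-{tag}.txt").write_text(results.summary() + "\n")
    return results
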