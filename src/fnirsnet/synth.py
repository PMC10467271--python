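"""Synthetic oddball-task fNIRS cohorts with known ground truth.

The generator emulates the acquisition this pipeline targets: 14-channel
bilateral DLPFC recordings at 11 Hz, a 20-s rest baseline followed by a
360-s auditory oddball train (25% deviants, 0.05-s stimuli, 1–3 s random
intervals), physiological nuisance components (cardiac, respiratory,
Mayer waves, linear drift), spike/shift motion artifacts, and
group-structured inter-channel covariance with a plantable PSD-vs-non-PSD
effect. Depressed (PSD) subjects carry HAMD scores ≥ 8, non-PSD < 8.

Every function takes an explicit seed or Generator; identical seeds yield
bitwise-identical cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import sosfiltfilt
from scipy.special import gammaln
from scipy.stats import wishart

from .montage import ChannelMontage, N_CHANNELS, default_montage
from .preprocess import DEFAULT_BAND_HZ, _design_bandpass, hemo_to_od
from .recording import DEFAULT_FS_HZ, DEFAULT_WAVELENGTHS_NM, OpticalRecording

# --------------------------------------------------------------------------
# stimulus schedule
# --------------------------------------------------------------------------

TASK_DURATION_S = 360.0
REST_DURATION_S = 20.0
STIM_DURATION_S = 0.05
DEVIANT_FRACTION = 0.25
ISI_RANGE_S = (1.0, 3.0)

HAMD_PSD_RANGE = (8, 25)      # inclusive integer range for the PSD group
HAMD_NONPSD_RANGE = (0, 7)


@dataclass(frozen=True)
class StimulusSchedule:
    """Oddball stimulus train plus rest/task segment boundaries (seconds)."""

    onsets_s: np.ndarray
    labels: np.ndarray            # "deviant" | "standard"
    stim_duration_s: float = STIM_DURATION_S
    rest_end_s: float = REST_DURATION_S
    task_end_s: float = REST_DURATION_S + TASK_DURATION_S

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets_s, dtype=float)
        if onsets.size and not np.all(np.diff(onsets) > 0):
            raise ValueError("onsets must be strictly increasing")
        if onsets.size != len(self.labels):
            raise ValueError("labels and onsets differ in length")
        if onsets.size and (onsets[0] < self.rest_end_s or onsets[-1] + self.stim_duration_s > self.task_end_s):
            raise ValueError("all stimuli must lie inside the task segment")

    @property
    def n_stimuli(self) -> int:
        return len(self.onsets_s)

    @property
    def deviant_fraction(self) -> float:
        return float(np.mean(self.labels == "deviant"))


def generate_stimulus_schedule(
    task_duration_s: float = TASK_DURATION_S,
    rest_duration_s: float = REST_DURATION_S,
    deviant_fraction: float = DEVIANT_FRACTION,
    isi_range_s: tuple[float, float] = ISI_RANGE_S,
    stim_duration_s: float = STIM_DURATION_S,
    seed: int | np.random.Generator = 0,
) -> StimulusSchedule:
    """Pack an oddball train into the task segment.

    Inter-onset gaps are ``stim_duration + U(isi_range)``; exactly
    ``round(deviant_fraction × N)`` stimuli are labelled deviant, with the
    label order shuffled by the seeded RNG.
    """
    if task_duration_s <= 0:
        raise ValueError("task_duration_s must be positive")
    if not 0 <= deviant_fraction <= 1:
        raise ValueError("deviant_fraction must be in [0, 1]")
    if not (0 <= isi_range_s[0] <= isi_range_s[1]):
        raise ValueError("isi_range_s must be well-ordered and nonnegative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rest_end = float(rest_duration_s)
    task_end = rest_end + float(task_duration_s)
    if rest_end + stim_duration_s > task_end:
        raise ValueError("task too short to place a single stimulus")
    onsets = []
    t = rest_end
    while t + stim_duration_s <= task_end:
        onsets.append(t)
        t += stim_duration_s + rng.uniform(*isi_range_s)
    onsets = np.asarray(onsets)
    n = len(onsets)
    n_dev = int(round(deviant_fraction * n))
    labels = np.array(["standard"] * n, dtype=object)
    labels[:n_dev] = "deviant"
    rng.shuffle(labels)
    return StimulusSchedule(
        onsets_s=onsets,
        labels=np.asarray(labels, dtype="U8"),
        stim_duration_s=stim_duration_s,
        rest_end_s=rest_end,
        task_end_s=task_end,
    )


# --------------------------------------------------------------------------
# group covariance structure
# --------------------------------------------------------------------------

BASELINE_HBO_SD_UM = 0.10     # per-channel SD of spontaneous HbO fluctuations, µM
_CORR_FLOOR = 0.15            # long-range correlation floor
_CORR_RANGE = 0.45            # short-range excess over the floor
_CORR_LENGTH_CM = 5.0         # spatial decay length of coupling

# planted PSD effects, stated with the montage's 1-based channel labels:
# task state — coupling between the mid-frontal channel 7 and the lateral
# channels 1, 3, 4, 10, 11, 13, 14 is weakened, and short-range
# within-hemisphere coupling (local clustering) is elevated;
# rest state — coupling 4–6 and 2–5 is elevated in the PSD group.
TASK_EFFECT_EDGES = tuple((6, j) for j in (0, 2, 3, 9, 10, 12, 13))
TASK_EFFECT_DELTA_R = -0.35
TASK_LOCAL_BOOST_R = +0.15    # applied to short-range pairs (< 5 cm) off channel 7
REST_EFFECT_EDGES = ((3, 5), (1, 4))
REST_EFFECT_DELTA_R = +0.25


def _channel_positions(n_channels: int) -> np.ndarray:
    """Planar channel midpoints; falls back to a line for non-default counts."""
    if n_channels == N_CHANNELS:
        mont = default_montage()
        return np.array(
            [(mont.sources[s] + mont.detectors[d]) / 2 for s, d in mont.channels]
        )
    return np.column_stack([3.0 * np.arange(n_channels), np.zeros(n_channels)])


def _base_correlation(n_channels: int = N_CHANNELS) -> np.ndarray:
    """Distance-dependent coupling: correlation decays with channel separation."""
    pos = _channel_positions(n_channels)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    corr = _CORR_FLOOR + _CORR_RANGE * np.exp(-d / _CORR_LENGTH_CM)
    np.fill_diagonal(corr, 1.0)
    return corr


def nearest_psd(mat: np.ndarray, tol: float = 0.0) -> np.ndarray:
    """Project a symmetric matrix onto the positive-semidefinite cone."""
    sym = (mat + mat.T) / 2
    w, v = np.linalg.eigh(sym)
    if w.min() >= -1e-10:
        return sym
    warnings.warn("covariance required projection to the nearest PSD matrix", RuntimeWarning)
    w = np.clip(w, tol, None)
    return (v * w) @ v.T


def generate_group_covariance(
    group: str,
    state: str,
    effect_size: float = 1.0,
    n_channels: int = N_CHANNELS,
    baseline_sd_um: float = BASELINE_HBO_SD_UM,
) -> np.ndarray:
    """Channel × channel HbO covariance for one (group, state) profile.

    At ``effect_size = 0`` all four profiles are identical. For the PSD
    group, ``effect_size > 0`` weakens the task-state coupling between the
    mid-frontal channel (7) and the lateral channels and elevates the
    rest-state 4–6 and 2–5 coupling; the non-PSD profiles are untouched.
    """
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    if group not in ("PSD", "nonPSD"):
        raise ValueError(f"unknown group {group!r}")
    if state not in ("rest", "task"):
        raise ValueError(f"unknown state {state!r}")
    corr = _base_correlation(n_channels)
    if group == "PSD" and effect_size > 0:
        edges = TASK_EFFECT_EDGES if state == "task" else REST_EFFECT_EDGES
        delta = (TASK_EFFECT_DELTA_R if state == "task" else REST_EFFECT_DELTA_R) * effect_size
        for i, j in edges:
            if i < n_channels and j < n_channels:
                r = np.clip(corr[i, j] + delta, -0.95, 0.95)
                corr[i, j] = corr[j, i] = r
        if state == "task":
            # elevated local clustering: boost short-range pairs not touching
            # the weakened mid-frontal channel
            pos = _channel_positions(n_channels)
            d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
            hit = set()
            for i, j in TASK_EFFECT_EDGES:
                hit.add((min(i, j), max(i, j)))
            for i in range(n_channels):
                for j in range(i + 1, n_channels):
                    if (i, j) in hit or 6 in (i, j) or d[i, j] >= _CORR_LENGTH_CM:
                        continue
                    r = np.clip(corr[i, j] + TASK_LOCAL_BOOST_R * effect_size, -0.95, 0.95)
                    corr[i, j] = corr[j, i] = r
    cov = nearest_psd(corr * baseline_sd_um**2)
    return cov


# --------------------------------------------------------------------------
# hemodynamic response
# --------------------------------------------------------------------------

HRF_PEAK_S = 6.0
HRF_UNDERSHOOT_S = 16.0
HRF_UNDERSHOOT_RATIO = 1.0 / 6.0
DEVIANT_AMPLITUDE_UM = 0.15   # peak ΔHbO per deviant stimulus
STANDARD_AMPLITUDE_UM = 0.05


def double_gamma_hrf(
    t: np.ndarray,
    peak_s: float = HRF_PEAK_S,
    undershoot_s: float = HRF_UNDERSHOOT_S,
    undershoot_ratio: float = HRF_UNDERSHOOT_RATIO,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, normalized to unit peak."""
    t = np.asarray(t, dtype=float)
    def g(x, shape):  # gamma pdf with unit rate
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.exp((shape - 1) * np.log(np.where(x > 0, x, 1.0)) - x - gammaln(shape))
        return np.where(x > 0, out, 0.0)
    h = g(t, peak_s + 1) - undershoot_ratio * g(t, undershoot_s + 1)
    peak = h.max()
    return h / peak if peak > 0 else h


def task_regressor(
    schedule: StimulusSchedule,
    fs_hz: float,
    n_samples: int,
    deviant_amplitude_um: float = DEVIANT_AMPLITUDE_UM,
    standard_amplitude_um: float = STANDARD_AMPLITUDE_UM,
    hrf_params: dict | None = None,
) -> np.ndarray:
    """Stimulus impulse train convolved with the canonical HRF (µM)."""
    impulses = np.zeros(n_samples)
    for onset, label in zip(schedule.onsets_s, schedule.labels):
        idx = int(round(onset * fs_hz))
        if idx < n_samples:
            amp = deviant_amplitude_um if label == "deviant" else standard_amplitude_um
            impulses[idx] += amp
    t_hrf = np.arange(0, 32.0, 1.0 / fs_hz)
    h = double_gamma_hrf(t_hrf, **(hrf_params or {}))
    return np.convolve(impulses, h)[:n_samples]


# --------------------------------------------------------------------------
# noise and artifact configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseParams:
    """Physiological nuisance components added on top of the planted signal.

    The cardiac, respiratory and Mayer-wave lines sit partly outside the
    0.01–0.2 Hz analysis band so the band-pass stage is testable. Amplitudes
    are µM; the drift slope is µM over the whole recording. The correlated
    background lives in the spontaneous low-frequency-oscillation band
    (``background_band_hz``); ``trial_jitter`` is the per-trial, per-channel
    relative variability of the evoked-response amplitude (hemodynamic
    responses are not perfectly reproducible across trials or channels, so
    the evoked component is only partially coherent between channels).
    """

    cardiac_hz: float = 1.2
    cardiac_amplitude_um: float = 0.15
    respiration_hz: float = 0.25
    respiration_amplitude_um: float = 0.10
    mayer_hz: float = 0.10
    mayer_amplitude_um: float = 0.05
    drift_amplitude_um: float = 0.20
    channel_gain_jitter: float = 0.2   # uniform ±20% per-channel HRF gain
    trial_jitter: float = 0.5          # uniform ±50% per-trial per-channel amplitude
    background_band_hz: tuple[float, float] = (0.03, 0.2)

    @classmethod
    def none(cls) -> "NoiseParams":
        return cls(
            cardiac_amplitude_um=0.0,
            respiration_amplitude_um=0.0,
            mayer_amplitude_um=0.0,
            drift_amplitude_um=0.0,
            channel_gain_jitter=0.0,
            trial_jitter=0.0,
        )


@dataclass(frozen=True)
class ArtifactParams:
    """Spike/shift motion artifacts injected into the optical-density series.

    Amplitudes are multiples of the channel's clean OD standard deviation;
    10× comfortably trips the 0.5 s / 6×SD detection rule.
    """

    n_spikes: int = 2
    n_shifts: int = 1
    spike_amplitude_sd: float = 10.0
    spike_duration_s: float = 0.4
    shift_amplitude_sd: float = 8.0

    @classmethod
    def none(cls) -> "ArtifactParams":
        return cls(n_spikes=0, n_shifts=0)


@dataclass
class GroundTruth:
    """What the generator actually planted, for closing the loop in tests.

    ``hbo_clean`` is the in-band clean HbO: the artifact-free hemodynamics
    (task signal, correlated background and physiological components)
    restricted to the 0.01–0.2 Hz analysis band. It is the signal a correct
    band-limited pipeline can recover; motion artifacts are never part of it.
    """

    hbo_clean: np.ndarray                       # (ch, t) µM, in-band, artifact-free
    covariances: dict                           # {"rest": Σ, "task": Σ} used for this subject
    hrf_params: dict
    artifact_log: list[tuple[int, float, float, str]]  # (channel, start_s, end_s, kind)
    seed: int | None = None


@dataclass
class SubjectRecord:
    """One synthetic subject: recording, schedule, group and HAMD score."""

    id: str
    group: str                 # "PSD" | "nonPSD"
    hamd: int
    recording: OpticalRecording
    schedule: StimulusSchedule
    ground_truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        if self.group == "PSD" and self.hamd < 8:
            raise ValueError("PSD subjects must have HAMD >= 8")
        if self.group == "nonPSD" and self.hamd >= 8:
            raise ValueError("non-PSD subjects must have HAMD < 8")


def _band_limited_noise(
    cov: dict[str, np.ndarray],
    schedule: StimulusSchedule,
    fs_hz: float,
    n_samples: int,
    rng: np.random.Generator,
    band_hz: tuple[float, float] = (0.03, 0.2),
) -> np.ndarray:
    """Correlated background noise, band-limited to the spontaneous LFO band.

    White multivariate Gaussian samples (rest covariance before
    ``rest_end_s``, task covariance after) are filtered with the same
    zero-phase band-pass used in preprocessing, then rescaled per channel to
    the target SD. Per-channel rescaling leaves the correlation structure
    intact, so the planted inter-channel correlations survive filtering.
    """
    n_ch = cov["rest"].shape[0]
    n_rest = int(round(schedule.rest_end_s * fs_hz))
    white = np.empty((n_ch, n_samples))
    chol = {}
    for state, seg in (("rest", slice(0, n_rest)), ("task", slice(n_rest, n_samples))):
        n_seg = len(range(*seg.indices(n_samples)))
        w, v = np.linalg.eigh(cov[state])
        root = (v * np.sqrt(np.clip(w, 0, None))) @ v.T
        white[:, seg] = root @ rng.standard_normal((n_ch, n_seg))
        chol[state] = root
    if not np.any(np.diag(cov["task"]) > 0):
        return np.zeros((n_ch, n_samples))
    sos = _design_bandpass(*band_hz, fs_hz)
    shaped = sosfiltfilt(sos, white, axis=-1)
    target_sd = np.sqrt(np.diag(cov["task"]))
    got_sd = shaped.std(axis=-1)
    scale = np.where(got_sd > 0, target_sd / np.where(got_sd > 0, got_sd, 1.0), 0.0)
    return shaped * scale[:, None]


def _draw_subject_covariance(
    cov: np.ndarray, df: float | None, rng: np.random.Generator
) -> np.ndarray:
    """Subject-level covariance: Wishart around the group covariance."""
    if df is None or not np.any(np.diag(cov) > 0):
        return cov
    n = cov.shape[0]
    if df < n:
        raise ValueError("subject_variability_df must be >= n_channels")
    w, v = np.linalg.eigh(cov)
    if w.min() <= 1e-12:  # singular group covariance: perturb in its range only
        cov = cov + 1e-10 * np.eye(n)
    return wishart.rvs(df=df, scale=cov / df, random_state=rng)


def generate_subject(
    group: str,
    state_covariances: dict[str, np.ndarray],
    schedule: StimulusSchedule,
    montage: ChannelMontage | None = None,
    noise_params: NoiseParams | None = None,
    artifact_params: ArtifactParams | None = None,
    seed: int | np.random.Generator = 0,
    fs_hz: float = DEFAULT_FS_HZ,
    wavelengths_nm: tuple[float, ...] = DEFAULT_WAVELENGTHS_NM,
    subject_id: str = "S000",
    emit_stage: str = "intensity",
    hbr_ratio: float = -1.0 / 3.0,
    hrf_params: dict | None = None,
    deviant_amplitude_um: float = DEVIANT_AMPLITUDE_UM,
    standard_amplitude_um: float = STANDARD_AMPLITUDE_UM,
) -> SubjectRecord:
    """Forward-model one subject from planted covariance and stimulus train.

    The clean HbO ground truth is the HRF-convolved stimulus regressor
    (deviants evoke larger responses than standards) plus band-limited
    multivariate Gaussian noise with the state covariance. Physiological
    sinusoids and linear drift are added on top, HbR is coupled as
    ``hbr_ratio × HbO``, and the forward modified Beer–Lambert model maps to
    light intensity at 730/808/850 nm with spike/shift artifacts injected in
    OD space. ``emit_stage="hbo"`` skips the optical forward model (used by
    large simulation studies; artifacts require the intensity stage).
    """
    montage = montage or default_montage()
    noise_params = noise_params or NoiseParams()
    artifact_params = artifact_params or ArtifactParams.none()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_ch = montage.n_channels
    for state in ("rest", "task"):
        if state_covariances[state].shape != (n_ch, n_ch):
            raise ValueError(f"{state} covariance does not match the {n_ch}-channel montage")
    n_samples = int(round(schedule.task_end_s * fs_hz))
    if schedule.task_end_s <= schedule.rest_end_s:
        raise ValueError("task_end_s must exceed rest_end_s")

    # planted signal: HRF-convolved stimulus train with per-channel gain and
    # per-trial, per-channel amplitude variability
    gains = 1.0 + noise_params.channel_gain_jitter * rng.uniform(-1, 1, size=n_ch)
    base_amp = np.array(
        [deviant_amplitude_um if lb == "deviant" else standard_amplitude_um for lb in schedule.labels]
    )
    impulses = np.zeros((n_ch, n_samples))
    onset_idx = np.round(np.asarray(schedule.onsets_s) * fs_hz).astype(int)
    keep = onset_idx < n_samples
    trial_amp = base_amp[keep][None, :] * (
        1.0 + noise_params.trial_jitter * rng.uniform(-1, 1, size=(n_ch, int(keep.sum())))
    )
    np.add.at(impulses, (np.arange(n_ch)[:, None], onset_idx[keep][None, :]), trial_amp)
    t_hrf = np.arange(0, 32.0, 1.0 / fs_hz)
    h = double_gamma_hrf(t_hrf, **(hrf_params or {}))
    signal = gains[:, None] * np.apply_along_axis(
        lambda x: np.convolve(x, h)[:n_samples], -1, impulses
    )

    noise = _band_limited_noise(
        state_covariances, schedule, fs_hz, n_samples, rng,
        band_hz=noise_params.background_band_hz,
    )
    hbo_clean = signal + noise

    t = np.arange(n_samples) / fs_hz
    physio = np.zeros((n_ch, n_samples))
    for f_hz, amp in (
        (noise_params.cardiac_hz, noise_params.cardiac_amplitude_um),
        (noise_params.respiration_hz, noise_params.respiration_amplitude_um),
        (noise_params.mayer_hz, noise_params.mayer_amplitude_um),
    ):
        if amp > 0:
            # systemic oscillations: one global phase, small per-channel lag
            phases = rng.uniform(0, 2 * np.pi) + rng.uniform(-0.3, 0.3, size=n_ch)
            physio += amp * np.sin(2 * np.pi * f_hz * t[None, :] + phases[:, None])
    if noise_params.drift_amplitude_um > 0:
        slopes = rng.uniform(-1, 1, size=n_ch) * noise_params.drift_amplitude_um
        physio += slopes[:, None] * (t / t[-1])[None, :]

    hbo_full = hbo_clean + physio
    # in-band clean reference: what an ideal band-limited pipeline recovers
    if n_samples > 30:
        sos = _design_bandpass(*DEFAULT_BAND_HZ, fs_hz)
        hbo_inband = sosfiltfilt(sos, hbo_full, axis=-1)
    else:
        hbo_inband = hbo_full.copy()
    hamd_lo, hamd_hi = HAMD_PSD_RANGE if group == "PSD" else HAMD_NONPSD_RANGE
    hamd = int(rng.integers(hamd_lo, hamd_hi + 1))
    gt = GroundTruth(
        hbo_clean=hbo_inband,
        covariances={k: v.copy() for k, v in state_covariances.items()},
        hrf_params={
            "peak_s": HRF_PEAK_S,
            "undershoot_ratio": HRF_UNDERSHOOT_RATIO,
            "deviant_amplitude_um": deviant_amplitude_um,
            "standard_amplitude_um": standard_amplitude_um,
            **(hrf_params or {}),
        },
        artifact_log=[],
        seed=seed if isinstance(seed, int) else None,
    )

    if emit_stage == "hbo":
        if artifact_params.n_spikes or artifact_params.n_shifts:
            raise ValueError("artifact injection requires emit_stage='intensity'")
        rec = OpticalRecording(hbo_full, "hbo", fs_hz=fs_hz, wavelengths_nm=None,
                               montage=montage, history=["synthetic"])
        return SubjectRecord(subject_id, group, hamd, rec, schedule, gt)

    hbr_full = hbr_ratio * hbo_full
    od = hemo_to_od(hbo_full, hbr_full, wavelengths_nm)

    # inject motion artifacts into the OD series (same perturbation at all λ)
    sd_od = od.std(axis=-1).mean(axis=-1)  # per channel, averaged over λ
    span = schedule.task_end_s
    events = [("spike", artifact_params.spike_duration_s, artifact_params.spike_amplitude_sd)] * artifact_params.n_spikes
    events += [("shift", None, artifact_params.shift_amplitude_sd)] * artifact_params.n_shifts
    for kind, dur, amp_sd in events:
        ch = int(rng.integers(0, n_ch))
        start = float(rng.uniform(1.0, span - 2.0))
        amp = amp_sd * sd_od[ch] * (1 if rng.random() < 0.5 else -1)
        i0 = int(round(start * fs_hz))
        if kind == "spike":
            i1 = min(n_samples, i0 + max(2, int(round(dur * fs_hz))))
            bump = np.hanning(2 * (i1 - i0))[i1 - i0 :]  # sharp rise, smooth decay
            od[ch, :, i0:i1] += amp * bump[None, : i1 - i0]
            gt.artifact_log.append((ch, start, i1 / fs_hz, "spike"))
        else:  # baseline shift persisting to the end of the recording
            od[ch, :, i0:] += amp
            gt.artifact_log.append((ch, start, n_samples / fs_hz, "shift"))

    i0_intensity = rng.uniform(0.5, 2.0, size=(n_ch, od.shape[1], 1))
    intensity = i0_intensity * 10.0 ** (-od)
    rec = OpticalRecording(intensity, "intensity", fs_hz=fs_hz,
                           wavelengths_nm=tuple(wavelengths_nm), montage=montage,
                           history=["synthetic"])
    return SubjectRecord(subject_id, group, hamd, rec, schedule, gt)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the target acquisition: 19 PSD vs 18 non-PSD subjects,
    20-s rest baseline, 360-s oddball task at 11 Hz, and a task-state-only
    planted group effect. ``rest_duration_s`` is exposed because a 20-s
    baseline is statistically thin for 0.01 Hz work; extend it if rest-state
    analyses are the object of study.
    """

    n_psd: int = 19
    n_nonpsd: int = 18
    effect_size_task: float = 1.0
    effect_size_rest: float = 0.0
    task_duration_s: float = TASK_DURATION_S
    rest_duration_s: float = REST_DURATION_S
    fs_hz: float = DEFAULT_FS_HZ
    subject_variability_df: float | None = 150.0
    noise: NoiseParams = field(default_factory=NoiseParams)
    artifacts: ArtifactParams = field(default_factory=ArtifactParams.none)
    emit_stage: str = "intensity"
    seed: int = 0


def generate_cohort(config: CohortConfig | None = None, **overrides) -> list[SubjectRecord]:
    """Generate a full two-group cohort under one set of study conditions."""
    if config is None:
        config = CohortConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    montage = default_montage()
    group_cov = {
        (g, s): generate_group_covariance(
            g, s, effect_size=(config.effect_size_task if s == "task" else config.effect_size_rest)
        )
        for g in ("PSD", "nonPSD")
        for s in ("rest", "task")
    }
    n_total = config.n_psd + config.n_nonpsd
    seeds = np.random.SeedSequence(config.seed).spawn(n_total + 1)
    schedule_rng = np.random.default_rng(seeds[0])
    subjects: list[SubjectRecord] = []
    for k in range(n_total):
        group = "PSD" if k < config.n_psd else "nonPSD"
        rng = np.random.default_rng(seeds[k + 1])
        schedule = generate_stimulus_schedule(
            task_duration_s=config.task_duration_s,
            rest_duration_s=config.rest_duration_s,
            seed=rng,
        )
        covs = {
            s: _draw_subject_covariance(group_cov[(group, s)], config.subject_variability_df, rng)
            for s in ("rest", "task")
        }
        subjects.append(
            generate_subject(
                group,
                covs,
                schedule,
                montage=montage,
                noise_params=config.noise,
                artifact_params=config.artifacts,
                seed=rng,
                fs_hz=config.fs_hz,
                subject_id=f"S{k + 1:03d}",
                emit_stage=config.emit_stage,
            )
        )
    return subjects
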