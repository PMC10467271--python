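"""Raw optical intensity to artifact-corrected, band-limited HbO.

The stages run in a fixed order: intensity → optical density (OD) →
motion-artifact detection and spline correction → 0.01–0.2 Hz zero-phase
band-pass → modified Beer–Lambert inversion to hemoglobin concentration
changes. ``run_preprocessing`` is the driver; every step is also callable
on its own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import butter, sosfiltfilt

from .recording import OpticalRecording

DEFAULT_WINDOW_S = 0.5
DEFAULT_K_SD = 6.0
DEFAULT_BAND_HZ = (0.01, 0.2)
DEFAULT_DPF = 6.0
DEFAULT_PATHLENGTH_CM = 3.0
_FILTER_ORDER = 3


def load_extinction_table() -> pd.DataFrame:
    """Molar extinction coefficients ε(λ) for HbO and HbR, cm⁻¹/(mol/L)."""
    with resources.files("fnirsnet.data").joinpath("extinction_coefficients.csv").open() as fh:
        tab = pd.read_csv(fh, comment="#")
    return tab.astype({"wavelength_nm": float}).set_index("wavelength_nm")


def intensity_to_od(rec: OpticalRecording, baseline: str = "mean") -> OpticalRecording:
    """Convert light intensity to optical density, OD(t) = −log10(I(t)/I₀).

    I₀ is the per-channel, per-wavelength mean intensity over the whole
    recording (``baseline="mean"``) or over the first ``baseline`` seconds
    when a float is given.
    """
    if rec.stage != "intensity":
        raise ValueError(f"expected intensity stage, got {rec.stage}")
    bad = rec.data <= 0
    if bad.any():
        ch, wl, t = (int(v[0]) for v in np.nonzero(bad))
        raise ValueError(f"nonpositive intensity at channel {ch + 1}, wavelength index {wl}, sample {t}")
    if baseline == "mean":
        i0 = rec.data.mean(axis=-1, keepdims=True)
    else:
        n0 = max(1, int(round(float(baseline) * rec.fs_hz)))
        i0 = rec.data[..., :n0].mean(axis=-1, keepdims=True)
    od = -np.log10(rec.data / i0)
    return rec.evolve(od, "od", "intensity_to_od")


def od_to_intensity(rec: OpticalRecording, i0: float | np.ndarray = 1.0) -> np.ndarray:
    """Inverse of the OD transform, I = I₀·10^(−OD); used as a test oracle."""
    return np.asarray(i0) * 10.0 ** (-rec.data)


@dataclass
class ArtifactMask:
    """Boolean flags over consecutive, non-overlapping windows per channel.

    ``flags[ch, w]`` is True when window ``w`` of channel ``ch`` exceeds the
    max−min > k_sd × whole-trial SD criterion in any wavelength.
    """

    flags: np.ndarray          # (n_channels, n_windows) bool
    window_samples: int
    window_s: float = DEFAULT_WINDOW_S
    k_sd: float = DEFAULT_K_SD

    @property
    def n_windows(self) -> int:
        return self.flags.shape[1]

    def sample_mask(self, n_samples: int) -> np.ndarray:
        """Expand window flags to a (n_channels, n_samples) boolean mask."""
        out = np.zeros((self.flags.shape[0], n_samples), dtype=bool)
        for w in range(self.n_windows):
            a = w * self.window_samples
            b = min(n_samples, a + self.window_samples)
            out[:, a:b] |= self.flags[:, [w]]
        return out


def detect_motion_artifacts(
    rec: OpticalRecording, window_s: float = DEFAULT_WINDOW_S, k_sd: float = DEFAULT_K_SD
) -> ArtifactMask:
    """Flag windows whose OD range exceeds ``k_sd`` × the whole-trial SD.

    The recording is tiled into consecutive non-overlapping windows of
    ``round(window_s × fs)`` samples (a trailing partial window is checked
    too). The trial SD is computed per channel per wavelength on the raw OD;
    a window is flagged if any wavelength violates the rule.
    """
    if rec.stage != "od":
        raise ValueError(f"expected od stage, got {rec.stage}")
    win = int(round(window_s * rec.fs_hz))
    if win < 2:
        raise ValueError("window_s × fs must cover at least 2 samples")
    data = rec.data  # (ch, wl, t)
    n_ch, _, n_t = data.shape
    sd = data.std(axis=-1)  # (ch, wl)
    zero_var = sd <= 0
    if zero_var.any():
        warnings.warn(
            f"zero-variance channel/wavelength pairs: {np.argwhere(zero_var).tolist()}; not flagged",
            RuntimeWarning,
        )
    n_win = int(np.ceil(n_t / win))
    flags = np.zeros((n_ch, n_win), dtype=bool)
    for w in range(n_win):
        seg = data[:, :, w * win : (w + 1) * win]
        rng_ = seg.max(axis=-1) - seg.min(axis=-1)  # (ch, wl)
        viol = (rng_ > k_sd * sd) & ~zero_var
        flags[:, w] = viol.any(axis=1)
    return ArtifactMask(flags=flags, window_samples=win, window_s=window_s, k_sd=k_sd)


def correct_motion_artifacts(rec: OpticalRecording, mask: ArtifactMask) -> OpticalRecording:
    """Replace flagged samples by a cubic spline through the clean samples.

    Unflagged samples are untouched bit-for-bit. Flagged stretches touching a
    recording edge are filled by nearest-value extrapolation (logged as a
    warning). A channel flagged in its entirety is an error.
    """
    if rec.stage != "od":
        raise ValueError(f"expected od stage, got {rec.stage}")
    n_t = rec.n_samples
    smask = mask.sample_mask(n_t)
    if smask.shape[0] != rec.n_channels:
        raise ValueError("mask channel count does not match recording")
    if not smask.any():
        return rec.evolve(rec.data.copy(), "od", "correct_motion_artifacts")
    out = rec.data.copy()
    t = np.arange(n_t, dtype=float)
    for ch in range(rec.n_channels):
        bad = smask[ch]
        if not bad.any():
            continue
        good = ~bad
        if not good.any():
            raise ValueError(f"channel {ch + 1} is entirely flagged; cannot interpolate")
        tg = t[good]
        for wl in range(rec.data.shape[1]):
            y = rec.data[ch, wl]
            spline = CubicSpline(tg, y[good], extrapolate=False)
            filled = spline(t[bad])
            # flagged samples beyond the clean support: hold the nearest clean value
            edge = ~np.isfinite(filled)
            if edge.any():
                warnings.warn(
                    f"flagged window at recording edge on channel {ch + 1}; nearest-value extrapolation",
                    RuntimeWarning,
                )
                tb = t[bad][edge]
                filled[edge] = np.where(tb < tg[0], y[good][0], y[good][-1])
            out[ch, wl, bad] = filled
    return rec.evolve(out, "od", "correct_motion_artifacts")


def _design_bandpass(low_hz: float, high_hz: float, fs_hz: float):
    return butter(_FILTER_ORDER, [low_hz, high_hz], btype="bandpass", fs=fs_hz, output="sos")


def bandpass(
    rec: OpticalRecording,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
) -> OpticalRecording:
    """Zero-phase Butterworth band-pass (order 3 per pass, forward-backward).

    The default 0.01–0.2 Hz band removes cardiac, respiratory and
    blood-pressure (Mayer-wave) components while keeping the hemodynamic
    response band.
    """
    if not (0 < low_hz < high_hz < rec.fs_hz / 2):
        raise ValueError("band must satisfy 0 < low < high < fs/2")
    sos = _design_bandpass(low_hz, high_hz, rec.fs_hz)
    # forward-backward filtering needs a few filter lengths of signal
    padlen = 3 * (2 * sos.shape[0] + 1)
    if rec.n_samples <= 3 * padlen:
        raise ValueError(
            f"recording too short for zero-phase filtering ({rec.n_samples} samples); "
            f"use a segment longer than {3 * padlen} samples"
        )
    filtered = sosfiltfilt(sos, rec.data, axis=-1)
    return rec.evolve(filtered, rec.stage, f"bandpass[{low_hz},{high_hz}]")


def _extinction_design(
    wavelengths_nm, dpf, pathlength_cm: float, extinction: pd.DataFrame
) -> np.ndarray:
    """Design matrix E with ΔOD(λ) = E @ (ΔHbO, ΔHbR) for concentrations in µM."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    if len(np.unique(wl)) < len(wl):
        raise ValueError("duplicate wavelengths make the extinction design singular")
    if len(wl) < 2:
        raise ValueError("at least 2 wavelengths are required to separate HbO and HbR")
    missing = [w for w in wl if w not in extinction.index]
    if missing:
        raise ValueError(f"extinction table does not cover wavelengths {missing}")
    dpf = np.broadcast_to(np.asarray(dpf, dtype=float), wl.shape)
    eps = extinction.loc[wl, ["eps_hbo", "eps_hbr"]].to_numpy()  # cm^-1 / M
    # 1e-6 converts molar extinction to per-µM concentrations
    return eps * (pathlength_cm * dpf[:, None]) * 1e-6


def od_to_hemo(
    rec: OpticalRecording,
    dpf: float | np.ndarray = DEFAULT_DPF,
    extinction_table: pd.DataFrame | None = None,
    pathlength_cm: float = DEFAULT_PATHLENGTH_CM,
    return_hbr: bool = False,
):
    """Modified Beer–Lambert inversion: ΔOD(λ) → (ΔHbO, ΔHbR) in µM.

    Solves ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR]·d·DPF(λ) by least
    squares over the available wavelengths (overdetermined with 3).
    Downstream analysis uses ΔHbO only; pass ``return_hbr=True`` to also
    get ΔHbR.
    """
    if rec.stage != "od":
        raise ValueError(f"expected od stage, got {rec.stage}")
    if extinction_table is None:
        extinction_table = load_extinction_table()
    E = _extinction_design(rec.wavelengths_nm, dpf, pathlength_cm, extinction_table)
    pinv = np.linalg.pinv(E)  # (2, n_wl)
    conc = np.einsum("cwt,kw->ckt", rec.data, pinv)  # (ch, 2, t)
    hbo = rec.evolve(conc[:, 0, :], "hbo", "od_to_hemo", wavelengths_nm=None)
    if return_hbr:
        return hbo, conc[:, 1, :]
    return hbo


def hemo_to_od(
    hbo: np.ndarray,
    hbr: np.ndarray,
    wavelengths_nm,
    dpf: float | np.ndarray = DEFAULT_DPF,
    extinction_table: pd.DataFrame | None = None,
    pathlength_cm: float = DEFAULT_PATHLENGTH_CM,
) -> np.ndarray:
    """Forward modified Beer–Lambert model, (ΔHbO, ΔHbR) in µM → ΔOD(λ)."""
    if extinction_table is None:
        extinction_table = load_extinction_table()
    E = _extinction_design(wavelengths_nm, dpf, pathlength_cm, extinction_table)
    conc = np.stack([hbo, hbr], axis=1)  # (ch, 2, t)
    return np.einsum("ckt,wk->cwt", conc, E)


def run_preprocessing(
    rec: OpticalRecording,
    window_s: float = DEFAULT_WINDOW_S,
    k_sd: float = DEFAULT_K_SD,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    dpf: float | np.ndarray = DEFAULT_DPF,
    extinction_table: pd.DataFrame | None = None,
) -> OpticalRecording:
    """Full preprocessing chain, intensity → HbO, in the fixed stage order."""
    od = intensity_to_od(rec)
    mask = detect_motion_artifacts(od, window_s=window_s, k_sd=k_sd)
    od = correct_motion_artifacts(od, mask)
    od = bandpass(od, *band_hz)
    return od_to_hemo(od, dpf=dpf, extinction_table=extinction_table)
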