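"""In-memory container for multichannel optical recordings.

A recording moves through three stages: raw light ``intensity`` (per channel
per wavelength), optical density ``od`` (per channel per wavelength) and
oxygenated-hemoglobin concentration change ``hbo`` (per channel, µM).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import ChannelMontage

DEFAULT_FS_HZ = 11.0
DEFAULT_WAVELENGTHS_NM = (730.0, 808.0, 850.0)

_STAGES = ("intensity", "od", "hbo")


@dataclass
class OpticalRecording:
    """Channels × samples optical time series with acquisition metadata.

    ``data`` has shape ``(n_channels, n_wavelengths, n_samples)`` for the
    ``intensity`` and ``od`` stages and ``(n_channels, n_samples)`` for the
    ``hbo`` stage (µM). ``history`` records the preprocessing steps applied,
    in order.
    """

    data: np.ndarray
    stage: str
    fs_hz: float = DEFAULT_FS_HZ
    wavelengths_nm: tuple[float, ...] | None = DEFAULT_WAVELENGTHS_NM
    montage: ChannelMontage | None = None
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {_STAGES}")
        self.data = np.asarray(self.data, dtype=float)
        if self.stage == "hbo":
            if self.data.ndim != 2:
                raise ValueError("hbo-stage data must be (channels, samples)")
        else:
            if self.data.ndim != 3:
                raise ValueError(f"{self.stage}-stage data must be (channels, wavelengths, samples)")
            if self.wavelengths_nm is None or self.data.shape[1] != len(self.wavelengths_nm):
                raise ValueError("wavelength axis does not match wavelengths_nm")
        if self.stage == "intensity" and not np.all(self.data > 0):
            ch, *_ = np.unravel_index(int(np.argmin(self.data)), self.data.shape)
            raise ValueError(f"intensity must be strictly positive (channel {ch + 1})")
        if self.stage != "intensity" and not np.all(np.isfinite(self.data)):
            raise ValueError(f"{self.stage} data must be finite")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[-1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz

    def evolve(self, data: np.ndarray, stage: str, step: str, **kw) -> "OpticalRecording":
        """Return a new recording at a later stage, appending ``step`` to history."""
        new = replace(self, data=data, stage=stage, history=[*self.history, step], **kw)
        return new
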