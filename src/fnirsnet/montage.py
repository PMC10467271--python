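"""Optode montage covering the left and right dorsolateral prefrontal cortex.

The probe holds 7 light sources and 6 detectors at a 3 cm source-detector
separation, yielding 14 measurement channels: channels 1-8 on the left
DLPFC patch and channels 9-14 on the right patch. Channel numbering in
files and reports is 1-based; in-memory indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_SOURCES = 7
N_DETECTORS = 6
N_CHANNELS = 14
SOURCE_DETECTOR_DISTANCE_CM = 3.0


@dataclass(frozen=True)
class ChannelMontage:
    """Planar optode layout and the ordered source-detector channel pairs.

    Positions are in centimetres in an arbitrary planar frame; only the
    source-detector separation (``distance_cm``) enters the optics.
    """

    sources: np.ndarray            # (n_sources, 2)
    detectors: np.ndarray          # (n_detectors, 2)
    channels: tuple[tuple[int, int], ...]  # (source_idx, detector_idx), 0-based
    distance_cm: float = SOURCE_DETECTOR_DISTANCE_CM

    def __post_init__(self) -> None:
        if self.sources.shape != (N_SOURCES, 2):
            raise ValueError(f"expected {N_SOURCES} sources, got {self.sources.shape}")
        if self.detectors.shape != (N_DETECTORS, 2):
            raise ValueError(f"expected {N_DETECTORS} detectors, got {self.detectors.shape}")
        if len(self.channels) != N_CHANNELS:
            raise ValueError(f"expected {N_CHANNELS} channels, got {len(self.channels)}")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_labels(self) -> list[str]:
        """1-based channel labels used in every file and report."""
        return [f"ch{i + 1:02d}" for i in range(self.n_channels)]


def default_montage() -> ChannelMontage:
    """The 7-source / 6-detector bilateral DLPFC montage.

    Left patch (4 sources, 3 detectors) provides channels 1-8; the mirrored
    right patch (3 sources, 3 detectors) provides channels 9-14. Every pair
    listed is separated by exactly 3 cm in the planar layout.
    """
    sources = np.array(
        [
            [0.0, 0.0],   # S1 left
            [6.0, 0.0],   # S2
            [3.0, 3.0],   # S3
            [0.0, 6.0],   # S4
            [15.0, 0.0],  # S5 right
            [12.0, 3.0],  # S6
            [18.0, 3.0],  # S7
        ]
    )
    detectors = np.array(
        [
            [3.0, 0.0],   # D1 left
            [0.0, 3.0],   # D2
            [6.0, 3.0],   # D3
            [12.0, 0.0],  # D4 right
            [18.0, 0.0],  # D5
            [15.0, 3.0],  # D6
        ]
    )
    channels = (
        # left DLPFC, channels 1-8
        (0, 0), (0, 1), (1, 0), (1, 2), (2, 0), (2, 1), (2, 2), (3, 1),
        # right DLPFC, channels 9-14
        (4, 3), (4, 4), (5, 3), (5, 5), (6, 4), (6, 5),
    )
    return ChannelMontage(sources=sources, detectors=detectors, channels=channels)


LEFT_CHANNELS = tuple(range(0, 8))
RIGHT_CHANNELS = tuple(range(8, 14))
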