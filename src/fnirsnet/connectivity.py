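"""Per-subject, per-state functional connectivity and binarized networks.

Connectivity is the Fisher-z-transformed Pearson correlation between the
HbO series of every channel pair, computed separately for the rest baseline
and the task segment. Weighted matrices are binarized over a sparsity sweep
(fraction of strongest positive edges retained) from 0.15 to 0.50 in steps
of 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .recording import OpticalRecording
from .synth import StimulusSchedule

FISHER_CLIP = 1.0 - 1e-7
SPARSITY_GRID = tuple(float(s) for s in np.round(np.arange(0.15, 0.501, 0.05), 2))


@dataclass
class ConnectivityMatrix:
    """Symmetric channel × channel Fisher-z matrix; the diagonal is zero."""

    z: np.ndarray
    state: str = "task"
    subject_id: str | None = None

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("z must be square")
        if not np.allclose(z, z.T):
            raise ValueError("z must be symmetric")
        if not np.all(np.isfinite(z)):
            raise ValueError("z must be finite")
        self.z = z

    @property
    def n_channels(self) -> int:
        return self.z.shape[0]


@dataclass
class BinaryNetwork:
    """Undirected binary network retained at one sparsity threshold."""

    adjacency: np.ndarray
    sparsity: float

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValueError("adjacency diagonal must be zero")
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def segment_states(
    rec: OpticalRecording, schedule: StimulusSchedule
) -> tuple[np.ndarray, np.ndarray]:
    """Split an HbO recording into (rest, task) sample blocks.

    Rest covers [0, rest_end_s), task covers [rest_end_s, task_end_s); the
    sample counts are floor(duration × fs).
    """
    if rec.stage != "hbo":
        raise ValueError(f"expected hbo stage, got {rec.stage}")
    n_rest = int(schedule.rest_end_s * rec.fs_hz)
    n_task_end = int(schedule.task_end_s * rec.fs_hz)
    if n_task_end > rec.n_samples:
        raise ValueError(
            f"schedule task_end ({schedule.task_end_s} s) exceeds the recording "
            f"({rec.duration_s:.2f} s)"
        )
    if n_rest < 1 or n_task_end - n_rest < 1:
        raise ValueError("empty rest or task segment")
    return rec.data[:, :n_rest], rec.data[:, n_rest:n_task_end]


def pearson_fisher(
    segment: np.ndarray, state: str = "task", subject_id: str | None = None
) -> ConnectivityMatrix:
    """Pearson correlation between all channel pairs, Fisher-z transformed.

    r is clipped to ±(1 − 1e−7) before atanh so perfectly correlated
    channels stay finite; the diagonal is set to zero.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 2 or segment.shape[1] < 3:
        raise ValueError("segment must be (channels, samples) with >= 3 samples")
    sd = segment.std(axis=1)
    if np.any(sd == 0):
        ch = int(np.argmin(sd))
        raise ValueError(f"zero-variance channel {ch + 1}; correlation undefined")
    r = np.corrcoef(segment)
    z = np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP))
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2
    return ConnectivityMatrix(z=z, state=state, subject_id=subject_id)


def binarize_by_sparsity(cm: ConnectivityMatrix | np.ndarray, sparsity: float) -> BinaryNetwork:
    """Keep the K = floor(sparsity × N(N−1)/2) strongest positive edges.

    Negative weights are zeroed first (only positive connectivity is
    analysed). If fewer than K positive weights exist, all of them become
    edges and a warning is logged. Ties among equal weights are broken by
    ascending channel-pair lexicographic order, deterministically.
    """
    if not 0 < sparsity < 1:
        raise ValueError("sparsity must be in (0, 1)")
    z = cm.z if isinstance(cm, ConnectivityMatrix) else np.asarray(cm, dtype=float)
    n = z.shape[0]
    k_target = int(sparsity * n * (n - 1) / 2)
    iu, ju = np.triu_indices(n, k=1)
    w = z[iu, ju].copy()
    w[w < 0] = 0.0
    positive = w > 0
    # sort by (-weight, i, j): equal weights resolve in pair order
    order = np.lexsort((ju, iu, -w))
    order = order[positive[order]]
    if len(order) < k_target:
        warnings.warn(
            f"only {len(order)} positive weights for {k_target} requested edges",
            RuntimeWarning,
        )
    keep = order[:k_target]
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[keep], ju[keep]] = True
    adj |= adj.T
    return BinaryNetwork(adjacency=adj, sparsity=float(sparsity))


def threshold_sweep(
    cm: ConnectivityMatrix | np.ndarray, sparsities=SPARSITY_GRID
) -> list[BinaryNetwork]:
    """Binarize over the sparsity grid (default 0.15 … 0.50, step 0.05)."""
    return [binarize_by_sparsity(cm, s) for s in sparsities]
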