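"""Core data containers shared across the analysis stages.

The pipeline moves through four in-memory representations: spike times with
region labels (:class:`SpikeData`), binned spike counts
(:class:`SpikeCountMatrix`), pairwise Pearson correlations
(:class:`CorrelationMatrix`), and the rectified, shuffle-thresholded
functional graph (:class:`FunctionalGraph`) that ensemble detection operates
on.  Partitions of the unit set live in :mod:`spikenets.partitions`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConfigError(ValueError):
    """A configuration value or input contract was violated."""


@dataclass
class SpikeData:
    """Per-unit spike times with anatomical region labels.

    Parameters
    ----------
    unit_ids : array-like
        One identifier per unit.
    spike_times : list of array-like
        Sorted spike times in seconds, one array per unit.
    region_labels : array-like
        One region label per unit.
    window : tuple of float
        ``(t_start, t_end)`` recording window in seconds; all spike times must
        fall inside it.
    """

    unit_ids: np.ndarray
    spike_times: list
    region_labels: np.ndarray
    window: tuple

    def __post_init__(self):
        self.unit_ids = np.asarray(self.unit_ids)
        self.region_labels = np.asarray(self.region_labels)
        if not (len(self.unit_ids) == len(self.spike_times) == len(self.region_labels)):
            raise ConfigError(
                "unit_ids, spike_times and region_labels must have equal length"
            )
        if len(np.unique(self.unit_ids)) != len(self.unit_ids):
            raise ConfigError("unit_ids must be unique")
        t0, t1 = float(self.window[0]), float(self.window[1])
        if not t1 > t0:
            raise ConfigError(f"empty or inverted recording window: {self.window!r}")
        self.window = (t0, t1)
        times = []
        for ts in self.spike_times:
            ts = np.asarray(ts, dtype=float)
            if ts.ndim != 1:
                raise ConfigError("each unit's spike times must be one-dimensional")
            if ts.size:
                if np.any(np.diff(ts) < 0):
                    raise ConfigError("spike times must be sorted")
                if ts[0] < t0 or ts[-1] > t1:
                    raise ConfigError("spike times fall outside the recording window")
            times.append(ts)
        self.spike_times = times

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def duration(self) -> float:
        return self.window[1] - self.window[0]

    @property
    def regions(self) -> np.ndarray:
        """Distinct region labels in order of first appearance."""
        _, idx = np.unique(self.region_labels, return_index=True)
        return self.region_labels[np.sort(idx)]

    def select(self, indices) -> "SpikeData":
        """Return a new :class:`SpikeData` restricted to ``indices`` (in order)."""
        indices = np.asarray(indices, dtype=int)
        return SpikeData(
            self.unit_ids[indices],
            [self.spike_times[i] for i in indices],
            self.region_labels[indices],
            self.window,
        )

    def total_spikes(self) -> int:
        return int(sum(len(ts) for ts in self.spike_times))


@dataclass
class SpikeCountMatrix:
    """Units x bins spike counts at one bin width.

    Bins tile ``[t_start, t_start + n_bins * bin_width)`` with half-open
    intervals ``[edge, edge + bin_width)``; a trailing partial bin is never
    included.
    """

    counts: np.ndarray
    bin_width: float
    t_start: float
    unit_ids: np.ndarray
    region_labels: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ConfigError("counts must be a 2-D units x bins array")
        if np.any(self.counts < 0):
            raise ConfigError("spike counts must be non-negative")
        if self.bin_width <= 0:
            raise ConfigError("bin_width must be positive")
        self.unit_ids = np.asarray(self.unit_ids)
        self.region_labels = np.asarray(self.region_labels)
        if len(self.unit_ids) != self.counts.shape[0]:
            raise ConfigError("unit_ids length must match the number of rows")
        if len(self.region_labels) != self.counts.shape[0]:
            raise ConfigError("region_labels length must match the number of rows")

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def span(self) -> float:
        """Length of the tiled interval in seconds."""
        return self.n_bins * self.bin_width

    @property
    def bin_edges(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_bins + 1) * self.bin_width


@dataclass
class CorrelationMatrix:
    """Symmetric pairwise Pearson correlation matrix with a validity mask.

    Entries for pairs where either count series has zero variance are
    undefined: ``values`` holds NaN there and ``valid`` is False.
    """

    values: np.ndarray
    valid: np.ndarray
    bin_width: float
    unit_ids: np.ndarray
    region_labels: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or self.valid.shape != (n, n):
            raise ConfigError("values and valid must be square and equally shaped")
        defined = self.values[self.valid]
        if defined.size and (np.nanmax(np.abs(defined)) > 1 + 1e-9):
            raise ConfigError("correlation values must lie in [-1, 1]")
        self.unit_ids = np.asarray(self.unit_ids)
        self.region_labels = np.asarray(self.region_labels)
        if len(self.unit_ids) != n or len(self.region_labels) != n:
            raise ConfigError("metadata length must match the matrix size")

    @property
    def n_units(self) -> int:
        return self.values.shape[0]


@dataclass
class FunctionalGraph:
    """Non-negative, symmetric, zero-diagonal weighted graph over units.

    This is the adjacency matrix W that ensemble detection compares against a
    weighted configuration-model null.  ``meta`` records provenance (bin width,
    edge transform mode, shuffle parameters, seeds).
    """

    weights: np.ndarray
    node_ids: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.weights.shape[0]
        if self.weights.ndim != 2 or self.weights.shape != (n, n):
            raise ConfigError("weights must be a square matrix")
        if not np.allclose(self.weights, self.weights.T, atol=1e-10):
            raise ConfigError("weights must be symmetric")
        if np.any(self.weights < 0):
            raise ConfigError("weights must be non-negative")
        if np.any(np.diag(self.weights) != 0):
            raise ConfigError("self-loops are not allowed (diagonal must be zero)")
        self.node_ids = np.asarray(self.node_ids)
        if len(self.node_ids) != n:
            raise ConfigError("node_ids length must match the matrix size")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def strengths(self) -> np.ndarray:
        """Node strengths s_i = sum_j W_ij."""
        return self.weights.sum(axis=1)

    @property
    def total_weight(self) -> float:
        """Total edge weight m = (1/2) sum_ij W_ij."""
        return float(self.weights.sum()) / 2.0

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    @property
    def density(self) -> float:
        n = self.n_nodes
        if n < 2:
            return 0.0
        return self.n_edges / (n * (n - 1) / 2)
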