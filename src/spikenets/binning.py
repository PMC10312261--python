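"""Spike-time binning, balanced per-region subsampling, and firing rates.

Binning tiles the recording window with half-open bins ``[edge, edge+width)``
anchored at the window start; a trailing partial bin is dropped so that spike
counts are conserved and re-binning at an integer multiple of the width equals
summing adjacent bins.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import ConfigError, SpikeCountMatrix, SpikeData

# Bin widths studied by the analysis; widths outside this range work but warn.
TYPICAL_BIN_RANGE = (0.01, 3.0)


def bin_spikes(spikes: SpikeData, bin_width: float) -> SpikeCountMatrix:
    """Count spikes per unit in half-open bins of ``bin_width`` seconds.

    Bins tile ``[t_start, t_start + floor(L / bin_width) * bin_width)``; any
    spikes in the trailing partial interval are not counted.
    """
    t0, t1 = spikes.window
    length = t1 - t0
    if bin_width <= 0:
        raise ConfigError("bin_width must be positive")
    if bin_width > length:
        raise ConfigError(
            f"bin_width {bin_width} s exceeds the window length {length} s"
        )
    if not TYPICAL_BIN_RANGE[0] <= bin_width <= TYPICAL_BIN_RANGE[1]:
        warnings.warn(
            f"bin_width {bin_width} s is outside the analysed range "
            f"{TYPICAL_BIN_RANGE}",
            stacklevel=2,
        )
    n_bins = int(np.floor(length / bin_width + 1e-9))
    edges = t0 + np.arange(n_bins + 1) * bin_width
    counts = np.zeros((spikes.n_units, n_bins), dtype=np.int64)
    for i, ts in enumerate(spikes.spike_times):
        if ts.size == 0:
            continue
        idx = np.searchsorted(edges, ts, side="right") - 1
        idx = idx[(idx >= 0) & (idx < n_bins)]
        counts[i] = np.bincount(idx, minlength=n_bins)
    return SpikeCountMatrix(
        counts, float(bin_width), t0, spikes.unit_ids, spikes.region_labels
    )


def _balanced_quotas(region_counts: list[int], target_total: int) -> list[int]:
    """Round-robin water-filling: one unit per region per turn, in region
    order, until the target is reached or every region is exhausted."""
    quotas = [0] * len(region_counts)
    remaining = target_total
    while remaining > 0 and any(q < c for q, c in zip(quotas, region_counts)):
        for r, cap in enumerate(region_counts):
            if remaining == 0:
                break
            if quotas[r] < cap:
                quotas[r] += 1
                remaining -= 1
    return quotas


def subsample_balanced(
    spikes: SpikeData, target_total: int, seed: int = 0
) -> SpikeData:
    """Randomly subsample ~``target_total`` units, balanced across regions.

    Each region contributes its round-robin quota (capped at the region's
    size, with the shortfall spread over the remaining regions), sampled
    without replacement.  The returned unit order groups units by region, in
    order of first appearance in the input.  If ``target_total`` is at least
    the number of units, all units are kept (grouped by region).
    """
    if target_total <= 0:
        raise ConfigError("target_total must be positive")
    regions = spikes.regions
    region_indices = [np.flatnonzero(spikes.region_labels == r) for r in regions]
    counts = [len(idx) for idx in region_indices]
    if target_total >= spikes.n_units:
        quotas = counts
    else:
        quotas = _balanced_quotas(counts, target_total)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chosen = []
    for idx, quota in zip(region_indices, quotas):
        pick = rng.choice(idx, size=quota, replace=False)
        chosen.append(np.sort(pick))
    return spikes.select(np.concatenate(chosen))


def firing_rates(counts: SpikeCountMatrix) -> np.ndarray:
    """Per-unit mean firing rate in Hz over the binned span."""
    if counts.n_bins == 0:
        raise ConfigError("cannot compute rates from an empty count matrix")
    return counts.counts.sum(axis=1) / counts.span
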