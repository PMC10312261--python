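"""Shuffle-percentile thresholding and rectification of correlation matrices.

Chance correlations are estimated per pair by permuting each unit's count
series independently many times; observed correlations inside the shuffled
5th-95th percentile band are set to zero, and the result is transformed to a
non-negative graph (default: negative weights rectified to zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import ConfigError, CorrelationMatrix, FunctionalGraph, SpikeCountMatrix

EDGE_MODES = ("positive", "absolute", "negative_only")


@dataclass
class ShuffleBounds:
    """Per-pair percentile bounds of the shuffled correlation distribution."""

    lo: np.ndarray
    hi: np.ndarray
    valid: np.ndarray
    n_shuffles: int
    percentiles: tuple
    seed: int


def shuffle_thresholds(
    counts: SpikeCountMatrix,
    n_shuffles: int = 100,
    seed: int = 0,
    percentiles: tuple = (5.0, 95.0),
) -> ShuffleBounds:
    """Empirical percentile bounds of pairwise r under time-bin shuffling.

    Each unit's count series is fully permuted, independently per unit and per
    shuffle, destroying all temporal alignment while preserving the marginal
    count distributions.  Pairs involving a zero-variance series are masked.
    """
    if n_shuffles < 20:
        raise ConfigError("need at least 20 shuffles for stable percentiles")
    if counts.n_bins < 2:
        raise ConfigError("need at least 2 bins to correlate")
    x = counts.counts.astype(float)
    xc = x - x.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", xc, xc)
    ok = ss > 0
    denom = np.sqrt(np.outer(ss, ss))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = counts.n_units
    stack = np.empty((n_shuffles, n, n))
    with np.errstate(invalid="ignore", divide="ignore"):
        for s in range(n_shuffles):
            xp = rng.permuted(xc, axis=1)
            stack[s] = (xp @ xp.T) / denom
    np.clip(stack, -1.0, 1.0, out=stack)
    lo, hi = np.percentile(stack, percentiles, axis=0)
    valid = np.outer(ok, ok)
    lo[~valid] = np.nan
    hi[~valid] = np.nan
    np.fill_diagonal(valid, False)
    return ShuffleBounds(lo, hi, valid, n_shuffles, tuple(percentiles), seed)


def apply_threshold_and_rectify(
    corr: CorrelationMatrix, bounds: ShuffleBounds, mode: str = "positive"
) -> FunctionalGraph:
    """Zero chance-level correlations, then transform to non-negative weights.

    Entries inside ``[lo, hi]`` are set to zero (chance level).  The surviving
    entries are then transformed according to ``mode``:

    - ``positive`` (default): negative entries set to zero;
    - ``absolute``: absolute value;
    - ``negative_only``: positive entries set to zero, then absolute value.
    """
    if mode not in EDGE_MODES:
        raise ConfigError(f"unknown edge mode {mode!r}; choose from {EDGE_MODES}")
    if bounds.lo.shape != corr.values.shape:
        raise ConfigError("shuffle bounds do not match the correlation matrix")
    r = np.where(corr.valid & bounds.valid, corr.values, 0.0)
    with np.errstate(invalid="ignore"):
        chance = (corr.values >= bounds.lo) & (corr.values <= bounds.hi)
    r[chance & bounds.valid] = 0.0
    if mode == "positive":
        w = np.maximum(r, 0.0)
    elif mode == "absolute":
        w = np.abs(r)
    else:  # negative_only
        w = np.abs(np.minimum(r, 0.0))
    np.fill_diagonal(w, 0.0)
    w = (w + w.T) / 2.0
    meta = {
        "bin_width_s": corr.bin_width,
        "mode": mode,
        "n_shuffles": bounds.n_shuffles,
        "percentiles": bounds.percentiles,
        "shuffle_seed": bounds.seed,
    }
    return FunctionalGraph(w, corr.unit_ids, meta=meta)
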