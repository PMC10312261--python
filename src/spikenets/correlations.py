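"""Pairwise spike-count correlations and their timescale statistics.

For each counting-bin width, the pairwise Pearson correlation matrix is split
into within-region and between-region pair values and the difference between
the two distributions is quantified with the Jensen-Shannon divergence (JSD)
on a fixed histogram grid over [-1, 1].  The JSD is also computed conditioned
on the pair's geometric mean firing rate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import entropy

from .datatypes import ConfigError, CorrelationMatrix, SpikeCountMatrix
from .partitions import Partition

# Shared histogram grid for all JSD estimates: 100 equal bins over [-1, 1].
JSD_N_BINS = 100
JSD_RANGE = (-1.0, 1.0)


def pearson_matrix(counts: SpikeCountMatrix) -> CorrelationMatrix:
    """Pearson correlation of binned spike counts for every unit pair.

    Pairs where either count series has zero variance are masked invalid
    (NaN) rather than set to zero, so they never enter downstream histograms
    or graphs.
    """
    if counts.n_bins < 2:
        raise ConfigError("need at least 2 bins to correlate")
    x = counts.counts.astype(float)
    xc = x - x.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", xc, xc)
    ok = ss > 0
    denom = np.sqrt(np.outer(ss, ss))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ xc.T) / denom
    r = (r + r.T) / 2.0
    r = np.clip(r, -1.0, 1.0)
    valid = np.outer(ok, ok)
    r[~valid] = np.nan
    np.fill_diagonal(r, np.where(ok, 1.0, np.nan))
    np.fill_diagonal(valid, ok)
    return CorrelationMatrix(
        r, valid, counts.bin_width, counts.unit_ids, counts.region_labels
    )


def split_within_between(
    corr: CorrelationMatrix, regions
) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle correlation values split by anatomical relationship.

    ``regions`` may be a :class:`Partition` over the correlation matrix's
    units or a label array aligned with them.  Masked (invalid) pairs are
    dropped.  Returns ``(within_values, between_values)``.
    """
    if isinstance(regions, Partition):
        labels = regions.restrict(corr.unit_ids).labels
    else:
        labels = np.asarray(regions)
        if len(labels) != corr.n_units:
            raise ConfigError("region labels do not match the correlation matrix")
    iu = np.triu_indices(corr.n_units, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    ok = corr.valid[iu]
    vals = corr.values[iu]
    return vals[same & ok], vals[~same & ok]


def _histogram_probs(sample: np.ndarray, n_bins: int, value_range) -> np.ndarray:
    sample = np.clip(np.asarray(sample, dtype=float), *value_range)
    hist, _ = np.histogram(sample, bins=n_bins, range=value_range)
    return hist / hist.sum()


def js_divergence(
    sample_a,
    sample_b,
    n_bins: int = JSD_N_BINS,
    value_range: tuple = JSD_RANGE,
) -> float:
    """Jensen-Shannon divergence between two samples, in bits.

    Both samples are histogrammed on the same fixed grid; the divergence is
    ``H(M) - (H(P) + H(Q))/2`` with ``M`` the equal mixture, using log base 2,
    so the result lies in [0, 1] bits and is symmetric in its arguments.
    """
    sample_a = np.asarray(sample_a, dtype=float)
    sample_b = np.asarray(sample_b, dtype=float)
    if sample_a.size == 0 or sample_b.size == 0:
        raise ConfigError("JSD requires two non-empty samples")
    p = _histogram_probs(sample_a, n_bins, value_range)
    q = _histogram_probs(sample_b, n_bins, value_range)
    m = (p + q) / 2.0
    jsd = entropy(m, base=2) - (entropy(p, base=2) + entropy(q, base=2)) / 2.0
    return float(min(max(jsd, 0.0), 1.0))


def pair_statistics(
    corr: CorrelationMatrix, rates: np.ndarray
) -> pd.DataFrame:
    """Per-pair records: unit ids, same-region flag, r, geometric mean rate."""
    rates = np.asarray(rates, dtype=float)
    if len(rates) != corr.n_units:
        raise ConfigError("rates length must match the correlation matrix")
    iu = np.triu_indices(corr.n_units, k=1)
    ok = corr.valid[iu]
    same = (corr.region_labels[iu[0]] == corr.region_labels[iu[1]])
    geo = np.sqrt(rates[iu[0]] * rates[iu[1]])
    return pd.DataFrame(
        {
            "unit_a": corr.unit_ids[iu[0]][ok],
            "unit_b": corr.unit_ids[iu[1]][ok],
            "same_region": same[ok],
            "r": corr.values[iu][ok],
            "geometric_rate_hz": geo[ok],
        }
    )


def default_rate_bins() -> np.ndarray:
    """Logarithmic rate-bin edges: 4 bins per decade over 0.1-100 Hz."""
    return np.logspace(-1, 2, 13)


def js_by_rate_bin(
    pairs: pd.DataFrame,
    rate_bin_edges=None,
    min_pairs: int = 20,
) -> pd.DataFrame:
    """JSD between within- and between-region correlations per rate bin.

    Rate bins with fewer than ``min_pairs`` pairs in either group are
    reported with NaN divergence (undefined, not zero).
    """
    edges = default_rate_bins() if rate_bin_edges is None else np.asarray(rate_bin_edges)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (pairs["geometric_rate_hz"] >= lo) & (pairs["geometric_rate_hz"] < hi)
        within = pairs.loc[sel & pairs["same_region"], "r"].to_numpy()
        between = pairs.loc[sel & ~pairs["same_region"], "r"].to_numpy()
        if len(within) >= min_pairs and len(between) >= min_pairs:
            jsd = js_divergence(within, between)
        else:
            jsd = float("nan")
        rows.append(
            {
                "rate_lo_hz": lo,
                "rate_hi_hz": hi,
                "jsd_bits": jsd,
                "n_within": len(within),
                "n_between": len(between),
            }
        )
    return pd.DataFrame(rows)


def sweep_summary(corr_by_width: dict, regions) -> pd.DataFrame:
    """Mean within/between correlation and JSD per bin width.

    ``corr_by_width`` maps bin width (s) to a :class:`CorrelationMatrix`.
    """
    if len(corr_by_width) < 2:
        raise ConfigError("a sweep needs at least 2 bin widths")
    rows = []
    for width in sorted(corr_by_width):
        within, between = split_within_between(corr_by_width[width], regions)
        rows.append(
            {
                "bin_width_s": width,
                "mean_within": float(within.mean()) if within.size else float("nan"),
                "mean_between": float(between.mean()) if between.size else float("nan"),
                "jsd_bits": js_divergence(within, between)
                if within.size and between.size
                else float("nan"),
                "n_within": len(within),
                "n_between": len(between),
            }
        )
    return pd.DataFrame(rows)
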