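"""Synthetic multi-region spike recordings and planted-partition graphs.

The spike generator is a log-Gaussian Cox model designed to emulate the
correlation structure of large multi-region recordings: each region owns a
private *fast* latent (an Ornstein-Uhlenbeck process with a sub-second
correlation time) and all units share one *slow* global latent (correlation
time of seconds).  Each unit fires as an inhomogeneous Poisson process whose
intensity is its baseline rate modulated exponentially by the latents, with
the log-normal bias removed so the mean intensity equals the baseline.  At
sub-second counting bins the region-private latent dominates the shared count
variance, producing within-region correlations that exceed between-region
ones; at multi-second bins the fast latent averages out and the global slow
latent dominates, making within- and between-region correlations similar.

The planted-graph generator produces weighted stochastic-block-model graphs
with exponential edge weights, used as ground truth for ensemble detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .datatypes import ConfigError, FunctionalGraph, SpikeData
from .partitions import Partition


@dataclass
class SynthConfig:
    """Configuration for the multi-region spike generator.

    Parameters
    ----------
    n_regions, neurons_per_region : int
        Layout of the simulated recording (default 9 regions, 20 units each).
    duration : float
        Recording length in seconds.
    rate_median, rate_sigma : float
        Log-normal baseline firing-rate law: median in Hz and the standard
        deviation of the natural log.  Defaults (3 Hz, 1.0) put the bulk of
        rates between roughly 1 and 10 Hz.
    rate_clip : tuple
        Baseline rates are clipped to this range in Hz.
    tau_fast, tau_slow : float
        Correlation times (seconds) of the region-private and global latents.
    fast_coupling, slow_coupling : float
        Mean per-neuron gains onto the region latent and the global latent
        (log-intensity units per latent standard deviation).
    coupling_cv : float
        Coefficient of variation of per-neuron gain heterogeneity (gamma
        distributed, mean 1); 0 gives identical gains for every neuron.
    dt_sim : float
        Simulation step in seconds; must satisfy ``dt_sim <= tau_fast / 5``.
    seed : int
        Master seed; fixed seed gives bit-identical spike times.
    """

    n_regions: int = 9
    neurons_per_region: int = 20
    duration: float = 600.0
    rate_median: float = 3.0
    rate_sigma: float = 1.0
    rate_clip: tuple = (0.2, 50.0)
    tau_fast: float = 0.05
    tau_slow: float = 2.0
    fast_coupling: float = 1.3
    slow_coupling: float = 0.6
    coupling_cv: float = 0.35
    dt_sim: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.n_regions < 1 or self.neurons_per_region < 1:
            raise ConfigError("n_regions and neurons_per_region must be >= 1")
        for name in ("duration", "rate_median", "rate_sigma", "tau_fast",
                     "tau_slow", "dt_sim"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if self.rate_clip[0] <= 0 or self.rate_clip[1] <= self.rate_clip[0]:
            raise ConfigError("rate_clip must be an increasing pair of positive rates")
        if self.dt_sim > self.tau_fast / 5 + 1e-12:
            raise ConfigError("dt_sim must not exceed tau_fast / 5")
        for name in ("fast_coupling", "slow_coupling"):
            g = getattr(self, name)
            if not math.isfinite(g) or g < 0:
                raise ConfigError(f"{name} must be finite and non-negative")
        if self.coupling_cv < 0:
            raise ConfigError("coupling_cv must be non-negative")


def _ou_paths(n_steps: int, n_series: int, tau: float, dt: float,
              rng: np.random.Generator) -> np.ndarray:
    """Stationary unit-variance Ornstein-Uhlenbeck paths, exact AR(1) update."""
    a = math.exp(-dt / tau)
    b = math.sqrt(1.0 - a * a)
    eps = rng.standard_normal((n_steps, n_series))
    z0 = rng.standard_normal(n_series)
    # z[t] = a z[t-1] + b eps[t], z[-1] = z0
    z, _ = lfilter([1.0], [1.0, -a], b * eps, axis=0, zi=(a * z0)[None, :])
    return z


def _heterogeneous_gains(mean: float, cv: float, size: int,
                         rng: np.random.Generator) -> np.ndarray:
    if mean == 0 or cv == 0:
        return np.full(size, float(mean))
    shape = 1.0 / cv**2
    return mean * rng.gamma(shape, 1.0 / shape, size)


def generate_multiregion_spikes(config: SynthConfig) -> SpikeData:
    """Simulate a multi-region recording under ``config``.

    Each unit's intensity is
    ``baseline * exp(g_f z_region(t) + g_s z_global(t) - (g_f^2 + g_s^2)/2)``
    so that the expected intensity equals the baseline exactly (the latents
    are stationary with unit variance).  Spike counts are drawn per simulation
    step as Poisson with ``intensity * dt_sim`` and jittered uniformly within
    the step to give continuous spike times.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n_regions, per = config.n_regions, config.neurons_per_region
    n_units = n_regions * per
    dt = config.dt_sim
    n_steps = int(round(config.duration / dt))
    if n_steps < 1:
        raise ConfigError("duration shorter than one simulation step")

    baselines = np.exp(
        rng.normal(math.log(config.rate_median), config.rate_sigma, n_units)
    ).clip(*config.rate_clip)
    g_fast = _heterogeneous_gains(config.fast_coupling, config.coupling_cv,
                                  n_units, rng)
    g_slow = _heterogeneous_gains(config.slow_coupling, config.coupling_cv,
                                  n_units, rng)

    z_fast = _ou_paths(n_steps, n_regions, config.tau_fast, dt, rng)
    z_slow = _ou_paths(n_steps, 1, config.tau_slow, dt, rng)[:, 0]

    region_of = np.repeat(np.arange(n_regions), per)
    step_starts = np.arange(n_steps) * dt

    spike_times = []
    for i in range(n_units):
        log_gain = (
            g_fast[i] * z_fast[:, region_of[i]]
            + g_slow[i] * z_slow
            - 0.5 * (g_fast[i] ** 2 + g_slow[i] ** 2)
        )
        lam = baselines[i] * np.exp(log_gain) * dt
        counts = rng.poisson(lam)
        nz = counts > 0
        total = int(counts[nz].sum())
        times = np.repeat(step_starts[nz], counts[nz]) + rng.random(total) * dt
        spike_times.append(np.sort(times))

    unit_ids = np.array(
        [f"r{r:02d}u{u:02d}" for r in range(n_regions) for u in range(per)]
    )
    region_labels = np.array([f"region_{r:02d}" for r in region_of])
    return SpikeData(unit_ids, spike_times, region_labels, (0.0, n_steps * dt))


@dataclass
class PlantedGraphConfig:
    """Weighted stochastic-block-model graph with known communities.

    Edges are Bernoulli with block-dependent densities; weights of realised
    edges are exponential with block-dependent means.  With
    ``within_weight_mean >= between_weight_mean`` (and likewise for the
    densities) the blocks are a planted ground truth for ensemble detection.
    """

    block_sizes: tuple = (20, 20, 20)
    within_weight_mean: float = 0.3
    between_weight_mean: float = 0.05
    edge_density_within: float = 0.9
    edge_density_between: float = 0.2
    n_nodes: int | None = None
    seed: int = 0

    def __post_init__(self):
        self.block_sizes = tuple(int(b) for b in self.block_sizes)
        if not self.block_sizes or any(b < 1 for b in self.block_sizes):
            raise ConfigError("block_sizes must be positive counts")
        total = sum(self.block_sizes)
        if self.n_nodes is None:
            self.n_nodes = total
        elif self.n_nodes != total:
            raise ConfigError(
                f"block_sizes sum to {total}, not n_nodes={self.n_nodes}"
            )
        for name in ("edge_density_within", "edge_density_between"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        for name in ("within_weight_mean", "between_weight_mean"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")


def generate_planted_graph(
    config: PlantedGraphConfig,
) -> tuple[FunctionalGraph, Partition]:
    """Sample a planted-partition graph; returns the graph and true labels."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_nodes
    labels = np.repeat(np.arange(len(config.block_sizes)), config.block_sizes)
    iu = np.triu_indices(n, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    dens = np.where(same, config.edge_density_within, config.edge_density_between)
    mean_w = np.where(same, config.within_weight_mean, config.between_weight_mean)
    present = rng.random(len(same)) < dens
    w = np.where(present, rng.exponential(1.0, len(same)) * mean_w, 0.0)
    weights = np.zeros((n, n))
    weights[iu] = w
    weights += weights.T
    node_ids = np.arange(n)
    graph = FunctionalGraph(
        weights, node_ids, meta={"kind": "planted", "seed": config.seed}
    )
    return graph, Partition(node_ids, labels)
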