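# Methods

This note documents the models, estimators and numerical conventions used by
`spikenets`, and the design decisions taken where more than one reasonable
choice existed.

## Synthetic multi-region recordings

`generate_multiregion_spikes` draws from a log-Gaussian Cox model chosen to
emulate the correlation structure the analysis is designed to detect, not
the biophysics of any particular circuit:

- **Latents.**  Each of the R regions owns a private fast latent and all
  units share one global slow latent.  Latents are stationary unit-variance
  Ornstein–Uhlenbeck processes simulated by their exact AR(1) discretisation
  at `dt_sim` (default 5 ms, constrained to ≤ τ_fast/5).  Defaults:
  τ_fast = 50 ms, τ_slow = 2 s.
- **Intensity.**  Unit *i* in region *r* fires as an inhomogeneous Poisson
  process with intensity
  bᵢ · exp(g_f,i z_r(t) + g_s,i z_glob(t) − (g²_f,i + g²_s,i)/2).
  The subtracted term removes the log-normal bias exactly, so the expected
  intensity equals the baseline bᵢ.  Counts are drawn per simulation step as
  Poisson(intensity · dt) and jittered uniformly within the step; at the
  analysed bin widths (≥ 10 ms ≫ dt) this is indistinguishable from exact
  thinning.
- **Baselines.**  Log-normal with median 3 Hz and σ_log = 1, clipped to
  [0.2, 50] Hz, placing the bulk of unit (and pairwise geometric-mean) rates
  between 1 and 10 Hz.
- **Gains.**  Per-neuron gains are gamma-distributed with mean equal to the
  module-level couplings and CV 0.35.  The mean gains (fast 1.3, slow 0.6)
  were calibrated against the generator's qualitative contract: the
  region-private latent must dominate the *shared* count variance of
  within-region pairs at sub-second bins — for every region, after Poisson
  counting noise — while the global latent dominates at multi-second bins.
  With weaker fast gains, individual regions whose sampled rates or gains
  were low dropped below the detection floor at fast bins, contradicting the
  regime the generator is meant to produce.  Gain heterogeneity plus the
  wide baseline-rate law give the pairwise correlation distributions a
  realistic spread so the within/between histograms overlap partially.

What the generator deliberately omits: refractoriness, bursting, oscillatory
structure, travelling waves, behavioural covariates, multiple slow factors,
and region-pair-specific connectivity.  Consequently, on synthetic data the
slow end of the sweep collapses to a *single* global ensemble (the only slow
structure is one shared latent), whereas real recordings may retain several
multi-region ensembles at slow timescales.  Passing the trend checks
therefore demonstrates that the pipeline resolves fast-local versus
slow-global organisation where it exists; it does not certify behaviour on
data with richer slow structure.

`generate_planted_graph` provides weighted stochastic-block-model ground
truth for the detector: Bernoulli edges and exponential weights with
block-dependent parameters (defaults: three blocks of 20, within
density 0.9 / mean weight 0.3, between 0.2 / 0.05).

## Binning and subsampling

Bins are half-open intervals [edge, edge + T) anchored at the window start;
the trailing partial bin is dropped.  This makes spike counts conserved
across widths and re-binning at an integer multiple exactly equal to summing
adjacent bins.  Units with zero spikes are retained through binning; the
correlation stage masks their pairs as undefined rather than scoring them 0,
so silent units never inflate the histogram mass at r = 0.

Balanced subsampling fills per-region quotas round-robin (one unit per
region per turn, regions in order of first appearance) until the target
count is reached, sampling without replacement within regions.  This yields
an exact total and caps each region at its size, spreading any shortfall
over the remaining regions.

## Correlation statistics

Pearson correlations are computed on the centred count series; pairs
involving a zero-variance series are masked invalid.  The Jensen–Shannon
divergence between the within- and between-region correlation values is
estimated on a fixed shared grid of 100 equal bins over [−1, 1] with log
base 2 and 0·log 0 = 0, giving a symmetric quantity in [0, 1] bits.  The
estimator's histogram bias is common to both arguments and is irrelevant for
the trend comparisons made with it.  Rate-conditioned JSD uses logarithmic
rate bins (4 per decade over 0.1–100 Hz) and reports bins with fewer than 20
pairs in either group as undefined rather than 0.

## Functional graph construction

Chance correlations are removed per pair using the 5th/95th percentiles of
correlations recomputed after fully permuting each unit's count series,
independently per unit and per shuffle (100 shuffles by default).  Whole-
series permutation destroys all temporal alignment while preserving each
unit's marginal count distribution.  Entries inside the band are zeroed;
the default transform then rectifies negative weights to zero.  Absolute-
value and negative-only transforms are available for sensitivity analyses.
The percentile band is applied before rectification in all modes so the
three transforms differ only in the final mapping.

## Ensemble detection

- **Null expectation.**  ⟨P⟩ = s sᵀ / 2m (node strengths s, total weight m),
  *including* the diagonal s²ᵢ/2m.  This is the standard modularity-matrix
  convention: the total expected weight matches the data exactly
  (Σ⟨P⟩ = 2m) and B = W − ⟨P⟩ has exact zero row sums.
- **Sparse null sampler.**  Edge presence is Bernoulli with
  pᵢⱼ = min(1, kᵢkⱼ/2M) from the binary degree sequence, preserving expected
  degrees and density.  The data's total weight is quantised to
  round(m·conversion) integer quanta (conversion 100, largest-remainder
  rounding so the quantum total is exact) and redistributed over realised
  edges with probability ∝ sᵢsⱼ/pᵢⱼ; the inverse-inclusion factor keeps node
  strengths preserved in expectation under heterogeneous degrees.  Two
  redistribution schemes are provided:
  - `chunks` (default): each data edge's quanta move as one indivisible
    chunk, so null samples inherit the data's empirical edge-weight
    distribution.  The null then treats weight disorder as part of the null
    hypothesis — graphs whose only structure is heavy-tailed weights are
    *not* flagged as communities — at the cost of a conservative bound.
  - `quanta`: individual quanta are scattered multinomially, giving smooth
    per-edge weights; appropriate when the data's weight disorder is itself
    the signal of interest.
  Total weight is conserved exactly (in quanta) in every sample.
- **Dimensionality.**  The null upper bound is the mean of the largest
  eigenvalues of the N = 100 sampled deviation matrices (no confidence-
  interval widening); d is the number of data eigenvalues above it.  d = 0
  short-circuits to a single community over all nodes.
- **Node rejection.**  Nodes are embedded as eigenvector rows scaled by
  √λ (the spectral embedding with X Xᵀ reproducing the retained part of B).
  A node is noise if its embedding norm is at or below the mean norm of the
  same node across the null samples' top-d embeddings.  The mean-based rule
  is the package's choice; a percentile variant would be stricter.
- **Clustering.**  k-means (10 initialisations per call) on the d-dimensional
  embedding, k scanned over 2…d+1, keeping the k with the largest
  Q(C) = Σ same-cluster Bᵢⱼ, ties to the smaller k.  Linear eigenvalue
  scaling of the embedding was rejected: it stretches high-λ dimensions
  enough that k-means reliably misses partitions whose quality exceeds every
  k-means solution (an optimisation failure, observable because Q of the
  planted partition exceeded all candidates).  The √λ embedding removed
  this failure mode.
- **Consensus.**  The co-assignment frequency matrix C over the 100 repeat
  partitions is compared with the expected co-assignment under random
  relabelling of each partition (preserving its cluster sizes); the deviation
  is spectrally clustered with the same k-means procedure, with the retained
  dimension set by a permutation-null eigenvalue bound (20 permuted
  ensembles), iterating until all off-diagonal entries of C are within 0.05
  of 0 or 1 (then communities = connected components of C ≥ 0.5) or 20
  iterations, returning the current grouping with a non-convergence flag.

All randomness (null sampling, k-means initialisation, consensus) derives
from one master seed through `numpy` `SeedSequence` substreams; identical
configuration and seed reproduce results bit for bit.

## Partition comparison

Entropy, mutual information and variation of information use log base 2
throughout (bits); VI is computed from the joint contingency table and
returns exactly 0 for identical groupings.  Rejected (noise) nodes are
excluded from VI and pair-fraction comparisons by default, with the noise
set reported separately; callers may instead fold them in as one extra
cluster.  Same-ensemble fractions are conditional probabilities over
unordered pairs (co-clustered | same region) and (co-clustered | different
region); a category with no pairs is undefined (NaN), not zero.

## Sweep defaults and problem sizes

The default bin-width grid is geometric from 10 ms to 3 s (9 points).  The
test suite and the acceptance script exercise the pipeline at the four-point
subset {25, 100, 400, 1600} ms on 9 regions × 20 units × 10 minutes — sizes
at which every stage's statistical behaviour (threshold calibration, null
bounds, recovery rates, trend ordering) is already stable while a full sweep
completes in tens of seconds.  Monotone-trend checks on VI and the
same-ensemble fraction difference use non-strict step-wise comparisons with
a strict net change across the sweep, because both quantities saturate
exactly at the fast end (VI = 0 under perfect region recovery) and at the
slow end (single global ensemble), where strict step-wise inequalities are
ill-posed.

## Known limitations

- Pearson correlation captures only linear, stationary co-variation averaged
  over the recording; transient synchrony and nonlinear coupling are out of
  scope.
- Ensembles are non-overlapping by construction.
- The shuffle thresholds use raw percentiles per pair, with no multiplicity
  correction across pairs.
- The spectral-rejection bound (mean of null maxima) is conservative under
  the chunk-redistribution null; weak genuine structure near the bulk edge
  may be missed, lowering d and capping the resolvable number of
  communities at d + 1.
- Storing the N null eigendecompositions is O(N·n²) memory (~26 MB at
  n = 180, N = 100); for recordings with thousands of units the node-
  rejection step should be reworked to stream the samples.
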