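# spikenets

Multi-timescale correlation structure and neural-ensemble detection for
multi-region spike recordings.

## The scientific problem

Large electrophysiology datasets now record hundreds of single units
simultaneously across many brain regions.  A basic organisational question is
whether groups of co-active neurons ("ensembles") stay confined to one
anatomical region or span several — and whether the answer depends on the
*timescale* at which co-activity is measured.  `spikenets` implements a
complete, reproducible pipeline for that question:

1. **Binning.**  Spike times are converted to spike-count series at a sweep
   of counting-bin widths *T* (10 ms – 3 s), with balanced per-region
   subsampling of units.
2. **Correlations.**  For every unit pair the sample Pearson correlation of
   the binned counts,

   r_XY = Σᵢ(xᵢ−x̄)(yᵢ−ȳ) / √(Σᵢ(xᵢ−x̄)² Σᵢ(yᵢ−ȳ)²),

   is split into within-region and between-region pair distributions; their
   difference is quantified by the Jensen–Shannon divergence (JSD, bits) on a
   fixed histogram grid over [−1, 1], overall and conditioned on the pair's
   geometric mean firing rate √(r_A r_B).
3. **Functional graph.**  Correlations inside the 5th–95th percentile band
   of per-unit shuffled surrogates are set to zero ("chance" edges), and the
   matrix is rectified to a non-negative weighted graph W (positive,
   absolute-value, or negative-only edge transforms).
4. **Ensemble detection (spectral rejection).**  W is compared with the
   weighted configuration model ⟨P⟩ᵢⱼ = sᵢsⱼ/2m via the deviation matrix
   B = W − ⟨P⟩.  Eigenvalues of B above the upper bound of a sampled sparse
   configuration-model eigenspectrum give the community dimensionality d;
   weakly projecting nodes are rejected as noise; the remaining nodes are
   k-means clustered in the retained eigenspace (k = 2…d+1, best
   modularity-style quality Q = Σ same-cluster Bᵢⱼ) 100 times and resolved by
   consensus clustering against an explicit permutation null.
5. **Partition comparison.**  Detected ensembles vs anatomical regions:
   entropy, mutual information, variation of information
   VI(X,Y) = H(X) + H(Y) − 2I(X,Y) (a metric on partitions, in bits), and
   same-ensemble pair fractions for same- vs different-region pairs.

A synthetic generator (`spikenets.synthetic`) produces multi-region
recordings with the assumed statistical structure — each region drives its
units with a private fast latent (Ornstein–Uhlenbeck, τ ≈ 50 ms) while one
global slow latent (τ ≈ 2 s) modulates every unit — so the whole pipeline is
testable end to end without any external dataset.  On such data the pipeline
reproduces the fast-local / slow-global signature: at sub-second bins
ensembles coincide with regions, at multi-second bins they merge across
regions.

## Worked example

```bash
spikenets simulate --out rec --n-regions 4 --neurons-per-region 8 \
    --duration 120 --seed 11
# wrote 13450 spikes from 32 units to rec

spikenets sweep --spikes rec --out sweep --widths 0.1,0.4,1.6 \
    --n-shuffles 50 --n-null 50 --n-repeats 30 --seed 11
```

which prints (abridged):

```
 bin_width_s  mean_within  mean_between  jsd_bits  d  n_ensembles  difference  vi_bits
         0.1     0.343112      0.037837  0.728514  2            3    1.000000 0.000000
         0.4     0.429349      0.130113  0.533143  1            2    0.761905 0.555556
         1.6     0.505365      0.253698  0.416435  0            1    0.000000 2.000000
```

Reading the rows: at 100 ms bins, within-region correlations (mean 0.34) far
exceed between-region ones (0.04); the correlation distributions are well
separated (JSD 0.73 bits); the detected ensembles coincide with anatomical
regions (VI 0 bits) and only same-region pairs share an ensemble
(difference 1.0).  At 1.6 s bins both means rise but converge, the JSD
drops, and a single brain-wide ensemble remains — the ensembles no longer
respect regional boundaries (VI = H(regions) = 2 bits).  `sweep/` also
contains the per-width ensemble memberships (JSON) and the full summary
(`sweep.csv`).

The same stages are available as library calls (`generate_multiregion_spikes`,
`bin_spikes`, `pearson_matrix`, `shuffle_thresholds`,
`apply_threshold_and_rectify`, `detect_ensembles`,
`variation_of_information`, `run_sweep`) and as the CLI subcommands
`simulate`, `bin`, `correlate`, `build-graph`, `detect`, `compare`, `sweep`.

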