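# Methods

This note documents the models behind each `pclong` component, the
parameters that matter, what the synthetic generators do and do not emulate,
and the numerical conventions adopted where the design was open.

## Track motility

A track is a cell's time-ordered positions (μm) at a fixed frame interval
(default 3 min, the standard two-photon time-lapse cadence). Statistics:

* **Track velocity** = total path length / (t_last − t_first), μm/min.
  **Displacement velocity** = |x_last − x_first| / duration. The triangle
  inequality guarantees displacement ≤ track velocity; both are reported
  because their ratio separates confined wiggling from directed motion.
* **MSD**: per track, the time-averaged squared displacement over *all*
  overlapping frame pairs at each integer-frame lag; the ensemble curve is
  the unweighted mean of per-track curves, so long tracks do not dominate.
  For an isotropic Gaussian walk with per-axis step sd σ in d dimensions,
  MSD(nΔt) = d·σ²·n; for ballistic motion at speed v, MSD(τ) = v²τ².
* **Fast fraction**: fraction of tracks with velocity strictly greater than
  1 μm/min. The inequality is strict; a cell at exactly the threshold is not
  a fast mover.
* **Ratio classification**: mean over frames of ch_yfp/ch_tomato; cells
  below 1.02 are called `llpc_bright` (stronger TdTomato depresses the
  ratio), at or above it `bulk_dim`. The tie at exactly 1.02 goes to
  `bulk_dim`, since only values *below* the threshold indicate brightness.
  Ratios are computed on the provided intensities; background subtraction
  belongs to the upstream imaging pipeline.
* **Gaps**: a track with missing frames can be split into contiguous
  segments (`split_at_gaps`); velocities then use actual elapsed time rather
  than interpolating unobserved motion. Whether to splice across gaps is a
  convention of this package, not a property of the data.

## Spatial statistics

* **k-NN mean distance**: for each query cell, the arithmetic mean of
  Euclidean distances to its k = 20 nearest cells of the reference
  population, which by default is the *total* pool (both subsets combined) —
  deliberately different from same-type nearest-neighbor statistics. The
  query cell never counts itself. Fewer than k eligible reference points is
  an error, never a silent truncation. Implemented with a k-d tree and
  verified against an exhaustive all-pairs oracle; distances are exact to
  floating-point, so ties in the k-th neighbor cannot change the mean.
* **Subsampling**: the per-subset sample size follows Cochran's formula with
  p = 0.5 and finite-population correction at 95% confidence / 5% margin,
  rounded up and capped at the population (upper bound 385). Two
  independent without-replacement draws are taken and reported both
  separately and pooled (concatenated), mirroring the practice of plotting
  pooled per-cell symbols.
* **Dimensionality**: patterns may be 2D or 3D; distance computations use
  whatever dimensionality the pattern carries. Dropping a depth axis before
  analysis is the caller's choice.
* **Cluster masking**: space is divided into cubic bins (default 20 μm);
  bins holding at least `min_count_per_bin` cells are masked; masked bins
  touching by face, edge or corner merge into one cluster; clusters with
  fewer than `min_cells_per_cluster` total cells are dropped. This
  grid-density design was chosen for parameter transparency and exact
  testability; it approximates smooth "cluster surfaces" by binned masks and
  is translation-equivariant only up to bin alignment. Points exactly on the
  upper domain boundary are assigned to the last bin.
* **Occupancy/residence**: per frame, the fraction of each subset's tracked
  cells inside any masked bin (inside + outside = 1); per cell, residence =
  number of inside frames × frame interval.

## Decay kinetics

Counts follow N(t) = (N₀ − plateau)·e^(−kt) + plateau with t₁/₂ = ln 2/k.
Fitting is nonlinear least squares on raw counts (not log counts), seeded by
a log-linear regression on the positive counts; bounds keep N₀, k ≥ 0.
Choices:

* **Plateau fixed at 0 by default**: with four timepoints a free plateau is
  weakly identified; long-term labeled-cell frequencies approach small
  values. A free-plateau mode (≥ 4 distinct timepoints) is exposed.
* **Infinite half-life convention**: when the fitted total decay over the
  observed span, k·(t_max − t_min), is below 10⁻⁶, the series is
  indistinguishable from constant and t₁/₂ is reported infinite. The
  threshold is span-relative because an absolute per-day cutoff would mean
  different things on different experimental durations.
* **Non-convergence** is flagged on the result, never silently replaced.
* **Half-life comparison**: case-resampling bootstrap — replicates are
  resampled with replacement within each timepoint of both series, both
  refitted, and the percentile interval of Δt₁/₂ reported. A bootstrap makes
  no variance-homogeneity assumption, which matters because multiplicative
  noise makes count variance scale with the mean. Requires ≥ 2 replicates
  per timepoint.

## Repertoire statistics

* **Clone key**: heavy-chain V gene with the allele suffix stripped
  (IGHV8-9\*01 → IGHV8-9) plus the exact CDR3 amino-acid sequence. Allele
  identity is kept per member sequence because SHM is aggregated per
  *allele*. Only IGH clones enter sharing/diversity statistics; light-chain
  rows are dropped with a logged count.
* **Size filter**: clones with summed duplicate count < 10 are removed at
  build time. Chao1 in the default pipeline therefore runs on filtered
  tables, where f₁ = f₂ = 0 and the estimator reduces to observed richness;
  building with `min_size=1` gives the pre-filter estimate. Both orders are
  supported because the correct order is genuinely ambiguous; neither is
  asserted as canonical.
* **Chao1**: S_obs + f₁²/(2f₂) when doubletons exist, else the
  bias-corrected S_obs + f₁(f₁−1)/2.
* **Overlap**: percentage of shared clone keys; Jaccard (shared/union) by
  default, with shared/|first| and shared/min(|a|,|b|) selectable since the
  denominator convention is ambiguous in practice.
* **Public clones**: keys present in ≥ 2 samples from ≥ 2 distinct mice.
  Ranking for top-N enrichment uses total abundance across samples, ties
  broken by lexicographic key for determinism; the baseline is the fraction
  of all observed clone keys present in target-subset samples.
* **SHM**: one member sequence per clone drawn uniformly (seeded) to avoid
  double-counting mutations within a clone; per-sequence frequency =
  mutation count / V length; per-allele value = mean over clones whose
  representative carries that allele. Comparisons use a paired t test on
  allele-matched values (unmatched alleles discarded; < 2 matches skips the
  comparison; a nonzero constant difference is flagged degenerate with no
  p-value, while identical vectors report t = 0, p = 1), with
  Benjamini–Hochberg adjustment across the family of comparisons.

## Synthetic generators

All generators are pure functions of their config, seed included.

* **Point patterns**: CSR places cells uniformly; the clustered process is
  Thomas-like — uniform parents, isotropic Gaussian offspring with sd
  `offspring_sd` (default 10 μm), offspring outside the box resampled rather
  than clipped to avoid boundary density artifacts. LLPCs join clusters with
  probability `llpc_cluster_affinity`. Defaults (500³ μm box, 500 bulk +
  150 LLPC, 10 parents) give unambiguous clustered-vs-CSR contrast at
  realistic densities. The in-vivo cluster-size distribution is not
  characterized; this process is a stand-in with one tightness knob, not a
  calibrated tissue model.
* **Tracks**: Gaussian random walks with per-frame arrest; sessile (step sd
  0.2 μm, arrest 0.5) vs motile (2.0 μm, arrest 0) phenotypes, 3-min
  frames. Channel intensities are Gaussian around phenotype means separated
  by 40 units at sd 1, so ratio classification should recover phenotypes
  exactly; no photon noise, optics or segmentation error is modeled.
* **Decay**: exact exponential times mean-corrected lognormal noise
  (σ² = ln(1+CV²), mean-correction −σ²/2) so replicate means are unbiased;
  noiseless limit reproduces the closed form to machine precision. Default
  timepoints 5/30/90/150 days match a timestamping design.
* **Repertoires**: clone sizes are Zipf-weighted (exponent 1.2) multinomial
  allocations of 6000 reads over 300 clones per sample, producing
  heavy-tailed sizes with singletons and doubletons; clones drawing zero
  reads are unobserved. Public clones are spiked into ≥ 2 samples from
  different mice with duplicate counts ≥ 10 (so they survive the size
  filter) and a 0.75 preference for LLPC samples; all private CDR3s are
  globally unique, making the spike-in list an exact ground truth.
  Mutation counts are Poisson (means 2 for LLPC, 6 for bulk); no
  sequence-level hypermutation or lineage structure is simulated. Passing
  tests on these data show the statistics are computed correctly, not that
  real repertoires satisfy the generators' independence assumptions.

## Problem sizes and determinism

The validation suite uses 50 random patterns (≤ 500 points) for the k-NN
oracle, 10,000 tracks for the MSD closed form, 500 noisy replicates for
half-life recovery, and 100 seed pairs for clustered-vs-CSR discrimination —
sizes at which Monte-Carlo error is comfortably below the asserted
tolerances. All CLI subcommands are deterministic given config and seed;
result tables rerun byte-identically, with only the manifest timestamp
changing.

## Known limitations

* The grid mask is a coarse stand-in for surface-based cluster definitions;
  cells in a cluster's sparse fringe bins fall outside the mask, so blob
  capture fractions plateau around 93–95% at the default bin size.
* Chao1 after size filtering is uninformative (by construction no
  singletons); use `min_size=1` for diversity questions.
* The bootstrap half-life comparison assumes replicates are exchangeable
  within timepoints; serial correlation across timepoints within an animal
  is not modeled.
* Intensity-ratio classification assumes stable channel gains; no drift or
  bleaching correction is applied.
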