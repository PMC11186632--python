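# pclong

Quantitative analysis tools for plasma-cell longevity studies: spatial and
motility statistics for timestamped bone-marrow plasma cells, cohort decay
kinetics, and BCR heavy-chain repertoire statistics — each paired with a
synthetic-data generator carrying known ground truth.

## The problem

Long-lived plasma cells (LLPCs) are antibody-secreting cells that persist for
months to years in the bone marrow, while the bulk plasma-cell pool turns
over quickly. Experiments that "timestamp" all plasma cells alive at one
moment with an irreversible fluorescent label, then image and sequence the
survivors, produce four kinds of quantitative data:

1. **Cell tracks** from intravital two-photon imaging (positions in μm every
   3 min, two fluorescence channels);
2. **Static point patterns** of labeled cell subsets in tissue;
3. **Cohort count series** of labeled cells over days;
4. **BCR repertoires** (clone tables derived from sequencing).

`pclong` implements the bespoke statistics these designs need.

## The statistics

* **Motility** — per-track *track velocity* (path length / duration, μm/min)
  and *displacement velocity* (net displacement / duration); ensemble
  mean-squared displacement MSD(τ), time-averaged per track over all
  overlapping frame pairs and then averaged without weighting across tracks;
  the fraction of fast movers (track velocity > 1 μm/min); and subset
  classification on the mean YFP/TdTomato intensity ratio (cells below the
  1.02 threshold are TdTomato-bright LLPCs).
* **Spatial clustering** — for each cell of a subset, the mean Euclidean
  distance to its k = 20 nearest cells of the *total* plasma-cell pool (self
  excluded), evaluated on a random subsample whose size comes from Cochran's
  formula with finite-population correction at 95% confidence / 5% margin
  (n₀ = z²·0.25/m², n = n₀/(1+(n₀−1)/N); 278 of 1000, 80 of 100), drawn
  twice independently. Smaller values mean tighter clustering. A
  grid-density mask (bins ≥ a count threshold, joined by full connectivity)
  marks high-density clusters and scores track occupancy and residence.
* **Decay kinetics** — one-phase decay N(t) = (N₀ − plateau)·e^(−kt) +
  plateau fitted to absolute counts by nonlinear least squares
  (log-linear initialization), reporting the half-life t₁/₂ = ln 2 / k, with
  a case-resampling bootstrap for half-life differences between cohorts.
* **Repertoire** — clones keyed by heavy-chain V gene + exact CDR3 amino-acid
  sequence, size-filtered (< 10 removed); Chao1 richness
  (S_obs + f₁²/2f₂, bias-corrected when f₂ = 0); pairwise clonal overlap
  (Jaccard and two alternative denominators); *public clones* shared by ≥ 2
  samples from different mice; enrichment of the top-100 most abundant
  public clones in a target subset; isotype composition; and somatic
  hypermutation aggregated per IGHV allele (one random sequence per clone,
  mutations / V length) compared across samples by paired t tests on
  matched alleles with Benjamini–Hochberg correction.

Every analysis has a matching generator in `pclong.synthetic` (uniform vs
Thomas-like clustered point processes, sessile vs motile random walks,
noisy exponential cohorts, Zipf-abundance repertoires with spiked public
clones), so each statistic can be validated end-to-end against ground truth.

## Worked example

```python
import pclong as pl

# Motility: 100 sessile + 100 motile simulated tracks
tracks = pl.gen_tracks(pl.TrackSimConfig(seed=1))
stats = [pl.track_statistics(t) for t in tracks]
print(pl.fast_fraction(stats))        # 0.345  (fraction > 1 um/min)

# Spatial: clustered vs uniform placement of 150 LLPCs among 500 bulk PCs
clu, _ = pl.gen_point_pattern(pl.SpatialSimConfig(process="clustered",
                                                  offspring_sd=10, seed=1))
csr, _ = pl.gen_point_pattern(pl.SpatialSimConfig(process="csr", seed=1))
print(pl.required_sample_size(150))                       # 109
print(pl.subsampled_nn(clu, "llpc", seed=1).pooled.mean())  # 21.44 um
print(pl.subsampled_nn(csr, "llpc", seed=1).pooled.mean())  # 79.44 um

# Decay: 5 replicates, CV 20% noise, true half-life 58 days
series = pl.gen_decay_cohort(pl.DecaySimConfig(n0=1000, t_half=58,
                                               noise_cv=0.2, seed=1))
print(pl.fit_one_phase_decay(series).t_half)              # 55.1 days
```

The fast-mover fraction is driven by the motile phenotype's step size; the
20-NN distance drops from ~79 μm under spatial randomness to ~21 μm when
cells sit in clusters of scatter 10 μm; the fitted half-life recovers the
generating 58 days to within the noise level.

The same pipeline runs from the shell:

```sh
pclong simulate --config examples/demo_config.yaml --seed 1 --out demo
pclong spatial    --input demo/points.csv     --seed 1 --out demo/spatial
pclong tracks     --input demo/tracks.csv              --out demo/tracks
pclong decay      --input demo/decay.csv               --out demo/decay
pclong repertoire --input demo/repertoire.tsv \
                  --metadata demo/sample_metadata.csv --seed 1 --out demo/rep
```

Each run writes result tables plus a `manifest.json` (config echo, version,
seed, input checksums); reruns with the same config and seed are
byte-identical apart from the manifest timestamp.

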