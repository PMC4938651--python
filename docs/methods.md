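# Methods notes

## The demographic model

All inference and simulation is built on a two-deme isolation-with-migration
(IM) model.  An ancestral population of diploid effective size N₀ splits
`t_div` generations before present into the FEN and ALP descendants (sizes
N_FEN, N_ALP), which then exchange migrants continuously.  Migration is
parameterized as scaled migrant numbers M = 2Nm: `mig_fen_alp` (M₁₂) is the
forward-time number of FEN→ALP migrants per generation, implemented backward
in time as lineages sampled in ALP jumping to FEN at rate M₁₂/(2·N_ALP) per
lineage per generation (and symmetrically for M₂₁).  Three ancestral
scenarios are supported:

- **constant** — ancestral size N₀ throughout;
- **growth** — looking backward from the split, the ancestral size shrinks
  exponentially, N(s) = N₀·e^(−αs) with s the time before the split; this
  anchors growth at the split, matching how SFS-based fitters usually
  parameterize an expanding ancestral population;
- **bottleneck** — the ancestral population drops to 0.001·N₀ for 100
  generations starting `t_bot` generations ago; the bottleneck must predate
  the split (`t_bot > t_div`), and depth and duration are fixed so that only
  its onset is free.

Time is converted to years with a generation time of 25 yr and a mutation
rate of 1.1×10⁻⁹ per site per year (so μ = 2.75×10⁻⁸ per generation).

### Units of the published size estimates

Composite-likelihood SFS fitters natively express population sizes as
numbers of **gene copies** (haploid genomes).  `fitted_constant_model()`
therefore interprets the published modal sizes (41,000 / 51,000 / 397,000)
as gene-copy counts and halves them to the diploid sizes the coalescent
engine uses.  Two observations support this reading: simulating the
88-locus panel under it reproduces the empirical SNP density (~2,400–2,500
segregating sites vs 2,791 observed) and an overall Hudson F_ST of
~0.033–0.037 (0.047 observed), whereas the diploid reading doubles the SNP
count and diversity.  Because the fit used only the *normalized* SNP SFS,
the absolute diversity scale is weakly constrained by the data that produced
these estimates; simulated per-pool π (~0.0033) accordingly undershoots the
observed ~0.005 under either reading, and this residual mismatch should be
kept in mind wherever absolute π matters.

## The coalescent engine

Each locus is an independent, non-recombining amplicon (free recombination
between loci, none within — reasonable for ~1.3 kb fragments).  The engine
runs a continuous-time structured coalescent: with k lineages in a deme of
diploid size N, pairs coalesce at rate k(k−1)/(4N); migration moves single
lineages between demes at the per-lineage rates above; at `t_div` the demes
merge.  In the growth scenario the waiting time uses the closed-form time
change of the exponential rate (evaluated in log space to avoid overflow);
the bottleneck uses piecewise-constant rates.  Each lineage carries the
count of sampled chromosomes beneath it in each pool, so a branch is fully
described by (d₁, d₂, length) and no explicit tree is kept.  Mutations are
infinite-sites: Poisson on branch length × μ × L, assigned distinct
positions; the rare excess beyond L positions is discarded.  Engine checks
in the test suite include E[TMRCA] = 2N for pairs, Watterson's E[S] = θ·a₁·L,
the neutral 1/i SFS after merging, F_ST → 1 under complete isolation, and a
cross-simulator comparison against msprime in a symmetric island model.

## Pooled read generation

Per library (pool × replicate) and amplicon, mean coverage is
gamma-distributed (shape 10) around the 200× target, emulating the
between-amplicon spread of real capture/amplification; read count is
Poisson; 109-bp reads are placed uniformly (clipped at the gene ends) with
Bernoulli(½) strands.  At each covered SNP a read carries the derived allele
with probability equal to the pool's true frequency, then flips to the
site's other allele with the error probability — a biallelic error model,
chosen so that error thresholds act on the same two alleles the SNP caller
sees.  Not modelled: indels, quality strings, mapping artifacts, paralogy,
PCR duplicates, or selection dynamics (selection is emulated only by
coupling nonsynonymous labels to low allele-frequency differences via a
tunable bias).

## Read processing

- **Library downsampling** retains a uniform random subset of a library,
  matching all libraries to the smallest one.
- **Per-gene sweep**: positions are visited 5'→3'; at each position,
  not-yet-decided reads covering it are retained (in random priority order)
  until the retained depth reaches 100 per strand, the rest are discarded;
  positions below the cap keep everything.  "100 on both strands" is read
  as 100 *per strand*, which makes the expected per-library depth ~200,
  matching the stated expectation.  The implementation uses a single pass
  with a global random priority, which is equivalent to independent random
  choices at each position.
- **SNP validation**: a minor allele is accepted only if some pool shows it
  in both sequencing replicates, and it has ≥2 reads in each of those
  replicates or ≥5 reads in total across the two pools.  Sites where two
  minor alleles pass are dropped (downstream statistics are biallelic);
  frequencies are pooled read fractions over replicates.  Rare alleles
  (pooled frequency < 0.01) are flagged, never auto-dropped; the 0.01/0.1
  minor-allele-frequency cutoffs are computed on the two pools' combined
  read counts.
- **Polarization** uses the outgroup allele where it matches one of the two
  observed alleles; otherwise the SNP stays minor-allele-folded and is
  excluded from SFS-based inference (but kept for F_ST/divD, which are
  polarization-invariant).

## Summary statistics

π uses the unbiased per-site heterozygosity Σ 2p(1−p)·n/(n−1)/L.  Tajima's
*D* reconstructs integer derived counts as round(p·n) with n = 96 (pool-seq
yields frequencies, not genotypes) and applies the standard constants.  The
joint SFS is built from the same reconstructed counts and projected to a
10×10 grid by hypergeometric down-sampling; the monomorphic corners are
masked for likelihood work.  Projection to the same size is the identity,
mass is conserved, and the operator is linear — all property-tested.

## Demographic fitting

The expected projected SFS under a parameter set is estimated by simulating
loci **directly at the projected sample size** (10+10 chromosomes): by
coalescent subsampling consistency this equals simulating 96+96 and
projecting, at a fraction of the cost.  Two variance-reduction choices make
the composite likelihood usable at desk scale:

- **Branch mode** — instead of sampling mutations, every branch adds its
  expected mutation mass (length × μL) to its (d₁, d₂) cell, removing all
  Poisson mutation noise;
- **Pseudo-count smoothing** (0.5 per unmasked cell) — tail cells that
  receive no simulated mass would otherwise hit the 10⁻¹² likelihood floor
  and swamp the surface with noise; the pseudo-count vanishes as the
  simulated mass grows, so the estimator remains consistent.

The composite log-likelihood is multinomial over unmasked cells.  Fitting
cycles through the free parameters (6 for the constant scenario, 7 with
growth rate or bottleneck onset), each maximized by a bounded scalar search
(log scale for sizes and times; bounds 10²–10⁷ diploids, 10²–10⁶
generations, M ∈ [0, 50], α ∈ [0, 10⁻²]) with a fixed simulation seed
shared across evaluations (common random numbers), stopping when a full
cycle gains < 0.01 log units.  The optimizer never returns a point below
its initialization.

A genuine caveat found while validating: with ~2,400 SNPs on a 10×10 grid
the IM likelihood has a ridge — a recent-split model with one very large
descendant population can fit marginally better than the generating deep
split.  Recovery experiments therefore initialize refits at the modal
estimates, mirroring bootstrap practice; from that start the refitted split
time stays inside the published 3.6–14 Myr interval in ≥ 8 of 10 repeats.

Bootstrap confidence intervals resample each SNP's derived count as
Binomial(96, p̂) per pool, rebuild the projected SFS and refit; the
per-replicate simulation seed is derived from a digest of the resampled
spectrum, so distinct replicates get fresh noise while identical
(degenerate) replicates reproduce identical fits.  Intervals are
percentile (2.5%/97.5%), point summaries are kernel-density modes, and
per-scenario Akaike support fractions use w_i = exp(−ΔAIC_i/2)/Σ.
Goodness of fit uses Poisson-family Anscombe residuals,
r = 1.5·(y^⅔ − m^⅔)/m^⅙, with expected counts scaled to the observed total.

## The divD scan

divD = √(F_ST² + AFD²) with AFD = |p₁−p₂|; negative per-SNP F_ST values
enter via their square (the statistic is a Euclidean norm).  Null datasets
draw the observed number of SNPs multinomially from the expected full-size
(97×97) joint SFS under the fitted model (one expected SFS per parameter
set; bootstrap parameter sets are cycled when provided) and group them into
genes matching the observed gene-size multiset.  Within each null dataset
the 95%/97.5%/99% envelopes are nearest-rank quantiles of divD (SNP-level
and gene-level); the final cutoff is the **maximum** across null datasets —
a deliberately conservative rule, and outliers must *strictly* exceed it.
Under the null, the flagged fraction at the 5% level stays below 5%
(typically 3–4% with 200 null datasets).  Gene-level scores are plain SNP
averages; outlier calls annotate near-fixation (p ≥ 0.99 or ≤ 0.01) and
intermediate (0.3–0.7) frequency regimes per pool.  Sensitivity reanalysis
repeats the scan on minor-allele-frequency subsets (≥ 0.01, ≥ 0.1) and
reports outlier overlap plus divD correlations (on shared SNPs, and between
matched distribution quantiles).

## Problem sizes and determinism

Default experiment sizes are chosen to resolve each question at desk scale:
10 replicate 88-locus datasets for F_ST/π summaries; 100,000 expected SNPs
for the projected expected SFS; 200 null datasets (of the observed SNP
count) for envelope construction with 20 fresh datasets for false-positive
checks; 20,000 expected SNPs per likelihood evaluation and ≤ 3 maximization
cycles for refit experiments.  Every random stage derives its seeds from a
single master seed via seed sequences (split per locus and per stage), and
fixture generation is byte-reproducible: identical seeds give identical
SHA-256 checksums.

## Known limitations

- Absolute diversity under the published modal parameters undershoots the
  observed π (see the units discussion above); F_ST, SNP density, SFS shape
  and the envelope calibration are the reliable self-consistency checks.
- Depth heterogeneity within amplicons, reference bias and paralogous
  mapping are not modelled; estimates of how the filters behave under such
  artifacts require real pileups.
- The composite likelihood treats SNPs as independent; within-amplicon
  linkage inflates the variance of observed spectra relative to the
  multinomial, which is why goodness of fit is summarized by the median
  (not the maximum) over replicate datasets.
- π/θ_W are unweighted by per-site depth (PoPoolation-style corrections are
  out of scope); LD statistics are not estimable from pooled frequencies.
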