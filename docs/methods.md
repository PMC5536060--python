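# Methods

## The design being emulated

The package models a QTL-seq experiment on tomato inflorescence branch
number (BN): an F2 of a cross between a highly-branched cultivated line
(10AS111A) and a single-branch wild relative (PI124039), phenotyped over
the first ten inflorescences per plant, with two DNA bulks — 60
single-branch plants (SB) and 11 highly-branched plants (HB, median
BN > 16) — sequenced at ~12× over ~15,640 SNPs. The highly-branched
parent is the read-mapping reference, so the SNP-index of a bulk estimates
its pooled frequency of the wild-parent allele. Two recessive loci drive
the trait: *FALSIFLORA* (FA, chromosome 3, major) and *COMPOUND
INFLORESCENCE* (S, chromosome 2, minor); only plants homozygous for the
cultivated alleles at both loci (`ffss`) are highly branched, giving the
15:1 two-locus ratio.

## Simulator

**Genome.** Twelve chromosomes at SL2.40-like lengths; SNPs placed
uniformly at random, apportioned by physical length, with the two causal
positions always included as markers. Uniform recombination at 2 cM/Mb
(~120 cM per 60 Mb chromosome).

**Meiosis.** Haldane model: per chromosome the crossover count is
Poisson(genetic length in Morgans), positions uniform, no interference;
each F2 receives two independent gametes. This is the simplest process
consistent with 1:2:1 marker segregation and an exponential decay of
linkage with map distance.

**Phenotype.** Each inflorescence draws a latent
`x ~ Normal(μ_class, σ)` on the log2(BN) scale and scores
`BN = max(1, round(2^x))`; the plant-level BN is the median over 10
inflorescences. Class means default to `F_S_ = 0.0`, `F_ss = 1.2`,
`ffS_ = 2.0`, `ffss = 5.0` with σ = 0.7. These are calibration choices,
not estimates: they reproduce the ordering of the four genotype classes,
put the `ffss` class at BN ≈ 32 (> 16, highly branched, preserving the
15:1 plant-level ratio), and centre the single-branch class on BN = 1.
The `F_S_` mean of 0.0 is deliberate: the single-branch bulk rule (median
BN = 1 **and** ≥ 70% single inflorescences) must be satisfiable by ~60 of
129 plants, as in the emulated study; with a mean much above 0 the
qualifying probability per `F_S_` plant drops quickly (at 0.3 it is ~0.54,
yielding ~39 qualifiers — too few to fill the bulk). Position-along-stem
effects on BN are ignored.

**Bulks and reads.** Bulk members are sampled uniformly among qualifying
plants. The bulk allele frequency at a SNP is the mean member dosage / 2
(equal DNA amounts per plant); per-SNP per-bulk depth is Poisson(12) by
default, and alternate reads are `Binomial(depth, f(1−e) + (1−f)e)` with a
flat per-read error `e = 0.01`. Read-level artifacts beyond this flat
error (mapping bias, duplicated repeats) are *not* modelled — which is
precisely why the low-index filter, designed against such artifacts,
removes almost nothing in simulated data. Passing tests therefore
demonstrate the statistical machinery, not robustness to real alignment
noise.

**Conditioning on bulk feasibility.** With Mendelian sampling, a 129-plant
F2 contains ≥ 11 `ffss` plants with probability ≈ 0.18 only, and ≥ 60
single-branch qualifiers with probability ≈ 0.77. The emulated study, by
construction, had both bulks; `simulate_study` therefore redraws the
population until both bulks are feasible and reports the number of draws.
`select_bulks` itself is strict and raises, naming the deficit, when a
bulk cannot be filled.

## Scan

SNP-index is `alt/(ref+alt)`; zero-depth sites are *uncovered*, never
index 0. The exclusion rule drops a SNP only when **both** bulks fall
below 0.2: a one-bulk rule would delete exactly the SNPs that carry the
signal at a QTL where the reference-parent bulk is fixed (HB index ≈ 0).
The one-bulk alternative and a depth-weighted window mean are available
behind flags. Windows are half-open `[start, start+2 Mb)` on a 50 kb grid
anchored at 1 (1-based); a window keeps its retained-SNP count but has its
means flagged missing below 3 SNPs. Δ is SB − HB, so the expected signal
at a recessive-driver QTL is positive: the SB bulk (dominant-class plants,
1:2 homozygote:heterozygote) sits at frequency 2/3 while the HB bulk is
fixed at 0, giving Δ ≈ 2/3 before read noise.

## Null bands

Under no QTL, both bulks are random draws of plants, so bulk frequencies
at a locus are means of 1:2:1 dosages — for the 11-plant HB bulk this
dominates the variance (sd ≈ 0.11, against ≈ 0.02 of read noise per
40-SNP window). Each replicate draws **one** frequency pair per window
(complete linkage: SNPs 2 Mb apart in an F2 recombine ~4% of the time),
then per-SNP depths and binomial reads with the same error and the same
filter as the real scan; the window mean over retained SNPs is one null
draw, and band edges are the α/2 and 1−α/2 sample quantiles. Replicates
with every SNP filtered are redrawn and counted. Thresholds are matched
per window on (retained SNP count, per-bulk mean depth rounded to the
nearest integer) and cached by that key; the per-key RNG is derived from
the seed and the key, so results are independent of window order. For
Poisson depths the (depth, alt) pair is sampled as two independent
Poissons (`Poisson(λp)`, `Poisson(λ(1−p))`), exactly equivalent to Poisson
depth with binomial thinning but much faster when grouped by the discrete
bulk frequency. No normal approximation is used anywhere.

## Interval calling

A window is significant when its Δ lies outside its band (both directions
are called). Maximal same-direction runs become intervals; runs separated
by ≤ `max_gap` non-significant windows merge, runs shorter than
`min_run = 2` are dropped (an isolated window at a pointwise α is an
expected false positive). An interval spans first window start to last
window end, so bounds land on the 50 kb grid; BED output converts the
1-based half-open span to 0-based half-open.

**Known limitation — genome-wide specificity.** The bands are pointwise:
by construction ~5% of null windows exceed them, and because adjacent
windows share 39/40 of their SNPs and bulk frequencies stay correlated
over tens of Mb (the HB bulk is only 22 haplotypes), those exceedances
arrive in runs that `min_run = 2` does not remove. A genome-wide scan at
α = 0.05 therefore always shows some intervals on chromosomes with no
causal locus; distinguishing them from real QTL requires the magnitude
criterion (Δ well above the band, SB/HB indices near their fixed-bulk
expectations) rather than pointwise significance alone. A family-wise band
is deliberately out of scope.

## Segregation statistics

Pearson chi-square with expectations from the normalized ratio and no
continuity correction (the uncorrected statistic reproduces the printed
1.73 for 21:56:22 against 1:2:1); p from the upper χ² tail with
classes − 1 df. H² uses `V_E = (V_P1 + V_P2 + V_F1)/3` (the source the
study cites prints no formula; the `(V_P1+V_P2+2V_F1)/4` weighting is
available as an option), clamped to [0, 1]. PVE is the one-way R² of the
marker classes on log2(BN); BN is log2-transformed before every
variance-based statistic. Jonckheere-Terpstra sums Mann-Whitney counts
over ordered group pairs with ties counted ½; z uses the standard null
mean/variance without a tie correction, and an exact enumeration method is
provided for small samples. Branch-type bins are (≤1], (1,4], (4,16],
(16,64], (>64) on the plant median, with "highly branched" strictly
> 16.

## Consequence calls

Gene models are strand-aware (1-based inclusive exons, CDS span, 2 kb
promoter 5′ of the transcript start); SNPs classify into
upstream/exon_cds/exon_utr/intron/downstream, and CDS hits are translated
under the standard nuclear code (silent / missense / nonsense; a change
creating a stop is nonsense, one destroying the start codon is missense
with a warning). Only biallelic SNPs are handled; indels are out of
scope. Minus-strand variants are complemented before translation, so the
protein-level call matches the equivalent forward-strand gene.

## Numerical and reproducibility choices

* All randomness flows through `numpy` Generators seeded explicitly;
  stage seeds are spawned from the study seed, and identical seed +
  configuration reproduce byte-identical output files (version, config
  hash and seed are stamped in every header).
* Quantiles are plain sample quantiles (`numpy` linear interpolation);
  with 10,000 replicates the Monte-Carlo sd of the 97.5% band edge is
  ≈ 0.002 on a band of ≈ 0.24.
* Window statistics use prefix sums over position-sorted SNPs; unsorted
  input is rejected rather than silently sorted.
* Degenerate inputs raise: zero-depth SNP-index, empty bulks, zero F2
  variance, constant phenotypes, empty trend groups.

## Problem sizes in tests and the acceptance script

Unit and property tests run on two-chromosome genomes with a few hundred
markers; the end-to-end acceptance checks use the full default study
(129 plants, 15,640 SNPs) with 20 replicate pipelines for the recovery
rate, 5 replicates for the reported peak-window quantities, and 10,000
Monte-Carlo replicates per null band. These sizes were chosen so the whole
suite completes in minutes while keeping every Monte-Carlo standard error
well inside the asserted tolerances.
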