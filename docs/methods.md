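# Methods

This note documents the models, conventions and numerical choices behind
`methylandscape`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Coordinates, units and input handling

All internal coordinates are 0-based half-open (BED convention); 1-based
formats (Bismark cytosine reports, coverage files) are converted at I/O.
Methylation levels are fractions in [0, 1] everywhere inside the package
and become percentages only in presentation. Bases are handled
case-insensitively and soft-masked (lowercase) bases count normally toward
G/C content: repeat content is part of the G/C landscape, and no masking
rule is applied. Any non-ACGT character is treated as N.

Strand merging folds a minus-strand CpG record at 1-based position *p*
onto the plus-strand C at 0-based *p* − 2 and sums counts; merging
conserves total counts exactly. A minus record without a plus partner is
still folded (and counted), since the site itself is well defined. Only
CpG-context rows are used; non-CpG methylation is out of scope.

## Binning and usability filters

Autosomes are tiled into non-overlapping fixed-width bins (500 kb for
landscape work, 10 kb for domain calling). The terminal partial bin is
retained and flagged rather than dropped, keeping the tiling lossless;
whether it participates downstream is a filtering decision. Per-bin G/C is
computed over non-N bases only, because gap-heavy bins would otherwise get
spuriously low G/C. A bin's CpG count includes only dinucleotides fully
inside the bin.

Bin levels are count-weighted: level = Σmeth / Σ(meth + unmeth) over
qualifying sites, never the mean of per-site levels. The per-site depth
filter for bin levels defaults to the same depth ≥ 5 used for the global
level — one uniform rule rather than a hidden inconsistency — and is
configurable (use 1 for aggregated single-cell data, whose per-site depth
is intrinsically low).

Ranking and grouping operate on *usable* bins: covered CpGs ≥ 10,
N fraction ≤ 0.5, defined G/C, and not a partial terminal bin, by default.
These thresholds are logged per run (every filter reports its casualty
counts) and overridable; real megabase-scale analyses clearly used some
such exclusion (per-group bin counts imply it), but no published rule
exists, so the defaults are documented choices.

## Three-class profiling

The methylation score is the plain difference of mean bin levels,
mean(top-K G/C-rich) − mean(top-K A/T-rich), K = 1,000 at genome scale.
Classification uses the *sign* of the score: an inverted landscape
(Class III) requires strictly positive score; score ≤ 0 falls to Class I
when the global level is ≥ 0.5 and Class II otherwise. A global level of
exactly 0.5 (a measure-zero case) maps to Class I. The rank-sum test
comparing the two bin sets' methylation ranks is reported alongside but
does not drive the classification. G/C ties at the K-th boundary are
broken by (chrom, start) lexicographic order, making selection
deterministic across runs and platforms; under heavy ties the two sets are
taken from opposite ends of one sorted order and are always disjoint.

The two-sided Wilcoxon rank-sum p-value is exact (full enumeration of the
null distribution) whenever the smaller group has ≤ 25 observations and
the pooled data are tie-free, and otherwise uses the normal approximation
with tie and continuity correction; the method used is always reported.
The exact path is delegated to `scipy.stats.mannwhitneyu` and is verified
in the test suite against an independent exhaustive-permutation
enumeration for all group sizes up to 8.

## PMD/HMD calling

Each informative 10-kb bin (≥ 1 covered CpG by default) is compared with
the sample's global level: below → small PMD, above → small HMD; exact
equality is uninformative, since "below or above" leaves equality
undefined. Non-overlapping 10-kb tiling is used; the calculation is
defined operationally by the division into bins, and an overlapping
sliding window adds nothing at this grain. Maximal runs of same-state bins
are merged into domains. Up to 5 consecutive uninformative (uncovered)
bins inside a run are bridged — sparse data would otherwise shatter
domains — but an opposite-state bin always terminates the run, and domain
end-points are trimmed to informative bins. The size filter is strict:
only domains larger than 100 kb are kept, so a 100,000-bp run is
discarded. Domain mean levels are count-weighted over informative bins.

Globally almost-unmethylated samples (oocyte lineage; global level < 0.2)
trigger a warning rather than an exclusion: below-global calling is
meaningless near complete demethylation, but that is a policy judgement
left to the user.

## Dynamics and the nine groups

Usable 500-kb bins are sorted by G/C and cut into 12 contiguous equal-size
groups (group 1 = most A/T-rich); if the usable count is not divisible by
12, the remainder bins with the lowest covered-CpG counts are dropped
first and logged. Stage-to-stage change is summarised per group with
count-weighted stage means, and the most G/C-rich group's per-bin deltas
are tested against the most A/T-rich group's.

The susceptibility classification ranks the same usable bins twice: by
level in the globally hypomethylated stage (top tertile = demethylation-
resistant, DR) and by level in the globally remethylated stage (top
tertile = methylation-susceptible, MS; "methylation-sensitive" in running
text is the same label). Tertiles are exact — 1,600 bins each when 4,800
bins are usable — with ties at tertile boundaries broken by
(level, chrom, start) and counted. The nine groups are the cross product;
the summary mirrors per-group bin counts, stage levels, G/C content and
annotation overlaps.

Annotation overlap is the union coverage of each bin by an interval set,
as a fraction of bin width, with boolean flags at the 50/70/90/98 %
thresholds used for LAD/PMD/HMD summaries. Intervals beyond the binned
chromosome end are clipped with a warning. LAD annotations are consumed as
BED in the same assembly as the bins; coordinate liftover is upstream of
this package.

## Zygote reconstruction

Only CpGs with ≥ 4 reads in both gametes are used. Depth equalisation
defaults to deterministic proportional rescaling to d = min(depths) with
round-half-up (meth′ = ⌊meth·d/depth + 0.5⌋, unmeth′ = d − meth′),
reproducible without a seed; a seeded hypergeometric subsampling mode is
provided for fidelity to read-level downsampling. The combined site has
counts (sperm_meth′ + oocyte_meth′, 2d − Σmeth′), so at equal depths the
level is the mean of the two gamete levels. The operation is
species-agnostic.

## Synthetic data: what it emulates

The generator is a pure function of (config, seed); reruns are
bit-identical.

- **G/C landscape.** Per-500-kb-bin G/C is Beta-distributed with mean 0.42
  (the mouse autosomal 500-kb mean, ≈ 41.9 %) and sd 0.035, spatially
  autocorrelated through a Gaussian-copula AR(1) with ≈ 2 Mb correlation
  length, mimicking isochore-scale structure. Two tiers exist: explicit
  sequence (i.i.d. bases at the target G/C per bin, from which CpG
  positions and realized G/C are derived — CpG frequency then emerges
  ∝ gc²) for small-genome FASTA round-trips, and a sequence-free tier
  where the targets are truth and CpGs are Poisson-placed at rate
  mean_cpg_density · (gc/0.42)². The default density is 0.01/bp
  (≈ 1 CpG / 100 bp, the mammalian genome-wide rate); the 4,800-bin
  landscape configuration lowers it to 2 × 10⁻⁴ so site tables stay small
  while bin statistics remain stable (~100 CpGs per bin).
- **Class models.** Bin mean μ = clip(intercept + slope·gc + ε, 0.01,
  0.99) with ε ~ N(0, sd) drawn per bin on the level scale (sd chosen on
  the level scale for direct interpretability; default 0.02). Defaults:
  Class I (0.85, −0.3), Class II (0.35, −0.3), Class III (0.55, +0.3),
  giving globals ≈ 0.72 / 0.22 / 0.68 at mean G/C. Depth is negative
  binomial (mean 15, dispersion 0.3 — mid-range for public WGBS, which
  spans roughly 1–30×); methylated counts are binomial at the bin mean.
- **Injected domains.** Low-methylation intervals (default 20 per genome,
  150 kb–2 Mb on the 10-kb grid, level 0.3, ≥ 200 kb apart) override the
  site-level mean. The domain-recovery scenario uses a flat background
  (slope and landscape noise zero): it isolates the segmentation mechanics
  of the caller, while landscape drift is exercised by the classification
  scenarios. ~9 % PMD coverage is a conservative load relative to real
  PMD-rich methylomes.
- **Stage pairs.** A latent lamina-proximity variable L = −standardised
  G/C + N(0, 0.5) couples the two stages: hypomethylated-stage mean
  0.30 + 0.12·L, remethylated-stage mean 0.70 − 0.12·L. A/T-rich,
  lamina-proximal bins thus resist both demethylation and remethylation,
  reproducing the expectation that the doubly-resistant (DR-MR) group is
  the most A/T-rich. Truth tertiles come from the noiseless means.
- **Gametes.** Independent counts per gamete at constant levels (defaults
  0.85 sperm, 0.40 oocyte); a configurable fraction of sites can be forced
  below 4 reads to exercise the zygote depth filter.

**What passing tests do not show.** The generator has no read-level
artefacts (bisulfite conversion failure, mapping bias, PCR duplicates), no
batch effects between samples, no CpG islands or fine-scale regulatory
structure, no sex chromosomes, and binomial (not beta-binomial) site-level
sampling within bins. Recovery results therefore validate the estimators
and segmentation logic under the stated statistical structure, not
robustness to real-world artefacts upstream of per-CpG calls.

## Problem sizes

Desk-scale analyses use 4 × 60 Mb genomes (480 bins of 500 kb, 24,000 of
10 kb, ~2.4 M CpGs) so that 12 G/C groups × 40 bins exist; genome-scale
group arithmetic (12 × 400 bins, tertiles of 1,600) runs on an 8 × 300 Mb
landscape at reduced CpG density. The acceptance script uses 60 methylomes
for class recovery, 20 seeds × 20 domains for PMD recovery, and 200
random inputs over all group sizes ≤ 8 for the exact-test oracle.

## Known limitations

- The usable-bin filter behind published bin counts is not recoverable
  from any stated rule; exact printed N values (e.g. per-chromosome bin
  counts) are reproduced only qualitatively.
- The domain caller is thresholding + run-merging by design; it will
  fragment domains in very sparse data beyond what bridging absorbs, and
  no HMM/ML caller is provided.
- `filter_acg_tcg` looks up the preceding base per site in Python; it is
  adequate for NOMe-type subsets but not optimised for whole-genome use.
- Exact rank-sum p-values require tie-free data; bin levels from finite
  counts can tie, in which case the corrected normal approximation is used
  (and reported).
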