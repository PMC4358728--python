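# Methods

This note records the models implemented in `soysweep`, the parameters
that matter, and the design decisions taken where the methodology was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model

Genotypes are diploid codes per sample × biallelic SNV
(0 hom-ref, 1 het, 2 hom-alt, −1 missing), 1-based coordinates internally
(VCF convention), 0-based half-open in every exported interval (BED
convention). Populations are `wild`, `landrace`, `elite`;
`cultivated = landrace ∪ elite`. Allele counts at a site use non-missing
diploids only, two alleles each; the package takes no position on why a
call is missing.

Consensus genotypes come from per-genotype likelihood triples: each
individual receives the arg-max genotype, ties broken toward the lowest
code (counted and logged), all-zero triples set missing and flagged. Under
the read model below, ties are essentially confined to zero-depth sites.

## Diversity statistics

Per window of span `L` (20 kb, stepped by 2 kb; terminal partial windows
are dropped so Z scores compare like with like; a chromosome shorter than
one window becomes a single whole-chromosome window):

- θπ sums the unbiased per-site heterozygosity `n/(n−1)·2p(1−p)` over
  segregating sites and divides by `L`. Each site uses its own allele
  count `n`, so missingness is handled per site.
- θw is `S/(a₁·L)` with `a₁` evaluated at the window's **median** haploid
  `n`; Tajima's D uses the same median-`n` constants on window totals.
  Median-`n` is a pragmatic choice for variable missingness; with the
  generator's complete matrices it is exact.
- Dividing by the full span rather than the callable length matches the
  per-nucleotide framing of published window diversities; a
  `callable_span` argument provides the alternative normalisation.
- Tajima's D is undefined (NaN, excluded from scans) when `S = 0` or
  `n < 4`.

SNV accumulation (rarefaction) counts, for each subset size `k`, the sites
at which at least one sampled accession carries the alternate allele —
discovery against a reference; subsets are drawn uniformly, or enumerated
exhaustively when requested. At `k = n` the count is exact and
seed-independent. The site-frequency spectrum treats the alternate allele
as derived (reference ≈ ancestral); this is an approximation, and a folded
variant is provided.

## Sweep scans

**Domestication.** Per window: `log((θπ_cult + δ)/(θπ_wild + δ))` with
pseudocount `δ = 10⁻⁵` (raw ratios are heavily right-skewed; the log
restores near-symmetry), and cultivated Tajima's D. Both are standardized
genome-wide and converted to lower-tail normal P; a window is selected
when both P < α (default 0.05). A configurable exclusion list drops
designated samples before grouping.

**Improvement.** Per window, Hudson (1992) F_ST as a ratio of per-site
numerator/denominator sums for the three population pairs, branch lengths
`T = −ln(1−F_ST)` (F_ST clamped to [0, 1−10⁻⁶]), and
`PBS_elite = (T_EL + T_EW − T_LW)/2`. Upper-tail P from the standardized
PBS is Bonferroni-corrected by the number of defined windows; selection
threshold corrected P < 0.001. With this implementation "corrected P <
0.001" and "raw P < 0.001/N" coincide. Overlapping windows make the
correction conservative. The Hudson estimator is the default because it is
robust to unequal sample sizes; Weir & Cockerham (1984) is available via
`estimator="weir_cockerham"`. Note the unbiased Hudson estimator is
slightly negative for identical finite samples; negative window averages
are clamped to zero before the PBS transform.

**Standardization.** Z scores use the median and the normal-consistent MAD
(1.4826 · median absolute deviation) over defined windows, not the plain
mean/sd. On a genome where selected regions are a small fraction of
windows the two coincide; on the deliberately small test genomes used
here, sweep windows are a non-negligible share and inflate the plain
moments with exactly the outliers the scan must find, de-calibrating the
test. Robust centring keeps the null calibration (verified by the
null-simulation tests) while leaving sweep z-scores interpretable.
`robust=False` restores plain moments. Scans refuse to run with fewer than
50 defined windows.

Selected windows merge when overlapping or book-ended; regions report
window count and minimum P. Diversity loss across the series is summarized
relative to the wild baseline: retention `100·θπ_cult/θπ_wild`, reduction
`100·(θπ_wild−θπ_land)/θπ_wild` in domestication and
`100·(θπ_land−θπ_elite)/θπ_wild` in improvement, so the two reductions
telescope to the total loss.

## Fixation screening

A locus is fixed in a group when every member has the *same genotype code*
(not necessarily homozygous — a uniform-heterozygote group is counted but
flagged as biologically implausible) while the comparison group shows at
least two codes. Screening requires a complete consensus matrix; the
pipeline drops sites with residual missing calls (counted). Strict
uniformity is fragile under read noise: at 10× mean depth a single
miscalled individual among ~40 un-fixes a locus, and the tests document
that a clear majority — not all — of injected fixations survive the
likelihood → consensus round trip.

Coding effects are classified on the longest-CDS transcript per gene
(per-transcript mode available): the spliced CDS is assembled from the
GFF3 segments in transcription order (reverse-complemented on minus
strand, first-segment phase honoured, junction-spanning codons assembled
across segments), the affected codon is translated with the standard
nuclear code for reference and alternate alleles, and the site is labelled
synonymous/nonsynonymous, noncoding outside every CDS, or unclassified
when the model is malformed (CDS length not divisible by 3, logged) or the
genome base contradicts the REF allele.

## Population structure

PCA centres each site by its mean genotype and scales by `√(p̄(1−p̄))`
(Patterson normalization), mean-imputes missing calls, and
eigendecomposes the sample covariance; signs follow a deterministic
convention. The scale factor depends on the site mean, so only the
unscaled variant (`scale=False`) is exactly invariant to shifting a
site's coding by a constant.

The tree uses allele-sharing distance (mean `|gᵢ−gⱼ|/2` over co-genotyped
sites; raw mismatch proportion behind a flag) and Saitou–Nei neighbor
joining with the Q criterion, ties broken toward the lowest index pair.
Negative branch lengths are retained and flagged rather than clamped,
preserving exact inversion of additive matrices. Bootstrap support
resamples sites with replacement and reports, for each internal
bipartition of the full-data tree, the fraction of replicate trees
containing it; the default is 1,000 replicates, and the pipeline's default
run uses a scaled-down 100.

## QTL narrowing and enrichment

QTLs qualify against sweep regions that carry at least one fixation locus
(all regions behind a flag); each QTL's retained footprint is the union of
its intersections, and summary totals use interval unions so overlapping
QTLs are not double counted. Genes are assigned to intervals by any
overlap of the gene span. Enrichment uses the one-sided hypergeometric
tail, a permutation test drawing gene sets of the observed size uniformly
from the background (gene length is ignored — a documented limitation),
empirical P `(1 + #{k* ≥ k})/(reps + 1)`, and Benjamini–Hochberg step-up
q-values. The enrichment background is a required explicit input; the
package takes no default gene universe.

## Synthetic data generator

The generator reproduces the quantities the analyses consume rather than
simulating forward in time:

- **Neutral background.** The number of sites at derived count `i` in an
  ancestral pool of `K = 2000` haplotypes is Poisson(θ·L/i) — the
  infinite-sites neutral expectation — so the realized wild θπ converges
  on θ per site and the sample SFS is ∝ 1/i. `K` is large enough that the
  finite-pool distortion of the sample spectrum is below sampling noise
  at the scales tested.
- **Bottlenecks.** Each transition resamples site frequencies through a
  binomial founder pool. Integer pool sizes `B` give heterozygosity
  retention `1−1/B` only at discrete values, so two adjacent sizes are
  mixed per site with weights solving `E[1/B] = 1 − retention`, hitting
  any retention in (0,1] in expectation.
- **Sweeps.** Inside a swept interval the population fixes a beneficial
  haplotype: one ancestral draw `h ~ Bernoulli(p)` per site, with the
  alternate allele at the site nearest the interval centre (the selected
  mutation). Hitchhiking decays linearly over a flank of half the
  interval width: flank frequencies become `(1−scale)·h + scale·p`. This
  produces both signatures a sweep leaves — diversity loss ramping to
  zero at the core, and allele-frequency divergence from the unswept
  populations — the latter being what the PBS scan detects; an earlier
  variant that only shrank flank heterozygosity toward each site's major
  allele leaves no divergence and is not representable as a haplotype
  history. Domestication sweeps act on the landrace founders (elite
  inherits through its own bottleneck); improvement sweeps act on elite
  after its resampling. Ground truth records each injected interval and
  every in-region site forced to exact fixation whose realized wild
  sample is polymorphic.
- **Read model.** Depth ~ Poisson(10), alternate-read count binomial with
  error 0.01 (hom-ref), 0.5 (het), 0.99 (hom-alt); likelihoods are the
  three binomial densities. These defaults mimic low-coverage
  resequencing.
- **Defaults.** 31/15/24 samples, θ = 0.0038 per site, retentions 0.625
  (domestication) and 0.867 (improvement) — the sample design and
  diversity series of the resequencing panels this generator emulates.
  The generator exposes retention fractions rather than effective sizes;
  this is a modelling stand-in, since the real populations' Nₑ is not
  identifiable from the quantities reproduced here.

**What passing tests do and do not show.** The generator has no linkage
disequilibrium (sites are exchangeable given their frequencies), no gene
flow between populations, no missing genotypes, and i.i.d. read depth.
Passing recovery tests therefore demonstrates the statistics and their
calibration under the stated frequency model — not robustness to LD,
admixture (which the source populations show), reference bias, or
structured missingness in real resequencing data. Genome-scale census
numbers (total SNV counts, Mb under selection in a ~1 Gb genome) require
the real data and are out of reach of these fixtures by design.

## Problem sizes

Tests and the acceptance script run on 0.1–2 Mb toy genomes
(≈2,000–40,000 SNVs), 20-seed Monte-Carlo batteries for stochastic
claims, 100-replicate bootstraps and 10⁴-replicate permutations — sizes
chosen so the full battery completes in minutes on a single core while
every estimator is still exercised against an independent oracle at
10⁻⁹–10⁻¹² tolerances.

## Known limitations

- Fixation screening inherits the strictness of genotype-identity
  uniformity; real pipelines typically add depth/quality calibration
  upstream, which this package deliberately leaves out of scope.
- The rarefaction "detection" rule (≥1 alternate carrier) is one of
  several reasonable definitions; it matches discovery against a
  reference.
- Bonferroni over stepped, overlapping windows is conservative.
- Permutation enrichment ignores gene length and category overlap
  structure.
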