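# Methods

## Lineage model

The package models a diploid, strictly clonal lineage reproducing by
central-fusion automixis. Each generation a single offspring inherits
its parent's genome modified by three processes:

* **De novo point mutations.** The count per generation is
  Poisson(2 μ G): μ is the per-site mutation rate per haploid genome per
  generation, G the haploid genome size, and the factor 2 counts the two
  genome copies at risk in a diploid. New mutations are placed uniformly
  (chromosome chosen proportional to length) at previously
  non-segregating positions and create a heterozygous genotype in the
  carrier; the alternate allele is drawn uniformly from the three
  non-reference bases.
* **Gene conversion.** Tract count per generation is
  Poisson(`conversion_rate`); tract lengths are geometric with mean
  `conversion_tract_mean` (default 300 bp), truncated at 999 bp so that
  conversion tracts stay in the sub-kilobase class that separates them
  from segmental events. Heterozygous sites inside a tract collapse to
  one allele.
* **Crossover-induced segmental LOH.** Crossovers are
  Poisson(`crossover_rate`) per chromosome with uniform positions. Under
  central fusion, each crossover independently renders all loci distal
  to it homozygous with probability 1/2 (one of the two segregation
  outcomes); the centromere is fixed at position 0 of every chromosome,
  so "distal" means toward the chromosome end. This reproduces the
  qualitative LOH geometry of central fusion without a full meiosis
  model; whether multiple crossovers per arm occur in any particular
  organism is left to `crossover_rate`, about which the simulator makes
  no biological claim.

Because founder haplotypes are not phased, the allele retained at each
homozygosed site is drawn independently per site; this is equivalent to
choosing a haplotype when only genotype classes are observed downstream.
Every planted event is logged with exact 0-based half-open coordinates
in a truth ledger (TSV), the oracle for all recovery tests.

## Depth emission

Read depth per site per sample is negative-binomial with mean
`mean_depth` (default 35, the target coverage of a typical resequencing
design) and variance m + d·m²; `depth_dispersion` d = 0 emits the
constant rounded mean (a deliberate degenerate case — the NB limit d→0
is Poisson, but a noiseless emission is more useful for exact tests).
The default d = 0.01 gives the mildly super-Poisson spread observed at
well-mapped sites in modern PCR-free libraries. Grossly over-depth sites
in real data arise from collapsed duplications and other mapping
artifacts, which this emission deliberately does not model — they are
exactly what the hard filter removes. Hemizygous deletions multiply the
expected depth by 0.5 for the affected samples.

## Filtering and normalization

Sites with any missing genotype are removed, as are sites where any
sample's depth is **greater than or equal to** twice the global median
depth. The doubling threshold uses one global median over all retained
genotype depths (a single realized cutoff is reported), while depth
*normalization* divides each sample's depths by that sample's own median
— per-sample medians are what differ when libraries are loaded at
slightly different concentrations. The threshold is computed before any
removal. Filtering realistic (unimodal) depth data is idempotent in
practice, but a second pass is not guaranteed to be a no-op for
arbitrary depth distributions, since removing the upper tail can shift
the median.

## Event detection and classification

A distinguishing site requires all focal samples to share a genotype
class that no reference sample carries; references may be polymorphic
among themselves. Classification: each focal-heterozygous site is one
point mutation; consecutive focal-homozygous sites at most `merge_gap`
(default 1,000 bp) apart merge into one LOH event, with the run broken
by any intervening heterozygous distinguishing site (the spanned
interval is then demonstrably not LOH throughout, and breaking keeps
events disjoint). Merged events with span at most `segmental_span`
(default 10,000 bp) are gene-conversion tracts; larger ones are
segmental LOH. The 10 kbp split is a configurable default chosen midway
(in log scale) between the sub-kilobase conversion class and
chromosome-scale events; no natural event falls near it in either the
simulator or the motivating data regime.

Chromosome-scale LOH is localized *before* the merge step, from the
positions where focal genotypes transition between heterozygous and
homozygous: over informative sites (heterozygous in all
reference-sister samples, falling back to all references), every
maximal focal-homozygous run with span above `segmental_span` becomes a
segmental event. Its **inner** bound is the first/last homozygous
informative site and its **outer** bound the adjacent flanking
heterozygous informative sites (or chromosome ends), so the true
breakpoint lies between inner and outer; the inner span is the headline
figure. Excising these runs first matters because informative-site
spacing is roughly exponential: at density 10⁻³/bp a fraction e⁻¹ ≈ 37%
of adjacent gaps exceed the 1 kbp merge gap, and a multi-Mbp run would
otherwise fragment into hundreds of spurious short events.

Copy-number status is assigned to segmental events only: the mean focal
normalized depth over the interval divided by the mean reference
normalized depth falls in the neutral band (0.85–1.15 → copy-neutral) or
the deletion band (0.35–0.65 → deletion-like), else the event is flagged
untested. The bands separate the two regimes with wide margins at ≥30×
coverage and a few hundred supporting SNPs; they are not meaningful for
single-SNP intervals, which is why conversion tracts are left untested.

The generations-since-origin estimate is n/(2 μ G) for n de novo point
mutations, with a 95% Poisson likelihood-ratio interval on the mean
(deviance ≤ χ²₁(0.95)); at n = 0 the lower bound is 0 and the upper
bound χ²₁(0.95)/2 on the count scale.

## Windows, profiles, alignment export

Windows (default 250 kbp) tile each chromosome without overlap; the
trailing partial window is retained and flagged. Relative
heterozygosity is the fraction of sister-clade-heterozygous sites in a
window that are heterozygous in all focal samples; windows with no
informative sites are undefined (NaN), never zero-filled, because
absence of informative sites means the reference clade itself is
homozygous there. "Heterozygous in the sister clade" defaults to the
strict intersection (all sister samples), using the clade's shared
ancestral heterozygosity as the denominator; `sister_mode="any"` is
available.

Chromosome profiles use element-level mutual exclusion: any TE element
overlapping any exon element is dropped entirely, and vice versa, before
per-chromosome merging; proportions divide merged occupancy by the
ungapped length (chromosome length minus assembly-gap runs). Structural
variants shorter than 50 bp are dropped and survivors merged, so
overlapping records are deduplicated by default. Element-level (rather
than base-level) exclusion is the primary mode because the feature sets
come from independent annotators and an overlapping pair is more likely
one mislabelled element than a genuine composite.

Alignment export writes one IUPAC symbol per sample per fully called
site (hom-ref → ref base, hom-alt → alt base, het → two-base ambiguity
code). The pairwise divergence matrix scores symbols sharing exactly one
allele as 0.5 and disjoint symbols as 1; it is a sanity companion for
external maximum-likelihood tree inference, not a substitute for it.

## Morphometrics

Traits are scaled linearly to [0, 1] within each species (min → 0,
max → 1); a trait constant within a species is set to 0 with a warning.
PCA runs on the covariance of the normalized traits with no further
standardization, since normalization already equalizes ranges. Size
matching removes one individual per step — the group whose mean deviates
more from the pooled mean loses its extreme (largest if its mean is
above the pooled mean, smallest otherwise); exact ties alternate
starting with the larger-mean group — re-testing after each removal
(Welch t-test by default, Mann-Whitney behind the `test` flag) and
stopping once p ≥ α (default 0.05). The procedure is deterministic given
the inputs and test choice and can only ever remove extremes.

## What the simulator does and does not emulate

Emulated: founder heterozygosity at configurable density, the three
mutational processes with exact truth coordinates, clonal sharing of
events within the focal clade, depth with copy-number signal, VCF/TSV
round-tripping. Not emulated: mapping artifacts (mis-mapped duplicated
loci that leave residual apparent heterozygosity inside real LOH
tracts), missing genotypes, indels, sequencing error in genotype calls,
within-reference-clade polymorphism (references are exact founder
copies), read-level data, selection, or population dynamics. Passing
recovery tests therefore demonstrates correctness of the inference
logic under clean genotypes, not robustness to artifact-heavy real
call sets — on real data the hard filter and the reported raw window
values are the guards, and residual-heterozygosity smoothing is left to
the user.

## Problem sizes and determinism

The test suite and the acceptance script use a 20 Mbp, 5-chromosome
planted cohort (2 focal + 15 reference samples, founder het density
10⁻³, 9 de novo SNPs, 19 conversion tracts, one 2.25 Mbp segmental LOH
and one 0.5 Mbp half-depth deletion control) and a 1,000-generation
Monte-Carlo calibration at μ = 3.5 × 10⁻⁹, G = 224 Mbp — sizes chosen so
the full suite runs in seconds on one core while leaving every statistic
well-resolved (the planted cohort yields ~20,000 SNPs; 3-standard-error
bands are used for all Monte-Carlo comparisons). In the planted design,
events are separated by at least 20 kbp and conversion tracts are placed
over at least one founder-heterozygous site, since a tract covering no
heterozygous site is undetectable in principle. All randomness flows
from a single integer seed through `numpy.random.default_rng`; a fixed
seed gives byte-identical VCF, truth ledger, and pipeline outputs.

## Known limitations

Multi-allelic records are excluded rather than split (two-haplotype
clonal samples rarely produce genuine triallelic SNPs). The centromere
is fixed at position 0, so simulated segmental LOH always reaches the
chromosome end. Boundary localization reports inner/outer brackets
rather than a point breakpoint; with informative-site spacing s the
inner span underestimates the true tract by ~2/s on average. The
enrichment test exposes its 2×2 table explicitly rather than deciding
what counts as a variant-gene association.
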