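# Methods

## The mapping model

A pooled-segregant experiment measures, at every parent-differentiating
SNP, how many sequencing reads from a pool of haploid F1 segregants
carry each parent's allele. Under Mendelian segregation without linkage
the expected parent-A fraction is 0.5 at every site; truncation
selection on a trait drags the favoured parent's allele frequency
towards 1 around each causative locus, decaying with genetic distance
through recombination. `bsaqtl` models that chain end to end.

### Cross simulation (`bsaqtl.cross`)

**Meiosis.** Crossovers per chromosome are Poisson with mean equal to
the chromosome's genetic length in Morgans, positions uniform on the
genetic map, starting parent a fair coin — the Haldane no-interference
model. Crossover interference is deliberately not modelled: it sharpens
local crossover spacing but has negligible effect on pool allele
frequencies at the scales mapped here.

**Phenotypes.** Trait value = baseline × Π(1 + eᵢ·Iᵢ) × ε, with Iᵢ = 1
when the segregant carries the favoured allele at QTL *i*. The
multiplicative rule (additive on the log scale) is the default because
allele effects in this kind of experiment are reported as percentages
of strain-specific baselines; an additive-on-level rule is available.
ε is log-normal with unit mean and coefficient of variation
`noise_cv`. The model's per-QTL dominance flag is carried for
completeness but does not enter the haploid simulation — F1 segregants
of this cross carry one allele each.

**Default study conditions.** 574 segregants; 24-member superior
(truncation-selected) and random pools; four planted QTLs, two per
parent, with fractional effects 0.25–0.40 matching the measured allele
effects of the motivating experiment (TOR1 ≈ 35–40 %, FAS2 ≈ 25–30 %);
baseline 1.7 ppm (the inferior-parent production level); `noise_cv` =
0.15, a mid-range repeatability for end-of-fermentation headspace
GC-FID measurements. The test-scale genome is 4 chromosomes × 500 kb,
one SNP per 2 kb, 1 Morgan per chromosome; a 16-chromosome yeast-scale
map (`GenomeMap.full_yeast`) with physical lengths of the S288c
karyotype and ≈0.33 cM/kb is available by configuration.

**Pool sequencing.** Per-site depth ~ Poisson(coverage); parent-A reads
~ Binomial(depth, f) with f the true pool allele fraction. A
beta-binomial option (intraclass correlation ρ) emulates unequal DNA
contributions of pool members, which inflates frequency variance the
way real random pools do. No read-level simulation (FASTQ, base
quality, alignment) is attempted: the analysis consumes allele depths,
so the binomial sampling layer is the part of the noise process that
matters for the statistics downstream.

### Filters and frequency track (`bsaqtl.poolfreq`)

Sites are kept when depth ≥ 20 (configurable) and the two parents carry
distinct alleles; parent-identical sites (parent-vs-reference SNPs,
not cross markers) are dropped and counted. Coordinates are 1-based
inclusive throughout, converted to 0-based half-open only on BED
output. Sites covered adequately in one pool only are excluded from
two-pool contrasts but retained for one-pool tests, maximizing usable
sites per test.

### Linkage tests (`bsaqtl.linkage`)

*Versus 0.5*: exact two-sided binomial on the parent-A read count,
minlike convention — P = Σ over outcomes whose point probability does
not exceed the observed one (with the standard 1 + 1e-7 relative
guard). At p₀ = 0.5 this equals doubling the smaller tail capped at 1,
and it reproduces the fine-mapping worked values exactly
(22/24 → 3.588 × 10⁻⁵, 19/24 → 6.611 × 10⁻³, 20/24 → 1.544 × 10⁻³).

*Versus the random pool*: two-sided Fisher exact test on the 2×2 table
of A/B counts in the two pools. A degenerate margin returns P = 1 by
convention. This contrast absorbs pool-composition noise that the 0.5
reference cannot (below).

*Smoothing*: a discrete-state HMM — 51 equally spaced latent frequency
levels on [0, 1], binomial emissions in the observed counts, and a
transition kernel that keeps the current state with probability
exp(−d/L) (d = inter-SNP distance, L = 20 kb default) and otherwise
redraws uniformly. Forward–backward posterior means give the smoothed
frequency; the smoothed P-value converts that mean back to an
equivalent count k* = round(f̂ · depth) and applies the exact binomial.
This operational definition anchors the smoothed track to the same
reproducible statistic used in fine mapping; it is *not* a
bit-compatible reimplementation of any published smoother. L → 0
degenerates to the raw per-site maximum-likelihood frequency. A
depth-weighted Nadaraya–Watson kernel smoother is available as an
alternative.

*QTL calls*: maximal runs of consecutive sites with smoothed P < 0.05
and consistent direction (frequency on one side of 0.5); same-direction
runs separated by < 20 kb are merged; merged runs with fewer than 5
significant sites are discarded (suppressing isolated noise peaks).
The peak is the site of minimum P, ties leftmost. No multiple-testing
correction by default, matching the raw P < 0.05 convention of the
experimental protocol; a Bonferroni option exists.

### Fine mapping (`bsaqtl.finemap`)

Markers spaced 5–15 kb across a called QTL are scored in each superior
segregant individually (experimentally by allele-specific PCR;
simulated by reading haplotypes with an independent per-call dropout).
Missing calls reduce n rather than being imputed, keeping the binomial
exact. The refined interval is the contiguous run of significant
markers containing the best marker — contiguity rather than a fixed
drop-from-peak rule, because significance is the quantity the
experiment actually thresholds.

**Resolution.** With 24 segregants and recombination rate r per bp, the
expected spacing of informative breakpoints near the QTL is
1/(24·r) per flank — ≈21 kb at the test scale (2 × 10⁻⁶ Morgan/bp). The
localisation test therefore asserts that the best marker falls within
30 kb (≈1.5× the per-flank breakpoint spacing) of the planted locus in
≥80 % of seeds; demanding much tighter localisation from 24 meioses is
not statistically possible regardless of effect size, as the best
marker sits on a likelihood plateau whose width is set by
recombination, not by read sampling.

### Null calibration and the random-pool problem

A genuinely unselected *finite* pool is not a clean null for the vs-0.5
test: 24 haploid genomes give the true pool frequency a per-site
standard deviation of √(0.25/24) ≈ 0.10, autocorrelated along
chromosomes in haplotype blocks. At depth ≥ 50 this composition
variance dominates read-sampling noise and produces sustained, real
deviations from 0.5 — the well-known "large variation in the random
pool" of small-pool experiments, and the reason the pipeline also
tests superior against random pool directly. The type-I calibration of
the *test itself* is therefore measured on a composition-balanced pool
(true f = 0.5 at every site), where the exact test's rejection rate at
α = 0.05 is ≈0.037 over 12 000 sites at depth ~100 — conservative, as
exact tests on discrete counts are. For the same reason,
selection-disabled end-to-end runs pool the entire segregant
population (composition sd ≈ 0.021), under which the scan calls no
QTLs.

### Allele comparison (`bsaqtl.alleles`)

Residue panels are compared position-wise between parents (nonsense
whenever either residue is a stop), and each parental residue is
scanned for uniqueness against all non-parent rows. Blank and 'X'
cells are missing data and never count as occurrences — a panel built
from heterogeneous genome assemblies has genuinely undetermined cells,
and treating them as absences would manufacture uniqueness. Protein
positions are 1-based. `translate_and_diff` builds the same comparison
from aligned in-frame coding sequences (standard genetic code,
translation continuing through internal stops so downstream codons are
still reported; synonymous changes counted separately).

### Edit design (`bsaqtl.editdesign`)

PAM is fixed to NGG (SpCas9); the discrimination region is the PAM plus
the 8 nt immediately 5′ of it on the protospacer strand — the seed
region dominating Cas9 specificity. A guide is allele-specific when a
parent-differing SNP falls in that region; a SNP that breaks the NGG
outright in the non-target parent is flagged as the strongest case.
SNPs inside the PAM that leave NGG intact still count as
discriminating but carry the weaker flag, and because a SNP differs on
both strands no strand restriction is imposed. Off-target scanning is
exhaustive: every genomic 20-mer on either strand within Hamming
distance 3 (unweighted, per the protocol's "three or fewer" rule)
followed by NGG, vectorised but verified against a quadratic reference
scan. Donors: point-mutation oligos are recipient sequence with the
single edited base centred between equal arms (35 bp default → 71 nt);
block-replacement donors carry the donor parent's block with the
largest available arms in 500–800 bp, cut in by two guides flanking
the block. Block length = end − start + 1 (1-based inclusive, the
convention of the block coordinate table).

## What the simulator does and does not show

Passing tests on synthetic crosses demonstrate that the statistical
machinery — selection response at linked markers, exact tests,
smoothing, calling, fine-mapping localisation — behaves correctly
under the binomial/Poisson sampling model with known truth. They do
not validate behaviour under alignment artefacts, reference bias,
copy-number variation, segregation distortion, or non-uniform
recombination landscapes, none of which the generator emulates. The
worked-example fixtures (residue panels, block coordinates, the 71-nt
donor) exercise the deterministic components on real published inputs.

## Numerical choices and problem sizes

Exact binomial P-values are computed by direct pmf summation (O(n) per
site, n = read depth); Fisher exact tests delegate to
`scipy.stats.fisher_exact`. HMM smoothing scales per-site emissions to
dodge underflow and clips probabilities at 1e-300. Tie-breaks are
leftmost throughout (peak sites, best markers, pool selection by id).
Degenerate inputs fail loudly: zero-depth sites in a frequency track,
n = 0 binomials, regions too short for a guide, donors with
insufficient flank.

Simulation-based checks use the 4 × 500 kb test genome with 574
segregants: 50 seeds for planted-QTL recovery, 100 seeds for
fine-mapping power, 12 000 sites for null calibration — sizes at which
every property under test has stabilised while the whole suite runs in
well under a minute. All randomness flows from explicit seeds through
`numpy.random.Generator`; identical seeds reproduce byte-identical
artifacts (checksummed in each run manifest).

## Known limitations

- Haploid crosses only; no diploid segregants, hence the dominance
  flag is descriptive.
- SNP markers only — indels and structural variants are out of scope,
  and parent haplotypes given to the edit designer must be
  equal-coordinate (SNP-only) alignments.
- The HMM smoother is a generic re-implementation of the smoothing
  *role*, not of any specific published algorithm; smoothed P-values
  are defined operationally via the equivalent-count construction.
- Guide design applies specificity rules only; cutting-efficiency
  scores (position-weighted mismatch models, chromatin) are not
  modelled.
- Variant calling, read alignment, and genotype likelihoods are
  upstream of this package: it starts from allelic depths.
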