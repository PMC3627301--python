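# Methods

`zfpg` implements a population-genomic workflow for wild and laboratory
zebrafish data: within-population diversity for SNPs and mtDNA,
among-population differentiation, F_ST outlier detection against a
hierarchical island-model coalescent null, and post-hoc genome scans for
selective-sweep signatures. This note records the models, estimators,
numerical choices and their limitations.

## Data model

Biallelic SNP genotypes are alt-allele counts (0/1/2, −1 missing) in a
samples × loci matrix with a sample→population map and an optional
population→group map (`popio.GenotypeDataset`). Coordinates are VCF-style
1-based; every window and bin downstream is a half-open interval
[start, end) in basepairs, tiled from position 1 per chromosome with the
partial terminal bin kept. mtDNA data are pre-aligned sequences with
population labels. Missing genotypes are excluded locus-wise from every
frequency computation; nothing is imputed.

## Filters

The standard locus filter removes fixed loci and loci with pooled
minor-allele frequency below 1%, computed over all samples together
(wild populations and laboratory strains pooled). LD pruning scans
same-chromosome pairs in (chrom, pos, pos) order and removes one member
of any pair with r² > 0.5, chosen by a fair coin from a seeded stream,
so the surviving set is reproducible. The outlier analysis runs on the
MAF-filtered but *unpruned* set (pruning could discard the very loci the
scan is looking for); the differentiation estimates run on the pruned
set with significant outliers removed.

## Diversity

Per-locus expected heterozygosity is the unbiased estimator
He = (2n/(2n−1))(1 − p² − q²); a population's H_S is the mean over all
retained loci, zeros included (the treatment of monomorphic loci matters
for absolute comparisons and is fixed here as "included"). Hardy–Weinberg
proportions are tested with the exact conditional (Levene) test: the
two-sided P-value sums the probabilities of all heterozygote counts, given
the allele counts, that are no more probable than the observed count.
The laboratory-versus-wild comparison of mean H_S is an equal-variance
pooled two-sample t with df = nA + nB − 2 and an upper-tail one-sided P.

mtDNA summaries use complete deletion (columns containing a gap or
ambiguity in any included sequence are dropped): segregating sites S,
haplotype diversity h = (n/(n−1))(1 − Σ f_i²), nucleotide diversity π as
the mean pairwise p-distance. Net divergence Da = dXY − (dX + dY)/2 uses
the plug-in (frequency-weighted, n² denominator) within-population mean
distance, which makes Da exactly zero when two samples share a
composition. Distances are uncorrected p-distances or Tamura–Nei (TN93)
with distinct purine/pyrimidine transition rates and base frequencies
estimated from the alignment; the invariant-sites extension (+I) is not
implemented — it belongs to substitution-model fitting, which is out of
scope, so TN93 distances here are mild underestimates for strongly
rate-heterogeneous data. TN93 saturation (a log argument ≤ 0) raises an
error naming the pair.

AMOVA takes a squared pairwise distance matrix and a fixed two-level
grouping and returns Excoffier-style variance components σa (among
groups), σb (among populations within groups), σc (within populations),
with Φ_CT = σa/σ, Φ_SC = σb/(σb+σc), Φ_ST = (σa+σb)/σ. Permutation
schemes: Φ_SC permutes sequences among populations within groups, Φ_CT
permutes whole populations among groups, Φ_ST permutes sequences freely.
P-values use the add-one rule (1 + #{perm ≥ obs})/(1 + n_perm), so they
are never zero. Groups containing a single population are allowed and
contribute no within-group component. All-zero distance matrices return
Φ = 0 with a degenerate flag.

## Differentiation

Weir–Cockerham variance components a, b, c are computed per biallelic
locus; the multilocus estimate is the ratio of sums Σa/Σ(a+b+c).
Negative per-locus components are kept (truncation would bias the
multilocus combination). The 95% CI bootstraps loci (percentile);
pairwise P-values permute individuals between the two populations.
Jost's D_est uses the Nei–Chesser unbiased H_S and H_T with the harmonic
mean sample size; the overall value is the mean of per-locus values, the
P-value permutes individuals among populations, and the CI bootstraps
individuals within populations. Note the unbiased estimators give
slightly negative D on literally identical finite samples; this is a
property of the estimator, not a bug. FDR control is Benjamini–Hochberg.

## The hierarchical coalescent null and outlier classification

The null model is a two-level island model: `n_groups` groups of
`demes_per_group` demes (20 × 100 by default). Lineages co-located in a
deme coalesce at rate k(k−1)/2; each lineage migrates to another deme of
its own group at total rate M1/2 and to a deme of another group at rate
M2/2 (M1, M2 are scaled rates, twice the per-lineage rate). Each sampled
population occupies its own deme; populations sharing an empirical group
share a simulated group. Each locus is one genealogy, simulated to the
MRCA by a compiled Gillespie event loop, carrying exactly one mutation
placed on a branch with probability proportional to branch length, so
every simulated locus is a polymorphic SNP.

Conditioning on a single mutation per genealogy means the site-frequency
spectrum is E[ℓ_i/L] rather than the infinite-sites 1/i law (the two
differ by a few percent at the singleton class because ℓ_i/L and L are
correlated). The same conditioning generates both the null table and the
synthetic datasets, so observed and null loci are exchangeable under
neutrality — which is what the outlier test requires.

Calibration bisects M2 on a log scale (holding M1/M2 = 10) until the mean
multilocus θ over probe loci matches the target F_ST within 0.01, using
common random numbers within a probe so the probed θ is a smooth
decreasing function of M2.

Each simulated locus contributes (total heterozygosity 2p̄(1−p̄), θ with
sampled demes as populations, gene copies paired randomly into diploids).
Classification of an observed locus conditions on heterozygosity: because
simulated heterozygosity is discrete (a function of the pooled derived
count) and θ's conditional distribution shifts across classes, the
comparison set is the nearest whole heterozygosity class (expanded only
if it falls below a floor). θ has discrete support within a class, so
tail P-values break ties with a seeded uniform draw and the add-one rule:
p_high = (#{sim > obs} + U·(1 + #{sim = obs}))/(m + 1), p_low its mirror
with the same U. Under the null these P-values are exactly uniform; the
attainable minimum is 1/(m+1), so detecting outliers at P < 0.01 needs
classes of ≳100 simulated loci (another reason for the 30 000-simulation
default). Loci are called high (directional) or low (balancing) at
P < 0.01, and filtered when scaled heterozygosity — total heterozygosity
× (1 − θ) — is ≤ 0.2. The multiplicative scaling maps total onto
within-deme heterozygosity under the island model; note it filters any
locus with θ ≳ 0.6 regardless of diversity, so extremely differentiated
loci never pass the filter (the division form is available via
`het_scale="divide"`).

## Genome scans

Outlier clustering: 20 Mb bins tiled per chromosome; the probability of
observing k outliers in a bin is the Poisson point mass with
λ = n_outliers / n_bins. A packaged chromosome-length table for the 25
zebrafish chromosomes (assembly-scale, representative values) yields 76
bins under this tiling.

Heterozygosity-valley scan: for each significant outlier, the window
[pos − w/2, pos + w/2) clipped to the chromosome; the statistic is mean
expected heterozygosity over the window's SNPs excluding the focal locus,
in a chosen population (or pooled). SNP membership uses polymorphism in
the whole dataset, so loci swept to local monomorphism count with He = 0
— dropping them would erase the valley being tested. The null is the set
of tiled non-overlapping windows lying fully outside every outlier window
with at least `min_snps` SNPs; the empirical lower-tail P uses the
add-one rule, significant below α = 0.05. The LD-elevation scan is the
mirror image on the mean r² between the focal locus and the other SNPs in
its window, with null windows centred on the SNP nearest each window
midpoint and an upper-tail P.

LD: r² comes from EM haplotype-frequency estimation over the
double-heterozygote ambiguity (convergence 1e−11 on p_AB, ≤ 5000
iterations). The likelihood can be multimodal, so EM runs from the
equilibrium start and both phase extremes, plus the exact frequency
bounds, keeping the highest-likelihood solution. Decay curves bin
syntenic pairs by distance (5 Mb default), fit mean r² = a·ln(d Mb) + b by
OLS over nonempty bins, and report two characteristic distances: the
fitted distance at which r² reaches 0.2, and the empirical half-length
(first linear-interpolated crossing of half the shortest-distance bin
mean — the fit is deliberately not used here because logarithmic fits
are unreliable at sub-bin distances).

## Synthetic data

The generator shares the coalescent engine, so neutral loci follow the
outlier test's null exactly. Positions are uniform over the chromosome
lengths; diploids pair gene copies within demes; missingness is
independent at a configurable rate. Defaults emulate the study's scale:
~1832 loci, hierarchical structure calibrated to overall F_ST ≈ 0.17,
populations of ~15 diploids.

Sweeps are planted by per-allele-copy thinning: within the favored
group's populations, each copy of the locally minor allele (major/minor
assessed on the favored group pooled — the swept haplotype is shared
across the group) is replaced by the major allele with probability
intensity × (1 − distance/radius). Heterozygotes become major
homozygotes with that probability, so within-population heterozygosity
falls approximately in proportion to intensity at the centre, and the
genotype-level edit keeps Hardy–Weinberg structure testable. An optional
differentiation boost drives the SNP nearest the sweep centre to
near-fixation of opposite alleles between the favored group and the rest
(alt frequency ≈ 0.99 vs 0.01). Loci are otherwise independent — there is
no recombination model — so background LD is created only by population
structure; controllable LD for scan tests comes from `plant_ld_block`,
which copies a genotype column at regular spacing with flip noise.

The mtDNA simulator draws a root sequence at a given base composition
(61% AT by default), places Poisson(d·L/2) substitutions on each clade
stem (so between-clade p-distance centres on the net divergence d) and
Poisson(θ·L/2) private substitutions per sequence (within-clade π centres
on θ), with transition:transversion odds 22:1 by default and distinct
sites per branch (no homoplasy within a branch). It therefore emulates
composition, divergence depth, transition bias and shallow within-clade
variation — not rate heterogeneity across sites, saturation, or
recombination-free genealogical structure within clades. Passing tests on
these data show the estimators recover planted parameters under the
island-model and clade-model assumptions; they do not validate behaviour
under demographic change, ascertainment bias, or intra-chromosomal
linkage, none of which are modelled.

## Problem sizes used in the checks

The bundled checks run at desk scale, chosen to keep every Monte Carlo
criterion well-powered: calibration and false-positive-rate checks use
the 10-population wild layout (5 groups, 15 diploids per population) in
the 20 × 100 island model with 5000-locus null tables and 2000-locus
observed sets over 3 seeds; the sweep-recovery check uses 2000 loci on 8
chromosomes of 40 Mb (≈ 6 SNPs/Mb) with completed hard sweeps
(intensity 1.0, radius 3 Mb) scanned in the favored group's pooled
populations with a 4 Mb window matched to the sweep width, against
control positions 20 Mb from every sweep. The design follows a simple
power calculation: the detectable effect is roughly intensity × ½ × mean
window He over the matched window, against a between-window standard
deviation of σ_He/√m, so the marker density (m ≈ 25 SNPs per window) and
the matched window are what make a 3 Mb sweep visible. At sparser
densities or mismatched window sizes the same sweeps are statistically
invisible (the valley is a fraction of one standard deviation of window
means) — the expected behaviour of a percentile test, not a failure of
the scan.

## Known limitations

- No recombination or intra-chromosomal linkage in the neutral engine.
- No demographic events (bottlenecks, growth) and no ascertainment-bias
  simulator; real EST-derived panels are enriched for common variants.
- TN93 without +I underestimates deep distances under strong
  rate heterogeneity.
- The multiplicative scaled-heterozygosity filter excludes all loci with
  θ ≳ 0.6 by construction.
- Randomized tie-breaking makes borderline outlier calls depend on the
  classification seed (they are exactly calibrated in distribution, and
  deterministic for a fixed seed).
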