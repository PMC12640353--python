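# Methods

## Scope and model

flockscape implements the statistical core of a temporal population-genomics
study of livestock breeds: each breed is observed as two cohorts of diploid
individuals genotyped on a medium-density SNP chip, sampled roughly twenty
years (about seven sheep generations) apart. The package covers the panel
preparation, diversity, differentiation, annotation, climate-correlation and
introgression-summary steps; upstream components with their own dedicated
tools (phasing, IBD segment detection, admixture deconvolution, the
local-ancestry HMM, LD-based Ne estimation) are consumed as tabular inputs,
not re-implemented.

Because real herd-book genotype panels are access-restricted, the package
ships a first-class synthetic-data generator whose defaults encode the study
design the analyses assume, with truth sidecars so every downstream claim can
be checked against known signal.

## Synthetic study generator (`flockscape.sim`)

Allele-frequency model. A base frequency vector is drawn per SNP from
Uniform(0.05, 0.95). Each breed's founder frequencies drift from this base
for `breed_divergence_generations` (default 50) generations of Wright–Fisher
binomial resampling of 2·Ne allele copies, giving realistic between-breed
structure; founder frequencies are then clamped to [1/(4Ne), 1 − 1/(4Ne)] to
limit fixation in short runs (fixed SNPs that arise later are retained — they
exercise degenerate-input handling downstream). The historical cohort is
drawn from the founder frequencies; the current cohort from frequencies
drifted a further t = 7 generations. Genotypes are Binomial(2, p)
(Hardy–Weinberg within cohorts); missing calls are i.i.d. at rate 0.02.

Defaults mirror the target design: 34 breeds, 20 individuals per cohort per
breed, 26 autosomes × 1750 SNPs at ~50 kb mean spacing (≈45k markers),
Ne = 150 per breed unless specified. The 7-generation interval is a
configuration default (generation interval is not an observable of the data),
as is everything else above.

Planted devices, all recorded in the `SimTruth` sidecar:

* **Adaptive SNPs.** Each coupled SNP receives a per-generation frequency
  push `coupling × trend(breed, variable)`. Climate trends are drawn
  N(trend_mean = 1, trend_sd = 1) per breed × variable — directional on
  average, as for observed warming/aridity shifts. Directionality matters:
  were trends symmetric around zero, temporal differentiation (a
  sign-symmetric quantity) could not correlate linearly with the trend.
* **Introgression tracts.** Inside randomly placed tracts covering a set
  genome fraction, the target breed's current-cohort frequencies become
  α·donor + (1−α)·target. The companion dosage generator emulates
  local-ancestry output: donor proportion centred on α inside tracts and on
  a 0.05 background outside, with Beta noise at concentration 50.
* **Planted ROH.** Chosen segments of chosen individuals are overwritten by
  a single haplotype sampled from the cohort frequencies and doubled —
  an identical-by-descent run, homozygous at every SNP, rather than
  per-genotype resampling.

Randomness: one global seed; every consumer derives a named substream
(`substream(seed, label)`), so adding a device never reorders existing draws
and identical seeds give byte-identical output.

What the generator does **not** emulate: linkage disequilibrium and
recombination (SNPs drift independently), pedigree structure, mutation,
selection other than the directional coupling device, and chip ascertainment
bias. Passing tests therefore demonstrate correctness of the estimators
under drift + sampling noise, not robustness to LD or ascertainment —
conclusions about real chip data inherit those caveats.

## Demography (`flockscape.demography`)

Percent change between census years is 100·(last − first)/first, infinite
when the breed did not exist at the first census. The yearly growth rate for
consecutive positive censuses is r = (N2/N1)^(1/t) (the antilog of the
per-year log-count difference); zero-registration years are excluded before
pairing, and the breed value is the arithmetic mean of interval rates (a
geometric mean is a documented alternative). Wright's effective size for
unequal sex ratios is Ne = 4·Nm·Nf/(Nm + Nf); the per-generation inbreeding
increase is ΔF = 1/(2Ne), reported in percent at two decimals, undefined at
Ne = 0.

Risk classification follows the FAO least-favourable-parameter rule: each
available parameter (breeding females, breeding males, total size, growth
rate, ΔF) maps to the worst tier whose threshold it violates; the breed gets
the worst tier over parameters, Extinct overriding everything when the
latest census is zero; the triggering parameter is recorded. The numeric
tier cutoffs are configuration defaults in the spirit of FAO's in-vivo
conservation guidance — they are deliberately not presented as any
publication's exact values, which are not machine-readably available.

The bundled `italian_sheep_demography_2010_2024.tsv` table (56 Italian
breeds; farms, animals, changes, growth rate, Ne, ΔF%, risk tier) serves as
an arithmetic cross-check fixture: the package's formulas reproduce its
printed percent-change and ΔF columns from the printed absolute counts. For
a few rows the printed ΔF is consistent only with an unrounded Ne (e.g. a
printed Ne of 4 with ΔF 13.89% implies Ne ≈ 3.6), so exact-match checks are
restricted to rows whose printed Ne is exact.

## QC (`flockscape.qc`)

Filtering runs individuals → SNP call rate → MAF (recomputed on retained
samples), mirroring PLINK's mind/geno/maf order; defaults are 95% call rate
and MAF 0.001 (0.1%; 0.01 is the more common community choice and is one
keyword away). LD pruning is greedy windowed `indep-pairwise (50, 10, 0.5)`:
within each 50-SNP window, while any retained pair exceeds r² = 0.5 the
lower-MAF member is removed (tie: later map position), then the window
advances 10 SNPs; missing genotypes are pairwise-deleted in r². The result
depends only on map order, never sample order.

Relative screening without pedigrees uses the Mendelian-inconsistency logic
pairwise: a parent–offspring pair can never be opposing-homozygous at a
locus, while unrelated pairs are opposing-homozygous at rate 2p²q² per locus
(0.125 at p = 0.5). Pairs at or below `opposing_hom_max` (default 0.02) are
parent-offspring-like; pairs with IBS2 fraction ≥ 0.95 are duplicates; one
member per flagged pair is marked for exclusion (fewest missing kept, ties
by id). The two thresholds are screening defaults, not published constants.

Population structure uses 1 − IBS/2 distances and classical (Torgerson) MDS
— eigendecomposition of the double-centred −D²/2 with a deterministic sign
convention — rather than SMACOF-style stress minimisation, matching the
PLINK `--mds-plot` family. Breed-size balancing caps breeds at 30 by
k-means (k = cap, k-means++, 50 restarts, fixed seed) on the first 10 MDS
dimensions, keeping the sample nearest each centroid; breeds under 10 are
dropped. Nearest-to-centroid selection was chosen for determinism among the
k-means-sampling variants in circulation.

## Diversity and ROH (`flockscape.diversity`)

Ho/He are per-SNP within breed (He = 2p̂(1−p̂)) averaged over the full
post-QC SNP universe, monomorphic SNPs contributing zeros. ROH detection
follows PLINK `--homozyg` semantics with the chip-density-tuned parameter
block (window and minimum run 49 SNPs, 0 hets and ≤2 missing per window,
≥1 Mb, gap ≤500 kb, density ≤73 kb/SNP, hit-fraction threshold 0.05): only
full 49-SNP windows are formed, SNPs near chromosome ends use their actual
window coverage as denominator, and segment bounds are the outermost in-run
SNP positions. The detector is verified against a literal enumeration of
these rules on hundreds of random chromosomes.

F_ROH divides summed ROH length by the SNP-covered autosomal span (sum of
last-minus-first marker positions per chromosome) — the genome the chip
actually surveys — with an assembly-length override available. Length
classes (1–2, 2–4, 4–8, 8–16, >16 Mb) are right-closed with the first bin
closed below so classes exactly partition the total.

## Differentiation (`flockscape.differentiation`)

Per-SNP Fst uses the two-population Weir & Cockerham (1984) variance
components a, b, c with θ = a/(a+b+c); genome-wide values are ratio-of-sums
Σa/Σ(a+b+c) (not mean of ratios). SNPs with a group below 2 called samples,
either group uncalled, or a+b+c = 0 are flagged undefined and excluded from
sums. The top-1% candidate set takes |θ| at or above the 99th percentile of
defined values, ties included.

**Temporal calibration.** In a temporal pair, the historical sample *is*
the ancestral population of the current one: the expected squared frequency
difference is F·p₀q₀ with F = 1 − (1 − 1/(2Ne))^t, half of the 2F̄·p₀q₀ a
symmetric two-population divergence would produce. The symmetric W&C
estimator therefore converges to F/2 ≈ t/(4Ne) on temporal data — the
classical reason temporal studies use Nei–Tajima/Jorde–Ryman F estimators.
`temporal_fst` reports both the raw genome-wide θ and the drift-calibrated
temporal F = 2θ; parameter-recovery checks (and the acceptance script)
compare 2θ with t/(2Ne). Per-SNP θ values are used as-is in scans, where
only relative ordering and cross-breed contrasts matter.

Reynolds' coancestry distance is Σ_l Σ_alleles (p1−p2)² / (2 Σ_l (1 −
Σ_alleles p1p2)), loci summed before dividing, undefined loci skipped; it is
symmetric, zero iff the frequency vectors agree, and not assumed to satisfy
the triangle inequality. Trees are Saitou–Nei neighbour joining (scikit-bio)
with negative branch lengths clamped to zero; bootstrap support resamples
SNP columns with replacement (100 replicates by default, seeded), counts
bipartitions, and writes percentages as internal node labels.

IBD haplotype-sharing summaries filter segments at ≥1.5 Mb and LOD ≥3.0,
sum surviving lengths per cross-breed individual pair, and take breed-pair
medians over *sharing* pairs (breed pairs with no surviving segment score
0); an inclusive-zero mode is available. Top edges are breed pairs at or
above the 95th percentile of nonzero medians.

## Annotation and enrichment (`flockscape.annotate`)

Candidate SNPs get ±20 kb windows (left-clipped at 1, never merged) —
roughly the distance at which LD halves on ovine chips. Feature overlap is
≥1 bp on inclusive coordinates, with the fraction of each feature covered
reported. Enrichment counts SNPs, not features: N = array SNPs whose
windows hit any QTL, K of those hitting the category, n and k the same for
candidates; p = P(X ≥ k) upper-tail hypergeometric (scipy), exactly the R
`phyper(k-1, K, N-K, n, lower.tail = FALSE)` idiom, verified against
exhaustive enumeration for all N ≤ 12. BH step-up correction is applied
across the categories of one run (cross-breed joint adjustment optional).

## Climate correlation (`flockscape.climate`)

The climate contract is tabular — per-farm values per variable per period,
e.g. extracted upstream at farm locations with a 10 km buffer; raster I/O is
out of scope. Farm values are within-period medians; the breed delta is the
mean over farms of farm-level period differences (mean-of-deltas first, the
alternative ordering is provided). The scan computes Pearson r between
per-breed per-SNP temporal Fst and per-breed deltas, two-sided p from the t
transform with (breeds used − 2) df after pairwise deletion, BH within each
variable, and flags candidates that are significant for ≥1 variable *and*
in some breed's top-1% Fst set. Zero-variance vectors are excluded as
undefined rather than reported as r = 0.

## Introgression summaries (`flockscape.introgression`)

Dosages (validated to sum to 2 per sample × SNP) are halved to proportions;
the module reports per-SNP source means, per-individual genome-wide means,
and the cohort mean ± sd computed across per-individual means (sample sd,
n−1) — the scale on which published "overall mean ± sd" ancestry values are
quoted — with per-SNP sds alongside. Highly introgressed SNPs are those at
or above the genome-wide 99th percentile of a source's per-SNP means
(per-chromosome thresholds are a documented alternative); the threshold is
the order statistic, so exactly ⌈0.01·m⌉ SNPs are called absent ties, ties
included, with a warning below 100 SNPs. Calls feed `annotate` unchanged.

## Numerical and interface choices

* Missing genotypes are a dedicated sentinel checked by identity; no −9
  arithmetic anywhere.
* PED carries no REF/ALT, so the alternate allele is the minor allele at
  read time, ties to the lexicographically later letter; every statistic in
  the package is invariant under per-SNP allele flips, so polarity is a
  coding convention, not a result.
* Coordinates are 1-based inclusive throughout (PLINK/MAP convention).
* All writers emit LF line endings; distance matrices, Fst tables, ROH
  segments (PLINK `.hom`-style columns) and reports are tab-separated.
* The pipeline manifest hashes every artifact; identical config + seed
  implies identical hashes.

## Problem sizes used in checks

The shipped verification runs use deliberately scaled designs chosen to
give tight Monte-Carlo error at interactive runtimes: drift recovery at
Ne = 100, t = 7 with 20k SNPs and 30+30 samples over 5 replicates; ROH
oracle equivalence on 200 random chromosomes of up to 500 SNPs plus planted
segments at 25 kb marker spacing; NJ bootstrap on six populations × 20k
SNPs; climate calibration and power on 12 breeds × 500 SNPs × 20 variables
(20 replicates); introgression calling on 10k SNPs. The analysis drivers
under `analysis/` use an 8-breed, 4,800-SNP study for the same reason.

## Known limitations

* No LD/recombination in the generator: window-based statistics (ROH, LD
  pruning) are exercised on planted rather than emergent structure.
* The W&C temporal halving is corrected at the genome-wide scale; per-SNP
  θ values retain the factor, which cancels in rankings and correlations.
* Hypergeometric enrichment p-values are discrete and conservative for
  small K; the null-calibration property is asserted on configurations
  large enough for the discreteness to be negligible.
* k-means breed balancing can select fewer than the cap when two centroids
  share a nearest sample; this is rare and accepted for determinism.
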