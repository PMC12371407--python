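# Methods

This note documents the statistical procedures `gvpop` implements, the model
behind its synthetic epidemic generator, the numerical and design choices
that were genuinely open, and what the test suite does and does not
demonstrate about real data.

## Diversity statistics

**Between-host π.** For a set of sites, each site contributes
π_site = n/(n−1) · (1 − Σ_a f_a²), where f_a are allele frequencies among the
n non-missing consensus calls at that site. This sample-size-corrected
heterozygosity is algebraically identical to the mean number of pairwise
differences per site; the identity is used as an exhaustive oracle in the
tests (all sample pairs, ≤ 20 samples, agreement to 1e-12). Two scales are
exposed, because both are scientifically meaningful and differ by orders of
magnitude: the mean over a chosen site set (e.g. segregating sites, where
values are O(0.1)), and the per-site sum divided by total genome length
(genome-wide, O(1e-4)); the denominator is always stated in output. Sites
with fewer than two non-missing calls are skipped with a warning; missing
calls reduce n per site and are never imputed.

**Within-host π.** From an isolate's read-level alternative-allele
frequencies p and depths D at the segregating sites:
π_site = 2p(1−p) · D/(D−1), the unbiased read-pair estimator (the
probability two reads drawn without replacement disagree). The D/(D−1)
correction is our choice — variant callers report frequencies, not an
estimator — and an uncorrected 2p(1−p) variant is available via
`corrected=False`. Sites with D < 2 are skipped; segregating sites absent
from an isolate's profile are fixed reference (p = 0). The estimator-choice
difference from any particular caller's convention is at most a factor
D/(D−1), i.e. below 1% at typical depths.

**Watterson's θ.** Per ORF, θ = S/(aₙ·L) with S the number of polymorphic
columns in the ORF, aₙ = Σ_{i=1}^{n−1} 1/i the harmonic number for n
sequences, and L the ORF length in bp. θ is monotone in S and strictly
decreasing in n for fixed S — both are property-tested.

**Nonsynonymous densities.** Per ORF, nonsynonymous SNV count divided by ORF
length in kbp; per functional group (replication, transcription, per os
infection, virion assembly/packaging, auxiliary, unknown), the unweighted
mean over member ORFs.

## Site selection

The structure analysis uses biallelic SNPs with minor allele frequency
strictly above 0.05, computed over non-missing haploid calls (indels and
sites with other than exactly two observed alleles removed) — the
conventional `--max-alleles 2 --maf 0.05 --remove-indels` semantics.
Segregating sites are positions whose alternative allele is carried by
strictly more than 7 consensus genomes ("more than seven" read literally:
≥ 8; at a 138-isolate cohort this is the ~5% level). Carrier counting is at
the consensus level, not the read level. Both filters are idempotent and
order-preserving, which the suite asserts by brute-force recounting.

## Variant effect taxonomy

SNVs are classified on the coding strand: the affected codon is recomputed,
start-codon and reference-stop-codon hits take precedence
(`translation_start_site_SNV`, `termination_site_SNV`), otherwise the call is
synonymous iff the translated amino acid is unchanged. A gained stop is
classified as nonsynonymous (the category names describe changes *in* start
or stop codons). Indels are frameshift iff the net length change is not a
multiple of three. An indel whose inserted/deleted sequence is a whole
number of copies of a 1–4 bp unit with at least `min_copies` (default 3)
tandem copies in the flanking reference is a microsatellite event; the
smallest qualifying unit wins. Unit lengths 1–4 are all supported (labelled
Types I–IV) although field datasets typically report I, III and IV only.
Overlapping ORFs each receive their own call — baculovirus genomes are
compact, and dropping either would corrupt per-gene counts.

*hr* regions are found by scanning the forward strand for the 10-bp
palindrome TTTACGTAAA with at most 1 mismatch (the motif equals its own
reverse complement, so one strand suffices; a non-palindromic motif draws a
warning). Hits within 500 bp of the previous hit merge into a region;
regions need ≥ 2 hits. The window and minimum-repeat defaults are ours:
published *hr* counts do not come with detection parameters, and both are
exposed.

## DAPC

The genotype matrix (samples × filtered SNPs, 0/1 alternative-allele
indicators, missing mean-imputed per site) is column-centred and decomposed
by SVD. Cluster number is selected by scoring seeded k-means solutions
(best of `restarts` initializations, default 20) for K = 1..40 with
BIC(K) = n·ln(WSS_K/n) + K·ln(n); best K minimizes BIC with ties to smaller
K. The scan runs on the full score matrix, as the original find.clusters
workflow does. This BIC is only informative in that regime: when k-means
runs on a low-dimensional projection, splitting even a single Gaussian
reduces WSS faster than the K·ln(n) penalty grows and the curve decreases
indefinitely — a property worth knowing before trusting any k-means BIC
curve.

The discriminant step solves the generalized eigenproblem of between- vs
within-group scatter on the first n_pca score columns (ridge 1e-8·tr(Sw)/d
for numerical safety), retaining n_da = min(groups−1, n_pca) axes.
Assignment probabilities are per-group Gaussian densities with pooled
covariance and equal priors in discriminant space; the
correct-assignment rate is the fraction of samples whose argmax group
matches their a-priori label. sklearn's LDA serves as an independent
cross-check in the tests, never as the implementation.

n_pca is chosen by stratified cross-validation: per candidate, PCA is refit
on each training fold, held-out samples are projected onto the training
loadings, and the per-fold misassignment fractions are aggregated as an
RMSE; lowest RMSE wins, ties to fewer components.

## Infection-pattern classification

The field description of the three within-host allele-frequency patterns is
qualitative (single distribution / bimodal / high diversity without
bimodality), so the classifier is our operationalization, with every
threshold exposed:

1. Frequencies at segregating sites observed at depth ≥ 10; fewer than 10
   usable sites → `undetermined`, never a silent Pattern A.
2. Sites with p in [0.10, 0.90] are *intermediate*. If the intermediate
   fraction is ≤ 0.05 → Pattern A.
3. Otherwise 1-D Gaussian mixtures with 1..4 components are fitted to the
   intermediate frequencies and the component count chosen by BIC.
   ≥ 3 components → Pattern C; 2 → Pattern B; 1 → Pattern B with a
   "merged modes" note (a single intermediate peak near 0.5 cannot come
   from one strain).
4. A 1–2-component fit whose component variance exceeds 4× the binomial
   sequencing-noise expectation mean p(1−p)/D is reclassified as Pattern C:
   frequencies too dispersed for two clean strains are the "high diversity,
   no bimodality" signature. The factor 4 separates binomial noise (σ² ≈
   0.0017 at depth 150) from multi-strain dispersion (σ² ≳ 0.01) by more
   than an order of magnitude on simulated mixtures.

Every mixture size is fitted to both orientations of the data (x and 1−x)
and the better likelihood kept, which makes the whole classification exactly
invariant under allele relabelling p → 1−p — asserted per host in the tests.
Frequencies enter the fit unweighted; the boundary between A and B/C is by
distribution shape, not by the isolate's π, so isolates in the π overlap
zone between patterns may be labelled differently than by any π-threshold
rule.

The mixed:single ratio is (#B + #C)/#A per (year, season, wave); strata with
no Pattern-A calls are reported infinite and excluded from the trend. The
trend statistic is the Spearman correlation of the stratum ratios against
wave ordinal, with a seeded permutation p-value (one-sided, negative
alternative).

## Wave-level trends

Median within-host π per (year, season, wave); empty strata are flagged
missing. A wave missing from one season may be imputed as the arithmetic
mean of the same wave's medians from the seasons that have it (imputed flag
set, isolate count zero, observed strata never altered); a wave missing from
every season is an error. The decline test is a one-sided permutation test
of median(π|W1) − median(π|W2∪W3), permuting wave labels *within* (year,
season) strata so the blocking of the sampling design is respected;
p = (1 + #{permuted ≥ observed})/(1 + R). The statistic depends on ranks
and medians only, so multiplying all π by a positive constant leaves p
unchanged (tested). The pooled W2∪W3 contrast is the headline; no named
test exists in the field literature for this contrast, so the permutation
design is this package's choice.

## The synthetic epidemic generator

The generator emulates the sampling design of a multi-year granulovirus
field study. Its default parameters are the study conditions: 138 isolates,
112 kb circular genome at 35% GC, 4 years × 2 rice seasons × 3 waves,
founder bottlenecks of (20, 5, 2) per wave (working values — no field
estimates of bottleneck size exist), mean depth 200, and
single/two/multi-strain infection probabilities per wave of (0.30, 0.25,
0.45) → (0.45, 0.28, 0.27) → (0.80, 0.12, 0.08), chosen so mixed infections
dominate the first wave and are rare by the third while the cohort-wide
single:two:multi split (~52/22/27%) is near the observed pattern
frequencies.

Model structure, in transmission order:

- **Reservoir.** One random reference genome (with planted ORFs carrying
  proper start/stop codons, and 12 planted *hr* clusters) and
  `reservoir_size` strains. The reservoir is structured into annual
  lineages (clades): each clade carries lineage substitutions at rate
  2.5e-3/site and every strain adds private substitutions at 5e-4/site, so
  same-year strains are several-fold closer than cross-year strains —
  without lineage structure a star-phylogeny pool makes all strains
  equidistant and no annual clustering exists to recover. Because
  granuloviruses recombine freely during co-infection, a lineage behaves
  like a small recombining population: each lineage variant segregates
  within its clade at a Beta(5, 1) frequency (mass near fixation, a tail of
  intermediate frequencies) and strains carry it independently per site.
  Each polymorphic site has one pre-drawn alternative base (biallelic pool).
- **Annual pools.** Each year starts from a random subset of its lineage
  plus a 10% minority of strains from other lineages (the soil reservoir
  persists across years) — these cross-lineage carryovers are what make
  some mixed infections as divergent as between-year differences.
- **Waves.** W1 founders are drawn from the year pool; each later wave's
  founders are resampled multinomially from the realized strain content of
  the previous wave, with `founder_count_per_wave` setting the bottleneck.
- **Hosts.** Each host receives k strains (k from the wave's multiplicity
  probabilities, >2 meaning 3–4) with Dirichlet(1) proportions, optionally
  rejection-sampled to a minimum proportion. Each within-host lineage is a
  per-site mosaic of its founder and a second parent from the wave pool
  (co-infection recombination), so every isolate carries a fresh recombinant
  haplotype rather than a duplicate of a clonal founder.
- **Observation.** Depth ~ Poisson(200) per site; alternative reads ~
  Binomial(depth, p) with p the proportion-weighted alternative frequency,
  a 1e-3 per-read miscall rate (giving single-strain isolates the ~0.001
  within-host π floor real sequencing shows), and a 5e-3 per-host-per-site
  artifact probability that flips the sampled frequency to 1−p (mis-mapping
  / whole-genome-amplification artifacts — the idiosyncratic noise floor
  real consensus assemblies show). The consensus call is the per-site
  majority allele; zero-depth sites are missing.

Emitted files (consensus FASTA, reference FASTA, VCF with exact AD counts,
metadata CSV, ORF GFF3, truth JSON) round-trip bit-exactly through the
package's own readers, and one seeded generator drives all randomness, so
reruns are byte-identical.

**What the generator does not model**: de-novo mutation within a season,
indels and structural variation (ORF-length variant inputs for the effect
classifier are built directly in tests), selection, migration between
sites, overdispersed sequencing depth, and within-host replication
dynamics. Passing recovery tests therefore shows the estimators and
classifiers recover truth under the stated statistical structure — not that
field data satisfy that structure.

## Problem sizes used in the test suite

Monte-Carlo checks run at reduced problem sizes chosen for statistical
sufficiency: structure recovery uses 4 × 30 isolates on 20 kb genomes
(100 replicates; the BIC scan covers K = 1..40 as in the full analysis),
pattern recovery uses 300 hosts at depth 150 with ≥ 50 segregating sites,
null calibration of the decline test uses 1,000 simulated cohorts with 499
permutations each (the discreteness of the permutation p-value makes
α = 25/500 exact), and power checks use 100 replicates of the full default
cohort. The structure-recovery cohorts use one cohort per year (no wave
substructure) because wave bottlenecks create genuine sub-annual clusters:
on the full default design the BIC scan resolves 7–11 clusters —
season/wave-level structure — rather than the 4 annual lineages, which the
controlled configuration recovers in ≥ 95% of replicates.

## Known limitations

- Between-host π with missing data uses per-site n; the exhaustive pairwise
  identity is exact only for fully-called matrices.
- The k-means BIC cluster count is meaningful only relative to the
  hierarchy present in the data; real cohorts with strong within-year
  substructure will legitimately yield K above the number of years.
- The Pattern B/C boundary for three-strain infections whose two minor
  strains have nearly equal proportions is fundamentally unidentifiable
  from marginal frequencies; the overdispersion rule recovers most but not
  all such hosts.
- `select_n_pca` cross-validation requires ≥ 2 samples per group per fold;
  singleton groups are excluded with a warning.
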