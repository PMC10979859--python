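# Methods

This note documents the statistical models implemented in `sweepscan`,
the design of the synthetic-data generator, the numerical choices, and
what the test suite does and does not establish about behaviour on real
data.

## Phenotype model

The unit of analysis is a bioassay-phenotyped mosquito: resistant means
alive after exposure to a high insecticide dose, susceptible means dead
after a lower dose. All association models are binomial-logit GLMs with
phenotype (resistant = 1) as the response. Marker codings follow field
convention: SNPs enter as alt-allele dose (0/1/2), CNV alleles as
presence/absence, and gene copy number as extra copies beyond diploid.

The GLM is fitted by iteratively reweighted least squares (tolerance
1e-8 on the step, at most 25 iterations). Complete or quasi-complete
separation is flagged when the fit fails to converge or any non-intercept
coefficient exceeds 10 on the log-odds scale; in that case the Wald
p-value is meaningless and a likelihood-ratio p-value against the
term-deleted model is reported instead. On a single binary predictor the
fitted coefficient is exactly the log odds ratio of the 2×2 table and
the standard error is sqrt(1/a + 1/b + 1/c + 1/d); both identities are
asserted in the tests against statsmodels and closed forms.

## Kinship and sample QC

KING-robust kinship is computed from called genotypes:
phi = (N_HetHet − 2·N_OppHom) / (N_Het(i) + N_Het(j)) over loci called in
both samples, after masking configurable exclusion regions (genomic
inversions behave like mega-loci and inflate phi; a strong sweep has the
same effect, so sweep regions can be masked the same way). Expected
values are 0.5 for self, 0.25 for full sibs, ~0 for unrelated samples.
Full-sib groups are connected components of the phi ≥ 0.185 graph; the
threshold is a configuration value. Cross-contaminated samples show
inflated heterozygosity and elevated kinship to everyone; a sample is
flagged when its median kinship exceeds the 0.99 quantile of all
pairwise values AND its heterozygosity z-score exceeds 4 (both
configurable — no principled universal constants exist here).

Sib handling: either one random member per group is retained, or (for
windowed FST) the statistic is averaged over 100 retention permutations,
which uses the whole cohort without pseudo-replication.

A caveat learned from the generator: phi estimates concentrate only when
many independent loci contribute. Cohorts simulated with few coalescent
blocks (each block is fully linked) give noisy phi and spurious sib
edges; the pipeline tests therefore use ≥ 20 blocks.

## Selection statistics

Within a SNP window, haplotypes are counted by exact allele-string match
(no mismatch tolerance — a deliberate choice; one private mutation
separates two haplotypes). From the descending frequency spectrum:
H1 = Σ pᵢ², H12 = (p₁+p₂)² + Σ_{i≥3} pᵢ² (sensitive to soft sweeps),
H1X = Σᵢ H_ia·H_ib over the distinct haplotypes of two cohorts (high when
a swept haplotype is shared), and ΔH12 = H12(res) − H12(sus). The window
size is a parameter, not a constant: 1000 SNPs is the conventional
genome-scale choice, while desk-scale simulated genomes use windows
matched to their block length.

## Windowed differentiation and peak filtering

Per-site Hudson FST components are
num = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1),
den = p₁(1−p₂) + p₂(1−p₁); windows combine them as Σnum/Σden (ratio of
sums). Sites with any missing call in the compared groups, or combined
minor allele count ≤ 1, are excluded before windows are laid down. Note
the estimator's finite-sample behaviour: for identical groups of n
samples the windowed value is exactly −1/(n−1), not 0.

PBS for focal f, sister s, outgroup o is (T_fs + T_fo − T_so)/2 with
T = −ln(1 − FST); windowed FST is clipped at 1 − 1e-12 before the log,
and windows with non-positive denominator sums are masked.

Peak candidates: the FST rule takes positive windows further than three
times the distance from the mode to the smallest negative value; the
mode is a Gaussian-KDE argmax (Silverman bandwidth, 512-point grid over
the data range) — chosen for smoothness and determinism, since a
histogram mode depends on binning. If the track has no negative values
the threshold is undefined and no peaks are called (logged). H12 and PBS
use 3 × the 98th and 95th centile respectively (linear interpolation).

The permutation filter re-tests candidates against an empirical null:
phenotype labels are permuted within location strata (locations are
analysed separately, so within-stratum exchange is the faithful null),
the statistic is recomputed on candidate windows only, and a peak is
retained iff the observed value strictly exceeds the 99% empirical
quantile of its permuted values. The counting p-value
(1 + #{perm ≥ obs})/(n_perm + 1) is reported alongside. This filter is
the defence against sweeps that are real but not phenotype-linked: a
sweep present in both classes produces a large observed value and an
equally large permutation spread, and is dropped.

Retained peaks must finally contain a haplotype cluster positively
associated with resistance: average-linkage (UPGMA) clustering on
pairwise Dxy (proportion of differing sites), tree cut at height 0.001,
clusters of ≥ 20 haplotypes tested by a GLM of phenotype on per-sample
cluster dose (0/1/2), requiring coefficient > 0 and p < 0.05. UPGMA and
the 0.05 level are package choices where the design was open; merge ties
break deterministically via SciPy's ordering, so runs are reproducible.

## Copy number from coverage

The HMM has total-copy-number states 0..12 (diploid 2 + up to 10 extra).
Emissions are Normal(state value, sigma) on the normalised scale where
diploid coverage is 2.0; the state-0 mean is floored at 0.1 because
deleted sequence still attracts mismapped reads. Transitions share one
change probability t split equally among non-self states; the initial
distribution is uniform; decoding is exact Viterbi (verified against
exhaustive path enumeration on small instances). Defaults sigma = 0.5,
t = 1e-4, chosen so that a single-window state flip requires an emission
log-likelihood advantage larger than ~23 nats — isolated flips are
effectively impossible, and errors concentrate at segment boundaries.
At sigma = 0.3 (realistic normalised-coverage noise) decoding accuracy
exceeds 99% of windows.

Per-gene copy number is the modal Viterbi state over windows overlapping
the gene, ties resolved to the lower state. Amplifications beyond the
state ceiling are quantified by the median normalised coverage over
windows fully inside the CNV region minus 2; on a planted 26-extra-copy
amplification this recovers the truth within ±1 copy while the HMM
saturates at 10 extra copies.

One spec-level invariant was corrected during development: scaling a
coverage track and sigma jointly does NOT leave the Viterbi path
unchanged, because emission means are anchored at the state values. The
invariance holds when track, sigma and the state means are scaled
together; `CoverageHMMParams.state_means` exists so the property can be
stated and tested in that correct form.

## GWAS

SNP-wise GWAS keeps sites with no missing data and minor allele count
≥ 5, then drops sites whose genotype dose is Spearman-correlated with
the per-sample contamination fraction at p < 0.05 (contamination-driven
artefact calls correlate with contamination level; Spearman is used
because the relationship need not be linear). Each surviving site gets a
binomial-logit GLM on dose. Multiple testing uses Benjamini–Hochberg at
Q = 1% — a deterministic, dependency-free substitution for empirical-null
local-FDR tools. The windowed rule ranks sites by p (ties by position),
takes the top 1000, tiles each contig with non-overlapping 100-kb
windows anchored at coordinate 0 (the phase is configurable), and flags
tiles holding ≥ 10 top sites.

Location enters association models as a fixed-effect covariate when
needed; with only two sampling locations a random-effect variance
component is not estimable.

## Power simulation

For a cohort of n mosquitoes, each is a CNV carrier with probability
equal to the carrier frequency; death occurs with the non-carrier or the
carrier mortality; the carrier GLM is fitted per replicate and power is
the fraction of replicates with carrier-term P < alpha (LRT under
separation; replicates with a single phenotype class or constant carrier
status count as non-significant and are tallied). Carrier counts are
resampled per replicate rather than fixed — the two designs agree to
within Monte Carlo error. At the reference design (n = 151, carrier
frequency 0.74, mortalities 0.442/0.167, 1000 replicates) the estimator
returns ~0.90–0.93 depending on seed; a 200,000-replicate closed-form
evaluation puts the exact power of this design at 0.914 (Wald) / 0.910
(LRT), so values in that range are the statistic, not noise.

## Synthetic-data generator

Each genomic block is an independent Kingman coalescent genealogy:
within-population coalescence back to a divergence time tau (units of 2N
generations), then a shared ancestral pool — tau is the differentiation
knob. Mutations are Poisson on branches at rate theta/2 per unit length
(so E[pairwise diversity] = theta per block, verified to 10% over 200
replicates), or conditioned on a fixed site count placed proportionally
to branch length when a deterministic site grid is wanted. Sites map to
uniform integer positions within the block's span; collisions redraw.
Block independence stands in for recombination.

The sweep is implanted by overwriting the focal block of a fraction f of
haplotypes with one core haplotype, then adding Poisson(0.25) private
flips per copy — enough sub-structure to mimic CNVs arising on an
already-sweeping background without destroying exact-match identity.
The core is drawn either from the swept population or (the study
configuration) from a diverged donor population: a "migrant-core" sweep.
The latter models the widely observed arrival of resistance haplotypes
by migration between populations and guarantees the swept haplotype is
distinguishable from the local background in allele frequency — a sweep
implanted on a random local haplotype is, in roughly one seed in six,
nearly invisible to FST/PBS (its alleles sit close to the population
centroid) even though H12 detects it every time. Haplotype-identity
statistics and frequency statistics genuinely differ in what sweeps they
can see; the study configuration plants a sweep visible to both.

CNV carriers are samples with ≥ 1 swept haplotype (with a linkage
probability knob); carriers draw 2–8 extra copies by default; coverage
per 300-bp window is Normal(true total copy number, 0.5) truncated at
zero, mean 2.0 outside the CNV region. Phenotypes are Bernoulli deaths
at 44.2% (non-carriers) vs 16.7% (carriers) — the reference bioassay
effect size. Full-sib pairs replace founder slots by drawing one
haplotype per parent per block (free recombination between blocks).
Contamination fractions are Uniform(0, 0.05), with an optional planted
genotype-contamination correlation to exercise the exclusion filter.

The end-to-end study conditions (`sweep_study_config`,
`simulate_study_cohort`) are: a bioassayed pool of 1100 mosquitoes in
the focal population, 16 blocks × 400 SNPs, a migrant-core sweep at
f = 0.6 in block 3 fully linked to the CNV, and case-control sequencing
of 200 dead + 200 alive individuals — mirroring the field practice of
sequencing balanced phenotype classes from a larger assayed pool. The
cohort size was set by a design analysis of these fixed effect sizes:
with an 84% carrier fraction and a ~2.6 survival odds ratio, the
haplotype-frequency contrast between classes is Δp ≈ 0.16, and the
99%-quantile permutation retention rule needs roughly 200 samples per
class for that contrast to clear it reliably. Scans on this cohort use
400-SNP H12 windows and 120-SNP FST windows (the filtered sweep block
spans ~330 sites, so at least one FST window falls fully inside it).

What the generator does not model: recombination within blocks (no LD
decay), demographic history beyond a clean split, selection acting
through time (the sweep is implanted, not evolved), read-level error or
mapping bias in coverage, and dose-response bioassay structure (a single
pair of mortalities, not a kill curve). Passing tests therefore show the
statistics and filters behave correctly on data satisfying their
assumptions — not that those assumptions hold in any particular field
dataset.

## Problem sizes in the test suite

The suite runs entirely on generated data: calibration checks use 200
null cohorts of 300 samples × 150 SNPs (GWAS uniformity), 200 small
permutation-filter cohorts, and 40 contamination cohorts; parameter
recovery uses 100 coverage tracks and 100 sib pairs; end-to-end recovery
uses 50 study cohorts plus 20 shared-sweep controls. These sizes give
binomial standard errors comfortably inside the asserted bounds.

## Known limitations

* Kinship from called genotypes, not genotype likelihoods — fine at high
  coverage, biased at low coverage.
* The coverage HMM assumes pre-normalised coverage; no GC correction.
* BH-FDR assumes (positive-dependence-tolerant) validity of per-SNP
  p-values; heavily structured cohorts would need a mixed model, which
  is out of scope.
* CNV allele identity (breakpoint-level genotyping from discordant or
  soft-clipped reads) is not implemented; coverage-level calls only.
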