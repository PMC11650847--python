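# Methods

`seldrift` implements the computational chain used to monitor selection and
drift in closed, pedigreed breeding populations — the setting of commercial
pig or poultry nucleus lines genotyped over a handful of birth-year cohorts.
This note records the models, the numerical choices, and what the synthetic
data do and do not establish.

## Effective population size from pedigree inbreeding

For each birth-year cohort of genotyped animals, mean kinship is

    f_t = 0.5 * mean off-diagonal of A restricted to the cohort,

with A the numerator relationship matrix computed by the tabular method over
the ancestor closure of the requested animals (provably identical to using
the full pedigree; diagonals are 1 + F_i). Ordinary least squares of
ln(1 - f_t) on calendar year gives a slope b, and

    dF_year = 1 - exp(b),   dF_gen = L * dF_year,   Ne = 1 / (2 dF_gen),

where the generation interval L is the mean parent age over all
offspring-parent links with both birth dates known. Worked example: a rate of
inbreeding of 0.36% per year with L = 1.43 years gives Ne = 1/(2·1.43·0.0036)
= 97.1, displayed as 97 (rounding is half-to-even).

Choices: cohorts are genotyped animals only, per line; years with fewer than
two cohort members are dropped with a warning; the covariate is calendar year,
not cohort index; a non-increasing kinship series yields an
undefined-with-flag Ne rather than an exception. Founders are animals with
both parents unknown; a single unknown parent side is treated as a unique
unrelated, non-inbred phantom founder (equivalently, its A-row contribution
is zero), which keeps kinship and gene dropping consistent.

## Genotype QC and imputation

Dosages are counted-allele counts (ALT for VCF input) in {0, 1, 2} with NaN
missing. QC removes, in order: animals with > 5% missing calls, exact
duplicate genotypes (identical calls and missing pattern; first id kept),
animals whose opposing-homozygote rate against a genotyped parent exceeds
2% (a standard surrogate for a pedigree-genotype conflict), then markers with
> 5% missingness and monomorphic markers (default scope: the combined
dataset across lines; a per-line scope is available). Because each removal
changes the missingness denominators of the rest, the stage sequence is
iterated to a fixed point, which makes QC idempotent.

Residual missingness is filled by per-marker mean imputation (the unrounded
marker mean). With at most 5% missingness per marker this perturbs a cohort
frequency by < 0.025 in the worst case; it trades a small loss of accuracy
against an LD-based imputation model for having no phasing machinery at all.
Near-duplicate (IBS-based) detection and haplotype-aware imputation are out
of scope.

## Gene dropping: the drift null

A single biallelic locus is simulated through the observed pedigree. Founders
receive two alleles drawn independently as the carrier allele with
probability equal to a founder MAF (Hardy-Weinberg sampling); each
non-founder inherits one uniformly chosen allele from each parent, a phantom
side drawing a fresh allele at the founder MAF. The founder MAF grid is
0.01–0.50 in steps of 0.01 with 1000 replicates per value by default. Cohort
frequencies are computed exactly as for observed genotypes (genotyped
animals per line and birth year).

The envelope conditions on the **realized baseline-year cohort MAF** (folded
to <= 0.5), not the founder-assignment MAF: observed SNPs are conditioned on
their baseline MAF, so the null must be conditioned the same way. Replicates
fixed at baseline (MAF exactly 0) cannot correspond to a segregating SNP and
are excluded. Bins of width 0.01 with fewer than 30 replicates are merged
with their right neighbour and flagged. Per bin and horizon year the envelope
reports the mean |dp|, a normal-approximation 95% CI of the mean across
replicates, the 0.95/0.99 quantiles and the maximum; per-SNP comparison
reports the envelope quantile of each observed |dp|, an exceeds-max flag,
and a two-sided z test of the per-bin observed mean against the drift mean.
The CI is across replicates (an alternative reading — across SNP-equivalents
— exists; this is the documented choice). Gene dropping is run per line
against the full combined-ancestry pedigree.

RNG: one root seed; per-founder-MAF child streams are spawned with
`numpy.random.SeedSequence`, with replicates vectorized inside each stream.
Results are bit-identical for a given seed.

Calibration: on a discrete-generation random-mating two-sex pedigree of
constant census size N, the founder cohort is itself one Hardy-Weinberg
sampling step from the base frequency, so the cohort born at generation g
has variance p(1-p)(1 - (1 - 1/(2Ne))^(g+1)) with Ne ~ N. The test tolerance
(variance ratio in [0.75, 1.30] at 1000 replicates) is about five standard
errors of a variance estimate at that replicate count plus a small allowance
for Ne(pedigree) deviating from N.

## Mixed-model GWAS

For trait y and each marker i the model is

    y = X b_i + Z1 u_i + Z2 a_i + w_i v_i + e_i,

with a ~ N(0, G sigma2_A), G the VanRaden method-1 GRM
(G = ZZ' / (2 sum p(1-p)), Z = M - 2P, frequencies from the analyzed animals
by default so the grand sum of G is zero), optional i.i.d. extra random
factors u (batch, litter, herd-year-season, ...), and v_i the fixed allele
substitution effect of the marker. Variance components are estimated once per
trait by REML under the null model (no SNP) and held fixed across the scan;
the covariance V is Cholesky-factored once and every marker costs one GLS
update, which is what makes a 40k-marker scan with a dense GRM tractable.

REML: animal-only models use the eigendecomposition of K = Z2 G Z2' and a
bounded 1-D profile-likelihood optimization of the heritability ratio
(tolerance 1e-10 on the ratio). Models with extra random factors maximize the
restricted log-likelihood over log-variances by Nelder-Mead with a
Cholesky-based likelihood (convergence 1e-8 on the log-likelihood);
components within 1e-6 of zero total variance are flagged as boundary
estimates, and non-convergence raises with the last iterate.

Scan inference: Wald z = v/SE with standard-normal two-sided p-values
(an optional t reference on n - rank(X) - 1 df is provided); SEs are exact
given the fixed V. Markers collinear with the fixed effects (e.g.
monomorphic in the analysis set) are reported as NaN sentinels and excluded
from the estimable count. The Bonferroni threshold is -log10(alpha/m) with m
the number of scanned markers (the fixed-m convention); per-SNP variance
explained is 2p(1-p)v^2, optionally as a fraction of phenotypic variance.
Genomic inflation lambda is the median Wald chi-square over 0.454936; QQ
plotting positions are k/(n+1). Imputed (fractional) dosages enter the scan
as-is.

## Synthetic breeding populations

The generator emulates a closed maternal nucleus line: overlapping
generations with parents used at ages 1–2 years (default mix 60/40, giving a
generation interval of ~1.4 years), seven birth-year cohorts (2015–2021),
unlinked biallelic markers with founder frequencies uniform on (0.05, 0.5) in
Hardy-Weinberg proportions, pleiotropic QTL whose per-trait effects are drawn
from a configurable genetic correlation matrix and scaled so the additive
variance at founder frequencies matches each trait's h2, phenotypes with
batch and litter effects (5% of phenotypic variance each by default), and
per-year genotyped cohorts at a configurable fraction. Selection is
truncation on the true index (sum of weighted true breeding values) within
each parent age class, or random selection for drift-only nulls. Two lines
are independent replicates sharing the marker map and counted alleles.
Desk-scale defaults (2 lines x 7 years x 2000 markers x ~300 genotyped/year)
keep every end-to-end test in seconds to minutes.

What the generator does **not** emulate: linkage (markers are unlinked by
default, so hitchhiking and LD between markers and causal loci are absent),
mutation, genotyping error, EBV-based selection (selection acts on true
index values), or a real genome map. Passing tests therefore establish the
statistical machinery — the drift null, the scan algebra, the Ne chain — on
populations with the assumed structure, not the biology of any particular
dataset.

Two auxiliary generators support calibration: a discrete-generation
random-mating two-sex population of constant census size (the idealized
population for drift-variance and Ne-recovery checks), and a cross-sectional
GWAS cohort of unrelated individuals with an optional planted QTL of chosen
phenotypic-variance fraction. In the cohort generator the polygenic
background can be built from a separate background-marker panel so that
tested markers form a clean null; when a QTL is planted inside the tested
panel its polygenic background effect is zeroed so the marginal effect is
exactly the configured one. For power checks the GRM is built on the union
of tested and background markers: with a small GRM panel the tested QTL's
share of G shrinks its own signal (proximal contamination), an artifact of
small marker counts that a chip-density panel makes negligible.

## Allele-frequency-change analytics

Changes are reported against the baseline-year cohort (signed dp and |dp|),
with the baseline MAF folded to <= 0.5. Strata for MAF-conditioned summaries
are (0, 0.05], (0.05, 0.1], (0.1, 0.2], (0.2, 0.5] with closed right edges.
Year-to-next-year change regressions use |dp| on |effect| and on -log10 p
(significance is unsigned, so the unsigned pairing is the coherent default; a
signed variant is a matter of passing signed columns). Between-line
correlation is the squared Pearson correlation of signed dp over shared
markers and requires counted-allele metadata on both tables — a silent
orientation flip would corrupt the sign. Trajectories of significant regions
are oriented to the allele that was below 0.5 in the baseline year (exactly
0.5 keeps the counted allele); the lead SNP is the maximum -log10 p, ties
broken by smaller position. "Change from the current to the next year" is a
birth-year-cohort step, which at a generation interval of ~1.4 years is ~0.7
generations; it is kept as year-to-year deliberately.

## Pipeline

`run_pipeline` executes simulate (or load provided inputs) -> QC -> Ne ->
cohort allele frequencies -> GWAS per line and trait -> gene dropping ->
change analytics -> report, writing TSV/JSON for every tested quantity and
SVG figures as artifacts. One root seed in the config drives every stage;
per-stage streams are derived from the seed and the stage name so reruns are
bit-identical and stages are individually reproducible. A failing stage
aborts with its name and leaves a partial manifest.

## Problem sizes in the test and acceptance runs

The bundled checks use: 1000 gene-drop replicates on an N = 100,
10-generation pedigree; 20 replicate pedigrees per census size for Ne
recovery; 100 seeds of 500 animals x 200 null markers for calibration;
12 runs of 2000 animals x 1000 tested markers (GRM on 7000) for power; and
drift/selection contrasts on 2 lines x 2000 markers x 7 cohorts. These sizes
were chosen so the whole suite completes in a few minutes while leaving the
Monte-Carlo tolerances meaningful.

## Known limitations

- No linkage: drift envelopes and GWAS are per-locus; clustered signals and
  LD-based clumping are out of scope.
- Mean imputation biases individual dosages toward the marker mean; with the
  enforced <= 5% missingness this is negligible for cohort frequencies but
  would not be acceptable for haplotype-level analyses.
- REML with many extra random factors uses a derivative-free optimizer; it is
  robust but slow for n well above ~2000 observations.
- The index trait in real data is a combination of estimated breeding values;
  here it is treated as an ordinary response column, and its "heritability"
  should not be over-interpreted.
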