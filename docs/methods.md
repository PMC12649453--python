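# Methods

## Scope and data model

The pipeline analyses a *cohort*: an animal × locus matrix of unphased
biallelic genotype calls joined to per-animal litter-size records. Loci
are opaque positional labels with explicit reference/alternate alleles;
heterozygotes are stored canonically (reference allele first), so
`A/G` and `G/A` are one call. Missing calls are excluded locus-wise
from every downstream count; no imputation is performed. Litter size
must be a positive integer because the sampling design only enrolls
ewes with a lambing record — a zero is treated as a data error.

## Diversity statistics and Hardy–Weinberg testing

Allele frequencies come from gene counting on raw genotype counts,
never from re-rounded genotype frequencies. Homozygosity,
heterozygosity, the effective number of alleles and PIC are computed
from the defining sums over allele frequencies; the code accepts *k*
alleles even though the shipped cohorts are biallelic. PIC classes use
the conventional cutoffs (< 0.25 low, 0.25–0.5 moderate, ≥ 0.5 high);
the boundary value 0.25 is assigned to "low" because the defining
inequalities are strict and leave it to convention.

The Hardy–Weinberg test is the uncorrected three-class χ² with
expectations (*p*², 2*pq*, *q*²) and 1 degree of freedom (three classes
minus one minus one estimated frequency). A homozygote class with zero
observations still contributes its expected term (0 − *np*ᵢ)²/*np*ᵢ —
dropping it changes the statistic materially at the rare-allele loci in
the reference tables. Monomorphic loci are reported as χ² = 0, p = 1
with *H*ₑ = PIC = 0 and *N*ₑ = 1. An exact test conditional on allele
counts is available behind a flag but is off by default: the reference
values this package reproduces are the plain χ² statistic.

## EM haplotype estimation and LD

For two biallelic loci only the double heterozygote is phase-ambiguous.
The EM split assigns it to the coupling (AB/ab) versus repulsion
(Ab/aB) configurations in proportion to the current haplotype-frequency
products; the M-step recounts haplotypes. Every iterate preserves the
single-locus allele frequencies (allele counts are sufficient
statistics for the margins), and the log-likelihood is non-decreasing.

Numerical choices:

- Initialization: linkage equilibrium (products of margins), plus —
  whenever double heterozygotes are present — three additional starts
  spread across the admissible one-parameter family of the coupling
  frequency (5%, 50%, 95% of its Fréchet range). The equilibrium point
  can be an *unstable fixed point* of EM (the 50/50 phase split maps to
  itself on some small tables), and the likelihood can be bimodal; the
  run with the highest final log-likelihood is returned. All starts are
  deterministic.
- Stopping: largest absolute frequency change < 10⁻⁸, iteration cap
  50 000. Near-degenerate tables with a boundary optimum converge
  linearly with rate very close to 1 and genuinely need tens of
  thousands of (trivially cheap) iterations to bring the log-likelihood
  within 10⁻⁶ of the optimum, which is the accuracy the test suite
  demands against an exhaustive grid oracle; a cap of 1 000 is not
  enough for those tables.
- Haplotype frequencies below 10⁻¹² are clamped to zero for reporting.
- Non-convergence returns the best estimate flagged
  `converged=False` with a warning.

D′ uses Lewontin's sign-dependent normalization
(D_max = min(p_A q_B, q_A p_B) for D > 0, min(p_A p_B, q_A q_B) for
D < 0). The "strongly linked" call is the conjunction D′ > 0.86 and
r² > 0.30; both thresholds are configurable. A monomorphic margin
leaves D′ and r² undefined and yields a flagged null result rather
than a number.

The test-suite oracle exploits the margin-sufficiency property: since
any likelihood maximum has haplotype margins equal to the sample
allele frequencies, the exhaustive search runs over the single free
coupling frequency on a fine grid (coarse-to-fine down to step 10⁻⁶)
instead of the full three-dimensional simplex.

## Association analysis

Litter size is treated as a general numeric trait (the mathematics
nowhere assumes it is binary, although the reconstructed cohorts are).
Groups with fewer than three animals are summarized (n, mean, sample
SD with n − 1 denominator) but excluded from testing, a literal reading
of the source's minimum-group rule. Eligible groups enter a classical
fixed-effects one-way ANOVA; pairwise comparisons default to
pooled-variance t tests using the ANOVA mean square error with its full
residual degrees of freedom (Fisher's LSD, unadjusted — the source
applies no multiplicity correction across its eight loci either).
Welch, Bonferroni-adjusted and Tukey HSD alternatives are exposed as
options, and a cross-check against statsmodels' Tukey implementation is
part of the test suite.

The compact letter display uses the insert-and-absorb algorithm:
starting from one letter shared by all groups, each significant pair
splits every column containing both, and columns that become subsets
of others are absorbed. The construction guarantees the defining
equivalence — two groups share a letter iff their pairwise p ≥ α —
which the tests verify against a brute-force checker on random
p-matrices. Letters are assigned in descending-mean order (ties broken
by group label); lowercase letters encode α = 0.05, uppercase α = 0.01,
computed independently.

## qPCR relative expression

Replicate Cts are averaged arithmetically per sample/gene before
differencing (the conventional procedure; replicate-outlier rejection
is out of scope). ΔΔCt is taken against the calibrator-*group* mean
ΔCt, not a single designated sample. Amplification efficiency is fixed
at 2. Group contrasts reuse the association ANOVA/letter machinery and
run on −ΔΔCt (log₂ fold) by default because fold ratios are
log-normal; a flag switches to the fold scale. Two-factor panels (e.g.
tissue × developmental stage) are lettered within each level of the
conditioning factor.

## Reproductive metrics

Fertility = lambed/mated × 100; fecundity = total lambs/mated × 100;
prolificacy is reported both as the percentage of lambed ewes with
multiples and as mean lambs per lambed ewe (the term is used both ways
in the livestock literature; the two fields are named distinctly).
Percentages are rendered at 1 decimal in reports, SDs at 3, other
floats at 2; JSON output always carries full precision.

## Synthetic data and the reconstructed cohort

The generator emulates the study conditions: genotypes drawn under
Hardy–Weinberg proportions at configured allele frequencies (or from
four-haplotype frequencies for linked pairs, by random union of
gametes), litter size 1 + Bernoulli with genotype-dependent twin
probability (per-locus probabilities combine multiplicatively on the
relative scale against a base twin probability of 0.5, roughly the
reconstructed cohort's twin fraction, capped to [0, 1]), and Ct
triplicates with Gaussian technical noise around a reference level of
15 cycles and a baseline ΔCt of 6 cycles. One named generator seeded
from a single integer drives all randomness; equal seeds give
byte-identical cohorts.

The reconstructed 157-ewe cohort is built per locus: class sizes come
from the published association table, and twin counts per class are
the integers whose group means round (half-up, 2 dp) to the printed
values while summing to the cohort's 79 twin litters. The inversion is
unique at seven of eight loci. What it does *not* emulate: joint
genotypes across loci (never published, so fixtures are single-locus
and multi-locus behaviour is only covered by the simulator), pedigree
relatedness, parity/age structure, and litters above 2. Passing
reproduction tests therefore demonstrate the arithmetic of the
pipeline on the published margins, not robustness to family structure
or covariates.

## Known inconsistencies in the reference tables

Recomputation from the tables' own genotype counts shows several
printed cells cannot be produced by the defining formulas; the test
suite asserts the disagreement instead of matching them:

- Diversity table: the heterozygosity/PIC pair at three rare-allele
  loci (printed 0.43/0.42, 0.68/0.65, 0.50/0.50 where the formulas give
  ≈ 0.04, 0.07, 0.05) and an effective allele number of 0.13 (< 1 is
  impossible; the formula gives 1.14). Three further *N*ₑ cells differ
  by one unit in the last digit, consistent with computing 1/*H*ₒ from
  the already-rounded homozygosity or truncating instead of rounding.
- Frequency/HWE table: one locus prints χ² = 2.85 although its
  genotype counts equal those of another locus printing 0.85; three
  genotype-frequency cells are off by 0.01 at 2 dp.
- Association table: one heterozygote group (n = 40, printed mean
  1.56) admits no integer twin count consistent with the cohort twin
  total; the reconstruction uses the nearest composition (22 twins,
  mean 1.55) and its row — plus the 0.001-off SD of the neighbouring
  ref-homozygote cell — is excluded from exact matching.
- Letter patterns: at the locus with classes of 150 and 7 animals the
  printed lowercase a/b pattern implies p < 0.05, but the
  reconstructed composition gives a pooled-variance p of 0.0515 (Welch:
  0.0388; normal approximation: 0.0497). No single standard pairwise
  test reproduces all four printed letter patterns simultaneously
  (Welch reproduces this one but breaks another locus's a/b/b). The
  package keeps the pooled default; the corresponding reproduction
  test case is expected to fail and documents this irreproducibility
  honestly rather than special-casing the method per locus.

## Test problem sizes

Stochastic guarantees use: type-I-error calibration of the HWE χ² at
n = 157 over 2 000 replicates (99% binomial bounds around 0.05, minor
allele frequency 0.3 where the three-class asymptotics are sound);
estimator recovery (allele frequency, PIC, r², twin-probability
difference) at n = 5 000 within 3 Monte-Carlo standard errors; EM
versus exhaustive grid on 200 random tables of up to 30 animals;
letter-display equivalence on hundreds of random p-matrices. These
sizes make the full suite run in well under a minute while keeping
every bound at the 3-sigma/99% level.
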