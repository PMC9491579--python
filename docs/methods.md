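# Methods

`methgwas` implements a conditional mixed-model GWAS workflow for transposon
non-CG methylation in selfing plant panels, together with the synthetic
study populations used to validate every stage. This note documents the
models, the numerical choices, and what the synthetic data do and do not
establish about behaviour on real data.

## Methylation phenotyping

Per-cytosine bisulfite calls arrive in allc-style records
(chrom, 1-based position, strand, context, methylated reads `mc`, total
reads `total`). The level of a feature (transposon or gene, 0-based
half-open interval `[start, end)`) in a context is the **weighted
methylation level** `sum(mc) / sum(total)` over cytosines with
`start < pos <= end`, both strands pooled. A feature with zero covered
reads is *undefined*, never 0; the per-line trait is the unweighted mean
over features with at least one mapped read. Length- or coverage-weighting
across transposons is deliberately not applied (unweighted averaging is the
simplest defensible reading of "average over all transposons with at least
one read"); this is a documented choice, not a measurement.

Transposons are classified as CMT2-targeted when wild-type minus *cmt2*
methylation exceeds 0.1 (strictly), RdDM-targeted analogously with
*drm1 drm2*. When both differences exceed 0.1 the larger one wins (the
source rule is silent; a flag allows overlapping sets). The
mutant-vs-wild-type differential caller flags a feature when a two-tailed
Welch t-test on replicate levels gives p < 0.01 **and** the absolute mean
difference exceeds 0.1; features with fewer than two replicates per group
are skipped with a warning.

## Kinship and REML

Kinship is identity-by-state: the fraction of jointly non-missing SNPs
(all SNPs, no MAF filter) at which two lines carry the same allele.
Genotypes are haploid-equivalent {0,1}; the panels are selfing inbred
lines, so no heterozygotes exist.

The null model is `Y = Xb + g + e`, `var(Y) = sg2*K + se2*I`. With
`K = U S U'` computed once, the restricted likelihood is profiled over the
variance ratio `delta = se2/sg2` on a 100-point log grid spanning
[1e-5, 1e5], refined by bounded Brent optimization; grid ties break toward
smaller delta, and boundary solutions are flagged. Pseudo-heritability is
`h2 = 1/(1+delta)`.

A practical identifiability caveat, visible throughout the test fixtures:
the information about `delta` comes from the *spread* of the eigenvalues of
K. An IBS matrix built from many more SNPs than lines has a nearly flat
bulk spectrum (plus one large near-constant eigenvalue), which leaves
`delta` weakly identified; recovery fixtures therefore use panels with
SNP counts comparable to line counts, where the bulk spectrum is spread.
This mirrors a real property of REML heritability estimation, not an
implementation artifact.

## Association scans

For a scan of trait `Y` (optionally conditioning on a correlated trait `L`
as fixed covariate), lines missing `Y` or `L` are dropped; `Y`, `L`, and
every tested SNP are z-scored over the retained lines (missing genotypes
mean-imputed first); SNPs must pass MAF > 0.05 (strict, as printed).
Two delta treatments are available:

* **default** — delta fixed at the no-SNP null estimate (EMMAX
  approximation); each SNP is then a GLS fit in the rotated space, Wald
  two-sided p from t with n − p degrees of freedom.
* **exact** — the profiled restricted likelihood is evaluated on the same
  grid for *every SNP with the SNP in the model*, vectorized across SNPs,
  and each SNP is tested at its own maximizing delta.

The distinction matters precisely for major-effect loci: the EMMAX null
absorbs a large tested effect into `sg2` ("proximal contamination"),
inflating the variance assigned to the SNP's own ancestry component and
attenuating its test — on the canonical fixture below, the planted locus
loses ~12 units of −log10 p under the default mode. The exact mode is
therefore used wherever a single locus carries ~10% of the variance; the
default remains appropriate (and two orders of magnitude faster) for
polygenic scans. Degenerate inputs are handled explicitly: a covariate
that explains the phenotype completely yields p = 1 everywhere; a SNP
collinear with the covariate gets p = 1 with a flag. Bonferroni correction
divides alpha by the number of MAF-passing SNPs actually tested.

## Bivariate multi-trait mixed model

Two z-scored traits are stacked with covariance `Vg (x) K + Ve (x) I`.
In the eigenbasis of K the model is block-diagonal in 2x2 blocks
`C_i = s_i*Vg + Ve`, so the REML likelihood is O(n). `Vg` and `Ve` are
parameterized by log variances and bounded correlations
`rho = 0.99*tanh(theta)` (residual variances floored at 1e-6), which keeps
every block nonsingular — including for perfectly correlated traits —
while spanning all covariance pairs with |rho| <= 0.99. Optimization is
Nelder-Mead from 5 deterministic starts (a moment-based start plus seeded
perturbations), tolerance 1e-8 on the log-likelihood.

Per SNP, trait-specific effects (b1, b2) are fitted by GLS with the null
covariance held fixed; three Wald chi-square tests are reported: **any**
(2 df, (b1,b2) = 0), **common** (1 df, shared effect under b1 = b2), and
**specific** (1 df, b1 − b2 = 0). When the two traits are numerically
identical the fit sits on a singular boundary: the specific statistic is
exactly zero (by symmetry of the limit), the fitted variance ratio matches
the univariate REML to ~1e-6, SNP ranking under the common test matches
the univariate scan, but the common statistic is a constant factor ~2
above the univariate t^2 (the duplicated observations are counted at the
limiting scale). Perfectly duplicated traits are outside the model's
domain; the scan still returns well-defined output there.

Two analytic facts shaped the tests: (i) for *uncorrelated* traits a
one-trait-only effect gives exactly equal common and specific statistics
(both half the 2-df statistic), so the specific-vs-common contrast only
exists for correlated traits; (ii) the genetic correlation is weakly
identified on small panels (per-fit sd ~0.1 at n = 500), so recovery is
assessed as a mean over replicate fits.

## Enrichment, FDR bound, genome rotation

Each gene receives the minimum p-value among MAF-passing SNPs within 15 kb
of its annotated boundaries (`start − w < pos <= end + w`; ties break to
the smaller position); genes with an empty window are flagged and excluded
from denominators. For a threshold p, `x_p` (`y_p`) is the fraction of a
priori (background) genes with assigned p strictly below it; enrichment is
`x_p/y_p` (undefined where `y_p = 0`), and `y_p/x_p`, clipped to [0,1], is
an upper bound on the FDR within the candidate set under the assumption
that all background associations are false. The bound is on the *rate*:
single-realization false-discovery proportions can exceed it, so the
validation pools replicates. The default threshold grid is −log10 p from
1 to 12 in steps of 0.25.

Rotation significance orders genes by (chrom, start), circularly shifts
the membership vector by a uniform offset, and recomputes enrichment;
p = (1 + #{rotation >= observed})/(R + 1), with comparisons done by
cross-multiplication so zero-background rotations are handled without
division. Exhaustive mode enumerates all G offsets and reports the exact
tail fraction #/G (the identity offset guarantees positivity, so the
sampling +1 correction would bias small-G comparisons). Rotation preserves
both the per-gene p-values and their order along the genome, hence the
LD-induced autocorrelation that makes naive permutation anticonservative.

## Allele analysis and permutation tests

The decreasing allele at a focal locus is the genotype code with negative
fitted effect in the (conditional) scan; an exactly zero effect cannot be
oriented. Cumulative counts, the additive (OLS) dose-response fit, and the
joint r² of the focal loci are straightforward; lines with missing focal
genotypes, longitude, or insertion data are dropped listwise per test.

Null SNP sets match each focal locus on its exact minor-allele count
(strictest reading of "same allele frequencies"); a frequency-bin mode
(default half-width 0.01) exists for panels where exact matching is too
sparse. Three tests share this null:

* **cline** — Pearson r between cumulative count and longitude, two-sided;
* **LD** — same with a partner locus genotype in place of longitude;
* **epistasis** — mean insertion count among partner-alt carriers with
  exactly k (configurable: >= k) decreasing alleles, one-sided (greater),
  per k in 0..5; empty classes are flagged, not zero-filled.

All permutation p-values use the add-one correction, so they live in
[1/(R+1), 1] and are deterministic under the permutation seed. Two calibration
caveats are documented rather than hidden: exact-MAC matching on small SNP
panels yields an atomically discrete null (calibration checks need many
candidates per locus), and under strong structure the class-conditional
carrier frequency of matched SNPs can drift from the partner's, making
low-dose classes slightly miscalibrated; the planted-effect classes sit
far beyond either effect.

## The synthetic study populations

Genotypes follow a Balding-Nichols scheme: ancestral frequency
p0 ~ U(maf_floor, 1 − maf_floor), per-cluster frequencies
Beta-distributed around p0 with divergence `fst`, lines Bernoulli within
clusters; optional block-copy LD (blocks of 10, flip rate 0.05) and a
missingness mask. Positions are laid out at 200 bp spacing over 5
chromosomes. Every generator is deterministic under its seed and all
planted quantities are exported to a truth file.

**Canonical two-trait architecture** (`default_config`): n = 800 lines,
10,000 SNPs, 10 clusters, fst = 0.5. A shared factor f (unit variance,
70% kinship-structured, 30% line-level/environment-like) enters trait1
with loading 1 and trait2 with loading 0.9; trait noise levels
(0.2236, 0.5933) make cor(trait1, trait2) = 0.8 in expectation, and one
trait-2-specific QTL at a strongly ancestry-differentiated SNP (cluster
frequencies alternating 0.01/0.99) has effect 0.2083 SD = 10% of
var(trait2 | trait1). These settings were chosen so that the univariate
mixed model genuinely confounds the QTL with the shared structured
variation (the scenario the conditional design addresses): a pure
variance-masking architecture cannot produce the conditional-vs-univariate
power contrast at correlation 0.8, because the univariate noncentrality is
then always 0.6x the conditional one. The strong divergence matters for a
second reason: the kinship matrix can only absorb ancestry-shaped trait
variance up to its own within/between contrast, so weakly structured
genotypes with strongly structured phenotypes leave the mixed model
miscalibrated — also a real-data phenomenon.

**Geography/epistasis architecture** (`clinal_config`): n = 900 lines,
five focal loci with cluster frequencies decreasing linearly along the
cluster (longitude) axis and planted trait-2 effects −0.15 each, an
unstructured partner locus at frequency 0.35, longitude = 0.46 x cluster
score + noise (scaled to a 10-50 degree range; cline strength chosen once
to give r(count, longitude) ~ −0.4), and insertion counts from a negative
binomial (mean 0.2, dispersion 1) whose log-mean gains log(30) for lines
carrying the partner alt allele and >= 2 decreasing alleles.

What the synthetic populations do **not** emulate: realistic LD decay and
recombination maps, rare-allele frequency spectra, admixture and isolation
by distance beyond a discrete cluster gradient, methylation context
mixtures within features, bisulfite conversion error, or shared
measurement batches. Passing tests therefore establish the statistical
machinery (calibration, recovery, power contrasts under the stated
architecture), not performance on any particular real panel.

## Problem sizes in the tests and acceptance script

The validation uses desk-scale panels chosen per property: oracle
equivalence at n = 28 (where explicit covariance inverses are exact and
cheap); null calibration at n = 300 with 1,000 near-unstructured SNPs x 20
replicates; variance-component recovery at n = 500 with ~1,000 SNPs;
the conditional-power contrast at the full fixture size (n = 800, 10,000
SNPs, 20 replicates, exact-mode scans); permutation tests at n = 900 with
3,000 draws. The real study's panel (774 lines, ~10.7M SNPs) differs only
in scale for the per-SNP operations, which are linear in SNP count.

## Known limitations

* One genetic variance component; no dominance (meaningless for inbreds),
  no GxE random effects.
* The exact mode maximizes delta on the grid points (4.3% log-spacing)
  rather than refining each SNP; the effect on p-values is far below the
  sampling noise of any fixture here.
* The FDR bound applies to the candidate set only and assumes candidates
  are exchangeable with background under the null.
* Exact-MAC permutation matching degrades on small panels (see above).
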