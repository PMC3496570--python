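# Methods note

## The statistical problem

A dairy GWAS sample assembled from artificial-insemination daughters is a
set of paternal half-sib families.  Family membership induces an
equicorrelated phenotype covariance within each family, and when one family
is very large, high-merit, and genetically distinct (an "elite" family), the
genome, pedigree and phenotype stratifications coincide.  An uncorrected
per-SNP test then confounds two signals it cannot distinguish: a true
allelic effect, and mere enrichment of an allele in a subgroup whose
phenotype mean differs for any reason.  The package implements three
corrections (half-sib GLS, an EMMAX-style mixed model, PCA covariates), the
uncorrected least-squares baseline, the elite-exclusion rerun, and the
descriptive analyses (MDS stratification, elite/average allele-frequency
differences) that characterise what the corrections remove.

## Models and estimators

### Half-sib GLS (`gls`)

Model: y = Xg + Zf + e, f ~ N(0, Iσ_f²) per sire family, e ~ N(0, Iσ_e²).
Within family i of size n_i, V_i = σ_e²I + σ_f²J; ρ = σ_f²/σ² with
σ² = σ_f² + σ_e².

* **Variance components** are estimated on the null model (intercept +
  covariates, no SNP) by maximum likelihood: for each ρ the scale σ² and the
  GLS mean have closed forms through the identity
  C⁻¹ = (I − r̃J)/(1 − ρ), so one likelihood evaluation costs O(n).  A
  200-point grid on ρ ∈ [0, 0.999] is followed by bounded scalar refinement
  (xatol 1e-10).  ρ = 0 is admissible; degenerate data (no within-family
  variance) report ρ at the upper search bound.  ML is the default because
  the estimation criterion must match the mixed model's when the two are
  cross-checked; REML is available via `criterion="reml"`.
* **Whitening.**  The factor L with L′L = V⁻¹ is built per family by a
  recursion that fills each row with one diagonal and one constant
  off-diagonal value (S₁ = 0; d_j = √((1−r)/σ_e² − S_j);
  c_j = (−r/σ_e² − S_j)/d_j; S_{j+1} = S_j + c_j²), i.e. O(n_i) storage and,
  using suffix sums, O(n_i) application.  Correctness is pinned to the
  verifiable contract ‖L′L − V⁻¹‖_max < 1e-8 against the closed-form
  compound-symmetry inverse and a dense Cholesky oracle, for family sizes up
  to 160 and ρ up to 0.9 (achieved: machine precision).
* **Per-SNP test.**  Genotypes enter as up to three class indicators
  (coding="classes", the default) or as an additive 0/1/2 dosage column
  (coding="dosage", for cross-method comparisons).  The whitened design is
  solved by least squares; additive (1, 0, −1) and dominance (−1, 2, −1)/2
  contrasts over the class values are t-tested with n − k df.  The contrast
  provider is pluggable so frequency-weighted contrast schemes can be
  substituted.  The per-SNP summary p is min(additive, dominance) with both
  retained — a documented convention, since a single ranking must combine
  the two effects somehow.  Variance components are estimated once per trait
  and reused for every SNP (the standard single-estimation scan shortcut).
* **Missing calls** drop the affected individuals from that SNP's test; the
  whitener is rebuilt for the reduced family sizes (same variance
  components).  No imputation, no call-rate filter by default.

### Mixed model (`mixed_model`)

var(y) = Kσ_a² + Iσ_e².  K is eigendecomposed once; the profile (REML by
default — the mixed-model convention; ML for exact comparisons with the GLS)
is maximised over δ = σ_e²/σ_a² on a 100-point log₁₀ grid spanning
1e-5..1e5 plus bounded refinement, with σ_a² closed-form at each δ.  Scans
rotate y, covariates and the dosage matrix once (O(n²m)) and then solve each
SNP in O(n) with weights 1/(σ_a²s_i + σ_e²).  The tested SNP is an additive
dosage regressor (3-class coding available); missing dosages are
mean-imputed per SNP for the scan only, never for kinship.  With
K = ZZ′ (family incidence) and ML on both sides, the mixed-model scan and
the GLS scan are the same model written in two parameterizations; the test
suite requires p-value agreement within 1e-6 (achieved ≈ 5e-8).

### Kinship (`kinship`)

IBS: s_ij = mean shared-allele fraction, computed from dosages as
1 − mean|d_i − d_j|/2 with three indicator matmuls; all called SNPs
contribute (a monomorphic locus adds full sharing).  BN: dosages centered by
2p̂ and scaled by √(2p̂(1−p̂)), K = SS′/m over polymorphic SNPs — the
standardized-genotype Gram matrix convention under which the expected
diagonal is 1 and σ_a²/(σ_a² + σ_e²) is a heritability.  Family: the 0/1
same-sire Gram matrix ZZ′.  Monomorphic SNPs are dropped from BN with a
logged count (standardization undefined there).

### PCA and least squares (`ls_pca`)

PCs are the left singular vectors of the column-centered standardized
dosage matrix; the default correction uses the top 20, computed once on all
SNPs including the tested one (no leave-one-chromosome-out, which is offered
nowhere because the emulated analyses used a single basis).  The
elite-exclusion rerun recomputes PCs and allele frequencies on the retained
individuals — it is a full reanalysis, not a row drop.  LS is the GLS
machinery with an identity whitener, so the ρ→0 equivalence is structural.

### Stratification (`stratification`)

Distance = 1 − IBS; classical (Torgerson) MDS via double-centering and
eigendecomposition, keeping positive-eigenvalue dimensions scaled by
√eigenvalue.  Elite/average assignment is 2-means on (C1, C2) with
deterministic seeding, the smaller cluster labelled elite; a known family id
bypasses clustering.  Axis signs can be fixed by forcing the elite mean
positive.  Cluster recovery is scored as purity = |A∩T| / max(|A|, |T|)
(= min(precision, recall)).  scikit-bio's principal-coordinates analysis
serves as an independent cross-check of the MDS in the tests, never as the
implementation.

### AFD (`afd`)

Per trait, the favorable allele is the one whose fitted additive effect
moves the trait in its desirable direction; low-favorable traits (SCS, SCE,
DCE, SSB, and DSB by analogy — overridable) reverse the sign rule.
Frequencies are counted over called genotypes per cluster;
AFD = |p_e − p_a| is invariant to which allele is designated, so genome-wide
threshold counts are orientation-free.

### Reporting (`reporting`)

Top-K extraction ranks by p with (chromosome, position) tie-breaks
(X after autosome 29); overlap tables count a reference method's top-K SNPs
inside every subset of comparison methods' top-K lists, with block totals
over the 13 production/health/reproduction and 18 conformation traits;
Bonferroni thresholds are α/n_tests with an explicit override slot for
replicating externally stated thresholds (e.g. 10^−6.4, which differs from
0.05/45,878 ≈ 10^−5.96 — the multiplicity behind the printed value is not
derivable, hence the override); significance flags are inclusive
(p ≤ threshold).  Small reference tables of published per-trait overlap
counts and elite/average frequency pairs ship with the package for
arithmetic cross-checks.

## The synthetic-data generator

`simulate.SimulationConfig` defaults ARE the emulated study conditions:
1,654 cows, 355 sires, a 160-daughter elite family (remaining family sizes
geometric, adjusted to sum, floor 1 — right-skewed like AI half-sib
families), 45,878 SNPs on 29 autosomes + X (50 kb spacing), base allele
frequencies Beta(2,2) clipped to [0.02, 0.98], σ_f² = 1 and σ_e² = 3
(ρ = 0.25), one expected crossover per chromosome per meiosis, all
individuals female.

Mechanics: each sire carries two autosomal haplotypes and a single X
haplotype drawn from population frequencies; a daughter's paternal gamete is
a Poisson-crossover recombination of the sire pair per autosome and the
intact sire X outside a configurable pseudo-autosomal prefix (whose boundary
has no claimed default — it is a free parameter).  Dams are unrelated
site-wise draws.  Phenotypes per trait are μ + planted additive effects
(sign flipped for low-favorable traits so planted allele 1 is always
favorable) + N(0, σ_f²) family effect + optional elite mean shift +
N(0, σ_e²) noise.

Design choices that matter:

* **Elite distinctness needs no planting.**  With zero planted divergence
  the elite family already separates in genome-wide MDS and produces a
  long AFD tail, because a sire allele that is rare in the population
  reaches ~50% among his daughters.  The study-default config therefore
  plants nothing; this also keeps the simulated AFD distribution
  (median ≈ 0.1, few loci ≥ 0.4) in line with real half-sib samples.
* **Planted loci plant cluster frequencies.**  At planted loci the elite
  family's paternal allele is an i.i.d. draw at the planted elite frequency
  (and elite dams draw from the elite frequency vector), because a single
  sire's two haplotypes cannot realise a designated cluster frequency —
  their sampling noise would dominate.  Realised frequencies then obey
  binomial bounds at the cluster sizes.  A planted X locus consequently
  breaks the shared-sire-haplotype identity at that site; tests plant on
  autosomes.
* **Confounded scenario** (`confounded_config`): elite sampling frequencies
  shifted by 0.4 at half the SNPs, twenty planted loci at 0.85/0.15 with
  zero effect, and an elite phenotype mean shift of 2.0 trait units (one
  phenotypic SD at the default variances; the emulated study reports no
  numeric shift, so one phenotypic SD was fixed as a realistic strong-
  selection displacement before any testing).  Every SNP is a true null, so
  rejections are pure stratification artifacts.
* **Two-cluster scenario** (`two_cluster_config`): the same 0.4-gap
  divergence with σ_f² = 0 — two homogeneous subpopulations, the canonical
  setting in which PCA correction must restore type-I calibration exactly
  (no residual family covariance remains for it to miss).
* **MDS scenario** (`mds_config`): 600 cows, a 60-daughter elite family
  among 121 sires (non-elite mean ≈ 4.5 daughters), 10 autosomes and X at
  80 SNPs each, no planted divergence.  The marker count per chromosome is
  deliberately in the regime where the per-autosome relatedness signal is
  marginal while the shared sire-X haplotype (which doubles within-family
  X similarity) remains clear; purity comparisons average 5 replicate
  populations because a single 2-means split of an 80-SNP chromosome is
  noisy.

What the generator does **not** emulate: linkage-disequilibrium decay
calibrated to the cattle genetic map, dam pedigrees and maternal
relatedness, multi-generation selection dynamics, genotyping error and
missingness patterns, and trait-trait correlations.  Passing tests
demonstrate the estimators' internal correctness and the direction of the
confounding mechanism under compound-symmetry assumptions, not quantitative
agreement with any real cattle data set.

## Problem sizes and numerical choices

Simulation-based checks run at reduced sizes chosen so each exercises the
relevant asymptotics while the whole suite stays interactive: type-I and
cross-method checks at 100 families × 10 with 2,000 SNPs; intraclass
recovery at 500 × 10 over 20 replicates; heritability at n = 1,000 with
2,000 SNPs; the confounding mechanism at n = 600 with 800 SNPs over 20
seeds; MDS structure at n = 600 over 5 replicates.  Stochastic assertions
use fixed seeds and the tolerance bands stated in the tests.

Tie-breaks are everywhere deterministic: (chromosome, position) ascending,
X ordered after autosome 29.  Rank vectors are permutations of 1..n_tested;
untestable (monomorphic) SNPs carry missing p and rank.  p-values are
two-sided throughout.  The ρ and δ profiles guard against refinement
regressions by falling back to the best grid point.  Degenerate designs
raise: rank deficiency names the column count, a zero standard error with a
nonzero estimate raises rather than fabricating a statistic, and σ_e²
underflow (ρ → 1) is reported with the offending value.

## Known limitations

* The GLS grouping is sire families only; other shared-environment groupings
  would need a different partition supplied as a `FamilyStructure`.
* No dominance variance component, multi-trait models, or epistasis scans.
* The mixed model re-estimates nothing per SNP (no exact per-SNP REML).
* Binary PLINK (.bed) and VCF are out of scope; genotype text I/O is the
  .ped/.map dialect only.
* Genomic-control λ is not implemented (not part of the analysis set this
  package reproduces).
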