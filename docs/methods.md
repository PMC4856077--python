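# Methods

## Model and procedure

The package analyses unphased biallelic genotypes for allele-specific
linkage disequilibrium. The pipeline is: (1) compute the four-element CCC
vector for every unordered SNP pair; (2) calibrate a significance
threshold by permutation; (3) join supra-threshold allelic pairs into
allele networks (connected components over 2n allele nodes); (4) compute
per-population network carrier frequencies; (5) regress carrier frequency
on latitude by weighted least squares; (6) run a parallel scalar-LD
analysis (r², D′ with step-down resampling correction) as the comparator.

### CCC

`CCC_ij[t] = (9/2) · R_ij[t] · (1 − f_it/q)(1 − f_jt/q)` over the four
allelic combinations *t*. The per-individual contribution to `R_ij[t]` is
the product of within-genotype allele frequencies (dosage/2 for the
counted allele, 1 − dosage/2 for the other). This contribution rule is
adopted because it exactly reproduces the canonical 10-individual example
(R = 0.05, 0.90, 0.00, 0.05); it requires no phase information — a double
heterozygote contributes 1/4 to every combination. Contributions and the
frequencies `f_kt` are both computed over the pairwise-complete individual
set, keeping all terms of the formula internally consistent (an
alternative per-SNP frequency basis is available via `freq_mode="per-snp"`;
the two coincide whenever a pair has no missing data). Pairs with no
pairwise-complete individual are flagged incalculable and carried through,
never silently dropped. Both 9/2 and q = 1.5 are treated as fixed
constants of the statistic.

Consequences worth knowing: Σ_t R[t] = 1 for every calculable pair; the
vector is symmetric under SNP exchange (transpose of the combination
grid) and equivariant under allele reorientation (a permutation of the
combination index); and because the statistic is an *uncentered* product
moment damped by allele frequency, its null mean varies strongly across
pairs with allele frequency — the null ceiling of a whole scan is set by
the most common allele combinations (frequencies near 0.75 maximise
f(1 − f/1.5)).

### Permutation null and threshold

The null permutes each SNP's genotype column independently across
individuals. The permutation unit is the diploid genotype, so per-SNP
genotype counts — including Hardy–Weinberg departures — are preserved
exactly, and missing calls travel with their genotype. Per trial, all
pairwise elements are recomputed and counted against candidate
thresholds. Two selection rules are exposed: *zero-false-positives* (the
smallest candidate at which no trial shows any supra-threshold element)
and *max-mean-rate* (the smallest candidate whose mean count per trial is
below a tolerance). Both rules exist because a scan may justifiably run
at a slightly lower threshold tolerating a known small false-positive
rate (≈0.1–0.15 per trial) rather than none. Threshold comparisons use
`>=` with no tolerance slack. One master seed spawns per-trial
substreams (`numpy` `SeedSequence`), so trials are reproducible and
order-independent.

Gene-block permutation moves intact per-gene multi-SNP genotype rows,
preserving within-gene LD while destroying between-gene association; it
is the null used when power is focused on unlinked (interchromosomal)
pairs.

### Networks and carriers

Edges are elements `>= threshold`; networks are connected components with
at least two nodes, named `<threshold%>_<rank>` by descending size.
Networks are allele-level: the two alleles of one SNP can sit in
different networks (the yin-yang pattern). A *carrier* holds at least one
copy of every network allele; individuals missing any network SNP leave
both numerator and denominator, so denominators vary across networks.
The any-copy rule is the default because it is the only simple rule
consistent with carrier frequencies reaching 1.0 while denominators
shrink with network size; `homozygous` and `dosage` (product of
within-genotype allele frequencies) variants are provided as strategy
switches. Reduction of a network to the SNPs scored in another panel
keeps membership semantics by node set even if edges disconnect.

### Cline regression

Weighted least squares of carrier frequency on latitude with weights
equal to the per-network denominators. The quadratic model is fitted
first (needing ≥ 4 populations and ≥ 3 distinct latitudes); if its
quadratic-term p-value exceeds α = 0.05 the linear model is refitted and
reported. R² = 1 − weighted RSS / weighted TSS about the weighted mean —
the quantity invariant to affine reparameterisation of predictors, which
is why R² (not raw coefficients) is the comparison surface for quadratic
fits against software that orthogonalises its design matrix. Coefficient
p-values use the t distribution with n − p degrees of freedom. Degenerate
designs (fewer than 3 usable populations, or a single latitude) raise an
explicit non-identifiability signal; named exclusion variants (e.g.
dropping sub-Saharan or East-Asian populations) record that signal per
variant instead of failing the batch. A constant response is reported as
R² = 0.

### Scalar LD

Haplotype frequencies come from an EM algorithm on the 3×3 genotype count
table: all cells except the double heterozygote resolve their two gametes
uniquely; the double-heterozygote mass is split between the two phase
pairs in proportion to the current estimate of `p_AB·p_ab` vs
`p_Ab·p_aB`. Iteration stops when every frequency moves less than `tol`
(default 1e−10, max 2000 iterations); the implementation is vectorised
over all pairs simultaneously. r² = D²/(p_A p_a p_B p_b) and
D′ = |D|/D_max from the EM frequencies (a composite dosage-correlation r²
is available); pairs monomorphic among pairwise-complete individuals are
flagged incalculable and excluded *before* multiplicity adjustment.
Family-wise control is Westfall–Young step-down: hypotheses ordered by
decreasing statistic; adjusted p_k is the fraction of null trials whose
maximum over hypotheses k..m reaches the observed value, with enforced
monotonicity. maxT (on the statistic) is the default; a minP variant
(step-down on per-hypothesis permutation p-values) is provided since the
choice between them is not determined by the procedure's description.

## Synthetic data

The generator emulates the statistical design the analysis assumes:
latitude-indexed populations (default: ten populations at latitudes 8–50°
with the study's sample sizes, 751 individuals total), eight unlinked
genes of eight SNPs on distinct chromosomes, per-SNP frequency clines
(constant, linear, logistic, or an in-/out-of-Africa step), within-gene
haplotype blocks including a complementary yin-yang pair, a planted
multilocus allele complex, and uniform missingness. Within populations
genotypes are two independent gametes (Hardy–Weinberg); populations are
independent, so population structure enters only through frequency
differences — exactly the confounder the permutation threshold must
absorb, since pooling differentiated populations manufactures LD even
between unlinked loci.

Planted-complex carriers are guaranteed ≥ 1 copy of every member allele
(heterozygous plant; homozygous option), which deliberately keeps the
network module's any-copy carrier rule the semantics under test. A pure
heterozygous plant on frequency-flat backgrounds cannot push a CCC
element past a globally calibrated threshold (its maximal attainable
element stays near 0.5 for competitive combination frequencies), so in
the reference scenarios the member alleles also cline — mirroring the
real multilocus networks, whose component SNPs show significant
single-locus clines. The truth record stores planted flags, realised
(post-plant) carrier status, and realised per-population allele
frequencies; with no missingness the realised carrier record equals the
network module's carrier count by construction, and that congruence is
tested.

The contrast benchmark (`contrast_scenario`) is tuned to the boundary
between the two methods' detection regions. Per pair, CCC elements and r²
respond to the same dosage covariance with near-identical efficiency; the
separation comes from family structure: the CCC scan's null ceiling is
governed by its few highest-frequency combinations (here the three member
pairs), while the scalar step-down corrects over all 1792 inter-gene
pairs, and the CCC threshold tolerates a small false-positive rate
(≤ 0.15/trial) where the scalar test holds 5% family-wise error. Member
step 0.61→0.81 at latitude 29 with a weak planted cline (0.02→0.10) lands
in that window: measured 45/50 CCC detections vs 44/50 all-null scalar
scans. This is a power statement about this configuration, not a theorem.

What the generator does not emulate: migration/admixture between
populations, LD decay with physical distance inside genes beyond the
declared blocks, genotyping error, ascertainment bias of SNP panels, and
selection dynamics. Passing recovery tests therefore demonstrate the
pipeline's behaviour under idealised population structure, not
performance guarantees on real cohorts.

## Problem sizes and runtime choices

Test-suite scales are chosen to exercise every code path at desk scale:
calibration tests use 30–500 trials (the analysis defaults remain
configuration, with 10³–10⁶ used in real scans); the recovery benchmark
runs 100 replicates of the strong scenario (10×150 individuals, 100-trial
calibration); the contrast benchmark 50 replicates (120-trial
calibration, 250-trial LD null); the genome-scale code path is exercised
on a 5000-SNP simulated panel through the block-streamed edge scanner
(512-SNP tiles), which bounds memory for panels far larger than the
all-pairs arrays.

## Numerical notes

* All-pairs CCC reduces to a handful of (p×n)(n×p) matrix products over
  masked within-genotype frequency matrices; the permuted-trial loop uses
  the same kernel, which is what makes 10⁴–10⁶-trial calibrations
  feasible.
* Network component partition is independent of edge input order; ties in
  network ordering break on the lexicographically smallest member SNP id.
* Fisher's exact test (two-tailed, summing hypergeometric probabilities
  not exceeding the observed table's) is delegated to scipy and verified
  against exhaustive enumeration in the tests.
* EM with both SNPs polymorphic converges monotonically in likelihood;
  when `p_AB·p_ab + p_Ab·p_aB = 0` the double-heterozygote split is set
  to 1/2.
* Latitudes are accepted signed in [−90, 90]; the bundled scenarios use
  northern-hemisphere values as printed in the study design they imitate.

## Known limitations

* PLINK text input carries no allele orientation, so `allele_a`/`allele_b`
  are assigned lexicographically on read; downstream statistics are
  orientation-equivariant, but combination labels may differ from another
  tool's.
* The EM-based r² matches the behaviour of haplotype-frequency-based LD
  tools; composite-correlation r² differs slightly on data with
  genotype-level (non-gametic) association.
* Carrier-rule ambiguity (any-copy vs homozygous) is resolvable only
  against the original study's genotype file; the any-copy default is the
  one consistent with the published frequency tables' structure, and the
  switch is exposed.
* The million-trial, million-SNP scales of the original analyses are out
  of desk scope; the same code paths run at reduced scale in the tests.
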