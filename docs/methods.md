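# Methods

## Pedigree inbreeding and depth

The pedigree is a DAG of animal records with optional sire/dam links;
loading normalizes unknown-parent sentinels ("", "0", "NA"), adds founder
records for parents referenced without a row of their own, topologically
sorts (Kahn), and rejects duplicates, self-parentage and cycles with the
offending id chain.

F_PED(i) is the kinship of i's recorded parents. We compute it with the
Meuwissen–Luo indirect method: with A = L D L′ (L the gametic-contribution
matrix, D the Mendelian-sampling variances D_jj = 0.5 − 0.25(F_s + F_d),
taking F = −1 for an unknown parent so founders get D = 1), the parents'
relationship a_sd = Σ_j L_sj L_dj D_jj is accumulated by one upward
traversal from the two parents, popping ancestors in reverse topological
order from a heap. Cost is O(n · depth), versus exponential for path
enumeration; the test suite checks exact agreement (1e-12) with a Wright
path-counting oracle on 200 random pedigrees.

Unknown parents contribute kinship 0 — no unknown-parent groups — so an
animal with any unrecorded parent has F_PED = 0. This is deliberate: the
workflow's whole point is that such zeros are an artefact of recording,
and the bridge regression corrects for them.

Depth metrics per animal: FullGen = 1 + min over parents (0 if either is
unknown), i.e. the deepest generation in which all 2^g ancestors are
recorded; MaxGen = 1 + max over known parents (founder = 0); EquiGen
follows the standard path-based recursion EquiGen(i) = Σ_known parents
0.5·(1 + EquiGen(p)), so a fully recorded g-generation pedigree scores
exactly g. No depth cap is applied. Wright's effective size uses the
sex-ratio form Ne = 4·Nm·Nf/(Nm+Nf) on counts of distinct sires and dams
(NaN if either is zero); the rate-of-inbreeding form 1/(2ΔF) is exposed
separately for users who prefer it.

## Genotypes, dialects and QC

Genotypes are int8 counts of each SNP's first-listed (A1) allele, −1 for
missing. Both PLINK dialects are read and written natively (BED v1.x
SNP-major with the 0x6c1b01 magic; 2-bit codes 00/01/10/11 = hom-A1 /
missing / het / hom-A2), with round-trip identity and cross-dialect
equality covered by tests. Chromosome bookkeeping is species-aware (goat
29 autosomes, sheep 26); "X"/"Y"/"MT" labels or numeric codes past the
last autosome count as sex-linked, label "0" or non-positive positions as
unplaced. Positions are 1-based bp; lengths are kept in bp internally and
reported in kb/Mb.

QC order is placement → SNP missingness (≥ 0.05 removed, threshold
inclusive) → individual call rate (< 0.95 removed, strict), because a call
rate is only meaningful over the markers that will actually be analysed;
whether the call-rate denominator uses the post-filter SNP set is
configurable (`callrate_after_snp_filter`, default true) since either
order is defensible. The QC report reconciles exactly: in − removed = out
on both axes. MAF < 0.05 filtering (strict inequality; monomorphic and
all-missing SNPs also dropped) is applied only before GRM construction —
rare alleles are kept for ROH calling so long homozygous stretches are not
fragmented.

## ROH detection and F_ROH

Scanning parameters (defaults): 20-SNP sliding window, 0 heterozygotes
and ≤ 2 missing calls per homozygous window, per-SNP hit rate ≥ 0.05
(the scanning tool's documented default, exposed as a parameter since it
is often left unstated), ≥ 20 SNPs and ≥ 1 Mb per segment, density
≤ 500 kb/SNP (applied as length_kb / n_snps ≤ 500), gaps > 500 kb split a
run. Segment length is end − start + 1 bp and segments start and end on
eligible SNPs. With the default window_het_max = 0 a heterozygous SNP can
never be eligible, so segments contain no heterozygotes but may contain
missing calls (including at their ends, if the SNP is eligible). Hit-rate
ties use ≥.

F_ROH = Σ segment lengths / L_AUTO, with L_AUTO = Σ over autosomes
(last − first + 1) of SNP-covered length. Length classes are half-open on
the left bound in Mb — [1,2), [2,4), [4,8), [8,16), [16,∞) — so an exact
16 Mb segment falls in the open class; the source convention is ambiguous
at boundaries and this one is fixed and documented. Class fractions sum
to total F_ROH by construction. The detector is validated against an
exhaustive per-window, per-run oracle on 500 random instances.

## GRM inbreeding

G = W W′/m with per-SNP standardization w = (x − 2p)/√(2p(1−p)), p the
sample allele frequency of the analysed (MAF-filtered) dataset. Missing
genotypes contribute 0 to numerators and each pair's denominator is its
count of jointly non-missing SNPs (pairwise-complete), which is unbiased
under missingness at random but can diverge slightly from tools using a
single global denominator. Four per-individual estimators are always
emitted: f_diag = G_ii − 1 (the default F_GRM), fhat1 (mean w² − 1;
identical to f_diag under this missing-data handling), fhat2
(1 − mean[x(2−x)/2pq], excess homozygosity) and fhat3 (correlation form).
All are invariant to swapping which allele is counted and may be negative.
Because p is estimated in-sample, f_diag degrades — and can even
anti-correlate with true autozygosity — when the sample itself is strongly
drifted/related (deep sire-overuse pedigrees); fhat2 is far more robust in
that regime. The validation test therefore checks f_diag's positive,
density-improving correlation with truth under random mating.

## The bridge regression

All animals of both species are pooled and F_PED ~ F_ROH is fitted by OLS
within each stratum FullGen ≥ k, k = 0..8 (fits with < 3 rows or constant
predictor are flagged empty). Per species, the selected stratum must keep
≥ 600 animals of that species (the analysis scripts scale this floor to
100 for desk-sized simulated herds) and maximize R²; ties break by higher
Pearson r, then deeper stratum, and a log warning flags the rare case
where the max-r and max-R² criteria disagree.

Residuals are taken as predicted − observed (the sign is immaterial to a
symmetric quartile rule), Z-scored with the sample SD (an
essentially-constant residual vector standardizes to all zeros), and
animals outside [Q1, Q3] of the Z distribution are dropped; quantiles use
linear interpolation of order statistics. Under any single standard
quantile convention the published exclusion counts (463 of 927, 358 of
717) are reproducible only to ±1, and the tests assert exactly that. The
model is then refitted on the retained animals ("refined") and applied to
every animal of the species' stratum to give a definitive estimated F_PED.

Class tables bin estimated F_PED into [0, 0.05), [0.05, 0.10), …;
negative estimates (the fitted intercepts are slightly negative) are
floored into the first bin by default (configurable). Per bin and breed:
n, F_ROH mean, SD, 95% CI = mean ± 1.96·SD/√n (blank at n = 1), min–max.
Report rounding is 3 decimals, half away from zero. Inverting the line,
(boundary − a)/b, recovers the F_ROH range endpoints of each bin;
`scripts/acceptance.py` recomputes these from the published refined
coefficients.

## Synthetic herds

The generator emulates medium-density SNP-array livestock data: discrete
generations, a few sires serving many dams (optionally with geometric
sire-overuse weights emulating heavy AI usage, which raises inbreeding),
a jittered-grid map of ~even marker density (default 10 chromosomes ×
100 Mb × 2,000 SNPs ≈ a 50k panel's autosomal half, scaled for desk runs),
founder allele frequencies uniform on [0.05, 0.5] (so the MAF filter is
near-inert on truth-checking runs), Poisson recombination at 1 cM/Mb with
no interference, and optional missing-call injection and pedigree-link
masking. IBD is defined at the founder-haplotype level, so F_true — the
autozygous fraction of map length — is exactly the quantity F_ROH
estimates, and E(F_true) = F_PED on the unmasked pedigree (verified by
Monte Carlo within 3 SE over 200 replicates).

What the simulator does *not* emulate: linkage disequilibrium among
founder haplotypes, selection, overlapping generations, genotyping error
beyond missingness, and real chip ascertainment. Passing tests therefore
demonstrate correctness of the algorithms and calibration logic under
Mendelian transmission, not field performance on any particular breed.

## Problem sizes and numerical choices

The validation suite uses scaled-down problem sizes chosen to keep the
whole run light while leaving the checked properties comfortably clear of
their thresholds: the ROH oracle runs 500 instances of ≤ 200 SNPs × ≤ 3
chromosomes; the pedigree oracle 200 pedigrees of ≤ 30 animals; the
truth-recovery scenario is 10 generations of sire overuse over 10
chromosomes × 2,000 SNPs (~460 animals), where corr(F_ROH, F_true)
reaches 1.00 against the ≥ 0.9 requirement. All simulations are seeded;
reruns are byte-identical. Tolerances: kinship oracle agreement 1e-12,
GRM symmetry 1e-10, class-fraction additivity 1e-12.

## Known limitations

* No unknown-parent groups or ancestral-allele corrections for incomplete
  pedigrees — by design, zeros stay zeros.
* The GRM is dense; herds beyond a few tens of thousands of genotyped
  animals would need a blocked implementation.
* A single pooled calibration line per stage; no breed random effects or
  nonlinear calibration.
* X-chromosome analysis is out of scope throughout (markers are removed
  in QC).
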