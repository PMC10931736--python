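# Methods

This note documents the statistical models, conventions and numerical
choices behind each pipeline stage, what the synthetic-data generators do
and do not emulate, and the known limitations.

## Read QC

A read is removed if, in this precedence, it (1) contains the adapter
sequence as an exact substring, (2) has N content strictly above 10%, or
(3) has bases with Phred quality ≤ 20 making up strictly more than 50% of
its length. All thresholds are strict inequalities — a read at exactly 10%
N or exactly 50% low-quality bases is kept — and each read lands in exactly
one report bucket, so `n_input = n_kept + n_adapter + n_highN + n_lowq`
holds for every input (property-tested on random batches). Reads are judged
independently; there is no pairing, no quality trimming, and no partial
(gapped or mismatched) adapter alignment — adapter detection is exact
substring match of a configurable sequence, with the 13-mer universal
Illumina adapter prefix as the default.

## Expression screening

FPKM_gs = counts_gs × 10⁹ / (total_s × length_g). A gene is expressed when
its mean FPKM across all samples is ≥ 0.1 (inclusive). The two-group screen
uses a Welch t-test on log₂(FPKM + 1) per gene — chosen as the simplest
defensible two-group test; the test function is pluggable and the module's
contract is the thresholds, not the test — with Benjamini–Hochberg FDR
control across genes. log₂FC is the ratio of group mean FPKM with a
pseudocount of 1 (avoids division by zero; compresses fold changes only for
genes whose mean FPKM is near or below 1), signed relative to the control
group. A gene is called iff FDR < 0.01 and |log₂FC| > 1, both strict.
Genes with zero variance in both groups get p = 1. NaN p-values propagate
through the BH adjustment without counting toward the number of tests.

## Gene-set selection

Term enrichment is the hypergeometric upper tail P(X ≥ overlap) with the
expressed-gene set as the universe; term membership is intersected with the
universe before testing. Significance is p ≤ 0.05 inclusive and, by
default, unadjusted — published livestock transcriptome screens typically
report raw term p-values — with a BH-adjusted column available. "Lipid
metabolism-related" terms are selected by a configurable case-insensitive
keyword list over term names (default: `lipid`, `fatty acid`, `adipo`);
curation by keyword approximates the manual curation a biologist would do.
Candidate genes are DEGs recurring in ≥ `min_terms` (default 5) significant
terms; candidate sets are merged by set union in lexicographic order so the
core-gene list is deterministic.

## Co-expression network

Correlations are Pearson, computed on log₂(FPKM + 1) (expression
correlations on the raw scale are dominated by a few high-abundance genes).
An edge joins two genes iff r strictly exceeds 0.6. The default mode is
signed (r > 0.6, the literal reading of a positive-correlation cutoff);
`absolute` mode (|r| > 0.6) is provided because negative co-regulation is
sometimes included in such networks. Hubs are the top-k nodes by degree;
degree ties break by summed |r| over incident edges, then by gene name, so
the ranking is total and deterministic. Zero-variance genes have undefined
correlations and contribute no edges.

## qPCR (2^−ΔΔCt)

Technical replicates are averaged on the Ct scale (arithmetic mean of
cycles; equivalently the geometric mean of template amounts).
ΔCt = Ct(target) − Ct(reference) per sample removes input-amount
variation — shifting every Ct of a sample by a constant leaves fold changes
unchanged, which is tested. ΔΔCt subtracts the calibrator group's mean ΔCt,
so the calibrator's geometric-mean fold is exactly 1 by construction.
Group comparison is a two-sided Welch t-test (robust to unequal variances;
with triplicate-averaged folds per animal the sample unit is the animal).
No amplification-efficiency (Pfaffl) correction is applied; 100% efficiency
is assumed.

## Image quantification

Positive-staining area is a single-channel threshold count — the fraction
of pixels strictly above (or below) an intensity cutoff, within a mask if
given. No color deconvolution is performed; for DAB/hematoxylin images the
caller must supply a channel in which positivity is monotone in intensity.
Colocalization: Pearson Rr over pixel-intensity pairs and the Manders
overlap R = ΣS₁S₂ / √(ΣS₁² ΣS₂²). R ∈ [0, 1] by Cauchy–Schwarz with
equality iff the channels are proportional; R is invariant to positive
scaling of either channel, Rr to affine rescaling. Both default to a
foreground mask (union of per-channel Otsu thresholds) because background
zeros inflate both coefficients; whole-image computation is available via
`mask=False`.

## SNP marker statistics

For genotype counts (n_AA, n_AB, n_BB), n individuals:

- allele frequency p = (2 n_AA + n_AB) / 2n; q = 1 − p
- observed homo-/heterozygosity: count proportions
- expected: hom = p² + q², het = 2pq
- effective allele number Ne = 1/(p² + q²) ∈ [1, 2]
- PIC (Botstein, biallelic) = 1 − (p² + q²) − 2p²q², maximum 0.375
- HWE χ² against expected counts (np², 2npq, nq²)

Two conventions are exposed. `exact` computes everything from the unrounded
p and is the default for new data. `paper_rounded` reproduces the
spreadsheet cascade used in published livestock diversity tables: genotype
frequencies rounded half-up to 2 decimals, then p = f_AA + f_AB/2 rounded
half-up to 2 decimals, q = 1 − p, all downstream statistics from the
rounded p, and Ne truncated (not rounded) to 2 decimals. Half-up rounding
(not banker's) is required: the pooled example in the shipped fixture has
p = 0.565 → 0.57. Rounding uses `decimal.Decimal` on the value's repr to
avoid float representation artifacts.

The HWE p-value's degrees of freedom are exposed as df ∈ {1, 2}. With p
estimated from the same sample, the correct reference distribution is
χ²(1) (three classes − 1 constraint − 1 estimated parameter); the df = 1
exact-convention test is Monte-Carlo calibrated in the suite (type-I error
≈ 5% over 2000 simulated equilibrium cohorts of n = 25). df = 2 (classes −
1, ignoring estimation) is what spreadsheet-era tables print and is used
for table reproduction. A monomorphic cohort with a contradicting observed
genotype yields an infinite χ² and p = 0, flagged rather than masked.

The pooled "All" row sums genotype counts across populations before
computing statistics (it is not an average of per-population statistics).

Printed PIC values in legacy tables sometimes exceed the biallelic maximum
0.375 and cannot come from any standard formula; this package always
reports Botstein PIC, and the report's Ho/He columns distinguish observed
from expected quantities explicitly because legacy tables are inconsistent
about which they print.

## Protein physicochemistry

Sequences are over the 20 standard residues plus selenocysteine (U).
Average molecular weight is the sum of Expasy average residue masses plus
one water (18.0153 Da); U's residue mass is 150.0379 Da, so an E→U edit is
+20.9224 Da on any sequence. Translation uses the standard genetic code;
selenocysteine recoding is never inferred from context (no SECIS logic) —
the caller names the codon positions decoded as U. A single trailing stop
codon is dropped; an internal stop outside the recoded positions is an
error naming the codon index.

Theoretical pI solves net-charge(pH) = 0 by bisection on [0, 14]; the net
charge is a Henderson–Hasselbalch sum over the termini and D, E, C, Y
(acidic), H, K, R (basic). Net charge is strictly decreasing in pH so the
root is unique; bisection runs to 0.001 and is verified against a
0.001-step grid scan. The pKa set is the classic textbook set (N-term
9.69, C-term 2.34, D 3.65, E 4.25, C 8.33, Y 10.07, H 6.00, K 10.53,
R 12.48), shipped as an importable table and overridable per call — web
calculators differ in their pKa sets, so absolute pI values are
convention-dependent, but ordering and mutation-induced shifts are robust.
U is not titrated by default (its selenol pKa is not part of any standard
pI convention). The instability index is (10/L) Σ DIWV(x_i, x_{i+1}) over
the published 20×20 dipeptide table (> 40 flags an unstable protein);
pairs involving U contribute 0. GRAVY is the mean Kyte–Doolittle
hydropathy; U defaults to cysteine's 2.5 (closest side-chain chemistry),
configurable.

Absolute MW/pI/II/GRAVY values for a specific protein fragment require
that fragment's sequence; the package asserts and tests the *differential*
signature of the E→U substitution (MW +20.92 Da, Asp+Glu count −1, pI and
GRAVY both upward), which is sequence-independent.

## Synthetic data: what it emulates and what it does not

All generators are deterministic functions of (seed, parameters), use
per-stage independent RNG substreams, and emit truth tables sufficient to
score downstream sensitivity and specificity.

- **Reads** (default 1000 × 100 bp): each read is assigned
  adapter/high-N/low-quality/clean labels at the configured rates (default
  5% each) and constructed to violate exactly the labeled rule. Not
  emulated: position-dependent error profiles, partial adapters,
  genome-derived sequence composition. Passing QC tests therefore shows the
  filtering rules are implemented exactly, not that the filters are optimal
  on real error profiles.
- **Counts** (default 2000 genes × 6 samples/group, matching a
  six-animals-per-population design): negative binomial with log-normal
  baseline means (median ≈ 200 counts) and var = μ + φμ². The default
  dispersion φ = 0.05 (biological CV ≈ 22%) reflects a controlled
  same-age, same-flock livestock cohort and makes the planted 4-fold
  effects (50 DEGs at log₂FC = 2) recoverable by the Welch screen at
  n = 6/group — the intended operating point of the emulated experiment.
  φ = 0 degenerates to Poisson (tested). Not emulated: gene-gene
  correlation, library-composition bias, outlier samples.
- **Genotypes**: multinomial draws from exact HWE proportions (p², 2pq,
  q²), default p = 0.48, n = 25 — the shipped fixture's minor-allele
  regime.
- **Images** (default 256², 8-bit): elliptical foreground blobs on a zero
  background; foreground pixel pairs from a bivariate normal with the
  target correlation, affinely mapped to [30, 225] so ρ = ±1 is exactly
  affine. The clipping attenuates |r| negligibly at the default scale.
  Not emulated: optics (PSF, bleed-through), cell morphology.
- **Ct tables**: reference gene flat, target shifted by −log₂(fold) in the
  cross, triplicates with 0.15-cycle Gaussian well noise.
- **Gene sets**: lipid-named terms draw half their members from the true
  DEG list; background terms sample uniformly.

## Problem sizes

The test suite and demo run at the defaults above (1000 reads, 2000 genes,
2000-replicate Monte-Carlo calibrations, 512² images for correlation
checks); these sizes give Monte-Carlo standard errors well inside the
asserted bands while keeping the suite fast on a single CPU.

## Known limitations

- No alignment or quantification from raw reads: the pipeline starts at
  the count matrix, as the upstream aligner is outside scope.
- The DE screen is a per-gene Welch t-test, not a count-model GLM; with
  very few replicates a moderated or NB-based test would be more powerful.
- GO graph structure is ignored (terms are flat gene sets).
- Colocalization is global (per image), not object- or cell-resolved.
- The popgen module is strictly biallelic; multi-allelic loci, LD and
  haplotypes are out of scope.
- Published absolute colocalization coefficients and protein-report values
  for specific micrographs/fragments are not reproducible without the
  underlying images/sequences; the package reproduces the computations,
  their invariants, and the diversity table that is fully determined by
  printed genotype counts.
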