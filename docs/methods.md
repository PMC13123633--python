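# Methods

This note documents the models, defaults and numerical choices behind each
stage of the pipeline, what the synthetic-data generators emulate, and the
limits of what passing tests demonstrate.

## Dosimetry model

Dose rates are a sum of three independent linear pathways, each a measured
quantity times a chain of coefficients:

| pathway | input | chain | default |
|---|---|---|---|
| internal ¹³⁷Cs | tissue activity, Bq/kg wet | × dc_internal_cs137 | 2.7×10⁻⁴ μGy/h per Bq/kg (≈35 kg canid) |
| internal ⁹⁰Sr | soil contamination, kBq/m² | × CR × dc_internal_sr90 | CR = 0.86, dc = 6.38×10⁻⁴ |
| external ¹³⁷Cs | dosimeter mean rate, μGy/h, or soil kBq/m² | measured, or × dc_external_cs137 | 1.1×10⁻⁴ |

Choices worth stating explicitly:

* **Wet/dry conversion.** Laboratory gamma counts on lyophilised tissue give
  Bq/g dry mass. Total activity is conserved while tissue mass grows by the
  wet:dry ratio, so `A_wet = A_dry / ratio`; the ratio convention is a field
  on the record, not hard-coded.
* **External precedence.** A collar-dosimeter average integrates the
  animal's actual movement through the contamination field and overrides a
  soil-map-derived estimate whenever both are present.
* **⁹⁰Sr chain units.** The concentration ratio maps areal soil
  contamination directly to tissue activity as one configurable linear
  chain; whether the soil quantity is areal (kBq/m²) or mass-based is left
  to the coefficient set rather than asserted by the code.
* **Time base.** 8760 h/y (non-leap). This reproduces the conventional
  5.4 μGy/h ≈ 47 mGy/y rounding; lifetime dose assumes a constant rate over
  the animal's (tooth-wear-estimated) age, so it inherits that estimate's
  coarseness.
* **mSv/mGy.** For the photon/beta emissions considered, absorbed dose in
  mGy is compared directly against mSv-denominated limits (radiation
  weighting factor 1).

Group differences use Welch's unequal-variance *t* with Satterthwaite
degrees of freedom; with group SDs this unequal (≈3.1 vs ≈0.01) the df
collapses to n−1 of the variable group, which is why n = 9 cohorts report
df ≈ 8.

## Genotype QC

Per-call masking is strict (`DP > 8`, `GQ > 20`); site filters then require
a single-base REF/ALT pair, membership in the configured autosome list,
missingness strictly below 0.20 and polymorphism after masking (monomorphic
sites carry no F_ST information). Masking precedes the missingness count,
so "missing" includes masked calls. The stage order
mask → site filters → annotation subset → LD prune is enforced by flags;
each filter is idempotent.

LD pruning is greedy and windowed: within each window of 50 consecutive
sites per chromosome (advancing by 10), pairwise r² is computed on allele
dosages over pairwise-complete samples, and while any retained pair exceeds
0.1 the later-positioned site of the first offending pair is dropped. Pairs
sharing fewer than two complete samples, or involving a constant vector,
count as uncorrelated. The later-site tie-break is deterministic and
documented; exact parity with other tools' internal tie-breaking is not
claimed. Tests audit the output with an exhaustive pairwise check over every
window placement.

## Selection scan

Per-site differentiation uses the Weir–Cockerham (1984) two-population θ̂ =
a/(a+b+c) computed from per-population sample sizes, allele frequencies and
observed heterozygote fractions; slightly negative estimates are a known
property of the estimator and are passed through. Sites where either
population lacks data, the pooled sample is monomorphic, or the component
denominator vanishes are undefined and excluded from every downstream
median, z-score and the BH family.

Branch lengths use the Cavalli-Sforza transform T = −ln(1 − F_ST) with F_ST
clamped to [0, 1−10⁻⁹]: negative noise would produce negative branch
lengths and fixed differences an infinite one; both the floor and cap are
configurable. PBS is the focal-branch length; PBE subtracts the
locus-specific expectation scaled from the sister–outgroup branch by the
genome-wide median ratio (medians over all analyzed sites, not
per-chromosome).

The p-value device follows the zero-negatives → z-score → upper-tail normal
→ BH order exactly as the procedure is conventionally run, with the z-score
mean/SD computed on the zeroed vector (ddof = 1). Because the zeroed
distribution is zero-inflated and right-skewed, these p-values are *not*
calibrated tail probabilities; they are an empirical ranking device, and the
type-I behaviour under the null is whatever the z construction implies
(typically a p < 0.05 fraction well below 5%). A rank-based empirical
p-value is available as a non-default alternative. Outlier tiers use strict
−log₁₀(p_adj) thresholds, default 8 (outlier) and 15 (extreme); both are
configurable because reasonable analyses also use 6/12.

Nearest-gene annotation treats annotation intervals as 0-based half-open
and VCF positions as 1-based (conversions centralized in `wolfscan.coords`).
A site inside a gene reports distance 0 and is exonic if it falls in an
exon sub-interval (or if the gene has no exon rows — transcript-derived
annotations); otherwise intronic. Outside genes, the gap is counted in bp
to the nearest gene with up/downstream orientation taken from that gene's
strand, ties broken toward the lower-coordinate gene.

### Known limitation: per-site PBE at small n

With n ≈ 10 diploids per branch, the per-site allele-frequency standard
error (≈0.11) dominates the focal-branch drift signal. Across tens of
thousands of loci, hundreds of neutral sites draw focal-specific sampling
deviations of 0.3+ and produce PBE values that interleave with genuinely
selected loci; top-k precision of the per-site ranking is therefore low at
these sample sizes even for frequency shifts of 0.4, and the simulations
show this is intrinsic (it persists when true post-drift frequencies are
used, since drift tails and shift-truncation overlap the selected range).
The scan's value at small n lies in the extreme tail (the strict 10⁻⁸
threshold), not in clean top-k retrieval, and enrichment-style readouts
(selected loci elevated in aggregate) remain well powered. A related
caveat: selection on the *sister* branch leaks mildly into focal PBE
(the convex −ln(1−F) transform inflates T_fs more than the median-scaled
T_so correction removes), so specificity claims should always be made
comparatively against the focal signal.

## Expression screen

Normalization is log₂(CPM + 1); the log base and pseudo-count are
conventions, configurable at the call. Low-expression filtering keeps genes
with mean raw count strictly above 10. Outlier samples are flagged when
their mean correlation to all other samples falls more than k_sd = 2.5 SDs
below the cohort mean of those means (k_sd is a convention; the reference
procedure shows a figure rather than a number).

Gene significance is the per-transcript correlation with total dose rate —
Spearman by default — with the student asymptotic p-value
t = r√(n−2)/√(1−r²) applied to ρ, matching the WGCNA-style
`corPvalueStudent` device; a permutation option exists for very small n.
The dose-correlated set intersects the top 0.95 quantile of |r| (ties at
the threshold included; |r| rather than signed r, so both tails are
captured — a signed option exists) with p < 0.05.

Module eigengenes are the leading right singular vector of the per-gene
z-scored module submatrix, unit-norm over samples and sign-oriented so the
mean correlation with member genes is positive. Trait association combines
(a) the eigengene–dose correlation with its student p and (b) a
likelihood-ratio test between nested Gaussian linear models fit by maximum
likelihood: full = dose + age + dose:age + monocyte + granulocyte + sex,
reduced = full minus the dose terms (or minus dose and age terms), χ² = 2Δℓ
on the parameter-count difference. Sex enters as a fixed covariate: with
n = 9 per site a random intercept over two sex levels is near-degenerate,
so the mixed-model formulation is deliberately simplified while preserving
the χ²/df semantics of the nested comparison. The χ² reference is
asymptotic; at n ≈ 9 the ML LRT is visibly anticonservative, which is why
calibration checks are run at n = 60. Rank-deficient designs raise an error
naming the collinear columns rather than silently dropping them.

Pathway PCA centers genes and reports per-sample PC1/PC2 scores with
variance fractions; it makes no sphering or scaling assumptions beyond
centering.

## Deconvolution

A deliberately simple reference-based estimator (the production tools in
this space add row-scaling heuristics and larger signature machinery;
parity with any of them is a non-goal). Signature genes are, per cell type,
the genes maximizing that type's share of the gene's row sum (50 per type
by default, union taken). Reference and mixture are restricted to shared
signature genes and each gene row is divided by the reference row maximum,
putting all features on [0, 1] in the reference. Fractions are the
non-negative least-squares solution renormalized to sum to one — hence
invariant to mixture rescaling — with a clipped pseudo-inverse fallback
(and a warning) when reference columns are collinear. Inputs are assumed
pre-mapped to the reference gene namespace (cross-species ortholog mapping
happens upstream). On synthetic mixtures with 10% multiplicative noise the
mean absolute fraction error is ≈0.003–0.01; real bulk profiles add
reference mismatch that this bound does not include.

## Synthetic data

The generators define the study conditions under which everything above is
tested; one integer seed makes every output byte-reproducible.

* **Genotypes.** Ancestral frequencies ~ U(0.05, 0.95); outgroup and a
  Eurasian intermediate drift from the ancestor by Balding–Nichols
  Beta(p(1−F)/F, (1−p)(1−F)/F) with F_split = 0.2; focal and sister drift
  from the intermediate with F = 0.01 each. Selection is a deterministic
  post-drift shift of the focal frequency by +0.4 toward fixation
  (truncated at 0.99) at 50 loci — simple and transparent, adequate for
  rank-recovery and enrichment testing, but not a forward-in-time sweep
  (no hitchhiking, no age structure). Genotypes are Hardy–Weinberg draws
  for 10/10/25 diploids; depth is negative-binomial (mean 30, size 10),
  GQ = min(99, 4·DP) — a crude coupling sufficient to exercise the QC
  filters, not an error-model of any caller — and 5% of calls are set
  missing.
* **Expression.** Gene baselines are lognormal on the log₂ scale (mean 7,
  SD 1.5 → median ≈128 counts); dose-responsive genes (20 of 1000) shift
  their log₂ mean by β = 1 per SD of dose; optional module genes share a
  latent factor a·dose_z + N(0,1). Counts are negative-binomial
  (var = m + 0.1·m²) with ±30% library-size variation. Real blood
  transcriptomes add batch structure, cell-composition confounding and
  count-depth heteroskedasticity that this generator does not emulate, so
  a passing recall test demonstrates the screen's statistics, not
  robustness to those artefacts.
* **Doses.** Total rates are lognormal with the two field cohorts' moments
  (focal 5.4 ± 3.1, reference 0.02 ± 0.01 μGy/h, n = 9 each), ages
  U(1, 8) years; the total is back-allocated onto the three measured
  pathways (0.6/0.25/0.15) so the dosimetry equations reproduce the
  emitted totals to 10⁻⁹. `moment_matched_lognormal` additionally rescales
  a lognormal draw so sample mean/SD match published summary statistics
  exactly — a synthetic stand-in for cohorts known only through their
  printed summaries, preserving skew but not the original per-animal data.

## Problem sizes and tolerances

The seeded checks run at 20,000 loci for the selection scan, 20 replicates
of the n = 9 expression screen, 100 noisy mixtures for deconvolution, and
500 replicates for the Welch power and null-LRT calibration checks — sizes
chosen so each property is measured with small Monte-Carlo error while the
whole suite stays fast. Numerical comparisons against oracles use 10⁻¹²
absolute tolerance; simplex and round-trip identities use 10⁻⁹.
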