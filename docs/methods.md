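# Methods

## The causal model

The package estimates the effect of genetically proxied IL-6 inhibition on
pleural infection under the standard instrumental-variable assumptions:
relevance (variants associate with IL-6R level and, downstream, CRP),
exchangeability (no confounder of variant and outcome) and exclusion
restriction (variants act on the outcome only through IL-6 signalling).
Restricting to the cis region around *IL6R* makes the exclusion restriction
biologically plausible — a variant in the receptor's own locus is far more
likely to act through the receptor than a trans hit — which is why the whole
design is anchored on a gene window rather than a genome-wide scan.

The exposure is scaled in units of natural-log CRP because the instrument is
weighted by CRP effects: CRP is the transcriptionally regulated readout of
IL-6 classical signalling, so "one unit decrease in log CRP" operationalises
"this much less IL-6 activity".  All effects are reported per *decrease* in
log CRP.  This sign convention is applied exactly once, when the instrument
is built (the effect allele is re-oriented to the IL6R-raising, CRP-lowering
allele and the CRP beta negated); estimators never re-flip signs, so an odds
ratio below 1 always reads as protection under IL-6 inhibition.

## Instrument construction

Selection runs in a fixed order: cis window → significance → CRP-direction
concordance → LD clumping → F filter.  Choices worth stating:

- **Window anchoring.** "Within 300 kb" is interpreted as the closed
  interval [gene start − window, gene end + window].  Gene coordinates and
  build are configuration, never inferred or hardcoded in analysis code.
- **Stage order.** Concordance filtering precedes clumping, following the
  narrative order of the selection rules; the composition is exposed as
  separate operations so either order can be run explicitly.
- **Clumping.** Greedy index-SNP selection: repeatedly take the remaining
  SNP with the lowest p-value and discard everything at r² ≥ threshold with
  it.  Ties on p are broken by position, then lexicographic snp_id, making
  output deterministic.  Retained sets are pairwise independent at the
  threshold by construction, always contain the globally most significant
  SNP, and can only shrink as the threshold tightens.
- **Inequalities are strict** throughout: p < 5×10⁻⁸, F > 10, discard at
  r² ≥ threshold.
- **F statistic.** Computed from the selection GWAS (the GWAS that
  establishes relevance).  A consequence worth knowing: at the default
  p < 5×10⁻⁸ the F > 10 filter is logically inert, because z > 5.45 implies
  F > 29.7 in the same GWAS; it only bites at relaxed significance
  thresholds, and the tests exercise it there.
- **Duplicates and indels** are resolved at parse time (lowest p-value wins;
  non-SNP alleles are dropped and counted), so downstream stages can assume
  clean biallelic records.

## Harmonisation

Outcome records are re-expressed per copy of the instrument's effect
allele: identical pairs pass, reversed pairs negate the outcome beta and
complement its allele frequency, base-complement pairs are treated as
strand flips.  Palindromic (A/T, C/G) SNPs cannot be oriented from letters;
they are resolved purely by allele-frequency agreement — a hidden strand
flip acts as a swap for a palindrome, so the decision reduces to whether the
two frequencies sit on the same side of 0.5 — and only when both
frequencies lie outside [limit, 1 − limit].  The limit defaults to 0.42,
the convention in two-sample MR practice; palindromes with missing or
ambiguous frequencies are dropped and counted.  The audit trail (one status
per input SNP, counts summing to the input size) is a mandatory output:
drop counts are part of the reproducibility surface.

No proxy-SNP lookup is attempted for variants missing from the outcome
GWAS; they are dropped and logged.

## Estimation

- **Wald SE** uses the first-order delta method σ_Y/|β_X|, consistent with
  the fixed-effects IVW weighting; with F well above 10 the neglected
  exposure-uncertainty term is second-order.  A `second_order=True` switch
  adds it for sensitivity.
- **IVW** is fixed-effects: se = (Σw)^(−1/2) with no heterogeneity
  inflation.  It is implemented in closed form and verified in the test
  suite against an independent weighted-least-squares route.
- **MR-Egger** orients all SNPs to non-negative exposure betas, then fits a
  weighted regression with intercept (weights 1/σ_Y²).  Standard errors use
  the multiplicative residual-variance scale and inference the t
  distribution on n − 2 df, the small-n-appropriate choice; the intercept
  estimates average directional pleiotropy.
- **Radial outliers.** Per-SNP contributions to Cochran's Q against the IVW
  fit are compared with the χ²₁ upper quantile at Bonferroni-corrected
  level α/n (α default 0.05); flagged SNPs are removed and the procedure
  iterated until no new outlier appears or only two SNPs remain.  Flagging
  every SNP is a hard error rather than a silent empty result.
- **Steiger.** Exposure r² per SNP from the t-statistic transform
  t²/(t² + n − 2).  For the binary outcome the log-OR is converted through a
  linear-probability approximation at the study case fraction φ:
  r² ≈ β_Y²·2p(1−p)·φ(1−φ).  Summed r² are compared by a z-test on
  Fisher-transformed correlations.  With 1,601 cases in 832,310 subjects φ
  is tiny, which makes the outcome r² small almost by construction — the
  test is therefore most informative in the simulator's balanced-cohort
  configurations, and the approximation choice is surfaced here because
  several variants exist in the literature.
- **Confidence intervals** are normal-approximation β ± 1.959964·se
  throughout (Egger p-values stay t-based).

## The synthetic generator

`simulate_two_sample` emulates the study's data flow: an IL-6R pQTL GWAS
(n = 54,219), a CRP weighting GWAS (n = 575,000 — the CRP meta-analysis
scale; the true sample size of such meta-analyses is in the
0.5–0.6 M range), and a case-control outcome GWAS (1,601 cases / 830,709
controls), over a 44-SNP panel.  Per-SNP effect magnitudes are uniform on
[0.5, 1.5] before rescaling so the panel explains exactly
`exposure_var_explained` of log-CRP variance (default 2 %, a realistic
figure for a strong cis instrument; the uniform floor keeps every SNP
genuinely significant, mirroring a panel that survived selection).  Each
SNP's written effect allele is the CRP-lowering allele with probability ½,
so harmonisation is exercised on every run.  Direct (pleiotropic) outcome
effects attach to the CRP-lowering allele, making `pleiotropy_mean ≠ 0`
genuinely directional rather than washed out by random allele orientation.

Estimated betas are truth plus independent Gaussian noise with the standard
large-sample SEs (quantitative: 1/√(2np(1−p)) for a unit-variance trait;
log-OR: √((1/ncase + 1/ncontrol)/(2p(1−p)))).  What the generator does
*not* model, and what passing tests therefore do not certify: winner's-curse
bias from selecting SNPs in the same GWAS used for weighting, the ~6.5 %
sample overlap between exposure and outcome cohorts, LD-correlated
estimation noise (off by default; `ld_noise=True` enables it), non-Gaussian
effect-size distributions, and allele-frequency mismatch between cohorts.
LD is consumed by clumping, not by the default noise model.

## Problem sizes and numerical choices

Calibration properties are established on replicate simulations at the
study geometry: 1,000 replicates for IVW bias/coverage and Egger test size,
500 for Steiger direction at n = 50,000, a 200-seed exhaustive sweep for
clumping-vs-brute-force equivalence, and 100 random instances for the
IVW/WLS identity at 1e-10.  These sizes give Monte-Carlo error comfortably
inside the asserted bands while keeping the full suite fast on one CPU.
P-values from extreme z-scores are floored at 1e-300 to stay inside (0, 1];
LD matrices are symmetrised by averaging only when asymmetry is ≤ 1e-8
(anything larger is treated as corrupt input); pipeline outputs carry no
timestamps so repeat runs are byte-identical.

## Known limitations

Single-exposure, single-outcome design: no multivariable MR, weighted
median/mode, or colocalisation.  The harmoniser does not search LD proxies
for missing outcome SNPs.  The Steiger binary-outcome r² is an
approximation (see above).  Real-data reproduction of the published
estimates requires the original GWAS summary statistics, which are not
bundled; the synthetic generator provides the verification surface instead.
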