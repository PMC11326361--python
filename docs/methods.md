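# Methods

## The mapping model

The package detects genotype-dependent 24-h rhythms in cohort expression
data. Each donor contributes a single expression measurement at a known time
of day, so rhythms are population-level curves fit across donors, not
per-donor time courses. Within a genotype group the model is the
single-harmonic cosinor at a fixed 24-h period,

    y_i = m + a·cos(2πt_i/24) + b·sin(2πt_i/24) + ε_i,   ε_i ~ N(0, σ²),

fit by ordinary least squares. Amplitude A = √(a² + b²) is half the
peak-to-trough difference; because the inputs are log2-normalized expression,
the linear peak-to-trough fold change is 2^(2A). The acrophase
φ = (24/2π)·atan2(b, a) mod 24 is the peak time in hours. Rhythmicity is an
F-test of the harmonic terms against the intercept-only model, with
(2, n − 3) degrees of freedom. A fixed period and a single harmonic are
deliberate: the sampling is sparse and irregular, and the scientific question
is about presence/shape of a 24-h rhythm, not period estimation.

Differential rhythmicity between the two largest genotype groups is decided
by BIC selection among five nested rhythm-sharing models (no rhythm; rhythm
in one group only, either side; one shared rhythm; two distinct rhythms),
with BIC = n·ln(RSS/n) + k·ln(n) and k counting mean and harmonic
coefficients (2, 4, 4, 4, 6). Two modeling choices matter:

* **Group-specific mesors in every model.** A variant that only shifts mean
  expression (an eQTL) is fit equally well by all five models, so it cannot
  be mistaken for a rhythm difference. This is what separates rhyQTL mapping
  from eQTL mapping.
* **The residual variance is not counted as a per-model parameter** — it is
  common to all five models and cancels in BIC differences.

Because genotype groups have unequal sizes and BIC's penalty depends on n,
the larger group is downsampled without replacement to the smaller group's
size before fitting. A single downsample is noisy, so selection is repeated
over 20 independent downsamples; the evidence that the pair is genuinely
differential is a G-test (G = 2ΣO·ln(O/E), df = 4) of the selected-model
frequencies against a uniform expectation of 4 per model. Uniformity is the
implemented null for "no stable model preference"; the expectation vector is
an argument of `g_test` for users who prefer a different null (for example,
all mass on the full-data winner). The final call requires all three of:
(1) some genotype group rhythmic at p ≤ 10⁻⁴ and fold change ≥ 1.5 —
evaluated on the full retained groups, not the downsamples; (2) the modal
selected model is differential; (3) G-test p < 0.05.

### Thresholds and defaults

| parameter | default | role |
|---|---|---|
| MAF minimum | 0.01 | variant QC, inclusive |
| HWE exact p minimum | 10⁻⁶ | variant QC (exact conditional test), inclusive |
| cis window | ±1,000,000 bp around the TSS, inclusive | pair formation |
| group-size minimum | n > 50 (i.e. ≥ 51) | a genotype group enters analysis |
| rhythmicity p | ≤ 10⁻⁴ | per-group cosinor F-test |
| fold change | ≥ 1.5 (A ≥ 0.2925 log2) | per-group peak-to-trough |
| downsampling repeats | 20 | model-selection resampling |
| G-test p | < 0.05 | differential-frequency evidence |
| replication rules | p < 0.05 / FC ratio > 1.5 / Δφ > 3 h | two-cohort comparison |

Boundary conventions are literal readings of the inequalities above:
thresholds written with ≤/≥ pass on ties; "greater than 50" excludes 50
exactly. Equal group sizes tie-break to the lower dosage code; modal-model
ties prefer a differential model, then the lowest model id — deterministic
and conservative in the sense that the differential class is only reported
when it at least ties.

## Covariate handling

Categorical covariates (sex, age band, ischemic-time band, death type in the
motivating use case) are regressed out per gene with indicator variables via
least squares before any rhythm fitting, and the gene's mean is added back so
values stay on the log2 scale and fold-change thresholds keep their meaning.
Rank-deficient covariate designs are handled by the pseudoinverse (redundant
columns contribute nothing) with a logged warning.

## Enrichment statistics

Annotation enrichment follows the baseline-normalized form
(EObs/EExp)/(BObs/BExp): observed QTLs versus an expected set of
number-matched SNPs drawn with the same MAF histogram (49 bins of width 0.01
over [0.01, 0.50]), repeated 30 times with the median reported. The expected
draws are restricted to SNPs inside the baseline regions, matching the
denominators, and by default exclude the observed QTLs themselves — with
QTLs left in the pool, a genuinely enriched set contaminates its own
background and the estimate is biased toward 1 (the option is exposed for
users who want the inclusive pool). Motif and GWAS-tag enrichments are plain
2×2 odds ratios OR = ad/bc with a two-sided Fisher exact test. GWAS-side
helpers implement the catalog filters (p ≤ 5×10⁻⁸, European-ancestry
studies, HLA region chr6:29,723,339–33,087,199 excluded), tag-SNP extension
by perfect LD (r² = 1 within 10⁻⁹), greedy p-ordered lead-SNP clumping
(1 Mb window, optional r² > 0.001 exclusion, deterministic tie-breaks by
position, order-independent), and lead-region classification (≥ 5 rhyQTLs
within ±1 Mb ⇒ contributing; additionally 0 eQTLs ⇒ exclusive).

Coordinates: VCF and TSS positions are 1-based; BED is 0-based half-open; a
1-based point p lies in BED [s, e) iff s < p ≤ e. Strand is read but ignored
(the cis window is symmetric). Samples missing a genotype at a SNP are
excluded from that SNP's analysis only.

## What the synthetic generator emulates — and what it does not

`synthetic_data` draws biallelic autosomal dosages as Binomial(2, p) per
donor (Hardy–Weinberg proportions, MAF uniform over a configurable range),
donor times uniform on [0, 24) by default (the time distribution is
pluggable; real donor-time distributions are not uniform and are not
published for the motivating cohort — this is a declared assumption), and
expression as mesor + genotype-conditional cosinor + categorical covariate
offsets + Gaussian noise on the log2 scale. Every planted effect is returned
as a truth record.

It does **not** simulate read-level noise, library-size artifacts,
heavy-tailed expression noise, linkage disequilibrium between SNPs (LD-pair
tables are supplied directly), population structure, or relatedness. Passing
validation studies therefore demonstrates correctness of the statistics
under the model's own assumptions — Gaussian noise, independent SNPs,
exchangeable donors — not robustness to the full messiness of real cohorts.

The enrichment fixture plants category membership independently of MAF with
P(member | non-QTL) = 0.05 and P(member | QTL) set to the requested
membership odds ratio; the baseline covers all SNPs. QTL labels are abundant
(40% of SNPs) so the in-category QTL count is large enough (~10³) that
counting error does not swamp a ±10% tolerance band; note the measured
(EObs/EExp) ratio is a ratio of rates, which approaches the odds ratio only
for small base rates — at these settings a planted OR of 3 measures ≈ 2.7.

## Numerical choices

* Core fits use `numpy.linalg.lstsq` on explicit design matrices (the
  pooled two-group designs for the five models); the 20×-resampling inner
  loop makes per-fit overhead the dominant cost. Tests cross-check RSS and
  selections against statsmodels OLS and closed-form per-group
  decompositions.
* RSS is floored at 10⁻³⁰⁰ before the log in BIC so exactly-interpolating
  fits (possible only on noise-free toys) do not produce −∞ ties; exact BIC
  ties resolve to the simplest (lowest-id) model.
* The HWE test is the exact conditional test: heterozygote-count
  probabilities given allele counts are computed with log-gamma, normalized,
  and summed over counts no more probable than the observed one (with a
  1 + 10⁻¹² relative tolerance for floating ties).
* Per-repeat downsampling seeds derive from (root seed, CRC32 of the pair
  id, repeat index) via `SeedSequence`, so results are independent of the
  order pairs are processed and reproducible pair-by-pair. All generator
  streams similarly split per SNP and per gene.
* Degenerate inputs: n < 4 or all-equal times (mod 24) raise a
  not-estimable error; inestimable downsampling repeats are excluded and
  counted; a zero expected cell in the G-test is an error (the caller must
  pool categories).

## Problem sizes in the validation studies

The sensitivity and type-I studies use 200 simulated pairs each at the
reference condition (one-genotype-only rhythm of A = 1.0 log2 or a shared
rhythm, noise sd 0.5, n = 150 per group, uniform times, 20 downsamples);
pair cohorts are built with exact group sizes to make the operating
characteristics interpretable. Calibration uses 1000 pure-noise fits at
n = 100; enrichment studies use 50,000 SNPs with 30 MAF-matched draws (20
independent trials for the null band); the power curve maps nested subsets
of sizes 50–400 from a 400-donor strong-effect cohort. At these sizes the
whole validation suite runs in well under a minute on one CPU.

## Known limitations

* Only the two largest genotype groups enter the differential stage, as in
  the motivating design; a heterozygote-specific rhythm in the smallest
  group is invisible to criterion (2) when that group is excluded.
* The five-model space subsumes amplitude-only and phase-only changes into
  the "distinct rhythms" model; it does not separate them, and the package
  reports per-group fits for users who need effect decomposition.
* The G-test's uniform expectation is an interpretive choice (see above);
  with 20 repeats the test is coarse, and its p-value should be read as a
  stability screen rather than a calibrated tail probability.
* Trans pairing (distance > 1 Mb or different chromosome) is implemented,
  but the package applies no multiple-testing correction across pairs —
  thresholds are per-pair by design.
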