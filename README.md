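# rhyqtl

Mapping **rhythmic quantitative trait loci (rhyQTLs)** — genetic variants
whose genotype determines whether, how strongly, or at what time of day a
nearby gene is rhythmically expressed over the 24-h cycle.

Classical cis-eQTL mapping asks whether a variant shifts a gene's *mean*
expression. This package implements the complementary question for population
cohorts with per-donor time-of-day annotation (one expression measurement per
donor): does the *rhythm* of expression differ between genotype groups? It is
aimed at researchers analyzing genotype + bulk-expression cohorts and at
anyone who wants a tested, self-contained reference implementation of the
mapping statistic with a synthetic-data generator for validation.

## The method

For each variant-gene pair (cis window: TSS ± 1 Mb; genotype groups with
n > 50; variants with MAF ≥ 0.01, exact Hardy–Weinberg p ≥ 10⁻⁶, autosomal):

1. **Cosinor regression per genotype group.** For samples with times tᵢ
   (hours) and log2 expression yᵢ, fit by OLS

   y = m + a·cos(2πt/24) + b·sin(2πt/24),

   giving amplitude A = √(a² + b²) (half peak-to-trough, log2 units),
   acrophase φ = (24/2π)·atan2(b, a) mod 24, peak-to-trough fold change
   2^(2A), and an F-test p-value against the intercept-only model. A group is
   *rhythmic* when p ≤ 10⁻⁴ and fold change ≥ 1.5.

2. **Differential rhythmicity by BIC model selection.** On the two largest
   genotype groups, five rhythm-sharing models are compared — no rhythm,
   rhythm in one group only (two models), one shared rhythm, two distinct
   rhythms — each with group-specific mesors so a pure expression-level
   (eQTL) difference can never pass as a rhythm difference. Models are scored
   by BIC = n·ln(RSS/n) + k·ln(n).

3. **Downsampling + G-test.** The larger group is downsampled to the smaller
   group's size; selection is repeated over 20 independent downsamples. A
   G-test (G = 2ΣO·ln(O/E), df = 4) asks whether the selected-model
   frequencies deviate from a uniform expectation over the five models.

4. **The rhyQTL call.** A pair is a rhyQTL iff (1) at least one genotype
   group is rhythmic, (2) the modal selected model is a differential one, and
   (3) the G-test p < 0.05.

Around the mapping core the package implements the accompanying enrichment
statistics: baseline-normalized annotation enrichment
(EObs/EExp)/(BObs/BExp) with number- and MAF-matched background SNPs (median
of 30 draws), motif and GWAS-tag 2×2 odds ratios with Fisher's exact test,
LD extension of tag SNPs at r² = 1, greedy lead-SNP clumping, lead-region
classification (≥ 5 rhyQTLs; eQTL-exclusivity), Bonferroni thresholds, and
AM/PM acrophase summaries. `rhyqtl.synthetic_data` generates genotype and
expression cohorts with planted, fully-known effects so every stage can be
scored against truth.

## Worked example

The `analysis/` scripts run a complete study on a simulated cohort
(400 donors, 30 SNPs, 8 planted rhyQTL effects, 2 pure eQTLs, 10 null genes):

```bash
python analysis/01_simulate_cohort.py --seed 1   # writes results/data/
python analysis/02_map_rhyqtls.py     --seed 1
```

```
20 variant-gene pairs analyzed; 8 rhyQTL calls
sensitivity on 8 planted rhyQTL pairs: 1.00
false-call rate on 12 null/eQTL pairs: 0.000
snp_id     gene_id modal_model          p_g  is_rhyqtl
  snp6   RHY_AMP_0  M_DISTINCT 3.480094e-13       True
  snp0 RHY_ONEGT_0    M_B_ONLY 3.480094e-13       True
  snp4 RHY_PHASE_0  M_DISTINCT 3.480094e-13       True
  ...
```

All 8 planted effects — one-genotype-only rhythms, 12-h phase shifts and
amplitude changes — are recovered with the expected modal model, and none of
the eQTL-only or null genes is called. The G-test p of 3.5 × 10⁻¹³
corresponds to all 20 downsamples selecting the same differential model
(G = 64.38 on 4 df). Continuing:

```bash
python analysis/03_power_vs_n.py    --seed 1     # power vs cohort size
python analysis/04_enrichment.py    --seed 1     # enrichment statistics
python analysis/05_phase_summary.py              # AM/PM acrophase summary
```

The power curve shows no calls at n = 100 (no genotype group clears the
n > 50 requirement in the subset), 7/8 at n = 150, and saturation at 8/8 from
n = 200 — the qualitative sample-size behavior expected of the design. The
enrichment script recovers a planted odds ratio of 3 as a median enrichment
of 2.79 and reports 1.00 for an unenriched category.

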