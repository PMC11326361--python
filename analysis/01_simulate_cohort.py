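#!/usr/bin/env python
"""Simulate the synthetic cohort used by the downstream analyses.

400 donors, 30 biallelic SNPs at Hardy-Weinberg proportions, uniform sampling
times, and 20 genes: 8 planted rhyQTL effects (rhythm in one genotype only,
phase shifts, amplitude changes), 2 pure eQTLs (mesor shift, no rhythm
difference) and 10 null genes. Writes VCF/TSV inputs plus the truth table
under results/data/.
"""

import argparse
from pathlib import Path

from rhyqtl import io_formats as iof
from rhyqtl import synthetic_data as sd


def build_config(seed: int) -> sd.SimulationConfig:
    flat = {0: 0.0, 1: 0.0, 2: 0.0}
    specs = []
    # rhythm present in the reference-homozygote group only
    for i in range(4):
        specs.append(sd.RhyEffectSpec(
            snp_id=f"snp{i}", gene_id=f"RHY_ONEGT_{i}",
            per_genotype_mesor={0: 5.0, 1: 5.0, 2: 5.0},
            per_genotype_amplitude={0: 1.0, 1: 0.0, 2: 0.0},
            per_genotype_phase={0: float((5 * i) % 24), 1: 0.0, 2: 0.0}))
    # rhythm in all genotypes, acrophase shifted by 12 h in carriers
    for i in range(2):
        specs.append(sd.RhyEffectSpec(
            snp_id=f"snp{4 + i}", gene_id=f"RHY_PHASE_{i}",
            per_genotype_mesor={0: 5.0, 1: 5.0, 2: 5.0},
            per_genotype_amplitude={0: 0.8, 1: 0.8, 2: 0.8},
            per_genotype_phase={0: 3.0, 1: 15.0, 2: 15.0}))
    # rhythm in all genotypes, amplitude attenuated in carriers
    for i in range(2):
        specs.append(sd.RhyEffectSpec(
            snp_id=f"snp{6 + i}", gene_id=f"RHY_AMP_{i}",
            per_genotype_mesor={0: 5.0, 1: 5.0, 2: 5.0},
            per_genotype_amplitude={0: 1.2, 1: 0.3, 2: 0.3},
            per_genotype_phase={0: 8.0, 1: 8.0, 2: 8.0}))
    # pure eQTLs: expression level differs, no rhythm anywhere
    for i in range(2):
        specs.append(sd.RhyEffectSpec(
            snp_id=f"snp{8 + i}", gene_id=f"EQTL_{i}",
            per_genotype_mesor={0: 4.0, 1: 4.6, 2: 5.2},
            per_genotype_amplitude=dict(flat), per_genotype_phase=dict(flat)))
    return sd.SimulationConfig(
        n_individuals=400, n_snps=30, maf_range=(0.25, 0.5), noise_sd=0.4,
        covariate_spec={"sex": {"levels": ["M", "F"], "effects": {"F": 0.3}}},
        effect_specs=specs, n_null_genes=10, seed=seed)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    config = build_config(args.seed)
    genotypes = sd.simulate_genotypes(config)
    times = sd.simulate_times(config)
    dataset, truth = sd.simulate_expression(genotypes, times, config)
    annotation = sd.make_annotation(genotypes, config)

    args.out.mkdir(parents=True, exist_ok=True)
    iof.write_genotypes_vcf(genotypes, args.out / "genotypes.vcf")
    iof.write_expression(dataset, args.out / "expression.tsv",
                         args.out / "samples.tsv")
    iof.write_annotation(annotation, args.out / "annotation.tsv")
    sd.write_truth(truth, args.out / "truth.tsv")

    n_rhy = sum(s.is_rhyqtl for s in truth)
    n_eqtl = sum(s.is_eqtl and not s.is_rhyqtl for s in truth)
    print(f"cohort: {config.n_individuals} donors, {config.n_snps} SNPs, "
          f"{len(dataset.genes)} genes")
    print(f"planted: {n_rhy} rhyQTL effects, {n_eqtl} pure eQTLs, "
          f"{config.n_null_genes} null genes")
    print(f"inputs written to {args.out}/")


if __name__ == "__main__":
    main()
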