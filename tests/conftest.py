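import numpy as np
import pytest

from rhyqtl import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    """A 400-donor cohort: 2 planted rhyQTL effects, 3 null genes, 6 SNPs."""
    specs = [
        sd.RhyEffectSpec(
            snp_id="snp0", gene_id="G0",
            per_genotype_mesor={0: 5.0, 1: 5.0, 2: 5.0},
            per_genotype_amplitude={0: 1.0, 1: 0.0, 2: 0.0},
            per_genotype_phase={0: 6.0, 1: 0.0, 2: 0.0},
        ),
        sd.RhyEffectSpec(
            snp_id="snp1", gene_id="G1",
            per_genotype_mesor={0: 4.0, 1: 4.5, 2: 5.0},
            per_genotype_amplitude={0: 0.8, 1: 0.8, 2: 0.8},
            per_genotype_phase={0: 3.0, 1: 15.0, 2: 15.0},
        ),
    ]
    config = sd.SimulationConfig(
        n_individuals=400, n_snps=6, maf_range=(0.35, 0.5), noise_sd=0.4,
        effect_specs=specs, n_null_genes=3, seed=777,
    )
    genotypes = sd.simulate_genotypes(config)
    times = sd.simulate_times(config)
    dataset, truth = sd.simulate_expression(genotypes, times, config)
    annotation = sd.make_annotation(genotypes, config)
    return config, genotypes, dataset, annotation, truth
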