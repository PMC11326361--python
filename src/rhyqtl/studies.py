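"""Validation studies: the package run against synthetic data with known truth.

Each function simulates a study at stated conditions, runs the production
mapping code, and returns the measured operating characteristic (sensitivity,
false-call rate, p-value calibration, enrichment recovery, power curve).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import differential, enrichment, phase, synthetic_data as sd
from .rhythm import cosinor_signal, fit_harmonic, phase_difference


def _subseed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0] % (2**31))


def _call_pair(pair, dataset, seed):
    times = dataset.times
    y = dataset.values.loc[pair.gene_id].to_numpy(dtype=float)
    fits = {g: fit_harmonic(times[m], y[m]) for g, m in pair.groups.items()}
    msr = differential.repeat_model_selection(pair, dataset, seed=seed)
    return differential.call_rhyqtl(pair, fits, msr)


def sensitivity_study(
    n_pairs: int = 200,
    n_per_group: int = 150,
    amplitude: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> dict:
    """Fraction of one-genotype-only rhythm pairs called as rhyQTLs.

    Each pair has a rhythm (log2 amplitude ``amplitude``, acrophase 6 h) in one
    homozygote group and flat expression in the other, with uniform sampling
    times and Gaussian noise.
    """
    called = 0
    for i in range(n_pairs):
        pair, ds, truth = sd.simulate_pair_cohort(
            n_per_group=n_per_group, amplitude=(amplitude, 0.0),
            noise_sd=noise_sd, seed=_subseed(seed, 1, i))
        assert truth.is_rhyqtl
        called += _call_pair(pair, ds, seed=_subseed(seed, 2, i)).is_rhyqtl
    return {"sensitivity": called / n_pairs, "n": n_pairs}


def type1_study(
    n_pairs: int = 200,
    n_per_group: int = 150,
    amplitude: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> dict:
    """rhyQTL call rate on pairs with an identical shared rhythm in both genotypes."""
    called = 0
    for i in range(n_pairs):
        pair, ds, truth = sd.simulate_pair_cohort(
            n_per_group=n_per_group, amplitude=(amplitude, amplitude),
            phase=(6.0, 6.0), noise_sd=noise_sd, seed=_subseed(seed, 3, i))
        assert not truth.is_rhyqtl
        called += _call_pair(pair, ds, seed=_subseed(seed, 4, i)).is_rhyqtl
    return {"false_call_rate": called / n_pairs, "n": n_pairs}


def noise_free_recovery(seed: int = 0, n_draws: int = 25) -> dict:
    """Worst-case cosinor parameter-recovery error on noise-free planted signals."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, 24.0, 0.5)
    max_amp_err = 0.0
    max_phase_err = 0.0
    for _ in range(n_draws):
        mesor = rng.uniform(-5, 8)
        amp = rng.uniform(0.1, 3.0)
        phi = rng.uniform(0, 24)
        fit = fit_harmonic(t, cosinor_signal(t, mesor, amp, phi))
        max_amp_err = max(max_amp_err, abs(fit.amplitude - amp))
        max_phase_err = max(max_phase_err, phase_difference(fit.phase, phi))
    return {"max_amplitude_error": max_amp_err,
            "max_phase_error_h": max_phase_err, "n": n_draws}


def null_p_calibration(n_reps: int = 1000, n: int = 100, seed: int = 0) -> dict:
    """P(p <= 0.05) of the cosinor F-test under pure Gaussian noise."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        t = rng.uniform(0, 24, n)
        hits += fit_harmonic(t, rng.normal(size=n)).p_value <= 0.05
    return {"rate_p_le_05": hits / n_reps, "n": n_reps}


def enrichment_null_study(
    n_trials: int = 20,
    n_snps: int = 50_000,
    seed: int = 0,
) -> dict:
    """Median baseline enrichment under independent category membership."""
    medians = []
    for i in range(n_trials):
        s = _subseed(seed, 5, i)
        snps, cats, base = sd.simulate_enrichment_tables(n_snps, 1, 1.0, seed=s)
        res = enrichment.baseline_enrichment(snps, snps["is_qtl"], cats[0],
                                             base, n_iter=30, seed=s)
        medians.append(res.median)
    medians = np.array(medians)
    return {"medians": medians.tolist(),
            "frac_in_band": float(np.mean((medians >= 0.9) & (medians <= 1.1))),
            "n": n_trials}


def enrichment_recovery_study(
    planted_or: float = 3.0,
    n_snps: int = 50_000,
    seed: int = 0,
) -> dict:
    """Recovered median enrichment for a category planted at a known odds ratio."""
    s = _subseed(seed, 6)
    snps, cats, base = sd.simulate_enrichment_tables(n_snps, 1, planted_or, seed=s)
    res = enrichment.baseline_enrichment(snps, snps["is_qtl"], cats[0], base,
                                         n_iter=30, seed=s)
    return {"median": res.median, "planted_or": planted_or, "n": n_snps}


def strong_effect_cohort(seed: int = 99, n_individuals: int = 400,
                         n_effects: int = 4):
    """A cohort with several strong one-genotype-only rhythms for power curves."""
    specs = [
        sd.RhyEffectSpec(
            snp_id=f"snp{i}", gene_id=f"G{i}",
            per_genotype_mesor={0: 5.0, 1: 5.0, 2: 5.0},
            per_genotype_amplitude={0: 1.2, 1: 0.0, 2: 0.0},
            per_genotype_phase={0: float((3 * i) % 24), 1: 0.0, 2: 0.0})
        for i in range(n_effects)
    ]
    config = sd.SimulationConfig(
        n_individuals=n_individuals, n_snps=n_effects, maf_range=(0.4, 0.5),
        noise_sd=0.4, effect_specs=specs, seed=seed)
    gm = sd.simulate_genotypes(config)
    times = sd.simulate_times(config)
    ds, truth = sd.simulate_expression(gm, times, config)
    return gm, ds, sd.make_annotation(gm, config), truth


def power_curve_study(sizes=(50, 150, 400), seed: int = 0) -> pd.DataFrame:
    """rhyQTL counts over nested random subsamples of a strong-effect cohort."""
    gm, ds, ann, _ = strong_effect_cohort(seed=_subseed(seed, 7))
    return phase.power_analysis(gm, ds, ann, sizes=list(sizes), seed=seed)
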