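"""Phase-distribution summaries and pipeline orchestration.

``map_rhyqtls`` wires the stages together: variant QC, covariate
residualization, cis pairing, per-genotype cosinor fits, the rhythmicity
screen, repeated-downsampling BIC model selection with the G-test, and the
three-criterion rhyQTL call. ``run_map_pipeline`` is the file-in/file-out
wrapper; ``power_analysis`` reruns the mapping on random sample subsets of
increasing size. Acrophases are classified as morning (AM, [0, 12)) or
afternoon (PM, [12, 24)).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential, io_formats, pairing
from .io_formats import ExpressionDataset, GeneAnnotation, GenotypeMatrix
from .rhythm import NotEstimableError, fit_harmonic, is_rhythmic

logger = logging.getLogger(__name__)


def classify_am_pm(phase: float) -> str:
    """AM iff phase in [0, 12); the boundary 12.0 is PM (half-open convention)."""
    if not (0.0 <= phase < 24.0):
        raise ValueError(f"phase {phase} outside [0, 24)")
    return "AM" if phase < 12.0 else "PM"


def phase_histogram(phases, n_bins: int = 24) -> np.ndarray:
    """Counts over equal-width circular bins [24k/n_bins, 24(k+1)/n_bins)."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    p = np.asarray(list(phases), dtype=float)
    if p.size and np.any((p < 0) | (p >= 24)):
        raise ValueError("phases must lie in [0, 24)")
    idx = np.floor(p * n_bins / 24.0).astype(int)
    return np.bincount(idx, minlength=n_bins)


@dataclass
class MapParams:
    """All thresholds of the mapping pipeline, at the study defaults."""

    maf_min: float = 0.01
    hwe_p_min: float = 1e-6
    autosomes_only: bool = True
    cis_window: int = 1_000_000
    mode: str = "cis"
    n_min: int = 50
    rhythm_p_max: float = 1e-4
    rhythm_fc_min: float = 1.5
    n_repeats: int = 20
    g_p_max: float = 0.05
    covariates: list | None = None


def map_rhyqtls(
    genotypes: GenotypeMatrix,
    expression: ExpressionDataset,
    annotation: GeneAnnotation,
    params: MapParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the full mapping on in-memory inputs; one result row per pair.

    Model selection is only run for pairs that pass the rhythmicity screen
    (rhythmic in at least one genotype group), mirroring the staged design;
    screened-out pairs are reported with ``is_rhyqtl = False``.
    """
    params = params or MapParams()
    gm = pairing.qc_variants(genotypes, params.maf_min, params.hwe_p_min,
                             params.autosomes_only)
    ds = pairing.regress_covariates(expression, params.covariates)
    pairs = pairing.build_pairs(gm, annotation, expression=ds,
                                window=params.cis_window, mode=params.mode,
                                n_min=params.n_min)
    # pairing subsets genotype samples to the expression intersection; the
    # group index arrays address positions in the shared sample order
    shared = gm.samples.intersection(ds.samples)
    ds = ds.subset_samples(shared)
    times = ds.times
    rows = []
    for pair in pairs:
        values = ds.values.loc[pair.gene_id].to_numpy(dtype=float)
        fits = {}
        for g, members in pair.groups.items():
            try:
                fits[g] = fit_harmonic(times[members], values[members])
            except NotEstimableError:
                continue
        if not fits:
            logger.warning("no estimable genotype group for %s", pair.pair_id)
            continue
        crit1 = any(
            is_rhythmic(f, params.rhythm_p_max, params.rhythm_fc_min)
            for f in fits.values()
        )
        row = {"snp_id": pair.snp_id, "gene_id": pair.gene_id,
               "chrom": pair.chrom, "pos": pair.pos, "distance": pair.distance}
        for g in (0, 1, 2):
            f = fits.get(g)
            row[f"n_{g}"] = pair.group_sizes.get(g, 0)
            row[f"amp_{g}"] = f.amplitude if f else np.nan
            row[f"phase_{g}"] = f.phase if f else np.nan
            row[f"p_{g}"] = f.p_value if f else np.nan
            row[f"fc_{g}"] = f.fc_ptt if f else np.nan
        row["crit1_rhythmic"] = crit1
        if crit1:
            msr = differential.repeat_model_selection(
                pair, ds, n_repeats=params.n_repeats, seed=seed)
            call = differential.call_rhyqtl(
                pair, fits, msr, params.rhythm_p_max, params.rhythm_fc_min,
                params.g_p_max)
            row.update({
                "model_freq": ";".join(str(int(c)) for c in msr.freq),
                "g_stat": msr.g_stat, "p_g": msr.p_g,
                "modal_model": msr.modal_model.name,
                "crit2_differential": call.crit2_differential_modal,
                "crit3_gtest": call.crit3_gtest,
                "is_rhyqtl": call.is_rhyqtl,
            })
        else:
            row.update({"model_freq": "", "g_stat": np.nan, "p_g": np.nan,
                        "modal_model": "", "crit2_differential": False,
                        "crit3_gtest": False, "is_rhyqtl": False})
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    """File-based configuration of ``run_map_pipeline``."""

    genotypes: str
    expression: str
    metadata: str
    annotation: str
    out_dir: str
    genotype_format: str | None = None
    params: MapParams = field(default_factory=MapParams)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = MapParams(**raw.pop("params", {}))
        return cls(params=params, **raw)


def run_map_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Read inputs, run the mapping, and write the result table plus a manifest."""
    genotypes = io_formats.read_genotypes(config.genotypes, config.genotype_format)
    expression = io_formats.read_expression(config.expression, config.metadata)
    annotation = io_formats.read_annotation(config.annotation)
    result = map_rhyqtls(genotypes, expression, annotation, config.params,
                         config.seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.to_csv(out / "rhyqtl_calls.tsv", sep="\t", index=False)
    from . import __version__

    manifest = {"version": __version__, "seed": config.seed,
                "params": asdict(config.params),
                "n_pairs": int(len(result)),
                "n_rhyqtl": int(result["is_rhyqtl"].sum()) if len(result) else 0}
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    if len(result) == 0:
        logger.warning("no variant-gene pairs survived QC and pairing")
    return result


def power_analysis(
    genotypes: GenotypeMatrix,
    expression: ExpressionDataset,
    annotation: GeneAnnotation,
    sizes: list[int],
    seed: int = 0,
    params: MapParams | None = None,
) -> pd.DataFrame:
    """Re-map on random sample subsets of each size; count rhyQTLs and rhyGenes."""
    shared = genotypes.samples.intersection(expression.samples)
    n_avail = len(shared)
    rows = []
    for size in sizes:
        if size > n_avail:
            raise ValueError(f"requested subset {size} > available {n_avail} samples")
        rng = np.random.default_rng(np.random.SeedSequence([seed, size]))
        # keep the original sample order so the full-size subset is the identity
        chosen = shared[np.sort(rng.choice(n_avail, size=size, replace=False))]
        res = map_rhyqtls(genotypes.subset_samples(chosen),
                          expression.subset_samples(chosen),
                          annotation, params, seed)
        n_rhy = int(res["is_rhyqtl"].sum()) if len(res) else 0
        n_genes = res.loc[res["is_rhyqtl"], "gene_id"].nunique() if len(res) else 0
        rows.append({"n_samples": size, "n_pairs": len(res),
                     "n_rhyqtl": n_rhy, "n_rhygenes": n_genes})
    return pd.DataFrame(rows)
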