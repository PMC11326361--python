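"""Synthetic genotype/expression cohorts with planted genotype-dependent rhythms.

The generator emulates the data model the mapping pipeline assumes: biallelic
autosomal SNPs at Hardy-Weinberg proportions, donor sampling times on [0, 24),
and log2 expression

    y_i = mesor_g + A_g * cos(2*pi*(t_i - phi_g)/24) + covariate offsets + noise

where g is sample i's dosage at the effect SNP, A_g is the genotype-conditional
amplitude (log2 units, half peak-to-trough), phi_g the genotype-conditional
acrophase (hours) and the noise is Gaussian on the log2 scale. Every planted
effect is returned as a truth record so parameter recovery, sensitivity and
false-call rates can be scored exactly.

All randomness flows from one integer seed; streams are split per SNP and per
gene (via ``numpy.random.SeedSequence``) so each SNP's or gene's draw is
independent of the order it is generated in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionDataset, GeneAnnotation, GenotypeMatrix, IntervalSet

_DOSAGES = (0, 1, 2)
_DEFAULT_MESOR = 5.0

# sub-stream tags, so the per-purpose generators never collide
_S_MAF, _S_GENO, _S_GENE, _S_COV, _S_TIME = 1, 2, 3, 4, 5


class ConfigurationError(ValueError):
    pass


@dataclass
class RhyEffectSpec:
    """Planted genotype-conditional rhythm (and optional mean effect) at one SNP-gene pair."""

    snp_id: str
    gene_id: str
    per_genotype_mesor: dict
    per_genotype_amplitude: dict
    per_genotype_phase: dict
    is_rhyqtl: bool = field(default=None)  # type: ignore[assignment]
    is_eqtl: bool = field(default=None)    # type: ignore[assignment]

    def __post_init__(self) -> None:
        for table in (self.per_genotype_mesor, self.per_genotype_amplitude,
                      self.per_genotype_phase):
            if set(table) != set(_DOSAGES):
                raise ConfigurationError("per-genotype tables need keys {0, 1, 2}")
        if any(a < 0 for a in self.per_genotype_amplitude.values()):
            raise ConfigurationError("amplitudes must be >= 0")
        if any(not (0 <= p < 24) for p in self.per_genotype_phase.values()):
            raise ConfigurationError("phases must lie in [0, 24)")
        derived_rhy = self._derive_is_rhyqtl()
        derived_eqtl = self._derive_is_eqtl()
        if self.is_rhyqtl is None:
            self.is_rhyqtl = derived_rhy
        elif self.is_rhyqtl != derived_rhy:
            raise ConfigurationError(
                f"is_rhyqtl={self.is_rhyqtl} inconsistent with parameter table "
                f"(derived {derived_rhy})"
            )
        if self.is_eqtl is None:
            self.is_eqtl = derived_eqtl
        elif self.is_eqtl != derived_eqtl:
            raise ConfigurationError(
                f"is_eqtl={self.is_eqtl} inconsistent with mesor table"
            )

    def _derive_is_rhyqtl(self) -> bool:
        amps = [self.per_genotype_amplitude[g] for g in _DOSAGES]
        rhythmic = [g for g in _DOSAGES if self.per_genotype_amplitude[g] > 0]
        if not rhythmic:
            return False
        if len(set(amps)) > 1:
            return True
        phases = {self.per_genotype_phase[g] for g in rhythmic}
        return len(phases) > 1

    def _derive_is_eqtl(self) -> bool:
        return len({self.per_genotype_mesor[g] for g in _DOSAGES}) > 1


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n_individuals: int
    n_snps: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    time_distribution: str = "uniform"  # or a callable(rng, n) -> hours
    noise_sd: float = 0.5
    covariate_spec: dict = field(default_factory=dict)
    effect_specs: list[RhyEffectSpec] = field(default_factory=list)
    n_null_genes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ConfigurationError("n_individuals must be > 0")
        if self.n_snps <= 0:
            raise ConfigurationError("n_snps must be > 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    @property
    def sample_ids(self) -> pd.Index:
        width = len(str(self.n_individuals))
        return pd.Index([f"S{i:0{width}d}" for i in range(self.n_individuals)])


# SNP regions are spaced far apart so each effect SNP pairs only with its own gene
_REGION_BP = 3_000_000
_SNP_OFFSET = 10_000


def _snp_position(i: int) -> tuple[str, int]:
    chrom = f"chr{(i % 22) + 1}"
    pos = _SNP_OFFSET + (i // 22) * _REGION_BP
    return chrom, pos


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw dosages as Binomial(2, p_alt) per individual (HWE proportions).

    Per-SNP MAFs are uniform over ``config.maf_range``; each SNP uses its own
    random stream so the matrix is reproducible SNP-by-SNP.
    """
    rng_maf = np.random.default_rng(np.random.SeedSequence([config.seed, _S_MAF]))
    mafs = rng_maf.uniform(*config.maf_range, size=config.n_snps)
    dosages = np.empty((config.n_snps, config.n_individuals))
    chroms, poss = [], []
    for i in range(config.n_snps):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, _S_GENO, i]))
        dosages[i] = rng.binomial(2, mafs[i], size=config.n_individuals)
        chrom, pos = _snp_position(i)
        chroms.append(chrom)
        poss.append(pos)
    n = config.n_snps
    return GenotypeMatrix(
        snp_ids=np.array([f"snp{i}" for i in range(n)], dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.full(n, "A", dtype=object),
        alt=np.full(n, "G", dtype=object),
        dosages=dosages,
        samples=config.sample_ids,
    )


def two_group_genotypes(
    n_per_group: int,
    dosages: tuple[int, int] = (0, 2),
    snp_id: str = "snp0",
    chrom: str = "chr1",
    pos: int = _SNP_OFFSET,
) -> GenotypeMatrix:
    """A single SNP with exactly ``n_per_group`` samples in each of two dosage groups.

    Used for parameter-recovery studies at controlled group sizes, which
    binomial HWE sampling cannot produce exactly.
    """
    n = 2 * n_per_group
    d = np.array([float(dosages[0])] * n_per_group + [float(dosages[1])] * n_per_group)
    width = len(str(n))
    samples = pd.Index([f"S{i:0{width}d}" for i in range(n)])
    return GenotypeMatrix(
        snp_ids=np.array([snp_id], dtype=object),
        chrom=np.array([chrom], dtype=object),
        pos=np.array([pos], dtype=np.int64),
        ref=np.array(["A"], dtype=object),
        alt=np.array(["G"], dtype=object),
        dosages=d[None, :],
        samples=samples,
    )


def simulate_times(config: SimulationConfig) -> np.ndarray:
    """Donor sampling times in hours on [0, 24); uniform by default."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _S_TIME]))
    if callable(config.time_distribution):
        t = np.asarray(config.time_distribution(rng, config.n_individuals), dtype=float)
        if np.any((t < 0) | (t >= 24)):
            raise ConfigurationError("time_distribution must return hours in [0, 24)")
        return t
    if config.time_distribution == "uniform":
        return rng.uniform(0.0, 24.0, size=config.n_individuals)
    raise ConfigurationError(f"unknown time_distribution {config.time_distribution!r}")


def _simulate_covariates(config: SimulationConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample categorical covariate levels and their summed additive offsets."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _S_COV]))
    n = config.n_individuals
    columns = {}
    offsets = np.zeros(n)
    for name, spec in config.covariate_spec.items():
        levels = list(spec["levels"])
        probs = spec.get("probs")
        draws = rng.choice(levels, size=n, p=probs)
        columns[name] = draws
        effects = spec.get("effects", {})
        offsets += np.array([effects.get(level, 0.0) for level in draws])
    return pd.DataFrame(columns, index=config.sample_ids), offsets


def simulate_expression(
    genotypes: GenotypeMatrix,
    times: np.ndarray,
    config: SimulationConfig,
) -> tuple[ExpressionDataset, list[RhyEffectSpec]]:
    """Generate log2 expression with the planted genotype-conditional rhythms.

    Genes named in ``config.effect_specs`` follow the cosinor model with
    parameters switched by the sample's dosage at the effect SNP; the
    ``config.n_null_genes`` extra genes are flat noise around the default
    mesor. Returns the dataset and the truth table verbatim.
    """
    times = np.asarray(times, dtype=float)
    if len(times) != genotypes.n_samples:
        raise ValueError("times and genotype samples differ in length")
    if np.any((times < 0) | (times >= 24)):
        raise ValueError("times must lie in [0, 24)")
    omega = 2.0 * np.pi / 24.0
    covs, cov_offsets = _simulate_covariates(config)
    gene_rows = {}
    gene_index = 0
    for spec in config.effect_specs:
        snp_row = genotypes.snp_index(spec.snp_id)  # raises if SNP absent
        d = genotypes.dosages[snp_row]
        mesor = np.array([spec.per_genotype_mesor[int(g)] for g in d])
        amp = np.array([spec.per_genotype_amplitude[int(g)] for g in d])
        phase = np.array([spec.per_genotype_phase[int(g)] for g in d])
        signal = mesor + amp * np.cos(omega * (times - phase))
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, _S_GENE, gene_index]))
        noise = rng.normal(0.0, config.noise_sd, size=len(times)) if config.noise_sd > 0 else 0.0
        gene_rows[spec.gene_id] = signal + cov_offsets + noise
        gene_index += 1
    for j in range(config.n_null_genes):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, _S_GENE, gene_index]))
        noise = rng.normal(0.0, config.noise_sd, size=len(times)) if config.noise_sd > 0 else np.zeros(len(times))
        gene_rows[f"GENE_NULL{j}"] = _DEFAULT_MESOR + cov_offsets + noise
        gene_index += 1
    values = pd.DataFrame(gene_rows, index=genotypes.samples).T
    metadata = pd.DataFrame({"time_h": times}, index=genotypes.samples)
    for col in covs.columns:
        metadata[col] = covs[col]
    return ExpressionDataset(values, metadata), list(config.effect_specs)


def make_annotation(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    tss_offset: int = 1_000,
) -> GeneAnnotation:
    """Place each effect gene's TSS near its SNP; null genes near the unused SNPs.

    Null genes cycle through the SNPs that carry no planted effect so that
    null variant-gene pairs exist for false-call-rate estimation.
    """
    rows = []
    used = set()
    for spec in config.effect_specs:
        i = genotypes.snp_index(spec.snp_id)
        used.add(i)
        rows.append({"gene_id": spec.gene_id, "chrom": genotypes.chrom[i],
                     "tss": int(genotypes.pos[i]) + tss_offset, "strand": "+"})
    free = [i for i in range(genotypes.n_snps) if i not in used] or list(range(genotypes.n_snps))
    for j in range(config.n_null_genes):
        i = free[j % len(free)]
        rows.append({"gene_id": f"GENE_NULL{j}", "chrom": genotypes.chrom[i],
                     "tss": int(genotypes.pos[i]) + tss_offset, "strand": "+"})
    return GeneAnnotation(pd.DataFrame(rows))


def simulate_pair_cohort(
    n_per_group: int = 150,
    amplitude: tuple[float, float] = (1.0, 0.0),
    phase: tuple[float, float] = (6.0, 6.0),
    mesor: tuple[float, float] = (5.0, 5.0),
    noise_sd: float = 0.5,
    seed: int = 0,
    snp_id: str = "snp0",
    gene_id: str = "G0",
):
    """One variant-gene pair with exactly ``n_per_group`` samples per genotype.

    The two homozygote dosage groups (0 and 2) carry the given cosinor
    parameters. Returns ``(pair, dataset, truth_spec)`` ready for
    :func:`rhyqtl.differential.repeat_model_selection`.
    """
    from .pairing import build_pairs

    gm = two_group_genotypes(n_per_group, snp_id=snp_id)
    spec = RhyEffectSpec(
        snp_id=snp_id, gene_id=gene_id,
        per_genotype_mesor={0: mesor[0], 1: mesor[1], 2: mesor[1]},
        per_genotype_amplitude={0: amplitude[0], 1: amplitude[1], 2: amplitude[1]},
        per_genotype_phase={0: phase[0], 1: phase[1], 2: phase[1]},
    )
    config = SimulationConfig(
        n_individuals=2 * n_per_group, n_snps=1, noise_sd=noise_sd, seed=seed,
        effect_specs=[spec],
    )
    times = simulate_times(config)
    dataset, truth = simulate_expression(gm, times, config)
    pairs = build_pairs(gm, make_annotation(gm, config), expression=dataset)
    if len(pairs) != 1:
        raise RuntimeError("pair cohort construction failed to yield one pair")
    return pairs[0], dataset, truth[0]


# ---------------------------------------------------------------------------
# truth table serialization
# ---------------------------------------------------------------------------

def truth_to_frame(specs: list[RhyEffectSpec]) -> pd.DataFrame:
    rows = []
    for s in specs:
        row = {"snp_id": s.snp_id, "gene_id": s.gene_id,
               "is_rhyqtl": s.is_rhyqtl, "is_eqtl": s.is_eqtl}
        for g in _DOSAGES:
            row[f"mesor_{g}"] = s.per_genotype_mesor[g]
            row[f"amplitude_{g}"] = s.per_genotype_amplitude[g]
            row[f"phase_{g}"] = s.per_genotype_phase[g]
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_truth(df: pd.DataFrame) -> list[RhyEffectSpec]:
    specs = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        specs.append(RhyEffectSpec(
            snp_id=d["snp_id"], gene_id=d["gene_id"],
            per_genotype_mesor={g: float(d[f"mesor_{g}"]) for g in _DOSAGES},
            per_genotype_amplitude={g: float(d[f"amplitude_{g}"]) for g in _DOSAGES},
            per_genotype_phase={g: float(d[f"phase_{g}"]) for g in _DOSAGES},
            is_rhyqtl=bool(d["is_rhyqtl"]), is_eqtl=bool(d["is_eqtl"]),
        ))
    return specs


def write_truth(specs: list[RhyEffectSpec], path) -> None:
    truth_to_frame(specs).to_csv(path, sep="\t", index=False)


def read_truth(path) -> list[RhyEffectSpec]:
    return frame_to_truth(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# enrichment fixtures with known truth
# ---------------------------------------------------------------------------

def simulate_enrichment_tables(
    n_snps: int,
    n_categories: int,
    planted_or: float,
    seed: int,
    qtl_fraction: float = 0.4,
    base_rate: float = 0.05,
) -> tuple[pd.DataFrame, list[IntervalSet], IntervalSet]:
    """SNP set with QTL labels plus category/baseline intervals at a known odds ratio.

    Category membership is drawn independently of MAF with
    P(in | non-QTL) = ``base_rate`` and P(in | QTL) set so the membership odds
    ratio equals ``planted_or``. The baseline covers every SNP, so the
    baseline-normalized enrichment estimates the planted odds ratio (at a
    small base rate the ratio-of-rates it measures approaches the odds
    ratio). QTL labels are deliberately abundant and the base rate moderate
    so the in-category QTL count is large enough that its counting error does
    not swamp the estimate. Returns (snps, per-category interval sets,
    baseline intervals).
    """
    if n_categories <= 0:
        raise ConfigurationError("n_categories must be >= 1")
    if planted_or <= 0:
        raise ConfigurationError("planted_or must be > 0")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xE17]))
    odds0 = base_rate / (1.0 - base_rate)
    odds1 = planted_or * odds0
    p1 = odds1 / (1.0 + odds1)
    pos = 100 + 10 * np.arange(n_snps)
    snps = pd.DataFrame({
        "snp_id": [f"snp{i}" for i in range(n_snps)],
        "chrom": "chr1",
        "pos": pos,
        "maf": rng.uniform(0.01, 0.5, size=n_snps),
        "is_qtl": rng.random(n_snps) < qtl_fraction,
    })
    member_p = np.where(snps["is_qtl"], p1, base_rate)
    categories = []
    for _ in range(n_categories):
        member = rng.random(n_snps) < member_p
        tuples = [("chr1", int(p) - 1, int(p)) for p in pos[member]]
        categories.append(IntervalSet.from_tuples(tuples))
    baseline = IntervalSet.from_tuples([("chr1", 0, int(pos[-1]) + 10)])
    return snps, categories, baseline
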