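"""Variant QC, covariate residualization, and variant-gene pair construction.

QC retains biallelic autosomal SNPs with MAF >= 0.01 and an exact
Hardy-Weinberg equilibrium p >= 1e-6. Cis pairs link a SNP to every gene whose
TSS lies within +/- 1 Mb (inclusive); a pair is analyzed only when at least two
genotype dosage groups have more than ``n_min`` (default 50) samples, i.e.
n >= 51 read literally from "greater than 50".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionDataset, GeneAnnotation, GenotypeMatrix
from .rhythm import fit_harmonic  # noqa: F401  (re-exported for pipeline use)

logger = logging.getLogger(__name__)


def maf(dosages) -> float:
    """Minor allele frequency from alt-allele dosages; missing (NaN) excluded."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if len(d) == 0:
        raise ValueError("all dosages missing; MAF undefined")
    f_alt = d.sum() / (2.0 * len(d))
    return float(min(f_alt, 1.0 - f_alt))


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose probability does not exceed the observed one
    (Wigginton-style two-sided exact test). Monomorphic sites return 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes")
    n_rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if n_rare == 0:
        return 1.0
    # heterozygote count shares parity with the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    from scipy.special import gammaln

    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    logp = (
        gammaln(n + 1)
        - gammaln(rare_hom + 1) - gammaln(common_hom + 1) - gammaln(hets + 1)
        + hets * np.log(2.0)
        + gammaln(n_rare + 1) + gammaln(2 * n - n_rare + 1) - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = np.nonzero(hets == n_Aa)[0]
    if len(obs) == 0:
        raise ValueError("observed heterozygote count inconsistent with allele counts")
    p_obs = probs[obs[0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def qc_variants(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-6,
    autosomes_only: bool = True,
) -> GenotypeMatrix:
    """Filter SNPs on MAF, exact HWE and autosomal location (all inclusive bounds)."""
    n = genotypes.n_snps
    keep = np.ones(n, dtype=bool)
    removed = {}
    if autosomes_only:
        auto = genotypes.is_autosomal()
        removed["non_autosomal"] = int((~auto).sum())
        keep &= auto
    mafs = np.full(n, np.nan)
    hwe = np.ones(n)
    for i in range(n):
        if not keep[i]:
            continue
        d = genotypes.dosages[i]
        d = d[~np.isnan(d)]
        if len(d) == 0:
            keep[i] = False
            continue
        mafs[i] = maf(d)
        hwe[i] = hwe_exact_p(int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))
    low_maf = keep & (mafs < maf_min)
    removed["low_maf"] = int(low_maf.sum())
    keep &= ~low_maf
    hwe_fail = keep & (hwe < hwe_p_min)
    removed["hwe"] = int(hwe_fail.sum())
    keep &= ~hwe_fail
    logger.info("variant QC removed %s; %d/%d retained", removed, keep.sum(), n)
    if keep.sum() == 0:
        logger.warning("no variants passed QC")
    return genotypes.subset_snps(keep)


def regress_covariates(dataset: ExpressionDataset, covariates: list[str] | None = None) -> ExpressionDataset:
    """Residualize expression on categorical covariates, keeping the gene mean.

    Each gene is regressed on indicator variables for every covariate level
    (least squares via pseudoinverse, so perfectly collinear columns are
    handled); residuals are shifted back by the gene's mean so values stay on
    the original log2 scale and fold-change thresholds remain meaningful.
    """
    cols = dataset.covariate_columns if covariates is None else covariates
    if not cols:
        return dataset
    dummies = pd.get_dummies(dataset.metadata[cols].astype("category"), drop_first=True)
    X = np.column_stack([np.ones(len(dummies)), dummies.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        logger.warning("collinear covariate design (rank %d < %d columns)", rank, X.shape[1])
    Y = dataset.values.to_numpy(dtype=float).T  # samples x genes
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    new_values = resid.T + Y.mean(axis=0)[:, None]
    values = pd.DataFrame(new_values, index=dataset.genes, columns=dataset.samples)
    return ExpressionDataset(values, dataset.metadata)


@dataclass
class VariantGenePair:
    """A SNP paired with a gene, with per-dosage genotype sample groups."""

    snp_id: str
    gene_id: str
    chrom: str
    pos: int
    tss: int
    distance: int
    mode: str  # "cis" | "trans"
    groups: dict = field(default_factory=dict)  # dosage -> np.ndarray of sample positions
    group_sizes: dict = field(default_factory=dict)

    @property
    def pair_id(self) -> str:
        return f"{self.snp_id}|{self.gene_id}"

    @property
    def retained_dosages(self) -> list[int]:
        return sorted(self.groups)


def top_two_groups(pair: VariantGenePair) -> tuple[int, int]:
    """Dosage codes of the two largest retained groups (ties: lower dosage first)."""
    if len(pair.groups) < 2:
        raise ValueError(f"pair {pair.pair_id} has fewer than 2 retained groups")
    ranked = sorted(pair.groups, key=lambda g: (-len(pair.groups[g]), g))
    return ranked[0], ranked[1]


def build_pairs(
    genotypes: GenotypeMatrix,
    annotation: GeneAnnotation,
    expression: ExpressionDataset | None = None,
    window: int = 1_000_000,
    mode: str = "cis",
    n_min: int = 50,
) -> list[VariantGenePair]:
    """Form variant-gene pairs and their genotype groups.

    cis: same chromosome and |pos - TSS| <= window (boundary inclusive).
    trans: different chromosome, or |pos - TSS| > window.
    Groups are formed per dosage over samples shared with ``expression`` (when
    given) after dropping missing dosages; a pair is retained iff at least two
    groups have n > n_min. Genes missing from the genotype sample space or
    annotation are skipped with a warning.
    """
    if mode not in ("cis", "trans"):
        raise ValueError(f"mode must be 'cis' or 'trans', got {mode!r}")
    if expression is not None:
        shared = genotypes.samples.intersection(expression.samples)
        if len(shared) == 0:
            raise ValueError("no samples shared between genotypes and expression")
        gm = genotypes.subset_samples(shared)
    else:
        gm = genotypes
    pairs: list[VariantGenePair] = []
    ann = annotation.table
    for gene_id, chrom, tss in zip(ann["gene_id"], ann["chrom"], ann["tss"]):
        same_chrom = gm.chrom == chrom
        dist = np.abs(gm.pos - int(tss))
        if mode == "cis":
            hit = same_chrom & (dist <= window)
        else:
            hit = ~same_chrom | (same_chrom & (dist > window))
        for i in np.nonzero(hit)[0]:
            d = gm.dosages[i]
            ok = ~np.isnan(d)
            groups = {}
            for g in (0, 1, 2):
                members = np.nonzero(ok & (d == g))[0]
                if len(members) > n_min:
                    groups[g] = members
            if len(groups) < 2:
                continue
            pairs.append(VariantGenePair(
                snp_id=str(gm.snp_ids[i]), gene_id=str(gene_id),
                chrom=str(gm.chrom[i]), pos=int(gm.pos[i]), tss=int(tss),
                distance=int(dist[i]) if gm.chrom[i] == chrom else -1,
                mode=mode, groups=groups,
                group_sizes={g: len(m) for g, m in groups.items()},
            ))
    pairs.sort(key=lambda p: (p.gene_id, p.snp_id))
    return pairs


def pairs_to_frame(pairs: list[VariantGenePair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        rows.append({
            "snp_id": p.snp_id, "gene_id": p.gene_id, "chrom": p.chrom,
            "pos": p.pos, "tss": p.tss, "distance": p.distance, "mode": p.mode,
            "n_per_dosage": ";".join(f"{g}:{n}" for g, n in sorted(p.group_sizes.items())),
            "retained_groups": ";".join(map(str, p.retained_dosages)),
        })
    return pd.DataFrame(rows)
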