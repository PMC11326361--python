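"""Enrichment statistics for rhyQTL and eQTL sets.

Two flavours are implemented:

* A 2x2 odds ratio OR = (a*d)/(b*c) with Fisher's exact test, used for motif
  and GWAS-tag enrichment.
* A baseline-normalized enrichment (EObs/EExp)/(BObs/BExp), where the expected
  set is a number-matched random SNP draw with the same MAF distribution as
  the observed QTLs; the draw is repeated (default 30 times) and the median is
  reported.

Plus the GWAS-side helpers: catalog filtering, LD extension of tag SNPs at
r^2 = 1, greedy p-value-ordered lead-SNP clumping, lead-region classification
(>= 5 rhyQTLs, eQTL exclusivity), and the Bonferroni threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import IntervalSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a = in both, b = row only, c = column only, d = neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero contingency table")


def odds_ratio(t: ContingencyTable, alternative: str = "two-sided") -> tuple[float, float]:
    """OR = (a*d)/(b*c) with Fisher's exact p; b*c = 0 with a*d > 0 gives +inf."""
    num = t.a * t.d
    den = t.b * t.c
    if den == 0:
        orr = float("inf") if num > 0 else (0.0 if t.a == 0 else float("nan"))
    else:
        orr = num / den
    _, p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative=alternative)
    return float(orr), float(p)


# ---------------------------------------------------------------------------
# MAF-matched background sampling and baseline enrichment
# ---------------------------------------------------------------------------

MAF_BIN_EDGES = np.round(np.linspace(0.01, 0.50, 50), 10)  # 49 bins of width 0.01


def _maf_bins(mafs: np.ndarray) -> np.ndarray:
    bins = np.digitize(mafs, MAF_BIN_EDGES[1:-1], right=False)
    return bins  # 0..48


def maf_matched_sample(
    target_mafs,
    pool_ids,
    pool_mafs,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a pool subset whose per-bin MAF histogram equals the target's.

    Bins are 49 intervals of width 0.01 over [0.01, 0.50]. Sampling is without
    replacement within each bin; a bin with too few pool SNPs raises an error
    naming the bin.
    """
    target_mafs = np.asarray(target_mafs, dtype=float)
    pool_ids = np.asarray(pool_ids)
    pool_mafs = np.asarray(pool_mafs, dtype=float)
    tbin = _maf_bins(target_mafs)
    pbin = _maf_bins(pool_mafs)
    chosen = []
    for b in np.unique(tbin):
        need = int((tbin == b).sum())
        candidates = pool_ids[pbin == b]
        if len(candidates) < need:
            lo, hi = MAF_BIN_EDGES[b], MAF_BIN_EDGES[b + 1]
            raise ValueError(
                f"MAF bin [{lo:.2f}, {hi:.2f}) has only {len(candidates)} pool "
                f"SNPs but needs {need}"
            )
        chosen.append(rng.choice(candidates, size=need, replace=False))
    return np.concatenate(chosen) if chosen else np.array([], dtype=pool_ids.dtype)


@dataclass
class BaselineEnrichment:
    """Baseline-normalized enrichment of a QTL set in an annotation category."""

    e_obs: int
    b_obs: int
    n_iterations: int
    per_iteration: list[float] = field(default_factory=list)
    n_excluded: int = 0

    @property
    def median(self) -> float:
        if not self.per_iteration:
            return float("nan")
        return float(np.median(self.per_iteration))


def baseline_enrichment(
    snps: pd.DataFrame,
    is_qtl,
    category: IntervalSet,
    baseline: IntervalSet,
    n_iter: int = 30,
    seed: int = 0,
    exclude_qtls_from_pool: bool = True,
) -> BaselineEnrichment:
    """Enrichment = (EObs/EExp)/(BObs/BExp), medianed over MAF-matched draws.

    ``snps`` needs columns snp_id, chrom, pos, maf; ``is_qtl`` flags the QTL
    subset. Expected sets are number-matched MAF-matched draws from the SNPs
    inside the baseline regions (matching the formula's baseline denominators);
    by default the observed QTLs are excluded from that pool, so a genuinely
    enriched QTL set cannot dilute its own background. Iterations with a zero
    denominator are excluded and counted.
    """
    is_qtl = np.asarray(is_qtl, dtype=bool)
    if len(is_qtl) != len(snps):
        raise ValueError("is_qtl length does not match snps")
    in_cat = category.contains_points(snps["chrom"], snps["pos"])
    in_base = baseline.contains_points(snps["chrom"], snps["pos"])
    qtl_in_base = is_qtl & in_base
    e_obs = int((is_qtl & in_cat).sum())
    b_obs = int(qtl_in_base.sum())
    in_pool = in_base & ~is_qtl if exclude_qtls_from_pool else in_base
    pool = snps[in_pool]
    pool_in_cat = in_cat[in_pool]
    target_mafs = snps.loc[qtl_in_base, "maf"].to_numpy()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x51E5]))
    values: list[float] = []
    n_excluded = 0
    pool_pos = np.arange(len(pool))
    pool_mafs = pool["maf"].to_numpy()
    for _ in range(n_iter):
        draw = maf_matched_sample(target_mafs, pool_pos, pool_mafs, rng)
        e_exp = int(pool_in_cat[draw].sum())
        b_exp = len(draw)
        if e_exp == 0 or b_obs == 0 or b_exp == 0:
            n_excluded += 1
            continue
        values.append((e_obs / e_exp) / (b_obs / b_exp))
    if n_excluded:
        logger.warning("%d/%d enrichment iterations excluded (zero denominator)",
                       n_excluded, n_iter)
    return BaselineEnrichment(e_obs=e_obs, b_obs=b_obs, n_iterations=n_iter,
                              per_iteration=values, n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# motif enrichment
# ---------------------------------------------------------------------------

def motif_enrichment(qtl_flags, motif_hits: pd.DataFrame) -> pd.DataFrame:
    """Per-motif 2x2 odds ratio of QTL membership vs motif overlap.

    ``qtl_flags`` is a boolean Series indexed by snp_id over the SNP universe;
    ``motif_hits`` has columns (snp_id, motif_id) listing precomputed motif
    overlaps. Motifs with zero hits in the universe are reported with NaN.
    """
    qtl_flags = pd.Series(qtl_flags)
    universe = qtl_flags.index
    n_qtl = int(qtl_flags.sum())
    n_all = len(universe)
    rows = []
    for motif, grp in motif_hits.groupby("motif_id"):
        in_motif = pd.Index(grp["snp_id"].unique()).intersection(universe)
        m = len(in_motif)
        if m == 0:
            rows.append({"motif_id": motif, "a": 0, "b": n_qtl, "c": 0,
                         "d": n_all - n_qtl, "odds_ratio": np.nan, "fisher_p": np.nan})
            continue
        a = int(qtl_flags.loc[in_motif].sum())
        b = n_qtl - a
        c = m - a
        d = n_all - n_qtl - c
        orr, p = odds_ratio(ContingencyTable(a, b, c, d))
        rows.append({"motif_id": motif, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": orr, "fisher_p": p})
    return pd.DataFrame(rows).set_index("motif_id")


# ---------------------------------------------------------------------------
# GWAS-side helpers
# ---------------------------------------------------------------------------

HLA_REGION = ("chr6", 29_723_339, 33_087_199)  # hg38


def filter_gwas_catalog(
    associations: pd.DataFrame,
    p_max: float = 5e-8,
    hla: tuple[str, int, int] = HLA_REGION,
    european_only: bool = True,
) -> pd.DataFrame:
    """Drop insignificant, non-European and HLA-locus associations.

    Expects columns (snp_id, chrom, pos, trait, category, p, ancestry).
    Per-filter removal counts are logged.
    """
    df = associations
    keep = df["p"] <= p_max
    n_p = int((~keep).sum())
    if european_only:
        eur = df["ancestry"].str.lower().eq("european")
        n_anc = int((keep & ~eur).sum())
        keep &= eur
    else:
        n_anc = 0
    chrom, start, end = hla
    in_hla = (df["chrom"] == chrom) & (df["pos"] >= start) & (df["pos"] <= end)
    n_hla = int((keep & in_hla).sum())
    keep &= ~in_hla
    logger.info("GWAS filter removed: %d insignificant, %d non-European, %d HLA",
                n_p, n_anc, n_hla)
    return df[keep].reset_index(drop=True)


def ld_extend(tag_snps, ld_pairs: pd.DataFrame, r2_tol: float = 1e-9) -> set:
    """Extend a tag-SNP set with partners in perfect LD (r^2 = 1), symmetrically."""
    tags = set(tag_snps)
    out = set(tags)
    if len(ld_pairs) == 0:
        return out
    r2 = ld_pairs["r2"].to_numpy(dtype=float)
    perfect = ld_pairs[np.abs(r2 - 1.0) <= r2_tol]
    for s1, s2 in zip(perfect["snp1"], perfect["snp2"]):
        if s1 in tags:
            out.add(s2)
        if s2 in tags:
            out.add(s1)
    return out


def clump_lead_snps(
    gwas_stats: pd.DataFrame,
    p_max: float = 5e-8,
    window_bp: int = 1_000_000,
    ld_pairs: pd.DataFrame | None = None,
    r2_max: float = 0.001,
) -> pd.DataFrame:
    """Greedy lead-SNP clumping: most significant independent SNP per signal.

    Significant SNPs are visited in ascending p (ties by chrom, pos); a SNP
    becomes a lead unless it lies within ``window_bp`` of an accepted lead on
    the same chromosome, or (when an LD table is supplied) is in LD r^2 >
    ``r2_max`` with one. The result is independent of input row order.
    """
    df = gwas_stats[gwas_stats["p"] <= p_max]
    df = df.sort_values(["p", "chrom", "pos"], kind="mergesort").reset_index(drop=True)
    ld: dict[tuple, float] = {}
    if ld_pairs is not None:
        for s1, s2, r2 in zip(ld_pairs["snp1"], ld_pairs["snp2"], ld_pairs["r2"]):
            ld[(s1, s2)] = float(r2)
            ld[(s2, s1)] = float(r2)
    leads: list[dict] = []
    for row in df.itertuples(index=False):
        clumped = False
        for lead in leads:
            if ld and ld.get((row.snp_id, lead["snp_id"]), 0.0) > r2_max:
                clumped = True
                break
            if lead["chrom"] == row.chrom and abs(lead["pos"] - row.pos) <= window_bp:
                clumped = True
                break
        if not clumped:
            leads.append({"snp_id": row.snp_id, "chrom": row.chrom,
                          "pos": int(row.pos), "p": float(row.p)})
    return pd.DataFrame(leads, columns=["snp_id", "chrom", "pos", "p"])


def classify_lead_region(
    lead: tuple[str, int],
    rhyqtls: pd.DataFrame,
    eqtls: pd.DataFrame,
    window: int = 1_000_000,
    min_rhy: int = 5,
) -> dict:
    """Count rhyQTLs/eQTLs within +/- window of a lead SNP and classify the region.

    ``rhy_contributed`` is true with >= ``min_rhy`` rhyQTLs in the region;
    ``rhy_exclusive`` additionally requires zero eQTLs there.
    """
    chrom, pos = lead

    def _count(df: pd.DataFrame) -> int:
        if len(df) == 0:
            return 0
        hit = (df["chrom"] == chrom) & (np.abs(df["pos"] - pos) <= window)
        return int(hit.sum())

    rhy_count = _count(rhyqtls)
    eqtl_count = _count(eqtls)
    contributed = rhy_count >= min_rhy
    return {
        "rhy_count": rhy_count,
        "eqtl_count": eqtl_count,
        "rhy_contributed": contributed,
        "rhy_exclusive": contributed and eqtl_count == 0,
    }


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def truncate_2sig(value: float) -> float:
    """Truncate (round toward zero) to two significant figures, for reporting."""
    if value == 0:
        return 0.0
    exp = int(np.floor(np.log10(abs(value))))
    scale = 10.0 ** (exp - 1)
    return float(np.trunc(value / scale) * scale)
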