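"""Readers and writers for the external file formats, with explicit coordinate conventions.

Conventions
-----------
* VCF and TSS annotation positions are 1-based.
* BED intervals are 0-based, half-open.
* All internal point logic is 1-based: a 1-based point ``p`` falls in a BED
  interval ``[s, e)`` iff ``s < p <= e``.
* Genotypes are alternate-allele dosages in ``{0, 1, 2}``; missing dosages are
  stored as ``NaN`` and excluded per-SNP downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

_AUTOSOMES = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}


class ParseError(ValueError):
    """A file failed to parse; the message names the offending location."""


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosage matrix (SNPs x individuals).

    ``dosages`` holds the count of alternate alleles per individual
    (0, 1 or 2); missing genotypes are ``NaN``.
    """

    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray  # 1-based
    ref: np.ndarray
    alt: np.ndarray
    dosages: np.ndarray  # float (n_snps, n_samples); NaN = missing
    samples: pd.Index
    n_skipped_multiallelic: int = 0

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.samples = pd.Index(self.samples)
        if self.dosages.shape != (len(self.snp_ids), len(self.samples)):
            raise ValueError("dosage matrix shape does not match snp/sample counts")
        if np.any(self.pos < 1):
            raise ValueError("positions must be 1-based (>= 1)")
        ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be in {0, 1, 2} or missing (NaN)")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            self.snp_ids[mask], self.chrom[mask], self.pos[mask],
            self.ref[mask], self.alt[mask], self.dosages[mask],
            self.samples, self.n_skipped_multiallelic,
        )

    def subset_samples(self, samples) -> "GenotypeMatrix":
        idx = self.samples.get_indexer(pd.Index(samples))
        if (idx < 0).any():
            raise KeyError("requested samples absent from genotype matrix")
        return GenotypeMatrix(
            self.snp_ids, self.chrom, self.pos, self.ref, self.alt,
            self.dosages[:, idx], pd.Index(samples), self.n_skipped_multiallelic,
        )

    def is_autosomal(self) -> np.ndarray:
        return np.array([c in _AUTOSOMES for c in self.chrom])

    def snp_index(self, snp_id: str) -> int:
        hits = np.nonzero(self.snp_ids == snp_id)[0]
        if len(hits) == 0:
            raise KeyError(f"SNP {snp_id!r} not in matrix")
        return int(hits[0])


@dataclass
class ExpressionDataset:
    """Gene x sample log2 expression plus per-sample metadata.

    ``metadata`` must carry a ``time_h`` column (hours in [0, 24)); any other
    columns are treated as categorical covariates.
    """

    values: pd.DataFrame   # genes x samples
    metadata: pd.DataFrame  # samples x (time_h, covariates...)

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.metadata.index):
            raise ValueError("expression sample set differs from metadata sample set")
        if "time_h" not in self.metadata.columns:
            raise ParseError("metadata is missing required column 'time_h'")
        t = self.metadata["time_h"].to_numpy(dtype=float)
        if not np.all(np.isfinite(t)):
            raise ValueError("time_h must be finite")

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def times(self) -> np.ndarray:
        return self.metadata["time_h"].to_numpy(dtype=float)

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.metadata.columns if c != "time_h"]

    def subset_samples(self, samples) -> "ExpressionDataset":
        samples = pd.Index(samples)
        return ExpressionDataset(self.values[samples], self.metadata.loc[samples])


@dataclass
class GeneAnnotation:
    """One transcription start site per gene."""

    table: pd.DataFrame  # columns: gene_id, chrom, tss, strand; index = gene_id

    def __post_init__(self) -> None:
        req = {"gene_id", "chrom", "tss", "strand"}
        missing = req - set(self.table.columns)
        if missing:
            raise ParseError(f"annotation is missing columns {sorted(missing)}")
        if self.table["gene_id"].duplicated().any():
            dupes = self.table.loc[self.table["gene_id"].duplicated(), "gene_id"]
            raise ValueError(f"multiple TSS records for gene(s) {list(dupes)[:3]}")
        bad = ~self.table["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError("strand must be '+' or '-'")
        if (self.table["tss"] < 1).any():
            raise ValueError("TSS positions are 1-based (>= 1)")
        self.table = self.table.set_index("gene_id", drop=False)

    @property
    def genes(self) -> pd.Index:
        return self.table.index


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

_GT_DOSAGE = {(0, 0): 0.0, (0, 1): 1.0, (1, 0): 1.0, (1, 1): 2.0}


def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from VCF (GT field) or the package's TSV dialect.

    Multiallelic VCF records are skipped with a warning; the skipped count is
    retained on the returned matrix. Missing genotypes (``./.``) stay missing.
    """
    path = str(path)
    if fmt is None:
        fmt = "vcf" if path.endswith((".vcf", ".vcf.gz")) else "tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tsv":
        return _read_genotype_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path: str) -> GenotypeMatrix:
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise ParseError(f"malformed VCF header in {path}: {exc}") from exc
    samples = pd.Index(list(vf.header.samples))
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    n_skipped = 0
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            n_skipped += 1
            continue
        row = np.full(len(samples), np.nan)
        for j, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            row[j] = float(sum(1 for a in gt if a == 1))
        ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
        chroms.append(rec.chrom)
        poss.append(rec.pos)
        refs.append(rec.ref)
        alts.append(rec.alts[0])
        rows.append(row)
    if n_skipped:
        logger.warning("skipped %d multiallelic record(s) in %s", n_skipped, path)
    dosages = np.vstack(rows) if rows else np.empty((0, len(samples)))
    return GenotypeMatrix(
        np.array(ids, dtype=object), np.array(chroms, dtype=object),
        np.array(poss, dtype=np.int64), np.array(refs, dtype=object),
        np.array(alts, dtype=object), dosages, samples, n_skipped,
    )


def _read_genotype_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    req = ["snp_id", "chrom", "pos", "ref", "alt"]
    missing = [c for c in req if c not in df.columns]
    if missing:
        raise ParseError(f"genotype TSV {path} missing columns {missing}")
    sample_cols = [c for c in df.columns if c not in req]
    dosages = df[sample_cols].to_numpy(dtype=float)
    return GenotypeMatrix(
        df["snp_id"].to_numpy(dtype=object), df["chrom"].to_numpy(dtype=object),
        df["pos"].to_numpy(), df["ref"].to_numpy(dtype=object),
        df["alt"].to_numpy(dtype=object), dosages, pd.Index(sample_cols),
    )


def write_genotypes_tsv(gm: GenotypeMatrix, path) -> None:
    df = pd.DataFrame({
        "snp_id": gm.snp_ids, "chrom": gm.chrom, "pos": gm.pos,
        "ref": gm.ref, "alt": gm.alt,
    })
    for j, s in enumerate(gm.samples):
        df[s] = gm.dosages[:, j]
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_genotypes_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 with GT only; heterozygotes are written 0/1."""
    chrom_order = list(dict.fromkeys(gm.chrom))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chrom_order:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, gm.samples)) + "\n")
        gt_str = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        order = np.lexsort((gm.pos, np.array([chrom_order.index(c) for c in gm.chrom])))
        for i in order:
            gts = "\t".join(
                "./." if np.isnan(d) else gt_str[d] for d in gm.dosages[i]
            )
            fh.write(f"{gm.chrom[i]}\t{gm.pos[i]}\t{gm.snp_ids[i]}\t{gm.ref[i]}\t"
                     f"{gm.alt[i]}\t.\t.\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def read_expression(expr_path, metadata_path) -> ExpressionDataset:
    """Read gene x sample expression and sample metadata; restrict to shared samples.

    ``time_h`` is normalized modulo 24. Raises on an empty sample intersection
    or a non-numeric expression cell (named by gene and sample).
    """
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    if "time_h" not in meta.columns:
        raise ParseError(f"metadata {metadata_path} is missing required column 'time_h'")
    for col in expr.columns:
        coerced = pd.to_numeric(expr[col], errors="coerce")
        bad = coerced.isna() & expr[col].notna()
        if bad.any():
            gene = expr.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"non-numeric expression value for gene {gene!r}, sample {col!r}"
            )
        expr[col] = coerced
    shared = expr.columns.intersection(meta.index)
    if len(shared) == 0:
        raise ValueError("no samples shared between expression and metadata")
    logger.info("expression/metadata sample intersection: %d samples", len(shared))
    meta = meta.loc[shared].copy()
    meta["time_h"] = meta["time_h"].astype(float) % 24.0
    expr = expr[shared].astype(float)
    expr.index.name = meta.index.name = None  # axis labels are file furniture
    return ExpressionDataset(expr, meta)


def write_expression(ds: ExpressionDataset, expr_path, metadata_path) -> None:
    ds.values.rename_axis("gene_id").to_csv(expr_path, sep="\t")
    ds.metadata.rename_axis("sample_id").to_csv(metadata_path, sep="\t")


def read_annotation(path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return GeneAnnotation(df)


def write_annotation(ann: GeneAnnotation, path) -> None:
    ann.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# intervals (BED3)
# ---------------------------------------------------------------------------

@dataclass
class IntervalSet:
    """Per-chromosome merged intervals, 0-based half-open."""

    trees: dict = field(default_factory=dict)  # chrom -> IntervalTree

    def contains_point(self, chrom: str, pos_1based: int) -> bool:
        """1-based point p is inside BED [s, e) iff s < p <= e, i.e. p-1 in [s, e)."""
        tree = self.trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos_1based - 1))

    def contains_points(self, chroms, positions) -> np.ndarray:
        return np.array([
            self.contains_point(c, int(p)) for c, p in zip(chroms, positions)
        ])

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self.trees):
            for iv in sorted(self.trees[chrom]):
                out.append((chrom, iv.begin, iv.end))
        return out

    def __len__(self) -> int:
        return sum(len(t) for t in self.trees.values())

    @classmethod
    def from_tuples(cls, tuples) -> "IntervalSet":
        trees: dict[str, IntervalTree] = {}
        for chrom, start, end in tuples:
            if start >= end:
                raise ParseError(f"interval start >= end: {chrom} {start} {end}")
            trees.setdefault(chrom, IntervalTree()).addi(int(start), int(end))
        for tree in trees.values():
            tree.merge_overlaps(strict=False)
        return cls(trees)


def read_intervals(path) -> IntervalSet:
    """Read a BED3 file; overlapping/adjacent intervals are merged per chromosome."""
    tuples = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            tuples.append((parts[0], start, end))
    return IntervalSet.from_tuples(tuples)


def write_intervals(ivs: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in ivs.intervals():
            fh.write(f"{chrom}\t{start}\t{end}\n")
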