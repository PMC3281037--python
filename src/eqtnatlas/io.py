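"""Reading and writing the pipeline's on-disk formats.

Gene models are BED12 (or minimal GFF-like exon tables), genotypes are
minimal VCF (GT fields) or dosage TSV, expression is a values TSV plus a
feature-metadata TSV. All coordinates are serialized 0-based half-open
(GFF input is converted on read). Every TSV written here carries a
leading ``#`` header line naming the producing stage and its parameters.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .models import ExpressionMatrix, GeneModel, GenotypeMatrix

__all__ = [
    "write_tsv",
    "read_tsv",
    "write_gene_models",
    "read_gene_models",
    "write_genotypes_vcf",
    "write_genotypes_tsv",
    "read_genotypes",
    "write_expression",
    "read_expression",
]

logger = logging.getLogger(__name__)


def write_tsv(df: pd.DataFrame, path: str | Path, stage: str, index: bool = True,
              **params: object) -> None:
    """Write a TSV with a '# stage=... key=value ...' provenance header."""
    path = Path(path)
    meta = " ".join(f"{k}={v}" for k, v in params.items())
    with open(path, "w") as fh:
        fh.write(f"# stage={stage}" + (f" {meta}" if meta else "") + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as BED12 (blocks in ascending genomic order)."""
    with open(Path(path), "w") as fh:
        for g in genes:
            blocks = sorted(g.exons)
            sizes = ",".join(str(e - s) for s, e in blocks)
            starts = ",".join(str(s - g.span_start) for s, _ in blocks)
            fh.write(
                "\t".join(
                    [
                        g.chrom, str(g.span_start), str(g.span_end), g.gene_id,
                        "0", g.strand, str(g.span_start), str(g.span_end),
                        "0", str(len(blocks)), sizes + ",", starts + ",",
                    ]
                )
                + "\n"
            )


def _bed12_record(fields: list[str], lineno: int) -> GeneModel:
    if len(fields) < 12:
        raise ValueError(f"line {lineno}: BED12 needs 12 fields, got {len(fields)}")
    chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
    strand = fields[5]
    n_blocks = int(fields[9])
    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
    offs = [int(x) for x in fields[11].rstrip(",").split(",")]
    if len(sizes) != n_blocks or len(offs) != n_blocks:
        raise ValueError(f"line {lineno}: blockCount does not match block lists")
    blocks = [(start + o, start + o + s) for o, s in zip(offs, sizes)]
    if blocks[-1][1] > end or blocks[0][0] != start:
        raise ValueError(f"line {lineno}: blocks exceed the record span")
    exons = tuple(blocks) if strand == "+" else tuple(blocks[::-1])
    try:
        return GeneModel(gene_id=name, chrom=chrom, strand=strand, exons=exons)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: {exc}") from exc


def read_gene_models(path: str | Path, format: str = "bed12") -> list[GeneModel]:
    """Read gene models from BED12 or a minimal GFF-like exon table.

    GFF-like input uses 1-based inclusive coordinates (converted to 0-based
    half-open on read); exon rows are grouped by a ``gene_id "..."`` or
    ``gene_id=...`` attribute. Records with overlapping exons are rejected
    with their line number.
    """
    path = Path(path)
    if format == "bed12":
        genes = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                genes.append(_bed12_record(line.split("\t"), lineno))
        return genes
    if format in ("gff", "gff-like", "gff3", "gtf"):
        per_gene: dict[str, dict] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 9:
                    raise ValueError(f"line {lineno}: GFF needs 9 fields")
                if fields[2].lower() != "exon":
                    continue
                chrom, start, end, strand, attrs = (
                    fields[0], int(fields[3]) - 1, int(fields[4]), fields[6], fields[8]
                )
                gid = None
                for token in attrs.replace(";", " ").split():
                    if token.startswith("gene_id="):
                        gid = token.split("=", 1)[1].strip('"')
                if gid is None and "gene_id" in attrs:
                    parts = attrs.split("gene_id")[1].strip().strip(";").strip()
                    gid = parts.strip('"').split('"')[0].strip()
                if gid is None:
                    raise ValueError(f"line {lineno}: no gene_id attribute")
                rec = per_gene.setdefault(
                    gid, {"chrom": chrom, "strand": strand, "exons": [], "line": lineno}
                )
                rec["exons"].append((start, end))
        genes = []
        for gid, rec in per_gene.items():
            blocks = sorted(rec["exons"])
            exons = tuple(blocks) if rec["strand"] == "+" else tuple(blocks[::-1])
            try:
                genes.append(GeneModel(gene_id=gid, chrom=rec["chrom"],
                                       strand=rec["strand"], exons=exons))
            except ValueError as exc:
                raise ValueError(f"gene {gid} (near line {rec['line']}): {exc}") from exc
        return genes
    raise ValueError(f"unknown gene model format {format!r}")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

_GT_OF_DOSE = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_genotypes_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as a minimal uncompressed VCF with GT fields."""
    with open(Path(path), "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(genotypes.chroms):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples) + "\n"
        )
        for i in range(genotypes.n_snps):
            gts = "\t".join(_GT_OF_DOSE[int(d)] for d in genotypes.dosages[i])
            fh.write(
                f"{genotypes.chroms[i]}\t{genotypes.positions[i] + 1}\t"
                f"{genotypes.snp_ids[i]}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_genotypes_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        genotypes.dosages,
        index=pd.Index(genotypes.snp_ids, name="snp_id"),
        columns=genotypes.samples,
    )
    df.insert(0, "chrom", genotypes.chroms)
    df.insert(1, "pos", genotypes.positions)
    write_tsv(df, path, stage="genotypes", n_snps=genotypes.n_snps)


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read a GenotypeMatrix from VCF (via cyvcf2) or dosage TSV.

    Biallelic records only (multi-allelic rows are skipped and counted);
    missing genotypes are mean-imputed per SNP (rounded back onto {0,1,2})
    with a log report; all-missing SNPs are dropped; the 1% MAF floor is
    applied.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix == ".vcf" or path.name.endswith(".vcf.gz") else "tsv"
    if format == "tsv":
        df = read_tsv(path)
        chroms = df["chrom"].to_numpy()
        pos = df["pos"].to_numpy(np.int64)
        dosages = df.drop(columns=["chrom", "pos"]).to_numpy(float)
        samples = [c for c in df.columns if c not in ("chrom", "pos")]
        return _finalize_genotypes(df.index.to_numpy(), chroms, pos, dosages, samples)
    if format != "vcf":
        raise ValueError(f"unknown genotype format {format!r}")
    from cyvcf2 import VCF

    reader = VCF(str(path), gts012=True)
    samples = list(reader.samples)
    ids, chroms, pos, rows = [], [], [], []
    n_multi = 0
    for v in reader:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        ids.append(v.ID if v.ID else f"{v.CHROM}:{v.POS}")
        chroms.append(v.CHROM)
        pos.append(v.start)
        gt = v.gt_types.astype(float)
        gt[gt == 3] = np.nan  # UNKNOWN
        rows.append(gt)
    if n_multi:
        logger.info("skipped %d multi-allelic records", n_multi)
    return _finalize_genotypes(
        np.asarray(ids, dtype=object), np.asarray(chroms, dtype=object),
        np.asarray(pos, dtype=np.int64), np.asarray(rows, dtype=float), samples
    )


def _finalize_genotypes(ids, chroms, pos, dosages, samples) -> GenotypeMatrix:
    n_missing = int(np.isnan(dosages).sum())
    all_missing = np.isnan(dosages).all(axis=1)
    if all_missing.any():
        warnings.warn(f"dropping {int(all_missing.sum())} all-missing SNPs")
        keep = ~all_missing
        ids, chroms, pos, dosages = ids[keep], chroms[keep], pos[keep], dosages[keep]
    if n_missing:
        logger.info("mean-imputing %d missing genotype calls", n_missing)
        means = np.nanmean(dosages, axis=1)
        nan_r, nan_c = np.nonzero(np.isnan(dosages))
        dosages[nan_r, nan_c] = means[nan_r]
    dosages = np.clip(np.rint(dosages), 0, 2).astype(np.int8)
    return GenotypeMatrix(ids, chroms, pos, dosages, samples)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def write_expression(expr: ExpressionMatrix, prefix: str | Path, stage: str,
                     **params: object) -> None:
    """Write values, feature metadata and sample metadata TSVs under a prefix."""
    prefix = Path(prefix)
    write_tsv(expr.values, prefix.with_suffix(".values.tsv"), stage=stage, **params)
    write_tsv(expr.features, prefix.with_suffix(".features.tsv"), stage=stage)
    write_tsv(expr.samples, prefix.with_suffix(".samples.tsv"), stage=stage)


def read_expression(prefix: str | Path) -> ExpressionMatrix:
    prefix = Path(prefix)
    values = read_tsv(prefix.with_suffix(".values.tsv"))
    features = read_tsv(prefix.with_suffix(".features.tsv"))
    samples = read_tsv(prefix.with_suffix(".samples.tsv"))
    return ExpressionMatrix(values, features, samples)
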