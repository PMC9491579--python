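"""Readers and writers for the pipeline's on-disk formats.

VCF (v4.2, haploid GT for inbred lines; homozygous diploid calls are
collapsed to 0/1), TSV genotype matrices, BED feature annotations (0-based
half-open), allc-style per-cytosine call tables (chrom, 1-based pos,
strand, context, mc, total), phenotype/metadata TSV, plain-text gene lists,
and YAML pipeline configs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import GenotypeMatrix, KinshipMatrix
from .methylation import FeatureAnnotation

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_genotype_tsv",
    "read_genotype_tsv",
    "write_bed",
    "read_bed",
    "write_allc",
    "read_allc",
    "read_phenotypes",
    "read_gene_list",
    "write_config",
    "read_config",
    "write_kinship_tsv",
    "read_kinship_tsv",
]


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write genotypes as a minimal VCF with haploid GT calls."""
    path = Path(path)
    chroms = pd.unique(geno.chrom)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=methgwas\n")
        for c in chroms:
            last = int(geno.pos[geno.chrom == c].max())
            fh.write(f"##contig=<ID={c},length={last + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, geno.line_ids)) + "\n")
        V = geno.values
        for j in range(geno.n_snps):
            calls = [
                "." if not np.isfinite(v) else str(int(v)) for v in V[:, j]
            ]
            fh.write(
                f"{geno.chrom[j]}\t{geno.pos[j]}\tsnp{j}\tA\tT\t.\tPASS\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF of biallelic SNPs into a 0/1 genotype matrix (via pysam).

    Haploid GT ("0"/"1") and homozygous diploid GT ("0/0", "1|1") are
    collapsed to 0/1; missing and heterozygous calls become NaN.
    """
    import pysam

    chroms, poss, rows = [], [], []
    with pysam.VariantFile(str(path)) as vf:
        line_ids = list(vf.header.samples)
        for rec in vf:
            chroms.append(rec.chrom)
            poss.append(rec.pos)
            row = []
            for sample in line_ids:
                alleles = {a for a in rec.samples[sample]["GT"] if a is not None}
                row.append(float(alleles.pop()) if len(alleles) == 1 else np.nan)
            rows.append(row)
    values = np.asarray(rows, dtype=float).T  # lines x snps
    return GenotypeMatrix(
        values=values, chrom=np.asarray(chroms), pos=np.asarray(poss), line_ids=line_ids
    )


def write_genotype_tsv(geno: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(geno.values.T, columns=geno.line_ids)
    df.insert(0, "pos", geno.pos)
    df.insert(0, "chrom", geno.chrom)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    line_ids = [c for c in df.columns if c not in ("chrom", "pos")]
    return GenotypeMatrix(
        values=df[line_ids].to_numpy(dtype=float).T,
        chrom=df["chrom"].to_numpy(),
        pos=df["pos"].to_numpy(),
        line_ids=line_ids,
    )


def write_bed(features, path) -> None:
    """BED with columns chrom, start, end, id, kind (0-based half-open)."""
    with Path(path).open("w") as fh:
        for f in features:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.id}\t{f.kind}\n")


def read_bed(path) -> list:
    feats = []
    with Path(path).open() as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            kind = parts[4] if len(parts) > 4 else "TE"
            name = parts[3] if len(parts) > 3 else f"feat{i}"
            feats.append(FeatureAnnotation(name, parts[0], int(parts[1]), int(parts[2]), kind))
    return feats


ALLC_COLUMNS = ["chrom", "pos", "strand", "context", "mc", "total"]


def write_allc(calls: pd.DataFrame, path) -> None:
    calls[ALLC_COLUMNS].to_csv(path, sep="\t", index=False, header=False)


def read_allc(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=ALLC_COLUMNS)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gene_list(path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_config(config: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))


def read_config(path) -> dict:
    out = yaml.safe_load(Path(path).read_text())
    return {} if out is None else out


def write_kinship_tsv(K: KinshipMatrix, path) -> None:
    pd.DataFrame(K.values, index=K.line_ids, columns=K.line_ids).to_csv(path, sep="\t")


def read_kinship_tsv(path) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return KinshipMatrix(values=df.to_numpy(dtype=float), line_ids=list(df.columns))
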