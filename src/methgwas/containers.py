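"""Core in-memory containers shared across the pipeline.

Genotypes are haploid-equivalent {0,1} calls for inbred (selfing) lines,
stored as a dense float matrix with NaN for missing entries.  Phenotypes and
line metadata travel as plain :class:`pandas.DataFrame` objects indexed by
line id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "KinshipMatrix"]


@dataclass
class GenotypeMatrix:
    """Biallelic 0/1 genotypes for inbred lines.

    Parameters
    ----------
    values
        ``(n_lines, n_snps)`` array of 0/1 calls; ``NaN`` marks missing.
    chrom, pos
        Per-SNP chromosome name and 1-based position.
    line_ids
        Line identifiers, one per row.
    clusters
        Optional ancestry-cluster label per line (simulation metadata).
    """

    values: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    line_ids: list = field(default_factory=list)
    clusters: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D matrix")
        n_lines, n_snps = self.values.shape
        if len(self.chrom) != n_snps or len(self.pos) != n_snps:
            raise ValueError("snp metadata length does not match n_snps")
        if not self.line_ids:
            self.line_ids = [f"line{i:04d}" for i in range(n_lines)]
        if len(self.line_ids) != n_lines:
            raise ValueError("line_ids length does not match n_lines")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and not np.isin(finite, (0.0, 1.0)).all():
            raise ValueError("genotypes must be 0/1 (NaN for missing)")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-SNP (MAC, MAF) over non-missing entries.

        MAC is ``min(#0, #1)``; MAF is MAC over the non-missing count.
        Monomorphic SNPs get MAC = MAF = 0.
        """
        ok = np.isfinite(self.values)
        n_ok = ok.sum(axis=0)
        ones = np.nansum(self.values, axis=0)
        zeros = n_ok - ones
        mac = np.minimum(ones, zeros)
        with np.errstate(invalid="ignore", divide="ignore"):
            maf = np.where(n_ok > 0, mac / n_ok, 0.0)
        return mac.astype(int), maf

    def snp_table(self) -> pd.DataFrame:
        mac, maf = self.allele_counts()
        return pd.DataFrame(
            {"chrom": self.chrom, "pos": self.pos, "mac": mac, "maf": maf}
        )

    def subset_lines(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            values=self.values[index],
            chrom=self.chrom,
            pos=self.pos,
            line_ids=[self.line_ids[i] for i in np.atleast_1d(index)],
            clusters=None if self.clusters is None else self.clusters[index],
        )


@dataclass
class KinshipMatrix:
    """Identity-by-state kinship: fraction of shared genotypes per line pair."""

    values: np.ndarray
    line_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("kinship must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kinship must be symmetric")
        if not self.line_ids:
            self.line_ids = [f"line{i:04d}" for i in range(n)]

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]
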