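"""Cumulative-allele modelling and frequency-matched permutation tests.

Given the handful of major loci found by the conditional scan, this module
orients each locus ("which allele lowers the phenotype"), counts
phenotype-decreasing alleles per line, fits the additive model, computes
the variance they jointly explain (r^2), and runs permutation tests against
null sets of randomly chosen SNPs with the same allele frequencies: the
geographic-cline test, inter-locus LD with a partner locus, and the
epistatic effect on transposon insertion counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

__all__ = [
    "FocalAlleleSet",
    "PermutationSpec",
    "orient_alleles",
    "cumulative_counts",
    "additive_fit",
    "variance_explained_r2",
    "matched_snp_sample",
    "clinal_test",
    "ld_with_focal_test",
    "epistasis_insertion_test",
]


@dataclass
class FocalAlleleSet:
    """Major loci with the orientation of their phenotype-decreasing allele.

    ``decreasing_code[j]`` is the genotype code (0 or 1) whose carriers have
    the lower phenotype at ``snp_indices[j]``, taken from the sign of the
    fitted SNP effect.
    """

    snp_indices: np.ndarray
    decreasing_code: np.ndarray

    def __post_init__(self) -> None:
        self.snp_indices = np.asarray(self.snp_indices, dtype=int)
        self.decreasing_code = np.asarray(self.decreasing_code, dtype=int)
        if self.snp_indices.shape != self.decreasing_code.shape:
            raise ValueError("indices and orientations must align")


@dataclass
class PermutationSpec:
    """How to draw frequency-matched null SNP sets."""

    n_perm: int = 3000
    mode: str = "exact-mac"  # or "frequency-bin"
    bin_half_width: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.mode not in ("exact-mac", "frequency-bin"):
            raise ValueError("mode must be 'exact-mac' or 'frequency-bin'")


def orient_alleles(scan, snp_indices) -> FocalAlleleSet:
    """Orient loci from the sign of the fitted effect in a scan.

    The genotype code 1 is z-scored with a positive loading, so beta < 0
    means the alt (1) allele decreases the phenotype; beta > 0 means the
    ref (0) allele does.  beta = 0 exactly cannot be oriented.
    """
    st = scan.table if hasattr(scan, "table") else scan
    st = st.set_index("snp_index")
    codes = []
    for j in snp_indices:
        if j not in st.index:
            raise KeyError(f"SNP index {j} was not tested in the scan")
        beta = float(st.loc[j, "beta"])
        if beta == 0.0:
            raise ValueError(f"SNP index {j}: beta is exactly 0, cannot orient")
        codes.append(1 if beta < 0 else 0)
    return FocalAlleleSet(snp_indices=np.asarray(snp_indices), decreasing_code=np.asarray(codes))


def cumulative_counts(geno: GenotypeMatrix, alleles: FocalAlleleSet) -> np.ndarray:
    """Per-line number of phenotype-decreasing alleles carried (0..k).

    Lines with a missing genotype at any focal SNP get NaN (dropped by the
    downstream tests).
    """
    G = geno.values[:, alleles.snp_indices]
    carried = np.where(alleles.decreasing_code[None, :] == 1, G, 1.0 - G)
    return carried.sum(axis=1)  # NaN propagates for missing focal genotypes


def additive_fit(y, counts) -> dict:
    """OLS of phenotype on the cumulative allele count, plus class means."""
    y = np.asarray(y, dtype=float)
    counts = np.asarray(counts, dtype=float)
    ok = np.isfinite(y) & np.isfinite(counts)
    y, counts = y[ok], counts[ok]
    classes = np.unique(counts)
    if classes.size < 2:
        raise ValueError("need >= 2 distinct count classes")
    X = np.column_stack([np.ones_like(counts), counts])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    per_class = pd.DataFrame(
        {
            "count": classes.astype(int),
            "mean": [y[counts == c].mean() for c in classes],
            "n": [int((counts == c).sum()) for c in classes],
        }
    )
    return {"intercept": float(coef[0]), "slope": float(coef[1]), "class_means": per_class}


def variance_explained_r2(y, geno: GenotypeMatrix, snp_indices) -> float:
    """R^2 of the joint OLS fit of y on the focal SNP genotypes."""
    y = np.asarray(y, dtype=float)
    G = geno.values[:, np.asarray(snp_indices, dtype=int)]
    ok = np.isfinite(y) & np.all(np.isfinite(G), axis=1)
    y, G = y[ok], G[ok]
    # drop duplicated columns before checking collinearity
    _, keep = np.unique(G.T, axis=0, return_index=True)
    G = G[:, np.sort(keep)]
    k = G.shape[1]
    if y.size <= k + 1:
        raise ValueError("need n > number of SNPs + 1")
    X = np.column_stack([np.ones(y.size), G])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("focal SNPs are collinear")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float((resid**2).sum()) / tss


def matched_snp_sample(
    geno: GenotypeMatrix, focal: FocalAlleleSet, spec: PermutationSpec
) -> np.ndarray:
    """Null SNP sets matched to the focal loci by allele frequency.

    Returns an ``(n_perm, k)`` array of SNP indices: per replicate, one
    random SNP per focal locus with the same MAC (exact mode) or with MAF
    within ``bin_half_width`` (bin mode), never the focal SNP itself,
    sampled with replacement across replicates.
    """
    mac, maf = geno.allele_counts()
    rng = np.random.default_rng(spec.seed)
    out = np.empty((spec.n_perm, len(focal.snp_indices)), dtype=int)
    for col, j in enumerate(focal.snp_indices):
        if spec.mode == "exact-mac":
            cand = np.where(mac == mac[j])[0]
        else:
            cand = np.where(np.abs(maf - maf[j]) <= spec.bin_half_width)[0]
        cand = cand[cand != j]
        if cand.size == 0:
            raise ValueError(
                f"no frequency-matched SNP for focal index {j} "
                f"(MAC {mac[j]}); try mode='frequency-bin'"
            )
        out[:, col] = rng.choice(cand, size=spec.n_perm, replace=True)
    return out


def _oriented_counts(geno: GenotypeMatrix, snp_set, codes) -> np.ndarray:
    G = geno.values[:, np.asarray(snp_set, dtype=int)]
    carried = np.where(np.asarray(codes)[None, :] == 1, G, 1.0 - G)
    return carried.sum(axis=1)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def clinal_test(geno: GenotypeMatrix, focal: FocalAlleleSet, longitude, spec: PermutationSpec) -> dict:
    """Cline test: cumulative allele count vs longitude.

    Observed statistic is the Pearson correlation between the per-line
    count of decreasing alleles and longitude; the null distribution is the
    same statistic over frequency-matched random SNP sets (same orientation
    codes).  Two-sided p = (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1).
    """
    longitude = np.asarray(longitude, dtype=float)
    counts = cumulative_counts(geno, focal)
    ok = np.isfinite(counts) & np.isfinite(longitude)
    if longitude[ok].std() == 0:
        raise ValueError("longitude is constant")
    r_obs = _pearson(counts[ok], longitude[ok])
    sets = matched_snp_sample(geno, focal, spec)
    r_perm = np.array(
        [_pearson(_oriented_counts(geno, s, focal.decreasing_code)[ok], longitude[ok]) for s in sets]
    )
    p = (1.0 + np.sum(np.abs(r_perm) >= abs(r_obs))) / (spec.n_perm + 1.0)
    return {"r_obs": r_obs, "r_perm": r_perm, "p_value": float(p)}


def ld_with_focal_test(
    geno: GenotypeMatrix, focal: FocalAlleleSet, partner_snp: int, spec: PermutationSpec
) -> dict:
    """Inter-locus LD test: cumulative count vs the partner-locus genotype."""
    partner = geno.values[:, int(partner_snp)]
    counts = cumulative_counts(geno, focal)
    ok = np.isfinite(counts) & np.isfinite(partner)
    if partner[ok].std() == 0:
        raise ValueError("partner locus is monomorphic")
    r_obs = _pearson(counts[ok], partner[ok])
    sets = matched_snp_sample(geno, focal, spec)
    r_perm = np.array(
        [_pearson(_oriented_counts(geno, s, focal.decreasing_code)[ok], partner[ok]) for s in sets]
    )
    p = (1.0 + np.sum(np.abs(r_perm) >= abs(r_obs))) / (spec.n_perm + 1.0)
    return {"r_obs": r_obs, "r_perm": r_perm, "p_value": float(p)}


def epistasis_insertion_test(
    insertions,
    geno: GenotypeMatrix,
    partner_snp: int,
    focal: FocalAlleleSet,
    spec: PermutationSpec,
    k_grid=range(0, 6),
    cumulative_classes: bool = False,
    partner_alt_code: int = 1,
) -> pd.DataFrame:
    """Epistasis on transposon mobilization, per allele-count class.

    For each k, the observed statistic is the mean insertion count among
    lines carrying the partner alt allele and exactly k (or >= k with
    ``cumulative_classes``) decreasing alleles.  The null replaces the
    partner locus by each of ``n_perm`` frequency-matched random SNPs
    (counts held fixed); one-sided p = (1 + #{perm >= obs}) / (n_perm + 1).
    Classes with no line are flagged with NaN, never zero-filled.
    """
    insertions = np.asarray(insertions, dtype=float)
    partner = geno.values[:, int(partner_snp)]
    if np.nanstd(partner) == 0:
        raise ValueError("partner locus is monomorphic")
    counts = cumulative_counts(geno, focal)
    ok = np.isfinite(insertions) & np.isfinite(counts) & np.isfinite(partner)

    partner_set = FocalAlleleSet(np.array([int(partner_snp)]), np.array([1]))
    perm_idx = matched_snp_sample(geno, partner_set, spec)[:, 0]
    P = geno.values[:, perm_idx]  # lines x n_perm

    rows = []
    for k in k_grid:
        in_class = (counts >= k) if cumulative_classes else (counts == k)
        sel_obs = ok & in_class & (partner == partner_alt_code)
        n_obs = int(sel_obs.sum())
        if n_obs == 0:
            rows.append({"k": int(k), "n": 0, "obs_mean": np.nan, "p_value": np.nan})
            continue
        obs = float(insertions[sel_obs].mean())
        base = ok & in_class
        carrier = P[base] == partner_alt_code  # lines-in-class x n_perm
        ins = insertions[base][:, None]
        n_perm_lines = carrier.sum(axis=0)
        with np.errstate(invalid="ignore"):
            perm_means = np.where(
                n_perm_lines > 0, (ins * carrier).sum(axis=0) / n_perm_lines, np.nan
            )
        valid = np.isfinite(perm_means)
        exceed = int(np.sum(perm_means[valid] >= obs))
        p = (1.0 + exceed) / (spec.n_perm + 1.0)
        rows.append({"k": int(k), "n": n_obs, "obs_mean": obs, "p_value": float(p)})
    return pd.DataFrame(rows)
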