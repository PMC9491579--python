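"""Synthetic study-population generator.

Emulates the statistical structure the downstream analyses assume:
structured inbred populations with a realistic minor-allele-frequency
spectrum (Balding-Nichols clusters), two strongly correlated quantitative
methylation-like traits built from shared + trait-specific planted QTLs +
kinship-structured polygenic background + noise, an ancestry-correlated
longitude cline, negative-binomial recent-transposon-insertion counts with
a planted genotype-by-genotype interaction, and per-cytosine methylation
calls for the phenotyping stage.

Every generator is deterministic under a fixed seed, and every planted
quantity is exported to a truth file so downstream recovery tests never
reach into generator internals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .methylation import FeatureAnnotation
from .utils import derive_rng

__all__ = [
    "SimulationConfig",
    "PhenotypeSimResult",
    "default_config",
    "clinal_config",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_insertion_counts",
    "simulate_methylation_calls",
    "simulate_annotations",
    "write_fixture_bundle",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study population.

    The defaults (see :func:`default_config`) encode the canonical two-trait
    architecture: an mCHH-like trait1 dominated by a shared factor that is
    mostly kinship-structured, and an mCHG-like trait2 that carries 0.9 of
    the same factor plus one trait-2-specific QTL explaining 10% of the
    conditional variance of trait2 given trait1, with trait correlation 0.8.
    """

    n_lines: int = 800
    n_snps: int = 10_000
    n_chromosomes: int = 5
    n_clusters: int = 10
    fst: float = 0.5
    maf_floor: float = 0.05
    # (snp_index, effect_on_trait1, effect_on_trait2) in SD units of the
    # z-scored genotype column
    qtl_spec: tuple = ()
    shared_factor_sd: float = 0.9  # loading of the shared factor on trait2
    # fraction of the (unit) shared-factor variance that is
    # kinship-structured (ancestry-confounded); the rest is line-level,
    # environment-like
    shared_structured_frac: float = 0.7
    h2_background_1: float = 0.0
    h2_background_2: float = 0.0
    noise_sd_1: float = 0.223607
    noise_sd_2: float = 0.593266
    cline_strength: float = 0.5
    insertion_baseline: float = 0.2
    insertion_interaction_log_ratio: float = float(np.log(30.0))
    insertion_dispersion: float = 1.0
    # per-SNP overrides of cluster allele frequencies, e.g. to plant
    # ancestry-differentiated loci: {snp_index: (f_cluster0, f_cluster1, ...)}
    cluster_freq_overrides: dict = field(default_factory=dict)
    # optional local LD: within blocks of ld_block_length SNPs, each column
    # is the previous one with Bernoulli(ld_flip_rate) flips
    ld_blocks: bool = False
    ld_block_length: int = 10
    ld_flip_rate: float = 0.05
    missing_rate: float = 0.0
    snp_spacing: int = 200  # bp between adjacent SNP positions
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.n_clusters <= self.n_lines):
            raise ValueError("invalid configuration: need 0 < n_clusters <= n_lines")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must be in [0, 1)")
        if not (0.0 < self.maf_floor < 0.5):
            raise ValueError("maf_floor must be in (0, 0.5)")
        for h2 in (self.h2_background_1, self.h2_background_2):
            if not (0.0 <= h2 < 1.0):
                raise ValueError("background variance fractions must be in [0, 1)")
        idx = [int(q[0]) for q in self.qtl_spec]
        if len(set(idx)) != len(idx):
            raise ValueError("qtl_spec indices must be unique")
        if any(i < 0 or i >= self.n_snps for i in idx):
            raise ValueError("qtl_spec index out of range")
        for j, freqs in self.cluster_freq_overrides.items():
            if not (0 <= int(j) < self.n_snps):
                raise ValueError("cluster_freq_overrides index out of range")
            if len(freqs) != self.n_clusters:
                raise ValueError("cluster_freq_overrides needs one frequency per cluster")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class PhenotypeSimResult:
    """Simulated phenotypes plus the true generating components."""

    table: pd.DataFrame  # line_id, trait1, trait2, longitude, latitude
    truth: dict


def _cluster_labels(config: SimulationConfig) -> np.ndarray:
    reps = int(np.ceil(config.n_lines / config.n_clusters))
    return np.tile(np.arange(config.n_clusters), reps)[: config.n_lines]


def _cluster_score(config: SimulationConfig) -> np.ndarray:
    """Standardized cluster index, the latent 'west-east' axis."""
    c = np.arange(config.n_clusters, dtype=float)
    return (c - c.mean()) / c.std() if config.n_clusters > 1 else np.zeros(1)


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Balding-Nichols genotypes for inbred lines.

    Ancestral frequency p0 ~ U(maf_floor, 1-maf_floor); per-cluster
    frequency ~ Beta(p0(1-fst)/fst, (1-p0)(1-fst)/fst); line genotype ~
    Bernoulli(cluster frequency).  Genotypes are haploid-equivalent {0,1}:
    the lines are selfing, so no heterozygotes are generated.
    """
    config.validate()
    rng = derive_rng(config.seed, "genotypes")
    clusters = _cluster_labels(config)

    p0 = rng.uniform(config.maf_floor, 1.0 - config.maf_floor, size=config.n_snps)
    if config.fst > 1e-9:
        a = p0 * (1.0 - config.fst) / config.fst
        b = (1.0 - p0) * (1.0 - config.fst) / config.fst
        cluster_freq = rng.beta(a, b, size=(config.n_clusters, config.n_snps))
    else:
        cluster_freq = np.tile(p0, (config.n_clusters, 1))
    for j, freqs in config.cluster_freq_overrides.items():
        cluster_freq[:, int(j)] = np.asarray(freqs, dtype=float)

    if config.ld_blocks:
        # block-copy LD: only block-leader frequencies are independent
        L = config.ld_block_length
        leaders = np.arange(0, config.n_snps, L)
        values = np.empty((config.n_lines, config.n_snps))
        prev = None
        for j in range(config.n_snps):
            if j in config.cluster_freq_overrides or j % L == 0 or prev is None:
                values[:, j] = rng.random(config.n_lines) < cluster_freq[clusters, j]
            else:
                flips = rng.random(config.n_lines) < config.ld_flip_rate
                values[:, j] = np.where(flips, 1.0 - prev, prev)
            prev = values[:, j]
        del leaders
    else:
        values = (rng.random((config.n_lines, config.n_snps)) < cluster_freq[clusters, :]).astype(float)

    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values[mask] = np.nan

    per_chrom = np.array_split(np.arange(config.n_snps), config.n_chromosomes)
    chrom = np.concatenate([np.full(len(ix), f"Chr{i + 1}") for i, ix in enumerate(per_chrom)])
    pos = np.concatenate(
        [config.snp_spacing * (np.arange(len(ix)) + 1) for ix in per_chrom]
    ).astype(int)

    return GenotypeMatrix(values=values, chrom=chrom, pos=pos, clusters=clusters)


def _structured_draw(K_values: np.ndarray, h2: float, rng: np.random.Generator) -> np.ndarray:
    """Polygenic draw with covariance h2 * K (K has unit diagonal)."""
    n = K_values.shape[0]
    if h2 == 0:
        return np.zeros(n)
    s, U = np.linalg.eigh((K_values + K_values.T) / 2.0)
    s = np.clip(s, 0.0, None)
    return U @ (np.sqrt(h2 * s) * rng.standard_normal(n))


def simulate_phenotypes(geno: GenotypeMatrix, kinship, config: SimulationConfig) -> PhenotypeSimResult:
    """Two correlated traits plus geographic metadata.

    trait1 (mCHH-like) = sum QTL_1 effects * z(genotype) + shared factor
    + polygenic(h2_background_1 * K) + noise; trait2 (mCHG-like) carries the
    same shared factor scaled by ``shared_factor_sd``.  Longitude follows the
    cluster score with strength ``cline_strength``; latitude is uniform.
    """
    config.validate()
    K_values = kinship.values if hasattr(kinship, "values") else np.asarray(kinship)
    if K_values.shape[0] != geno.n_lines:
        raise ValueError("kinship dimension does not match genotypes")
    rng = derive_rng(config.seed, "phenotypes")
    n = geno.n_lines
    clusters = geno.clusters if geno.clusters is not None else _cluster_labels(config)

    vs = float(np.clip(config.shared_structured_frac, 0.0, 1.0))
    f = _structured_draw(K_values, vs, rng) + np.sqrt(1.0 - vs) * rng.standard_normal(n)

    qtl1 = np.zeros(n)
    qtl2 = np.zeros(n)
    for j, e1, e2 in config.qtl_spec:
        x = geno.values[:, int(j)]
        x = np.where(np.isfinite(x), x, np.nanmean(x))
        sd = x.std()
        if sd == 0:
            continue
        z = (x - x.mean()) / sd
        qtl1 += float(e1) * z
        qtl2 += float(e2) * z

    b1 = _structured_draw(K_values, config.h2_background_1, rng)
    b2 = _structured_draw(K_values, config.h2_background_2, rng)
    e1 = config.noise_sd_1 * rng.standard_normal(n)
    e2 = config.noise_sd_2 * rng.standard_normal(n)

    trait1 = qtl1 + f + b1 + e1
    trait2 = qtl2 + config.shared_factor_sd * f + b2 + e2

    score = _cluster_score(config)[clusters]
    cs = config.cline_strength
    lon_raw = cs * score + np.sqrt(max(0.0, 1.0 - cs**2)) * rng.standard_normal(n)
    longitude = 10.0 + 20.0 * lon_raw
    latitude = rng.uniform(35.0, 60.0, size=n)

    table = pd.DataFrame(
        {
            "line_id": geno.line_ids,
            "trait1": trait1,
            "trait2": trait2,
            "longitude": longitude,
            "latitude": latitude,
        }
    )
    truth = {
        "qtl_spec": [[int(j), float(e1_), float(e2_)] for j, e1_, e2_ in config.qtl_spec],
        "qtl_chrom_pos": [
            [str(geno.chrom[int(j)]), int(geno.pos[int(j)])] for j, _, _ in config.qtl_spec
        ],
        "shared_factor_sd": config.shared_factor_sd,
        "h2_background": [config.h2_background_1, config.h2_background_2],
        "noise_sd": [config.noise_sd_1, config.noise_sd_2],
        "cline_strength": config.cline_strength,
        "components": {
            "shared": f.tolist(),
            "qtl1": qtl1.tolist(),
            "qtl2": qtl2.tolist(),
        },
    }
    return PhenotypeSimResult(table=table, truth=truth)


def simulate_insertion_counts(
    geno: GenotypeMatrix,
    focal_snp: int,
    modifier_snps,
    config: SimulationConfig,
    k: int = 2,
) -> np.ndarray:
    """Per-line recent-transposon-insertion counts with planted epistasis.

    counts ~ NegBin with log-mean = log(baseline) +
    log_ratio * 1[focal alt allele AND >= k modifier alt alleles],
    mirroring mobilization restricted to lines that combine the partner
    non-reference allele with two or more methylation-decreasing alleles.
    """
    for j in [focal_snp, *modifier_snps]:
        if not (0 <= int(j) < geno.n_snps):
            raise ValueError(f"SNP index {j} out of range")
    rng = derive_rng(config.seed, "insertions")
    focal = geno.values[:, int(focal_snp)]
    mod = geno.values[:, [int(j) for j in modifier_snps]]
    count = np.nansum(mod, axis=1)
    boost = (focal == 1.0) & (count >= k)
    mu = config.insertion_baseline * np.exp(config.insertion_interaction_log_ratio * boost)
    shape = config.insertion_dispersion
    p = shape / (shape + mu)
    return rng.negative_binomial(shape, p).astype(int)


def simulate_methylation_calls(
    features,
    true_levels,
    depth: float,
    seed: int = 0,
    sites_per_feature: int = 20,
    context: str = "CHG",
) -> pd.DataFrame:
    """Per-cytosine call records for a set of features.

    Each feature gets ``sites_per_feature`` cytosines placed within its
    interval; per site, total ~ Poisson(depth) (zero-coverage sites are
    emitted with zero counts) and mc ~ Binomial(total, feature level).

    ``true_levels`` is one fraction per feature (sequence aligned with
    ``features``) or a mapping feature id -> fraction.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if isinstance(true_levels, dict):
        levels = [true_levels[f.id] for f in features]
    else:
        levels = list(true_levels)
    if any(not (0.0 <= lv <= 1.0) for lv in levels):
        raise ValueError("true levels must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for f, lv in zip(features, levels):
        span = f.end - f.start
        m = min(sites_per_feature, span)
        # 1-based positions inside (start, end]
        offs = np.sort(rng.choice(span, size=m, replace=False)) + 1
        totals = rng.poisson(depth, size=m)
        mcs = rng.binomial(totals, lv)
        for i, (off, tot, mc) in enumerate(zip(offs, totals, mcs)):
            rows.append(
                {
                    "chrom": f.chrom,
                    "pos": int(f.start + off),
                    "strand": "+" if i % 2 == 0 else "-",
                    "context": context,
                    "mc": int(mc),
                    "total": int(tot),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "mc", "total"])


def simulate_annotations(
    config: SimulationConfig,
    n_tes: int = 60,
    n_genes: int = 120,
    te_length: int = 400,
    gene_length: int = 1500,
) -> tuple[list, list]:
    """Non-overlapping TE and gene intervals laid out along the chromosomes."""
    chrom_len = (config.n_snps // config.n_chromosomes + 1) * config.snp_spacing
    rng = derive_rng(config.seed, "annotations")
    tes, genes = [], []
    per_chrom_te = np.array_split(np.arange(n_tes), config.n_chromosomes)
    per_chrom_gene = np.array_split(np.arange(n_genes), config.n_chromosomes)
    for c in range(config.n_chromosomes):
        name = f"Chr{c + 1}"
        n_t, n_g = len(per_chrom_te[c]), len(per_chrom_gene[c])
        slots = n_t + n_g
        if slots == 0:
            continue
        step = max(chrom_len // (slots + 1), te_length + gene_length)
        kinds = ["TE"] * n_t + ["gene"] * n_g
        rng.shuffle(kinds)
        t_i = g_i = 0
        for s, kind in enumerate(kinds):
            start = (s + 1) * step
            if kind == "TE":
                tes.append(FeatureAnnotation(f"TE_{name}_{t_i:03d}", name, start, start + te_length, "TE"))
                t_i += 1
            else:
                genes.append(
                    FeatureAnnotation(f"G_{name}_{g_i:03d}", name, start, start + gene_length, "gene")
                )
                g_i += 1
    return tes, genes


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Canonical two-trait architecture.

    One trait-2-specific QTL planted at a strongly ancestry-differentiated
    SNP (cluster frequencies alternating 0.01/0.99) with effect 0.2083 SD,
    so that it explains 10% of var(trait2 | trait1); the shared factor
    (0.7 kinship-structured, 0.3 environment-like) enters the two traits
    with loadings (1, 0.9) and the noise levels are chosen so that
    cor(trait1, trait2) = 0.8 in expectation.
    """
    cfg = SimulationConfig(seed=seed)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    qtl_idx = cfg.n_snps // 2
    alt = np.where(np.arange(cfg.n_clusters) % 2 == 0, 0.01, 0.99)
    cfg.qtl_spec = ((qtl_idx, 0.0, 0.208310),)
    cfg.cluster_freq_overrides = {qtl_idx: tuple(alt)}
    cfg.validate()
    return cfg


def clinal_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Geography/epistasis architecture: five clinal focal loci + partner.

    Five trait-2-decreasing QTLs planted at SNPs whose cluster frequencies
    follow the cluster (longitude) axis, an unstructured partner locus at
    frequency 0.35, longitude with cline strength 0.5, and insertion counts
    boosted 30-fold for lines carrying the partner alt allele and >= 2
    decreasing alleles.
    """
    cfg = SimulationConfig(n_lines=900, seed=seed)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    score = _cluster_score(cfg)
    focal = [int(frac * cfg.n_snps) for frac in (0.1, 0.3, 0.5, 0.7, 0.9)]
    partner = int(0.2 * cfg.n_snps)
    overrides_freq = {
        j: tuple(np.clip(0.5 - 0.28 * score, 0.05, 0.95)) for j in focal
    }
    overrides_freq[partner] = tuple(np.full(cfg.n_clusters, 0.35))
    cfg.cluster_freq_overrides = overrides_freq
    cfg.qtl_spec = tuple((j, 0.0, -0.15) for j in focal)
    cfg.cline_strength = 0.46
    cfg.validate()
    return cfg


def write_fixture_bundle(config: SimulationConfig, out_dir) -> dict:
    """Generate and write the full fixture bundle; returns the path map.

    Writes genotypes (VCF + TSV matrix), phenotype/metadata table, BED
    annotations, allc-style calls, an a priori gene list, the config echo,
    and a truth file with every planted quantity.
    """
    from . import io as mio  # local import: io depends on containers only
    from .lmm import compute_kinship

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geno = simulate_genotypes(config)
    K = compute_kinship(geno)
    phen = simulate_phenotypes(geno, K, config)
    tes, genes = simulate_annotations(config)

    focal = [int(j) for j, _, _ in config.qtl_spec]
    partner = None
    non_qtl = [j for j in config.cluster_freq_overrides if j not in focal]
    if non_qtl:
        partner = int(non_qtl[0])
    table = phen.table.copy()
    if focal and partner is not None:
        table["insertion_count"] = simulate_insertion_counts(geno, partner, focal, config)

    rng_levels = derive_rng(config.seed, "te_levels")
    te_levels = rng_levels.uniform(0.1, 0.7, size=len(tes))
    calls = simulate_methylation_calls(tes, te_levels, depth=20, seed=derive_rng(config.seed, "calls").integers(2**31))

    apriori = [g.id for g in genes[:: max(1, len(genes) // 40)]][:40]

    paths = {
        "vcf": out / "genotypes.vcf",
        "matrix": out / "genotypes.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "annotations": out / "annotations.bed",
        "allc": out / "allc.tsv",
        "apriori": out / "apriori_genes.txt",
        "truth": out / "truth.json",
        "config": out / "config.yaml",
    }
    mio.write_vcf(geno, paths["vcf"])
    mio.write_genotype_tsv(geno, paths["matrix"])
    table.to_csv(paths["phenotypes"], sep="\t", index=False)
    mio.write_bed(tes + genes, paths["annotations"])
    mio.write_allc(calls, paths["allc"])
    paths["apriori"].write_text("\n".join(apriori) + "\n")
    truth = dict(phen.truth)
    truth["te_true_levels"] = {t.id: float(lv) for t, lv in zip(tes, te_levels)}
    truth["focal_snps"] = focal
    truth["partner_snp"] = partner
    truth["clusters"] = (geno.clusters if geno.clusters is not None else np.zeros(geno.n_lines, int)).tolist()
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    mio.write_config(asdict_config(config), paths["config"])
    return {k: str(v) for k, v in paths.items()}


def asdict_config(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["qtl_spec"] = [list(q) for q in config.qtl_spec]
    d["cluster_freq_overrides"] = {int(k): list(map(float, v)) for k, v in config.cluster_freq_overrides.items()}
    return d
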