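"""Candidate-gene enrichment, FDR upper bound, genome rotation.

Assigns each gene the strongest association within 15 kb of its
boundaries, then asks whether an a priori candidate list is enriched for
small p-values.  At a threshold p, with x_p the fraction of candidates and
y_p the fraction of background genes below p, enrichment is x_p/y_p and
y_p/x_p bounds the false-discovery rate within the candidate set.
Significance comes from circularly rotating candidate membership along the
genome, which preserves the spatial autocorrelation of gene p-values.
"""

import numpy as np

from methgwas import (
    assign_gene_pvalues,
    association_scan,
    compute_kinship,
    rotation_significance,
    simulate_genotypes,
    simulate_phenotypes,
)
from methgwas.simulate import default_config, simulate_annotations

cfg = default_config(seed=11, n_lines=300, n_snps=2000)
qtl = cfg.qtl_spec[0][0]
geno = simulate_genotypes(cfg)
K = compute_kinship(geno)
phen = simulate_phenotypes(geno, K, cfg)
cond = association_scan(
    phen.table.trait2.to_numpy(), geno, K, covariate=phen.table.trait1.to_numpy(), exact=True
)

_, genes = simulate_annotations(cfg, n_tes=0, n_genes=120)
# a priori set: 20 genes including those nearest the planted QTL
qtl_chrom, qtl_pos = geno.chrom[qtl], geno.pos[qtl]
near = sorted(
    (g for g in genes if g.chrom == qtl_chrom),
    key=lambda g: abs((g.start + g.end) // 2 - qtl_pos),
)[:2]
apriori = [g.id for g in near] + [g.id for g in genes[::7]][:18]

table = assign_gene_pvalues(cond, genes, apriori, window=15_000)
grid = np.arange(1.0, 7.0, 1.0)
res = rotation_significance(table, grid, n_rotations=3000, seed=5)

print(f"{len(genes)} genes, {len(set(apriori))} a priori candidates, "
      f"{table.table.no_snp.sum()} genes with no SNP in the 15 kb window")
print("\n -log10p   x_p     y_p     enrich   FDR<=   rotation p")
for i, row in res.table.iterrows():
    print(f"   {row.neg_log10_threshold:4.1f}   {row.x_p:.3f}   {row.y_p:.3f}"
          f"   {row.enrichment if np.isfinite(row.enrichment) else float('nan'):6.2f}"
          f"   {row.fdr_bound if np.isfinite(row.fdr_bound) else float('nan'):5.2f}"
          f"   {res.rotation_p[i]:.4f}")
print("\nenrichment > 1 at strict thresholds with small rotation p means the"
      "\ncandidate list genuinely tags the association signal; y/x bounds the"
      "\nFDR for calling candidates at that threshold")
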