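"""Permutation test: is a gene cluster enriched for selection signal?

Each gene is scored by the median -log10 p of scan SNPs in the 25 kb
window upstream of its TSS; a cluster's score is compared to 1000
redraws of equally many genes from the genome-wide pool (size-matched
windows by construction).  Here one cluster's genes sit just downstream
of a planted sweep, so their upstream windows cover it.
"""

from crestscan import (
    AnnotationSimConfig,
    EnrichConfig,
    GeneAnnotation,
    HapSimConfig,
    cluster_enrichment_test,
    simulate_annotation,
    simulate_haplotypes,
    xpehh_scan,
)
from crestscan.enrichment import score_genes

cfg = HapSimConfig(seed=3, sweep_position=500_000, selection_coefficient=0.5)
A, B = simulate_haplotypes(cfg)
records = xpehh_scan(A, B)

background = simulate_annotation(AnnotationSimConfig(n_genes=80, seed=11))
near_sweep = [
    GeneAnnotation(f"ncc{j}", "chr1", 502_000 + 2_000 * j, 505_000 + 2_000 * j, "+")
    for j in range(10)
]
genes = background + near_sweep

ecfg = EnrichConfig(window_bp=25_000, n_iter=1000, seed=3)
scores = score_genes(genes, records, ecfg)

hot = cluster_enrichment_test([g.gene_id for g in near_sweep], genes, records,
                              ecfg, cluster_id="near_sweep", scores=scores)
ctrl = cluster_enrichment_test([g.gene_id for g in background[:10]
                                if g.gene_id in scores],
                               genes, records, ecfg, cluster_id="control",
                               scores=scores)
for res in (hot, ctrl):
    print(f"cluster {res.cluster_id}: {res.n_genes_scored} genes scored, "
          f"observed median logp {res.observed_stat:.2f}, "
          f"empirical p = {res.empirical_p:.4f}")
# The near-sweep cluster's observed statistic exceeds essentially every
# permutation (p ~ 1/1001); the control cluster is indistinguishable
# from the null.
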