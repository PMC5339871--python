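"""Pre-ranked GSEA of a module's kME ranking against planted gene sets.

Genes are ranked by |kME| to the MD-linked module; the planted set (the
module's exact membership) should reach family-wise significance while
random decoy sets should not.
"""

from radnet import gsea, network, synthetic

cohort = synthetic.generate_cohort(n_genes=500, n_samples=40, seed=1)
partition = cohort.truth.module_labels
eigengenes = network.module_eigengene(cohort.expression, partition)
kme = network.kme(cohort.expression, eigengenes)

md_module = cohort.truth.trait_module_links["MD"][0]
ranking = gsea.rank_genes(kme[md_module].abs())
result = gsea.gsea_preranked(ranking, cohort.gene_sets, n_perm=1000, seed=2)

cols = ["size", "ES", "NES", "p_nominal", "p_FWER"]
print(result[cols].sort_values("p_FWER").round(4).to_string())
# the planted MD-module set tops the table at the permutation floor
# (p_FWER ~ 0.001 at 1000 permutations); decoys stay non-significant
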