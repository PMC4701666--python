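"""Permutation validation of modules and module-DE overlap enrichment.

Compares each detected module's mean topological overlap with 100 random
gene sets of the same size (z-score, normal p, BH FDR <= 0.2), then tests
every (module, time point) pair for DE-gene enrichment with the compound
rule p <= 0.005 AND odds ratio > 3.
"""

from common import COHORT_SEED, normalized_cohort, outdir
from cienet.diffexpr import fit_de, select_network_genes
from cienet.enrichment import module_de_overlap, validate_modules
from cienet.network import build_network

norm, truth = normalized_cohort()
out = outdir("05_enrichment")

res = fit_de(norm)
universe = select_network_genes({"PFC": res.table["F_fdr"]}, 0.01)
sub = norm.subset_genes(sorted(universe.gene_ids))
net, part = build_network(sub, beta=6, deep_split=2, min_module_size=30)

validation = validate_modules(net, part, n_permutations=100, rng_seed=COHORT_SEED)
validation.round(4).to_csv(out / "module_validation.tsv", sep="\t")

de_sets = {
    tp: s for tp, s in res.de_sets(0.01).items()
}
restricted = {
    tp: type(s)(s.name, frozenset(s.gene_ids & universe.gene_ids))
    for tp, s in de_sets.items()
}
overlap = module_de_overlap(part, restricted, universe.gene_ids)
overlap.round(6).to_csv(out / "module_de_overlap.tsv", sep="\t", index=False)

n_sig = int(validation["significant"].sum())
print(f"validated modules: {n_sig}/{len(validation)} at FDR <= 0.2")
print(validation[["size", "observed", "z", "fdr", "significant"]].to_string())
sig_cells = overlap[overlap.significant]
print(f"significant (module, timepoint) overlap cells: {len(sig_cells)}")
print(sig_cells[["module", "de_set", "overlap", "p", "odds_ratio"]].to_string(index=False))
print(f"tables written to {out}")
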