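"""Co-expression network, module detection, and eigengene kinetics.

Builds the soft-thresholded (beta = 6) unsigned network on the
ANOVA-selected genes, detects modules at deep split 2 (min size 30),
compares them with the planted truth (adjusted Rand index), and summarizes
each module eigengene's CIE vs Ctrl time course.
"""

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from common import normalized_cohort, outdir
from cienet.diffexpr import fit_de, select_network_genes
from cienet.network import build_network, eigengene_timecourse, pick_soft_threshold

norm, truth = normalized_cohort()
out = outdir("04_network")

report = pick_soft_threshold(norm, powers=(1, 2, 3, 4, 5, 6, 7, 8, 10, 12))
report.round(4).to_csv(out / "soft_threshold_report.tsv", sep="\t")

res = fit_de(norm)
universe = select_network_genes({"PFC": res.table["F_fdr"]}, 0.01)
sub = norm.subset_genes(sorted(universe.gene_ids))
net, part = build_network(sub, beta=6, deep_split=2, min_module_size=30)

labels = part.labels
ari = adjusted_rand_score(truth.module_labels.loc[labels.index], labels)
sizes = labels.value_counts().rename("n_genes")
composition = pd.crosstab(truth.module_labels.loc[labels.index], labels)
sizes.to_csv(out / "module_sizes.tsv", sep="\t", index_label="module")
composition.to_csv(out / "module_vs_truth.tsv", sep="\t")
part.kim.round(4).to_csv(out / "kim.tsv", sep="\t", index_label="gene_id")

tcs = []
for m in part.modules:
    tc = eigengene_timecourse(part.eigengenes[m], norm.metadata)
    tc.insert(0, "module", m)
    tcs.append(tc)
pd.concat(tcs).round(4).to_csv(out / "eigengene_timecourse.tsv", sep="\t", index=False)

print(f"network genes (ANOVA union): {len(universe.gene_ids)}")
print(f"modules at deep split 2: {len(part.modules)}, grey {part.n_grey}, "
      f"ARI vs planted truth {ari:.3f}")
print(composition.to_string())
print(f"tables written to {out}")
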