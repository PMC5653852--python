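"""Preranked enrichment of an NF-kB target signature in the therapy response.

Ranks all genes of the in vivo dataset by signed log2 fold change
(descending) and screens a 50-set hallmark-style collection: the planted
NF-kB target set concentrates at the bottom of the ranking (genes lowered
by therapy), so it comes out with a strongly negative NES and low FDR q.
"""

import numpy as np

from reciprome.enrichment import GeneSetCollection, RankedList, normalize_and_fdr
from reciprome.synthetic import aat_gene_sets, aat_gene_truth, generate_expression_datasets

truth = aat_gene_truth(seed=1)
ds1, _ = generate_expression_datasets(truth["up_genes"], truth["down_genes"], seed=2)

scores = np.log2(ds1.records.groupby("gene_id")["fold_change"].min())
ranked = RankedList.from_scores(scores, weight_exponent=1.0)
collection = GeneSetCollection.from_dict(aat_gene_sets(truth, seed=3))

out = normalize_and_fdr(ranked, collection, n_perm=500, seed=4)
print("most down-enriched sets (negative NES = concentrated among genes")
print("down-regulated by therapy):")
print(out.sort_values("nes").head(5)[["es", "nes", "nominal_p", "fdr_q"]].round(3).to_string())
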