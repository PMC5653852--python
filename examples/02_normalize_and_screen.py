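"""Normalize counts by the positive controls and screen ZZ vs MM.

Prints the features altered more than 3-fold between asymptomatic ZZ and
MM monocytes, with their fold changes and exact permutation p-values
(n = 3 vs 3 enumerates all 20 label assignments, so the smallest possible
two-sided p is 0.1).
"""

from reciprome.nanostring import compare_groups, normalize_counts, screen
from reciprome.synthetic import aat_mirna_effects, aat_study_design, generate_mirna_counts

counts = generate_mirna_counts(aat_study_design(seed=1), aat_mirna_effects())
norm = normalize_counts(counts)
print(f"detected {int(norm.detected.sum())} of {len(norm.detected)} endogenous probes")

results = compare_groups(norm, "ZZ_ASYMP", "MM", n_perm=10_000, seed=1)
hits = screen(results, fold_cutoff=3.0)
print(f"\n{len(hits)} features altered >3-fold (ZZ_ASYMP vs MM):")
print(hits[["fold_change", "log2_fc", "direction", "p_perm"]].round(3).to_string())
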