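"""Validate lead miRNAs by 2^-ddCt with Bonferroni-corrected t-tests.

Simulates Taqman-style triplicate Ct tables (U6-normalized, n = 4 per
group) with planted ZZ/MM folds of 22x, 28x, 16x for the leads and 5x for
the miR-30a negative control, then prints the recovered folds and the
per-comparison significance at the family threshold 0.05/3 = 0.0167.
"""

from reciprome.qpcr import assess_relative_expression, bonferroni_threshold
from reciprome.synthetic import (
    LEAD_MIRNAS,
    NEGATIVE_CONTROL_MIRNA,
    aat_qpcr_folds,
    aat_study_design,
    generate_ct_table,
)

assays = [*LEAD_MIRNAS, NEGATIVE_CONTROL_MIRNA]
table = generate_ct_table(
    aat_study_design(seed=8, n_per_group=4),
    targets=assays,
    reference="U6",
    planted_fold=aat_qpcr_folds(),
)

print(f"Bonferroni threshold (3 test miRNAs): {bonferroni_threshold(0.05, 3):.4f}\n")
for assay in assays:
    rel = assess_relative_expression(table, assay, "ZZ_ASYMP", "MM", family_size=3)
    print(
        f"{assay:20s} ddCt={rel.delta_delta_ct:+.2f} fold={rel.fold:6.1f} "
        f"p={rel.p_value:.2e} significant={rel.significant}"
    )
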