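"""Filter screened miRNAs by NF-kB promoter sites at a functional distance.

A binding site must lie 100-10,000 bp upstream of the TSS to count as
functional: miR-598 / miR-199a-5p / miR-320a qualify, while miR-30a-5p's
site at -45 bp is too close to the TSS and is excluded.
"""

from reciprome.promoter import classify_regulated, intersect_with_screen
from reciprome.synthetic import aat_promoter_sites, generate_promoter_annotations

ann = generate_promoter_annotations(aat_promoter_sites())
calls = classify_regulated(ann, tf="NFKB", window=(100, 10_000))
for c in calls:
    print(f"{c.mirna_id:20s} regulated={str(c.regulated):5s} reason={c.reason:9s} sites={c.qualifying_sites}")

screened = ["hsa-miR-199a-5p", "hsa-miR-598", "hsa-miR-320a", "hsa-miR-30a-5p", "miR-zz-up-01"]
print("\nNF-kB candidates among screened miRNAs:", intersect_with_screen(calls, screened))
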