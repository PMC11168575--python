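"""Fine-mapping interval logic: recombinant narrowing and interval length.

Reproduces the marker-interval arithmetic of a KASP fine-mapping step: three
critical recombinants restrict the causal locus to the adjacent marker pair
(CmoM17 at 791,681 bp, CmoM18 at 842,449 bp), a 50.77 kb window.
"""

import pandas as pd

from bsaqtl import regions

markers = ["CmoM15", "CmoM16", "CmoM17", "CmoM18", "CmoM19", "CmoM20"]
genotypes = pd.DataFrame.from_dict(
    {
        "F2-89":  ["P1hom"] * 3 + ["P2hom"] * 3,  # breakpoint between M17/M18
        "F2-21":  ["P2hom"] * 3 + ["P1hom"] * 3,  # reciprocal breakpoint
        "F2-273": ["het"] * 3 + ["P1hom"] * 3,    # right-side recombinant
        "F2-01":  ["P1hom"] * 6,
        "F2-02":  ["P2hom"] * 6,
        "F2-03":  ["het"] * 6,
    },
    orient="index", columns=markers,
)
phenotype_classes = {
    "F2-89": "P2hom", "F2-21": "P1hom", "F2-273": "P2hom",
    "F2-01": "P1hom", "F2-02": "P2hom", "F2-03": "het",
}

left, right = regions.narrow_by_recombinants(genotypes, phenotype_classes)
print(f"causal locus flanked by: {left} - {right}")

coords = {"CmoM17": 791_681, "CmoM18": 842_449}
kb = regions.interval_length_kb(coords[left], coords[right])
print(f"interval: {coords[left]:,} - {coords[right]:,} bp = {kb} kb")
# every individual whose genotype across the flanking pair is uniform and
# parental matches that parent's phenotype class, so no recombinant
# contradicts this placement of the locus.
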