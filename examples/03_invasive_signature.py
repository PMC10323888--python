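"""Derive an invasiveness signature from a three-group carcinogenesis study.

Simulates normal / PanIN / PDAC groups with planted up-regulated genes,
runs moderated differential expression for both contrasts, applies the
log2FC > 1 and q < 0.05 filters, and intersects the two up-lists with an
anchor signature.  Also reproduces the packaged worked example in which the
24-gene SALL4 signature filters down to the fixed 7-gene invasiveness set.
"""

from stromasig import (
    GeneSet,
    derive_invasive_signature,
    dge,
    filter_dge,
    generate_panin_study,
    load_packaged_signatures,
)

expr, labels, truth = generate_panin_study(
    n_per_group=10, n_genes=1000, n_up_pdac_vs_panin=40,
    n_up_pdac_vs_normal=40, n_shared_up=10, effect_log2fc=2.0, seed=1,
)

up_lists = {}
for contrast in ("PanIN", "normal"):
    two = labels[labels.isin(["PDAC", contrast])]
    res = dge(expr, two, groups=("PDAC", contrast), method="moderated")
    up = filter_dge(res, lfc_min=1.0, q_max=0.05, direction="up",
                    name=f"up_vs_{contrast}")
    up_lists[contrast] = up
    print(f"PDAC vs {contrast}: {len(up)} genes pass log2FC>1, q<0.05")

anchor = truth.planted_de_genes  # genes planted up in both contrasts
invasive = derive_invasive_signature(up_lists["PanIN"], up_lists["normal"], anchor)
print(f"triple intersection: {len(invasive)} genes "
      f"(expected {len(anchor)} planted shared genes)\n")

sigs = load_packaged_signatures()
seven = sigs["SALL4_INVASIVE_7"].genes
fixture = derive_invasive_signature(
    GeneSet(name="up_vs_panin", genes=frozenset(seven | {"KRT19", "S100A4"})),
    GeneSet(name="up_vs_normal", genes=frozenset(seven | {"CEACAM5", "MUC1"})),
    sigs["SALL4_CORRELATED_24"],
)
print("packaged worked example ->", ", ".join(fixture.genes_sorted))
# The fixed point of the worked example is the published 7-gene invasiveness
# set: COL1A1, COL5A2, COL11A1, MMP11, NUAK1, PTK7, SERPINH1.
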