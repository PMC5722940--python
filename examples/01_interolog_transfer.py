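"""Transfer known interactions from two template species onto a target species.

A template interaction (A, B) in species s maps to a predicted target pair
for every combination of A's and B's orthologs; pairs witnessed by several
species merge, and N counts the distinct supporting species.
"""

from interoppi import (
    AlignmentHit,
    TemplateInteraction,
    filter_orthologs,
    transfer_interactions,
)

# BLASTp-style hits: identity %, query span, e-value, query length.
# Only hits with identity >= 60, query coverage >= 80 and e-value <= 1e-10
# admit an ortholog pair.
hits = [
    AlignmentHit("ath_HSP90", "Me001", 82.0, 1, 650, 1e-120, 700),
    AlignmentHit("ath_HSP90", "Me002", 74.0, 1, 640, 1e-95, 700),   # paralog
    AlignmentHit("ath_SGT1", "Me010", 68.0, 1, 330, 1e-60, 360),
    AlignmentHit("osa_Hsp90", "Me001", 77.0, 1, 660, 1e-110, 710),
    AlignmentHit("osa_Sgt1", "Me010", 64.0, 1, 300, 1e-40, 350),
    AlignmentHit("ath_WEAK", "Me099", 45.0, 1, 200, 1e-5, 400),     # fails all three
]
orthologs = filter_orthologs(hits)
print(f"ortholog pairs admitted: {len(orthologs)} (ath_WEAK rejected)")

templates = [
    TemplateInteraction("ath", "ath_HSP90", "ath_SGT1", "experimental", "IntAct"),
    TemplateInteraction("osa", "osa_Hsp90", "osa_Sgt1", "computational", "PRIN"),
]
predictions, report = transfer_interactions(templates, orthologs)

print(f"templates: {report.n_templates}, transferred: {report.n_transferred_templates}")
for p in predictions:
    print(f"  predicted {p.pair[0]} -- {p.pair[1]}  N={p.n_species}  species={p.species}")
# The ath pair expands through the Me001/Me002 paralogs (cross-product), and
# the pair supported by both ath and osa carries N=2: two independent
# template species strengthen the same target-species interaction.
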