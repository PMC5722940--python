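"""Score predicted interactions: CV = CV_interolog x CV_DDI, then tier them.

CV_interolog averages the per-species evidence weight M (1 experimental,
0.5 computational); CV_DDI = d * D rewards pairs whose domains are known to
interact.  Edges without DDI support are Basal (B); supported edges are
split into H1/H2/H3 by the percentile rank of CV.
"""

from interoppi import (
    TemplateInteraction,
    assess_pair,
    assign_tiers,
    filter_orthologs,
    score_predictions,
    transfer_interactions,
)
from interoppi.io_formats import AlignmentHit, canonical_pair

# The canonical worked configuration: a 3-domain protein facing a 4-domain
# protein with 2 of the 12 possible cross-domain pairs reported as DDIs.
annotations = {
    "Me1": frozenset({"PF001", "PF002", "PF003"}),
    "Me2": frozenset({"PF101", "PF102", "PF103", "PF104"}),
}
rules = {canonical_pair("PF001", "PF101"), canonical_pair("PF002", "PF103")}
a = assess_pair(("Me1", "Me2"), annotations, rules)
print(f"ddi_count={a.ddi_count}  D={a.D:.4f}  d={a.d}  CV_DDI={a.cv_ddi:.4f}")
# D = 2/12 = 0.1667: one sixth of the possible domain pairings is supported.

# A small network: one experimentally backed edge, one computational.
hits = [
    AlignmentHit("ath_A", "Me1", 80.0, 1, 450, 1e-80, 500),
    AlignmentHit("ath_B", "Me2", 75.0, 1, 400, 1e-70, 450),
    AlignmentHit("ath_C", "Me3", 70.0, 1, 350, 1e-60, 400),
]
templates = [
    TemplateInteraction("ath", "ath_A", "ath_B", "experimental", "IntAct"),
    TemplateInteraction("ath", "ath_A", "ath_C", "computational", "AtPID"),
]
preds, _ = transfer_interactions(templates, filter_orthologs(hits))
score_predictions(preds, annotations, rules)
assign_tiers(preds)
for p in preds:
    s = p.score
    print(
        f"{p.pair[0]}--{p.pair[1]}: CV_interolog={s.cv_interolog}  "
        f"CV_DDI={s.ddi.cv_ddi:.4f}  CV={s.cv:.4f}  tier={p.tier}"
    )
# The experimentally supported, DDI-backed edge scores CV = 1 x 2/12 and is
# the lone High-tier edge; the Me1--Me3 pair has no domain support, so its
# CV collapses to 0 and it stays Basal regardless of interolog evidence.
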