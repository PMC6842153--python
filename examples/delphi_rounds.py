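"""Two iterative Delphi voting rounds over a synthetic expert panel.

Builds a 76-panelist panel in which each item follows a known behavioural
archetype, classifies round-2 votes under the a priori consensus rule
(median 7-9, IQR <= 2, >= 75% scoring 7-9), sends feedback for the
equivocal items, and re-votes them under the conformity model.
"""

from consensuskit import PanelDesign, build_feedback, gen_round3, gen_votes, run_round

design = PanelDesign(
    items=(
        ("clear-favourite", "strong_include"),
        ("clear-reject", "strong_exclude"),
        ("contested", "equivocal"),
        ("warming-up", "converging"),
    ),
    n_panelists=76,
    seed=11,
)

round2 = gen_votes(design)
result2 = run_round(round2)
print("round 2 decisions:")
for item_id, decision in result2.decisions.items():
    s = result2.summaries[item_id]
    print(f"  {item_id:16s} median={s.median:.1f} iqr={s.iqr:.1f} "
          f"%agree={s.pct_agree:5.1f} -> {decision.label}")

feedback = []
for item_id in result2.carried_forward:
    own = {pid: int(round2.scores[p, round2.item_ids.index(item_id)])
           for p, pid in enumerate(round2.panelist_ids)}
    feedback.extend(build_feedback(item_id, result2.summaries[item_id],
                                   "equivocal", own))

round3 = gen_round3(round2, feedback, design)
result3 = run_round(round3)
print("round 3 (re-voted equivocal items):")
for item_id, decision in result3.decisions.items():
    s = result3.summaries[item_id]
    print(f"  {item_id:16s} median={s.median:.1f} iqr={s.iqr:.1f} "
          f"%agree={s.pct_agree:5.1f} -> {decision.label}")

# The forced archetypes decide immediately; the converging item typically
# crosses the 75% supermajority only after dissenters move to the median,
# while the uniform item stays equivocal and would end as "no consensus".
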