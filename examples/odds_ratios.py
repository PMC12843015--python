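"""Odds-ratio analogue of the correlated relative-risk comparison.

With a frequent outcome (90% / 80% / 60% unfavorable) the odds ratio
exaggerates the relative effect: the same trial that shows a 33% relative
risk-reduction shows a ~167% odds-ratio reduction.  The OR route is the one
to use when the study design only identifies odds (e.g. case-control data);
for rare outcomes the two coincide.
"""

from corrisk import compare_or, compare_rr, make_table, render_report

table = make_table([54, 6, 48, 12, 36, 24])

rr = compare_rr(table)
odds = compare_or(table)
print(render_report({"or": odds}))

print(
    f"OR reduction {odds.ror_reduction_percent:.2f}% vs RR reduction "
    f"{rr.rld_percent:.3f}%:\nthe odds ratio overstates the benefit because "
    "the unfavorable event is common.\nBoth tests reject equality of the two "
    f"relative effects (p = {odds.p_interaction:.5f} vs {rr.p_interaction:.5f})."
)
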