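"""Match prioritized alterations against the bundled druggability rules.

The rules table (gene + alteration pattern -> drug, predicted effect,
evidence level) is an illustrative, editable fixture — not clinical
guidance.  A variant may match several rules; matches sort strongest
evidence first (FDA > NCCN > trials > case report > pre-clinical).
"""

from somascape import (
    default_rules,
    expand_carriers,
    match_rules,
    summarize_actionability,
    table4_records,
)

calls = expand_carriers(table4_records())  # the 16 recurrent variants
report = match_rules(calls, default_rules())
summary = summarize_actionability(report, n_samples=50)

print(
    f"patients with >=1 predicted druggable alteration: "
    f"{summary.n_druggable} ({100 * summary.fraction_druggable:.0f}% of 50)"
)
print(f"per-patient match counts: {summary.min_matches}..{summary.max_matches}\n")
sid = "C273T"  # a KRAS G12D carrier
for m in report.matches[sid]:
    print(
        f"{sid}: {m.rule.gene} {m.variant.aa_change} -> "
        f"{m.rule.effect.value} to {m.rule.drug} [{m.rule.evidence.value}]"
    )
# KRAS G12D predicts resistance to EGFR/ERBB2 monoclonal antibodies and
# response to MEK-combination regimens, each at its evidence level
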