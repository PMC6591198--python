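"""Retention screening of the published 69-item provisional questionnaire.

Loads the packaged per-item table of the QLQ-AA/PNH phase-III study
(48 patients, 69 four-point Likert items), tallies the eight retention
criteria, and applies the recorded expert-panel decisions.
"""

import itemscreen as its

stats, flags, decisions = its.load_phase3_item_table()

totals = its.tabulate_flags(flags)
print(f"items analysed:                  {totals.n_items}")
print(f"criterion passes c1..c8:         {totals.as_tuple()[:8]}")
print(f"keep-rule passes (>=5 of c1-7, or c8): {totals.overall}")
# 67 of 69 items pass the a-priori keep rule; only s34 and s50 fail it.

roster = its.apply_group_decisions(flags, decisions)
print(f"\nexpert decisions: {roster.n_keep} kept, {roster.n_delete} deleted, "
      f"{roster.n_change} changed, {roster.n_expand} expanded")
print(f"final questionnaire size: {roster.final_item_count} items")
# The panel may override the screen (to shorten the instrument); the
# items it removed despite a passing screen are listed here:
print(f"screen overrides: {', '.join(roster.discordant)}")

print("\nfirst rows of the rendered report:")
print("\n".join(its.render_table(stats, flags, decisions,
                                 fmt="markdown").splitlines()[:6]))
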