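# itemscreen

Item analysis and retention screening for Likert questionnaire
development, built around the phase-III pretesting pipeline of the
QLQ-AA/PNH quality-of-life instrument for patients with acquired
aplastic anaemia (AA) and/or paroxysmal nocturnal haemoglobinuria
(PNH).

In EORTC-style module development, a provisional questionnaire (here
69 items answered 1 "not at all" to 4 "very much") is administered to
a small cohort (here 48 patients) together with a debriefing interview
(was the item upsetting? difficult to understand? especially relevant?
was anything missing?). Each item is then screened against eight
a-priori criteria, and an expert panel decides what stays.

## What the package computes

For each item *i*, with the enrolled cohort of size *n* as denominator
for all fractions (missing responses count in neither category):

- mean over non-missing responses, observed range;
- `frac_low` (share scoring 1–2), `frac_high` (share scoring 3–4),
  compliance = `frac_low + frac_high`;
- debriefing fractions: upsetting, difficult, priority.

The eight retention criteria (strict inequalities except c8):

| # | criterion | rule |
|---|-----------|------|
| 1 | relevance | mean > 1.5 |
| 2 | relevance | frac_high > 50% |
| 3 | no floor/ceiling | frac_low > 10% and frac_high > 10% |
| 4 | range | responses span the full 1–4 scale |
| 5 | acceptability | < 5% found it upsetting |
| 6 | easiness | < 5% found it difficult |
| 7 | compliance | > 95% completed it |
| 8 | priority | ≥ 2% named it especially relevant |

**Keep rule:** an item is screened as *keep* when at least five of
criteria 1–7 hold, or criterion 8 holds. A missing issue is added when
at least five distinct patients mention it. Internal consistency of a
hypothesised k-item scale is Cronbach's

    alpha = k/(k-1) * (1 - sum_i var(item_i) / var(total score))

over listwise-complete patients. Reverse-coded items (those worded so
high raw scores mean fewer problems) are recoded x → 5 − x first.

The package ships the published study's complete per-item table
(statistics, printed criterion flags, and the expert panel's decision
for every one of the 69 items) and a synthetic-cohort generator with a
single-factor-per-scale latent model, so every stage is testable
without patient data.

## Worked example

```python
import itemscreen as its

stats, flags, decisions = its.load_phase3_item_table()
totals = its.tabulate_flags(flags)
print(totals.as_tuple())    # (69, 17, 69, 69, 69, 63, 57, 23, 67)

roster = its.apply_group_decisions(flags, decisions)
print(roster.n_keep, roster.final_item_count)   # 47 54
```

All 69 items had mean > 1.5 and spanned the full range; 17 had a
majority scoring 3–4; 57 met the 95% compliance bar; 23 were named
especially relevant by ≥ 2% of patients; 67 passed the keep rule. The
panel kept 47 items unchanged, deleted 16, reworded 5, and split one
into two — a 54-item final questionnaire. The `examples/` directory
has narrative scripts for the published table, a synthetic end-to-end
run, and alpha recovery against its closed form.

A thin CLI mirrors the stages
(`itemscreen simulate | stats | criteria | alpha | report | pipeline`):

```sh
itemscreen simulate --seed 1 --out cohort/
itemscreen pipeline --responses cohort/responses.csv \
    --questionnaire cohort/questionnaire.yaml --debrief cohort/debrief \
    --out report/
```

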