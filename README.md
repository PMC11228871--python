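# coldscreen

Analysis pipeline for **temperature-differential synthetic genetic array
(SGA) screens** — genome-wide colony-growth screens in which a query mutant
(e.g. fission-yeast *taz1Δ*, whose telomere entanglements are lethal in the
cold) is crossed into an arrayed deletion library and the double/triple
mutants are grown in parallel at a permissive reference temperature (30 °C)
and a restrictive cold temperature (19 °C). It is written for groups running
arrayed plate screens who need a reproducible, testable route from raw
colony-size tables to classified genetic interactors and ontology-group
enrichments.

## The statistics at the core

For every colony, growth is normalized to its plate (removing plate-to-plate
multiplicative effects):

```
NG = colony size / median colony size on that plate
```

Per gene and temperature, replicate NG values (technical triplicates) are
aggregated by their median. The cold-specificity statistic is the
**normalized growth ratio**

```
NGR = NG(19 °C) / NG(30 °C)
```

NGR > 1 means relatively better growth in the cold (a candidate suppressor
of the query's cold sensitivity); NGR < 1 means cold-specific sickness; the
interaction measure at the permissive temperature is log₂ NG(30 °C).
Outliers ("hits") on the log₂ statistics are assigned either as the **top
25th percentile** of a tail or by the **2 SD rule** (≥ 2 sample SDs from the
distribution median). Across the five parallel query screens (*taz1*,
*rif1*, *S-rif1⁺*, *taz1 rif1*, *taz1 S-rif1⁺*) hits are combined into three
classes: query-specific synthetic-sick interactors, cold-sensitivity
suppressors, and **reverters** — deletions that abolish suppression in both
double-query screens without affecting the single mutants. Hit sets are
tested for ontology-group over-representation with a one-sided
hypergeometric test and Benjamini–Hochberg adjustment.

A synthetic-screen generator (`coldscreen.synthetic_data`) produces colony
tables with the same structure — log-normal colony noise, per-plate
multiplicative effects, dropout, triplicates — plus a ground-truth table of
planted interactions, so the whole pipeline is testable end to end.

## Worked example

```
coldscreen run-all --seed 11 --out-dir runs/demo
```

runs a full simulated five-screen study (2,000 genes by default) through
scoring, hit calling, classification and enrichment, and prints:

```
run complete; report at runs/demo/report.json
  none: 1265
  cs_suppressor: 470
  taz1_specific_negative_30: 147
  reverter: 118
```

Here 470 genes fall in the top quartile of the *taz1* screen's log₂ NGR
(the planted suppressors plus the upper tail of the background interaction
spectrum), 147 genes are *taz1*-specific negative interactors at 30 °C
after filtering out genes that behave similarly with *rif1*, and 118 genes
are cold-specific negative hits in both double-query screens while staying
quiet in both single-mutant screens — the 40 planted reverters plus chance
intersections of the two screens' bottom quartiles, an inherent property of
rank-based calling (the stricter 2 SD caller, `hit_method: two_sd`, prunes
these). `runs/demo/` also holds the per-gene score tables, hit lists with
the thresholds used, the Venn partition of the double-screen hit sets, the
enrichment tables, and `report.json` with per-stage row counts and the
echoed configuration.

The same stages are available programmatically
(`score_screen`, `call_hits_percentile` / `call_hits_two_sd`,
`classify_suppressors` / `classify_reverters`, `enrich`) and as individual
CLI subcommands (`simulate`, `score`, `call-hits`, `classify`, `enrich`).

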