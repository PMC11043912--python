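# mtlnova

Tools for asking how far the UK's multiple-traffic-light (MTL)
front-of-pack nutrient labelling overlaps with the NOVA food-processing
classification, on any food-composition databank with per-100 g nutrient
content. Written for nutrition epidemiologists and food-policy analysts
who want the whole comparison — scoring engine, hyper-palatability
criteria and statistical battery — as one tested, reusable pipeline.

## What it computes

**Traffic lights.** Each of fat, saturated fat, total sugar and salt is
coloured against the DH/FSA cut-offs (per 100 g of food, stricter per
100 ml of drink): green iff value ≤ low bound, red iff value > high
bound, amber otherwise. Composites per item: red/green counts, any-red /
any-green flags, the continuous MTL score

MTL = Σ₄ s(light),  s(green)=1, s(amber)=2, s(red)=3  ∈ [4, 12]

and an 8-level ordinal version merging the rare top scores {11, 12}.
Cut-offs ship as versioned JSON data and can be swapped without code
changes.

**Hyper-palatable foods (HPF).** A food is hyper-palatable when it
exceeds any of three paired thresholds on energy fractions and sodium
mass fraction: fat+Na (>25 % kcal from fat, ≥0.30 % Na by weight),
fat+sugar (>20 % kcal each), carb+Na (>40 % kcal from carbohydrate,
≥0.20 % Na). Sodium falls back to salt/2.5 when not recorded; drinks are
out of the definition's scope.

**Statistics.** Per NOVA group (MPF, PCI, PF, UPF) the pipeline reports
median/IQR nutrient summaries with Kruskal–Wallis + Dunn/Bonferroni,
light-distribution χ² tests, binary logistic odds ratios for any-red and
any-green (Woolf/Wald, Haldane–Anscombe corrected on separation),
proportional-odds (cumulative-logit) models of red counts, green counts
and the MTL score with PCI+PF pooling, a median-split and linear-model
sensitivity battery, "no red" and "no red + ≥2 green" subgroup analyses,
and HPF proportions among foods.

## Worked example

```
python examples/printed_counts_study.py
```

builds the deterministic built-in fixture databank (3105 items, of which
109 are outside the NOVA classification and 16 lack nutrient linkage,
leaving 2980), runs the full study and prints, among other tables:

```
 analysis      contrast    or  ci_low  ci_high
  any_red    PCI vs MPF 28.54   13.80    59.05
  any_red     PF vs MPF  3.69    2.76     4.92
  any_red    UPF vs MPF  4.59    3.79     5.57
any_green PCI+PF vs MPF  0.08    0.04     0.18
any_green    UPF vs MPF  0.05    0.02     0.10
```

i.e. ultra-processed items have 4.59 (95 % CI 3.79–5.57) times the odds
of carrying at least one red light relative to minimally processed
foods, and 0.05 (0.02–0.10) times the odds of carrying a green one; the
no-red ("healthy") subgroup is 61.9 % of items, 46.3 % of it
ultra-processed; 79.8 % of hyper-palatable foods are ultra-processed.
Other examples: `examples/score_items.py` (per-item scoring),
`examples/hyperpalatability.py` (HPF clusters),
`examples/synthetic_study.py` (parameter recovery on a synthetic
databank).

A thin CLI wraps the same functions:

```
mtlnova fixture --out bank.csv          # emit the fixture databank
mtlnova simulate --out synth.csv --seed 7   # draw a synthetic databank
mtlnova profile bank.csv --out lights.csv   # per-item traffic lights
mtlnova run bank.csv --outdir results/      # full study tables
```

## Your own databank

One CSV row per item: `item_id`, `nova_group` (MPF/PCI/PF/UPF/EXCLUDED
or NOVA codes 1–4), `is_drink`, `energy_kcal`, `fat_g`, `satfat_g`,
`sugar_g`, `salt_g`, optionally `sodium_g`, `protein_g`, `fibre_g`,
`carb_g`, `water_g`, `name`, `subgroup_code`; different headers can be
mapped via the `schema` argument of `read_databank`. Items coded
EXCLUDED or missing any scoring nutrient are removed (with a removal
report) before analysis.

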