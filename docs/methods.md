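# Methods

## Scope and model

The package compares food/drink items across NOVA processing groups
(minimally processed foods MPF, processed culinary ingredients PCI,
processed foods PF, ultra-processed foods UPF) on three axes: UK
multiple-traffic-light (MTL) front-of-pack scoring, hyper-palatability
criteria, and per-100 g nutrient content. All analyses are per 100 g of
food or 100 ml of drink (assumed equivalent; no density correction) and
unadjusted: group is the only covariate anywhere.

## Traffic-light scoring

Cut-offs are the DH/FSA 2016 guidance values, shipped as JSON
(`mtlnova/data/thresholds_fsa_2016.json`), per 100 g food / 100 ml
drink:

| nutrient | food low ≤ | food high > | drink low ≤ | drink high > |
|---|---|---|---|---|
| fat | 3.0 | 17.5 | 1.5 | 8.75 |
| saturated fat | 1.5 | 5.0 | 0.75 | 2.5 |
| total sugars | 5.0 | 22.5 | 2.5 | 11.25 |
| salt | 0.3 | 1.5 | 0.3 | 0.75 |

Boundary convention: green includes its bound (≤), red strictly exceeds
its bound (>), so an item printed exactly at a "low" cut-off is green.
The drink "low" bounds are the guidance's nutrition-claim-based values;
where only the amber/red cut-offs differ from food (salt), the food low
bound is retained. Lights order GREEN < AMBER < RED; for a fixed basis
the assignment is monotone in the nutrient value, and a drink's light is
never below the same value's food light.

Composites: n_red, n_green, any-red, any-green; continuous MTL score
(green 1 / amber 2 / red 3, summed; range 4–12, equivalently
4 + n_amber + 2·n_red); 8-level ordinal score = min(score, 11) − 3,
merging continuous 11 (three reds + one amber) and 12 (four reds), which
are rare in real databanks.

## Hyper-palatability

Energy fractions use 9 kcal/g (fat) and 4 kcal/g (sugar, carbohydrate);
the carbohydrate factor is configurable because some UK composition
tables use 3.75. Sodium % by weight equals sodium g/100 g, taken from a
sodium column when present, else salt/2.5. Cluster inequalities are
applied exactly as defined (strict > on energy fractions, ≥ on sodium).
Zero-energy items have all fractions defined as 0 and are therefore
never hyper-palatable; drinks return `applicable=False` with all flags
false. A missing carbohydrate column disables only the carb+Na cluster
(with a warning).

## Statistics

* 2×2 odds ratios: Woolf — OR = ad/bc, SE(ln OR) = √(1/a+1/b+1/c+1/d),
  CI = exp(ln OR ∓ 1.96·SE). Any zero cell: Haldane–Anscombe +0.5 on all
  cells, flagged `corrected`. 1.96 (not the exact normal quantile) is
  used throughout, matching common software output.
* Binary logistic: Newton ML with dummy coding (tolerance 1e-10, ≤100
  iterations), Wald CIs. On a saturated design this reproduces the 2×2
  Woolf OR and SE exactly (tested to 6 significant digits). Contrasts
  with a zero cell (separation) are excluded from the ML fit and
  reported via the corrected 2×2 instead.
* Proportional odds: cumulative-logit model, BFGS ML (gradient tolerance
  1e-8, ≤200 iterations; non-convergence raises with the gradient norm).
  OR > 1 means higher odds of more-extreme levels toward the top of the
  scale. With two outcome levels this reduces to binary logistic
  (tested to 4 decimals against an independent likelihood maximiser).
* Kruskal–Wallis: tie-corrected H, χ² reference on k−1 df. All-identical
  samples short-circuit to H = 0, p = 1 (the tie correction would
  otherwise zero the denominator). Post-hoc: Dunn's z on pooled ranks
  with the tie-corrected variance, Bonferroni over all k(k−1)/2 pairs —
  the standard follow-up when only "Bonferroni correction" is specified.
* Mann–Whitney: tie-corrected normal approximation with continuity
  correction (within 0.01 of exhaustive enumeration at n ≤ 8).
* χ²: Pearson, no continuity correction; zero margins are errors naming
  the offending row/column.
* Median/IQR: the (n+1)p weighted-average quantile convention (numpy
  `method="weibull"`, SPSS HAVERAGE): {1,2,3,4,5} → 3 (1.5, 4.5). Other
  conventions differ by at most one order-statistic gap; the choice is
  fixed for reproducibility.
* Median splits dichotomise at the whole-sample median with event =
  strictly above; constant samples make the outcome constant and are
  rejected rather than modelled.
* Linear score models: OLS with dummy coding; coefficients equal
  group-mean differences; t-based CIs; groups with <2 items dropped.

## Pipeline conventions

Reference group MPF everywhere. PCI and PF are pooled ("PCI+PF") for the
ordinal models and the binary any-green model, where sparse cells make
separate estimates unstable; the any-red binary model keeps all four
groups. Energy density = kcal/100 g ÷ 100 (kcal/g). All location
summaries are median/IQR (nutrient content is strongly right-skewed);
means are never reported. Subgroups: "healthy" = no red light; the
stricter sensitivity subgroup additionally requires ≥2 greens; subgroup
sets are nested by construction. HPF denominators exclude drinks.
Re-running the study on identical inputs writes byte-identical tables.
Pairwise group comparisons are emitted as a Bonferroni-adjusted p-value
matrix rather than letter groupings (presentation-only and
convention-dependent).

## Synthetic databanks

`generate_databank` draws each nutrient from a log-normal
(median · exp(σZ)) per group — matching the median ≪ IQR-width skew of
real composition data — then clips saturated fat to fat and sugar to
carbohydrate, resamples compositions exceeding 100 g solids/100 g
(count recorded in provenance), sets water = 100 − solids and derives
energy as 9·fat + 4·carb + 4·protein + 2·fibre unless an explicit energy
distribution is configured. Drinks are a configured leading fraction of
each group with draws scaled by a dilution factor (default 0.3).

The default scenario fixes group sizes 1650/986/283/61
(UPF/MPF/PF/PCI — shares 55.4/33.1/9.5/2.0 % of 2980) and log-normal
medians placing UPF above MPF in fat (9 vs 1.2 g), sugar (8 vs 4 g),
salt (0.8 vs 0.1 g) and derived energy density (≈1.8 vs ≈0.6 kcal/g),
with PF intermediate and PCI fat/salt-heavy with few items. These
defaults are the study conditions, not tuning knobs. What the generator
does **not** emulate: real food names/subgroups, nutrient correlations
beyond the composition constraints, and the exact real-databank medians
(unidentifiable from marginal summaries) — so passing recovery tests
shows the pipeline detects orderings and OR directions under realistic
skew, not that it reproduces any real survey's magnitudes.

`fixture_printed_counts` is the complement: a deterministic databank of
archetype items hitting target marginal counts per group exactly —
any-red, no-green, no-red-with-≥2-green, drinks and the three HPF
cluster memberships (with a cluster-1∩2 overlap category). Margins are
allocated to four light patterns (GGGG; one green + three ambers; one
red + three ambers; one red + one green + two ambers) with
hyper-palatable categories packed into compatible patterns; infeasible
margin combinations raise an error naming the violated constraint. The
default spec realizes the published analysis of 2980 UK items, including
109 excluded and 16 nutrient-incomplete padding rows so filtering is
exercised. Archetype values sit ≥10 % from every default cut-off, so
realized margins are invariant to ±8 % threshold perturbations (tested).
The fixture realizes marginal outcome counts, not joint nutrient
realism: its medians and ordinal-model magnitudes are not meaningful,
only its contingency-derived quantities are.

## Problem sizes and runtime

The full pipeline on 2980 items runs in ≈1.5 s. The test suite uses 2000
null replicates for type-I calibration (Monte-Carlo SE ≈0.005 on a 0.05
rate, so the ±0.01 acceptance band is a ≈2σ check) and 20 full-scale
synthetic replicates for parameter recovery; scaled-down databanks
(`scale` parameter) are used where only plumbing is under test.

## Known limitations

Per-100 g comparability ignores portion sizes. Total sugar stands in for
the HPF definition's "naturally occurring or added sugars" (composition
databanks carry total sugar only). Drink MTL "low" bounds and the split
of some published marginals across PCI/PF are under-determined by public
sources; the shipped values document the choices made (see the fixture
spec) and are swappable data. Proportional-odds fits assume a common
group effect across category splits; no proportionality diagnostic is
emitted. No survey weighting or covariate adjustment is implemented.
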