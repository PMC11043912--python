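"""Generate a synthetic databank and check what the pipeline recovers.

The default scenario draws 2980 items (55.4 % UPF, 33.1 % MPF, 9.5 % PF,
2.0 % PCI) with right-skewed log-normal nutrient content, UPF shifted
above MPF in fat, sugar, salt and energy density. Running the study on
such a draw should recover those orderings and the any-red / any-green
odds-ratio directions. A scale factor shrinks the databank for a quick
run.
"""

from mtlnova import AnalysisConfig, default_scenario, generate_databank, run_study

bank = generate_databank(default_scenario(seed=7, scale=0.5))
print(bank.provenance)

report = run_study(bank, AnalysisConfig(seed=7))
s = report.nutrient_summary
for nutrient in ("fat", "sugar", "salt", "energy_density_kcal_per_g"):
    row = {
        g: s[(s.nutrient == nutrient) & (s.nova_group == g)]["median"].iloc[0]
        for g in ("MPF", "UPF")
    }
    print(f"median {nutrient:28s} MPF {row['MPF']:7.2f}   "
          f"UPF {row['UPF']:7.2f}   (expect MPF < UPF)")

b = report.binary_or
for analysis in ("any_red", "any_green"):
    row = b[(b.analysis == analysis) & (b.contrast == "UPF vs MPF")].iloc[0]
    print(f"UPF vs MPF {analysis:10s} OR {row['or']:6.2f} "
          f"({row['ci_low']:.2f}-{row['ci_high']:.2f})")

# The any-red OR lands well above 1 and the any-green OR well below 1:
# the generator's processing-group contrasts are recoverable end to end.
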