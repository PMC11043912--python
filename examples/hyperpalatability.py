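"""Classify items against the three hyper-palatable food (HPF) clusters.

An item is hyper-palatable when it exceeds paired thresholds on energy
fractions and sodium mass fraction: fat+sodium (>25 % kcal fat, >=0.30 %
Na), fat+sugar (>20 % kcal each) or carbohydrate+sodium (>40 % kcal carb,
>=0.20 % Na). Drinks are outside the definition's scope.
"""

from mtlnova import FoodItem, NovaGroup, classify_hpf

items = [
    FoodItem("bacon", NovaGroup.PF, False, energy_kcal=290, fat_g=22,
             satfat_g=8, sugar_g=0.5, salt_g=2.3, carb_g=0.5,
             name="back bacon"),
    FoodItem("biscuit", NovaGroup.UPF, False, energy_kcal=480, fat_g=22,
             satfat_g=11, sugar_g=30, salt_g=0.6, carb_g=62,
             name="chocolate biscuit"),
    FoodItem("lettuce", NovaGroup.MPF, False, energy_kcal=15, fat_g=0.2,
             satfat_g=0.05, sugar_g=1.2, salt_g=0.01, carb_g=1.7,
             name="lettuce"),
]

for item in items:
    res = classify_hpf(item)
    flags = [name for name, on in (
        ("fat+Na", res.cluster_fat_na),
        ("fat+sugar", res.cluster_fat_sugar),
        ("carb+Na", res.cluster_carb_na),
    ) if on]
    print(f"{item.name:18s} kcal from fat {res.frac_kcal_fat:5.1%}  "
          f"sugar {res.frac_kcal_sugar:5.1%}  carb {res.frac_kcal_carb:5.1%}  "
          f"Na {res.na_pct_weight:.2f} % wt  "
          f"HPF={'yes (' + ', '.join(flags) + ')' if res.any_hpf else 'no'}")

# Bacon trips the fat+Na cluster (68 % of kcal from fat, 0.92 % Na); the
# biscuit trips fat+sugar (41 % / 25 % of kcal) and carb+Na; lettuce, with
# almost no fat or sodium, trips nothing despite its high carb fraction.
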