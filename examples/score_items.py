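"""Traffic-light score a handful of items and print their MTL profiles.

Each of fat, saturated fat, total sugar and salt is coloured green/amber/
red against the UK per-100 g (food) or per-100 ml (drink) cut-offs; the
continuous MTL score sums green=1/amber=2/red=3 over the four lights
(4 = healthiest, 12 = least healthy).
"""

from mtlnova import FoodItem, NovaGroup, default_thresholds, profile_item

items = [
    FoodItem("apple", NovaGroup.MPF, False, energy_kcal=52, fat_g=0.2,
             satfat_g=0.05, sugar_g=10.4, salt_g=0.01, name="apple"),
    FoodItem("crisps", NovaGroup.UPF, False, energy_kcal=530, fat_g=34,
             satfat_g=3.5, sugar_g=0.5, salt_g=1.6, name="potato crisps"),
    FoodItem("cola", NovaGroup.UPF, True, energy_kcal=42, fat_g=0.0,
             satfat_g=0.0, sugar_g=10.6, salt_g=0.02, name="cola (drink)"),
]

cfg = default_thresholds()
for item in items:
    prof = profile_item(item, cfg)
    lights = "/".join(l.name[0] for l in prof.lights)
    print(f"{item.name:16s} lights(F/SF/TS/Salt)={lights}  "
          f"reds={prof.n_red} greens={prof.n_green}  "
          f"MTL score={prof.mtl_continuous} (ordinal level "
          f"{prof.mtl_ordinal8})")

# The apple's 10.4 g sugar is amber (above the 5 g food "low" bound); the
# cola's 10.6 g is also amber on the stricter drink basis but would turn
# red above 11.25 g/100 ml. The crisps carry red fat and red salt for an
# MTL score of 9 on the 4-12 scale.
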