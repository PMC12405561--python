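"""Roll component measurements up the eight-level summation hierarchy.

A temperate forest site with stem, branch, both litter fractions and both
root fractions measured, and the herb/shrub/moss layer verified absent.
Herbivory was never measured, so the broadest total stays incomplete — the
hierarchy distinguishes "absent" from "nobody looked".
"""

from nppdb import Biome, Component, compute_levels

levels = compute_levels(
    {
        Component.STEM: 400.0,
        Component.BRANCH: 80.0,
        Component.FOLIAGE_LITTER: 300.0,
        Component.EXTRA_LITTER: 50.0,
        Component.FINE_ROOT: 350.0,
        Component.COARSE_ROOT: 90.0,
    },
    absent={Component.HERB, Component.SHRUB, Component.NON_VASCULAR},
    biome=Biome.FOREST,
)

for name, lv in levels.as_dict().items():
    value = f"{lv.value:7.1f}" if lv.value is not None else "      –"
    print(f"{name:22s} {value}  [{lv.status.value}]")
# wood = stem+branch, litterfall = leaf+extra litter, tree = wood+litterfall,
# BNPP = fine+coarse roots; total 1 = tree + non-tree + BNPP (g m^-2 yr^-1);
# total 2 additionally needs herbivory, which is unmeasured here
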