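"""Köppen-Geiger main class and aridity class from monthly normals."""

from nppdb import ClimateNormals, aridity, koppen_main_class

examples = {
    "lowland tropics": ClimateNormals(
        "demo1", [26.5] * 12, [160.0] * 12, [120.0] * 12),
    "continental interior": ClimateNormals(
        "demo2",
        [-12, -10, -4, 4, 11, 16, 18, 16, 10, 3, -5, -10],
        [25, 22, 28, 35, 50, 70, 80, 70, 55, 40, 32, 28],
        [5, 8, 20, 50, 90, 110, 120, 100, 60, 30, 10, 5]),
    "desert margin": ClimateNormals(
        "demo3", [12, 14, 18, 22, 27, 30, 32, 31, 28, 22, 16, 12],
        [8, 6, 5, 3, 1, 0, 0, 0, 1, 3, 6, 9],
        [90, 110, 150, 190, 230, 260, 270, 250, 200, 150, 100, 85]),
}

for label, normals in examples.items():
    region = koppen_main_class(normals)
    res = aridity(sum(normals.monthly_precipitation),
                  sum(normals.monthly_pet))
    print(f"{label:22s} -> {region.value:9s}  AI = {res.ai:5.2f} "
          f"({res.aridity_class.value})")
# the Köppen main class comes from the warmest/coldest month and a dryness
# threshold; AI = annual precipitation / annual PET, with AI << 1 marking a
# water deficit
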