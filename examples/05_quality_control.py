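"""Technical-validation checks: coordinates, summation audit, outliers."""

import pandas as pd

from nppdb import SynthConfig, flag_outliers, generate_database, run_qc
from nppdb.uncertainty import site_class_values

db = generate_database(SynthConfig(n_sites=120, seed=3))
report = run_qc(db)
print(f"coordinate issues: {len(report.coordinate_issues)}")
print(f"outliers flagged (biome-stratified boxplot rule, k=1.5): "
      f"{len(report.outliers)}")
for f in report.outliers[:3]:
    print(f"  {f.site_id} {f.variable}={f.value:.0f} outside "
          f"[{f.fence_low:.0f}, {f.fence_high:.0f}] in {f.stratum}")
# flagged sites are candidates for a manual double-check, not deletions:
# QC only reports, it never mutates the data

# an obvious transcription error stands out against its stratum
demo = pd.DataFrame(
    [{"site_id": f"s{i}", "biome": "grassland", "anpp": v, "bnpp": None}
     for i, v in enumerate([410, 450, 480, 510, 560, 4800])]
)
for f in flag_outliers(demo):
    print(f"typo candidate: {f.site_id} ANPP={f.value:.0f} "
          f"(fences {f.fence_low:.0f}..{f.fence_high:.0f})")
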