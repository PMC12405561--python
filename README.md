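# nppdb

Tools for building and analysing harmonized site-level databases of
terrestrial **net primary production** (NPP).

Field NPP estimates are scattered across six decades of literature, measured
with methods of very different quality, reported for different subsets of
plant components (stemwood, foliage litter, herbs, fine roots, …), and often
only partially summed.  A usable global compilation therefore needs, beyond
the data themselves: a controlled component vocabulary with referential
validation, a gated summation hierarchy that distinguishes "component absent"
from "component never measured", a *harmonized* measurement uncertainty that
can be compared across studies, rule-based biome/management and climate
classification, and quality-control checks.  `nppdb` implements that whole
pipeline, plus a synthetic-database generator so every stage can be tested
end to end without any external download.

## The uncertainty model

Reported uncertainties cannot be pooled across methodologies, so every
measurement receives a harmonized uncertainty built from the data and a
method catalogue:

- **Biome spread** — for biome *i* and component class *k* ∈ {ANPP, BNPP,
  TNPP}: `P_i^k = (D90_i^k − D10_i^k) / 2`, half the 90th–10th
  interpercentile range of site-level values, derived from the database
  itself.
- **Per-measurement uncertainty** — `S_ij^k = P_i^k · RF_j^k / √(l_ij^k)`,
  where `RF_j^k ∈ (0, 1]` is the method's reduction factor (19 catalogued
  methods: 7 aboveground, 8 belowground, 4 whole-plant; more accurate method
  ⇒ smaller RF) and `l` is the measurement-series length in years.
- **Combined RF** — when one main part used several methods, the mean RF
  rounded to one decimal, with exact midpoints resolved toward the dominant
  component (fine roots for belowground production).  Example: minirhizotron
  fine roots (0.3) + allometric coarse roots (0.6) → 0.45 → **0.4**.
- **Propagation** — `S^TNPP = √((S^ANPP)² + (S^BNPP)²)` per measurement, and
  `S_i^k = √(Σ_j S_ij^k²) / N_i^k` across the `N_i^k` measurements of a site.

The resulting `1/S²` weights plug into nonlinear climate–NPP regression
(the Miami model, `NPP = min(A/(1+e^(b−cT)), A(1−e^(−dP)))`), where
down-weighting noisy high-productivity sites can substantially lower the
fitted NPP surface relative to an unweighted fit.

## Worked example

```python
>>> from nppdb import average_rf, compute_levels, Biome, Component
>>> average_rf([0.3, 0.6], dominant_rf=0.3)   # the combined belowground RF
0.4
>>> levels = compute_levels(
...     {Component.STEM: 400, Component.BRANCH: 80,
...      Component.FOLIAGE_LITTER: 300, Component.EXTRA_LITTER: 50,
...      Component.FINE_ROOT: 350, Component.COARSE_ROOT: 90},
...     absent={Component.HERB, Component.SHRUB, Component.NON_VASCULAR},
...     biome=Biome.FOREST)
>>> levels.total_npp_1.value
1270.0
>>> levels.total_npp_2.status.value   # herbivory never measured
'incomplete'
```

Wood ANPP is 480 (stem + branch), litterfall 350, tree ANPP 830, BNPP 440,
and total NPP 1 = 1270 g m⁻² yr⁻¹; the broadest total stays gated because
herbivory was neither measured nor verified absent.

The `examples/` directory holds one short script per capability
(validation, summation, uncertainty, climate classification, QC, weighted
regression).  For instance `python examples/03_uncertainty.py` prints:

```
combined BNPP RF: 0.4
same answer via the pipeline: 0.4
S(P=100, RF=0.4, l= 1) = 40.0
S(P=100, RF=0.4, l= 4) = 20.0
S(P=100, RF=0.4, l=16) = 10.0
```

— the combined reduction factor, and the 1/√l payoff of longer measurement
series.

A thin CLI wraps the same functions for shell use:

```bash
nppdb simulate --n-sites 100 --seed 17 --out ./demo_db
nppdb validate ./demo_db
nppdb summarize ./demo_db --out levels.csv
nppdb uncertainty ./demo_db --out s.csv
nppdb qc ./demo_db --report qc.json
```

## Layout

```
src/nppdb/
  schema.py          typed data model + the 19-method RF catalogue
  io.py              CSV / SQLite reading, writing, row-level validation
  summation.py       the eight gated summation levels; main/minor audits
  uncertainty.py     P spreads, S values, RF averaging, propagation
  classification.py  biome & management rules, aridity, Köppen main class
  qc.py              coordinate / summation / outlier checks
  regression.py      Miami model, weighted fits, fit comparison
  synthetic.py       seeded synthetic database generator
  cli.py             thin click wrapper
docs/methods.md      model assumptions, conventions, limitations
examples/            one narrative script per capability
```
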