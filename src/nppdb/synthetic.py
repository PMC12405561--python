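"""Synthetic multi-table NPP databases with realistic statistical structure.

The generator emulates the structure of a harmonized global NPP compilation:
sites spread over six biomes and five Köppen climate regions, component-level
production records with method tags from the catalogue, series lengths of
1–16 years (42 % single-year, half between 2 and 5 years), a fraction of
sites carrying only a whole-plant NPP estimate, and managed/unmanaged
labels.  Site climate normals are drawn from per-region monthly templates
chosen so they classify back to the intended Köppen class, true NPP follows
a Miami-type surface over the site's mean annual temperature and
precipitation, and observed component values are the true values plus
heteroscedastic noise whose spread scales with the method reduction factor
and shrinks with 1/√(series length) — mirroring the uncertainty model the
pipeline assumes.

One global seed governs everything through named sub-streams, so adding a
new table or field never perturbs draws made for existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .regression import CLASSIC, MiamiParams, miami_predict
from .schema import (
    Biome,
    ClimateNormals,
    ClimateRegion,
    Component,
    Database,
    Fertility,
    Management,
    METHOD_CATALOGUE,
    NppRecord,
    SiteRecord,
    StudyType,
)

#: Observed global biome counts used as default mixing proportions
#: (forest, grassland, cropland, peatland, tundra, dry shrubland out of 456).
DEFAULT_BIOME_MIX: dict[Biome, float] = {
    Biome.FOREST: 206 / 456,
    Biome.GRASSLAND: 145 / 456,
    Biome.CROPLAND: 34 / 456,
    Biome.PEATLAND: 34 / 456,
    Biome.TUNDRA: 21 / 456,
    Biome.DRY_SHRUBLAND: 16 / 456,
}

DEFAULT_CLIMATE_MIX: dict[ClimateRegion, float] = {
    ClimateRegion.COLD: 191 / 455,
    ClimateRegion.TEMPERATE: 125 / 455,
    ClimateRegion.TROPICAL: 80 / 455,
    ClimateRegion.ARID: 45 / 455,
    ClimateRegion.POLAR: 14 / 455,
}

#: Climate regions a biome can plausibly occupy.
_COMPATIBLE_REGIONS: dict[Biome, tuple[ClimateRegion, ...]] = {
    Biome.FOREST: (ClimateRegion.TROPICAL, ClimateRegion.TEMPERATE,
                   ClimateRegion.COLD),
    Biome.GRASSLAND: (ClimateRegion.TROPICAL, ClimateRegion.ARID,
                      ClimateRegion.TEMPERATE, ClimateRegion.COLD),
    Biome.CROPLAND: (ClimateRegion.TROPICAL, ClimateRegion.ARID,
                     ClimateRegion.TEMPERATE, ClimateRegion.COLD),
    Biome.TUNDRA: (ClimateRegion.COLD, ClimateRegion.POLAR),
    Biome.PEATLAND: (ClimateRegion.COLD, ClimateRegion.POLAR),
    Biome.DRY_SHRUBLAND: (ClimateRegion.ARID, ClimateRegion.TEMPERATE),
}

#: Component split of true total NPP by biome (fractions sum to 1), and the
#: components verified absent.  Tree components are absent from herbaceous
#: biomes; the herb/shrub layer is absent under closed forest canopies.
_BIOME_FRACTIONS: dict[Biome, dict[Component, float]] = {
    Biome.FOREST: {
        Component.STEM: 0.28, Component.BRANCH: 0.07,
        Component.FOLIAGE_LITTER: 0.25, Component.EXTRA_LITTER: 0.04,
        Component.REPRODUCTIVE: 0.04, Component.HERBIVORY: 0.02,
        Component.FINE_ROOT: 0.24, Component.COARSE_ROOT: 0.06,
    },
    Biome.GRASSLAND: {
        Component.HERB: 0.55, Component.FINE_ROOT: 0.42,
        Component.HERBIVORY: 0.03,
    },
    Biome.CROPLAND: {
        Component.HERB: 0.60, Component.FINE_ROOT: 0.38,
        Component.HERBIVORY: 0.02,
    },
    Biome.TUNDRA: {
        Component.HERB: 0.30, Component.SHRUB: 0.25,
        Component.NON_VASCULAR: 0.10, Component.FINE_ROOT: 0.33,
        Component.HERBIVORY: 0.02,
    },
    Biome.PEATLAND: {
        Component.HERB: 0.28, Component.SHRUB: 0.22,
        Component.NON_VASCULAR: 0.18, Component.FINE_ROOT: 0.30,
        Component.HERBIVORY: 0.02,
    },
    Biome.DRY_SHRUBLAND: {
        Component.HERB: 0.25, Component.STEM: 0.15, Component.BRANCH: 0.05,
        Component.FOLIAGE_LITTER: 0.15, Component.EXTRA_LITTER: 0.02,
        Component.FINE_ROOT: 0.35, Component.HERBIVORY: 0.03,
    },
}

_BIOME_ABSENT: dict[Biome, tuple[Component, ...]] = {
    Biome.FOREST: (Component.HERB, Component.SHRUB, Component.NON_VASCULAR),
    Biome.GRASSLAND: (Component.SHRUB, Component.NON_VASCULAR,
                      Component.REPRODUCTIVE),
    Biome.CROPLAND: (Component.SHRUB, Component.NON_VASCULAR,
                     Component.REPRODUCTIVE),
    Biome.TUNDRA: (Component.REPRODUCTIVE,),
    Biome.PEATLAND: (Component.REPRODUCTIVE,),
    Biome.DRY_SHRUBLAND: (Component.SHRUB, Component.NON_VASCULAR,
                          Component.REPRODUCTIVE),
}

#: Candidate methods per component (ids into the catalogue).
_COMPONENT_METHODS: dict[Component, tuple[str, ...]] = {
    Component.STEM: ("AG_INC", "AG_INC_DEC", "AG_ALLOM"),
    Component.BRANCH: ("AG_INC", "AG_ALLOM"),
    Component.FOLIAGE_LITTER: ("AG_INC", "AG_INC_DEC"),
    Component.EXTRA_LITTER: ("AG_INC",),
    Component.REPRODUCTIVE: ("AG_INC", "AG_FIXPROP"),
    Component.HERB: ("AG_PEAK", "AG_MAXMIN", "AG_INC"),
    Component.SHRUB: ("AG_INC", "AG_ALLOM"),
    Component.NON_VASCULAR: ("AG_INC", "AG_MAXMIN"),
    Component.UNDERSTORY: ("AG_PEAK",),
    Component.HERBIVORY: ("AG_FIXPROP",),
    Component.TROPICAL_LEAF_DECOMPOSITION: ("AG_FIXPROP",),
    Component.FINE_ROOT: ("BG_MINIRHIZ", "BG_INGROWTH",
                          "BG_SEQCORE_LD", "BG_SEQCORE"),
    Component.COARSE_ROOT: ("BG_ALLOM", "BG_FIXPROP"),
    Component.TOTAL_NPP: ("TOT_FLUX", "TOT_MODEL", "TOT_RADIOC"),
}

#: Monthly climate templates per region: (MAT mean, MAT sd, seasonal
#: amplitude mean, amplitude sd, annual precipitation median mm, log-sd,
#: annual PET median mm, latitude band).
_REGION_CLIMATE = {
    ClimateRegion.TROPICAL: (26.0, 1.2, 1.5, 0.5, 1800.0, 0.25, 1500.0, (0, 22)),
    ClimateRegion.ARID: (19.0, 2.5, 9.0, 1.5, 200.0, 0.30, 1900.0, (15, 35)),
    ClimateRegion.TEMPERATE: (12.0, 1.5, 7.0, 1.0, 900.0, 0.25, 800.0, (30, 50)),
    ClimateRegion.COLD: (2.0, 1.8, 16.0, 1.5, 600.0, 0.25, 600.0, (45, 65)),
    ClimateRegion.POLAR: (-8.0, 2.0, 9.0, 1.5, 300.0, 0.30, 350.0, (60, 75)),
}


@dataclass
class SynthConfig:
    """Study conditions for the generator.

    Defaults mirror the marginals of the real compilation: 456 sites with
    the observed biome and climate mixes, series lengths of 1–16 years with
    42 % single-year and 50 % in 2–5 years, and roughly one site in nine
    carrying only a whole-plant NPP estimate.
    """

    n_sites: int = 456
    biome_mix: dict = field(default_factory=lambda: dict(DEFAULT_BIOME_MIX))
    climate_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLIMATE_MIX))
    miami_params: MiamiParams = CLASSIC
    noise_model: float = 1.0
    total_only_fraction: float = 50 / 456
    incomplete_fraction: float = 0.05
    carbon_unit_fraction: float = 0.2
    multi_campaign_fraction: float = 0.2
    seed: int = 17

    def __post_init__(self) -> None:
        for name in ("biome_mix", "climate_mix"):
            probs = list(getattr(self, name).values())
            if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
                raise ValueError(f"{name} must be a probability vector")
        for name in ("total_only_fraction", "incomplete_fraction",
                     "carbon_unit_fraction", "multi_campaign_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_model < 0:
            raise ValueError("noise_model must be >= 0")
        for biome in self.biome_mix:
            if Biome(biome) not in _BIOME_FRACTIONS:
                raise ValueError(f"no component model for biome {biome}")


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named sub-stream: independent generator per logical table."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(stream.encode())])
    )


def _sample_series_length(rng: np.random.Generator) -> int:
    u = rng.random()
    if u < 0.42:
        return 1
    if u < 0.92:
        return int(rng.integers(2, 6))
    return int(rng.integers(6, 17))


def _monthly_temperature(mat: float, amp: float, hemisphere: str) -> list[float]:
    months = np.arange(1, 13)
    peak = 7 if hemisphere == "N" else 1
    return list(mat + amp * np.cos(2 * np.pi * (months - peak) / 12.0))


def _monthly_precip(map_total: float, seasonality: float, hemisphere: str,
                    rng: np.random.Generator) -> list[float]:
    months = np.arange(1, 13)
    peak = 7 if hemisphere == "N" else 1
    shape = 1.0 + seasonality * np.cos(2 * np.pi * (months - peak) / 12.0)
    shape = np.clip(shape, 0.05, None)
    shape = shape / shape.sum()
    return list(map_total * shape)


def _monthly_pet(pet_total: float, temps: list[float]) -> list[float]:
    w = np.clip(np.asarray(temps), 0.0, None) + 5.0
    w = w / w.sum()
    return list(pet_total * w)


def generate_climate(
    region: ClimateRegion, site_id: str, latitude: float,
    rng: np.random.Generator,
) -> ClimateNormals:
    """Monthly normals drawn around the region's template."""
    mat_mu, mat_sd, amp_mu, amp_sd, map_med, map_lsd, pet_med, _ = \
        _REGION_CLIMATE[region]
    mat = float(rng.normal(mat_mu, mat_sd))
    amp = float(max(0.5, rng.normal(amp_mu, amp_sd)))
    map_total = float(map_med * np.exp(rng.normal(0.0, map_lsd)))
    pet_total = float(pet_med * np.exp(rng.normal(0.0, 0.15)))
    hemisphere = "N" if latitude >= 0 else "S"
    temps = _monthly_temperature(mat, amp, hemisphere)
    # mild warm-season concentration of rain, never >70 % in one half-year
    precip = _monthly_precip(map_total, 0.4, hemisphere, rng)
    return ClimateNormals(
        site_id=site_id,
        monthly_temperature=temps,
        monthly_precipitation=precip,
        monthly_pet=_monthly_pet(pet_total, temps),
        hemisphere=hemisphere,
    )


def _site_latitude(region: ClimateRegion, rng: np.random.Generator) -> float:
    lo, hi = _REGION_CLIMATE[region][7]
    lat = float(rng.uniform(lo, hi))
    south = rng.random() < (0.4 if region is ClimateRegion.TROPICAL else 0.1)
    return -lat if south else lat


def generate_database(config: Optional[SynthConfig] = None) -> Database:
    """Generate a complete, validation-clean synthetic database.

    Deterministic for a given ``config.seed``; identical configs yield
    bit-identical databases.  With ``noise_model = 0`` the observed component
    values equal the Miami-surface truth split by the biome's component
    fractions exactly.
    """
    config = config or SynthConfig()
    db = Database(methods={m.method_id: m for m in METHOD_CATALOGUE})

    biomes = list(config.biome_mix.keys())
    biome_p = np.array(list(config.biome_mix.values()), dtype=float)
    rng_site = _rng(config.seed, "sites")
    rng_climate = _rng(config.seed, "climate")
    rng_rec = _rng(config.seed, "npp_records")
    rng_noise = _rng(config.seed, "noise")

    truth_rows = []
    for i in range(config.n_sites):
        sid = f"S{i + 1:04d}"
        biome = Biome(biomes[int(rng_site.choice(len(biomes), p=biome_p))])
        regions = _COMPATIBLE_REGIONS[biome]
        weights = np.array(
            [config.climate_mix.get(r, 0.0) for r in regions], dtype=float
        )
        if weights.sum() == 0:
            raise ValueError(
                f"biome {biome.value} has no compatible climate region with "
                f"non-zero probability"
            )
        region = regions[int(rng_site.choice(len(regions),
                                             p=weights / weights.sum()))]
        latitude = _site_latitude(region, rng_site)
        longitude = float(rng_site.uniform(-180.0, 180.0))
        if biome is Biome.CROPLAND:
            management = Management.MANAGED
        else:
            p_managed = 0.28 if biome in (Biome.FOREST, Biome.GRASSLAND) else 0.08
            management = (
                Management.MANAGED if rng_site.random() < p_managed
                else Management.UNMANAGED
            )
        u = rng_site.random()
        study_type = (
            StudyType.FIELD_ASSESSMENT if u < 0.93
            else StudyType.MANIPULATION_CONTROL if u < 0.97
            else StudyType.MANIPULATION_TREATMENT
        )
        fertility = Fertility(
            ["L", "M", "H", "unknown"][int(rng_site.choice(4, p=[0.25, 0.35, 0.18, 0.22]))]
        )
        db.sites[sid] = SiteRecord(
            site_id=sid,
            latitude=latitude,
            longitude=longitude,
            elevation=float(np.round(rng_site.gamma(2.0, 300.0), 0)),
            biome=biome,
            management=management,
            study_type=study_type,
            climate_region=region,
            fertility=fertility,
        )
        normals = generate_climate(region, sid, latitude, rng_climate)
        db.climate[sid] = normals
        mat = float(np.mean(normals.monthly_temperature))
        map_total = float(np.sum(normals.monthly_precipitation))
        truth_rows.append((sid, biome, region, mat, map_total))

    n_total_only = int(round(config.total_only_fraction * config.n_sites))
    total_only = set(
        rng_rec.choice(config.n_sites, size=n_total_only, replace=False).tolist()
    )
    n_incomplete = int(round(config.incomplete_fraction * config.n_sites))
    candidates = [i for i in range(config.n_sites) if i not in total_only]
    incomplete = set(
        rng_rec.choice(len(candidates), size=min(n_incomplete, len(candidates)),
                       replace=False).tolist()
    )
    incomplete = {candidates[i] for i in incomplete}

    rec_no = 0
    for idx, (sid, biome, region, mat, map_total) in enumerate(truth_rows):
        truth_total = float(
            miami_predict(mat, map_total, config.miami_params)
        )
        l = _sample_series_length(rng_rec)
        year_end = int(rng_rec.integers(1995, 2021))
        year_start = year_end - l + 1
        spread = 0.3 * truth_total  # stands in for the biome spread P

        if idx in total_only:
            method_id = str(rng_rec.choice(_COMPONENT_METHODS[Component.TOTAL_NPP]))
            rf = db.methods[method_id].rf
            noise = rng_noise.normal() * config.noise_model * spread * rf / np.sqrt(l)
            rec_no += 1
            db.npp_records.append(
                NppRecord(
                    record_id=f"R{rec_no:05d}", site_id=sid,
                    component=Component.TOTAL_NPP,
                    value=max(0.0, truth_total + noise),
                    method_id=method_id,
                    year_start=year_start, year_end=year_end, series_length=l,
                )
            )
            continue

        fractions = dict(_BIOME_FRACTIONS[biome])
        if biome is Biome.FOREST and region is ClimateRegion.TROPICAL:
            fractions = {c: f * 0.97 for c, f in fractions.items()}
            fractions[Component.TROPICAL_LEAF_DECOMPOSITION] = 0.03
        drop: Optional[Component] = None
        if idx in incomplete:
            mains = [c for c in (Component.FINE_ROOT, Component.STEM,
                                 Component.HERB, Component.FOLIAGE_LITTER)
                     if c in fractions]
            drop = mains[int(rng_rec.integers(len(mains)))]

        campaigns = [(year_start, year_end, l)]
        if rng_rec.random() < config.multi_campaign_fraction:
            l2 = _sample_series_length(rng_rec)
            y2_end = year_start - 1
            campaigns.append((y2_end - l2 + 1, y2_end, l2))

        for comp, frac in fractions.items():
            if comp is drop:
                continue
            truth_comp = truth_total * frac
            method_id = str(rng_rec.choice(_COMPONENT_METHODS[comp]))
            rf = db.methods[method_id].rf
            # one record per campaign only for the two largest fluxes; the
            # minor components are measured once
            comp_campaigns = campaigns if frac >= 0.2 else campaigns[:1]
            for (y0, y1, lc) in comp_campaigns:
                sd = config.noise_model * spread * frac * rf / np.sqrt(lc)
                value = max(0.0, truth_comp + rng_noise.normal() * sd)
                carbon_content = (
                    float(rng_rec.choice([0.45, 0.47, 0.50]))
                    if rng_rec.random() < config.carbon_unit_fraction else None
                )
                rec_no += 1
                db.npp_records.append(
                    NppRecord(
                        record_id=f"R{rec_no:05d}", site_id=sid,
                        component=comp, value=value, method_id=method_id,
                        year_start=y0, year_end=y1, series_length=lc,
                        carbon_content=carbon_content,
                    )
                )
        for comp in _BIOME_ABSENT[biome]:
            rec_no += 1
            db.npp_records.append(
                NppRecord(
                    record_id=f"R{rec_no:05d}", site_id=sid, component=comp,
                    value=0.0,
                    method_id=str(_COMPONENT_METHODS[comp][0]),
                    year_start=year_start, year_end=year_end, series_length=1,
                    component_absent_flag=True,
                )
            )

    db.ancillary = _ancillary_tables(db, config)
    return db


def _ancillary_tables(db: Database, config: SynthConfig) -> dict[str, pd.DataFrame]:
    rng = _rng(config.seed, "ancillary")
    sids = list(db.sites)
    soil = pd.DataFrame(
        {"site_id": sids,
         "ph": np.round(rng.uniform(3.5, 8.0, len(sids)), 1),
         "cn_ratio": np.round(rng.uniform(8.0, 35.0, len(sids)), 1)}
    )
    ndep = pd.DataFrame(
        {"site_id": sids,
         "n_deposition_kg_ha_yr": np.round(rng.gamma(2.0, 3.0, len(sids)), 2)}
    )
    fert = pd.DataFrame(
        {"site_id": sids,
         "evidence": ["soil survey"] * len(sids)}
    )
    stc = pd.DataFrame(
        {"site_id": sids,
         "mat_measurement_years": [
             float(np.round(np.mean(db.climate[s].monthly_temperature) +
                            rng.normal(0, 0.3), 2)) for s in sids],
         "map_measurement_years": [
             float(np.round(np.sum(db.climate[s].monthly_precipitation) *
                            np.exp(rng.normal(0, 0.05)), 1)) for s in sids]}
    )
    bioc = pd.DataFrame(
        {"site_id": sids,
         "bio1_mat": [float(np.round(np.mean(db.climate[s].monthly_temperature), 2))
                      for s in sids],
         "bio12_map": [float(np.round(np.sum(db.climate[s].monthly_precipitation), 1))
                       for s in sids]}
    )
    refs = pd.DataFrame(
        {"site_id": sids,
         "reference": [f"synthetic-source-{i % 40 + 1}" for i in range(len(sids))]}
    )
    return {
        "soil": soil, "nitrogen_deposition": ndep, "fertility_evidence": fert,
        "short_term_climate": stc, "bioclimatic": bioc, "study_references": refs,
    }


def generate_worked_example() -> Database:
    """Minimal one-site fixture for the combined-RF rule.

    A single forest site whose belowground production was measured with two
    methods: fine roots by minirhizotron (RF 0.3) and coarse roots by
    allometric relations (RF 0.6).  The combined belowground RF reported for
    this site is 0.4 — the mean rounded to one decimal in favour of the
    fine-root method.
    """
    db = Database(methods={m.method_id: m for m in METHOD_CATALOGUE})
    db.sites["WE01"] = SiteRecord(
        site_id="WE01", latitude=51.2, longitude=4.4,
        biome=Biome.FOREST, management=Management.UNMANAGED,
        climate_region=ClimateRegion.TEMPERATE,
    )
    db.npp_records = [
        NppRecord(
            record_id="WE01-FR", site_id="WE01", component=Component.FINE_ROOT,
            value=350.0, method_id="BG_MINIRHIZ",
            year_start=2005, year_end=2005, series_length=1,
        ),
        NppRecord(
            record_id="WE01-CR", site_id="WE01", component=Component.COARSE_ROOT,
            value=90.0, method_id="BG_ALLOM",
            year_start=2005, year_end=2005, series_length=1,
        ),
    ]
    return db


def scaled(db: Database, factor: float) -> Database:
    """Copy of the database with every NPP value multiplied by ``factor``.

    Used to exercise the scale-equivariance of the uncertainty chain.
    """
    out = Database(
        sites=dict(db.sites),
        npp_records=[replace(r, value=r.value * factor) for r in db.npp_records],
        methods=dict(db.methods),
        climate=dict(db.climate),
        ancillary=dict(db.ancillary),
    )
    return out
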