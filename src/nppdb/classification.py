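"""Rule-based biome, management, aridity and climate-region classification.

Biomes are assigned from production shares and simple site attributes:
ecosystems dominated (>50 % of production) by woody vegetation outside arid
climates are forests, herb-dominated ecosystems below the treeline are
grasslands, anything above the treeline is tundra, shrub/herb co-dominated
ecosystems in cold climates are (northern) peatlands, annual grain/tuber
crops are croplands (always managed), and dry ecosystems with reduced,
patchy cover are dry shrublands.  Because these definitions overlap for cold
shrub-herb systems, a fixed precedence is applied and reported.

The climate region is the Köppen-Geiger main class (A tropical, B arid,
C temperate, D cold, E polar) computed from monthly temperature and
precipitation normals; the aridity index AI = PRE/PET (annual totals) maps
onto five aridity classes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .schema import Biome, ClimateNormals, ClimateRegion, Management


class VegetationCover(str, enum.Enum):
    CONTINUOUS = "continuous"
    REDUCED_PATCHY = "reduced_patchy"


class GrazingIntensity(str, enum.Enum):
    NONE = "none"
    LOW_MODERATE = "low_moderate"
    INTENSIVE = "intensive"


@dataclass
class SiteAttributes:
    """Everything the classification rules may consult.

    Production shares are fractions of total production; ``None`` means
    unknown.  The ``years_since_*`` fields are years before the measurement
    (``None`` = never / unknown).
    """

    woody_production_share: Optional[float] = None
    herb_production_share: Optional[float] = None
    above_treeline: bool = False
    arid_climate: bool = False
    cold_climate: bool = False
    vegetation_cover: VegetationCover = VegetationCover.CONTINUOUS
    crop: bool = False
    shrub_herb_codominant: bool = False
    plantation: bool = False
    years_since_thinning_or_harvest: Optional[float] = None
    years_since_fertilization: Optional[float] = None
    years_since_planting: Optional[float] = None
    years_since_disturbance: Optional[float] = None
    years_protected: Optional[float] = None
    grazing_intensity: GrazingIntensity = GrazingIntensity.NONE
    irrigated: bool = False
    annual_burning: bool = False
    mowing: bool = False

    def __post_init__(self) -> None:
        for name in ("woody_production_share", "herb_production_share"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class BiomeClassification:
    biome: Optional[Biome]
    reasons: list[str] = field(default_factory=list)

    @property
    def classifiable(self) -> bool:
        return self.biome is not None


def classify_biome(attrs: SiteAttributes) -> BiomeClassification:
    """Assign a biome from site attributes.

    Precedence: cropland (annual crops), then tundra (above the treeline),
    then forest/grassland by dominant production share, then peatland
    (shrub/herb co-dominance in cold climate), then dry shrubland (dry with
    reduced, patchy cover).  Transition zones with equal woody and herb
    shares fall through to the co-dominance rules.
    """
    if attrs.crop:
        return BiomeClassification(Biome.CROPLAND, ["annual grain/tuber crop"])
    if attrs.above_treeline:
        return BiomeClassification(Biome.TUNDRA, ["above the treeline"])
    woody = attrs.woody_production_share
    herb = attrs.herb_production_share
    if woody is not None and woody > 0.5:
        if not attrs.arid_climate:
            return BiomeClassification(
                Biome.FOREST, ["woody vegetation dominates production (>50%)"]
            )
        if attrs.vegetation_cover is VegetationCover.REDUCED_PATCHY:
            return BiomeClassification(
                Biome.DRY_SHRUBLAND,
                ["woody-dominated but arid with reduced, patchy cover"],
            )
        return BiomeClassification(
            None,
            ["woody-dominated in arid climate with continuous cover: no rule applies"],
        )
    if herb is not None and herb > 0.5:
        return BiomeClassification(
            Biome.GRASSLAND, ["herbs dominate production (>50%), below treeline"]
        )
    if attrs.shrub_herb_codominant and attrs.cold_climate:
        return BiomeClassification(
            Biome.PEATLAND,
            ["shrubs and herbs co-dominate (<50% each) in cold climate"],
        )
    if attrs.arid_climate and \
            attrs.vegetation_cover is VegetationCover.REDUCED_PATCHY:
        return BiomeClassification(
            Biome.DRY_SHRUBLAND, ["dry ecosystem with reduced, patchy cover"]
        )
    reasons = []
    if woody is None or herb is None:
        reasons.append("production shares unavailable")
    else:
        reasons.append("no dominance rule matched the given shares")
    return BiomeClassification(None, reasons)


@dataclass
class ManagementClassification:
    management: Management
    low_confidence: bool = False
    reasons: list[str] = field(default_factory=list)


def classify_management(biome: Biome, attrs: SiteAttributes) -> ManagementClassification:
    """Managed/unmanaged status given a biome.

    Forests: managed if thinned/harvested within 50 years, fertilized within
    25 years, or a newly (<10 yr) established plantation; planted forests
    untouched for at least 10 years count as natural.  Grasslands: fertilized
    or irrigated grasslands (or swards established the measurement year) are
    managed, while annual burning, low-moderate grazing and non-intensive
    mowing leave them unmanaged.  Croplands are always managed.  Tundra,
    peatland and dry shrubland are unmanaged unless fertilized as part of a
    manipulation experiment.
    """
    if biome is Biome.CROPLAND:
        return ManagementClassification(Management.MANAGED, False,
                                        ["croplands are always managed"])
    fert = attrs.years_since_fertilization
    if biome is Biome.FOREST:
        reasons = []
        th = attrs.years_since_thinning_or_harvest
        if th is not None and th <= 50:
            reasons.append("thinning/harvest in the last 50 years")
        if fert is not None and fert <= 25:
            reasons.append("fertilization in the last 25 years")
        if attrs.plantation and attrs.years_since_planting is not None \
                and attrs.years_since_planting < 10:
            reasons.append("newly (<10 yr) established plantation")
        if reasons:
            return ManagementClassification(Management.MANAGED, False, reasons)
        known = th is not None or fert is not None or \
            attrs.years_since_planting is not None
        return ManagementClassification(
            Management.UNMANAGED, not known,
            ["no intervention within the management horizons"],
        )
    if biome is Biome.GRASSLAND:
        reasons = []
        if fert is not None and fert <= 25:
            reasons.append("fertilized grassland")
        if attrs.irrigated:
            reasons.append("irrigated grassland")
        if attrs.grazing_intensity is GrazingIntensity.INTENSIVE:
            reasons.append("intensive grazing")
        if attrs.years_since_planting is not None and \
                attrs.years_since_planting < 1:
            reasons.append("established the measurement year")
        if reasons:
            return ManagementClassification(Management.MANAGED, False, reasons)
        passive = []
        if attrs.annual_burning:
            passive.append("annual burning")
        if attrs.grazing_intensity is GrazingIntensity.LOW_MODERATE:
            passive.append("low-moderate grazing")
        if attrs.mowing:
            passive.append("non-intensive mowing")
        known = bool(passive) or fert is not None
        return ManagementClassification(
            Management.UNMANAGED, not known,
            passive or ["no management intervention recorded"],
        )
    # tundra, peatland, dry shrubland
    if fert is not None:
        return ManagementClassification(
            Management.MANAGED, False, ["fertilized in a manipulation experiment"]
        )
    return ManagementClassification(
        Management.UNMANAGED, False, ["pristine unless fertilized"]
    )


# ---------------------------------------------------------------------------
# Aridity
# ---------------------------------------------------------------------------

class AridityClass(str, enum.Enum):
    HUMID = "humid"
    DRY_SUBHUMID = "dry_subhumid"
    SEMI_ARID = "semi_arid"
    ARID = "arid"
    HYPER_ARID = "hyper_arid"


@dataclass(frozen=True)
class AridityResult:
    ai: float
    aridity_class: AridityClass


def aridity(pre_annual: float, pet_annual: float) -> AridityResult:
    """Aridity index AI = PRE/PET (annual totals, mm) and its class.

    Classes partition [0, ∞): hyper-arid [0, 0.03), arid [0.03, 0.2),
    semi-arid [0.2, 0.5), dry sub-humid [0.5, 0.65], humid (0.65, ∞).  The
    published thresholds leave the boundary values unassigned; here each
    lower boundary belongs to the wetter (higher) class, and AI = 0.65 stays
    dry sub-humid because humid is defined by a strict AI > 0.65.  The index
    is undefined for PET = 0.
    """
    if pre_annual < 0:
        raise ValueError(f"annual precipitation must be >= 0, got {pre_annual}")
    if pet_annual <= 0:
        raise ValueError(
            "aridity index is only defined for PET > 0"
        )
    ai = pre_annual / pet_annual
    if ai < 0.03:
        cls = AridityClass.HYPER_ARID
    elif ai < 0.2:
        cls = AridityClass.ARID
    elif ai < 0.5:
        cls = AridityClass.SEMI_ARID
    elif ai <= 0.65:
        cls = AridityClass.DRY_SUBHUMID
    else:
        cls = AridityClass.HUMID
    return AridityResult(ai, cls)


# ---------------------------------------------------------------------------
# Köppen-Geiger main class
# ---------------------------------------------------------------------------

#: High-sun ("summer") months by hemisphere: April–September in the north,
#: October–March in the south.  Equatorial sites use the northern convention.
_SUMMER_MONTHS = {
    "N": (3, 4, 5, 6, 7, 8),   # zero-based April..September
    "S": (9, 10, 11, 0, 1, 2),  # zero-based October..March
}


def koppen_main_class(
    normals: ClimateNormals,
    cold_month_boundary: float = 0.0,
) -> ClimateRegion:
    """Köppen-Geiger main class from monthly normals.

    Criteria (applied in order):

    * polar (E): warmest month below 10 °C;
    * arid (B): annual precipitation below 10 × the dryness threshold, where
      the threshold is 2 × MAT if ≥70 % of precipitation falls in the winter
      half-year, 2 × MAT + 28 if ≥70 % falls in the summer half-year, and
      2 × MAT + 14 otherwise;
    * tropical (A): coldest month at or above 18 °C;
    * temperate (C): coldest month above ``cold_month_boundary`` (0 °C in the
      modern formulation; the classic −3 °C variant is available through the
      argument);
    * cold (D): everything else.
    """
    t = [float(v) for v in normals.monthly_temperature]
    p = [float(v) for v in normals.monthly_precipitation]
    t_hot, t_cold = max(t), min(t)
    if t_hot < 10.0:
        return ClimateRegion.POLAR
    mat = sum(t) / 12.0
    map_total = sum(p)
    summer = _SUMMER_MONTHS[normals.hemisphere]
    p_summer = sum(p[i] for i in summer)
    if map_total > 0 and p_summer / map_total >= 0.7:
        threshold = 2.0 * mat + 28.0
    elif map_total > 0 and (map_total - p_summer) / map_total >= 0.7:
        threshold = 2.0 * mat
    else:
        threshold = 2.0 * mat + 14.0
    if map_total < 10.0 * threshold:
        return ClimateRegion.ARID
    if t_cold >= 18.0:
        return ClimateRegion.TROPICAL
    if t_cold > cold_month_boundary:
        return ClimateRegion.TEMPERATE
    return ClimateRegion.COLD


def classify_sites_climate(db) -> "pd.DataFrame":  # noqa: F821
    """Köppen class, AI and aridity class for every site with normals."""
    import pandas as pd

    rows = []
    for sid, normals in db.climate.items():
        region = koppen_main_class(normals)
        pre = float(sum(normals.monthly_precipitation))
        pet = float(sum(normals.monthly_pet))
        if pet > 0:
            res = aridity(pre, pet)
            ai, acls = res.ai, res.aridity_class.value
        else:
            ai, acls = None, None
        stored = db.sites[sid].climate_region
        rows.append(
            {
                "site_id": sid,
                "koppen_class": region.value,
                "stored_climate_region": stored.value if stored else None,
                "climate_region_match": (
                    None if stored is None else stored is region
                ),
                "ai": ai,
                "aridity_class": acls,
            }
        )
    return pd.DataFrame(rows)
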