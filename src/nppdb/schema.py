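"""Domain types for harmonized site-level net-primary-production databases.

The database is organised around sites.  Each site carries one or more
component-level NPP measurements (g dry mass m⁻² yr⁻¹), each tagged with the
field method used to obtain it.  Methods are catalogued with a dimensionless
reduction factor RF ∈ (0, 1] expressing their relative accuracy: the more
direct and complete the method, the smaller the RF and the smaller the
uncertainty assigned to measurements made with it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence


class Biome(str, enum.Enum):
    FOREST = "forest"
    GRASSLAND = "grassland"
    CROPLAND = "cropland"
    TUNDRA = "tundra"
    PEATLAND = "peatland"
    DRY_SHRUBLAND = "dry_shrubland"


class Management(str, enum.Enum):
    MANAGED = "managed"
    UNMANAGED = "unmanaged"


class ClimateRegion(str, enum.Enum):
    """Köppen-Geiger main classes A–E."""

    TROPICAL = "tropical"
    ARID = "arid"
    TEMPERATE = "temperate"
    COLD = "cold"
    POLAR = "polar"


class StudyType(str, enum.Enum):
    FIELD_ASSESSMENT = "field_assessment"
    MANIPULATION_CONTROL = "manipulation_control"
    MANIPULATION_TREATMENT = "manipulation_treatment"


class Fertility(str, enum.Enum):
    L = "L"
    M = "M"
    H = "H"
    UNKNOWN = "unknown"


class Component(str, enum.Enum):
    """Controlled vocabulary for NPP components.

    Source labels vary wildly; records keep the verbatim ``original_label``
    while all computation runs on this closed set.
    """

    STEM = "stem"
    BRANCH = "branch"
    FOLIAGE_LITTER = "foliage_litter"
    EXTRA_LITTER = "extra_litter"
    REPRODUCTIVE = "reproductive"
    HERB = "herb"
    SHRUB = "shrub"
    NON_VASCULAR = "non_vascular"
    UNDERSTORY = "understory"
    FINE_ROOT = "fine_root"
    COARSE_ROOT = "coarse_root"
    HERBIVORY = "herbivory"
    TROPICAL_LEAF_DECOMPOSITION = "tropical_leaf_decomposition"
    VOC_EXUDATES_SYMBIONTS = "voc_exudates_symbionts"
    TOTAL_NPP = "total_npp"


class MethodScope(str, enum.Enum):
    ABOVEGROUND = "aboveground"
    BELOWGROUND = "belowground"
    TOTAL = "total"


#: Scopes a method may legally have when tagging a given component.
COMPONENT_SCOPES: dict[Component, frozenset[MethodScope]] = {
    Component.STEM: frozenset({MethodScope.ABOVEGROUND}),
    Component.BRANCH: frozenset({MethodScope.ABOVEGROUND}),
    Component.FOLIAGE_LITTER: frozenset({MethodScope.ABOVEGROUND}),
    Component.EXTRA_LITTER: frozenset({MethodScope.ABOVEGROUND}),
    Component.REPRODUCTIVE: frozenset({MethodScope.ABOVEGROUND}),
    Component.HERB: frozenset({MethodScope.ABOVEGROUND}),
    Component.SHRUB: frozenset({MethodScope.ABOVEGROUND}),
    Component.NON_VASCULAR: frozenset({MethodScope.ABOVEGROUND}),
    Component.UNDERSTORY: frozenset({MethodScope.ABOVEGROUND}),
    Component.HERBIVORY: frozenset({MethodScope.ABOVEGROUND}),
    Component.TROPICAL_LEAF_DECOMPOSITION: frozenset({MethodScope.ABOVEGROUND}),
    Component.FINE_ROOT: frozenset({MethodScope.BELOWGROUND}),
    Component.COARSE_ROOT: frozenset({MethodScope.BELOWGROUND}),
    # VOC goes with aboveground production, exudates/symbiont transfer with
    # belowground; a single record may represent either.
    Component.VOC_EXUDATES_SYMBIONTS: frozenset(
        {MethodScope.ABOVEGROUND, MethodScope.BELOWGROUND}
    ),
    Component.TOTAL_NPP: frozenset({MethodScope.TOTAL}),
}

#: Components contributing to aboveground production (ANPP).
ABOVEGROUND_COMPONENTS: frozenset[Component] = frozenset(
    c for c, s in COMPONENT_SCOPES.items()
    if s == frozenset({MethodScope.ABOVEGROUND})
)

#: Components contributing to belowground production (BNPP).
BELOWGROUND_COMPONENTS: frozenset[Component] = frozenset(
    {Component.FINE_ROOT, Component.COARSE_ROOT}
)


@dataclass(frozen=True)
class MethodSpec:
    """A catalogued measurement method with its reduction factor."""

    method_id: str
    name: str
    scope: MethodScope
    rf: float

    def __post_init__(self) -> None:
        if not 0.0 < self.rf <= 1.0:
            raise ValueError(f"rf must be in (0, 1], got {self.rf}")


def _m(mid: str, name: str, scope: MethodScope, rf: float) -> MethodSpec:
    return MethodSpec(mid, name, scope, rf)


#: The fixed method catalogue: 7 aboveground, 8 belowground and 4 whole-plant
#: methods, each with its reduction factor.  Any method outside this list is
#: not admissible in a harmonized database.
METHOD_CATALOGUE: tuple[MethodSpec, ...] = (
    # aboveground
    _m("AG_ISO", "Isotope turnover", MethodScope.ABOVEGROUND, 0.1),
    _m("AG_INC_DEC", "Sum of increments in live biomass adjusted for decomposition",
       MethodScope.ABOVEGROUND, 0.2),
    _m("AG_INC", "Sum of increments in live biomass", MethodScope.ABOVEGROUND, 0.3),
    _m("AG_PEAK", "Peak standing crop", MethodScope.ABOVEGROUND, 0.4),
    _m("AG_MAXMIN", "Maximum minus minimum live biomass", MethodScope.ABOVEGROUND, 0.4),
    _m("AG_ALLOM", "Allometric/biometric methods", MethodScope.ABOVEGROUND, 0.4),
    _m("AG_FIXPROP", "Fixed proportion of other NPP component",
       MethodScope.ABOVEGROUND, 0.8),
    # belowground
    _m("BG_ISO", "Isotope turnover", MethodScope.BELOWGROUND, 0.2),
    _m("BG_MINIRHIZ", "Minirhizotron or root window (fine roots)",
       MethodScope.BELOWGROUND, 0.3),
    _m("BG_INGROWTH", "Ingrowth core (fine roots)", MethodScope.BELOWGROUND, 0.3),
    _m("BG_ALLOM", "Allometric relations (coarse roots)", MethodScope.BELOWGROUND, 0.6),
    _m("BG_CBUDGET", "Carbon budget and mass balance (all roots)",
       MethodScope.BELOWGROUND, 0.6),
    _m("BG_SEQCORE_LD",
       "Sequential coring, with sum of increments in live and dead biomass (fine roots)",
       MethodScope.BELOWGROUND, 0.7),
    _m("BG_SEQCORE", "Sequential biomass coring (fine roots)",
       MethodScope.BELOWGROUND, 0.8),
    _m("BG_FIXPROP", "Fixed proportion of other NPP component (coarse roots)",
       MethodScope.BELOWGROUND, 0.9),
    # whole-plant (above- and belowground indistinguishable)
    _m("TOT_RADIOC", "Radiocarbon", MethodScope.TOTAL, 0.6),
    _m("TOT_PEAT", "Peat formation in peatlands", MethodScope.TOTAL, 0.6),
    _m("TOT_MODEL", "Process-based model", MethodScope.TOTAL, 0.6),
    _m("TOT_FLUX", "Flux components, incl. eddy covariance measurements",
       MethodScope.TOTAL, 1.0),
)

METHODS_BY_ID: dict[str, MethodSpec] = {m.method_id: m for m in METHOD_CATALOGUE}


class Unit(str, enum.Enum):
    G_DRY_MASS = "g_dry_mass"
    G_CARBON = "g_c"


@dataclass
class SiteRecord:
    site_id: str
    latitude: float
    longitude: float
    biome: Biome
    management: Management
    study_type: StudyType = StudyType.FIELD_ASSESSMENT
    elevation: Optional[float] = None
    climate_region: Optional[ClimateRegion] = None
    species_info: Optional[str] = None
    fertility: Fertility = Fertility.UNKNOWN


@dataclass
class NppRecord:
    """One component-level production measurement.

    ``value`` is always g dry mass m⁻² yr⁻¹ once loaded; records reported in
    g C are converted at load time using ``carbon_content``.
    ``series_length`` is the number of measurement years the value averages
    over, which enters the uncertainty model as 1/√l.
    """

    record_id: str
    site_id: str
    component: Component
    value: float
    method_id: str
    year_start: int
    year_end: int
    series_length: int = 1
    carbon_content: Optional[float] = None
    component_absent_flag: bool = False
    includes_reproductive: bool = False
    original_label: Optional[str] = None


@dataclass
class ClimateNormals:
    """Long-term monthly climate normals for one site."""

    site_id: str
    monthly_temperature: Sequence[float]   # °C, Jan..Dec
    monthly_precipitation: Sequence[float]  # mm, Jan..Dec
    monthly_pet: Sequence[float]            # mm, Jan..Dec
    hemisphere: str = "N"                   # "N" or "S"

    def __post_init__(self) -> None:
        for name in ("monthly_temperature", "monthly_precipitation", "monthly_pet"):
            vals = getattr(self, name)
            if len(vals) != 12:
                raise ValueError(f"{name} must have 12 entries, got {len(vals)}")
        if any(p < 0 for p in self.monthly_precipitation):
            raise ValueError("monthly precipitation must be >= 0")
        if any(p < 0 for p in self.monthly_pet):
            raise ValueError("monthly PET must be >= 0")
        if self.hemisphere not in ("N", "S"):
            raise ValueError("hemisphere must be 'N' or 'S'")


@dataclass
class ValidationIssue:
    """One row-level validation failure; rows are reported, never dropped silently."""

    table: str
    row_id: str
    field: str
    message: str


@dataclass
class Database:
    """In-memory multi-table NPP database.

    ``ancillary`` holds the pass-through tables (soil, nitrogen deposition,
    fertility evidence, short-term climate, bioclimatic variables, study
    references) as raw DataFrames; they are carried but not interpreted.
    """

    sites: dict[str, SiteRecord] = field(default_factory=dict)
    npp_records: list[NppRecord] = field(default_factory=list)
    methods: dict[str, MethodSpec] = field(default_factory=dict)
    climate: dict[str, ClimateNormals] = field(default_factory=dict)
    ancillary: dict = field(default_factory=dict)
    validation_issues: list[ValidationIssue] = field(default_factory=list)

    def records_for_site(self, site_id: str) -> list[NppRecord]:
        return [r for r in self.npp_records if r.site_id == site_id]
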