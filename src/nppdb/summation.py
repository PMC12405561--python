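"""Gated hierarchical summation of NPP components.

Component-level measurements roll up through eight intermediary levels:

1. herb+shrub ANPP          herb + shrub
2. non-tree ANPP            herb + shrub + non-vascular
3. wood ANPP                stem + branch increments
4. total litterfall ANPP    foliage litter + extra litter
5. tree (overstory) ANPP    wood + total litterfall
6. BNPP                     fine roots + coarse roots
7. total NPP 1              tree + non-tree + BNPP
8. total NPP 2              total NPP 1 + herbivory + reproductive material
                            (when not already inside total litterfall) +
                            rapidly decomposed leaf litter (tropical forests)

A level is reported only when every constituent has been measured or is
verified absent at the site; otherwise the level is flagged incomplete and no
value is emitted.  This gating is what lets a database user distinguish "zero
because absent" from "zero because nobody measured it".

For non-forested biomes all root production is assumed captured by the fine
root estimate, so coarse roots are auto-flagged absent there.  Likewise the
tree (overstory) branch of the hierarchy is auto-flagged absent for
herbaceous biomes (grassland, cropland, tundra, peatland) where shrub woody
increments are carried in the shrub slot instead.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .schema import Biome, Component, NppRecord


class LevelStatus(str, enum.Enum):
    COMPLETE = "complete"
    INCOMPLETE = "incomplete"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class LevelValue:
    status: LevelStatus
    value: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.status is LevelStatus.COMPLETE) != (self.value is not None):
            raise ValueError("value must be present iff status is complete")


LEVEL_NAMES = (
    "herb_shrub_anpp",
    "non_tree_anpp",
    "wood_anpp",
    "total_litterfall_anpp",
    "tree_anpp",
    "bnpp",
    "total_npp_1",
    "total_npp_2",
)


@dataclass
class SummationLevels:
    herb_shrub_anpp: LevelValue
    non_tree_anpp: LevelValue
    wood_anpp: LevelValue
    total_litterfall_anpp: LevelValue
    tree_anpp: LevelValue
    bnpp: LevelValue
    total_npp_1: LevelValue
    total_npp_2: LevelValue
    mixed_campaign: bool = False

    def as_dict(self) -> dict[str, LevelValue]:
        return {name: getattr(self, name) for name in LEVEL_NAMES}


class DoubleCountError(ValueError):
    """Reproductive material appears both inside litterfall and separately."""


#: Biomes whose overstory/tree branch is not part of the expected hierarchy;
#: shrub woody increments are carried in the shrub slot instead.
_HERBACEOUS_BIOMES = frozenset(
    {Biome.GRASSLAND, Biome.CROPLAND, Biome.TUNDRA, Biome.PEATLAND}
)

_TREE_COMPONENTS = frozenset(
    {Component.STEM, Component.BRANCH,
     Component.FOLIAGE_LITTER, Component.EXTRA_LITTER}
)


def _group(values: Mapping[Component, float], absent: frozenset[Component],
           members: Iterable[Component]) -> LevelValue:
    total = 0.0
    n_measured = 0
    for c in members:
        if c in values:
            total += values[c]
            n_measured += 1
        elif c in absent:
            continue
        else:
            return LevelValue(LevelStatus.INCOMPLETE)
    if n_measured == 0:
        return LevelValue(LevelStatus.NOT_APPLICABLE)
    return LevelValue(LevelStatus.COMPLETE, total)


def _combine(parts: Iterable[LevelValue]) -> LevelValue:
    total = 0.0
    n_complete = 0
    for p in parts:
        if p.status is LevelStatus.INCOMPLETE:
            return LevelValue(LevelStatus.INCOMPLETE)
        if p.status is LevelStatus.COMPLETE:
            total += p.value
            n_complete += 1
    if n_complete == 0:
        return LevelValue(LevelStatus.NOT_APPLICABLE)
    return LevelValue(LevelStatus.COMPLETE, total)


def compute_levels(
    values: Mapping[Component, float],
    absent: Iterable[Component],
    biome: Biome,
    *,
    tropical: bool = False,
    reproductive_in_litterfall: bool = False,
    mixed_campaign: bool = False,
) -> SummationLevels:
    """Compute the eight summation levels for one site view.

    ``values`` are per-component production values (site means for a single
    campaign, or across campaigns with ``mixed_campaign=True`` to stamp the
    caveat); ``absent`` lists components verified absent at the site.

    ``reproductive_in_litterfall`` marks that the extra-litter estimate
    already includes reproductive material; a separately measured
    reproductive record then raises :class:`DoubleCountError`.
    """
    if not isinstance(biome, Biome):
        raise ValueError(f"unknown biome {biome!r}")
    values = {Component(c): float(v) for c, v in values.items()}
    absent = frozenset(Component(c) for c in absent)

    if reproductive_in_litterfall and Component.REPRODUCTIVE in values:
        raise DoubleCountError(
            "reproductive material is flagged as included in litterfall but "
            "is also measured separately"
        )

    auto_absent: set[Component] = set()
    if biome is not Biome.FOREST:
        auto_absent.add(Component.COARSE_ROOT)
    if biome in _HERBACEOUS_BIOMES:
        auto_absent.update(_TREE_COMPONENTS)
    absent = absent | frozenset(c for c in auto_absent if c not in values)

    herb_shrub = _group(values, absent, (Component.HERB, Component.SHRUB))
    non_tree = _group(
        values, absent,
        (Component.HERB, Component.SHRUB, Component.NON_VASCULAR),
    )
    wood = _group(values, absent, (Component.STEM, Component.BRANCH))
    litterfall = _group(
        values, absent, (Component.FOLIAGE_LITTER, Component.EXTRA_LITTER)
    )
    tree = _combine((wood, litterfall))
    bnpp = _group(values, absent, (Component.FINE_ROOT, Component.COARSE_ROOT))
    total_1 = _combine((tree, non_tree, bnpp))

    extras = [Component.HERBIVORY]
    if not reproductive_in_litterfall:
        extras.append(Component.REPRODUCTIVE)
    if tropical and biome is Biome.FOREST:
        extras.append(Component.TROPICAL_LEAF_DECOMPOSITION)
    extras_level = _group(values, absent, extras)
    if total_1.status is LevelStatus.INCOMPLETE or \
            extras_level.status is LevelStatus.INCOMPLETE:
        total_2 = LevelValue(LevelStatus.INCOMPLETE)
    else:
        total_2 = _combine((total_1, extras_level))

    return SummationLevels(
        herb_shrub_anpp=herb_shrub,
        non_tree_anpp=non_tree,
        wood_anpp=wood,
        total_litterfall_anpp=litterfall,
        tree_anpp=tree,
        bnpp=bnpp,
        total_npp_1=total_1,
        total_npp_2=total_2,
        mixed_campaign=mixed_campaign,
    )


def levels_from_records(
    records: list[NppRecord],
    biome: Biome,
    *,
    tropical: bool = False,
) -> SummationLevels:
    """Site-mean view of the records rolled into summation levels.

    If the site's components were measured across different campaigns (years
    or methods), the levels are still computed on the site-mean view but
    stamped ``mixed_campaign`` to preserve the caveat that no single-campaign
    summation exists.
    """
    by_comp: dict[Component, list[float]] = {}
    absent: set[Component] = set()
    campaigns: set[tuple[int, int]] = set()
    reproductive_in_litterfall = False
    for r in records:
        if r.component is Component.TOTAL_NPP:
            continue
        if r.component_absent_flag:
            absent.add(r.component)
            continue
        by_comp.setdefault(r.component, []).append(r.value)
        campaigns.add((r.year_start, r.year_end))
        if r.includes_reproductive and r.component is Component.EXTRA_LITTER:
            reproductive_in_litterfall = True
    values = {c: sum(v) / len(v) for c, v in by_comp.items()}
    return compute_levels(
        values,
        absent,
        biome,
        tropical=tropical,
        reproductive_in_litterfall=reproductive_in_litterfall,
        mixed_campaign=len(campaigns) > 1,
    )


# ---------------------------------------------------------------------------
# Component expectations: main vs. minor components by ecosystem type
# ---------------------------------------------------------------------------

class EcosystemType(str, enum.Enum):
    BOREAL_FOREST = "boreal_forest"
    TROPICAL_FOREST = "tropical_forest"
    OTHER_FOREST = "other_forest"
    FRUIT_PLANTATION = "fruit_plantation"
    GRASSLAND = "grassland"
    CROPLAND = "cropland"
    PEATLAND_TUNDRA_VASCULAR = "peatland_tundra_vascular"
    PEATLAND_TUNDRA_NON_VASCULAR = "peatland_tundra_non_vascular"
    WOODLAND_SAVANNA = "woodland_savanna"


@dataclass(frozen=True)
class ComponentExpectation:
    ecosystem_type: EcosystemType
    main_components: frozenset[Component]
    minor_components: frozenset[Component]

    def __post_init__(self) -> None:
        if self.main_components & self.minor_components:
            raise ValueError("main and minor component sets must be disjoint")


def _exp(et, main, minor):
    return ComponentExpectation(et, frozenset(main), frozenset(minor))


C = Component
#: Which aboveground/belowground components count as main (their absence
#: disqualifies a site) versus minor (informational) for each ecosystem type.
#: Understory stands for the herb/shrub layer under a forest canopy; trees in
#: herbaceous biomes appear as a minor "overstory" via the stem slot.  Coarse
#: roots are minor everywhere they appear because they are nearly always
#: derived from aboveground components rather than measured.
COMPONENT_EXPECTATIONS: dict[EcosystemType, ComponentExpectation] = {
    e.ecosystem_type: e
    for e in (
        _exp(EcosystemType.BOREAL_FOREST,
             {C.STEM, C.FOLIAGE_LITTER, C.UNDERSTORY, C.FINE_ROOT},
             {C.REPRODUCTIVE, C.HERBIVORY, C.COARSE_ROOT}),
        _exp(EcosystemType.TROPICAL_FOREST,
             {C.STEM, C.FOLIAGE_LITTER, C.FINE_ROOT},
             {C.UNDERSTORY, C.REPRODUCTIVE, C.HERBIVORY,
              C.TROPICAL_LEAF_DECOMPOSITION, C.COARSE_ROOT}),
        _exp(EcosystemType.OTHER_FOREST,
             {C.STEM, C.FOLIAGE_LITTER, C.FINE_ROOT},
             {C.UNDERSTORY, C.REPRODUCTIVE, C.HERBIVORY, C.COARSE_ROOT}),
        _exp(EcosystemType.FRUIT_PLANTATION,
             {C.STEM, C.FOLIAGE_LITTER, C.REPRODUCTIVE, C.FINE_ROOT},
             {C.UNDERSTORY, C.HERBIVORY, C.COARSE_ROOT}),
        _exp(EcosystemType.GRASSLAND,
             {C.HERB, C.FINE_ROOT},
             {C.STEM, C.HERBIVORY}),
        _exp(EcosystemType.CROPLAND,
             {C.HERB, C.FINE_ROOT},
             {C.STEM, C.HERBIVORY}),
        _exp(EcosystemType.PEATLAND_TUNDRA_VASCULAR,
             {C.HERB, C.SHRUB, C.FINE_ROOT},
             {C.STEM, C.NON_VASCULAR, C.REPRODUCTIVE, C.HERBIVORY,
              C.COARSE_ROOT}),
        _exp(EcosystemType.PEATLAND_TUNDRA_NON_VASCULAR,
             {C.HERB, C.SHRUB, C.NON_VASCULAR, C.FINE_ROOT},
             {C.STEM, C.REPRODUCTIVE, C.HERBIVORY, C.COARSE_ROOT}),
        _exp(EcosystemType.WOODLAND_SAVANNA,
             {C.HERB, C.STEM, C.FOLIAGE_LITTER, C.FINE_ROOT},
             {C.HERBIVORY, C.COARSE_ROOT}),
    )
}
del C


def ecosystem_type_for(
    biome: Biome,
    climate_region=None,
    *,
    fruit_plantation: bool = False,
    substantial_non_vascular: bool = False,
) -> EcosystemType:
    """Map a (biome, climate region) pair onto its expectation row."""
    from .schema import ClimateRegion

    if biome is Biome.FOREST:
        if fruit_plantation:
            return EcosystemType.FRUIT_PLANTATION
        if climate_region is ClimateRegion.TROPICAL:
            return EcosystemType.TROPICAL_FOREST
        if climate_region in (ClimateRegion.COLD, ClimateRegion.POLAR):
            return EcosystemType.BOREAL_FOREST
        return EcosystemType.OTHER_FOREST
    if biome is Biome.GRASSLAND:
        return EcosystemType.GRASSLAND
    if biome is Biome.CROPLAND:
        return EcosystemType.CROPLAND
    if biome in (Biome.TUNDRA, Biome.PEATLAND):
        return (
            EcosystemType.PEATLAND_TUNDRA_NON_VASCULAR
            if substantial_non_vascular
            else EcosystemType.PEATLAND_TUNDRA_VASCULAR
        )
    return EcosystemType.WOODLAND_SAVANNA


@dataclass
class CompletenessAudit:
    ecosystem_type: EcosystemType
    missing_main: frozenset[Component]
    missing_minor: frozenset[Component]

    @property
    def usable(self) -> bool:
        """A site missing a main component does not qualify for the database."""
        return not self.missing_main


def completeness_audit(
    measured: Iterable[Component],
    absent: Iterable[Component],
    ecosystem_type: EcosystemType,
) -> CompletenessAudit:
    """List main and minor components neither measured nor verified absent.

    The understory expectation in forests is met either by an explicit
    understory record or by the herb and shrub layers both being covered.
    Coarse roots in non-forest ecosystem types are considered covered by the
    fine-root estimate.
    """
    exp = COMPONENT_EXPECTATIONS[ecosystem_type]
    measured = frozenset(Component(c) for c in measured)
    absent = frozenset(Component(c) for c in absent)
    forest_types = {
        EcosystemType.BOREAL_FOREST, EcosystemType.TROPICAL_FOREST,
        EcosystemType.OTHER_FOREST, EcosystemType.FRUIT_PLANTATION,
    }
    if ecosystem_type not in forest_types:
        absent = absent | {Component.COARSE_ROOT}
    covered = measured | absent
    if (Component.HERB in covered and Component.SHRUB in covered):
        covered = covered | {Component.UNDERSTORY}

    def missing(expected: frozenset[Component]) -> frozenset[Component]:
        return frozenset(c for c in expected if c not in covered)

    return CompletenessAudit(
        ecosystem_type=ecosystem_type,
        missing_main=missing(exp.main_components),
        missing_minor=missing(exp.minor_components),
    )
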