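"""Gated summation levels and component completeness audits."""

import random

import pytest

from nppdb import (
    Biome,
    Component,
    EcosystemType,
    LevelStatus,
    completeness_audit,
    compute_levels,
    ecosystem_type_for,
)
from nppdb.schema import ClimateRegion
from nppdb.summation import DoubleCountError

C = Component


class TestLevelArithmetic:
    def test_forest_hierarchy_sums(self):
        """Hand-summed forest: wood 480, litterfall 350, tree 830, roots 440,
        total-1 1270; total-2 stays incomplete because herbivory is unmeasured."""
        levels = compute_levels(
            {C.STEM: 400, C.BRANCH: 80, C.FOLIAGE_LITTER: 300,
             C.EXTRA_LITTER: 50, C.FINE_ROOT: 350, C.COARSE_ROOT: 90},
            absent={C.HERB, C.SHRUB, C.NON_VASCULAR},
            biome=Biome.FOREST,
        )
        assert levels.wood_anpp.value == pytest.approx(480)
        assert levels.total_litterfall_anpp.value == pytest.approx(350)
        assert levels.tree_anpp.value == pytest.approx(830)
        assert levels.bnpp.value == pytest.approx(440)
        assert levels.total_npp_1.value == pytest.approx(1270)
        assert levels.total_npp_2.status is LevelStatus.INCOMPLETE

    def test_grassland_gating_blocks_non_tree(self):
        """Non-vascular neither measured nor flagged absent gates non-tree ANPP."""
        levels = compute_levels(
            {C.HERB: 600, C.FINE_ROOT: 500},
            absent={C.SHRUB},
            biome=Biome.GRASSLAND,
        )
        assert levels.herb_shrub_anpp.value == pytest.approx(600)
        assert levels.non_tree_anpp.status is LevelStatus.INCOMPLETE
        assert levels.non_tree_anpp.value is None

    def test_tundra_roots_absorbed_into_fine_roots(self):
        """Tundra carries no tree branch of the hierarchy; coarse roots are
        covered by the fine-root estimate."""
        levels = compute_levels(
            {C.HERB: 150, C.SHRUB: 50, C.NON_VASCULAR: 80, C.FINE_ROOT: 120},
            absent={C.COARSE_ROOT},
            biome=Biome.TUNDRA,
        )
        assert levels.non_tree_anpp.value == pytest.approx(280)
        assert levels.total_npp_1.value == pytest.approx(400)

    def test_tree_equals_wood_plus_litterfall_and_totals_nest(self):
        levels = compute_levels(
            {C.STEM: 400, C.BRANCH: 80, C.FOLIAGE_LITTER: 300,
             C.EXTRA_LITTER: 50, C.FINE_ROOT: 350, C.COARSE_ROOT: 90,
             C.HERBIVORY: 15, C.REPRODUCTIVE: 25},
            absent={C.HERB, C.SHRUB, C.NON_VASCULAR},
            biome=Biome.FOREST,
        )
        assert levels.tree_anpp.value == pytest.approx(
            levels.wood_anpp.value + levels.total_litterfall_anpp.value
        )
        assert levels.total_npp_2.value == pytest.approx(1310)
        assert levels.total_npp_2.value >= levels.total_npp_1.value
        for name, lv in levels.as_dict().items():
            if lv.status is LevelStatus.COMPLETE:
                assert lv.value <= levels.total_npp_2.value + 1e-9, name

    def test_reproductive_double_count_is_rejected(self):
        with pytest.raises(DoubleCountError):
            compute_levels(
                {C.FOLIAGE_LITTER: 300, C.EXTRA_LITTER: 60, C.REPRODUCTIVE: 20},
                absent=set(),
                biome=Biome.FOREST,
                reproductive_in_litterfall=True,
            )

    def test_reproductive_inside_litterfall_waives_the_extra(self):
        levels = compute_levels(
            {C.STEM: 400, C.BRANCH: 80, C.FOLIAGE_LITTER: 300,
             C.EXTRA_LITTER: 50, C.FINE_ROOT: 350, C.COARSE_ROOT: 90,
             C.HERBIVORY: 15},
            absent={C.HERB, C.SHRUB, C.NON_VASCULAR},
            biome=Biome.FOREST,
            reproductive_in_litterfall=True,
        )
        assert levels.total_npp_2.value == pytest.approx(1285)

    def test_unknown_biome_rejected(self):
        with pytest.raises(ValueError):
            compute_levels({C.HERB: 100}, set(), "savanna")


def _random_site_view(rng):
    biome = rng.choice(list(Biome))
    values, absent = {}, set()
    for comp in Component:
        if comp in (Component.TOTAL_NPP, Component.VOC_EXUDATES_SYMBIONTS,
                    Component.UNDERSTORY):
            continue
        u = rng.random()
        if u < 0.45:
            values[comp] = rng.uniform(0, 500)
        elif u < 0.7:
            absent.add(comp)
    if Component.REPRODUCTIVE in values and rng.random() < 0.5:
        # keep the view legal: no simultaneous in-litterfall flag
        pass
    return values, absent, biome


def test_gating_is_monotone_under_new_information():
    """Adding a measurement or an absence flag never flips a level from
    complete to incomplete."""
    rng = random.Random(42)
    for _ in range(150):
        values, absent, biome = _random_site_view(rng)
        before = compute_levels(values, absent, biome).as_dict()
        candidates = [
            c for c in Component
            if c not in values and c not in absent
            and c not in (Component.TOTAL_NPP, Component.VOC_EXUDATES_SYMBIONTS,
                          Component.UNDERSTORY)
        ]
        if not candidates:
            continue
        extra = rng.choice(candidates)
        if rng.random() < 0.5:
            after = compute_levels({**values, extra: 10.0}, absent, biome)
        else:
            after = compute_levels(values, absent | {extra}, biome)
        for name, lv in after.as_dict().items():
            if before[name].status is LevelStatus.COMPLETE:
                assert lv.status is LevelStatus.COMPLETE, (name, extra, biome)
                assert lv.value >= before[name].value - 1e-9


class TestCompletenessAudit:
    def test_boreal_forest_requires_understory(self):
        audit = completeness_audit(
            measured={C.STEM, C.FOLIAGE_LITTER, C.FINE_ROOT},
            absent=set(),
            ecosystem_type=EcosystemType.BOREAL_FOREST,
        )
        assert audit.missing_main == {C.UNDERSTORY}
        assert not audit.usable

    def test_herb_and_shrub_cover_the_understory_slot(self):
        audit = completeness_audit(
            measured={C.STEM, C.FOLIAGE_LITTER, C.FINE_ROOT, C.HERB},
            absent={C.SHRUB},
            ecosystem_type=EcosystemType.BOREAL_FOREST,
        )
        assert audit.missing_main == frozenset()

    def test_fruit_plantation_requires_reproductive(self):
        audit = completeness_audit(
            measured={C.STEM, C.FOLIAGE_LITTER, C.FINE_ROOT},
            absent=set(),
            ecosystem_type=EcosystemType.FRUIT_PLANTATION,
        )
        assert audit.missing_main == {C.REPRODUCTIVE}

    def test_coarse_roots_are_minor_in_woody_biomes(self):
        audit = completeness_audit(
            measured={C.STEM, C.FOLIAGE_LITTER, C.FINE_ROOT},
            absent=set(),
            ecosystem_type=EcosystemType.OTHER_FOREST,
        )
        assert audit.missing_main == frozenset()
        assert C.COARSE_ROOT in audit.missing_minor
        assert audit.usable

    def test_main_and_minor_sets_are_disjoint_everywhere(self):
        from nppdb.summation import COMPONENT_EXPECTATIONS
        for exp in COMPONENT_EXPECTATIONS.values():
            assert not exp.main_components & exp.minor_components

    def test_ecosystem_type_mapping(self):
        assert ecosystem_type_for(Biome.FOREST, ClimateRegion.TROPICAL) \
            is EcosystemType.TROPICAL_FOREST
        assert ecosystem_type_for(Biome.FOREST, ClimateRegion.COLD) \
            is EcosystemType.BOREAL_FOREST
        assert ecosystem_type_for(Biome.FOREST, ClimateRegion.TEMPERATE,
                                  fruit_plantation=True) \
            is EcosystemType.FRUIT_PLANTATION
        assert ecosystem_type_for(Biome.TUNDRA, substantial_non_vascular=True) \
            is EcosystemType.PEATLAND_TUNDRA_NON_VASCULAR
        assert ecosystem_type_for(Biome.DRY_SHRUBLAND) \
            is EcosystemType.WOODLAND_SAVANNA
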