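"""Biome/management rules, aridity classes and Köppen main classes."""

import numpy as np
import pytest

from nppdb import (
    AridityClass,
    Biome,
    ClimateNormals,
    ClimateRegion,
    Management,
    SiteAttributes,
    aridity,
    classify_biome,
    classify_management,
    koppen_main_class,
)
from nppdb.classification import GrazingIntensity, VegetationCover


class TestBiomeRules:
    def test_woody_dominated_non_arid_is_forest(self):
        res = classify_biome(SiteAttributes(woody_production_share=0.7,
                                            herb_production_share=0.3))
        assert res.biome is Biome.FOREST

    def test_above_treeline_is_tundra_regardless_of_shares(self):
        res = classify_biome(SiteAttributes(herb_production_share=0.8,
                                            above_treeline=True))
        assert res.biome is Biome.TUNDRA

    def test_cold_codominance_is_peatland(self):
        res = classify_biome(
            SiteAttributes(woody_production_share=0.5, herb_production_share=0.5,
                           cold_climate=True, shrub_herb_codominant=True)
        )
        assert res.biome is Biome.PEATLAND

    def test_crop_wins(self):
        assert classify_biome(SiteAttributes(crop=True)).biome is Biome.CROPLAND

    def test_herb_dominated_below_treeline_is_grassland(self):
        res = classify_biome(SiteAttributes(woody_production_share=0.2,
                                            herb_production_share=0.8))
        assert res.biome is Biome.GRASSLAND

    def test_woody_transition_resolved_by_larger_share(self):
        """Woody grasslands split on whichever component produces more."""
        forest = classify_biome(SiteAttributes(woody_production_share=0.55,
                                               herb_production_share=0.45))
        grass = classify_biome(SiteAttributes(woody_production_share=0.45,
                                              herb_production_share=0.55))
        assert forest.biome is Biome.FOREST
        assert grass.biome is Biome.GRASSLAND

    def test_dry_patchy_cover_is_shrubland(self):
        res = classify_biome(
            SiteAttributes(woody_production_share=0.4, herb_production_share=0.4,
                           arid_climate=True,
                           vegetation_cover=VegetationCover.REDUCED_PATCHY)
        )
        assert res.biome is Biome.DRY_SHRUBLAND

    def test_insufficient_attributes_reported(self):
        res = classify_biome(SiteAttributes())
        assert res.biome is None
        assert res.reasons


class TestManagementRules:
    def test_forest_recent_harvest_is_managed(self):
        res = classify_management(
            Biome.FOREST, SiteAttributes(years_since_thinning_or_harvest=30)
        )
        assert res.management is Management.MANAGED

    def test_old_untouched_plantation_is_unmanaged(self):
        res = classify_management(
            Biome.FOREST,
            SiteAttributes(plantation=True, years_since_planting=40),
        )
        assert res.management is Management.UNMANAGED

    def test_new_plantation_is_managed(self):
        res = classify_management(
            Biome.FOREST,
            SiteAttributes(plantation=True, years_since_planting=5),
        )
        assert res.management is Management.MANAGED

    def test_grassland_annual_burning_stays_unmanaged(self):
        res = classify_management(
            Biome.GRASSLAND,
            SiteAttributes(annual_burning=True,
                           grazing_intensity=GrazingIntensity.LOW_MODERATE),
        )
        assert res.management is Management.UNMANAGED
        assert not res.low_confidence

    def test_irrigated_grassland_is_managed(self):
        res = classify_management(Biome.GRASSLAND, SiteAttributes(irrigated=True))
        assert res.management is Management.MANAGED

    def test_cropland_always_managed(self):
        res = classify_management(Biome.CROPLAND, SiteAttributes())
        assert res.management is Management.MANAGED

    def test_fertilized_tundra_experiment_is_managed(self):
        res = classify_management(
            Biome.TUNDRA, SiteAttributes(years_since_fertilization=1)
        )
        assert res.management is Management.MANAGED

    def test_missing_antecedents_default_unmanaged_low_confidence(self):
        res = classify_management(Biome.FOREST, SiteAttributes())
        assert res.management is Management.UNMANAGED
        assert res.low_confidence


class TestAridity:
    @pytest.mark.parametrize(
        "pre, pet, ai, cls",
        [
            (1300.0, 1000.0, 1.3, AridityClass.HUMID),
            (0.0, 1000.0, 0.0, AridityClass.HYPER_ARID),
            (100.0, 1000.0, 0.1, AridityClass.ARID),
            (300.0, 1000.0, 0.3, AridityClass.SEMI_ARID),
            (600.0, 1000.0, 0.6, AridityClass.DRY_SUBHUMID),
        ],
    )
    def test_examples(self, pre, pet, ai, cls):
        res = aridity(pre, pet)
        assert res.ai == pytest.approx(ai)
        assert res.aridity_class is cls

    @pytest.mark.parametrize(
        "boundary, cls",
        [
            (0.03, AridityClass.ARID),
            (0.2, AridityClass.SEMI_ARID),
            (0.5, AridityClass.DRY_SUBHUMID),
            (0.65, AridityClass.DRY_SUBHUMID),  # humid is strictly > 0.65
        ],
    )
    def test_pinned_boundary_convention(self, boundary, cls):
        assert aridity(boundary * 1000.0, 1000.0).aridity_class is cls

    def test_zero_pet_is_undefined(self):
        with pytest.raises(ValueError):
            aridity(500.0, 0.0)

    def test_classes_partition_the_nonnegative_axis(self):
        """Every AI value maps to exactly one of the five classes."""
        ais = np.concatenate([
            np.linspace(0.0, 2.0, 2001),
            [0.029999, 0.030001, 0.199999, 0.200001,
             0.499999, 0.500001, 0.649999, 0.650001, 10.0, 1e6],
        ])
        for ai in ais:
            res = aridity(ai * 1000.0, 1000.0)
            assert isinstance(res.aridity_class, AridityClass)


# ---------------------------------------------------------------------------
# Independent rule oracle for the Köppen main class
# ---------------------------------------------------------------------------

def koppen_oracle(t, p, hemisphere):
    """Literal re-statement of the main-class criteria, written separately
    from the implementation."""
    t, p = list(t), list(p)
    if max(t) < 10.0:
        return "polar"
    mat = sum(t) / 12.0
    total_p = sum(p)
    if hemisphere == "N":
        summer_idx = [3, 4, 5, 6, 7, 8]
    else:
        summer_idx = [9, 10, 11, 0, 1, 2]
    p_summer = sum(p[i] for i in summer_idx)
    p_winter = total_p - p_summer
    if total_p > 0 and p_summer >= 0.7 * total_p:
        pth = 2.0 * mat + 28.0
    elif total_p > 0 and p_winter >= 0.7 * total_p:
        pth = 2.0 * mat
    else:
        pth = 2.0 * mat + 14.0
    if total_p < 10.0 * pth:
        return "arid"
    if min(t) >= 18.0:
        return "tropical"
    if min(t) > 0.0:
        return "temperate"
    return "cold"


def _normals(t, p, hemisphere="N"):
    return ClimateNormals(
        site_id="x",
        monthly_temperature=t,
        monthly_precipitation=p,
        monthly_pet=[50.0] * 12,
        hemisphere=hemisphere,
    )


class TestKoppen:
    def test_warm_wet_flat_climate_is_tropical(self):
        n = _normals([27.0] * 12, [200.0] * 12)
        assert koppen_main_class(n) is ClimateRegion.TROPICAL

    def test_cool_summer_is_polar(self):
        n = _normals([-15 + 20 * np.exp(-((m - 7) ** 2) / 8) for m in range(1, 13)],
                     [30.0] * 12)
        assert max(n.monthly_temperature) < 10
        assert koppen_main_class(n) is ClimateRegion.POLAR

    def test_flat_warm_dry_climate_is_arid(self):
        n = _normals([20.0] * 12, [5.0] * 12)
        assert koppen_main_class(n) is ClimateRegion.ARID

    def test_agrees_with_independent_oracle_on_random_normals(self):
        """1,000 random monthly vectors, both hemispheres."""
        rng = np.random.default_rng(20240917)
        mismatches = 0
        for _ in range(1000):
            t = rng.uniform(-25.0, 32.0, 12)
            p = rng.uniform(0.0, 250.0, 12)
            hemi = "N" if rng.random() < 0.5 else "S"
            got = koppen_main_class(_normals(list(t), list(p), hemi)).value
            want = koppen_oracle(t, p, hemi)
            mismatches += got != want
        assert mismatches == 0
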