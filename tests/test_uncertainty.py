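"""The harmonized uncertainty model: spread, RF averaging, propagation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nppdb import (
    Component,
    METHOD_CATALOGUE,
    MethodScope,
    average_rf,
    biome_variance,
    combine_method_rfs,
    compute_p_table,
    database_uncertainty,
    measurement_uncertainty,
    propagate_total,
    site_uncertainty,
)
from nppdb.synthetic import SynthConfig, generate_database, scaled


class TestBiomeVariance:
    def test_degenerate_distribution_is_zero(self):
        assert biome_variance([500.0] * 7) == 0.0

    def test_eleven_point_ladder(self):
        """{0..10}: the 10th/90th percentiles are 1 and 9 under linear
        interpolation, so the half interpercentile range is 4."""
        assert biome_variance(list(range(11))) == pytest.approx(4.0)

    @given(
        st.lists(st.floats(0, 1e4), min_size=2, max_size=30),
        st.floats(0.01, 100.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_equivariance(self, values, c):
        assert biome_variance([c * v for v in values]) == pytest.approx(
            c * biome_variance(values), rel=1e-9, abs=1e-9
        )

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            biome_variance([100.0])


class TestMeasurementUncertainty:
    def test_unit_series_length_returns_p_times_rf(self):
        assert measurement_uncertainty(250.0, 0.3, 1) == pytest.approx(75.0)

    def test_formula_value(self):
        assert measurement_uncertainty(100.0, 0.4, 4) == pytest.approx(20.0)

    @given(st.floats(1.0, 1e4), st.sampled_from([0.1, 0.3, 0.6, 1.0]),
           st.integers(1, 16))
    @settings(max_examples=100, deadline=None)
    def test_quadrupling_series_length_halves_s(self, p, rf, l):
        assert measurement_uncertainty(p, rf, 4 * l) == pytest.approx(
            measurement_uncertainty(p, rf, l) / 2.0
        )

    @given(st.floats(1.0, 1e4), st.integers(1, 16))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_rf(self, p, l):
        s = [measurement_uncertainty(p, rf, l)
             for rf in (0.1, 0.3, 0.6, 0.9)]
        assert s == sorted(s)

    def test_series_length_below_one_rejected(self):
        with pytest.raises(ValueError):
            measurement_uncertainty(100.0, 0.5, 0.5)


class TestAverageRf:
    def test_worked_example_midpoint_favours_fine_roots(self):
        """0.3 and 0.6 average to 0.45; the midpoint resolves toward the
        dominant fine-root method, giving 0.4."""
        assert average_rf([0.3, 0.6], dominant_rf=0.3) == 0.4

    def test_single_method_is_identity(self):
        assert average_rf([0.7]) == 0.7

    def test_exact_mean_needs_no_tie_break(self):
        assert average_rf([0.2, 0.4]) == 0.3

    def test_midpoint_with_unknown_dominance_rounds_down(self):
        assert average_rf([0.1, 0.2]) == 0.1

    def test_midpoint_toward_dominant_can_round_up(self):
        assert average_rf([0.3, 0.6], dominant_rf=0.6) == 0.5

    def test_non_catalogue_rf_rejected(self):
        with pytest.raises(ValueError):
            average_rf([0.35])

    def test_combine_selects_fine_roots_as_dominant(self):
        rf = combine_method_rfs(
            [(0.3, Component.FINE_ROOT, 350.0),
             (0.6, Component.COARSE_ROOT, 900.0)]  # even with larger flux
        )
        assert rf == 0.4

    def test_mixed_scopes_rejected(self):
        with pytest.raises(ValueError):
            combine_method_rfs(
                [(0.3, Component.STEM, 400.0),
                 (0.3, Component.FINE_ROOT, 350.0)]
            )


class TestPropagation:
    def test_zero_partner_is_identity(self):
        assert propagate_total(0.0, 7.5) == pytest.approx(7.5)

    def test_three_four_five(self):
        assert propagate_total(3.0, 4.0) == pytest.approx(5.0)

    @given(st.floats(0, 1e4), st.floats(0, 1e4))
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, a, b):
        assert propagate_total(a, b) == propagate_total(b, a)


class TestSiteUncertainty:
    def test_single_measurement_identity(self):
        assert site_uncertainty([12.5]) == pytest.approx(12.5)

    @given(st.floats(0.1, 1e3), st.integers(1, 20))
    @settings(max_examples=50, deadline=None)
    def test_equal_inputs_shrink_by_sqrt_n(self, s, n):
        assert site_uncertainty([s] * n) == pytest.approx(s / math.sqrt(n))

    @given(st.lists(st.floats(0, 1e3), min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_never_exceeds_largest_input(self, values):
        assert site_uncertainty(values) <= max(values) + 1e-9

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            site_uncertainty([])


class TestCatalogue:
    def test_rf_multisets_by_scope(self):
        by_scope = {}
        for m in METHOD_CATALOGUE:
            by_scope.setdefault(m.scope, []).append(m.rf)
        assert sorted(by_scope[MethodScope.ABOVEGROUND]) == \
            [0.1, 0.2, 0.3, 0.4, 0.4, 0.4, 0.8]
        assert sorted(by_scope[MethodScope.BELOWGROUND]) == \
            [0.2, 0.3, 0.3, 0.6, 0.6, 0.7, 0.8, 0.9]
        assert sorted(by_scope[MethodScope.TOTAL]) == [0.6, 0.6, 0.6, 1.0]

    def test_names_resolve_uniquely_within_scope(self):
        seen = set()
        for m in METHOD_CATALOGUE:
            key = (m.name, m.scope)
            assert key not in seen
            seen.add(key)


class TestDatabaseUncertainty:
    def test_recomputation_is_bit_identical(self, small_db):
        a = database_uncertainty(small_db)
        b = database_uncertainty(small_db)
        assert a.equals(b)

    def test_every_complete_site_has_finite_s_tnpp(self):
        db = generate_database(
            SynthConfig(n_sites=60, seed=11, incomplete_fraction=0.0)
        )
        unc = database_uncertainty(db)
        assert unc["s_tnpp"].notna().all()
        assert (unc["s_tnpp"].to_numpy() >= 0).all()

    def test_doubling_values_doubles_every_s(self, small_db):
        base = database_uncertainty(small_db).set_index("site_id")
        twice = database_uncertainty(scaled(small_db, 2.0)).set_index("site_id")
        for col in ("s_anpp", "s_bnpp", "s_tnpp"):
            a, b = base[col].to_numpy(), twice[col].to_numpy()
            mask = ~np.isnan(a)
            assert np.allclose(b[mask], 2.0 * a[mask], rtol=1e-9)
        # RFs are ratios of the same methods, untouched by scaling
        for col in ("rf_anpp", "rf_bnpp"):
            a, b = base[col].to_numpy(), twice[col].to_numpy()
            mask = ~np.isnan(a)
            assert np.array_equal(a[mask], b[mask])

    def test_single_biome_database_p_table(self):
        from nppdb import Biome
        db = generate_database(
            SynthConfig(
                n_sites=25, seed=5,
                biome_mix={Biome.FOREST: 1.0},
                total_only_fraction=0.0, incomplete_fraction=0.0,
            )
        )
        pt = compute_p_table(db)
        assert set(pt["biome"]) == {"forest"}
        assert set(pt["component_class"]) == {"ANPP", "BNPP", "TNPP"}
        assert (pt["p"] >= 0).all()
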