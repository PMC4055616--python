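import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phytogrowth.errors import CoverageError, NitrateQCWarning, ValidationError
from phytogrowth.hydrography import (
    DepthProfile,
    derive_hydrography,
    euphotic_depth,
    frame_to_profiles,
    mixed_layer_depth,
    nitrate_at_euphotic_base,
    profiles_to_frame,
    stratification_index,
)
from .conftest import profile_from_sigma


def exp_par_profile(k=0.1, surface=100.0, zmax=100.0, dz=5.0):
    z = np.arange(0.0, zmax + dz, dz)
    return profile_from_sigma(z, np.full(z.size, 26.0), par=surface * np.exp(-k * z))


class TestProfileValidation:
    def test_requires_two_levels(self):
        with pytest.raises(ValidationError, match="at least 2"):
            DepthProfile("x", [0.0], [10.0], [35.0])

    def test_requires_strictly_increasing_depth(self):
        with pytest.raises(ValidationError, match="strictly increasing"):
            DepthProfile("x", [0, 50, 50], [10, 10, 10], [35, 35, 35])

    def test_requires_surface_sample(self):
        with pytest.raises(ValidationError, match="surface"):
            DepthProfile("x", [10, 50], [10, 10], [35, 35])

    def test_rejects_nonpositive_par(self):
        with pytest.raises(ValidationError, match="PAR"):
            DepthProfile("x", [0, 50], [10, 10], [35, 35], par=[100.0, 0.0])

    def test_length_mismatch(self):
        with pytest.raises(ValidationError, match="length"):
            DepthProfile("x", [0, 50], [10, 10, 10], [35, 35])


class TestMixedLayerDepth:
    def test_linear_profile_analytic_crossing(self):
        z = np.linspace(0, 100, 21)
        p = profile_from_sigma(z, 26.0 + z / 100.0)
        depth, flag = mixed_layer_depth(p)
        assert flag is None
        assert depth == pytest.approx(12.5, abs=1e-6)

    def test_coarse_sampling_interpolates_between_brackets(self):
        p = profile_from_sigma([0, 30, 35, 100], [26.0, 26.0, 26.5, 26.5])
        depth, flag = mixed_layer_depth(p)
        assert flag is None
        assert depth == pytest.approx(31.25, abs=1e-6)

    def test_discrete_variant_returns_sampled_level(self):
        p = profile_from_sigma([0, 30, 35, 100], [26.0, 26.0, 26.5, 26.5])
        depth, _ = mixed_layer_depth(p, interpolate=False)
        assert depth == 35.0

    def test_homogeneous_column_flags_not_reached(self):
        z = np.arange(0, 101, 10)
        p = profile_from_sigma(z, np.full(z.size, 26.0))
        depth, flag = mixed_layer_depth(p)
        assert depth == 100.0
        assert flag == "uml_not_reached"

    def test_monotone_nondecreasing_in_threshold(self):
        z = np.linspace(0, 200, 41)
        p = profile_from_sigma(z, 26.0 + (z / 200.0) ** 2)
        depths = [mixed_layer_depth(p, threshold=th)[0]
                  for th in (0.05, 0.125, 0.3, 0.6, 0.9)]
        assert all(a <= b for a, b in zip(depths, depths[1:]))


class TestEuphoticDepth:
    def test_exponential_profile_closed_form(self):
        p = exp_par_profile(k=0.1)
        depth, flag = euphotic_depth(p)
        assert flag is None
        assert depth == pytest.approx(math.log(100) / 0.1, abs=1e-6)

    def test_two_point_exponential_sampling_is_exact(self):
        # PAR at 50 m on a k=0.1 exponential: 100*e^-5; two samples suffice.
        p = profile_from_sigma([0, 50], [26.0, 26.0],
                               par=[100.0, 100.0 * math.exp(-5)])
        depth, _ = euphotic_depth(p)
        assert depth == pytest.approx(math.log(100) / 0.1, abs=1e-9)

    def test_two_point_log_linear_interpolation(self):
        # 1% of surface PAR between (0, 100) and (50, 0.5), linearly in log PAR:
        # z = 50 * ln(100) / ln(200) = 43.4589 m.
        p = profile_from_sigma([0, 50], [26.0, 26.0], par=[100.0, 0.5])
        depth, _ = euphotic_depth(p)
        assert depth == pytest.approx(50 * math.log(100) / math.log(200), abs=1e-9)

    def test_clear_water_flags_floor_not_reached(self):
        p = exp_par_profile(k=0.02)  # 1% level at 230 m
        depth, flag = euphotic_depth(p)
        assert depth == 100.0
        assert flag == "par_floor_not_reached"

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        k=st.floats(min_value=0.02, max_value=0.5),
        dz=st.floats(min_value=1.0, max_value=5.0),
    )
    def test_log_linear_exact_on_any_exponential_grid(self, k, dz):
        analytic = math.log(100) / k
        z = np.arange(0.0, analytic * 1.5 + dz, dz)
        p = profile_from_sigma(z, np.full(z.size, 26.0),
                               par=1500.0 * np.exp(-k * z))
        depth, flag = euphotic_depth(p)
        assert flag is None
        assert depth == pytest.approx(analytic, abs=1e-6)


class TestStratificationIndex:
    def test_linear_profile(self):
        z = np.linspace(0, 100, 11)
        p = profile_from_sigma(z, 26.0 + z / 100.0)
        assert stratification_index(p, 50.0) == pytest.approx(0.5, abs=1e-9)

    def test_homogeneous_is_zero(self):
        p = profile_from_sigma([0, 50, 100], [26.0, 26.0, 26.0])
        assert stratification_index(p, 70.0) == pytest.approx(0.0, abs=1e-9)

    def test_piecewise_linear_lookup(self):
        p = profile_from_sigma([0, 40, 120], [25.8, 25.9, 27.1])
        assert stratification_index(p, 80.0) == pytest.approx(0.7, abs=1e-6)

    def test_outside_range_is_error(self):
        p = profile_from_sigma([0, 100], [26.0, 26.5])
        with pytest.raises(CoverageError):
            stratification_index(p, 150.0)


class TestNitrateAtEuphoticBase:
    def test_linear_interpolation(self):
        p = profile_from_sigma([0, 100], [26.0, 26.5], nitrate=[0.1, 10.0])
        value, flag = nitrate_at_euphotic_base(p, 50.0)
        assert value == pytest.approx(5.05, abs=1e-9)
        assert flag is None

    def test_below_detection_censored_then_interpolated(self):
        p = profile_from_sigma([0, 100], [26.0, 26.5], nitrate=[0.01, 10.0])
        value, flag = nitrate_at_euphotic_base(p, 50.0)
        assert value == pytest.approx(5.025, abs=1e-9)
        assert flag == "no3_censored"

    def test_no_coverage_is_error(self):
        p = profile_from_sigma([0, 20, 40], [26.0, 26.1, 26.2],
                               nitrate=[1.0, 2.0, 3.0])
        with pytest.raises(CoverageError):
            nitrate_at_euphotic_base(p, 80.0)

    def test_low_value_emits_qc_warning(self):
        p = profile_from_sigma([0, 100], [26.0, 26.5], nitrate=[0.1, 0.15])
        with pytest.warns(NitrateQCWarning):
            nitrate_at_euphotic_base(p, 50.0)


class TestDeriveHydrography:
    def test_homogeneous_transparent_column_flags(self):
        z = np.arange(0, 101, 10)
        p = profile_from_sigma(z, np.full(z.size, 26.0),
                               par=100.0 * np.exp(-0.01 * z))
        d = derive_hydrography(p)
        assert d.flags == {"uml_not_reached", "par_floor_not_reached"}
        assert d.uml_depth == 100.0 and d.euphotic_depth == 100.0

    def test_missing_nitrate_yields_nan_not_error(self):
        z = np.linspace(0, 100, 11)
        p = profile_from_sigma(z, 26.0 + z / 100.0, par=100.0 * np.exp(-0.1 * z))
        d = derive_hydrography(p)
        assert math.isnan(d.no3_euphotic_base)

    def test_row_order_invariance_through_csv_layer(self, rng):
        z = np.linspace(0, 100, 11)
        p = profile_from_sigma(z, 26.0 + z / 100.0,
                               par=100.0 * np.exp(-0.08 * z),
                               nitrate=np.linspace(0.5, 12.0, 11))
        frame = profiles_to_frame([p])
        shuffled = frame.sample(frac=1.0, random_state=7)
        (p2,) = frame_to_profiles(shuffled)
        d1, d2 = derive_hydrography(p), derive_hydrography(p2)
        assert d1 == d2

    def test_grid_refinement_converges(self):
        # Smooth analytic water column: every derived quantity approaches a
        # limit as the sampling grid refines, with shrinking error.
        def make(dz):
            z = np.arange(0.0, 150.0 + dz, dz)
            sig = 26.0 + 0.9 / (1 + np.exp(-(z - 40.0) / 8.0))
            return profile_from_sigma(z, sig, par=1200 * np.exp(-0.05 * z),
                                      nitrate=0.2 + 10 / (1 + np.exp(-(z - 60) / 10)))

        coarse, mid, fine = (derive_hydrography(make(dz)) for dz in (10.0, 2.0, 0.25))
        for attr in ("uml_depth", "euphotic_depth", "delta_sigma_t",
                     "no3_euphotic_base"):
            err_mid = abs(getattr(mid, attr) - getattr(fine, attr))
            err_coarse = abs(getattr(coarse, attr) - getattr(fine, attr))
            assert err_mid <= err_coarse + 1e-12
        assert mid.uml_depth == pytest.approx(fine.uml_depth, abs=0.2)
        assert mid.delta_sigma_t == pytest.approx(fine.delta_sigma_t, abs=0.005)
        assert mid.no3_euphotic_base == pytest.approx(fine.no3_euphotic_base, abs=0.05)
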