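"""Mean-profile binning and oxygen-threshold strata delimitation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from midwater.hydrography import (
    DepthStrata,
    assign_stratum,
    compute_mean_profile,
    define_ul_boundary,
    detect_omz,
)
from midwater.io import CtdCast

from conftest import make_profile


def _cast(station, cast_id, depth, oxy=None, temp=None):
    depth = np.asarray(depth, dtype=float)
    return CtdCast(
        station=station,
        cast_id=cast_id,
        depth_m=depth,
        temp_C=np.asarray(temp, float) if temp is not None else np.full_like(depth, 15.0),
        sal_psu=np.full_like(depth, 35.0),
        oxy_umol_kg=np.asarray(oxy, float) if oxy is not None else np.full_like(depth, 200.0),
        chla_mg_m3=np.full_like(depth, 0.1),
    )


class TestMeanProfile:
    def test_single_cast_has_zero_sd(self):
        profile = compute_mean_profile([_cast("A", "C1", [10, 20, 30])])
        assert (profile.sd("oxy_umol_kg") == 0).all()

    def test_mean_and_sd_match_hand_calculation(self):
        casts = [
            _cast("A", "C1", [100.0], oxy=[100.0]),
            _cast("B", "C2", [100.0], oxy=[120.0]),
        ]
        profile = compute_mean_profile(casts)
        assert profile.mean("oxy_umol_kg").iloc[0] == pytest.approx(110.0)
        # n-1 denominator: sd of {100, 120} is 20/sqrt(2)
        assert profile.sd("oxy_umol_kg").iloc[0] == pytest.approx(14.142135623730951)

    def test_sample_assigned_to_half_open_bin(self):
        profile = compute_mean_profile([_cast("A", "C1", [7.3])], bin_width_m=5.0)
        # 7.3 m falls in [5, 10), reported at midpoint 7.5
        assert profile.depth_m.tolist() == [7.5]

    def test_empty_cast_list_rejected(self):
        with pytest.raises(ValueError):
            compute_mean_profile([])


class TestDetectOmz:
    def test_oxygen_never_below_threshold_means_no_omz(self):
        profile = make_profile([100, 400, 700], oxy=[200, 200, 200])
        assert detect_omz(profile) is None

    def test_piecewise_linear_crossings_are_analytic(self):
        profile = make_profile([200, 400, 600], oxy=[150, 30, 150])
        strata = detect_omz(profile, threshold_umol_kg=60.0)
        assert strata.z2 == pytest.approx(350.0, abs=1e-9)
        assert strata.z3 == pytest.approx(450.0, abs=1e-9)

    def test_secondary_shallow_minimum_is_ignored(self):
        # shallow dip to 50 at 100 m; the OMZ proper dips to 35 at 400 m
        depths = [50, 100, 150, 300, 400, 500, 700]
        oxy = [200, 50, 200, 150, 35, 150, 200]
        strata = detect_omz(make_profile(depths, oxy=oxy))
        assert 300 < strata.z2 < 400
        assert 400 < strata.z3 < 500

    def test_crossings_match_fine_resampling_oracle(self, rng):
        """Brute force: scan a 0.1 m linearly interpolated grid for crossings."""
        for _ in range(25):
            depths = np.sort(rng.uniform(0, 1000, 15))
            oxy = rng.uniform(10, 250, 15)
            profile = make_profile(depths, oxy=oxy)
            fine = np.arange(depths[0], depths[-1], 0.1)
            fine_oxy = np.interp(fine, depths, oxy)
            below = fine_oxy < 60.0
            strata = detect_omz(profile, z1=1e-6, z_max=2000.0)
            if not below.any():
                assert strata is None
                continue
            imin = int(np.argmin(fine_oxy))
            lo = imin
            while lo > 0 and below[lo - 1]:
                lo -= 1
            hi = imin
            while hi < len(fine) - 1 and below[hi + 1]:
                hi += 1
            assert strata.z2 == pytest.approx(fine[lo], abs=0.15)
            assert strata.z3 == pytest.approx(fine[hi], abs=0.15)

    def test_omz_thickness_monotone_in_deficit_amplitude(self):
        depths = np.arange(2.5, 1000, 5.0)
        widths = []
        for minimum in (55, 45, 35, 25, 15):
            oxy = 220 - (220 - minimum) * np.exp(-((depths - 400) ** 2) / (2 * 150**2))
            strata = detect_omz(make_profile(depths, oxy=oxy))
            widths.append(strata.z3 - strata.z2)
        assert all(b >= a for a, b in zip(widths, widths[1:]))


class TestUlBoundary:
    def test_fixed_method_returns_config_value(self):
        profile = make_profile([10, 50, 100], temp=[25, 20, 15])
        assert define_ul_boundary(profile, "fixed", fixed_m=92.0) == 92.0

    def test_max_gradient_finds_logistic_thermocline(self):
        depths = np.arange(2.5, 400, 5.0)
        temp = 6 + 19 / (1 + np.exp((depths - 60) / 20))
        z1 = define_ul_boundary(make_profile(depths, temp=temp), "max-gradient")
        assert z1 == pytest.approx(60.0, abs=5.0)

    def test_isothermal_profile_has_no_thermocline(self):
        depths = np.arange(2.5, 300, 5.0)
        profile = make_profile(depths, temp=np.full_like(depths, 15.0))
        with pytest.raises(ValueError, match="no thermocline"):
            define_ul_boundary(profile, "max-gradient")


class TestAssignStratum:
    @pytest.mark.parametrize(
        "depth,expected", [(50, "UL"), (400, "OMZ"), (700, "LOC"), (92, "UL"),
                           (200, "UOC")]
    )
    def test_published_strata_membership(self, paper_strata, depth, expected):
        assert assign_stratum(depth, paper_strata) == expected

    def test_boundary_depth_belongs_to_shallower_stratum(self, paper_strata):
        assert assign_stratum(paper_strata.z2, paper_strata) == "UOC"
        assert assign_stratum(paper_strata.z3, paper_strata) == "OMZ"

    def test_depth_beyond_sampled_range_rejected(self, paper_strata):
        with pytest.raises(ValueError):
            assign_stratum(1200.0, paper_strata)

    @given(depth=st.floats(min_value=0.0, max_value=1000.0,
                           allow_nan=False, allow_infinity=False))
    @settings(max_examples=200, deadline=None)
    def test_total_and_single_valued_on_column(self, depth):
        strata = DepthStrata(z1=92.0, z2=304.0, z3=503.0, z_max=1000.0)
        assert assign_stratum(depth, strata) in ("UL", "UOC", "OMZ", "LOC")


def test_invalid_strata_ordering_rejected():
    with pytest.raises(ValueError):
        DepthStrata(z1=300.0, z2=200.0, z3=500.0, z_max=1000.0)
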