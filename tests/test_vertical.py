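"""Vertical profiles, weighted mean depth, splitting, and migration tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from midwater.abundance import CalibrationFactor, aggregate_counts, to_concentration
from midwater.synthetic import DesignSpec, TaxonSpec, generate_community_counts
from midwater.vertical import (
    SplitRule,
    TaxonVerticalProfile,
    apply_split,
    build_profiles,
    dvm_test,
    station_wmds,
    weighted_mean_depth,
)


def _profile(taxon, period, data):
    """data: dict station -> dict depth -> concentration (missing = NaN)."""
    table = pd.DataFrame(data)
    table.index.name = "transect_depth_m"
    return TaxonVerticalProfile(taxon=taxon, period=period, station_table=table)


class TestWeightedMeanDepth:
    def test_single_nonzero_depth(self):
        assert weighted_mean_depth([100, 300, 500], [0, 0, 7]) == 500.0

    def test_symmetric_abundance_gives_midpoint(self):
        assert weighted_mean_depth([100, 300], [4, 4]) == 200.0

    @pytest.mark.parametrize(
        "abundances,expected", [((1, 2, 1), 400.0), ((1, 1, 2), 475.0)]
    )
    def test_matches_formula_oracle(self, abundances, expected):
        depths = (100, 400, 700)
        brute = sum(a * z for a, z in zip(abundances, depths)) / sum(abundances)
        assert brute == expected
        assert weighted_mean_depth(depths, abundances) == pytest.approx(expected)

    def test_zero_total_abundance_is_undefined(self):
        assert np.isnan(weighted_mean_depth([100, 200], [0, 0]))

    @given(
        scale=st.floats(min_value=1e-3, max_value=1e3),
        shift=st.floats(min_value=-500, max_value=500),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance_and_translation_equivariance(self, scale, shift):
        depths = np.array([100.0, 400.0, 700.0])
        abund = np.array([1.0, 5.0, 2.0])
        base = weighted_mean_depth(depths, abund)
        assert weighted_mean_depth(depths, abund * scale) == pytest.approx(base)
        assert weighted_mean_depth(depths + shift, abund) == pytest.approx(
            base + shift, abs=1e-6
        )


class TestBuildProfiles:
    def _abundances(self):
        rows = []
        for station, depth, conc in [
            ("A", 400.0, 10.0), ("B", 400.0, 30.0),
            ("A", 700.0, 8.0),  # station B never sampled 700 m
        ]:
            rows.append(
                {
                    "station": station, "deployment_id": f"{station}-day",
                    "transect_depth_m": depth, "period": "day",
                    "taxon": "Beroe", "concentration_per_1000m3": conc,
                }
            )
        return pd.DataFrame(rows)

    def test_pooled_mean_across_stations(self):
        profiles = build_profiles(self._abundances())
        pooled = profiles[("Beroe", "day")].pooled
        assert pooled[400.0] == pytest.approx(20.0)

    def test_missing_station_not_zero_imputed(self):
        profiles = build_profiles(self._abundances())
        pooled = profiles[("Beroe", "day")].pooled
        # only station A sampled 700 m; pooled mean is A's value, not 4.0
        assert pooled[700.0] == pytest.approx(8.0)

    def test_single_station_pooled_equals_station_vector(self):
        df = self._abundances()
        df = df[df["station"] == "A"]
        profiles = build_profiles(df)
        prof = profiles[("Beroe", "day")]
        pd.testing.assert_series_equal(
            prof.pooled, prof.station_table["A"].dropna(),
            check_names=False,
        )


class TestApplySplit:
    def test_groups_partition_at_split_depth(self):
        prof = _profile(
            "Beroe", "day", {"A": {100.0: 5.0, 400.0: 1.0, 700.0: 4.0}}
        )
        shallow, deep = apply_split(prof, SplitRule("Beroe", 400.0))
        assert shallow.taxon == "Beroe_shallow"
        assert list(shallow.station_table.index) == [100.0, 400.0]
        assert list(deep.station_table.index) == [700.0]

    def test_empty_deep_group_yields_undefined_wmd(self):
        prof = _profile("Doliolida", "day", {"A": {100.0: 5.0, 200.0: 3.0, 700.0: 0.0}})
        _, deep = apply_split(prof, SplitRule("Doliolida", 400.0))
        assert np.isnan(station_wmds(deep)["A"])

    def test_split_outside_sampled_range_rejected(self):
        prof = _profile("Beroe", "day", {"A": {100.0: 5.0, 700.0: 4.0}})
        with pytest.raises(ValueError, match="outside the sampled range"):
            apply_split(prof, SplitRule("Beroe", 1500.0))

    def test_group_wmds_recover_planted_bimodal_modes(self):
        """A two-mode mixture split mid-gap has group WMDs near the modes."""
        taxon = TaxonSpec(
            "Beroe", "bimodal", day_mode_m=120, sigma_m=40,
            second_mode_m=650, second_sigma_m=50, peak_conc_per_1000m3=300,
        )
        ann, transects = generate_community_counts([taxon], DesignSpec(), seed=7)
        counts = aggregate_counts(ann, transects)
        abund = to_concentration(counts, transects, CalibrationFactor(15.0))
        profiles = build_profiles(abund)
        shallow, deep = apply_split(
            profiles[("Beroe", "day")], SplitRule("Beroe", 400.0)
        )
        s_pooled, d_pooled = shallow.pooled, deep.pooled
        s_wmd = weighted_mean_depth(s_pooled.index.to_numpy(), s_pooled.to_numpy())
        d_wmd = weighted_mean_depth(d_pooled.index.to_numpy(), d_pooled.to_numpy())
        assert abs(s_wmd - 120) < 30
        assert abs(d_wmd - 650) < 30


class TestDvmTest:
    def test_identical_day_and_night_wmds(self):
        wmds = pd.Series([300.0, 310, 290, 305, 295], index=list("ABCDE"))
        result = dvm_test(wmds, wmds.copy(), taxon="x")
        assert result.t_stat == 0.0
        assert result.p_value == 1.0
        assert not result.significant

    def test_matches_textbook_paired_t_oracle(self):
        # differences (50, 60, 55, 45, 40): mean 50, sd 7.9057, t = 14.1421
        night = pd.Series([300.0, 300, 300, 300, 300], index=list("ABCDE"))
        day = night + [50, 60, 55, 45, 40]
        result = dvm_test(day, night, taxon="x")
        assert result.t_stat == pytest.approx(14.142135623730951, rel=1e-9)
        assert result.p_value == pytest.approx(0.00014512817061319757, rel=1e-6)
        assert result.significant
        assert result.direction == 1

    def test_two_pairs_is_insufficient(self):
        day = pd.Series([300.0, 400.0], index=list("AB"))
        night = pd.Series([200.0, 300.0], index=list("AB"))
        result = dvm_test(day, night, taxon="x")
        assert result.status == "insufficient pairs"
        assert not result.significant

    def test_pairs_formed_only_from_stations_with_both_periods(self):
        day = pd.Series([400.0, 420, np.nan, 410, 390], index=list("ABCDE"))
        night = pd.Series([300.0, 310, 305, np.nan, 290], index=list("ABCDE"))
        result = dvm_test(day, night, taxon="x")
        assert result.n_pairs == 3

    def test_constant_nonzero_shift_is_maximally_significant(self):
        day = pd.Series([500.0, 500, 500], index=list("ABC"))
        night = day - 150.0
        result = dvm_test(day, night, taxon="x")
        assert result.p_value == 0.0
        assert result.significant
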