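"""Count aggregation, calibration estimation and volumetric conversion."""

import numpy as np
import pandas as pd
import pytest

from midwater.abundance import (
    CalibrationFactor,
    aggregate_counts,
    estimate_calibration,
    match_reference_concentration,
    to_concentration,
)
from midwater.io import AnnotationRecord, TransectMeta


def _ann(station, deployment, depth, period, taxon):
    return AnnotationRecord(station, deployment, depth, period, taxon)


class TestAggregateCounts:
    def test_events_summed_per_transect(self, simple_transects):
        ann = [_ann("A", "A-day", 400.0, "day", "Beroe")] * 3
        counts = aggregate_counts(ann, simple_transects)
        row = counts[
            (counts["station"] == "A")
            & (counts["period"] == "day")
            & (counts["transect_depth_m"] == 400.0)
        ]
        assert row["count"].item() == 3

    def test_absent_taxon_is_a_true_zero(self, simple_transects):
        ann = [_ann("A", "A-day", 400.0, "day", "Beroe")]
        counts = aggregate_counts(ann, simple_transects, taxa=["Beroe", "Atolla"])
        atolla = counts[counts["taxon"] == "Atolla"]
        assert len(atolla) == len(simple_transects)
        assert (atolla["count"] == 0).all()

    def test_hand_tally_on_mixed_fixture(self, simple_transects):
        events = (
            [_ann("A", "A-day", 100.0, "day", "Beroe")] * 4
            + [_ann("A", "A-day", 100.0, "day", "Atolla")] * 2
            + [_ann("B", "B-night", 700.0, "night", "Solmissus")] * 5
            + [_ann("B", "B-night", 700.0, "night", "Beroe")] * 1
        )
        counts = aggregate_counts(events, simple_transects)
        tally = counts.set_index(["station", "period", "transect_depth_m", "taxon"])[
            "count"
        ]
        assert tally[("A", "day", 100.0, "Beroe")] == 4
        assert tally[("A", "day", 100.0, "Atolla")] == 2
        assert tally[("B", "night", 700.0, "Solmissus")] == 5
        assert tally[("B", "night", 700.0, "Beroe")] == 1
        # 12 events in total, zero-fill everywhere else
        assert counts["count"].sum() == 12


class TestEstimateCalibration:
    def test_definitional_recovery(self):
        ref = pd.DataFrame(
            {"count": [10], "duration_min": [10.0], "conc_per_m3": [0.1]}
        )
        factor = estimate_calibration(ref)
        assert factor.volume_per_minute_m3 == pytest.approx(10.0)
        assert factor.source == "estimated"

    def test_pooled_ratio_hand_calculation(self):
        ref = pd.DataFrame(
            {"count": [4, 6], "duration_min": [11.0, 22.0],
             "conc_per_m3": [0.05, 0.05]}
        )
        factor = estimate_calibration(ref)
        assert factor.volume_per_minute_m3 == pytest.approx((10 / 33) / 0.05)

    def test_all_zero_counts_cannot_estimate(self):
        ref = pd.DataFrame(
            {"count": [0, 0], "duration_min": [11.0, 11.0],
             "conc_per_m3": [0.05, 0.05]}
        )
        with pytest.raises(ValueError, match="cannot estimate"):
            estimate_calibration(ref)

    def test_transects_without_concentration_match_are_excluded(self):
        ref = pd.DataFrame(
            {"count": [10, 999], "duration_min": [10.0, 10.0],
             "conc_per_m3": [0.1, np.nan]}
        )
        factor = estimate_calibration(ref)
        assert factor.volume_per_minute_m3 == pytest.approx(10.0)

    def test_pooled_estimate_invariant_to_splitting_a_transect(self, rng):
        # one 22-min transect vs the same data cut into two 11-min halves
        counts = rng.poisson(30, 5)
        whole = pd.DataFrame(
            {"count": counts, "duration_min": 22.0, "conc_per_m3": 0.08}
        )
        split_counts = []
        for c in counts:
            first = rng.integers(0, c + 1)
            split_counts += [first, c - first]
        halves = pd.DataFrame(
            {"count": split_counts, "duration_min": 11.0, "conc_per_m3": 0.08}
        )
        f1 = estimate_calibration(whole).volume_per_minute_m3
        f2 = estimate_calibration(halves).volume_per_minute_m3
        assert f1 == pytest.approx(f2, rel=1e-12)


class TestToConcentration:
    def _counts(self, count):
        return pd.DataFrame(
            {
                "station": ["A"], "deployment_id": ["A-day"],
                "transect_depth_m": [400.0], "period": ["day"],
                "taxon": ["Beroe"], "count": [count],
            }
        )

    def _transects(self, duration):
        return [TransectMeta("A", "A-day", 400.0, "day", duration)]

    def test_hand_calculation(self):
        out = to_concentration(
            self._counts(13), self._transects(22.0), CalibrationFactor(5.0)
        )
        assert out["sampled_volume_m3"].item() == pytest.approx(110.0)
        assert out["concentration_per_1000m3"].item() == pytest.approx(13 / 110 * 1000)

    def test_zero_count_is_zero_concentration(self):
        out = to_concentration(
            self._counts(0), self._transects(22.0), CalibrationFactor(5.0)
        )
        assert out["concentration_per_1000m3"].item() == 0.0

    def test_doubling_duration_halves_concentration(self):
        short = to_concentration(
            self._counts(10), self._transects(11.0), CalibrationFactor(5.0)
        )["concentration_per_1000m3"].item()
        long = to_concentration(
            self._counts(10), self._transects(22.0), CalibrationFactor(5.0)
        )["concentration_per_1000m3"].item()
        assert long == pytest.approx(short / 2)


def test_match_reference_concentration_window():
    profile = pd.DataFrame(
        {"depth_m": [350.0, 400.0, 450.0, 800.0], "conc_per_m3": [0.2, 0.4, 0.6, 9.9]}
    )
    assert match_reference_concentration(profile, 400.0, 25.0) == pytest.approx(0.4)
    assert match_reference_concentration(profile, 400.0, 60.0) == pytest.approx(0.4)
    assert np.isnan(match_reference_concentration(profile, 600.0, 25.0))


def test_concentration_estimator_unbiased_on_synthetic_counts(rng):
    """Mean estimated concentration over many simulated transects stays
    within 3 Monte-Carlo standard errors of the true concentration."""
    true_conc = 0.12  # per m3
    factor = CalibrationFactor(8.0)
    duration = 11.0
    volume = factor.volume_per_minute_m3 * duration
    counts = rng.poisson(true_conc * volume, 1000)
    estimates = counts / volume
    se = estimates.std(ddof=1) / np.sqrt(len(estimates))
    assert abs(estimates.mean() - true_conc) < 3 * se
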