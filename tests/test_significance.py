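"""The robust-quantile outlier statistic and its intensity-binned form."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import erfc

import silacmap as sm
from silacmap.errors import StatisticError
from silacmap.significance import bin_sizes


def brute_force_percentile(values, pct):
    """Independent linear-interpolation percentile (oracle)."""
    ordered = sorted(values)
    rank = (len(ordered) - 1) * pct / 100.0
    lo = math.floor(rank)
    hi = math.ceil(rank)
    return ordered[lo] + (ordered[hi] - ordered[lo]) * (rank - lo)


class TestRobustQuantiles:
    def test_three_point_sample_matches_interpolation_oracle(self):
        values = [-1.0, 0.0, 1.0]
        q = sm.robust_quantiles(values)
        assert q.r_minus == pytest.approx(brute_force_percentile(values, 15.87))
        assert q.r_zero == pytest.approx(0.0)
        assert q.r_plus == pytest.approx(brute_force_percentile(values, 84.13))
        # frozen oracle values for the stated sample
        assert q.r_minus == pytest.approx(-0.6826, abs=1e-12)
        assert q.r_plus == pytest.approx(0.6826, abs=1e-12)

    def test_constant_sample_collapses_to_point(self):
        q = sm.robust_quantiles([2.5] * 7)
        assert q.r_minus == q.r_zero == q.r_plus == 2.5

    def test_large_normal_sample_recovers_unit_quantiles(self):
        rng = np.random.default_rng(0)
        q = sm.robust_quantiles(rng.standard_normal(200_000))
        assert q.r_minus == pytest.approx(-1.0, abs=0.02)
        assert q.r_zero == pytest.approx(0.0, abs=0.02)
        assert q.r_plus == pytest.approx(1.0, abs=0.02)

    def test_empty_and_nonfinite_rejected(self):
        with pytest.raises(StatisticError):
            sm.robust_quantiles([])
        with pytest.raises(StatisticError):
            sm.robust_quantiles([0.0, np.inf])

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=200))
    def test_ordering_invariant(self, values):
        q = sm.robust_quantiles(values)
        assert q.r_minus <= q.r_zero <= q.r_plus


class TestSignificanceA:
    def setup_method(self):
        self.q = sm.RobustQuantiles(-1.0, 0.0, 2.0)

    def test_median_scores_one_half(self):
        p, side = sm.significance_a(0.0, self.q)
        assert p == 0.5 and side == "center"

    def test_upper_quantile_scores_normal_tail_at_one_sigma(self):
        p, side = sm.significance_a(2.0, self.q)
        assert side == "right"
        assert p == pytest.approx(0.5 * erfc(1 / math.sqrt(2)), rel=1e-12)
        assert p == pytest.approx(0.15865525, abs=1e-6)

    def test_sides_use_their_own_spread(self):
        p_left, side = sm.significance_a(-1.0, self.q)
        assert side == "left"
        assert p_left == pytest.approx(0.5 * erfc(1 / math.sqrt(2)), rel=1e-12)

    def test_zero_spread_on_needed_side_is_an_error(self):
        degenerate = sm.RobustQuantiles(-1.0, 0.0, 0.0)
        with pytest.raises(StatisticError):
            sm.significance_a(0.5, degenerate)
        # the intact side still works
        p, side = sm.significance_a(-0.5, degenerate)
        assert side == "left" and 0 < p < 0.5

    @given(
        lower=st.floats(0.01, 20),
        upper=st.floats(0.01, 20),
        a=st.floats(-30, 30),
        b=st.floats(-30, 30),
    )
    def test_p_decreases_with_distance_from_median(self, lower, upper, a, b):
        q = sm.RobustQuantiles(-lower, 0.0, upper)
        pa, side_a = sm.significance_a(a, q)
        pb, side_b = sm.significance_a(b, q)
        assert 0 < pa <= 0.5 and 0 < pb <= 0.5
        if side_a == side_b and side_a != "center":
            if abs(a) > abs(b):
                assert pa <= pb

    def test_monte_carlo_calibration_on_standard_normal(self):
        """Right-side p < 0.05 should occur for ~5% of a standard-normal
        sample scored against its own robust quantiles."""
        rng = np.random.default_rng(1)
        sample = rng.standard_normal(20_000)
        q = sm.robust_quantiles(sample)
        hits = sum(
            1
            for r in sample
            if r > q.r_zero and sm.significance_a(float(r), q)[0] < 0.05
        )
        # binomial 99.9% interval around 0.05 of 20000
        assert 860 <= hits <= 1145


class TestSignificanceB:
    def _records(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "protein_id": [f"P{i:05d}" for i in range(n)],
                "replicate": 1,
                "log2_hl_norm": rng.standard_normal(n),
                "total_intensity": 10 ** rng.uniform(5, 9, n),
            }
        )

    @pytest.mark.parametrize(
        "n, bin_size, expected",
        [(900, 300, [300, 300, 300]), (950, 300, [300, 300, 350]), (500, 300, [500]), (50, 300, [50])],
    )
    def test_bin_partition_and_trailing_merge(self, n, bin_size, expected):
        assert bin_sizes(n, bin_size) == expected
        result = sm.significance_b(self._records(n), bin_size=bin_size)
        counts = result.groupby("bin_index").size().tolist()
        assert counts == expected
        assert len(result) == n  # bin conservation

    def test_single_bin_equals_significance_a(self):
        """For n < 2*bin_size the binned statistic must coincide with the
        plain statistic over the whole replicate (oracle equivalence)."""
        records = self._records(500)
        result = sm.significance_b(records, bin_size=300)
        q = sm.robust_quantiles(records["log2_hl_norm"])
        lookup = result.set_index("protein_id")
        for row in records.itertuples():
            expected_p, expected_side = sm.significance_a(row.log2_hl_norm, q)
            assert lookup.loc[row.protein_id, "p_sigb"] == pytest.approx(expected_p, rel=1e-12)
            assert lookup.loc[row.protein_id, "side"] == expected_side

    def test_null_ratios_excluded_before_binning(self):
        records = self._records(600)
        records.loc[records.index[:100], "log2_hl_norm"] = np.nan
        result = sm.significance_b(records, bin_size=300)
        assert len(result) == 500
        assert result["p_sigb"].notna().all()

    def test_intensity_ties_broken_by_protein_id(self):
        records = self._records(40)
        records["total_intensity"] = 1e6
        a = sm.significance_b(records, bin_size=10)
        b = sm.significance_b(records.sample(frac=1, random_state=4), bin_size=10)
        pd.testing.assert_frame_equal(
            a.sort_values("protein_id").reset_index(drop=True),
            b.sort_values("protein_id").reset_index(drop=True),
        )

    def test_too_few_records_or_tiny_bins_rejected(self):
        with pytest.raises(StatisticError):
            sm.significance_b(self._records(2))
        with pytest.raises(StatisticError):
            sm.significance_b(self._records(100), bin_size=5)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert sm.bh_adjust([0.01]) == pytest.approx([0.01])

    def test_hand_computed_step_up(self):
        adjusted = sm.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert adjusted == pytest.approx([0.04, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=50))
    def test_adjusted_never_below_raw(self, p_values):
        adjusted = sm.bh_adjust(p_values)
        assert np.all(adjusted >= np.asarray(p_values) - 1e-15)
        assert np.all(adjusted <= 1.0)
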