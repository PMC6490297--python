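import io

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from recmotif import (
    AnchorSet,
    RecombinationMap,
    loess_smooth,
    moving_median,
    normalize_to_cM,
    read_map,
    split_high_low,
)
from recmotif.recmap import EXCLUDED, HIGH, LOW, UNIT_CM, UNIT_RHO, _moving_median_1d


def make_map(values, bin_size=1000, unit=UNIT_CM, chrom="chr1"):
    values = np.asarray(values, dtype=float)
    return RecombinationMap(
        bin_size=bin_size,
        unit=unit,
        rates={chrom: values},
        lengths={chrom: len(values) * bin_size},
    )


class TestReadMap:
    def test_toy_csv(self):
        csv = "chrom,start,end,rate\nchr1,0,1000,1.5\nchr1,1000,2000,2.5\nchr1,2000,3000,0.5\n"
        m = read_map(io.StringIO(csv))
        assert m.bin_size == 1000
        assert m.n_bins("chr1") == 3
        np.testing.assert_array_equal(m.rates["chr1"], [1.5, 2.5, 0.5])

    def test_order_invariance(self):
        rows = ["chr1,1000,2000,2.5", "chr1,2000,3000,0.5", "chr1,0,1000,1.5"]
        m = read_map(io.StringIO("chrom,start,end,rate\n" + "\n".join(rows)))
        np.testing.assert_array_equal(m.rates["chr1"], [1.5, 2.5, 0.5])

    def test_gap_becomes_missing(self):
        csv = "chrom,start,end,rate\nchr1,0,1000,1.0\nchr1,2000,3000,2.0\n"
        m = read_map(io.StringIO(csv))
        assert np.isnan(m.rates["chr1"][1])

    @pytest.mark.parametrize(
        "rows",
        [
            "chr1,0,1000,1.0\nchr1,1000,2500,2.0\nchr1,2500,3500,1.0",  # odd width
            "chr1,0,1000,1.0\nchr1,500,1500,2.0",  # overlap
            "chr1,0,1000,-1.0",  # negative
        ],
    )
    def test_format_errors(self, rows):
        with pytest.raises(ValueError):
            read_map(io.StringIO("chrom,start,end,rate\n" + rows))


class TestNormalize:
    def test_uniform_forcing(self):
        m = make_map(np.full(1000, 7.0), unit=UNIT_RHO)
        anchors = AnchorSet([("chr1", 0, 1_000_000, 2.0)])
        out = normalize_to_cM(m, anchors)
        np.testing.assert_allclose(out.rates["chr1"], 2.0, rtol=1e-12)
        assert out.unit == UNIT_CM

    def test_scale_invariance(self):
        vals = np.linspace(1, 5, 500)
        anchors = AnchorSet([("chr1", 0, 500_000, 3.0)])
        a = normalize_to_cM(make_map(vals, unit=UNIT_RHO), anchors)
        b = normalize_to_cM(make_map(vals * 2, unit=UNIT_RHO), anchors)
        np.testing.assert_allclose(a.rates["chr1"], b.rates["chr1"], rtol=1e-12)

    def test_two_anchor_resummation(self):
        # 25% of rho mass in the first quarter, 75% in the rest
        vals = np.concatenate([np.full(250, 4.0), np.full(750, 4.0)])
        m = make_map(vals, unit=UNIT_RHO)
        anchors = AnchorSet(
            [("chr1", 0, 250_000, 1.0), ("chr1", 250_000, 1_000_000, 3.0)]
        )
        out = normalize_to_cM(m, anchors)
        # re-sum genetic length over the anchor intervals: must equal 4 cM
        rate = out.rates["chr1"]
        total_cm = rate.sum() * 1000 / 1e6
        assert abs(total_cm - 4.0) < 1e-9

    def test_zero_mass_error(self):
        m = make_map(np.zeros(100), unit=UNIT_RHO)
        with pytest.raises(ValueError):
            normalize_to_cM(m, AnchorSet([("chr1", 0, 100_000, 1.0)]))

    def test_requires_rho_unit(self):
        m = make_map([1, 2, 3], unit=UNIT_CM)
        with pytest.raises(ValueError):
            normalize_to_cM(m, AnchorSet([("chr1", 0, 3000, 1.0)]))


class TestMovingMedian:
    def test_constant_unchanged(self):
        m = make_map(np.full(50, 2.0))
        out = moving_median(m, 5)
        np.testing.assert_array_equal(out.rates["chr1"], 2.0)

    def test_small_example_with_truncated_edges(self):
        m = make_map([1, 5, 2, 8, 3])
        out = moving_median(m, 3).rates["chr1"]
        # interior: sort-per-window; edges: lower central order statistic
        np.testing.assert_array_equal(out, [1, 2, 5, 3, 3])

    def test_membership_property(self, rng):
        vals = rng.exponential(2.0, size=2001)
        m = make_map(vals)
        for w in (3, 25, 101):
            out = moving_median(m, w).rates["chr1"]
            half = w // 2
            for i in range(half, len(vals) - half, 97):
                window = vals[i - half : i + half + 1]
                assert out[i] in window

    def test_matches_naive_oracle(self, rng):
        vals = rng.exponential(1.0, size=3000)
        vals[rng.choice(3000, 100, replace=False)] = np.nan
        m = make_map(vals)
        for w in (5, 25, 101):
            out = moving_median(m, w).rates["chr1"]
            half = w // 2
            for i in range(0, 3000, 131):
                window = vals[max(0, i - half) : i + half + 1]
                window = window[~np.isnan(window)]
                if len(window) == 0:
                    assert np.isnan(out[i])
                else:
                    expected = np.sort(window)[(len(window) - 1) // 2]
                    assert out[i] == expected

    def test_monotone_preserving(self):
        vals = np.sort(np.random.default_rng(0).uniform(0, 5, 200))
        out = moving_median(make_map(vals), 9).rates["chr1"]
        assert np.all(np.diff(out) >= 0)

    def test_window_one_is_identity(self):
        vals = np.random.default_rng(1).uniform(size=20)
        out = moving_median(make_map(vals), 1).rates["chr1"]
        np.testing.assert_array_equal(out, vals)

    def test_parameter_errors(self):
        m = make_map(np.ones(10))
        with pytest.raises(ValueError):
            moving_median(m, 4)  # even window
        with pytest.raises(ValueError):
            moving_median(m, 11)  # longer than the chromosome
        with pytest.raises(ValueError):
            moving_median(m, 2.5)  # not a whole number of bins

    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=7, max_size=60))
    def test_full_window_membership(self, values):
        vals = np.asarray(values)
        out = _moving_median_1d(vals, 7)
        for i in range(3, len(vals) - 3):
            assert out[i] in vals[i - 3 : i + 4]


class TestLoess:
    def test_reproduces_lines(self):
        vals = np.linspace(0.5, 4.5, 200)
        out = loess_smooth(make_map(vals), span=0.3).rates["chr1"]
        np.testing.assert_allclose(out, vals, atol=1e-9)

    def test_constant(self):
        out = loess_smooth(make_map(np.full(50, 2.0)), span=0.5).rates["chr1"]
        np.testing.assert_allclose(out, 2.0, atol=1e-9)

    def test_step_track_matches_naive_oracle(self):
        import math

        vals = np.concatenate([np.ones(60), np.full(60, 4.0)])
        span = 0.3
        out = loess_smooth(make_map(vals), span=span).rates["chr1"]
        # independent naive per-point tricube weighted least squares
        x = np.arange(len(vals), dtype=float)
        n = len(x)
        k = max(2, math.ceil(span * n))
        expected = np.empty(n)
        for i in range(n):
            d = np.abs(x - x[i])
            dmax = np.sort(d)[k - 1]
            w = np.clip(1 - (d / dmax) ** 3, 0, None) ** 3
            A = np.stack([np.ones(n), x - x[i]], axis=1)
            sw = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(A * sw[:, None], vals * sw, rcond=None)
            expected[i] = coef[0]
        np.testing.assert_allclose(out, np.clip(expected, 0, None), atol=1e-9)

    def test_span_bounds(self):
        m = make_map(np.arange(20, dtype=float))
        with pytest.raises(ValueError):
            loess_smooth(m, 0.0)
        with pytest.raises(ValueError):
            loess_smooth(m, 1.5)


class TestSplitHighLow:
    def test_no_tie_case(self):
        labels = split_high_low(make_map([1, 2, 3, 4])).labels["chr1"]
        np.testing.assert_array_equal(labels, [LOW, LOW, HIGH, HIGH])

    def test_tie_at_median_goes_low(self):
        labels = split_high_low(make_map([1, 2, 2, 3])).labels["chr1"]
        np.testing.assert_array_equal(labels, [LOW, LOW, LOW, HIGH])

    def test_all_equal_gives_empty_high(self):
        labels = split_high_low(make_map([2, 2, 2, 2])).labels["chr1"]
        np.testing.assert_array_equal(labels, [LOW] * 4)

    def test_missing_excluded_and_partition(self, rng):
        vals = rng.uniform(size=500)
        vals[rng.choice(500, 40, replace=False)] = np.nan
        labels = split_high_low(make_map(vals)).labels["chr1"]
        missing = np.isnan(vals)
        assert np.all(labels[missing] == EXCLUDED)
        assert np.all(labels[~missing] != EXCLUDED)
        med = np.median(vals[~missing])
        np.testing.assert_array_equal(labels[~missing] == HIGH, vals[~missing] > med)

    def test_all_missing_error(self):
        with pytest.raises(ValueError):
            split_high_low(make_map([np.nan, np.nan, np.nan]))
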