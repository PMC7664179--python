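"""Agreement statistics: matching, MAD, Bland-Altman, ICC, Mann-Whitney."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitmark.agreement import (MatchedPairs, agreement_report, bland_altman,
                                classify_icc, icc_agreement, mann_whitney_u,
                                match_events, matched_stride_times,
                                mean_abs_difference, stride_times)
from gaitmark.signals import EventSeries, GaitEvent

from .oracles import mwu_by_pairwise_counting, mwu_exact_p_enumeration


def _pairs(diffs_s):
    d = np.asarray(diffs_s, dtype=float)
    return MatchedPairs(np.zeros_like(d), d, 0, 0)


class TestMatchEvents:
    def test_clean_pairing(self):
        p = match_events([1.00, 2.00], [1.01, 2.02])
        np.testing.assert_allclose(p.diffs, [0.01, 0.02])
        assert (p.n_unmatched_ref, p.n_unmatched_test) == (0, 0)

    def test_redundant_event_left_unmatched(self):
        p = match_events([1.00, 2.00], [1.01, 1.50, 2.02])
        assert p.n == 2
        assert p.n_unmatched_test == 1
        np.testing.assert_allclose(p.diffs, [0.01, 0.02])

    def test_tolerance_excludes_distant_events(self):
        p = match_events([1.0], [1.2], tolerance_s=0.1)
        assert p.n == 0
        assert (p.n_unmatched_ref, p.n_unmatched_test) == (1, 1)

    def test_pairing_never_crosses(self):
        # greedy accepts (1.05, 1.04) first; the remaining candidate
        # (1.00 -> 1.06) would cross it and must be refused
        p = match_events([1.00, 1.05], [1.04, 1.06], tolerance_s=0.1)
        assert p.n == 1
        np.testing.assert_allclose(p.ref_times, [1.05])
        np.testing.assert_allclose(p.test_times, [1.04])
        assert (p.n_unmatched_ref, p.n_unmatched_test) == (1, 1)

    @given(st.data())
    @settings(max_examples=40)
    def test_swap_symmetry(self, data):
        seed = data.draw(st.integers(0, 2 ** 20))
        rng = np.random.default_rng(seed)
        a = np.sort(rng.uniform(0, 30, rng.integers(1, 25)))
        b = np.sort(rng.uniform(0, 30, rng.integers(1, 25)))
        ab = match_events(a, b)
        ba = match_events(b, a)
        assert ab.n == ba.n
        assert ab.n_unmatched_ref == ba.n_unmatched_test
        assert ab.n_unmatched_test == ba.n_unmatched_ref
        np.testing.assert_allclose(np.sort(ab.diffs), np.sort(-ba.diffs))


class TestMeanAbsDifference:
    @pytest.mark.parametrize("diffs,expected", [
        ([-0.001, 0.001], (1.0, 0.0)),
        ([0.0, 0.0, 0.0], (0.0, 0.0)),
        ([0.010, 0.020, 0.030], (20.0, 10.0)),
    ])
    def test_hand_computed_values(self, diffs, expected):
        mad, sd = mean_abs_difference(_pairs(diffs))
        assert (mad, sd) == pytest.approx(expected)

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            mean_abs_difference(_pairs([]))


class TestBlandAltman:
    def test_zero_variance(self):
        assert bland_altman(_pairs([0.005] * 4)) == pytest.approx((5.0, 5.0, 5.0))

    def test_closed_form_sd_one_ms(self):
        bias, lo, hi = bland_altman(_pairs([0.001, 0.002, 0.003]))
        assert bias == pytest.approx(2.0)
        assert lo == pytest.approx(2.0 - 1.96)
        assert hi == pytest.approx(2.0 + 1.96)

    def test_symmetric_diffs_give_zero_bias(self):
        bias, lo, hi = bland_altman(_pairs([-0.004, -0.002, 0.002, 0.004]))
        assert bias == pytest.approx(0.0, abs=1e-12)
        assert lo == pytest.approx(-hi)

    def test_loa_width_identity(self, rng):
        d = rng.normal(0.005, 0.01, 200)
        bias, lo, hi = bland_altman(_pairs(d))
        assert hi - lo == pytest.approx(2 * 1.96 * np.std(d * 1e3, ddof=1))

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(_pairs([0.001]))


class TestStrideTimes:
    def test_successive_differences(self):
        assert stride_times([1.0, 2.2, 3.4]) == pytest.approx([1.2, 1.2])
        assert stride_times([1.0, 2.0, 3.5]) == pytest.approx([1.0, 1.5])
        assert stride_times([1.0]).size == 0

    def test_filters_by_kind_side_source(self):
        es = EventSeries([GaitEvent(1.0, "IC", "L", "OMC"),
                          GaitEvent(1.6, "TC", "L", "OMC"),
                          GaitEvent(2.1, "IC", "L", "OMC"),
                          GaitEvent(3.3, "IC", "L", "OMC"),
                          GaitEvent(1.5, "IC", "R", "OMC")])
        assert stride_times(es, "IC", "L", "OMC") == pytest.approx([1.1, 1.2])

    def test_matched_strides_skip_over_gaps(self):
        ref = [1.0, 2.0, 3.0, 4.0]
        test = [1.01, 3.01, 4.02]       # event at 2.0 omitted by test method
        pairs = match_events(ref, test)
        a, b = matched_stride_times(pairs)
        # only the 3->4 interval has consecutively matched endpoints
        np.testing.assert_allclose(a, [1.0])
        np.testing.assert_allclose(b, [1.01])


class TestIcc:
    def test_identical_series_give_exactly_one(self):
        a = [1.0, 1.1, 1.2, 1.05, 0.98]
        assert icc_agreement(a, a) == (1.0, 1.0, 1.0)

    def test_large_offset_destroys_absolute_agreement(self, rng):
        a = rng.normal(1.1, 0.03, 300)
        b = a + 0.30            # 10 x between-stride SD
        icc, _, _ = icc_agreement(a, b)
        assert icc < 0.5
        assert np.corrcoef(a, b)[0, 1] > 0.999
        # consistency form ignores the offset entirely
        assert icc_agreement(a, b, form="consistency")[0] > 0.99

    def test_matches_pingouin_reference(self, rng):
        import pandas as pd
        import pingouin as pg
        for n in (5, 9, 16):
            a = rng.normal(1.1, 0.05, n)
            b = a + rng.normal(0.002, 0.01, n)
            icc, lo, hi = icc_agreement(a, b)
            df = pd.DataFrame({"t": np.r_[np.arange(n), np.arange(n)],
                               "r": ["A"] * n + ["B"] * n, "y": np.r_[a, b]})
            row = pg.intraclass_corr(df, "t", "r", "y")
            row = row[row.Type == "ICC(A,1)"].iloc[0]
            assert icc == pytest.approx(row.ICC, abs=1e-10)
            assert lo == pytest.approx(row.CI95[0], abs=6e-3)  # theirs rounded
            assert hi == pytest.approx(row.CI95[1], abs=6e-3)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            icc_agreement([1.0, 2.0], [1.0, 2.0])          # n < 3
        with pytest.raises(ValueError):
            icc_agreement([1.0] * 5, [1.0] * 5)            # zero variance
        with pytest.raises(ValueError):
            icc_agreement([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], form="magic")


class TestClassifyIcc:
    @pytest.mark.parametrize("icc,label", [
        (0.45, "poor"), (0.5, "moderate"), (0.75, "moderate"),
        (0.80, "good"), (0.9, "good"), (0.91, "excellent"),
        (0.986, "excellent"), (-0.2, "poor"),
    ])
    def test_band_boundaries(self, icc, label):
        assert classify_icc(icc) == label

    def test_monotone_in_icc(self):
        order = ["poor", "moderate", "good", "excellent"]
        grid = [classify_icc(v) for v in np.linspace(-1, 1, 401)]
        assert [order.index(g) for g in grid] == \
            sorted(order.index(g) for g in grid)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_icc(float("nan"))


class TestMannWhitney:
    def test_separated_samples_exact_p(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)   # 2 of C(6,3)=20 assignments

    def test_tied_identical_samples(self):
        u, p = mann_whitney_u([1, 2], [1, 2])
        assert u == 2.0                  # n^2/2 with midrank ties
        assert p == 1.0

    @given(st.data())
    @settings(max_examples=40)
    def test_u_statistics_sum_to_n1_n2(self, data):
        seed = data.draw(st.integers(0, 2 ** 20))
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(1, 12, 2)
        x = rng.integers(0, 6, n1)       # integer pool forces ties
        y = rng.integers(0, 6, n2)
        ux, _ = mann_whitney_u(x, y)
        uy, _ = mann_whitney_u(y, x)
        assert ux + uy == pytest.approx(n1 * n2)
        assert ux == mwu_by_pairwise_counting(x, y)

    def test_exact_mode_agrees_with_value_enumeration(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(2, 7, 2)
            x = rng.integers(0, 5, n1)
            y = rng.integers(0, 5, n2)
            _, p = mann_whitney_u(x, y, exact=True)
            assert p == pytest.approx(mwu_exact_p_enumeration(x, y))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestAgreementReport:
    def _series(self, times, source, offset=0.0):
        evts = []
        for side in ("L", "R"):
            shift = 0.0 if side == "L" else 0.55
            for i, t in enumerate(times):
                evts.append(GaitEvent(t + shift + offset,
                                      ("IC", "TC")[i % 2], side, source))
        return EventSeries(evts, "FW")

    def test_identical_series_perfect_agreement(self):
        rng = np.random.default_rng(1)
        base = list(np.cumsum([1.0] + list(rng.uniform(0.5, 0.6, 20))))
        ref = self._series(base, "OMC")
        test = self._series(base, "IMU")
        reports = agreement_report(ref, test)
        for kind in ("IC", "TC"):
            r = reports[kind]
            assert (r.mad_ms, r.mad_sd_ms, r.bias_ms) == (0.0, 0.0, 0.0)
            assert (r.loa_low_ms, r.loa_high_ms) == (0.0, 0.0)
            assert r.icc == 1.0 and r.icc_class == "excellent"
            assert (r.n_unmatched_ref, r.n_unmatched_test) == (0, 0)

    def test_constant_shift_moves_bias_not_spread(self):
        rng = np.random.default_rng(0)
        base = list(np.cumsum([1.0] + list(rng.uniform(0.5, 0.6, 24))))
        ref = self._series(base, "OMC")
        test = self._series(base, "IMU", offset=0.010)
        reports = agreement_report(ref, test)
        for r in reports.values():
            assert r.mad_ms == pytest.approx(10.0)
            assert r.mad_sd_ms == pytest.approx(0.0, abs=1e-9)
            assert r.bias_ms == pytest.approx(10.0)
            assert r.loa_low_ms == pytest.approx(10.0)
            assert r.loa_high_ms == pytest.approx(10.0)

    def test_per_side_reports_available(self):
        rng = np.random.default_rng(2)
        base = list(np.cumsum([1.0] + list(rng.uniform(0.5, 0.6, 12))))
        ref = self._series(base, "OMC")
        test = self._series(base, "IMU")
        reports = agreement_report(ref, test, pool_sides=False)
        assert set(reports) == {(k, s) for k in ("IC", "TC")
                                for s in ("L", "R")}

    def test_loa_bracket_invariant_enforced(self):
        from gaitmark.agreement import AgreementReport
        with pytest.raises(ValueError):
            AgreementReport("IC", 5, 1.0, 1.0, 5.0, 6.0, 7.0, None, None,
                            None, 0, 0, 0)
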