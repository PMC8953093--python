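"""RR intervals, ventricular response, regularity, P presence, AF rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ecgdelin as ed
from ecgdelin.af import RRSeries
from ecgdelin.errors import InsufficientDataError, ValidationError


def series(rr_ms):
    rr_ms = np.asarray(rr_ms, dtype=float)
    return RRSeries(rpeaks=np.concatenate(([0], np.cumsum(rr_ms))).astype(int),
                    fs=1000.0, rr_ms=rr_ms, bpm=60000.0 / rr_ms)


class TestRrIntervals:
    def test_one_second_intervals(self):
        rr = ed.rr_intervals([0, 250, 500], fs=250.0)
        np.testing.assert_allclose(rr.rr_ms, [1000.0, 1000.0])
        np.testing.assert_allclose(rr.bpm, [60.0, 60.0])

    def test_half_second_interval(self):
        rr = ed.rr_intervals([0, 125], fs=250.0)
        assert rr.rr_ms[0] == pytest.approx(500.0)
        assert rr.bpm[0] == pytest.approx(120.0)

    def test_nonincreasing_rejected(self):
        with pytest.raises(ValidationError):
            ed.rr_intervals([10, 10, 20], fs=250.0)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 300), min_size=1, max_size=30))
    def test_telescoping_sum(self, gaps):
        peaks = np.concatenate(([0], np.cumsum(gaps)))
        rr = ed.rr_intervals(peaks, fs=250.0)
        assert rr.rr_ms.sum() == pytest.approx((peaks[-1] - peaks[0]) / 250.0 * 1000)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 300), min_size=2, max_size=20))
    def test_agrees_with_pairwise_oracle(self, gaps):
        peaks = np.concatenate(([0], np.cumsum(gaps)))
        rr = ed.rr_intervals(peaks, fs=200.0)
        oracle = [(peaks[i + 1] - peaks[i]) / 200.0 * 1000 for i in range(len(peaks) - 1)]
        np.testing.assert_allclose(rr.rr_ms, oracle)


class TestVentricularResponse:
    @pytest.mark.parametrize(
        "bpm, expected",
        [(80, "normal"), (45, "slow"), (120, "rapid"),
         (60, "normal"), (100, "normal"), (59.9, "slow"), (100.1, "rapid")],
    )
    def test_banding(self, bpm, expected):
        assert ed.classify_response(bpm) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            ed.classify_response(0)


class TestRegularity:
    def test_constant_rr_is_regular(self):
        regular, trace = ed.assess_regularity(series([800.0] * 16))
        assert regular
        assert all(w["patterned"] for w in trace)

    def test_alternating_rr_is_irregular(self):
        # every 6-interval window of 600/1200 has median 900; deviation 300/900 > 10%
        regular, trace = ed.assess_regularity(series([600, 1200] * 8))
        assert not regular
        assert not any(w["patterned"] for w in trace)

    def test_slow_drift_is_regular(self):
        # 800 -> 840 ms in 5 ms steps: within-window deviation from median
        # is at most 12.5/~812 < 10%
        rr = [800 + 5 * i for i in range(9)]
        regular, _ = ed.assess_regularity(series(rr))
        assert regular

    def test_band_disagreement_breaks_pattern(self):
        # steady timing but straddling the 60 BPM boundary: 990 vs 1010 ms
        rr = [990, 1010] * 6
        regular, trace = ed.assess_regularity(series(rr))
        assert not regular

    def test_too_few_intervals_is_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            ed.assess_regularity(series([800] * 4))

    def test_invalid_window_size_rejected(self):
        with pytest.raises(ValidationError):
            ed.assess_regularity(series([800] * 20), window_beats=4)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.5, 2.0), st.integers(0, 5))
    def test_tolerance_verdicts_invariant_to_uniform_time_rescaling(self, scale, seed):
        """The relative-tolerance part of the pattern rule is scale-free;
        only the absolute 60/100 BPM bands may change under rescaling."""
        rng = np.random.default_rng(seed)
        rr = 800 + 80 * rng.standard_normal(15)
        _, trace_a = ed.assess_regularity(series(rr))
        _, trace_b = ed.assess_regularity(series(rr * scale))
        assert [w["within_tolerance"] for w in trace_a] == \
            [w["within_tolerance"] for w in trace_b]


class TestPPresence:
    def mask_with_p(self, n_p):
        classes = np.full(370, 3)
        classes[10:10 + n_p] = 0
        return ed.LabelMask(classes)

    def test_all_beats_with_p(self):
        masks = [self.mask_with_p(20) for _ in range(5)]  # 80 ms runs
        present, trace = ed.detect_p_presence(masks, 250.0)
        assert present
        assert all(b["has_p"] for b in trace)

    def test_no_p_anywhere(self):
        masks = [ed.LabelMask(np.full(370, 3))] * 5
        present, _ = ed.detect_p_presence(masks, 250.0)
        assert not present

    def test_four_of_ten_below_majority(self):
        masks = [self.mask_with_p(18) for _ in range(4)]  # 72 ms, has P
        masks += [ed.LabelMask(np.full(370, 3))] * 6
        present, trace = ed.detect_p_presence(masks, 250.0, beat_fraction=0.5)
        assert sum(b["has_p"] for b in trace) == 4
        assert not present

    def test_sub_duration_runs_dont_count(self):
        masks = [self.mask_with_p(10) for _ in range(5)]  # 40 ms < 60 ms
        present, _ = ed.detect_p_presence(masks, 250.0)
        assert not present

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            ed.detect_p_presence([], 250.0)


class TestIdentifyAf:
    @pytest.mark.parametrize(
        "p_present, regular, expected",
        [(True, True, "NSR"), (False, True, "NSR"),
         (True, False, "AF"), (False, False, "AF")],
    )
    def test_truth_table(self, p_present, regular, expected):
        result = ed.identify_af(p_present, regular)
        assert result.decision == expected
        # regularity alone drives the decision
        assert (result.decision == "AF") == (not regular)
        assert result.evidence["inputs"] == {
            "p_present": p_present, "regular": regular}


class TestPpvNpv:
    def test_perfect_agreement(self):
        ppv, npv, f1, counts = ed.ppv_npv(["AF", "NSR"], ["AF", "NSR"])
        assert (ppv, npv, f1) == (1.0, 1.0, 1.0)

    def test_hand_counts(self):
        decisions = ["AF"] * 10 + ["NSR"] * 10
        truth = ["AF"] * 8 + ["NSR"] * 2 + ["NSR"] * 9 + ["AF"] * 1
        ppv, npv, f1, counts = ed.ppv_npv(decisions, truth)
        assert counts == {"TP": 8, "FP": 2, "TN": 9, "FN": 1}
        assert ppv == pytest.approx(0.8)
        assert npv == pytest.approx(0.9)

    def test_no_positive_calls_null_flags_ppv(self):
        ppv, npv, f1, _ = ed.ppv_npv(["NSR", "NSR"], ["AF", "NSR"])
        assert ppv is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            ed.ppv_npv(["AF"], ["AF", "NSR"])


class TestScreenRecord:
    def test_short_record_abstains(self, trained_estimator):
        record, _, _ = ed.generate_record(ed.RhythmSpec.nsr(seed=1, n_beats=3))
        result = ed.screen_record(record, trained_estimator)
        assert result.decision is None
        assert result.abstained is not None

    def test_nsr_and_af_records_classified(self, trained_estimator):
        nsr, _, _ = ed.generate_record(ed.RhythmSpec.nsr(seed=101, n_beats=20))
        af, _, _ = ed.generate_record(ed.RhythmSpec.af(seed=101, n_beats=20))
        res_nsr = ed.screen_record(nsr, trained_estimator)
        res_af = ed.screen_record(af, trained_estimator)
        assert res_nsr.decision == "NSR"
        assert res_nsr.p_present is True
        assert res_af.decision == "AF"
        assert res_af.p_present is False
        # evidence reproduces the decision
        assert (res_af.decision == "AF") == (not res_af.regular)

    def test_screener_estimator_scores(self, trained_estimator):
        records, truth = [], []
        for i in range(3):
            r, _, _ = ed.generate_record(ed.RhythmSpec.nsr(seed=300 + i, n_beats=15))
            records.append(r)
            truth.append("NSR")
        screener = ed.AfScreener(model=trained_estimator).fit()
        assert screener.score(records, truth) == 1.0
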