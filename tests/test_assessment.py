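"""Confusion counting, detection scores, RMSE gating and delta correlation."""

import numpy as np
import pytest

from swimprog.assessment import (
    ConfusionCounts,
    DeltaRecord,
    build_delta_records,
    classify_pairs,
    delta_correlation,
    detection_scores,
    effect_size_summary,
    filter_by_rmse,
    metric_detects,
    p_value_stars,
)
from swimprog.effect_size import EffectSizeResult
from swimprog.pipeline import ComparisonPair


def _effect(d, significant):
    lo, hi = (0.2, 0.99) if (significant and d > 0) else (-0.5, 0.5)
    if significant and d < 0:
        lo, hi = -0.99, -0.2
    return EffectSizeResult(
        d=d, ci_lower=lo, ci_upper=hi, confidence_level=0.95,
        significant=significant, dominance_rows=(d,) * 5,
        dominance_cols=(d,) * 5, s_d2=0.01, t_crit=2.3,
    )


def _pair(meaningful, metric_d, metric_sig, delta=0.1, laptime_change=1.0):
    return ComparisonPair(
        swimmer_id="A",
        session_m=1,
        session_n=2,
        laptime_effect=_effect(0.9, True),
        metric_effects={"swim_vavg": _effect(metric_d, metric_sig)},
        median_laptime_change=laptime_change,
        median_metric_change={"swim_vavg": delta},
        significant_laptime=True,
        meaningful_progress=meaningful,
    )


class TestClassifyPairs:
    def test_association_rules(self):
        pairs = [
            _pair(True, 0.9, True),    # TP
            _pair(False, 0.1, False),  # TN
            _pair(False, 0.9, True),   # FP
            _pair(True, 0.1, False),   # FN
        ]
        c = classify_pairs(pairs, metrics=("swim_vavg",))["swim_vavg"]
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 1, 1)

    def test_significant_worsening_does_not_detect(self):
        # significant velocity *decrease* is not an improvement signal
        pair = _pair(True, -0.9, True)
        assert not metric_detects(pair, "swim_vavg")
        c = classify_pairs([pair], metrics=("swim_vavg",))["swim_vavg"]
        assert (c.tp, c.fn) == (0, 1)

    def test_counts_partition_pairs(self):
        pairs = (
            [_pair(True, 0.9, True)] * 3
            + [_pair(False, 0.1, False)] * 4
            + [_pair(False, 0.9, True)]
            + [_pair(True, 0.1, False)] * 2
        )
        c = classify_pairs(pairs, metrics=("swim_vavg",))["swim_vavg"]
        assert c.total == len(pairs) == 10

    def test_missing_metric_skipped(self):
        c = classify_pairs([_pair(True, 0.9, True)], metrics=("push_vmax",))
        assert c["push_vmax"].total == 0


class TestDetectionScores:
    def test_formula_example(self):
        s = detection_scores(ConfusionCounts(tp=3, tn=4, fp=1, fn=2))
        assert s.accuracy == pytest.approx(0.70)
        assert s.precision == pytest.approx(0.75)
        assert s.sensitivity == pytest.approx(0.60)
        assert s.specificity == pytest.approx(0.80)

    def test_perfect_detector(self):
        s = detection_scores(ConfusionCounts(tp=5, tn=7, fp=0, fn=0))
        assert (s.accuracy, s.precision, s.sensitivity, s.specificity) == (
            1.0, 1.0, 1.0, 1.0,
        )

    def test_zero_sensitivity(self):
        s = detection_scores(ConfusionCounts(tp=0, tn=1, fp=0, fn=3))
        assert s.sensitivity == 0.0

    def test_undefined_denominators_are_none(self):
        s = detection_scores(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert s.precision is None
        assert s.sensitivity is None
        assert s.specificity == 1.0

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            detection_scores(ConfusionCounts())

    def test_sensitivity_algebra(self):
        c = ConfusionCounts(tp=13, tn=9, fp=4, fn=6)
        s = detection_scores(c)
        assert s.sensitivity * (c.tp + c.fn) == pytest.approx(c.tp)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1)


class TestEffectSizeSummary:
    def test_all_ones(self):
        pairs = [_pair(True, 1.0, True)] * 3
        frame = effect_size_summary(pairs, metrics=("swim_vavg",))
        row = frame[frame["variable"] == "swim_vavg"].iloc[0]
        assert row["effect_size"] == 1.0
        lap = frame[frame["variable"] == "lap_time"].iloc[0]
        assert lap["n_pairs"] == 3

    def test_empty_selection(self):
        frame = effect_size_summary(
            [_pair(False, 0.1, False)], metrics=("swim_vavg",)
        )
        assert frame.empty


class TestRmseFilter:
    def test_inside_band_removed(self):
        recs = [DeltaRecord("swim_vavg", 0.05, -0.5)]
        assert filter_by_rmse(recs, {"swim_vavg": 0.1}) == []

    def test_zero_band_keeps_nonzero(self):
        recs = [DeltaRecord("swim_vavg", v, -0.5) for v in (0.05, -0.2, 1.0)]
        assert len(filter_by_rmse(recs, {"swim_vavg": 0.0})) == 3

    def test_mixed_set(self):
        recs = [
            DeltaRecord("swim_vavg", v, -0.5) for v in (0.05, 0.15, -0.12)
        ]
        kept = filter_by_rmse(recs, {"swim_vavg": 0.1})
        assert sorted(r.delta_value for r in kept) == [-0.12, 0.15]

    def test_missing_rmse_names_metric(self):
        with pytest.raises(KeyError, match="push_vmax"):
            filter_by_rmse([DeltaRecord("push_vmax", 0.1, -0.5)], {})

    def test_monotone_in_rmse(self, rng):
        recs = [
            DeltaRecord("swim_vavg", float(v), -0.5)
            for v in rng.normal(0, 0.2, size=200)
        ]
        sizes = [
            len(filter_by_rmse(recs, {"swim_vavg": band}))
            for band in (0.0, 0.05, 0.1, 0.2, 0.4)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestDeltaCorrelation:
    def test_exact_linear_gives_minus_one(self):
        recs = [
            DeltaRecord("swim_vavg", 0.1 * i, -0.2 * i + 0.05) for i in range(10)
        ]
        frame = delta_correlation(recs, metrics=("swim_vavg",))
        assert frame.iloc[0]["r"] == pytest.approx(-1.0)
        assert frame.iloc[0]["stars"] == "***"

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(99)
        recs = [
            DeltaRecord("swim_vavg", float(x), float(y))
            for x, y in zip(rng.normal(size=500), rng.normal(size=500))
        ]
        frame = delta_correlation(recs, metrics=("swim_vavg",))
        assert abs(frame.iloc[0]["r"]) < 0.1

    def test_too_few_records_skipped(self):
        recs = [DeltaRecord("swim_vavg", 0.1, -0.2)] * 2
        assert delta_correlation(recs, metrics=("swim_vavg",)).empty

    def test_zero_variance_flagged(self):
        recs = [DeltaRecord("swim_vavg", 0.1, -0.2 * i) for i in range(5)]
        frame = delta_correlation(recs, metrics=("swim_vavg",))
        assert np.isnan(frame.iloc[0]["r"])
        assert frame.iloc[0]["stars"] == ""

    def test_invalid_records_excluded(self):
        recs = [
            DeltaRecord("swim_vavg", 0.1 * i, -0.2 * i, valid=i % 2 == 0)
            for i in range(10)
        ]
        frame = delta_correlation(recs, metrics=("swim_vavg",))
        assert frame.iloc[0]["n"] == 5


def test_build_delta_records_meaningful_only():
    pairs = [
        _pair(True, 0.9, True, delta=0.2, laptime_change=1.0),
        _pair(False, 0.1, False, delta=0.05, laptime_change=0.1),
    ]
    recs = build_delta_records(pairs, metrics=("swim_vavg",))
    assert len(recs) == 1
    assert recs[0].delta_value == pytest.approx(0.2)
    assert recs[0].delta_laptime == pytest.approx(-1.0)
    assert len(build_delta_records(pairs, metrics=("swim_vavg",),
                                   meaningful_only=False)) == 2


@pytest.mark.parametrize(
    "p, stars",
    [(0.2, ""), (0.049, "*"), (0.009, "**"), (0.0009, "***"), (0.05, "")],
)
def test_p_value_stars(p, stars):
    assert p_value_stars(p) == stars
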