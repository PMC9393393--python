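"""Scoring goal metrics as detectors of meaningful progress.

Each comparison pair is mapped to one confusion-matrix cell per goal
metric: the metric "detects" when its effect size is significant in the
improvement direction (velocity increase), and the reference label is the
pair's meaningful-progress flag.  Accuracy, precision, sensitivity and
specificity summarize each metric; effect sizes are pooled for the pairs
where both detection and progress agree; and per-pair metric changes are
correlated with the lap-time change after discarding changes smaller in
magnitude than the metric's estimation RMSE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pipeline import GOAL_METRICS, ComparisonPair

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "DetectionScores",
    "DeltaRecord",
    "metric_detects",
    "classify_pairs",
    "detection_scores",
    "effect_size_summary",
    "build_delta_records",
    "filter_by_rmse",
    "delta_correlation",
    "p_value_stars",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN counts for one goal metric over a set of pairs."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class DetectionScores:
    """Accuracy, precision, sensitivity, specificity for one metric.

    A score whose denominator is zero is reported as ``None`` (undefined),
    never silently coerced to 0 or 1.
    """

    accuracy: float | None
    precision: float | None
    sensitivity: float | None
    specificity: float | None


@dataclass(frozen=True)
class DeltaRecord:
    """Per-pair change in one goal metric paired with the lap-time change.

    ``delta_value`` is later-minus-earlier in m/s, ``delta_laptime``
    later-minus-earlier in seconds (negative when the swimmer got faster).
    ``valid`` is set by the RMSE gate: changes no larger in magnitude than
    the metric's estimation error are too small to trust.
    """

    metric_name: str
    delta_value: float
    delta_laptime: float
    valid: bool = True


def metric_detects(pair: ComparisonPair, metric: str) -> bool:
    """Whether a goal metric signals improvement for this pair.

    Detection requires the metric's effect size to be significant *and*
    oriented as an improvement (velocity increase in the later session,
    i.e. d > 0 under the later-vs-earlier convention).
    """
    effect = pair.metric_effects[metric]
    return effect.significant and effect.d > 0


def classify_pairs(
    pairs: Iterable[ComparisonPair],
    metrics: Sequence[str] = GOAL_METRICS,
) -> dict[str, ConfusionCounts]:
    """Confusion counts per goal metric against meaningful progress.

    Association rules: TP = metric detects and the pair is meaningful
    progress; TN = neither; FP = metric detects without meaningful
    progress; FN = meaningful progress the metric misses.  Pairs lacking a
    metric are skipped for that metric (and logged), so per-metric totals
    can differ.
    """
    counts = {m: {"tp": 0, "tn": 0, "fp": 0, "fn": 0} for m in metrics}
    for pair in pairs:
        for metric in metrics:
            if metric not in pair.metric_effects:
                logger.warning(
                    "swimmer %s pair (%d, %d): metric %r unavailable, not "
                    "counted",
                    pair.swimmer_id, pair.session_m, pair.session_n, metric,
                )
                continue
            detected = metric_detects(pair, metric)
            if pair.meaningful_progress:
                key = "tp" if detected else "fn"
            else:
                key = "fp" if detected else "tn"
            counts[metric][key] += 1
    return {m: ConfusionCounts(**c) for m, c in counts.items()}


def _ratio(num: int, den: int, name: str, metric: str | None) -> float | None:
    if den == 0:
        label = f" for {metric!r}" if metric else ""
        logger.warning("%s undefined%s: zero denominator", name, label)
        return None
    return num / den


def detection_scores(
    c: ConfusionCounts, metric: str | None = None
) -> DetectionScores:
    """The four detection ratios from a set of confusion counts.

    accuracy = (TP+TN)/(TP+TN+FP+FN), precision = TP/(TP+FP),
    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).  Zero-denominator
    scores come back as ``None`` with a logged warning.
    """
    if c.total == 0:
        raise ValueError("cannot score an empty set of pairs")
    return DetectionScores(
        accuracy=_ratio(c.tp + c.tn, c.total, "accuracy", metric),
        precision=_ratio(c.tp, c.tp + c.fp, "precision", metric),
        sensitivity=_ratio(c.tp, c.tp + c.fn, "sensitivity", metric),
        specificity=_ratio(c.tn, c.tn + c.fp, "specificity", metric),
    )


def effect_size_summary(
    pairs: Iterable[ComparisonPair],
    metrics: Sequence[str] = GOAL_METRICS,
) -> pd.DataFrame:
    """Pooled effect sizes for pairs with meaningful progress.

    For each goal metric, pairs where the progress was meaningful *and* the
    metric detected it are pooled: the summary effect size is the median
    ``d`` and the pooled interval is the min/max of the individual CI
    bounds.  A ``lap_time`` row pools the lap-time effect over all
    meaningful-progress pairs.  Returns an empty frame (logged) when no
    pair qualifies.
    """
    rows = []
    pairs = list(pairs)
    for metric in metrics:
        selected = [
            p
            for p in pairs
            if p.meaningful_progress
            and metric in p.metric_effects
            and metric_detects(p, metric)
        ]
        if not selected:
            continue
        effects = [p.metric_effects[metric] for p in selected]
        rows.append(
            {
                "variable": metric,
                "n_pairs": len(selected),
                "effect_size": float(np.median([e.d for e in effects])),
                "ci_lower": min(e.ci_lower for e in effects),
                "ci_upper": max(e.ci_upper for e in effects),
            }
        )
    meaningful = [p for p in pairs if p.meaningful_progress]
    if meaningful:
        effects = [p.laptime_effect for p in meaningful]
        rows.append(
            {
                "variable": "lap_time",
                "n_pairs": len(meaningful),
                "effect_size": float(np.median([e.d for e in effects])),
                "ci_lower": min(e.ci_lower for e in effects),
                "ci_upper": max(e.ci_upper for e in effects),
            }
        )
    if not rows:
        logger.warning("effect-size summary: no qualifying pairs")
        return pd.DataFrame(
            columns=["variable", "n_pairs", "effect_size", "ci_lower", "ci_upper"]
        )
    return pd.DataFrame(rows)


def build_delta_records(
    pairs: Iterable[ComparisonPair],
    metrics: Sequence[str] = GOAL_METRICS,
    *,
    meaningful_only: bool = True,
) -> list[DeltaRecord]:
    """Per-pair metric/lap-time changes, by default for meaningful pairs only."""
    records = []
    for pair in pairs:
        if meaningful_only and not pair.meaningful_progress:
            continue
        delta_lt = -pair.median_laptime_change
        for metric in metrics:
            if metric not in pair.median_metric_change:
                continue
            records.append(
                DeltaRecord(
                    metric_name=metric,
                    delta_value=pair.median_metric_change[metric],
                    delta_laptime=delta_lt,
                )
            )
    return records


def filter_by_rmse(
    deltas: Iterable[DeltaRecord],
    rmse_per_metric: Mapping[str, float],
) -> list[DeltaRecord]:
    """Keep records whose change magnitude strictly exceeds the metric RMSE.

    Changes inside the ±RMSE band are attributable to estimation error and
    are dropped; the number removed per metric is logged.  Every metric
    present in ``deltas`` must have an RMSE entry.
    """
    removed: dict[str, int] = {}
    kept = []
    for rec in deltas:
        try:
            rmse = rmse_per_metric[rec.metric_name]
        except KeyError:
            raise KeyError(
                f"no RMSE configured for metric {rec.metric_name!r}"
            ) from None
        if rmse < 0:
            raise ValueError(f"RMSE for {rec.metric_name!r} must be >= 0")
        if abs(rec.delta_value) > rmse:
            kept.append(
                DeltaRecord(rec.metric_name, rec.delta_value, rec.delta_laptime, True)
            )
        else:
            removed[rec.metric_name] = removed.get(rec.metric_name, 0) + 1
    for metric, n in sorted(removed.items()):
        logger.info("RMSE filter removed %d delta records for %r", n, metric)
    return kept


def p_value_stars(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def delta_correlation(
    deltas: Iterable[DeltaRecord],
    metrics: Sequence[str] = GOAL_METRICS,
) -> pd.DataFrame:
    """Pearson correlation of each metric's change with the lap-time change.

    One row per metric with at least 3 valid records: mean, sd and range of
    the metric change, Pearson r against the lap-time change, the two-sided
    p-value and its star rendering.  Zero variance in either variable makes
    r undefined (NaN, flagged).
    """
    deltas = [d for d in deltas if d.valid]
    rows = []
    for metric in metrics:
        sub = [d for d in deltas if d.metric_name == metric]
        if len(sub) < 3:
            logger.warning(
                "correlation for %r skipped: %d valid records (< 3)",
                metric, len(sub),
            )
            continue
        x = np.array([d.delta_value for d in sub])
        y = np.array([d.delta_laptime for d in sub])
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("correlation for %r undefined: zero variance", metric)
            r, p = float("nan"), float("nan")
            stars = ""
        else:
            r, p = stats.pearsonr(x, y)
            stars = p_value_stars(p)
        rows.append(
            {
                "metric": metric,
                "n": len(sub),
                "mean_delta": float(x.mean()),
                "sd_delta": float(x.std(ddof=1)),
                "range_delta": float(np.ptp(x)),
                "r": float(r),
                "p_value": float(p),
                "stars": stars,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "metric", "n", "mean_delta", "sd_delta", "range_delta",
            "r", "p_value", "stars",
        ],
    )
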