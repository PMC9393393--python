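"""Within-swimmer session comparison: pair enumeration, the meaningful
lap-time-change (MLTC) threshold, and two-step progress detection.

Step one flags session pairs whose lap times differ significantly under
Cliff's delta at the configured confidence level.  Step two retains, among
the significant pairs, only those whose median lap-time decrease (later
session faster) strictly exceeds the MLTC threshold; these are the pairs
with *meaningful progress*.

Sign conventions
----------------
``median_laptime_change`` is ``median(earlier) - median(later)`` so positive
values mean improvement (shorter lap times later).  Effect sizes for lap
time are computed as earlier-vs-later and for goal metrics as
later-vs-earlier, so in both cases ``d > 0`` points in the improvement
direction (faster laps, higher velocities).
"""

from __future__ import annotations

import itertools
import logging
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .effect_size import EffectSizeResult, cliff_delta_ci

logger = logging.getLogger(__name__)

__all__ = [
    "GOAL_METRICS",
    "SessionRecord",
    "ComparisonPair",
    "MltcEstimate",
    "enumerate_pairs",
    "compute_mltc",
    "detect_progress",
]

#: Canonical goal-metric column order: wall push-off peak velocity, glide end
#: velocity, stroke-preparation average velocity, free-swimming average
#: velocity, whole-lap average velocity (all m/s).
GOAL_METRICS = ("push_vmax", "glid_vend", "stpr_vavg", "swim_vavg", "lap_vavg")


@dataclass(frozen=True)
class SessionRecord:
    """One swimmer-session: five lap times plus per-lap goal metrics."""

    swimmer_id: str
    session_index: int
    lap_times: tuple[float, ...]
    goal_metrics: Mapping[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        if len(self.lap_times) != 5:
            raise ValueError(
                f"{self.swimmer_id} session {self.session_index}: expected "
                f"5 lap times, got {len(self.lap_times)}"
            )
        if any(not np.isfinite(t) or t <= 0 for t in self.lap_times):
            raise ValueError(
                f"{self.swimmer_id} session {self.session_index}: lap times "
                "must be finite and positive"
            )
        for name, vals in self.goal_metrics.items():
            if len(vals) != len(self.lap_times):
                raise ValueError(
                    f"{self.swimmer_id} session {self.session_index}: metric "
                    f"{name!r} has {len(vals)} values for "
                    f"{len(self.lap_times)} laps"
                )
            if any(not np.isfinite(v) or v <= 0 for v in vals):
                raise ValueError(
                    f"{self.swimmer_id} session {self.session_index}: metric "
                    f"{name!r} must be finite and positive"
                )

    @property
    def median_lap_time(self) -> float:
        return statistics.median(self.lap_times)


@dataclass(frozen=True)
class MltcEstimate:
    """Meaningful lap-time-change threshold derived from 3-week-apart pairs."""

    value: float
    dispersion: float
    n_pairs: int

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("MLTC value must be non-negative")
        if self.n_pairs < 1:
            raise ValueError("MLTC requires at least one comparison pair")


@dataclass(frozen=True)
class ComparisonPair:
    """All effect sizes and labels for one within-swimmer session pair.

    ``session_m < session_n``; m is the earlier session.  ``metric_effects``
    holds later-vs-earlier effect sizes keyed by metric name and
    ``median_metric_change`` the later-minus-earlier change in the per-lap
    median of each metric (m/s).
    """

    swimmer_id: str
    session_m: int
    session_n: int
    laptime_effect: EffectSizeResult
    metric_effects: Mapping[str, EffectSizeResult]
    median_laptime_change: float
    median_metric_change: Mapping[str, float] = field(default_factory=dict)
    significant_laptime: bool = False
    meaningful_progress: bool = False

    def __post_init__(self) -> None:
        if self.session_m == self.session_n:
            raise ValueError("a session cannot be compared to itself")
        if self.meaningful_progress and not self.significant_laptime:
            raise ValueError("meaningful progress requires lap-time significance")


def _by_swimmer(
    cohort: Iterable[SessionRecord],
) -> dict[str, dict[int, SessionRecord]]:
    grouped: dict[str, dict[int, SessionRecord]] = {}
    for rec in cohort:
        sessions = grouped.setdefault(rec.swimmer_id, {})
        if rec.session_index in sessions:
            raise ValueError(
                f"duplicate session {rec.session_index} for swimmer "
                f"{rec.swimmer_id}"
            )
        sessions[rec.session_index] = rec
    return grouped


def enumerate_pairs(
    cohort: Iterable[SessionRecord],
) -> list[tuple[str, int, int]]:
    """All unordered within-swimmer pairs of present sessions.

    Each pair is emitted once as ``(swimmer_id, m, n)`` with ``m < n``.
    Swimmers with fewer than two present sessions contribute nothing.  There
    are no cross-swimmer pairs: each swimmer is compared only to themselves.
    """
    pairs: list[tuple[str, int, int]] = []
    grouped = _by_swimmer(cohort)
    for swimmer_id in sorted(grouped):
        present = sorted(grouped[swimmer_id])
        pairs.extend(
            (swimmer_id, m, n) for m, n in itertools.combinations(present, 2)
        )
    return pairs


def compute_mltc(
    cohort: Iterable[SessionRecord],
    *,
    use_absolute: bool = False,
) -> MltcEstimate:
    """Derive the MLTC threshold from session pairs exactly 3 weeks apart.

    For every swimmer and every present pair of sessions ``(s, s + 3)`` the
    difference of median lap times ``median(s) - median(s + 3)`` is taken
    (positive when the swimmer got faster); the threshold is the mean of
    these differences over all pairs and swimmers and the dispersion their
    sample standard deviation.

    Parameters
    ----------
    use_absolute : bool
        Average ``|difference|`` instead of the signed difference.  The
        signed mean is the default; pairs where the swimmer got slower then
        enter with a negative sign.

    Raises
    ------
    ValueError
        If no swimmer has two present sessions exactly 3 apart; callers
        should then supply an explicit threshold instead.
    """
    diffs: list[float] = []
    grouped = _by_swimmer(cohort)
    for swimmer_id in sorted(grouped):
        sessions = grouped[swimmer_id]
        for s in sorted(sessions):
            later = sessions.get(s + 3)
            if later is None:
                continue
            diff = sessions[s].median_lap_time - later.median_lap_time
            diffs.append(abs(diff) if use_absolute else diff)
    if not diffs:
        raise ValueError(
            "no session pairs exactly 3 weeks apart in the cohort; supply an "
            "explicit MLTC value instead of deriving one"
        )
    mean = float(np.mean(diffs))
    if mean < 0:
        logger.warning(
            "mean 3-week lap-time change is negative (%.3f s); clamping the "
            "MLTC threshold to 0",
            mean,
        )
        mean = 0.0
    sd = float(np.std(diffs, ddof=1)) if len(diffs) > 1 else 0.0
    return MltcEstimate(value=mean, dispersion=sd, n_pairs=len(diffs))


def detect_progress(
    cohort: Iterable[SessionRecord],
    mltc: MltcEstimate,
    confidence_level: float = 0.95,
    metrics: Sequence[str] = GOAL_METRICS,
) -> list[ComparisonPair]:
    """Run the two-step detection over all within-swimmer session pairs.

    Step 1 computes the lap-time effect size with its confidence interval
    for every pair; pairs whose interval excludes zero are significant.
    Step 2 keeps, among the significant pairs, those whose median lap time
    dropped by strictly more than ``mltc.value`` in the later session; those
    are labelled ``meaningful_progress``.  Per-metric effect sizes are
    computed alongside for the assessment stage.

    A metric absent from either session of a pair is skipped for that pair
    and logged; no multiple-testing correction is applied across pairs.
    """
    cohort = list(cohort)
    grouped = _by_swimmer(cohort)
    out: list[ComparisonPair] = []
    for swimmer_id, m, n in enumerate_pairs(cohort):
        earlier = grouped[swimmer_id][m]
        later = grouped[swimmer_id][n]

        laptime_effect = cliff_delta_ci(
            earlier.lap_times, later.lap_times, confidence_level
        )
        median_change = earlier.median_lap_time - later.median_lap_time
        significant = laptime_effect.significant
        meaningful = significant and median_change > mltc.value

        metric_effects: dict[str, EffectSizeResult] = {}
        metric_changes: dict[str, float] = {}
        for metric in metrics:
            try:
                vals_m = earlier.goal_metrics[metric]
                vals_n = later.goal_metrics[metric]
            except KeyError:
                logger.warning(
                    "swimmer %s pair (%d, %d): metric %r missing, excluded",
                    swimmer_id, m, n, metric,
                )
                continue
            metric_effects[metric] = cliff_delta_ci(
                vals_n, vals_m, confidence_level
            )
            metric_changes[metric] = float(
                statistics.median(vals_n) - statistics.median(vals_m)
            )

        out.append(
            ComparisonPair(
                swimmer_id=swimmer_id,
                session_m=m,
                session_n=n,
                laptime_effect=laptime_effect,
                metric_effects=metric_effects,
                median_laptime_change=median_change,
                median_metric_change=metric_changes,
                significant_laptime=significant,
                meaningful_progress=meaningful,
            )
        )
    return out
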