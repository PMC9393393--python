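"""Synthetic swimmer cohorts with ground-truth progress labels.

The generator emulates a weekly training study: each swimmer has a latent
lap time that starts at an individual baseline and falls linearly with
training (optionally plateauing), observed through per-lap variability plus
an independent stopwatch recording error.  Goal-metric velocities are
emitted directly: the whole-lap average velocity is pool length over the
noisy lap duration, the free-swimming velocity is strongly coupled to it,
and the push/glide/stroke-preparation velocities follow mostly independent
per-swimmer trajectories with weak coupling.  Whole sessions drop out at a
configurable absence rate.

All distributional choices (Gaussian noise, linear trends, i.i.d. laps
within a session) are modelling assumptions, not measured properties; they
are exposed as configuration so tests can tighten or remove them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .pipeline import GOAL_METRICS, SessionRecord

__all__ = [
    "MetricSpec",
    "decoupled_control_spec",
    "SyntheticConfig",
    "GroundTruth",
    "generate_cohort",
    "inject_plateau",
    "swimmer_ids",
]


@dataclass(frozen=True)
class MetricSpec:
    """Generation parameters for one goal metric.

    ``coupling`` scales how strongly the metric tracks deviations of the
    true lap velocity from the swimmer's baseline velocity; ``own_rate``
    parameters govern the metric's independent weekly trend; ``rmse`` is
    the estimation error used downstream as the delta-validity band.
    """

    base_mean: float
    base_sd: float
    coupling: float
    own_rate_mean: float
    own_rate_sd: float
    noise_sd: float
    rmse: float


def _default_metric_specs() -> dict[str, MetricSpec]:
    return {
        "push_vmax": MetricSpec(2.50, 0.20, 0.30, 0.010, 0.010, 0.080, 0.10),
        "glid_vend": MetricSpec(1.90, 0.15, 0.30, 0.010, 0.010, 0.070, 0.10),
        "stpr_vavg": MetricSpec(1.50, 0.15, 0.30, 0.010, 0.015, 0.080, 0.10),
        "swim_vavg": MetricSpec(1.30, 0.10, 0.85, 0.000, 0.000, 0.020, 0.03),
        # lap_vavg is pool_length / noisy lap time plus noise_sd; base and
        # coupling fields are ignored for it.
        "lap_vavg": MetricSpec(1.25, 0.00, 1.00, 0.000, 0.000, 0.018, 0.02),
    }


def decoupled_control_spec() -> MetricSpec:
    """A control metric with no coupling to lap time.

    Its trajectory is an independent per-swimmer weekly trend (mostly
    improving, some declining) plus noise, so it fires regularly but
    carries no information about lap-time progress.  Useful as the
    baseline a genuinely coupled metric must beat.
    """
    return MetricSpec(2.50, 0.20, 0.0, 0.04, 0.05, 0.04, 0.10)


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-simulation parameters.

    Defaults mirror the target study design: 16 swimmers, 10 weekly
    sessions of 5 one-way 25 m laps each, with occasional absences.
    """

    n_swimmers: int = 16
    n_sessions: int = 10
    laps_per_session: int = 5
    pool_length: float = 25.0
    baseline_mean: float = 20.0
    baseline_sd: float = 1.5
    improvement_mean: float = 0.20
    improvement_sd: float = 0.05
    lap_noise_sd: float = 0.18
    stopwatch_sd: float = 0.10
    absence_probability: float = 0.04
    metric_specs: Mapping[str, MetricSpec] = field(
        default_factory=_default_metric_specs
    )
    true_progress_threshold: float = 0.5
    plateaus: Mapping[str, int] = field(default_factory=dict)
    worsen_from: Mapping[str, int] = field(default_factory=dict)
    worsen_metric: str | None = None
    worsen_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.n_swimmers < 1:
            problems.append("n_swimmers must be >= 1")
        if self.n_sessions < 1:
            problems.append("n_sessions must be >= 1")
        if self.laps_per_session != 5:
            problems.append("laps_per_session must be 5 (analysis contract)")
        if self.pool_length <= 0:
            problems.append("pool_length must be > 0")
        for name in ("baseline_sd", "improvement_sd", "lap_noise_sd",
                     "stopwatch_sd", "worsen_rate"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if not 0.0 <= self.absence_probability <= 1.0:
            problems.append("absence_probability must be in [0, 1]")
        if self.true_progress_threshold < 0:
            problems.append("true_progress_threshold must be >= 0")
        missing = [m for m in GOAL_METRICS if m not in self.metric_specs]
        if missing:
            problems.append(f"metric_specs missing {missing}")
        for name, spec in self.metric_specs.items():
            if min(spec.base_sd, spec.noise_sd, spec.own_rate_sd, spec.rmse) < 0:
                problems.append(f"metric_specs[{name!r}] has a negative sd/rmse")
        known = set(swimmer_ids(self.n_swimmers))
        for field_name in ("plateaus", "worsen_from"):
            unknown = sorted(set(getattr(self, field_name)) - known)
            if unknown:
                problems.append(
                    f"{field_name} references unknown swimmers {unknown}"
                )
        if self.worsen_metric is not None and self.worsen_metric not in GOAL_METRICS:
            problems.append(f"unknown worsen_metric {self.worsen_metric!r}")
        if problems:
            raise ValueError("invalid SyntheticConfig: " + "; ".join(problems))

    @property
    def rmse_per_metric(self) -> dict[str, float]:
        return {name: spec.rmse for name, spec in self.metric_specs.items()}


def swimmer_ids(n: int) -> list[str]:
    return [f"S{i:02d}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free latent state behind a generated cohort.

    ``true_median_lap_time`` maps (swimmer_id, session_index) of every
    *present* session to its latent lap time; ``labels`` holds the true
    progress label of every present within-swimmer pair at the config's
    threshold.  ``labels_at`` relabels at any other threshold, e.g. the
    MLTC actually derived from the observed data.
    """

    true_median_lap_time: Mapping[tuple[str, int], float]
    labels: Mapping[tuple[str, int, int], bool]
    threshold: float

    def labels_at(self, threshold: float) -> dict[tuple[str, int, int], bool]:
        out = {}
        for (sid, m, n) in self.labels:
            drop = (
                self.true_median_lap_time[(sid, m)]
                - self.true_median_lap_time[(sid, n)]
            )
            out[(sid, m, n)] = drop > threshold
        return out


def _effective_weeks(week: int, plateau_from: int | None) -> int:
    """Weeks of accumulated improvement by `week` (1-based), honouring a plateau."""
    if plateau_from is None:
        return week - 1
    return min(week, plateau_from) - 1


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[SessionRecord], GroundTruth]:
    """Generate session records and their ground truth.

    Latent lap time: baseline minus accumulated weekly improvement.
    Observed lap time: latent + per-lap noise + stopwatch error.  Whole-lap
    average velocity: pool length / (latent + per-lap noise) + metric
    noise, so with zero metric noise velocity times the pre-stopwatch lap
    time reproduces the pool length exactly.  Fully reproducible from the
    config seed.
    """
    rng = np.random.default_rng(config.seed)
    ids = swimmer_ids(config.n_swimmers)
    specs = config.metric_specs
    n_laps = config.laps_per_session

    records: list[SessionRecord] = []
    latent_by_key: dict[tuple[str, int], float] = {}

    for sid in ids:
        base = rng.normal(config.baseline_mean, config.baseline_sd)
        rate = rng.normal(config.improvement_mean, config.improvement_sd)
        metric_base = {
            m: rng.normal(specs[m].base_mean, specs[m].base_sd)
            for m in GOAL_METRICS
        }
        metric_rate = {
            m: rng.normal(specs[m].own_rate_mean, specs[m].own_rate_sd)
            for m in GOAL_METRICS
        }
        absent = rng.random(config.n_sessions) < config.absence_probability
        plateau_from = config.plateaus.get(sid)
        base_velocity = config.pool_length / base

        for week in range(1, config.n_sessions + 1):
            weeks_trained = _effective_weeks(week, plateau_from)
            latent = base - rate * weeks_trained

            lap_noise = rng.normal(0.0, config.lap_noise_sd, n_laps)
            stopwatch = rng.normal(0.0, config.stopwatch_sd, n_laps)
            metric_noise = {
                m: rng.normal(0.0, specs[m].noise_sd, n_laps)
                for m in GOAL_METRICS
            }
            if absent[week - 1]:
                continue  # draws above keep the stream aligned across configs
            latent_by_key[(sid, week)] = latent

            true_lap_time = np.maximum(latent + lap_noise, 1e-3)
            observed_lt = np.maximum(true_lap_time + stopwatch, 1e-3)
            lap_velocity = config.pool_length / true_lap_time

            metrics: dict[str, tuple[float, ...]] = {}
            for m in GOAL_METRICS:
                if m == "lap_vavg":
                    vals = lap_velocity + metric_noise[m]
                else:
                    trend = metric_rate[m] * weeks_trained
                    worsen_start = config.worsen_from.get(sid)
                    if config.worsen_metric == m and worsen_start is not None:
                        trend -= config.worsen_rate * max(week - worsen_start, 0)
                    vals = (
                        metric_base[m]
                        + specs[m].coupling * (lap_velocity - base_velocity)
                        + trend
                        + metric_noise[m]
                    )
                metrics[m] = tuple(float(v) for v in np.maximum(vals, 1e-3))

            records.append(
                SessionRecord(
                    swimmer_id=sid,
                    session_index=week,
                    lap_times=tuple(float(t) for t in observed_lt),
                    goal_metrics=metrics,
                )
            )

    labels: dict[tuple[str, int, int], bool] = {}
    present: dict[str, list[int]] = {}
    for sid, week in latent_by_key:
        present.setdefault(sid, []).append(week)
    for sid, weeks in present.items():
        weeks.sort()
        for i, m in enumerate(weeks):
            for n in weeks[i + 1:]:
                drop = latent_by_key[(sid, m)] - latent_by_key[(sid, n)]
                labels[(sid, m, n)] = drop > config.true_progress_threshold

    truth = GroundTruth(
        true_median_lap_time=latent_by_key,
        labels=labels,
        threshold=config.true_progress_threshold,
    )
    return records, truth


def inject_plateau(
    config: SyntheticConfig,
    ids: Iterable[str],
    from_week: int,
    *,
    plateau_lap: bool = True,
    worsen_metric: str | None = None,
    worsen_rate: float = 0.02,
) -> SyntheticConfig:
    """Config copy whose named swimmers stop improving after ``from_week``.

    With ``worsen_metric`` set, those swimmers' values for that metric
    decline by ``worsen_rate`` (m/s per week) from ``from_week`` on; pass
    ``plateau_lap=False`` to worsen the metric while lap-time improvement
    continues (metric regression amid genuine progress).  An empty id list
    returns the config unchanged.
    """
    ids = list(ids)
    if not ids:
        return config
    if not 1 <= from_week <= config.n_sessions:
        raise ValueError(
            f"from_week must be in 1..{config.n_sessions}, got {from_week}"
        )
    known = set(swimmer_ids(config.n_swimmers))
    unknown = sorted(set(ids) - known)
    if unknown:
        raise ValueError(f"unknown swimmer ids: {unknown}")
    kwargs: dict = {}
    if plateau_lap:
        plateaus = dict(config.plateaus)
        plateaus.update({sid: from_week for sid in ids})
        kwargs["plateaus"] = plateaus
    if worsen_metric is not None:
        worsen_from = dict(config.worsen_from)
        worsen_from.update({sid: from_week for sid in ids})
        kwargs["worsen_from"] = worsen_from
        kwargs["worsen_metric"] = worsen_metric
        kwargs["worsen_rate"] = worsen_rate
    if not kwargs:
        return config
    return replace(config, **kwargs)
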