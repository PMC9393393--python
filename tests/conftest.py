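import numpy as np
import pytest

from swimprog.pipeline import GOAL_METRICS, SessionRecord


def make_session(
    swimmer_id: str,
    session_index: int,
    lap_times,
    metrics: dict | None = None,
) -> SessionRecord:
    """Build a SessionRecord, filling unspecified metrics with distinct
    constant-plus-jitter values so effect sizes stay well defined."""
    base = {m: tuple(1.0 + 0.01 * i for i in range(5)) for m in GOAL_METRICS}
    if metrics:
        base.update({k: tuple(v) for k, v in metrics.items()})
    return SessionRecord(
        swimmer_id=swimmer_id,
        session_index=session_index,
        lap_times=tuple(lap_times),
        goal_metrics=base,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def default_cohort():
    from swimprog.synthetic import SyntheticConfig, generate_cohort

    return generate_cohort(SyntheticConfig(seed=7))
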