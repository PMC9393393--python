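"""Session-log CSV reading and writing.

One row per lap: ``swimmer_id, session_index, lap_index, lap_time_s`` plus
one column per goal metric (m/s).  Reading validates structure row by row
and rejects malformed sessions individually, so one bad session does not
discard the rest of a file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .pipeline import GOAL_METRICS, SessionRecord
from .synthetic import GroundTruth

logger = logging.getLogger(__name__)

__all__ = [
    "SessionLogError",
    "read_sessions",
    "write_sessions",
    "write_ground_truth",
]

REQUIRED_COLUMNS = ("swimmer_id", "session_index", "lap_index", "lap_time_s")


class SessionLogError(ValueError):
    """Structural problem in a session-log file (named row/column)."""


@dataclass
class _SessionBuffer:
    laps: dict[int, tuple[float, dict[str, float]]]


def write_sessions(
    records: Iterable[SessionRecord],
    path: str | Path,
    metrics: tuple[str, ...] = GOAL_METRICS,
) -> None:
    """Write records as a lap-per-row CSV (deterministic formatting)."""
    rows = []
    for rec in records:
        for lap_idx, lap_time in enumerate(rec.lap_times, start=1):
            row = {
                "swimmer_id": rec.swimmer_id,
                "session_index": rec.session_index,
                "lap_index": lap_idx,
                "lap_time_s": f"{lap_time:.6f}",
            }
            for m in metrics:
                row[m] = f"{rec.goal_metrics[m][lap_idx - 1]:.6f}"
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Write per-pair true progress labels keyed by swimmer and sessions."""
    rows = [
        {
            "swimmer_id": sid,
            "session_m": m,
            "session_n": n,
            "true_lap_time_m": f"{truth.true_median_lap_time[(sid, m)]:.6f}",
            "true_lap_time_n": f"{truth.true_median_lap_time[(sid, n)]:.6f}",
            "true_progress": label,
        }
        for (sid, m, n), label in sorted(truth.labels.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sessions(
    path: str | Path,
    laps_per_session: int = 5,
    metrics: tuple[str, ...] = GOAL_METRICS,
) -> list[SessionRecord]:
    """Read and validate a session-log CSV.

    Sessions with a wrong lap count, duplicate lap indices, or
    out-of-range/non-positive values are rejected with a logged row-level
    diagnostic; valid sessions load regardless.  File-level problems
    (missing columns, non-numeric cells, duplicate keys) raise
    :class:`SessionLogError` naming the offending row or column.
    """
    try:
        frame = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise SessionLogError(f"cannot parse {path}: {exc}") from exc

    missing = [c for c in (*REQUIRED_COLUMNS, *metrics) if c not in frame.columns]
    if missing:
        raise SessionLogError(f"{path}: missing columns {missing}")

    numeric_cols = ["lap_time_s", *metrics]
    for col in numeric_cols + ["session_index", "lap_index"]:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[converted.isna() & frame[col].notna()]
        if len(bad) > 0:
            raise SessionLogError(
                f"{path}: non-numeric value in column {col!r} at row "
                f"{int(bad[0]) + 2}"  # +2: header line and 1-based rows
            )
        if converted.isna().any():
            row = int(frame.index[converted.isna()][0]) + 2
            raise SessionLogError(
                f"{path}: empty value in column {col!r} at row {row}"
            )
        frame[col] = converted

    dupes = frame.duplicated(
        subset=["swimmer_id", "session_index", "lap_index"], keep=False
    )
    if dupes.any():
        row = int(frame.index[dupes][0]) + 2
        raise SessionLogError(
            f"{path}: duplicate (swimmer_id, session_index, lap_index) key "
            f"at row {row}"
        )

    records: list[SessionRecord] = []
    grouped = frame.groupby(["swimmer_id", "session_index"], sort=True)
    for (sid, session), sub in grouped:
        session = int(session)
        lap_indices = sorted(int(i) for i in sub["lap_index"])
        if lap_indices != list(range(1, laps_per_session + 1)):
            logger.warning(
                "%s: swimmer %s session %d rejected: lap indices %s, "
                "expected 1..%d",
                path, sid, session, lap_indices, laps_per_session,
            )
            continue
        sub = sub.sort_values("lap_index")
        try:
            records.append(
                SessionRecord(
                    swimmer_id=str(sid),
                    session_index=session,
                    lap_times=tuple(float(t) for t in sub["lap_time_s"]),
                    goal_metrics={
                        m: tuple(float(v) for v in sub[m]) for m in metrics
                    },
                )
            )
        except ValueError as exc:
            logger.warning(
                "%s: swimmer %s session %d rejected: %s", path, sid, session, exc
            )
    return records
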