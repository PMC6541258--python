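"""Data model and CSV I/O for camera-trap capture, deployment and refresh logs.

Three tabular inputs drive the pipeline:

* a capture log — one row per photo event (species, station, timestamp),
* a deployment log — one row per station with its active window and any
  days the camera was non-functional,
* an attractant refresh log — one row per bait/lure service visit.

Timestamps are naive local time: the study design assumes a single local
clock, and the diel analysis is meaningless across time zones.  A trap-day
is a calendar date on which a station was active; occasions are calendar
days with the boundary at local midnight.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CaptureRecord",
    "Deployment",
    "RefreshEvent",
    "RunConfig",
    "read_captures",
    "read_deployments",
    "read_refresh_log",
    "write_captures",
    "write_deployments",
    "write_refresh_log",
    "total_trap_days",
]


@dataclass(frozen=True, order=True)
class CaptureRecord:
    """One photo event of one species at one station."""

    species: str
    station_id: str
    timestamp: dt.datetime
    survey_id: str = "survey1"
    outside_deployment: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species must be non-empty")
        if not self.station_id:
            raise ValueError("station_id must be non-empty")


@dataclass(frozen=True)
class Deployment:
    """A station's active window; effort is the span minus inactive dates."""

    station_id: str
    survey_id: str
    start_date: dt.date
    end_date: dt.date
    inactive_dates: frozenset[dt.date] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValueError(
                f"station {self.station_id}: start_date {self.start_date} "
                f"after end_date {self.end_date}"
            )
        object.__setattr__(self, "inactive_dates", frozenset(self.inactive_dates))
        bad = [d for d in self.inactive_dates
               if not (self.start_date <= d <= self.end_date)]
        if bad:
            raise ValueError(
                f"station {self.station_id}: inactive dates {sorted(bad)} outside "
                f"deployment window"
            )
        if self.trap_days <= 0:
            raise ValueError(f"station {self.station_id}: no active trap-days")

    @property
    def span_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    @property
    def trap_days(self) -> int:
        """Active trap-days: calendar span minus inactive dates."""
        return self.span_days - len(self.inactive_dates)

    def active_dates(self) -> list[dt.date]:
        return [
            self.start_date + dt.timedelta(days=k)
            for k in range(self.span_days)
            if (self.start_date + dt.timedelta(days=k)) not in self.inactive_dates
        ]

    def covers(self, ts: dt.datetime) -> bool:
        return self.start_date <= ts.date() <= self.end_date


@dataclass(frozen=True, order=True)
class RefreshEvent:
    """One attractant placement or refresh at a station."""

    station_id: str
    timestamp: dt.datetime


@dataclass
class RunConfig:
    """Run-level settings for a full analysis.

    ``occasion_length_days`` and ``max_bin_days`` are fixed by the design
    (daily occasions; the short-term analysis is restricted to one week) and
    are validated rather than varied.
    """

    independence_window_hours: float = 1.0
    occasion_length_days: int = 1
    n_randomizations: int = 1000
    max_bin_days: int = 7
    alpha: float = 0.05
    rng_seed: int = 0
    captures_path: str | None = None
    deployments_path: str | None = None
    refresh_path: str | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.independence_window_hours <= 0:
            raise ValueError("independence_window_hours must be > 0")
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.occasion_length_days != 1:
            raise ValueError("occasion_length_days is fixed at 1")
        if self.max_bin_days != 7:
            raise ValueError("max_bin_days is fixed at 7")


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

_CAPTURE_COLS = ["species", "station_id", "timestamp", "survey_id"]
_DEPLOY_COLS = ["station_id", "survey_id", "start_date", "end_date", "inactive_dates"]
_REFRESH_COLS = ["station_id", "timestamp"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _parse_ts(value: str, path: str | Path, row: int) -> dt.datetime:
    try:
        ts = pd.Timestamp(value)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: row {row}: unparseable timestamp {value!r}") from exc
    if pd.isna(ts):
        raise ValueError(f"{path}: row {row}: unparseable timestamp {value!r}")
    return ts.to_pydatetime()


def read_captures(
    path: str | Path,
    deployments: Iterable[Deployment] | None = None,
) -> list[CaptureRecord]:
    """Read a capture log, sorted by (species, station, timestamp).

    If ``deployments`` is given, captures falling outside every deployment
    window of their station are flagged (``outside_deployment=True``) and a
    warning is emitted; the records are retained.
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, _CAPTURE_COLS, path)
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        records.append(
            CaptureRecord(
                species=str(row.species),
                station_id=str(row.station_id),
                timestamp=_parse_ts(row.timestamp, path, i + 2),
                survey_id=str(row.survey_id),
            )
        )
    if deployments is not None:
        windows: dict[str, list[Deployment]] = {}
        for d in deployments:
            windows.setdefault(d.station_id, []).append(d)
        flagged = []
        n_bad = 0
        for rec in records:
            ok = any(d.covers(rec.timestamp) for d in windows.get(rec.station_id, []))
            if not ok:
                rec = replace(rec, outside_deployment=True)
                n_bad += 1
            flagged.append(rec)
        records = flagged
        if n_bad:
            warnings.warn(
                f"{path}: {n_bad} capture(s) fall outside every deployment window "
                f"of their station; retained with outside_deployment=True",
                stacklevel=2,
            )
    records.sort(key=lambda r: (r.species, r.station_id, r.timestamp))
    return records


def read_deployments(path: str | Path) -> list[Deployment]:
    """Read a deployment log; ``inactive_dates`` is a semicolon-joined list."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, _DEPLOY_COLS[:4], path)
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        inactive: frozenset[dt.date] = frozenset()
        raw = getattr(row, "inactive_dates", None)
        if raw is not None and isinstance(raw, str) and raw.strip():
            inactive = frozenset(
                _parse_ts(tok, path, i + 2).date() for tok in raw.split(";")
            )
        out.append(
            Deployment(
                station_id=str(row.station_id),
                survey_id=str(row.survey_id),
                start_date=_parse_ts(row.start_date, path, i + 2).date(),
                end_date=_parse_ts(row.end_date, path, i + 2).date(),
                inactive_dates=inactive,
            )
        )
    return out


def read_refresh_log(path: str | Path) -> list[RefreshEvent]:
    """Read an attractant refresh log; timestamps must increase per station."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, _REFRESH_COLS, path)
    events = [
        RefreshEvent(
            station_id=str(row.station_id),
            timestamp=_parse_ts(row.timestamp, path, i + 2),
        )
        for i, row in enumerate(df.itertuples(index=False))
    ]
    last: dict[str, dt.datetime] = {}
    for i, ev in enumerate(events):
        prev = last.get(ev.station_id)
        if prev is not None and ev.timestamp <= prev:
            raise ValueError(
                f"{path}: row {i + 2}: refresh timestamps not strictly increasing "
                f"for station {ev.station_id} ({ev.timestamp} after {prev})"
            )
        last[ev.station_id] = ev.timestamp
    return events


def write_captures(records: Iterable[CaptureRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "species": r.species,
                "station_id": r.station_id,
                "timestamp": r.timestamp.isoformat(),
                "survey_id": r.survey_id,
            }
            for r in records
        ],
        columns=_CAPTURE_COLS,
    )
    df.to_csv(path, index=False)


def write_deployments(deployments: Iterable[Deployment], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "station_id": d.station_id,
                "survey_id": d.survey_id,
                "start_date": d.start_date.isoformat(),
                "end_date": d.end_date.isoformat(),
                "inactive_dates": ";".join(
                    x.isoformat() for x in sorted(d.inactive_dates)
                ),
            }
            for d in deployments
        ],
        columns=_DEPLOY_COLS,
    )
    df.to_csv(path, index=False)


def write_refresh_log(events: Iterable[RefreshEvent], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {"station_id": e.station_id, "timestamp": e.timestamp.isoformat()}
            for e in events
        ],
        columns=_REFRESH_COLS,
    )
    df.to_csv(path, index=False)


def total_trap_days(deployments: Iterable[Deployment]) -> int:
    """Total survey effort: sum of active trap-days over stations."""
    return sum(d.trap_days for d in deployments)
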