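"""Capture-event processing: independence filtering, attractant age,
detection/covariate matrices, and descriptive survey summaries.

The pipeline's unit of analysis is the *independent capture*: a photo event
separated from the previous retained event of the same species at the same
station by at least the independence window (1 h by default).  Anchoring the
window on the previous *retained* event (the sliding independent-event
convention) guarantees retained events are pairwise at least one window
apart and makes the filter idempotent.

Occasions are calendar days.  Detection histories y_ij are 0/1 with missing
cells on dates the station was inactive; covariate matrices share the same
station x date alignment.
"""

from __future__ import annotations

import datetime as dt
import math
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_io import CaptureRecord, Deployment, RefreshEvent

__all__ = [
    "IndependentCapture",
    "DetectionMatrix",
    "CovariateMatrix",
    "filter_independent",
    "hours_since_refresh",
    "assign_day_bin",
    "attach_refresh_times",
    "build_detection_matrix",
    "build_covariate_matrix",
    "capture_rate",
    "naive_summaries",
]

HOURS_PER_DAY = 24.0
MAX_BIN_DAYS = 7


@dataclass(frozen=True)
class IndependentCapture:
    """A retained capture annotated with attractant age.

    ``hours_since_refresh`` is the elapsed time from the most recent
    attractant refresh at the station; ``day_bin`` is the 24-h bin 1..7
    (bin d covers [24(d-1), 24d) hours) or ``None`` beyond one week.
    """

    species: str
    station_id: str
    timestamp: dt.datetime
    survey_id: str
    hours_since_refresh: float
    day_bin: int | None

    def __post_init__(self) -> None:
        if self.hours_since_refresh < 0:
            raise ValueError("hours_since_refresh must be >= 0")


def filter_independent(
    captures: Sequence[CaptureRecord], window_hours: float = 1.0
) -> list[CaptureRecord]:
    """Keep captures >= ``window_hours`` after the previous retained capture
    of the same species at the same station.

    The first capture of each (species, station) is always retained.  The
    filter is idempotent and retained events are pairwise >= window apart.
    """
    if window_hours <= 0:
        raise ValueError("window_hours must be > 0")
    ordered = sorted(captures, key=lambda r: (r.species, r.station_id, r.timestamp))
    window = dt.timedelta(hours=window_hours)
    retained: list[CaptureRecord] = []
    last_key: tuple[str, str] | None = None
    last_ts: dt.datetime | None = None
    for rec in ordered:
        key = (rec.species, rec.station_id)
        if key != last_key or rec.timestamp - last_ts >= window:
            retained.append(rec)
            last_key, last_ts = key, rec.timestamp
    return retained


class _RefreshIndex:
    """Per-station sorted refresh timestamps for last-refresh lookups."""

    def __init__(self, refresh_events: Iterable[RefreshEvent]) -> None:
        self._by_station: dict[str, list[dt.datetime]] = {}
        for ev in refresh_events:
            self._by_station.setdefault(ev.station_id, []).append(ev.timestamp)
        for ts_list in self._by_station.values():
            ts_list.sort()

    def last_refresh(self, station_id: str, ts: dt.datetime) -> dt.datetime | None:
        ts_list = self._by_station.get(station_id, [])
        i = bisect_right(ts_list, ts)
        return ts_list[i - 1] if i else None

    def refresh_dates(self, station_id: str) -> list[dt.date]:
        return [t.date() for t in self._by_station.get(station_id, [])]


def hours_since_refresh(
    capture: CaptureRecord, refresh_events: Iterable[RefreshEvent] | _RefreshIndex
) -> float:
    """Hours from the most recent prior-or-equal refresh at the capture's
    station to the capture; errors if the station was never baited before."""
    index = (
        refresh_events
        if isinstance(refresh_events, _RefreshIndex)
        else _RefreshIndex(refresh_events)
    )
    last = index.last_refresh(capture.station_id, capture.timestamp)
    if last is None:
        raise ValueError(
            f"no refresh at or before {capture.timestamp} for station "
            f"{capture.station_id} (capture of {capture.species})"
        )
    return (capture.timestamp - last).total_seconds() / 3600.0


def assign_day_bin(hours: float) -> int | None:
    """24-h bin since refresh: bin d covers [24(d-1), 24d) h, d = 1..7;
    ``None`` at or beyond 168 h (the analysis is restricted to one week)."""
    if hours < 0:
        raise ValueError("hours must be >= 0")
    if hours >= MAX_BIN_DAYS * HOURS_PER_DAY:
        return None
    return int(math.floor(hours / HOURS_PER_DAY)) + 1


def attach_refresh_times(
    retained: Sequence[CaptureRecord], refresh_events: Iterable[RefreshEvent]
) -> list[IndependentCapture]:
    """Annotate retained captures with attractant age and day bin."""
    index = _RefreshIndex(refresh_events)
    out = []
    for rec in retained:
        hrs = hours_since_refresh(rec, index)
        out.append(
            IndependentCapture(
                species=rec.species,
                station_id=rec.station_id,
                timestamp=rec.timestamp,
                survey_id=rec.survey_id,
                hours_since_refresh=hrs,
                day_bin=assign_day_bin(hrs),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Detection / covariate matrices
# ---------------------------------------------------------------------------


def _occasion_dates(deployments: Sequence[Deployment]) -> list[dt.date]:
    start = min(d.start_date for d in deployments)
    end = max(d.end_date for d in deployments)
    return [start + dt.timedelta(days=k) for k in range((end - start).days + 1)]


def _active_mask(
    deployments: Sequence[Deployment],
    station_ids: Sequence[str],
    dates: Sequence[dt.date],
) -> np.ndarray:
    by_station = {d.station_id: d for d in deployments}
    date_pos = {day: j for j, day in enumerate(dates)}
    mask = np.zeros((len(station_ids), len(dates)), dtype=bool)
    for i, sid in enumerate(station_ids):
        dep = by_station[sid]
        for day in dep.active_dates():
            mask[i, date_pos[day]] = True
    return mask


@dataclass
class DetectionMatrix:
    """Daily detection histories for one species: stations x occasion dates.

    Cells are 1 (>=1 independent capture that date), 0 (active, none), or
    NaN (station not active that date).
    """

    species: str
    station_ids: list[str]
    dates: list[dt.date]
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (len(self.station_ids), len(self.dates)):
            raise ValueError("y shape does not match station/date labels")

    @property
    def observed(self) -> np.ndarray:
        return ~np.isnan(self.y)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.y,
            index=pd.Index(self.station_ids, name="station_id"),
            columns=[d.isoformat() for d in self.dates],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, na_rep="NA")


@dataclass
class CovariateMatrix:
    """A detection covariate aligned with a :class:`DetectionMatrix`.

    ``kind`` is one of ``attractant_age`` (whole days since the most recent
    refresh at the start of the occasion), ``incremental_effort`` (number of
    active days accrued through the occasion, 1..E_i), or ``total_effort``
    (E_i, constant across a station's row).
    """

    kind: str
    station_ids: list[str]
    dates: list[dt.date]
    x: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in {"attractant_age", "incremental_effort", "total_effort"}:
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        self.x = np.asarray(self.x, dtype=float)
        if self.x.shape != (len(self.station_ids), len(self.dates)):
            raise ValueError("x shape does not match station/date labels")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.x,
            index=pd.Index(self.station_ids, name="station_id"),
            columns=[d.isoformat() for d in self.dates],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, na_rep="NA")


def build_detection_matrix(
    independent_captures: Sequence[CaptureRecord | IndependentCapture],
    deployments: Sequence[Deployment],
    species: str,
) -> DetectionMatrix:
    """Build the stations x dates 0/1/NaN history for one species.

    The number of 1-cells equals the number of distinct (station, date)
    pairs with at least one independent capture of the species.
    """
    if not deployments:
        raise ValueError("no deployments given")
    station_ids = sorted(d.station_id for d in deployments)
    dates = _occasion_dates(deployments)
    mask = _active_mask(deployments, station_ids, dates)
    y = np.where(mask, 0.0, np.nan)
    row = {sid: i for i, sid in enumerate(station_ids)}
    col = {day: j for j, day in enumerate(dates)}
    for cap in independent_captures:
        if cap.species != species:
            continue
        i = row.get(cap.station_id)
        j = col.get(cap.timestamp.date())
        if i is None or j is None or not mask[i, j]:
            continue  # outside deployment window / inactive day
        y[i, j] = 1.0
    return DetectionMatrix(species=species, station_ids=station_ids, dates=dates, y=y)


def build_covariate_matrix(
    kind: str,
    deployments: Sequence[Deployment],
    refresh_events: Sequence[RefreshEvent] | None = None,
) -> CovariateMatrix:
    """Build a covariate matrix aligned with :func:`build_detection_matrix`.

    ``attractant_age`` requires ``refresh_events`` and resets to 0 on each
    refresh date; ``incremental_effort`` counts only effectively active days;
    ``total_effort`` is the station's total active trap-days.
    """
    if not deployments:
        raise ValueError("no deployments given")
    station_ids = sorted(d.station_id for d in deployments)
    dates = _occasion_dates(deployments)
    mask = _active_mask(deployments, station_ids, dates)
    by_station = {d.station_id: d for d in deployments}
    x = np.full(mask.shape, np.nan)

    if kind == "attractant_age":
        if refresh_events is None:
            raise ValueError("attractant_age requires refresh_events")
        index = _RefreshIndex(refresh_events)
        for i, sid in enumerate(station_ids):
            rdates = sorted(set(index.refresh_dates(sid)))
            for j, day in enumerate(dates):
                if not mask[i, j]:
                    continue
                k = bisect_right(rdates, day)
                if k == 0:
                    raise ValueError(
                        f"station {sid}: no refresh on or before {day} "
                        f"(installation baiting missing from the log)"
                    )
                x[i, j] = (day - rdates[k - 1]).days
    elif kind == "incremental_effort":
        for i in range(len(station_ids)):
            x[i, mask[i]] = np.arange(1, mask[i].sum() + 1)
    elif kind == "total_effort":
        for i, sid in enumerate(station_ids):
            x[i, mask[i]] = by_station[sid].trap_days
    else:
        raise ValueError(f"unknown covariate kind {kind!r}")
    return CovariateMatrix(kind=kind, station_ids=station_ids, dates=dates, x=x)


# ---------------------------------------------------------------------------
# Descriptive summaries
# ---------------------------------------------------------------------------


def capture_rate(n_independent: int, trap_days: float) -> float:
    """Capture rate per 100 trap-days: 100 * n / effort."""
    if trap_days <= 0:
        raise ValueError("trap_days must be > 0")
    if n_independent < 0:
        raise ValueError("n_independent must be >= 0")
    return 100.0 * n_independent / trap_days


def naive_summaries(matrix: DetectionMatrix) -> tuple[float, float]:
    """(naive occupancy, naive detection) uncorrected for imperfect detection.

    Naive occupancy is the fraction of stations with >= 1 detection; naive
    detection is the fraction of non-missing occasions with a detection.
    """
    obs = matrix.observed
    if obs.sum() == 0:
        return 0.0, 0.0
    detected_station = np.nansum(matrix.y, axis=1) > 0
    naive_occ = float(detected_station.mean())
    naive_det = float(np.nansum(matrix.y) / obs.sum())
    return naive_occ, naive_det
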