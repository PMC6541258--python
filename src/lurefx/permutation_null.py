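"""Randomization null for short-term station-visitation response to
attractant refreshing.

For each species, the observed statistic is the proportion of its
independent captures falling in each 24-h bin (day 1..7) since the
attractant was last refreshed.  The null distribution is built from random
capture histories of the same sample size: each random capture picks a
station uniformly from the stations at which the species was actually
captured, a date uniformly from that station's active dates, and a time of
day from the species' fitted diel activity density; elapsed time since
refresh is then computed exactly as for the observed data.

The p-value for bin d is the rank of the observed proportion in the null,

    p = (#{null < observed} + 0.5 * #{null = observed} + 1) / (N + 1),

so low p means the species visited less often than expected when bait was
that fresh and high p means more often; with alpha = 0.05, p < 0.025 is
classified "decreased" and p > 0.975 "increased".
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .activity_density import CircularDensity, fit_activity, sample_times
from .data_io import Deployment, RefreshEvent
from .event_processing import IndependentCapture, MAX_BIN_DAYS

__all__ = [
    "PermutationResult",
    "observed_proportions",
    "generate_random_history",
    "build_null_distribution",
    "permutation_pvalue",
    "classify_response",
    "run_permutation_test",
]

_EPOCH = dt.date(2000, 1, 1)


def observed_proportions(
    independent_captures: Sequence[IndependentCapture],
) -> np.ndarray:
    """Per-bin proportions of a species' independent captures (days 1..7).

    The denominator is the total independent captures of the species,
    including those beyond one week, so the 7 proportions sum to <= 1.
    """
    if not independent_captures:
        raise ValueError("no captures given")
    total = len(independent_captures)
    props = np.zeros(MAX_BIN_DAYS)
    for cap in independent_captures:
        if cap.day_bin is not None:
            props[cap.day_bin - 1] += 1
    return props / total


def _date_hours(day: dt.date) -> float:
    return (day - _EPOCH).days * 24.0


class _NullSampler:
    """Vectorised sampler of random capture times for one species."""

    def __init__(
        self,
        station_ids: Sequence[str],
        deployments: Sequence[Deployment],
        refresh_events: Sequence[RefreshEvent],
        density: CircularDensity,
    ) -> None:
        if not station_ids:
            raise ValueError("species was captured at no station")
        by_station = {d.station_id: d for d in deployments}
        missing = [s for s in station_ids if s not in by_station]
        if missing:
            raise ValueError(f"no deployment for station(s) {missing}")
        self.station_ids = list(station_ids)
        self.density = density
        # concatenated per-station active-date midnights (epoch hours)
        dates_per_station = [
            np.array([_date_hours(d) for d in by_station[s].active_dates()])
            for s in self.station_ids
        ]
        self.n_active = np.array([len(a) for a in dates_per_station])
        self.offsets = np.concatenate([[0], np.cumsum(self.n_active[:-1])])
        self.flat_dates = np.concatenate(dates_per_station)
        # per-station sorted refresh instants (epoch hours)
        self.refresh_times = []
        for s in self.station_ids:
            times = sorted(
                e.timestamp for e in refresh_events if e.station_id == s
            )
            self.refresh_times.append(
                np.array(
                    [_date_hours(t.date())
                     + t.hour + t.minute / 60 + t.second / 3600 for t in times]
                )
            )

    def draw_elapsed(self, m: int, rng: np.random.Generator) -> np.ndarray:
        return self.draw_components(m, rng)[1]

    def draw_components(
        self, m: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        """Draw m random captures; return (station indices, elapsed hours).

        Entries whose sampled instant precedes the first refresh at the
        station (possible only before the installation baiting's time of
        day on the first date) are resampled.
        """
        station = rng.integers(0, len(self.station_ids), m)
        elapsed = np.full(m, np.nan)
        pending = np.arange(m)
        for _ in range(100):
            idx = self.offsets[station[pending]] + (
                rng.random(len(pending)) * self.n_active[station[pending]]
            ).astype(np.int64)
            t = self.flat_dates[idx] + sample_times(
                self.density, len(pending), rng
            )
            for s in np.unique(station[pending]):
                sel = station[pending] == s
                pos = np.searchsorted(self.refresh_times[s], t[sel], side="right")
                e = np.full(sel.sum(), np.nan)
                ok = pos > 0
                e[ok] = t[sel][ok] - self.refresh_times[s][pos[ok] - 1]
                elapsed[pending[sel]] = e
            pending = pending[np.isnan(elapsed[pending])]
            if len(pending) == 0:
                return station, elapsed
        raise RuntimeError(
            "could not place random captures after a refresh; is the "
            "installation baiting missing from the refresh log?"
        )


def generate_random_history(
    species_station_ids: Sequence[str],
    n_caps: int,
    deployments: Sequence[Deployment],
    refresh_events: Sequence[RefreshEvent],
    density: CircularDensity,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """One random capture history: hours-since-refresh for ``n_caps`` draws."""
    if n_caps < 1:
        raise ValueError("n_caps must be >= 1")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    sampler = _NullSampler(species_station_ids, deployments, refresh_events, density)
    return sampler.draw_elapsed(n_caps, rng)


def _props_from_elapsed(elapsed: np.ndarray, n_histories: int, n_caps: int) -> np.ndarray:
    b = np.floor(elapsed / 24.0).astype(np.int64)
    valid = (b >= 0) & (b < MAX_BIN_DAYS)
    hist = np.repeat(np.arange(n_histories), n_caps)
    counts = np.zeros((n_histories, MAX_BIN_DAYS))
    np.add.at(counts, (hist[valid], b[valid]), 1.0)
    return counts / n_caps


def build_null_distribution(
    species_station_ids: Sequence[str],
    n_caps: int,
    deployments: Sequence[Deployment],
    refresh_events: Sequence[RefreshEvent],
    density: CircularDensity,
    n_randomizations: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """N random histories of size n_caps -> (N, 7) bin-proportion matrix."""
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    sampler = _NullSampler(species_station_ids, deployments, refresh_events, density)
    elapsed = sampler.draw_elapsed(n_randomizations * n_caps, rng)
    return _props_from_elapsed(elapsed, n_randomizations, n_caps)


def permutation_pvalue(observed: float, random_values: np.ndarray) -> float:
    """Rank-style permutation probability in (0, 1]; ties count half."""
    random_values = np.asarray(random_values, dtype=float)
    n = len(random_values)
    if n < 1:
        raise ValueError("need at least one randomized value")
    less = np.count_nonzero(random_values < observed)
    ties = np.count_nonzero(random_values == observed)
    return (less + 0.5 * ties + 1.0) / (n + 1.0)


def classify_response(p: float, alpha: float = 0.05) -> str:
    """'decreased' if p < alpha/2, 'increased' if p > 1 - alpha/2, else 'none'."""
    if not (0 < p <= 1):
        raise ValueError("p must be in (0, 1]")
    if p < alpha / 2:
        return "decreased"
    if p > 1 - alpha / 2:
        return "increased"
    return "none"


@dataclass
class PermutationResult:
    """Observed vs randomized daily visitation proportions for one species."""

    species: str
    observed_props: np.ndarray       # (7,)
    random_props: np.ndarray         # (N, 7)
    p_values: np.ndarray             # (7,)
    classification: list[str]
    n_randomizations: int
    seed: int
    alpha: float = 0.05

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "day_bin": np.arange(1, MAX_BIN_DAYS + 1),
                "observed_prop": self.observed_props,
                "null_mean": self.random_props.mean(axis=0),
                "null_lo": np.quantile(self.random_props, 0.025, axis=0),
                "null_hi": np.quantile(self.random_props, 0.975, axis=0),
                "p_value": self.p_values,
                "classification": self.classification,
            }
        )

    def null_draws_long(self) -> pd.DataFrame:
        """Long-form null draws for violin-style plotting."""
        n, k = self.random_props.shape
        return pd.DataFrame(
            {
                "species": self.species,
                "day_bin": np.tile(np.arange(1, k + 1), n),
                "null_prop": self.random_props.ravel(),
            }
        )


def run_permutation_test(
    species: str,
    independent_captures: Sequence[IndependentCapture],
    deployments: Sequence[Deployment],
    refresh_events: Sequence[RefreshEvent],
    n_randomizations: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    density: CircularDensity | None = None,
) -> PermutationResult:
    """Full randomization test for one species.

    The diel density is fitted from the species' own capture times unless
    supplied.  Deterministic for fixed seed and inputs.
    """
    caps = [c for c in independent_captures if c.species == species]
    if not caps:
        raise ValueError(f"no independent captures of {species!r}")
    observed = observed_proportions(caps)
    if density is None:
        times = np.array(
            [c.timestamp.hour + c.timestamp.minute / 60 + c.timestamp.second / 3600
             for c in caps]
        )
        density = fit_activity(times)
    stations = sorted({c.station_id for c in caps})
    random_props = build_null_distribution(
        stations, len(caps), deployments, refresh_events, density,
        n_randomizations, seed,
    )
    p_values = np.array(
        [permutation_pvalue(observed[d], random_props[:, d])
         for d in range(MAX_BIN_DAYS)]
    )
    classification = [classify_response(p, alpha) for p in p_values]
    return PermutationResult(
        species=species,
        observed_props=observed,
        random_props=random_props,
        p_values=p_values,
        classification=classification,
        n_randomizations=n_randomizations,
        seed=seed,
        alpha=alpha,
    )
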