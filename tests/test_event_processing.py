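import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lurefx.data_io import CaptureRecord, Deployment, RefreshEvent
from lurefx.event_processing import (
    assign_day_bin,
    attach_refresh_times,
    build_covariate_matrix,
    build_detection_matrix,
    capture_rate,
    filter_independent,
    hours_since_refresh,
    naive_summaries,
)
from lurefx.synthetic_data import generate_survey

from conftest import ts


class TestIndependenceFilter:
    def test_within_window_collapsed(self):
        caps = [CaptureRecord("g", "A", ts(2, 10)), CaptureRecord("g", "A", ts(2, 10, 30))]
        assert filter_independent(caps) == [caps[0]]

    def test_retained_anchor_rule(self):
        """10:00, 10:45, 11:30 -> keep 10:00 and 11:30: the window restarts
        at the previous retained capture, not the previous raw photo."""
        caps = [
            CaptureRecord("g", "A", ts(2, 10)),
            CaptureRecord("g", "A", ts(2, 10, 45)),
            CaptureRecord("g", "A", ts(2, 11, 30)),
        ]
        kept = filter_independent(caps)
        assert [c.timestamp for c in kept] == [ts(2, 10), ts(2, 11, 30)]

    def test_species_windows_independent(self):
        caps = [CaptureRecord("g", "A", ts(2, 10)), CaptureRecord("c", "A", ts(2, 10, 5))]
        assert len(filter_independent(caps)) == 2

    def test_empty_in_empty_out(self):
        assert filter_independent([]) == []

    @given(
        minutes=st.lists(st.integers(0, 60 * 24 * 5), min_size=0, max_size=40),
        window=st.floats(0.25, 6.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_idempotent_and_pairwise_spaced(self, minutes, window):
        base = dt.datetime(2013, 6, 1)
        caps = [
            CaptureRecord("g", "A", base + dt.timedelta(minutes=m))
            for m in sorted(set(minutes))
        ]
        kept = filter_independent(caps, window)
        assert filter_independent(kept, window) == kept
        gaps = np.diff([c.timestamp.timestamp() for c in kept]) / 3600.0
        assert np.all(gaps >= window - 1e-9)


class TestRefreshTiming:
    def test_hours_from_most_recent_refresh(self):
        cap = CaptureRecord("g", "A", ts(4, 6))          # Tue 06:00
        refresh = [RefreshEvent("A", ts(3, 12))]          # Mon 12:00
        assert hours_since_refresh(cap, refresh) == 18.0

    def test_capture_at_refresh_instant(self):
        cap = CaptureRecord("g", "A", ts(3, 12))
        assert hours_since_refresh(cap, [RefreshEvent("A", ts(3, 12))]) == 0.0

    def test_most_recent_rule(self):
        refresh = [RefreshEvent("A", ts(3, 12)), RefreshEvent("A", ts(7, 12))]
        cap = CaptureRecord("g", "A", ts(8, 12))          # Sat, after Fri refresh
        assert hours_since_refresh(cap, refresh) == 24.0

    def test_no_prior_refresh_errors(self):
        cap = CaptureRecord("g", "A", ts(2, 6))
        with pytest.raises(ValueError, match="station A"):
            hours_since_refresh(cap, [RefreshEvent("A", ts(5, 12))])

    def test_attach_assigns_bins(self, small_captures, small_refresh):
        annotated = attach_refresh_times(
            filter_independent(small_captures), small_refresh
        )
        assert all(a.hours_since_refresh >= 0 for a in annotated)
        assert all(a.day_bin in {1, 2, 3} for a in annotated)


class TestDayBin:
    @pytest.mark.parametrize(
        "hours,expected",
        [(0.5, 1), (0.0, 1), (23.99, 1), (24.0, 2), (144.0, 7),
         (167.9, 7), (168.0, None), (500.0, None)],
    )
    def test_half_open_24h_bins(self, hours, expected):
        assert assign_day_bin(hours) == expected

    def test_negative_hours_rejected(self):
        with pytest.raises(ValueError):
            assign_day_bin(-1.0)


class TestDetectionMatrix:
    def test_no_captures_all_zero_with_missing(self, small_deployments):
        dm = build_detection_matrix([], small_deployments, "genet")
        assert np.nansum(dm.y) == 0
        # station B inactive on June 5 -> missing cell
        j = dm.dates.index(dt.date(2013, 6, 5))
        i = dm.station_ids.index("B")
        assert np.isnan(dm.y[i, j])
        assert dm.observed.sum() == 19

    def test_same_day_captures_single_one(self, small_deployments):
        caps = [CaptureRecord("g", "A", ts(2, 6)), CaptureRecord("g", "A", ts(2, 20))]
        dm = build_detection_matrix(caps, small_deployments, "g")
        assert np.nansum(dm.y) == 1

    def test_cell_sum_matches_distinct_station_dates(self, tiny_survey):
        """Recount oracle: 1-cells = distinct (station, date) capture pairs."""
        kept = filter_independent(tiny_survey.captures)
        for species in ("genet", "duiker"):
            dm = build_detection_matrix(kept, tiny_survey.deployments, species)
            pairs = {
                (c.station_id, c.timestamp.date())
                for c in kept
                if c.species == species
            }
            assert np.nansum(dm.y) == len(pairs)


class TestCovariateMatrix:
    def test_attractant_age_resets_on_refresh(self):
        dep = [Deployment("A", "s1", dt.date(2013, 6, 1), dt.date(2013, 6, 10))]
        refresh = [RefreshEvent("A", ts(1, 0)), RefreshEvent("A", ts(8, 12))]
        cm = build_covariate_matrix("attractant_age", dep, refresh)
        assert cm.x[0].tolist() == [0, 1, 2, 3, 4, 5, 6, 0, 1, 2]

    def test_incremental_and_total_effort(self):
        dep = [Deployment("A", "s1", dt.date(2013, 6, 1), dt.date(2013, 6, 10))]
        inc = build_covariate_matrix("incremental_effort", dep)
        tot = build_covariate_matrix("total_effort", dep)
        assert inc.x[0].tolist() == list(range(1, 11))
        assert set(tot.x[0]) == {10}

    def test_effort_counts_only_active_days(self):
        inactive = frozenset({dt.date(2013, 6, 4), dt.date(2013, 6, 7)})
        dep = [Deployment("A", "s1", dt.date(2013, 6, 1), dt.date(2013, 6, 10),
                          inactive_dates=inactive)]
        inc = build_covariate_matrix("incremental_effort", dep)
        tot = build_covariate_matrix("total_effort", dep)
        active_vals = inc.x[0][~np.isnan(inc.x[0])]
        assert active_vals.tolist() == list(range(1, 9))
        assert np.nanmax(tot.x[0]) == 8

    def test_age_bounded_by_days_since_start_and_zero_on_refresh(self, tiny_survey):
        cm = build_covariate_matrix(
            "attractant_age", tiny_survey.deployments, tiny_survey.refresh_events
        )
        by_station = {d.station_id: d for d in tiny_survey.deployments}
        refresh_dates = {}
        for ev in tiny_survey.refresh_events:
            refresh_dates.setdefault(ev.station_id, set()).add(ev.timestamp.date())
        for i, sid in enumerate(cm.station_ids):
            start = by_station[sid].start_date
            for j, day in enumerate(cm.dates):
                v = cm.x[i, j]
                if np.isnan(v):
                    continue
                assert v <= (day - start).days
                if day in refresh_dates[sid]:
                    assert v == 0


class TestSummaries:
    def test_capture_rate_examples(self):
        assert capture_rate(0, 100) == 0.0
        assert capture_rate(38, 301) == pytest.approx(12.62, abs=0.005)

    @given(n=st.integers(0, 10_000), effort=st.floats(1.0, 1e5),
           scale=st.integers(1, 20))
    @settings(max_examples=50, derandomize=True)
    def test_capture_rate_linear_in_n_inverse_in_effort(self, n, effort, scale):
        base = capture_rate(n, effort)
        assert capture_rate(scale * n, effort) == pytest.approx(scale * base)
        assert capture_rate(n, scale * effort) == pytest.approx(base / scale)

    def test_naive_summaries(self, small_deployments):
        caps = [
            CaptureRecord("g", "A", ts(2, 6)),
            CaptureRecord("g", "B", ts(3, 6)),
            CaptureRecord("g", "B", ts(4, 6)),
        ]
        dm = build_detection_matrix(caps, small_deployments, "g")
        occ, det = naive_summaries(dm)
        assert occ == 1.0                       # both stations detected
        assert det == pytest.approx(3 / 19)     # 19 non-missing occasions

    def test_all_zero_matrix(self, small_deployments):
        dm = build_detection_matrix([], small_deployments, "g")
        assert naive_summaries(dm) == (0.0, 0.0)
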