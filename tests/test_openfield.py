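"""Open-field metric panel: definitions, binning, and rest-gap rules."""

import numpy as np
import pandas as pd
import pytest

from colitis_metasig.openfield import (
    Apparatus,
    BeamEventStream,
    OpenFieldConfig,
    compute_metrics,
    gap_rest_time,
)
from colitis_metasig.synthdata import BeamSimConfig, simulate_beam_stream

AP = Apparatus()


def _stream(rows, session=3600.0):
    df = pd.DataFrame(rows, columns=["t_start", "t_end", "kind", "beam_x", "beam_y"])
    return BeamEventStream("test", session, df, AP)


class TestComputeMetrics:
    def test_empty_stream(self):
        m = compute_metrics(_stream([]))
        assert m.session[["basic_movements", "rears", "xy_ambulation"]].sum() == 0
        assert m.session["immobility_time"] == 3600.0
        assert m.session["rest_time"] == 3600.0
        assert np.isnan(m.normalized_rears) and np.isnan(m.avg_rear_duration)
        assert set(m.undefined) == {"normalized_rears", "avg_rear_duration"}

    def test_definitional_ratios(self):
        # 30 rears totalling 45 s and 120 ambulation steps
        rows = []
        t = 0.0
        x, y = AP.start_position
        for i in range(120):
            x = x + 1 if x < AP.n_beams_x - 1 else x - 1
            rows.append((t, t + 0.1, "horizontal", x, y))
            t += 10.0
        for i in range(30):
            rows.append((t, t + 1.5, "vertical", x, y))
            t += 10.0
        m = compute_metrics(_stream(rows))
        assert m.session["xy_ambulation"] == 120
        assert m.session["rears"] == 30
        assert m.session["rearing_time"] == pytest.approx(45.0)
        assert m.normalized_rears == pytest.approx(0.25)
        assert m.avg_rear_duration == pytest.approx(1.5)

    def test_fine_movements_do_not_relocate(self):
        x, y = AP.start_position
        rows = [
            (0.0, 0.1, "horizontal", x + 1, y),  # ambulation
            (10.0, 10.1, "horizontal", x + 1, y),  # fine (same position)
            (20.0, 20.1, "horizontal", x + 1, y + 1),  # ambulation
        ]
        m = compute_metrics(_stream(rows))
        assert m.session["xy_ambulation"] == 2
        assert m.session["fine_movements"] == 1
        assert m.session["distance"] == pytest.approx(2 * AP.beam_pitch)

    @pytest.mark.parametrize("seed", [3, 17])
    def test_simulated_stream_matches_truth_exactly(self, seed):
        stream, truth = simulate_beam_stream(BeamSimConfig(seed=seed))
        m = compute_metrics(stream)
        for key, val in truth.items():
            got = getattr(m, key, None)
            if got is None:
                got = m.session[key]
            assert got == val, key

    def test_bin_additivity(self):
        stream, _ = simulate_beam_stream(BeamSimConfig(seed=5))
        m = compute_metrics(stream)
        assert len(m.per_bin) == 12
        for col in ["basic_movements", "fine_movements", "xy_ambulation", "rears"]:
            assert m.per_bin[col].sum() == m.session[col], col
        for col in ["rearing_time", "immobility_time", "rest_time", "distance"]:
            assert m.per_bin[col].sum() == pytest.approx(m.session[col], rel=1e-9), col

    def test_adding_rear_changes_only_vertical_metrics(self):
        stream, _ = simulate_beam_stream(BeamSimConfig(seed=7, session_length=600))
        gap_start = stream.events["t_end"].max() + 30.0
        extra = pd.concat(
            [
                stream.events,
                pd.DataFrame(
                    [(gap_start, gap_start + 2.0, "vertical", 8, 8)],
                    columns=stream.events.columns,
                ),
            ],
            ignore_index=True,
        )
        aug = compute_metrics(BeamEventStream("x", 3600.0, extra, AP))
        base_full = compute_metrics(
            BeamEventStream("x", 3600.0, stream.events, AP)
        )
        assert aug.session["rears"] == base_full.session["rears"] + 1
        assert aug.session["rearing_time"] == pytest.approx(
            base_full.session["rearing_time"] + 2.0
        )
        for col in ["basic_movements", "fine_movements", "xy_ambulation", "distance"]:
            assert aug.session[col] == base_full.session[col], col

    def test_immobility_complements_active_time(self):
        stream, _ = simulate_beam_stream(BeamSimConfig(seed=9))
        m = compute_metrics(stream)
        active = sum(
            t1 - t0 for t0, t1 in zip(stream.events["t_start"], stream.events["t_end"])
        )
        assert m.session["immobility_time"] + active == pytest.approx(3600.0)
        assert m.session["rest_time"] <= m.session["immobility_time"] + 1e-9

    def test_unsorted_events_rejected(self):
        rows = [(10.0, 10.1, "horizontal", 8, 8), (5.0, 5.1, "horizontal", 8, 8)]
        with pytest.raises(ValueError, match="sorted"):
            _stream(rows)

    def test_out_of_bounds_beam_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            _stream([(0.0, 0.1, "horizontal", 99, 0)])


class TestGapRestTime:
    def _events(self, intervals):
        return pd.DataFrame(
            [(a, b, "horizontal", 8, 8) for a, b in intervals],
            columns=["t_start", "t_end", "kind", "beam_x", "beam_y"],
        )

    def test_fourteen_second_gap_is_not_rest(self):
        ev = self._events([(0.0, 1.0), (15.0, 100.0)])  # 14 s gap
        assert gap_rest_time(ev, 100.0, 15.0) == 0.0

    def test_twenty_second_gap_counts_fully(self):
        ev = self._events([(0.0, 1.0), (21.0, 100.0)])  # 20 s gap
        assert gap_rest_time(ev, 100.0, 15.0) == pytest.approx(20.0)

    def test_exact_threshold_gap_excluded(self):
        ev = self._events([(0.0, 1.0), (16.0, 100.0)])  # exactly 15 s: strict
        assert gap_rest_time(ev, 100.0, 15.0) == 0.0

    def test_leading_and_trailing_gaps_counted(self):
        ev = self._events([(30.0, 31.0)])
        assert gap_rest_time(ev, 100.0, 15.0) == pytest.approx(30.0 + 69.0)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_bruteforce_scan(self, seed):
        rng = np.random.default_rng(seed)
        starts = np.sort(rng.uniform(0, 590, 40))
        starts = starts[np.insert(np.diff(starts) > 0.6, 0, True)]  # non-overlapping
        ev = self._events([(t, t + 0.5) for t in starts])
        # brute force: walk all boundaries
        bounds = [0.0] + [v for t in starts for v in (t, t + 0.5)] + [600.0]
        expected = 0.0
        for i in range(0, len(bounds), 2):
            gap = bounds[i + 1] - bounds[i]
            if gap > 15.0:
                expected += gap
        assert gap_rest_time(ev, 600.0, 15.0) == pytest.approx(expected)
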