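"""Open-field beam-break phenotyping: the ten-measure panel and pain surrogates.

An open-field session is recorded by two horizontal laser-beam arrays: a
lower array broken by horizontal movement and an upper array broken when
the animal rears on its hind legs. From the timestamped break events we
compute, per 5-minute bin and per 60-minute session:

  basic_movements   any horizontal beam cross (count)
  fine_movements    horizontal crosses without relocation (grooming etc.)
  xy_ambulation     complete relocations of the body (position change)
  rears             vertical beam-cross episodes (count)
  rearing_time      summed vertical episode durations (s)
  immobility_time   time with no active break of either kind (s)
  rest_time         summed break-free gaps strictly longer than 15 s (s)
  distance          city-block beam displacement x beam pitch

plus the two derived visceral-discomfort surrogates: normalized rears
(rears / xy_ambulation, controlling for overall mobility) and average rear
duration (rearing_time / rears, shorter rears suggesting reluctance to
sustain abdominal stretch). Derived ratios are reported as missing when
their denominator is zero.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Apparatus",
    "BeamEventStream",
    "OpenFieldConfig",
    "OpenFieldMetrics",
    "read_stream",
    "write_stream",
    "compute_metrics",
    "gap_rest_time",
    "COUNT_METRICS",
    "TIME_METRICS",
]

COUNT_METRICS = ["basic_movements", "fine_movements", "xy_ambulation", "rears"]
TIME_METRICS = ["rearing_time", "immobility_time", "rest_time"]


@dataclasses.dataclass
class Apparatus:
    """Beam-frame geometry. The commercial frame's exact grid is configurable."""

    beam_pitch: float = 2.54  # cm between adjacent beams
    n_beams_x: int = 16
    n_beams_y: int = 16

    @property
    def start_position(self) -> tuple[int, int]:
        # animals are placed at the center of the field; the relocation
        # reference starts there
        return self.n_beams_x // 2, self.n_beams_y // 2


@dataclasses.dataclass
class BeamEventStream:
    """One animal's session of beam-break events.

    ``events`` columns: t_start, t_end (s), kind ('horizontal'|'vertical'),
    beam_x, beam_y (integer beam indices). Events are time-ordered and lie
    within [0, session_length].
    """

    animal_id: str
    session_length: float
    events: pd.DataFrame
    apparatus: Apparatus = dataclasses.field(default_factory=Apparatus)

    def __post_init__(self) -> None:
        e = self.events
        required = {"t_start", "t_end", "kind", "beam_x", "beam_y"}
        if not required.issubset(e.columns):
            raise ValueError(f"missing event columns: {required - set(e.columns)}")
        if self.session_length <= 0:
            raise ValueError("session_length must be positive")
        if len(e):
            if not e["t_start"].is_monotonic_increasing:
                raise ValueError(f"{self.animal_id}: events not sorted by t_start")
            if (e["t_start"] < 0).any() or (e["t_end"] > self.session_length).any():
                raise ValueError(f"{self.animal_id}: event outside session window")
            if (e["t_end"] <= e["t_start"]).any():
                raise ValueError(f"{self.animal_id}: non-positive event duration")
            if not set(e["kind"]).issubset({"horizontal", "vertical"}):
                raise ValueError(f"{self.animal_id}: unknown event kind")
            ap = self.apparatus
            if (
                (e["beam_x"] < 0).any()
                or (e["beam_x"] >= ap.n_beams_x).any()
                or (e["beam_y"] < 0).any()
                or (e["beam_y"] >= ap.n_beams_y).any()
            ):
                raise ValueError(f"{self.animal_id}: beam index out of apparatus bounds")
        self.events = e.reset_index(drop=True)


@dataclasses.dataclass
class OpenFieldConfig:
    bin_length: float = 300.0  # 5-minute bins
    rest_threshold: float = 15.0  # gaps strictly longer than this are rest
    relocation_threshold: int = 1  # beam-index change registering ambulation

    def __post_init__(self) -> None:
        if self.bin_length <= 0 or self.rest_threshold < 0:
            raise ValueError("invalid open-field config")


@dataclasses.dataclass
class OpenFieldMetrics:
    """Per-bin table (one row per 5-min bin) plus the session totals row."""

    animal_id: str
    per_bin: pd.DataFrame
    session: pd.Series
    normalized_rears: float  # NaN when xy_ambulation == 0
    avg_rear_duration: float  # NaN when rears == 0
    undefined: list[str] = dataclasses.field(default_factory=list)


def read_stream(
    path: str | Path,
    animal_id: str | None = None,
    session_length: float = 3600.0,
    apparatus: Apparatus | None = None,
) -> BeamEventStream:
    path = Path(path)
    df = pd.read_csv(path)
    return BeamEventStream(
        animal_id or path.stem,
        session_length,
        df,
        apparatus or Apparatus(),
    )


def write_stream(s: BeamEventStream, path: str | Path) -> None:
    s.events.to_csv(path, index=False)


def _merged_intervals(events: pd.DataFrame) -> list[tuple[float, float]]:
    """Merge overlapping/adjacent break intervals, in time order."""
    merged: list[tuple[float, float]] = []
    for t0, t1 in zip(events["t_start"], events["t_end"]):
        if merged and t0 <= merged[-1][1]:
            if t1 > merged[-1][1]:
                merged[-1] = (merged[-1][0], t1)
        else:
            merged.append((t0, t1))
    return merged


def _gaps(events: pd.DataFrame, session_length: float) -> list[tuple[float, float]]:
    """Break-free intervals, including the leading and trailing ones."""
    merged = _merged_intervals(events)
    gaps = []
    cursor = 0.0
    for t0, t1 in merged:
        if t0 > cursor:
            gaps.append((cursor, t0))
        cursor = max(cursor, t1)
    if cursor < session_length:
        gaps.append((cursor, session_length))
    return gaps


def gap_rest_time(
    events: pd.DataFrame, session_length: float, threshold: float = 15.0
) -> float:
    """Total rest time: full durations of break-free gaps strictly > threshold.

    The whole qualifying gap counts as rest (the definition names the gap,
    not the excess over the threshold); leading and trailing gaps included.
    """
    total = 0.0
    for g0, g1 in _gaps(events, session_length):
        if g1 - g0 > threshold:
            total += g1 - g0
    return total


def _overlap_with_bin(t0: float, t1: float, b0: float, b1: float) -> float:
    return max(0.0, min(t1, b1) - max(t0, b0))


def compute_metrics(
    s: BeamEventStream, cfg: OpenFieldConfig | None = None
) -> OpenFieldMetrics:
    """Compute the full metric panel for one session.

    Counts are assigned to the bin containing the event's t_start; durations
    are split across bins by actual time overlap, so every metric's 12 bins
    sum to the session value. Relocation is registered when a horizontal
    event's beam position differs from the last registered position by at
    least ``relocation_threshold`` beam indices (city block), starting from
    the center of the field.
    """
    cfg = cfg or OpenFieldConfig()
    n_bins = s.session_length / cfg.bin_length
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("session_length must be divisible by bin_length")
    n_bins = int(round(n_bins))
    e = s.events
    edges = [i * cfg.bin_length for i in range(n_bins + 1)]

    cols = COUNT_METRICS + TIME_METRICS + ["distance"]
    per_bin = pd.DataFrame(0.0, index=pd.RangeIndex(n_bins, name="bin"), columns=cols)

    def bin_of(t: float) -> int:
        return min(int(t // cfg.bin_length), n_bins - 1)

    # horizontal events: classify as ambulation vs fine movement
    pos = s.apparatus.start_position
    horiz = e[e["kind"] == "horizontal"]
    total_steps = 0
    for t0, bx, by in zip(horiz["t_start"], horiz["beam_x"], horiz["beam_y"]):
        b = bin_of(t0)
        per_bin.loc[b, "basic_movements"] += 1
        step = abs(int(bx) - pos[0]) + abs(int(by) - pos[1])
        if step >= cfg.relocation_threshold:
            per_bin.loc[b, "xy_ambulation"] += 1
            per_bin.loc[b, "distance"] += s.apparatus.beam_pitch * step
            total_steps += step
            pos = (int(bx), int(by))
        else:
            per_bin.loc[b, "fine_movements"] += 1

    # vertical episodes: rears and rearing time (durations split across bins)
    vert = e[e["kind"] == "vertical"]
    for t0, t1 in zip(vert["t_start"], vert["t_end"]):
        per_bin.loc[bin_of(t0), "rears"] += 1
    for b in range(n_bins):
        tot = 0.0
        for t0, t1 in zip(vert["t_start"], vert["t_end"]):
            tot += _overlap_with_bin(t0, t1, edges[b], edges[b + 1])
        per_bin.loc[b, "rearing_time"] = tot

    # immobility: bin length minus active (merged break) time in the bin
    merged = _merged_intervals(e)
    for b in range(n_bins):
        active = 0.0
        for t0, t1 in merged:
            active += _overlap_with_bin(t0, t1, edges[b], edges[b + 1])
        per_bin.loc[b, "immobility_time"] = cfg.bin_length - active

    # rest: qualifying session-level gaps, apportioned to bins by overlap
    rest_gaps = [
        (g0, g1)
        for g0, g1 in _gaps(e, s.session_length)
        if g1 - g0 > cfg.rest_threshold
    ]
    for b in range(n_bins):
        tot = 0.0
        for g0, g1 in rest_gaps:
            tot += _overlap_with_bin(g0, g1, edges[b], edges[b + 1])
        per_bin.loc[b, "rest_time"] = tot

    session = per_bin.sum(axis=0)
    # session-level durations recomputed directly so they are exact, not a
    # resummation of bin splits (the two agree to float precision; tests
    # check bin additivity explicitly)
    session["rearing_time"] = float(sum(t1 - t0 for t0, t1 in zip(vert["t_start"], vert["t_end"])))
    session["immobility_time"] = s.session_length - float(
        sum(t1 - t0 for t0, t1 in merged)
    )
    session["rest_time"] = float(sum(g1 - g0 for g0, g1 in rest_gaps))
    session["distance"] = s.apparatus.beam_pitch * total_steps

    undefined = []
    if session["xy_ambulation"] > 0:
        normalized_rears = float(session["rears"] / session["xy_ambulation"])
    else:
        normalized_rears = float("nan")
        undefined.append("normalized_rears")
    if session["rears"] > 0:
        avg_rear_duration = float(session["rearing_time"] / session["rears"])
    else:
        avg_rear_duration = float("nan")
        undefined.append("avg_rear_duration")

    return OpenFieldMetrics(
        animal_id=s.animal_id,
        per_bin=per_bin,
        session=session,
        normalized_rears=normalized_rears,
        avg_rear_duration=avg_rear_duration,
        undefined=undefined,
    )


def metrics_frame(metrics: list[OpenFieldMetrics]) -> pd.DataFrame:
    """Wide per-animal session table (one row per animal) for group statistics."""
    rows = []
    for m in metrics:
        row = m.session.to_dict()
        row["animal_id"] = m.animal_id
        row["normalized_rears"] = m.normalized_rears
        row["avg_rear_duration"] = m.avg_rear_duration
        rows.append(row)
    df = pd.DataFrame(rows).set_index("animal_id")
    return df
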