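"""Quantify parental-histone inheritance from live-cell pulse-chase traces.

The input contract is a set of per-cell time series of integrated (whole-
nucleus summed) fluorescence at a fixed frame interval, with lineage links
from each mother to her two daughters and an optional geminin cell-cycle
channel. Segmentation and background subtraction are upstream of this
module.

Cell-cycle points are called either from a known mitosis time by fixed
offsets — G1/S 11 h before mitosis (12 h for the double-mutant preset),
G2 1 h before, next G1 1 h after — or from the geminin channel (signal
appearance marks G1/S, its reduction marks mitosis). Signals are then
normalized per cell to the G1/S value, and group differences are assessed
with the two-tailed unpaired (equal-variance) Student t test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sstats

__all__ = [
    "CellTrace",
    "PhaseOffsets",
    "GemininThresholds",
    "PhaseCalls",
    "InheritanceStats",
    "DurationSummary",
    "DOUBLE_MUTANT_OFFSETS",
    "call_phases",
    "quantify_inheritance",
    "ttest_two_sample",
    "g1s_to_mitosis_duration",
]


@dataclass
class CellTrace:
    """One cell's time series with optional lineage and geminin channel."""

    cell_id: str
    parent_id: str | None
    time_h: np.ndarray
    signal: np.ndarray
    geminin: np.ndarray | None = None
    mitosis_time: float | None = None

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.geminin is not None:
            self.geminin = np.asarray(self.geminin, dtype=float)
            if self.geminin.shape != self.time_h.shape:
                raise ValueError("geminin series must match the time axis")
        if self.time_h.shape != self.signal.shape:
            raise ValueError("signal series must match the time axis")
        if self.time_h.size >= 2:
            dt = np.diff(self.time_h)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time must increase strictly at constant spacing")
        if np.any(self.signal < 0):
            raise ValueError("signals must be nonnegative")

    @property
    def frame_interval_h(self) -> float:
        if self.time_h.size < 2:
            raise ValueError("trace too short to define a frame interval")
        return float(self.time_h[1] - self.time_h[0])

    def value_at(self, t: float) -> float:
        """Signal at the frame nearest to t (within half a frame)."""
        idx = int(np.argmin(np.abs(self.time_h - t)))
        if abs(self.time_h[idx] - t) > self.frame_interval_h / 2 + 1e-9:
            raise ValueError(
                f"time {t} h outside trace {self.cell_id} "
                f"[{self.time_h[0]}, {self.time_h[-1]}]"
            )
        return float(self.signal[idx])


@dataclass(frozen=True)
class PhaseOffsets:
    """Hours relative to mitosis used by offset-mode phase calling."""

    g1s_hours: float = 11.0
    g2_hours: float = 1.0
    next_g1_hours: float = 1.0


#: Double mutants take ~12 h from G1/S to mitosis; their offset preset.
DOUBLE_MUTANT_OFFSETS = PhaseOffsets(g1s_hours=12.0)


@dataclass(frozen=True)
class GemininThresholds:
    """Geminin appearance/reduction crossings, as fractions of the trace max."""

    appear_frac: float = 0.50
    fall_frac: float = 0.25
    sustain_frames: int = 2


@dataclass
class PhaseCalls:
    cell_id: str
    t_g1s: float
    t_g2: float
    mitosis_time: float
    t_next_g1: float
    mode: str

    def __post_init__(self) -> None:
        if not (self.t_g1s < self.t_g2 < self.mitosis_time < self.t_next_g1):
            raise ValueError(
                f"phase order violated for {self.cell_id}: "
                f"G1/S={self.t_g1s}, G2={self.t_g2}, "
                f"mitosis={self.mitosis_time}, nextG1={self.t_next_g1}"
            )


def _snap(t: float, frame_h: float, toward: float) -> float:
    """Snap t to the nearest frame; ties round toward the reference time."""
    lo = math.floor(t / frame_h) * frame_h
    hi = lo + frame_h
    if abs(t - lo) < abs(hi - t):
        return lo
    if abs(hi - t) < abs(t - lo):
        return hi
    return lo if abs(lo - toward) < abs(hi - toward) else hi


def call_phases(
    trace: CellTrace,
    mode: str = "offset",
    offsets: PhaseOffsets = PhaseOffsets(),
    geminin_thresholds: GemininThresholds = GemininThresholds(),
) -> PhaseCalls:
    """Call G1/S, G2 and next-G1 times for one cell.

    Offset mode places them at fixed distances from a known mitosis time,
    snapped to the frame grid. Geminin mode locates G1/S at the first
    sustained upward crossing of the appearance threshold and mitosis at
    the first subsequent drop below the reduction threshold, then applies
    the G2/next-G1 offsets.
    """
    frame_h = trace.frame_interval_h
    if mode == "offset":
        if trace.mitosis_time is None:
            raise ValueError(f"offset mode requires mitosis_time on {trace.cell_id}")
        t_mit = trace.mitosis_time
    elif mode == "geminin":
        if trace.geminin is None:
            raise ValueError(f"geminin mode requires a geminin series on {trace.cell_id}")
        g = trace.geminin
        peak = float(g.max())
        up = g >= geminin_thresholds.appear_frac * peak
        k = geminin_thresholds.sustain_frames
        rise_idx = None
        for i in range(g.size - k + 1):
            if up[i : i + k].all():
                rise_idx = i
                break
        if rise_idx is None:
            raise ValueError(f"geminin appearance not found in {trace.cell_id}")
        down = g < geminin_thresholds.fall_frac * peak
        fall = np.nonzero(down[rise_idx:])[0]
        if fall.size == 0:
            raise ValueError(f"mitosis not found in {trace.cell_id}: geminin never falls")
        t_mit = float(trace.time_h[rise_idx + fall[0]])
        t_g1s = float(trace.time_h[rise_idx])
        return PhaseCalls(trace.cell_id, t_g1s,
                          _snap(t_mit - offsets.g2_hours, frame_h, t_mit),
                          t_mit,
                          _snap(t_mit + offsets.next_g1_hours, frame_h, t_mit),
                          mode="geminin")
    else:
        raise ValueError(f"unknown phase-calling mode {mode!r}")

    return PhaseCalls(
        trace.cell_id,
        _snap(t_mit - offsets.g1s_hours, frame_h, t_mit),
        _snap(t_mit - offsets.g2_hours, frame_h, t_mit),
        t_mit,
        _snap(t_mit + offsets.next_g1_hours, frame_h, t_mit),
        mode="offset",
    )


@dataclass
class InheritanceStats:
    """Per-cell G1/S-normalized signal summaries for one cohort.

    ``per_cell`` has one row per mother with columns g1s_signal,
    g2_over_g1s, d1_over_g1s, d2_over_g1s, daughters_over_g1s,
    daughters_over_g2 (the conservation ratio). ``summary`` maps each of
    those ratio columns to (mean, sd). ``tests`` holds unpaired two-sided
    Student t results between normalized quantities.
    """

    per_cell: pd.DataFrame
    summary: dict[str, tuple[float, float]]
    n: int
    n_excluded: int
    tests: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)


_RATIO_COLUMNS = ("g2_over_g1s", "d1_over_g1s", "d2_over_g1s",
                  "daughters_over_g1s", "daughters_over_g2")


def quantify_inheritance(
    traces: Iterable[CellTrace],
    calls: Mapping[str, PhaseCalls],
) -> InheritanceStats:
    """Summarize inheritance for every mother with phase calls and 2 daughters.

    Signals are read at the called G1/S and G2 frames of the mother and at
    the next-G1 frame of each daughter, then normalized to the mother's
    G1/S value (so G1/S == 1 per cell by construction). Mothers missing a
    daughter link or a phase call are excluded and counted.
    """
    by_id = {t.cell_id: t for t in traces}
    daughters: dict[str, list[CellTrace]] = {}
    for t in by_id.values():
        if t.parent_id is not None:
            daughters.setdefault(t.parent_id, []).append(t)

    rows = []
    n_excluded = 0
    for cell_id, call in calls.items():
        mother = by_id.get(cell_id)
        kids = sorted(daughters.get(cell_id, []), key=lambda d: d.cell_id)
        if mother is None or len(kids) != 2:
            n_excluded += 1
            continue
        g1s = mother.value_at(call.t_g1s)
        if g1s <= 0:
            n_excluded += 1
            continue
        g2 = mother.value_at(call.t_g2)
        d1 = kids[0].value_at(call.t_next_g1)
        d2 = kids[1].value_at(call.t_next_g1)
        rows.append({
            "cell_id": cell_id,
            "g1s_signal": g1s,
            "g2_over_g1s": g2 / g1s,
            "d1_over_g1s": d1 / g1s,
            "d2_over_g1s": d2 / g1s,
            "daughters_over_g1s": (d1 + d2) / g1s,
            "daughters_over_g2": (d1 + d2) / g2,
        })
    per_cell = pd.DataFrame(rows, columns=["cell_id", "g1s_signal", *_RATIO_COLUMNS])
    summary = {
        col: (float(per_cell[col].mean()), float(per_cell[col].std(ddof=1)))
        for col in _RATIO_COLUMNS
    }
    tests: dict[tuple[str, str], tuple[float, float]] = {}
    if len(per_cell) >= 2:
        ones = np.ones(len(per_cell))  # G1/S-normalized reference (==1 per cell)
        for col in ("g2_over_g1s", "daughters_over_g1s"):
            tests[("g1s", col)] = ttest_two_sample(ones, per_cell[col].to_numpy())
        tests[("g2_over_g1s", "daughters_over_g1s")] = ttest_two_sample(
            per_cell["g2_over_g1s"].to_numpy(),
            per_cell["daughters_over_g1s"].to_numpy(),
        )
    return InheritanceStats(per_cell, summary, len(per_cell), n_excluded, tests)


def ttest_two_sample(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-tailed unpaired Student t test (equal-variance by default).

    Classic pooled-variance t with ``df = n_a + n_b - 2``; Welch's variant
    behind ``equal_var=False``. Two samples with zero pooled variance give
    ``(0, 1)`` when their means agree, else an infinite t with ``p = 0``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each sample needs n >= 2")
    mean_diff = a.mean() - b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if equal_var:
        df = na + nb - 2
        pooled = ((na - 1) * va + (nb - 1) * vb) / df
        se = math.sqrt(pooled * (1.0 / na + 1.0 / nb))
    else:
        se = math.sqrt(va / na + vb / nb)
        if se > 0:
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        else:
            df = na + nb - 2
    if se == 0:
        if mean_diff == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, mean_diff), 0.0
    t = mean_diff / se
    p = 2.0 * float(_sstats.t.sf(abs(t), df))
    return float(t), p


@dataclass
class DurationSummary:
    mean_hours: float
    sd_hours: float
    n: int
    n_failed: int


def g1s_to_mitosis_duration(
    traces: Iterable[CellTrace],
    thresholds: GemininThresholds = GemininThresholds(),
) -> DurationSummary:
    """Mean +/- SD of the geminin-defined G1/S -> mitosis time per cohort.

    Per cell, mitosis minus the geminin-called G1/S time; cells whose
    geminin channel cannot be called are excluded and counted.
    """
    durations: list[float] = []
    n_failed = 0
    any_trace = False
    for trace in traces:
        if trace.parent_id is not None:
            continue  # duration is defined on mother traces
        any_trace = True
        try:
            call = call_phases(trace, mode="geminin", geminin_thresholds=thresholds)
        except ValueError:
            n_failed += 1
            continue
        durations.append(call.mitosis_time - call.t_g1s)
    if not any_trace:
        raise ValueError("empty cohort: no mother traces provided")
    if not durations:
        raise ValueError("no cell yielded a geminin-defined duration")
    arr = np.asarray(durations)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return DurationSummary(float(arr.mean()), sd, arr.size, n_failed)
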