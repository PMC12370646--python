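"""Gait-event detection from shank sagittal angular velocity.

During walking the shank gyroscope's sagittal channel shows one large
positive peak per stride (forward swing).  The first local minimum before
that peak is terminal contact (TC, toe-off) and the first local minimum
after it is initial contact (IC, heel strike); a gait cycle of one side is
the triple IC -> TC -> next IC of that side.  Detection is deterministic:
a local minimum is a sample strictly smaller than its neighbours, with
plateaus resolved to their leftmost sample.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as _sig

from .segment import Section

IC = "IC"
TC = "TC"


@dataclasses.dataclass(frozen=True)
class GaitEvent:
    side: str  # "L" or "R"
    type: str  # "IC" or "TC"
    sample: int
    time_s: float

    def __post_init__(self) -> None:
        if self.side not in ("L", "R"):
            raise ValueError("side must be 'L' or 'R'")
        if self.type not in (IC, TC):
            raise ValueError("type must be 'IC' or 'TC'")


@dataclasses.dataclass(frozen=True)
class GaitCycle:
    """One stride: IC -> TC -> next IC of the same side (sample indices)."""

    side: str
    ic_start: int
    tc: int
    ic_end: int

    def __post_init__(self) -> None:
        if not self.ic_start < self.tc < self.ic_end:
            raise ValueError("gait cycle requires ic_start < tc < ic_end")


def detect_swing_peaks(
    signal: np.ndarray,
    fs: float,
    section: Section | None = None,
    min_height_deg_s: float = 30.0,
    min_prominence_deg_s: float = 50.0,
    min_separation_s: float = 0.4,
) -> np.ndarray:
    """Prominent positive swing peaks of a shank sagittal angular-velocity series.

    When ``section`` is given only peaks inside its half-open interval are
    returned (as absolute sample indices).  An empty array means the
    section yields no gait cycles.
    """
    signal = np.asarray(signal, dtype=float)
    lo, hi = (0, len(signal)) if section is None else (section.start_sample, section.end_sample)
    window = signal[lo:hi]
    if window.size < 3:
        return np.asarray([], dtype=int)
    peaks, _ = _sig.find_peaks(
        window,
        height=min_height_deg_s,
        prominence=min_prominence_deg_s,
        distance=max(int(min_separation_s * fs), 1),
    )
    return peaks + lo


def _is_local_min(signal: np.ndarray, i: int, lo: int, hi: int) -> bool:
    """Leftmost-of-plateau local-minimum predicate on ``signal[lo:hi]``.

    Sample ``i`` is a local minimum when it is strictly smaller than its
    left neighbour and the next differing sample to the right (both inside
    the window) is strictly larger.
    """
    if i <= lo or i >= hi - 1:
        return False
    if not signal[i] < signal[i - 1]:
        return False
    j = i + 1
    while j < hi and signal[j] == signal[i]:
        j += 1
    return j < hi and signal[j] > signal[i]


def local_minima(signal: np.ndarray, lo: int = 0, hi: int | None = None) -> np.ndarray:
    """All interior local minima of ``signal[lo:hi]`` (absolute indices)."""
    signal = np.asarray(signal, dtype=float)
    hi = len(signal) if hi is None else hi
    return np.asarray(
        [i for i in range(lo + 1, hi - 1) if _is_local_min(signal, i, lo, hi)], dtype=int
    )


def _first_min_left(signal: np.ndarray, start: int, lo: int, hi: int) -> int | None:
    """First local minimum strictly before ``start`` (walking left)."""
    for i in range(start - 1, lo, -1):
        if _is_local_min(signal, i, lo, hi):
            return i
    return None


def _first_min_right(signal: np.ndarray, start: int, lo: int, hi: int) -> int | None:
    """First local minimum strictly after ``start`` (walking right)."""
    for i in range(start + 1, hi - 1):
        if _is_local_min(signal, i, lo, hi):
            return i
    return None


def detect_ic_tc(
    signal: np.ndarray,
    peaks: np.ndarray,
    fs: float,
    side: str,
    lo: int = 0,
    hi: int | None = None,
) -> list[GaitEvent]:
    """IC/TC events flanking each swing peak.

    For each peak, TC is the first local minimum strictly before it and IC
    the first local minimum strictly after it, both restricted to
    ``[lo, hi)``.  A peak lacking a flanking minimum inside the window
    produces no event on that flank; a valley shared by two peaks serves
    as IC of the first and TC of the second.  Events are deduplicated per
    (type, sample) and returned time-ordered.
    """
    signal = np.asarray(signal, dtype=float)
    hi = len(signal) if hi is None else hi
    seen = set()
    events = []
    for p in np.sort(np.asarray(peaks, dtype=int)):
        tc = _first_min_left(signal, p, lo, hi)
        ic = _first_min_right(signal, p, lo, hi)
        for typ, s in ((TC, tc), (IC, ic)):
            if s is None:
                continue
            if (typ, s) not in seen:
                seen.add((typ, s))
                events.append(GaitEvent(side, typ, int(s), s / fs))
    events.sort(key=lambda e: (e.sample, e.type))
    return events


def assemble_cycles(events: list[GaitEvent]) -> list[GaitCycle]:
    """Maximal non-overlapping IC -> TC -> IC triples of one side.

    Consecutive cycles share the boundary IC; leading TCs and incomplete
    trailing patterns are dropped.
    """
    if not events:
        return []
    sides = {e.side for e in events}
    if len(sides) > 1:
        raise ValueError("assemble_cycles expects events of a single side")
    ordered = sorted(events, key=lambda e: e.sample)
    cycles = []
    ic_start = None
    tc = None
    for e in ordered:
        if e.type == IC:
            if ic_start is not None and tc is not None:
                cycles.append(GaitCycle(e.side, ic_start, tc, e.sample))
            ic_start = e.sample
            tc = None
        else:  # TC
            if ic_start is not None and e.sample > ic_start:
                tc = e.sample
    return cycles


def detect_section_events(
    signal: np.ndarray,
    fs: float,
    section: Section,
    side: str,
    **peak_kwargs,
) -> list[GaitEvent]:
    """Swing-peak detection plus IC/TC extraction inside one section."""
    peaks = detect_swing_peaks(signal, fs, section=section, **peak_kwargs)
    return detect_ic_tc(
        signal, peaks, fs, side, lo=section.start_sample, hi=section.end_sample
    )


def events_to_frame(participant_id: str, events: list[GaitEvent]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "participant": participant_id,
                "side": e.side,
                "type": e.type,
                "sample": e.sample,
                "time_s": e.time_s,
            }
            for e in events
        ]
    )
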