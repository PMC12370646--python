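"""Trial segmentation: split each shuttle-walk trial into straight-walk
and turning sections from the waist heading curve.

Each trial of the protocol is walk - 180-degree turn - walk - 180-degree
turn, so the waist heading rises by 180 degrees twice per trial.  Peaks in
the waist rotation curve mark the turning events; here this is
operationalized on the smoothed absolute heading *rate* (deg/s): every
turn produces one prominent rate peak, and the turn's onset/completion are
the threshold crossings (a fixed fraction of the peak rate) on either side
of it.  The four crossings per trial play the role of the four turning
peaks: the first and second bound the first turn, the third and fourth the
second turn, and the active-walking remainder is straight walking.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage as _ndi
from scipy import signal as _sig


class SegmentationFailure(RuntimeError):
    """A trial did not expose the expected turning structure."""


@dataclasses.dataclass(frozen=True)
class Section:
    """Half-open ``[start_sample, end_sample)`` interval of one section.

    ``kind`` is ``"SW"`` (straight walk) or ``"T"`` (turn); ``ordinal``
    counts sections of that kind 1..6 across the whole assessment.
    """

    participant_id: str
    trial: int
    kind: str
    ordinal: int
    start_sample: int
    end_sample: int

    def __post_init__(self) -> None:
        if self.kind not in ("SW", "T"):
            raise ValueError("kind must be 'SW' or 'T'")
        if not self.start_sample < self.end_sample:
            raise ValueError("section must satisfy start < end")

    def duration_s(self, fs: float) -> float:
        return (self.end_sample - self.start_sample) / fs

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample


def sections_to_frame(sections: list[Section]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "participant": s.participant_id,
                "trial": s.trial,
                "kind": s.kind,
                "ordinal": s.ordinal,
                "start_sample": s.start_sample,
                "end_sample": s.end_sample,
            }
            for s in sections
        ]
    )


def smoothed_rate(series: np.ndarray, fs: float, smooth_s: float = 0.15) -> np.ndarray:
    """Absolute first derivative of an angle series, gaussian-smoothed."""
    rate = np.gradient(np.asarray(series, dtype=float)) * fs
    sigma = max(smooth_s * fs / 2.0, 1.0)
    return np.abs(_ndi.gaussian_filter1d(rate, sigma))


def active_interval(
    shank_energy: np.ndarray, fs: float, threshold_frac: float = 0.05
) -> tuple[int, int]:
    """First/last sample where the smoothed shank angular-velocity energy
    exceeds ``threshold_frac`` of its maximum (trims standing-still padding)."""
    env = _ndi.gaussian_filter1d(np.abs(np.asarray(shank_energy, float)), 0.2 * fs)
    peak = env.max()
    if peak <= 0:
        raise SegmentationFailure("no movement detected")
    idx = np.flatnonzero(env > threshold_frac * peak)
    return int(idx[0]), int(idx[-1]) + 1


def detect_turn_peaks(
    heading: np.ndarray,
    fs: float,
    min_prominence_deg_s: float = 30.0,
    min_separation_s: float = 1.0,
    edge_frac: float = 0.15,
    lo: int = 0,
    hi: int | None = None,
    merge_gap_s: float = 1.5,
    smooth_s: float = 0.15,
) -> list[int]:
    """Turn onset/completion samples from an unwrapped, detrended heading.

    Finds prominent peaks of the smoothed absolute heading rate inside
    ``[lo, hi)`` and converts each into the pair of samples where the rate
    crosses ``edge_frac`` of the peak value.  Crossing pairs closer than
    ``merge_gap_s`` are merged into one turn — a freezing episode can halt
    the rotation mid-turn, splitting its rate peak in two, yet it is still
    a single 180-degree turn.  The merged (onset, completion) samples are
    returned in time order; fewer than 4 boundaries raise
    :class:`SegmentationFailure` (the trial cannot be segmented).
    """
    hi = len(heading) if hi is None else hi
    rate = smoothed_rate(heading, fs, smooth_s)
    window = rate[lo:hi]
    peaks, _ = _sig.find_peaks(
        window,
        prominence=min_prominence_deg_s,
        distance=max(int(min_separation_s * fs), 1),
    )
    intervals: list[list[int]] = []
    for p in peaks:
        thresh = edge_frac * window[p]
        left = p
        while left > 0 and window[left - 1] > thresh:
            left -= 1
        right = p
        while right < len(window) - 1 and window[right + 1] > thresh:
            right += 1
        intervals.append([lo + left, lo + right])
    intervals.sort()
    merged: list[list[int]] = []
    for iv in intervals:
        if merged and iv[0] - merged[-1][1] < merge_gap_s * fs:
            merged[-1][1] = max(merged[-1][1], iv[1])
        else:
            merged.append(iv)
    boundaries = [b for iv in merged for b in iv]
    if len(boundaries) < 4:
        raise SegmentationFailure(
            f"found {len(boundaries)} turn boundaries in window, need at least 4"
        )
    return boundaries


def segment_trial(
    participant_id: str,
    trial: int,
    peaks: list[int],
    active_start: int,
) -> list[Section]:
    """Build the SW, T, SW, T sections of one trial from its 4 turn boundaries.

    ``peaks`` are the (onset1, end1, onset2, end2) samples returned by
    :func:`detect_turn_peaks`; ordinals are assigned later across trials.
    """
    if len(peaks) != 4:
        raise ValueError(f"expected exactly 4 turn boundaries, got {len(peaks)}")
    p1, p2, p3, p4 = peaks
    if not (active_start < p1 < p2 < p3 < p4):
        raise ValueError("turn boundaries must be strictly increasing after the active start")
    mk = lambda kind, a, b: Section(participant_id, trial, kind, 0, int(a), int(b))
    return [
        mk("SW", active_start, p1),
        mk("T", p1, p2),
        mk("SW", p2, p3),
        mk("T", p3, p4),
    ]


def _assign_ordinals(sections: list[Section]) -> list[Section]:
    counters = {"SW": 0, "T": 0}
    out = []
    for s in sorted(sections, key=lambda s: s.start_sample):
        counters[s.kind] += 1
        out.append(dataclasses.replace(s, ordinal=counters[s.kind]))
    return out


def segment_recording(
    heading: np.ndarray,
    shank_gyro_sag: np.ndarray,
    fs: float,
    participant_id: str = "p",
    n_trials: int = 3,
    min_prominence_deg_s: float = 30.0,
    min_separation_s: float = 1.0,
    edge_frac: float = 0.15,
    min_gap_s: float = 0.8,
) -> list[Section]:
    """Segment a full assessment into 6 SW + 6 T sections.

    Trials are located as contiguous active-movement intervals of the
    smoothed shank angular-velocity envelope separated by standing-still
    gaps of at least ``min_gap_s``; each trial then yields two turns and
    two straight walks.  Trials whose turn structure cannot be resolved
    raise :class:`SegmentationFailure`.
    """
    env = _ndi.gaussian_filter1d(np.abs(np.asarray(shank_gyro_sag, float)), 0.15 * fs)
    peak = env.max()
    if peak <= 0:
        raise SegmentationFailure("no movement detected")
    active = env > 0.05 * peak
    # close gaps shorter than min_gap_s so within-trial lulls do not split trials
    lab, n_lab = _ndi.label(~active)
    for i in range(1, n_lab + 1):
        idx = np.flatnonzero(lab == i)
        if len(idx) < min_gap_s * fs and idx[0] > 0 and idx[-1] < len(active) - 1:
            active[idx] = True
    lab, n_lab = _ndi.label(active)
    # refine trial edges with a narrow envelope: the coarse envelope above is
    # good at separating trials but blurs their start/end by ~2 smoothing widths
    fine = _ndi.gaussian_filter1d(np.abs(np.asarray(shank_gyro_sag, float)), 0.05 * fs)
    intervals = []
    for i in range(1, n_lab + 1):
        idx = np.flatnonzero(lab == i)
        if len(idx) <= 1.0 * fs:  # ignore sub-second movement blips
            continue
        lo, hi = int(idx[0]), int(idx[-1]) + 1
        margin = int(0.5 * fs)
        wlo, whi = max(lo - margin, 0), min(hi + margin, len(fine))
        local = fine[wlo:whi]
        above = np.flatnonzero(local > 0.05 * local.max())
        if above.size:
            lo, hi = wlo + int(above[0]), wlo + int(above[-1]) + 1
        intervals.append((lo, hi))
    if len(intervals) != n_trials:
        raise SegmentationFailure(
            f"expected {n_trials} active trials, found {len(intervals)}"
        )
    sections: list[Section] = []
    for trial, (lo, hi) in enumerate(intervals, start=1):
        boundaries = detect_turn_peaks(
            heading,
            fs,
            min_prominence_deg_s=min_prominence_deg_s,
            min_separation_s=min_separation_s,
            edge_frac=edge_frac,
            lo=lo,
            hi=hi,
        )
        if len(boundaries) != 4:
            raise SegmentationFailure(
                f"trial {trial}: found {len(boundaries) // 2} turns, expected 2"
            )
        sections.extend(segment_trial(participant_id, trial, boundaries, lo))
    return _assign_ordinals(sections)


def match_to_ground_truth(
    pred: list[Section], truth: list[Section], fs: float, tol_s: float = 0.25
) -> dict:
    """Per-boundary absolute time error between predicted and true sections.

    Sections are matched by (trial, kind, ordinal); a count mismatch is
    reported, not raised.  Returns boundary errors in seconds and the
    fraction within ``tol_s``.
    """
    key = lambda s: (s.trial, s.kind, s.ordinal)
    truth_map = {key(s): s for s in truth}
    errors = []
    unmatched = 0
    for s in pred:
        t = truth_map.get(key(s))
        if t is None:
            unmatched += 1
            continue
        errors.append(abs(s.start_sample - t.start_sample) / fs)
        errors.append(abs(s.end_sample - t.end_sample) / fs)
    errors = np.asarray(errors, dtype=float)
    frac = float(np.mean(errors <= tol_s)) if errors.size else 0.0
    return {
        "boundary_errors_s": errors,
        "fraction_within_tol": frac,
        "tol_s": tol_s,
        "n_matched": len(errors) // 2,
        "n_unmatched": unmatched,
        "count_mismatch": len(pred) != len(truth),
    }
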