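"""Kinematic feature catalog and the two-step feature construction.

Three feature categories are computed from a segmented recording:

1. cycle-based features — computed per gait cycle inside straight-walk
   sections, then averaged within each section;
2. segmentation features — computed directly per section (straight walk
   or turn), independent of gait-cycle detection;
3. whole-assessment features — one value per participant.

Construction then happens in two steps.  Step 1 replaces every per-section
base feature by its max / min / mean / diff_mean over the six applicable
sections (``diff_mean`` is the mean absolute consecutive-section
difference, a variability measure).  Step 2 collapses every left/right
pair into (max), (min) and (diff) = |L - R|; central-sensor features pass
through unchanged.  Names follow the ``Base—agg (pair)`` convention, e.g.
``Shank—Swing RoM—mean (max)``.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from . import events as ev
from .preprocess import AngleSeries, RawRecording
from .segment import Section, smoothed_rate

logger = logging.getLogger(__name__)

STEP1_AGGS = ("max", "min", "mean", "diff_mean")
STEP2_AGGS = ("max", "min", "diff")

#: sensor groups used for model-contribution reporting (L/R merged)
SENSOR_GROUPS = ("waist", "chest", "hand", "thigh", "shank", "foot")


@dataclasses.dataclass(frozen=True)
class FeatureDef:
    base_name: str
    category: str  # cycle_based | segmentation | whole
    sensors: tuple[str, ...]  # subset of SENSOR_GROUPS
    sidedness: str  # bilateral | central
    units: str
    applies_to: str  # SW | T | WT

    def __post_init__(self) -> None:
        if self.category not in ("cycle_based", "segmentation", "whole"):
            raise ValueError(f"unknown category {self.category}")
        if self.category == "cycle_based" and self.applies_to != "SW":
            raise ValueError("cycle-based features reference straight-walk sections only")
        if self.category == "whole" and self.applies_to != "WT":
            raise ValueError("whole features reference the whole assessment")
        if self.sidedness not in ("bilateral", "central"):
            raise ValueError(f"unknown sidedness {self.sidedness}")
        unknown = set(self.sensors) - set(SENSOR_GROUPS)
        if unknown:
            raise ValueError(f"unknown sensor groups {unknown}")


_REGISTRY: dict[str, FeatureDef] = {}


def register_feature(fdef: FeatureDef) -> FeatureDef:
    """Add a feature definition to the catalog (extension point)."""
    _REGISTRY[fdef.base_name] = fdef
    return fdef


def feature_registry() -> dict[str, FeatureDef]:
    return dict(_REGISTRY)


for _f in [
    # --- cycle-based (straight walks only) -------------------------------
    FeatureDef("Gait Speed", "cycle_based", ("shank",), "central", "m/s", "SW"),
    FeatureDef("Cadence", "cycle_based", ("shank",), "central", "steps/min", "SW"),
    FeatureDef("Step Length", "cycle_based", ("shank",), "central", "m", "SW"),
    FeatureDef("Stride Time", "cycle_based", ("shank",), "bilateral", "s", "SW"),
    FeatureDef("Double Support", "cycle_based", ("shank", "foot"), "bilateral", "%", "SW"),
    FeatureDef("Shank—Swing RoM", "cycle_based", ("shank",), "bilateral", "deg", "SW"),
    FeatureDef(
        "Trunk—Max Sagittal Angular Velocity", "cycle_based", ("chest",), "central", "deg/s", "SW"
    ),
    # --- segmentation features -------------------------------------------
    FeatureDef(
        "SW—Lumbar—Difference of Sagittal Sway", "segmentation", ("waist",), "central", "deg", "SW"
    ),
    FeatureDef("Straight-Walking Duration", "segmentation", ("shank",), "central", "s", "SW"),
    FeatureDef("Trunk—Forward Sway Max", "segmentation", ("chest",), "central", "deg", "SW"),
    FeatureDef("180° Turn—Duration", "segmentation", ("waist",), "central", "s", "T"),
    FeatureDef("180° Turn—Steps", "segmentation", ("shank",), "central", "count", "T"),
    FeatureDef("180° Turn—Max Angular Velocity", "segmentation", ("waist",), "central", "deg/s", "T"),
    FeatureDef("180° Turn—Mean Angular Velocity", "segmentation", ("waist",), "central", "deg/s", "T"),
    FeatureDef(
        "180° Turn—Trunk—Sagittal Mean Sway", "segmentation", ("chest",), "central", "deg", "T"
    ),
    # --- whole-assessment features ---------------------------------------
    FeatureDef("WT—Trunk—Difference of Coronal Sway", "whole", ("chest",), "central", "deg", "WT"),
    FeatureDef("Effective Trial Duration", "whole", ("shank", "waist"), "central", "s", "WT"),
    FeatureDef("180° Turn—Total Duration", "whole", ("waist",), "central", "s", "WT"),
]:
    register_feature(_f)


def _section_label(section: Section) -> str:
    return f"{section.kind}{section.ordinal}"


def section_labels() -> list[str]:
    return [f"SW{i}" for i in range(1, 7)] + [f"T{i}" for i in range(1, 7)]


def _stance_array(section: Section, section_events: list[ev.GaitEvent]) -> np.ndarray:
    """Boolean per-sample stance indicator for one side inside a section.

    The leg is in stance from IC to the next TC.  The state before the
    first event is inferred from that event's type (a TC implies the leg
    was in stance)."""
    n = section.n_samples
    stance = np.zeros(n, dtype=bool)
    evs = sorted(section_events, key=lambda e: e.sample)
    if not evs:
        return stance
    state = evs[0].type == ev.TC
    prev = section.start_sample
    for e in evs:
        stance[prev - section.start_sample : e.sample - section.start_sample] = state
        state = e.type == ev.IC
        prev = e.sample
    stance[prev - section.start_sample :] = state
    return stance


@dataclasses.dataclass
class SectionFeatures:
    """Per-section base feature values of one participant.

    ``matrix`` rows are base feature names (sided bases carry an
    `` L``/`` R`` suffix), columns SW1..SW6, T1..T6; NaN marks missing.
    ``whole`` maps whole-assessment feature names to values.
    """

    participant_id: str
    matrix: pd.DataFrame
    whole: dict[str, float]


def compute_cycle_features(
    recording: RawRecording,
    angles: AngleSeries,
    sections: list[Section],
    section_events: dict[tuple[str, str], list[ev.GaitEvent]],
    path_length_m: float = 3.6,
) -> dict[tuple[str, str], float]:
    """Cycle-based features, averaged over the cycles of each SW section.

    ``section_events`` maps (section label, side) to the gait events
    detected inside that section.  Returns {(feature, section label):
    value}; sections without cycles contribute nothing (logged).
    """
    fs = recording.fs
    out: dict[tuple[str, str], float] = {}
    for section in sections:
        if section.kind != "SW":
            continue
        label = _section_label(section)
        duration = section.duration_s(fs)
        evs = {side: section_events.get((label, side), []) for side in ("L", "R")}
        cycles = {side: ev.assemble_cycles(evs[side]) for side in ("L", "R")}
        n_steps = sum(1 for side in ("L", "R") for e in evs[side] if e.type == ev.IC)
        out[("Gait Speed", label)] = path_length_m / duration
        if n_steps:
            out[("Step Length", label)] = path_length_m / n_steps
        all_stride_times = [
            (c.ic_end - c.ic_start) / fs for side in ("L", "R") for c in cycles[side]
        ]
        if all_stride_times:
            # steps/min from cycle durations (2 steps per stride), immune to
            # partial strides at section edges
            out[("Cadence", label)] = 120.0 / float(np.mean(all_stride_times))
        stance = {side: _stance_array(section, evs[side]) for side in ("L", "R")}
        both = stance["L"] & stance["R"]
        trunk_rate = np.abs(recording.gyr("chest")[:, 1])
        trunk_vals = []
        for side in ("L", "R"):
            shank = recording.gyr(f"shank_{side.lower()}")[:, 1]
            side_cycles = cycles[side]
            if not side_cycles:
                logger.info("%s %s: no %s-side cycles", recording.participant_id, label, side)
                continue
            stride_t, ds, rom = [], [], []
            for c in side_cycles:
                stride_t.append((c.ic_end - c.ic_start) / fs)
                lo = c.ic_start - section.start_sample
                hi = c.ic_end - section.start_sample
                ds.append(100.0 * np.mean(both[lo:hi]))
                rom.append(np.sum(shank[c.tc : c.ic_end]) / fs)
                trunk_vals.append(np.max(trunk_rate[c.ic_start : c.ic_end]))
            out[(f"Stride Time {side}", label)] = float(np.mean(stride_t))
            out[(f"Double Support {side}", label)] = float(np.mean(ds))
            out[(f"Shank—Swing RoM {side}", label)] = float(np.mean(rom))
        if trunk_vals:
            out[("Trunk—Max Sagittal Angular Velocity", label)] = float(np.mean(trunk_vals))
    return out


def compute_segment_features(
    recording: RawRecording,
    angles: AngleSeries,
    sections: list[Section],
    section_events: dict[tuple[str, str], list[ev.GaitEvent]],
) -> dict[tuple[str, str], float]:
    """Per-section features that do not rely on gait-cycle assembly."""
    fs = recording.fs
    waist_sag = angles.sagittal("waist")
    chest_sag = angles.sagittal("chest")
    turn_rate = smoothed_rate(angles.heading("waist"), fs)
    out: dict[tuple[str, str], float] = {}
    for section in sections:
        label = _section_label(section)
        lo, hi = section.start_sample, section.end_sample
        if section.kind == "SW":
            out[("SW—Lumbar—Difference of Sagittal Sway", label)] = float(
                waist_sag[hi - 1] - waist_sag[lo]
            )
            out[("Straight-Walking Duration", label)] = section.duration_s(fs)
            out[("Trunk—Forward Sway Max", label)] = float(np.min(chest_sag[lo:hi]))
        else:
            out[("180° Turn—Duration", label)] = section.duration_s(fs)
            n_steps = sum(
                1
                for side in ("L", "R")
                for e in section_events.get((label, side), [])
                if e.type == ev.IC
            )
            out[("180° Turn—Steps", label)] = float(n_steps)
            out[("180° Turn—Max Angular Velocity", label)] = float(np.max(turn_rate[lo:hi]))
            out[("180° Turn—Mean Angular Velocity", label)] = float(np.mean(turn_rate[lo:hi]))
            out[("180° Turn—Trunk—Sagittal Mean Sway", label)] = float(np.mean(chest_sag[lo:hi]))
    return out


def compute_whole_features(
    recording: RawRecording, angles: AngleSeries, sections: list[Section]
) -> dict[str, float]:
    """Whole-assessment summary features."""
    fs = recording.fs
    ordered = sorted(sections, key=lambda s: s.start_sample)
    chest_cor = angles.coronal("chest")
    return {
        "WT—Trunk—Difference of Coronal Sway": float(
            chest_cor[ordered[-1].end_sample - 1] - chest_cor[ordered[0].start_sample]
        ),
        "Effective Trial Duration": float(sum(s.duration_s(fs) for s in sections)),
        "180° Turn—Total Duration": float(
            sum(s.duration_s(fs) for s in sections if s.kind == "T")
        ),
    }


def build_section_matrix(
    participant_id: str,
    cycle_vals: dict[tuple[str, str], float],
    segment_vals: dict[tuple[str, str], float],
    whole_vals: dict[str, float],
) -> SectionFeatures:
    """Assemble the participant's base-feature x section matrix."""
    combined = {**cycle_vals, **segment_vals}
    rows = sorted({k[0] for k in combined})
    matrix = pd.DataFrame(np.nan, index=rows, columns=section_labels())
    for (feat, label), value in combined.items():
        matrix.loc[feat, label] = value
    return SectionFeatures(participant_id, matrix, dict(whole_vals))


# ---------------------------------------------------------------------------
# two-step construction
# ---------------------------------------------------------------------------


def construct_step1(
    features: SectionFeatures,
    min_sections: int = 2,
    diff_mean_mode: str = "abs",
) -> dict[str, float]:
    """Per-base max/min/mean/diff_mean over the applicable sections.

    ``diff_mean_mode='abs'`` (default) averages absolute
    consecutive-section differences; ``'signed'`` averages raw differences
    (which telescopes to (last-first)/(n-1)).  Bases with fewer than
    ``min_sections`` non-missing sections yield no aggregates (logged).
    """
    if diff_mean_mode not in ("abs", "signed"):
        raise ValueError("diff_mean_mode must be 'abs' or 'signed'")
    out: dict[str, float] = {}
    for base, row in features.matrix.iterrows():
        values = row.dropna().to_numpy(dtype=float)
        if values.size < min_sections:
            logger.info(
                "%s: base %r has %d section values (<%d), aggregates skipped",
                features.participant_id, base, values.size, min_sections,
            )
            continue
        diffs = np.diff(values)
        if diff_mean_mode == "abs":
            diffs = np.abs(diffs)
        vmax, vmin = float(np.max(values)), float(np.min(values))
        out[f"{base}—max"] = vmax
        out[f"{base}—min"] = vmin
        # clamp: the float mean of identical values can drift below min by
        # one ulp, which would break the exact min <= mean <= max invariant
        out[f"{base}—mean"] = float(np.clip(np.mean(values), vmin, vmax))
        out[f"{base}—diff_mean"] = float(np.mean(diffs))
    return out


def _split_sided(step1_name: str) -> tuple[str, str, str] | None:
    """Split ``'Base L—agg'`` into (Base, side, agg); None for central names."""
    base, _, agg = step1_name.rpartition("—")
    if base.endswith(" L") or base.endswith(" R"):
        return base[:-2], base[-1], agg
    return None


def construct_step2(step1: dict[str, float], whole: dict[str, float] | None = None) -> dict[str, float]:
    """Collapse L/R pairs into (max)/(min)/(diff); pass central features through.

    Whole-assessment features (already one value per participant) are
    appended unchanged.  Pairs with one side missing are skipped (logged).
    """
    out: dict[str, float] = {}
    sided: dict[tuple[str, str], dict[str, float]] = {}
    for name, value in step1.items():
        parts = _split_sided(name)
        if parts is None:
            out[name] = value
        else:
            base, side, agg = parts
            sided.setdefault((base, agg), {})[side] = value
    for (base, agg), pair in sorted(sided.items()):
        if set(pair) != {"L", "R"}:
            logger.info("pair %r—%s: only side %s present, skipped", base, agg, list(pair))
            continue
        left, right = pair["L"], pair["R"]
        out[f"{base}—{agg} (max)"] = float(max(left, right))
        out[f"{base}—{agg} (min)"] = float(min(left, right))
        out[f"{base}—{agg} (diff)"] = float(abs(left - right))
    for name, value in (whole or {}).items():
        out[name] = value
    return out


def construct_feature_vector(features: SectionFeatures, **step1_kwargs) -> dict[str, float]:
    """Full two-step construction for one participant."""
    return construct_step2(construct_step1(features, **step1_kwargs), features.whole)


def base_of_constructed(name: str) -> str:
    """Base catalog feature behind a constructed feature name.

    ``'Shank—Swing RoM—mean (max)'`` -> ``'Shank—Swing RoM'``;
    whole-assessment names map to themselves.
    """
    if name in _REGISTRY:
        return name
    stem = name.split(" (")[0]
    base, _, agg = stem.rpartition("—")
    if agg in STEP1_AGGS and base:
        if base.endswith(" L") or base.endswith(" R"):
            base = base[:-2]
        if base in _REGISTRY:
            return base
    raise KeyError(f"constructed feature {name!r} has no registered base")


def sensors_of_constructed(name: str) -> tuple[str, ...]:
    return _REGISTRY[base_of_constructed(name)].sensors
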