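"""Synthetic shuttle-walk cohorts with ground-truth sections, gait events
and clinical item scores.

The generator emulates the standardized assessment this package analyses:
three consecutive shuttle-walk trials, each walking a 3.6 m path, turning
180 degrees, walking back and turning again, recorded by ten body-worn
IMUs at 100 Hz.  A participant is described by five latent severities in
[0, 1] — one per clinical gait/posture item (arising from chair, gait,
freezing of gait, postural stability, posture) — that drive the kinematic
targets monotonically:

* gait speed, cadence and shank swing range of motion fall with the gait
  severity;
* turn duration and turning step count rise with the freezing and
  postural-stability severities (freezing additionally inserts a
  low-amplitude, high-step-rate episode at turn initiation);
* turn angular velocity falls as turns lengthen;
* forward trunk tilt magnitude rises with the posture severity;
* trunk sagittal angular velocity falls with the chair severity.

Signal synthesis is kinematics-first: per-sensor angular trajectories are
composed from stride-periodic templates (whose swing peaks are flanked by
local minima at the ground-truth TC/IC instants), heading ramps for the
turns, and tilt oscillations; accelerometer channels are the gravity
projection of the tilt trajectories plus white noise.  Full rigid-body
consistency across segments is not attempted — the downstream pipeline
consumes only the signal properties listed above.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .events import GaitEvent
from .preprocess import GRAVITY, SENSOR_LAYOUT, RawRecording
from .segment import Section

ITEMS = ("item_3_9", "item_3_10", "item_3_11", "item_3_12", "item_3_13")

#: latent severity driving each clinical item score
ITEM_THETA = {
    "item_3_9": "theta_chair",
    "item_3_10": "theta_gait",
    "item_3_11": "theta_fog",
    "item_3_12": "theta_stability",
    "item_3_13": "theta_posture",
}

_STANCE_FRAC = 0.6  # phase fraction of a stride spent in stance
_C = 2.0 / math.pi  # mean of a half-sine lobe


@dataclasses.dataclass(frozen=True)
class SeverityProfile:
    """Latent clinical state of one participant.

    Thetas are severities in [0, 1]; a theta of 0 generates the kinematics
    of an unimpaired walker and 1 the most severe presentation the rating
    scale covers (item scores are ~ 4*theta plus rater noise).
    """

    theta_chair: float
    theta_gait: float
    theta_fog: float
    theta_stability: float
    theta_posture: float
    age: float = 63.0
    sex: str = "F"
    pd_duration: float = 6.5

    def __post_init__(self) -> None:
        for name in ITEM_THETA.values():
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not self.age > 0:
            raise ValueError("age must be positive")
        if self.pd_duration < 0:
            raise ValueError("pd_duration must be non-negative")
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")

    def theta(self, item: str) -> float:
        return getattr(self, ITEM_THETA[item])


@dataclasses.dataclass(frozen=True)
class ProtocolConfig:
    """Assessment protocol and sensor-noise settings."""

    path_length_m: float = 3.6
    n_trials: int = 3
    fs_hz: float = 100.0
    noise_sd_gyro: float = 1.0  # deg/s
    noise_sd_acc: float = 0.05  # m/s^2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.fs_hz < 20:
            raise ValueError("fs_hz < 20 Hz cannot represent stride dynamics")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.path_length_m <= 0:
            raise ValueError("path_length_m must be positive")
        if self.noise_sd_gyro < 0 or self.noise_sd_acc < 0:
            raise ValueError("noise SDs must be non-negative")


@dataclasses.dataclass
class GroundTruth:
    """Generator-side truth for one participant."""

    sections: list[Section]
    events: list[GaitEvent]
    item_scores: dict[str, int]
    subscale: int
    generator_params: dict[str, float]
    #: optional per-sensor (n, 3) [sagittal, coronal, heading] truth angles
    angle_truth: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.subscale != sum(self.item_scores.values()):
            raise ValueError("subscale must equal the sum of item scores")


def kinematic_targets(profile: SeverityProfile) -> dict[str, float]:
    """Deterministic kinematic targets implied by a severity profile.

    All monotone links stated in the module docstring live here; units are
    m/s, steps/min, deg, s and counts.
    """
    tc, tg = profile.theta_chair, profile.theta_gait
    tf, ts, tp = profile.theta_fog, profile.theta_stability, profile.theta_posture
    freeze_dur = 0.0 if tf <= 0.6 else 0.4 + 2.0 * (tf - 0.6)
    turn_ramp = 2.0 + 1.6 * ts + 1.2 * tf
    base_steps = 5.0 + 7.0 * tf + 3.0 * ts
    return {
        "gait_speed_mps": 1.25 - 0.80 * tg - 0.10 * ts,
        "cadence_spm": 112.0 - 30.0 * tg,
        "swing_rom_deg": 72.0 - 42.0 * tg,
        "turn_ramp_s": turn_ramp,
        "freeze_dur_s": freeze_dur,
        "turn_duration_s": turn_ramp + freeze_dur,
        "turn_steps": base_steps + 2.0 * freeze_dur / 0.45,
        "trunk_tilt_deg": -(2.0 + 16.0 * tp),
        "trunk_sag_av_deg_s": 28.0 - 14.0 * tc - 6.0 * tg,
        "asymmetry": 0.04,
    }


def assign_item_scores(
    profile: SeverityProfile, rater_noise_sd: float, seed: int
) -> dict[str, int]:
    """Ordinal 0-4 item scores: clip(round(4*theta + eps), 0, 4).

    ``eps ~ Normal(0, rater_noise_sd)`` models rater disagreement;
    deterministic given ``seed``.
    """
    if rater_noise_sd < 0:
        raise ValueError("rater_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, rater_noise_sd, size=len(ITEMS))
    return {
        item: int(np.clip(np.rint(4.0 * profile.theta(item) + e), 0, 4))
        for item, e in zip(ITEMS, eps)
    }


# ---------------------------------------------------------------------------
# stride-periodic shank template
# ---------------------------------------------------------------------------


def _stride_template_params(rom_deg: float, period_s: float) -> tuple[float, float, float]:
    """Swing amplitude A, dip depth D and stance plateau P (deg/s).

    The template has a positive half-sine swing lobe whose time integral
    equals ``rom_deg`` (the swing range of motion) and a negative stance
    lobe sized so the net rotation per stride is zero (the shank pitch
    oscillates instead of drifting); the minima at the stance/swing
    boundaries are the TC and IC instants.  Fixing the plateau at 35 % of
    the dip depth yields the closed forms below.
    """
    swing_frac = 1.0 - _STANCE_FRAC
    # stance balance: -D*sf + (D - 0.35 D)*c*sf = -rom/T
    depth = (rom_deg / period_s) / (_STANCE_FRAC * (1.0 - 0.65 * _C))
    plateau = 0.35 * depth
    # swing lobe: -D*wf + (A + D)*c*wf = rom/T
    amp = (rom_deg / period_s + depth * swing_frac) / (_C * swing_frac) - depth
    return amp, depth, plateau


def _stride_wave(
    n: int, fs: float, period_s: float, rom_deg: float, phase0: float
) -> tuple[np.ndarray, list[int], list[int]]:
    """Stride-periodic sagittal angular velocity plus TC/IC sample lists.

    ``phase0`` in stride units shifts the template (0.5 for the
    contralateral side).  Only complete swings — TC and IC both inside the
    segment — are rendered and reported; a swing the segment would cut off
    is replaced by the stance plateau so no half swing lobe (and no
    spurious swing peak) appears at a segment edge.
    """
    amp, depth, plateau = _stride_template_params(rom_deg, period_s)
    t = np.arange(n) / fs
    w = np.zeros(n)
    tcs, ics = [], []
    t_first = None
    t_last = 0.0
    k_lo = math.floor(phase0) - 1
    k_hi = math.ceil(phase0 + n / fs / period_s) + 1
    for k in range(k_lo, k_hi):
        t0 = (k - phase0) * period_s
        t1 = (k + 1.0 - phase0) * period_s
        s_ic = int(round(t1 * fs))
        if t0 < 0 or s_ic > n - 1:
            continue  # partial stride at a segment edge: not rendered
        mask = (t >= t0) & (t < t1)
        phi = (t[mask] - t0) / period_s
        w[mask] = np.where(
            phi < _STANCE_FRAC,
            -depth + (depth - plateau) * np.sin(np.pi * phi / _STANCE_FRAC),
            -depth
            + (amp + depth) * np.sin(np.pi * (phi - _STANCE_FRAC) / (1.0 - _STANCE_FRAC)),
        )
        tcs.append(int(round((k + _STANCE_FRAC - phase0) * period_s * fs)))
        ics.append(s_ic)
        if t_first is None:
            t_first = t0
        t_last = t1
    # fill edge gaps with a zero-net, sub-threshold wiggle so the walking
    # envelope stays active without creating detectable swing peaks
    gaps = [(0.0, t_first)] if t_first is not None else [(0.0, n / fs)]
    if t_first is not None:
        gaps.append((t_last, n / fs))
    for g0, g1 in gaps:
        dur = g1 - g0
        if dur * fs < 4:
            continue
        mask = (t >= g0) & (t < g1)
        w[mask] = 20.0 * np.sin(2.0 * np.pi * (t[mask] - g0) / dur)
    return w, tcs, ics


def _cos_ramp(n: int, delta: float) -> np.ndarray:
    """Raised-cosine ramp from 0 to ``delta`` over ``n`` samples."""
    u = np.linspace(0.0, 1.0, n, endpoint=False)
    return delta * 0.5 * (1.0 - np.cos(np.pi * u))


# ---------------------------------------------------------------------------
# participant simulation
# ---------------------------------------------------------------------------


def simulate_participant(
    profile: SeverityProfile,
    cfg: ProtocolConfig | None = None,
    participant_id: str = "p000",
    rater_noise_sd: float = 0.3,
    return_angle_truth: bool = False,
) -> tuple[RawRecording, GroundTruth]:
    """Generate one participant's 10-sensor recording and its ground truth.

    Deterministic given ``cfg.rng_seed``: the same profile, config and
    seed reproduce bit-identical recordings.  Each trial contributes a
    rest pad, SW, turn, SW, turn, rest pad; sections, TC/IC events, the
    kinematic targets actually used and the (noisy-rater) item scores are
    returned as :class:`GroundTruth`.
    """
    cfg = cfg or ProtocolConfig()
    fs = cfg.fs_hz
    rng = np.random.default_rng(cfg.rng_seed)
    tg = kinematic_targets(profile)

    pad_n = int(round(0.7 * fs))
    sw_n = int(round(cfg.path_length_m / tg["gait_speed_mps"] * fs))
    ramp_n = int(round(tg["turn_ramp_s"] * fs))
    freeze_n = int(round(tg["freeze_dur_s"] * fs))
    stride_s = 2.0 * 60.0 / tg["cadence_spm"]

    # --- timeline ---------------------------------------------------------
    # segments: (kind, n_samples, turn_id, heading_delta_deg); a freezing
    # episode splits a turn into ramp / heading-hold / ramp, all part of the
    # same turn section
    segments: list[tuple[str, int, int | None, float]] = []
    turn_id = 0
    for _ in range(cfg.n_trials):
        segments.append(("rest", pad_n, None, 0.0))
        for _half in range(2):
            segments.append(("sw", sw_n, None, 0.0))
            if freeze_n:
                h = ramp_n // 2
                segments.append(("ramp", h, turn_id, 90.0))
                segments.append(("freeze", freeze_n, turn_id, 0.0))
                segments.append(("ramp", ramp_n - h, turn_id, 90.0))
            else:
                segments.append(("ramp", ramp_n, turn_id, 180.0))
            turn_id += 1
        segments.append(("rest", pad_n, None, 0.0))
    n_total = sum(seg[1] for seg in segments)
    t = np.arange(n_total) / fs

    # --- per-segment shank waves, heading and ground truth ---------------
    shank = {"L": np.zeros(n_total), "R": np.zeros(n_total)}
    heading = np.zeros(n_total)
    sections: list[Section] = []
    events: list[GaitEvent] = []
    asym = tg["asymmetry"]
    rom_side = {"L": tg["swing_rom_deg"] * (1 - asym), "R": tg["swing_rom_deg"] * (1 + asym)}

    n_side_turn = max(1, round((5.0 + 7.0 * profile.theta_fog + 3.0 * profile.theta_stability) / 2.0))
    # slightly shorter than ramp/n so the n-th IC of each side still falls
    # inside the ramp segment (strides are only rendered when complete)
    turn_period = tg["turn_ramp_s"] / (n_side_turn + 0.15)

    def _emit(side: str, base: int, tcs: list[int], ics: list[int]) -> None:
        events.extend(GaitEvent(side, "TC", base + s, (base + s) / fs) for s in tcs)
        events.extend(GaitEvent(side, "IC", base + s, (base + s) / fs) for s in ics)

    pos = 0
    heading_level = 0.0
    turn_bounds: dict[int, list[int]] = {}
    for kind, n_seg, tid, delta in segments:
        sl = slice(pos, pos + n_seg)
        if kind == "rest":
            heading[sl] = heading_level
        elif kind == "sw":
            heading[sl] = heading_level
            for side in ("L", "R"):
                w, tcs, ics = _stride_wave(
                    n_seg, fs, stride_s, rom_side[side], 0.0 if side == "R" else 0.5
                )
                shank[side][sl] = w
                _emit(side, pos, tcs, ics)
            sections.append(Section(participant_id, 0, "SW", 0, pos, pos + n_seg))
        elif kind == "freeze":
            heading[sl] = heading_level
            for side in ("L", "R"):
                w, tcs, ics = _stride_wave(n_seg, fs, 0.45, 5.0, 0.0 if side == "R" else 0.5)
                shank[side][sl] = w
                _emit(side, pos, tcs, ics)
        elif kind == "ramp":
            heading[sl] = heading_level + _cos_ramp(n_seg, delta)
            heading_level += delta
            for side in ("L", "R"):
                w, tcs, ics = _stride_wave(
                    n_seg, fs, turn_period, 18.0, 0.0 if side == "R" else 0.5
                )
                shank[side][sl] = w
                _emit(side, pos, tcs, ics)
        if tid is not None:
            lo, hi_ = turn_bounds.setdefault(tid, [pos, pos + n_seg])
            turn_bounds[tid] = [min(lo, pos), max(hi_, pos + n_seg)]
        pos += n_seg
    for tid in sorted(turn_bounds):
        lo, hi_ = turn_bounds[tid]
        sections.append(Section(participant_id, 0, "T", 0, lo, hi_))

    # trials and ordinals: 4 sections per trial, chronological
    counters = {"SW": 0, "T": 0}
    final_sections = []
    for i, s in enumerate(sorted(sections, key=lambda s: s.start_sample)):
        counters[s.kind] += 1
        final_sections.append(
            dataclasses.replace(s, trial=i // 4 + 1, ordinal=counters[s.kind])
        )
    sections = final_sections
    events.sort(key=lambda e: (e.sample, e.side, e.type))
    turn_spans = [(s.start_sample, s.end_sample) for s in sections if s.kind == "T"]
    tg["turn_steps_realized"] = sum(
        1
        for e in events
        if e.type == "IC" and any(lo <= e.sample < hi for lo, hi in turn_spans)
    ) / len(turn_spans)

    # --- walking envelope and step clock ----------------------------------
    walking = np.zeros(n_total, dtype=bool)
    for s in sections:
        walking[s.start_sample : s.end_sample] = True
    f_step = tg["cadence_spm"] / 60.0
    step_phase = 2.0 * np.pi * f_step * t

    # --- trunk / pelvis / arm angle trajectories ---------------------------
    osc_amp = tg["trunk_sag_av_deg_s"] / (2.0 * np.pi * f_step)
    slow = 1.2 * np.sin(2.0 * np.pi * t / 20.0)
    chest_sag = (
        tg["trunk_tilt_deg"]
        + slow
        + np.where(walking, osc_amp, 0.2) * np.sin(step_phase)
    )
    waist_sag = 0.6 * tg["trunk_tilt_deg"] + 0.8 * slow + np.where(
        walking, 0.8 * osc_amp, 0.1
    ) * np.sin(step_phase + 0.6)
    cor_amp = 0.8 + 1.2 * profile.theta_stability
    chest_cor = cor_amp * np.sin(2.0 * np.pi * 1.3 * t / t[-1] + 0.4)
    waist_cor = 0.5 * chest_cor
    arm_amp = 12.0 * (1.0 - 0.5 * profile.theta_gait)
    wrist_l_sag = np.where(walking, arm_amp, 0.0) * np.sin(0.5 * step_phase)
    wrist_r_sag = -wrist_l_sag

    dt = 1.0 / fs

    def _integrate(rate: np.ndarray, init: float = 0.0) -> np.ndarray:
        out = np.concatenate([[0.0], np.cumsum((rate[1:] + rate[:-1]) * 0.5 * dt)])
        return init + out

    def _rate(angle: np.ndarray) -> np.ndarray:
        return np.gradient(angle) * fs

    head_rate = _rate(heading)

    def _sensor_block(sag: np.ndarray, cor: np.ndarray, sag_rate=None) -> np.ndarray:
        sag_rate = _rate(sag) if sag_rate is None else sag_rate
        cor_rate = _rate(cor)
        sag_r, cor_r = np.radians(sag), np.radians(cor)
        acc = np.column_stack(
            [
                GRAVITY * np.sin(cor_r),
                -GRAVITY * np.sin(sag_r) * np.cos(cor_r),
                GRAVITY * np.cos(sag_r) * np.cos(cor_r),
            ]
        )
        gyr = np.column_stack([cor_rate, sag_rate, head_rate])
        return np.column_stack([acc, gyr])

    zeros = np.zeros(n_total)
    truth_angles: dict[str, tuple[np.ndarray, np.ndarray]] = {
        "chest": (chest_sag, chest_cor),
        "waist": (waist_sag, waist_cor),
        "wrist_l": (wrist_l_sag, zeros),
        "wrist_r": (wrist_r_sag, zeros),
    }
    leg_rates: dict[str, np.ndarray] = {}
    for side in ("L", "R"):
        suffix = side.lower()
        for sensor, scale in ((f"shank_{suffix}", 1.0), (f"thigh_{suffix}", 0.45), (f"foot_{suffix}", 1.15)):
            rate = scale * shank[side]
            truth_angles[sensor] = (_integrate(rate), zeros)
            leg_rates[sensor] = rate
    data: dict[str, np.ndarray] = {
        sensor: _sensor_block(sag, cor, sag_rate=leg_rates.get(sensor))
        for sensor, (sag, cor) in truth_angles.items()
    }

    if cfg.noise_sd_acc > 0 or cfg.noise_sd_gyro > 0:
        for sensor in SENSOR_LAYOUT:
            block = data[sensor]
            block[:, :3] += rng.normal(0.0, cfg.noise_sd_acc, size=(n_total, 3))
            block[:, 3:] += rng.normal(0.0, cfg.noise_sd_gyro, size=(n_total, 3))

    recording = RawRecording(participant_id, fs, data)

    scores = assign_item_scores(profile, rater_noise_sd, seed=int(cfg.rng_seed) + 1)
    angle_truth = None
    if return_angle_truth:
        angle_truth = {
            sensor: np.column_stack([sag, cor, heading])
            for sensor, (sag, cor) in truth_angles.items()
        }
    truth = GroundTruth(
        sections=sections,
        events=events,
        item_scores=scores,
        subscale=sum(scores.values()),
        generator_params=dict(tg),
        angle_truth=angle_truth,
    )
    return recording, truth


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def default_profile_sampler(rng: np.random.Generator) -> SeverityProfile:
    """Draw one participant's severity profile from the default cohort mix.

    Severities share a common axial-severity factor plus item-specific
    variation, both beta-distributed and skewed toward the mild end so
    high item scores are rare, mirroring clinic score histograms.
    """
    shared = rng.beta(1.2, 2.5)
    own = rng.beta(1.2, 3.0, size=5)
    thetas = np.clip(0.55 * shared + 0.55 * own, 0.0, 1.0)
    return SeverityProfile(
        theta_chair=float(thetas[0]),
        theta_gait=float(thetas[1]),
        theta_fog=float(thetas[2]),
        theta_stability=float(thetas[3]),
        theta_posture=float(thetas[4]),
        age=float(np.clip(rng.normal(63.0, 10.5), 35.0, 90.0)),
        sex="F" if rng.random() < 0.47 else "M",
        pd_duration=float(np.clip(rng.gamma(2.4, 2.7), 0.2, 25.0)),
    )


@dataclasses.dataclass
class Cohort:
    """A simulated cohort: labels table plus per-participant ground truth.

    ``labels`` has one row per participant with the columns of the labels
    CSV dialect (participant, the five item scores, age, sex,
    pd_duration).  ``recordings`` is populated only when requested — raw
    streams for large cohorts are better re-generated on the fly from
    the per-participant seeds in ``participant_seeds``.
    """

    labels: pd.DataFrame
    truths: dict[str, GroundTruth]
    profiles: dict[str, SeverityProfile]
    participant_seeds: dict[str, int]
    cfg: ProtocolConfig
    rater_noise_sd: float
    recordings: dict[str, RawRecording] | None = None

    @property
    def n(self) -> int:
        return len(self.labels)

    def participant_config(self, participant_id: str) -> ProtocolConfig:
        return dataclasses.replace(self.cfg, rng_seed=self.participant_seeds[participant_id])

    def regenerate_recording(self, participant_id: str) -> tuple[RawRecording, GroundTruth]:
        return simulate_participant(
            self.profiles[participant_id],
            self.participant_config(participant_id),
            participant_id=participant_id,
            rater_noise_sd=self.rater_noise_sd,
        )


def cohort_participant_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-participant simulation seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31 - 1)]


def simulate_cohort(
    n: int,
    cfg: ProtocolConfig | None = None,
    seed: int = 0,
    profile_sampler=None,
    rater_noise_sd: float = 0.3,
    keep_recordings: bool = False,
) -> Cohort:
    """Simulate ``n`` independent participants.

    Profiles are drawn from ``profile_sampler`` (default:
    :func:`default_profile_sampler`); per-participant simulation seeds are
    derived deterministically from ``seed``.  With
    ``keep_recordings=False`` only labels and ground truth are retained
    and raw streams can be re-generated per participant on demand.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = cfg or ProtocolConfig()
    sampler = profile_sampler or default_profile_sampler
    rng = np.random.default_rng(seed)
    seeds = cohort_participant_seeds(seed, n)
    rows = []
    truths: dict[str, GroundTruth] = {}
    profiles: dict[str, SeverityProfile] = {}
    seed_map: dict[str, int] = {}
    recordings: dict[str, RawRecording] = {}
    for i in range(n):
        pid = f"p{i:04d}"
        profile = sampler(rng)
        pcfg = dataclasses.replace(cfg, rng_seed=seeds[i])
        scores = assign_item_scores(profile, rater_noise_sd, seed=seeds[i] + 1)
        profiles[pid] = profile
        seed_map[pid] = seeds[i]
        if keep_recordings:
            rec, truth = simulate_participant(
                profile, pcfg, participant_id=pid, rater_noise_sd=rater_noise_sd
            )
            recordings[pid] = rec
            truths[pid] = truth
            scores = truth.item_scores
        rows.append(
            {
                "participant": pid,
                **scores,
                "age": profile.age,
                "sex": profile.sex,
                "pd_duration": profile.pd_duration,
            }
        )
    labels = pd.DataFrame(rows)
    return Cohort(
        labels=labels,
        truths=truths,
        profiles=profiles,
        participant_seeds=seed_map,
        cfg=cfg,
        rater_noise_sd=rater_noise_sd,
        recordings=recordings if keep_recordings else None,
    )
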