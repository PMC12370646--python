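"""Shared fixtures: small synthetic recordings and session-scoped cohorts.

The expensive artifacts (noise-free 20-participant cohort for the
segmentation/event recovery checks, the n=200 recovery experiment, the
monotonicity cohort) are computed once per session.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from gaitbench import events as ev
from gaitbench.pipeline import REDUCED_SEARCH, extract_participant, run_experiment
from gaitbench.preprocess import detrend_heading, estimate_orientation, lowpass
from gaitbench.segment import match_to_ground_truth, segment_recording
from gaitbench.synth import (
    ProtocolConfig,
    SeverityProfile,
    default_profile_sampler,
    simulate_participant,
)

NOISE_FREE = ProtocolConfig(noise_sd_gyro=0.0, noise_sd_acc=0.0)


@pytest.fixture(scope="session")
def mid_participant():
    """One mid-severity participant with default sensor noise."""
    profile = SeverityProfile(0.4, 0.5, 0.3, 0.4, 0.6)
    cfg = ProtocolConfig(rng_seed=11)
    rec, truth = simulate_participant(profile, cfg, "p_mid", return_angle_truth=True)
    return rec, truth


def analyse_participant(rec, truth):
    """Segment + detect events for one participant; return error stats."""
    filt = lowpass(rec)
    ang = estimate_orientation(filt)
    heading = detrend_heading(ang.heading("waist"))
    energy = np.abs(filt.gyr("shank_l")[:, 1]) + np.abs(filt.gyr("shank_r")[:, 1])
    sections = segment_recording(heading, energy, rec.fs, rec.participant_id)
    report = match_to_ground_truth(sections, truth.sections, rec.fs)
    event_errors = []
    cycle_counts = []
    for side, sensor in (("L", "shank_l"), ("R", "shank_r")):
        sig = filt.gyr(sensor)[:, 1]
        truth_ev = [(e.type, e.sample) for e in truth.events if e.side == side]
        for s in [x for x in sections if x.kind == "SW"]:
            detected = ev.detect_section_events(sig, rec.fs, s, side)
            for det in detected:
                err = min(
                    abs(det.sample - ts) for tt, ts in truth_ev if tt == det.type
                )
                event_errors.append(err / rec.fs)
            n_truth_ic = sum(
                1
                for e in truth.events
                if e.side == side
                and e.type == "IC"
                and s.start_sample <= e.sample < s.end_sample
            )
            cycles = ev.assemble_cycles(detected)
            # strides = consecutive IC pairs; ground truth has n_ic ICs
            cycle_counts.append((len(cycles), max(n_truth_ic - 1, 0)))
    return {
        "sections": sections,
        "boundary_report": report,
        "event_errors_s": np.asarray(event_errors),
        "cycle_counts": cycle_counts,
    }


@pytest.fixture(scope="session")
def noise_free_cohort():
    """20 noise-free participants (default severity mix) fully analysed."""
    rng = np.random.default_rng(2024)
    out = []
    for i in range(20):
        profile = default_profile_sampler(rng)
        cfg = dataclasses.replace(NOISE_FREE, rng_seed=9000 + i)
        rec, truth = simulate_participant(profile, cfg, f"nf{i:02d}")
        res = analyse_participant(rec, truth)
        res["truth"] = truth
        res["vector"] = extract_participant(rec).vector
        out.append(res)
    return out


@pytest.fixture(scope="session")
def mono_features():
    """Feature table of a noise-free cohort sweeping one severity per axis.

    theta_gait rises over participants while theta_fog follows an
    independent (shuffled) sweep, so the monotone links of both drivers
    can be checked from a single extraction pass.
    """
    n = 24
    rng = np.random.default_rng(7)
    gait = np.linspace(0.0, 1.0, n)
    fog = rng.permutation(np.linspace(0.0, 1.0, n))
    rows = []
    for i in range(n):
        profile = SeverityProfile(0.2, float(gait[i]), float(fog[i]), 0.2, 0.2)
        cfg = dataclasses.replace(NOISE_FREE, rng_seed=500 + i)
        rec, truth = simulate_participant(profile, cfg, f"m{i:02d}")
        vec = extract_participant(rec).vector
        rows.append((gait[i], fog[i], vec, truth))
    return rows


@pytest.fixture(scope="session")
def experiment200():
    """The synthetic-recovery benchmark: n=200 cohort, rater noise SD 0.3,
    reduced top-K sweep {5, 15, 25}."""
    return run_experiment(n=200, seed=1, search=REDUCED_SEARCH, rater_noise_sd=0.3)
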