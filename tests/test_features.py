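"""Feature computation and two-step construction: arithmetic examples,
naming conventions, invariants on random tables, and the monotone
severity links measured end to end."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gaitbench.events import GaitEvent
from gaitbench.features import (
    FeatureDef,
    SectionFeatures,
    base_of_constructed,
    compute_segment_features,
    compute_whole_features,
    construct_feature_vector,
    construct_step1,
    construct_step2,
    feature_registry,
    register_feature,
    section_labels,
    sensors_of_constructed,
)
from gaitbench.preprocess import AngleSeries, SENSOR_LAYOUT
from gaitbench.segment import Section

FS = 100.0


def make_features(rows: dict, whole=None) -> SectionFeatures:
    matrix = pd.DataFrame(np.nan, index=list(rows), columns=section_labels())
    for base, values in rows.items():
        cols = [c for c in section_labels() if c.startswith("SW")][: len(values)]
        matrix.loc[base, cols] = values
    return SectionFeatures("p", matrix, whole or {})


class TestStep1:
    def test_four_aggregates_arithmetic(self):
        out = construct_step1(make_features({"Gait Speed L": [1, 2, 3, 4, 5, 6]}))
        assert out == {
            "Gait Speed L—max": 6.0,
            "Gait Speed L—min": 1.0,
            "Gait Speed L—mean": 3.5,
            "Gait Speed L—diff_mean": 1.0,
        }

    def test_constant_sections(self):
        out = construct_step1(make_features({"Cadence": [7.0] * 6}))
        assert out["Cadence—max"] == out["Cadence—min"] == out["Cadence—mean"] == 7.0
        assert out["Cadence—diff_mean"] == 0.0

    def test_signed_diff_mean_telescopes(self):
        values = [1.0, 5.0, 2.0, 8.0]
        out = construct_step1(make_features({"X": values}), diff_mean_mode="signed")
        assert out["X—diff_mean"] == pytest.approx((values[-1] - values[0]) / 3)

    def test_single_section_skipped(self):
        out = construct_step1(make_features({"X": [1.0]}))
        assert out == {}

    def test_missing_sections_excluded(self):
        feats = make_features({"X": [1.0, np.nan, 3.0, np.nan, np.nan, np.nan]})
        out = construct_step1(feats)
        assert out["X—mean"] == 2.0

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            construct_step1(make_features({"X": [1, 2]}), diff_mean_mode="median")


class TestStep2:
    def test_pair_collapse_values_and_names(self):
        step1 = {"Gait Speed L—mean": 10.0, "Gait Speed R—mean": 12.0}
        out = construct_step2(step1)
        assert out == {
            "Gait Speed—mean (max)": 12.0,
            "Gait Speed—mean (min)": 10.0,
            "Gait Speed—mean (diff)": 2.0,
        }

    def test_one_bilateral_base_yields_12_constructed_from_8(self):
        feats = make_features(
            {"Swing L": [1, 2, 3, 4, 5, 6], "Swing R": [2, 3, 4, 5, 6, 7]}
        )
        step1 = construct_step1(feats)
        assert len(step1) == 8
        out = construct_step2(step1)
        assert len(out) == 12

    def test_central_features_pass_through(self):
        out = construct_step2({"Cadence—mean": 100.0})
        assert out == {"Cadence—mean": 100.0}

    def test_one_sided_pair_skipped(self):
        out = construct_step2({"Swing L—mean": 1.0, "Cadence—mean": 2.0})
        assert out == {"Cadence—mean": 2.0}

    def test_whole_features_appended_unchanged(self):
        out = construct_step2({}, whole={"Effective Trial Duration": 36.0})
        assert out == {"Effective Trial Duration": 36.0}


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(
        st.floats(min_value=-100, max_value=100, allow_nan=False), min_size=2, max_size=6
    ),
    st.lists(
        st.floats(min_value=-100, max_value=100, allow_nan=False), min_size=2, max_size=6
    ),
)
def test_construction_invariants_on_random_tables(left, right):
    n = min(len(left), len(right))
    feats = make_features({"F L": left[:n], "F R": right[:n]})
    step1 = construct_step1(feats)
    for agg in ("max", "min", "mean", "diff_mean"):
        for side in ("L", "R"):
            assert f"F {side}—{agg}" in step1
    for side in ("L", "R"):
        assert step1[f"F {side}—min"] <= step1[f"F {side}—mean"] <= step1[f"F {side}—max"]
        assert step1[f"F {side}—diff_mean"] >= 0
    out = construct_step2(step1)
    for agg in ("max", "min", "mean", "diff_mean"):
        mx, mn, df = (out[f"F—{agg} ({x})"] for x in ("max", "min", "diff"))
        assert df == pytest.approx(mx - mn)
        assert df == pytest.approx(abs(step1[f"F L—{agg}"] - step1[f"F R—{agg}"]))


class TestSegmentAndWholeFeatures:
    def make_turn_setup(self):
        """One 2 s turn with a sigmoid 180-degree heading ramp."""
        n = 600
        heading = np.zeros(n)
        u = np.linspace(0, 1, 200, endpoint=False)
        heading[200:400] = 180 * 0.5 * (1 - np.cos(np.pi * u))
        heading[400:] = 180.0
        angles = AngleSeries(
            "p", FS, {s: np.column_stack([np.zeros(n), np.zeros(n), heading]) for s in SENSOR_LAYOUT}
        )
        section = Section("p", 1, "T", 1, 200, 400)
        recording = SimpleNamespace(fs=FS)
        events = {
            ("T1", "L"): [GaitEvent("L", "IC", 210 + 40 * i, 0.0) for i in range(4)],
            ("T1", "R"): [GaitEvent("R", "IC", 230 + 40 * i, 0.0) for i in range(4)],
        }
        return recording, angles, [section], events

    def test_turn_duration_steps_and_angular_velocity(self):
        rec, angles, sections, events = self.make_turn_setup()
        out = compute_segment_features(rec, angles, sections, events)
        assert out[("180° Turn—Duration", "T1")] == pytest.approx(2.0)
        assert out[("180° Turn—Steps", "T1")] == 8
        mean_av = out[("180° Turn—Mean Angular Velocity", "T1")]
        max_av = out[("180° Turn—Max Angular Velocity", "T1")]
        assert mean_av == pytest.approx(90.0, abs=2.0)
        assert max_av > mean_av

    def test_whole_assessment_sums(self):
        n = 4000
        angles = AngleSeries(
            "p", FS, {s: np.zeros((n, 3)) for s in SENSOR_LAYOUT}
        )
        sections = []
        for i in range(6):
            sections.append(Section("p", i // 2 + 1, "SW", i + 1, 600 * i, 600 * i + 300))
            sections.append(Section("p", i // 2 + 1, "T", i + 1, 600 * i + 300, 600 * i + 600))
        out = compute_whole_features(SimpleNamespace(fs=FS), angles, sections)
        assert out["Effective Trial Duration"] == pytest.approx(36.0)
        assert out["180° Turn—Total Duration"] == pytest.approx(18.0)
        assert out["WT—Trunk—Difference of Coronal Sway"] == 0.0


class TestRegistry:
    def test_catalog_covers_named_base_parameters(self):
        reg = feature_registry()
        for base in (
            "Gait Speed",
            "Cadence",
            "Step Length",
            "Double Support",
            "Shank—Swing RoM",
            "Trunk—Max Sagittal Angular Velocity",
            "SW—Lumbar—Difference of Sagittal Sway",
            "Straight-Walking Duration",
            "180° Turn—Duration",
            "180° Turn—Steps",
            "180° Turn—Max Angular Velocity",
            "180° Turn—Mean Angular Velocity",
            "180° Turn—Trunk—Sagittal Mean Sway",
            "Trunk—Forward Sway Max",
            "WT—Trunk—Difference of Coronal Sway",
            "Effective Trial Duration",
            "180° Turn—Total Duration",
        ):
            assert base in reg, base

    def test_constructed_name_maps_back_to_base(self):
        assert base_of_constructed("Shank—Swing RoM—mean (max)") == "Shank—Swing RoM"
        assert base_of_constructed("Cadence—diff_mean") == "Cadence"
        assert base_of_constructed("Effective Trial Duration") == "Effective Trial Duration"
        assert sensors_of_constructed("Effective Trial Duration") == ("shank", "waist")

    def test_unregistered_constructed_name_raises(self):
        with pytest.raises(KeyError):
            base_of_constructed("Totally Unknown—mean (max)")

    def test_extension_registration(self):
        fdef = FeatureDef("Arm—Swing RoM", "cycle_based", ("hand",), "bilateral", "deg", "SW")
        register_feature(fdef)
        try:
            assert base_of_constructed("Arm—Swing RoM—mean (diff)") == "Arm—Swing RoM"
        finally:
            feature_registry()  # registry is module-level; leave entry in place

    def test_cycle_features_must_reference_straight_walks(self):
        with pytest.raises(ValueError):
            FeatureDef("Bad", "cycle_based", ("shank",), "central", "x", "T")


@pytest.fixture(scope="module")
def truth_driven_cycle_features():
    """Cycle features computed on ground-truth sections and events.

    Separates the feature formulas from detection bias: durations and
    event times are the generator's own, so the values must hit the
    kinematic targets almost exactly.
    """
    import dataclasses

    from gaitbench.features import compute_cycle_features
    from gaitbench.preprocess import estimate_orientation, lowpass
    from gaitbench.synth import ProtocolConfig, SeverityProfile, simulate_participant

    out = []
    for i, thetas in enumerate([(0.1,) * 5, (0.45,) * 5, (0.8,) * 5]):
        cfg = ProtocolConfig(rng_seed=300 + i, noise_sd_gyro=0.0, noise_sd_acc=0.0)
        rec, truth = simulate_participant(SeverityProfile(*thetas), cfg, f"td{i}")
        filt = lowpass(rec)
        angles = estimate_orientation(filt)
        events = {}
        for s in truth.sections:
            label = f"{s.kind}{s.ordinal}"
            for side in ("L", "R"):
                events[(label, side)] = [
                    e
                    for e in truth.events
                    if e.side == side and s.start_sample <= e.sample < s.end_sample
                ]
        vals = compute_cycle_features(filt, angles, truth.sections, events)
        out.append((truth, vals))
    return out


class TestCycleFeatureOracles:
    def test_gait_speed_within_5pct_of_target(self, truth_driven_cycle_features):
        for truth, vals in truth_driven_cycle_features:
            target = truth.generator_params["gait_speed_mps"]
            speeds = [v for (f, _), v in vals.items() if f == "Gait Speed"]
            assert len(speeds) == 6
            for got in speeds:
                assert abs(got - target) / target < 0.05

    def test_double_support_is_constructed_20pct(self, truth_driven_cycle_features):
        for _, vals in truth_driven_cycle_features:
            ds = [v for (f, _), v in vals.items() if f.startswith("Double Support")]
            assert ds
            for got in ds:
                assert got == pytest.approx(20.0, abs=2.0)

    def test_swing_rom_matches_target(self, truth_driven_cycle_features):
        for truth, vals in truth_driven_cycle_features:
            target = truth.generator_params["swing_rom_deg"]
            roms = [v for (f, _), v in vals.items() if f.startswith("Shank—Swing RoM")]
            for got in roms:
                assert abs(got - target) / target < 0.10

    def test_cadence_matches_target(self, truth_driven_cycle_features):
        for truth, vals in truth_driven_cycle_features:
            target = truth.generator_params["cadence_spm"]
            cadences = [v for (f, _), v in vals.items() if f == "Cadence"]
            for got in cadences:
                assert abs(got - target) / target < 0.15  # edge strides not rendered


class TestEndToEndFeatureAccuracy:
    def test_gait_speed_tracks_target_through_detection(self, noise_free_cohort):
        # detected section boundaries blur the turn edges slightly, so the
        # tolerance is wider than for the truth-driven oracle above
        for res in noise_free_cohort:
            target = res["truth"].generator_params["gait_speed_mps"]
            got = res["vector"]["Gait Speed—mean"]
            assert abs(got - target) / target < 0.10

    def test_double_support_near_constructed_20pct(self, noise_free_cohort):
        for res in noise_free_cohort:
            got = res["vector"]["Double Support—mean (max)"]
            assert got == pytest.approx(20.0, abs=6.0)

    def test_turn_steps_near_generated_count(self, noise_free_cohort):
        for res in noise_free_cohort:
            target = res["truth"].generator_params["turn_steps_realized"]
            got = res["vector"]["180° Turn—Steps—mean"]
            assert abs(got - target) <= 2.0

    def test_forward_sway_tracks_trunk_tilt(self, noise_free_cohort):
        for res in noise_free_cohort:
            tilt = res["truth"].generator_params["trunk_tilt_deg"]
            got = res["vector"]["Trunk—Forward Sway Max—min"]
            assert got < 0
            assert abs(got - tilt) < 8.0  # oscillation + sway ride on the base tilt

    def test_min_mean_max_ordering_everywhere(self, noise_free_cohort):
        for res in noise_free_cohort:
            vec = res["vector"]
            bases = {n.rsplit("—", 1)[0] for n in vec if n.endswith("—mean")}
            for b in bases:
                if f"{b}—min" in vec and f"{b}—max" in vec:
                    assert vec[f"{b}—min"] <= vec[f"{b}—mean"] <= vec[f"{b}—max"]


class TestMonotoneSeverityLinks:
    def test_speed_and_swing_rom_fall_with_gait_severity(self, mono_features):
        gait = [g for g, _, _, _ in mono_features]
        speed = [v["Gait Speed—mean"] for _, _, v, _ in mono_features]
        rom = [v["Shank—Swing RoM—mean (max)"] for _, _, v, _ in mono_features]
        assert stats.spearmanr(gait, speed).statistic <= -0.9
        assert stats.spearmanr(gait, rom).statistic <= -0.9

    def test_turn_steps_rise_with_freezing_severity(self, mono_features):
        fog = [f for _, f, _, _ in mono_features]
        steps = [v["180° Turn—Steps—mean"] for _, _, v, _ in mono_features]
        assert stats.spearmanr(fog, steps).statistic >= 0.9
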