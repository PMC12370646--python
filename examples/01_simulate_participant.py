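"""Simulate one shuttle-walk assessment and inspect its ground truth.

A participant is described by five latent severities in [0, 1], one per
clinical gait/posture item.  The generator turns them into a 10-sensor
IMU recording (3 trials of walk / 180-degree turn / walk / turn at 100
Hz) plus the ground-truth sections, gait events and item scores.
"""

from gaitbench import ProtocolConfig, SeverityProfile, simulate_participant

profile = SeverityProfile(
    theta_chair=0.3,
    theta_gait=0.6,      # slow gait, reduced shank swing
    theta_fog=0.7,       # freezing: extra steps and a pause inside turns
    theta_stability=0.4,
    theta_posture=0.5,   # stooped posture: forward trunk lean
)
recording, truth = simulate_participant(profile, ProtocolConfig(rng_seed=42), "demo")

print(f"recording: {recording.n_samples} samples x 10 sensors at {recording.fs:.0f} Hz "
      f"({recording.duration_s:.1f} s)")
print(f"sections:  {len(truth.sections)} "
      f"({sum(s.kind == 'SW' for s in truth.sections)} straight walks, "
      f"{sum(s.kind == 'T' for s in truth.sections)} turns)")
print(f"events:    {len(truth.events)} ground-truth IC/TC instants")
print("item scores (0-4):", truth.item_scores, "-> subscale", truth.subscale)
print("kinematic targets used by the generator:")
for key, value in truth.generator_params.items():
    print(f"  {key:24s} {value:8.3f}")
# The targets are monotone in the severities: higher theta_gait means lower
# gait_speed_mps and swing_rom_deg; higher theta_fog means more turn_steps
# and a longer turn_duration_s (here including a freezing episode).
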