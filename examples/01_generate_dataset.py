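"""Generate one synthetic subject's reaching dataset and inspect it.

Builds the 20-condition factorial (5 directions x 2 amplitudes x 2 cycle
frequencies, 10 cycles each) plus the four natural-transition trials,
runs the planar-arm pipeline (minimum-jerk endpoint -> inverse kinematics
-> inverse dynamics -> static optimisation) and prints what came out.
"""

import numpy as np

from informrc import generate_dataset

ds = generate_dataset(seed=42)

print(f"main trials: {len(ds.trials)}, natural-transition trials: {len(ds.natural)}")
print(f"selected muscles (of {ds.arm.n_muscles} candidates): {ds.selection}")

trial = ds.trials["C2@1Hz"]  # straight ahead, 40 cm, 1.0 Hz
print(f"\ntrial C2@1Hz: {trial.n_samples} samples at {trial.fs:g} Hz, "
      f"{trial.n_cycles} cycles")
print(f"goal channels      : {trial.goal.shape[0]} (endpoint x, y, z in m)")
print(f"efference channels : {trial.efference.shape[0]} "
      f"(activations in [{trial.efference.min():.2f}, {trial.efference.max():.2f}])")
print(f"afference channels : {trial.afference.shape[0]} (muscle length + velocity)")
peak = np.hypot(*trial.goal[:2]).max()
print(f"peak endpoint excursion: {peak:.3f} m (amplitude 0.40 m plus jitter)")

# The efference/afference pair is physically consistent: each velocity
# channel is the time derivative of its length channel.
lengths, velocities = trial.afference[:8], trial.afference[8:]
dev = np.max(np.abs(velocities - np.gradient(lengths, 1 / trial.fs, axis=1)))
print(f"max |velocity - d(length)/dt| = {dev:.2e} m/s (machine-level)")
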