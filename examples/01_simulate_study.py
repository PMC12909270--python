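"""Generate a small synthetic EEG/behavior study and inspect its structure.

Builds a 6-participant study with the default two injected components
(weak 100-300 ms, strong 440-860 ms) and prints trial counts, the
behavioral table, and where the decodable signal lives.
"""

import numpy as np

from erpdecode import SimConfig, generate_study

config = SimConfig(
    n_participants=6,
    group_sizes=(2, 2, 2),
    n_images=40,
    n_channels=32,
    signal_amplitude=25.0,  # μV per unit of latent appeal
)
datasets, behavior, truth = generate_study(config, seed=1)

ds = datasets[0]
print(f"participants: {len(datasets)}")
print(f"trials per participant: {ds.n_trials} "
      f"({config.n_images} images x 3 question dimensions)")
print(f"epochs: {ds.n_channels} channels x {ds.n_samples} samples, "
      f"{ds.times[0]:.0f}..{ds.times[-1]:.0f} ms at {ds.sampling_rate:.0f} Hz")
print(f"signal channels: {', '.join(truth.signal_channels)}")
print(f"late component window: {config.signal_window} ms, "
      f"early: {config.early_window} ms at 0.4x amplitude")

print("\nper-group mean ratings (0-100):")
print(behavior.groupby("group")["mean_rating"].mean().round(1).to_string())
print("\nMean injected amplitude on Yes vs No trials (appealing):")
img = {f"img-{i + 1:03d}": i for i in range(config.n_images)}
amps = {"yes": [], "no": []}
for p, d in enumerate(datasets):
    for t in d.trials:
        if t.dimension == "appealing" and t.response in amps:
            amps[t.response].append(truth.late_amplitude[p, img[t.image_id]])
print(f"  yes: {np.mean(amps['yes']):+.2f} μV   no: {np.mean(amps['no']):+.2f} μV")
print("Yes trials carry larger injected amplitudes because responses and")
print("EEG signal share the same latent appeal variable.")
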