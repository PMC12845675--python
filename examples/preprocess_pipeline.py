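"""The preprocessing pipeline on a synthetic continuous recording.

Builds a continuous 3-channel signal with a 10 Hz rhythm, a 50 Hz
mains-like interference and cue events, then runs the fixed pipeline —
channel selection, resampling to 250 Hz, 0.5-40 Hz zero-phase bandpass,
[0.5, 3.5) s epoching — and prints what each stage did.  Real GDF
recordings go through the same path via ``read_gdf``.
"""

import numpy as np

from mstsefnet import ContinuousRecording, PreprocessConfig, preprocess

fs = 500.0
t = np.arange(int(60 * fs)) / fs
rng = np.random.default_rng(0)
base = (np.sin(2 * np.pi * 10 * t)          # sensorimotor rhythm
        + 0.5 * np.sin(2 * np.pi * 50 * t)  # mains interference
        + 0.3 * rng.standard_normal(t.size))
data = np.stack([base, 0.8 * base, 1.2 * base])
events = [(int((5 + 6 * i) * fs), 769 + i % 2) for i in range(8)]
rec = ContinuousRecording(data, fs, ["C3", "Cz", "C4"], events)

cfg = PreprocessConfig(band=(0.5, 40.0), window=(0.5, 3.5), target_fs=250.0,
                       channels=["C3", "Cz", "C4"], dataset="2b")
ep = preprocess(rec, cfg)

print(f"input : {rec.data.shape[0]} ch x {rec.n_timepoints} samples @ {fs:.0f} Hz, "
      f"{len(events)} cues")
print(f"output: {ep.n_trials} epochs x {ep.n_channels} ch x {ep.n_samples} samples "
      f"@ {ep.fs:.0f} Hz  (3 s windows -> 750 samples)")


def power_at(x, freq):
    spec = np.abs(np.fft.rfft(x)) ** 2
    f = np.fft.rfftfreq(x.size, 1 / 250.0)
    return spec[np.argmin(np.abs(f - freq))]


p10, p50 = power_at(ep.data[0, 0], 10.0), power_at(ep.data[0, 0], 50.0)
print(f"10 Hz vs 50 Hz power in epoch 0: {p10:.1f} vs {p50:.4f} "
      "(the bandpass kept the rhythm and crushed the interference)")
print("labels:", ep.labels.tolist(), "->", ep.class_names)
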