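"""Generate synthetic motor-imagery EEG and verify its class structure.

Builds a small 2-class dataset over C3/Cz/C4 with strong event-related
desynchronisation (ERD), then measures 8-30 Hz band power per channel and
class.  Imagining the left hand suppresses the rhythm over the right
motor cortex (C4) and vice versa — the printed band powers should show
exactly that contralateral dip.
"""

import numpy as np
from scipy import signal

from mstsefnet import SyntheticSpec, generate_dataset, make_layout

layout = make_layout(1, 1, 5, 40, n_classes=2, channel_names=("C3", "Cz", "C4"))
spec = SyntheticSpec(layout=layout, erd_depth=0.8, noise_scale=0.5,
                     window_length=2.0, seed=7)
ds = generate_dataset(spec)
print(f"dataset: {ds.n_trials} trials x {ds.n_channels} channels x "
      f"{ds.n_samples} samples @ {ds.fs:.0f} Hz")

sos = signal.butter(4, [8, 30], btype="bandpass", fs=ds.fs, output="sos")
band_power = signal.sosfiltfilt(sos, ds.data, axis=2).var(axis=2)

print("\nmean 8-30 Hz band power (arbitrary units):")
print(f"{'class':>12} " + " ".join(f"{c:>8}" for c in ds.channel_names))
for c, name in enumerate(ds.class_names):
    row = band_power[ds.labels == c].mean(axis=0)
    print(f"{name:>12} " + " ".join(f"{v:8.3f}" for v in row))
print("\nThe attenuated (contralateral) channel shows roughly "
      f"(1-erd_depth)^2 = {(1 - spec.erd_depth) ** 2:.2f}x the rhythm power "
      "of its counterpart, riding on the shared 1/f background.")
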