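"""Synthetic motor-imagery EEG with event-related desynchronisation (ERD).

Real MI-EEG carries two exploitable regularities: a broadband 1/f
background, and sensorimotor rhythms (mu, 8–12 Hz; beta, 13–30 Hz) whose
amplitude drops over the motor cortex contralateral to the imagined limb
(ERD).  The generator reproduces exactly that structure — coloured noise
plus amplitude-modulated band oscillations, attenuated on a per-class set
of channels — on dataset layouts mirroring the two public benchmark
protocols: a 4-class, 22-electrode set (9 subjects × 2 sessions × 6 runs
× 48 trials) and a 2-class, 3-electrode set (9 × 5 × 10 × 20).

Every trial is drawn from its own seed stream derived from the root seed
and the trial index, so trial ``i`` is reproducible regardless of how many
trials are generated around it.

The generator deliberately omits ocular/muscular artifacts, volume
conduction and session-to-session drift; it provides class-conditional
band-power structure and nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .containers import EpochedEEG

__all__ = [
    "DatasetLayout", "SyntheticSpec", "make_layout",
    "generate_background", "generate_mi_trial", "generate_dataset",
    "spec_2a", "spec_2b", "CHANNELS_2A", "CHANNELS_2B",
]

# Standard 22-electrode montage of the 4-class benchmark recordings
CHANNELS_2A = [
    "Fz", "FC3", "FC1", "FCz", "FC2", "FC4", "C5", "C3", "C1", "Cz", "C2",
    "C4", "C6", "CP3", "CP1", "CPz", "CP2", "CP4", "P1", "Pz", "P2", "POz",
]
CHANNELS_2B = ["C3", "Cz", "C4"]

CLASSES_2A = ["left_hand", "right_hand", "feet", "tongue"]
CLASSES_2B = ["left_hand", "right_hand"]

# Contralateral MI physiology: imagining one hand attenuates rhythms over
# the opposite hemisphere; feet project to the vertex; tongue diffusely.
DEFAULT_LATERALIZATION_4 = {
    "left_hand": ["C4"],
    "right_hand": ["C3"],
    "feet": ["Cz"],
    "tongue": ["C3", "Cz", "C4"],
}
DEFAULT_LATERALIZATION_2 = {
    "left_hand": ["C4"],
    "right_hand": ["C3"],
}
# the tongue class attenuates all three mildly (half depth)
MILD_CLASSES = {"tongue"}


@dataclass(frozen=True)
class DatasetLayout:
    n_subjects: int
    n_sessions: int
    n_runs: int
    trials_per_run: int
    n_classes: int = 2
    channel_names: tuple[str, ...] = tuple(CHANNELS_2B)
    fs: float = 250.0

    def __post_init__(self):
        for name in ("n_subjects", "n_sessions", "n_runs", "trials_per_run"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_classes < 1:
            raise ValueError("n_classes must be at least 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def total_trials(self) -> int:
        return self.n_subjects * self.n_sessions * self.n_runs * self.trials_per_run


def make_layout(n_subjects: int, n_sessions: int, n_runs: int, trials_per_run: int,
                n_classes: int = 2, channel_names=tuple(CHANNELS_2B),
                fs: float = 250.0) -> DatasetLayout:
    """Build a dataset layout; ``total_trials`` is the product of the counts."""
    return DatasetLayout(n_subjects, n_sessions, n_runs, trials_per_run,
                         n_classes, tuple(channel_names), fs)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters for synthetic ERD epochs.

    ``erd_depth`` is the fractional attenuation of the rhythm amplitude on
    the channels mapped to the active class (0 = no class information,
    1 = rhythm fully suppressed).  ``lateralization`` maps class name →
    list of attenuated channel labels.
    """

    layout: DatasetLayout
    class_names: tuple[str, ...] = tuple(CLASSES_2B)
    mu_band: tuple[float, float] = (8.0, 12.0)
    beta_band: tuple[float, float] = (13.0, 30.0)
    erd_depth: float = 0.5
    background_exponent: float = 1.0
    noise_scale: float = 1.0
    osc_amplitude: float = 1.0
    window_length: float = 3.0  # seconds per epoch (0.5–3.5 s cue window)
    lateralization: dict[str, list[str]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must lie in [0, 1]")
        nyq = self.layout.fs / 2
        for lo, hi in (self.mu_band, self.beta_band):
            if not (0 < lo < hi < nyq):
                raise ValueError("band edges must be ordered and below Nyquist")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")
        if len(self.class_names) != self.layout.n_classes:
            raise ValueError("class_names must match layout.n_classes")
        lat = self.lateralization or self._default_lateralization()
        object.__setattr__(self, "lateralization", lat)
        if self.erd_depth > 0:
            for cname in self.class_names:
                chans = lat.get(cname, [])
                if not chans:
                    raise ValueError(f"class {cname!r} maps to no channels")
                for ch in chans:
                    if ch not in self.layout.channel_names:
                        raise ValueError(f"lateralization channel {ch!r} not in layout")

    def _default_lateralization(self) -> dict[str, list[str]]:
        table = DEFAULT_LATERALIZATION_4 if self.layout.n_classes > 2 else DEFAULT_LATERALIZATION_2
        out = {}
        for cname in self.class_names:
            chans = [c for c in table.get(cname, []) if c in self.layout.channel_names]
            out[cname] = chans or list(self.layout.channel_names)
        return out


def spec_2a(**overrides) -> SyntheticSpec:
    """4-class layout: 9 subjects × 2 sessions × 6 runs × 48 trials = 5184."""
    layout = make_layout(9, 2, 6, 48, n_classes=4, channel_names=tuple(CHANNELS_2A))
    kw = dict(layout=layout, class_names=tuple(CLASSES_2A))
    kw.update(overrides)
    return SyntheticSpec(**kw)


def spec_2b(**overrides) -> SyntheticSpec:
    """2-class layout: 9 subjects × 5 sessions × 10 runs × 20 trials = 9000."""
    layout = make_layout(9, 5, 10, 20, n_classes=2, channel_names=tuple(CHANNELS_2B))
    kw = dict(layout=layout, class_names=tuple(CLASSES_2B))
    kw.update(overrides)
    return SyntheticSpec(**kw)


def _trial_rng(seed: int, trial_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(trial_index,)))


def generate_background(n_channels: int, n_samples: int, fs: float,
                        exponent: float = 1.0, scale: float = 1.0,
                        seed: int | np.random.Generator = 0) -> np.ndarray:
    """Coloured (1/f^exponent) noise background, shape (n_channels, n_samples).

    Gaussian white noise is shaped in the frequency domain by
    ``f**(-exponent/2)`` and transformed back, then standardised so that
    ``scale`` sets the per-channel RMS.
    """
    if n_samples <= 1:
        raise ValueError("n_samples must exceed 1")
    if exponent < 0:
        raise ValueError("exponent must be non-negative")
    if scale < 0:
        raise ValueError("scale must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal((n_channels, n_samples))
    if scale == 0:
        return np.zeros((n_channels, n_samples))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC component
    spectrum = np.fft.rfft(white, axis=1) * shaping
    sig = np.fft.irfft(spectrum, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(sig ** 2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return scale * sig / rms


def _band_oscillation(rng: np.random.Generator, band: tuple[float, float],
                      t: np.ndarray, amplitude: float) -> np.ndarray:
    """One amplitude-modulated sinusoid with random frequency and phase."""
    f = rng.uniform(*band)
    phase = rng.uniform(0, 2 * np.pi)
    am_f = rng.uniform(0.3, 1.2)  # slow waxing/waning envelope
    am_phase = rng.uniform(0, 2 * np.pi)
    envelope = 1.0 + 0.3 * np.sin(2 * np.pi * am_f * t + am_phase)
    return amplitude * envelope * np.sin(2 * np.pi * f * t + phase)


def generate_mi_trial(class_label: int, spec: SyntheticSpec,
                      seed: int | np.random.Generator | None = None) -> np.ndarray:
    """One trial (n_channels × n_samples): background + mu/beta rhythms with
    class-lateralised ERD attenuation."""
    if not 0 <= class_label < spec.layout.n_classes:
        raise ValueError(f"class_label {class_label} invalid for {spec.layout.n_classes} classes")
    if seed is None:
        seed = spec.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = spec.layout.fs
    n_samples = int(round(spec.window_length * fs))
    n_channels = len(spec.layout.channel_names)
    t = np.arange(n_samples) / fs

    trial = generate_background(n_channels, n_samples, fs, spec.background_exponent,
                                spec.noise_scale, rng)
    cname = spec.class_names[class_label]
    attenuated = set(spec.lateralization.get(cname, []))
    depth = spec.erd_depth * (0.5 if cname in MILD_CLASSES else 1.0)
    for ci, ch in enumerate(spec.layout.channel_names):
        gain = (1.0 - depth) if ch in attenuated else 1.0
        for band in (spec.mu_band, spec.beta_band):
            trial[ci] += gain * _band_oscillation(rng, band, t, spec.osc_amplitude)
    return trial


def generate_dataset(spec: SyntheticSpec) -> EpochedEEG:
    """Full epoched dataset for the layout; labels balanced within each run.

    Pure function of ``(spec, spec.seed)``; trial ``i`` uses a seed stream
    derived from ``(seed, i)`` only.
    """
    layout = spec.layout
    if layout.trials_per_run and layout.trials_per_run % layout.n_classes:
        raise ValueError("trials_per_run must be divisible by n_classes for balance")
    n_total = layout.total_trials
    fs = layout.fs
    n_samples = int(round(spec.window_length * fs))
    n_channels = len(layout.channel_names)

    data = np.empty((n_total, n_channels, n_samples))
    labels = np.empty(n_total, dtype=np.int64)
    per_class = layout.trials_per_run // layout.n_classes if layout.n_classes else 0
    run_labels = np.repeat(np.arange(layout.n_classes), per_class)
    i = 0
    n_runs_total = layout.n_subjects * layout.n_sessions * layout.n_runs
    for run in range(n_runs_total):
        # deterministic within-run order, seeded from (root seed, run)
        run_rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(1, run)))
        order = run_rng.permutation(run_labels)
        for lab in order:
            data[i] = generate_mi_trial(int(lab), spec, _trial_rng(spec.seed, i))
            labels[i] = lab
            i += 1
    return EpochedEEG(data, labels, fs, list(layout.channel_names), list(spec.class_names))


def with_params(spec: SyntheticSpec, **overrides) -> SyntheticSpec:
    """Return a copy of ``spec`` with fields replaced."""
    return replace(spec, **overrides)
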