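"""Synthetic two-class motor-imagery EEG with planted ERD/ERS structure.

Each channel of a trial is a sum of narrowband oscillations (mu, beta) whose
post-cue amplitude is scaled by a class-, channel- and band-specific
envelope factor (``erd_depth``: 1 = no change, < 1 = desynchronization,
> 1 = synchronization), plus broadband noise. Oscillations are band-limited
Gaussian noise, not pure tones, so the generalized-eigenvalue problem the
features module solves is well conditioned. Optionally a fraction of each
rhythm's amplitude (``phase_locking``) is a trial-invariant waveform built
from harmonics of ``1/template_period``; this gives the planted rhythm a
well-defined dominant direction under sliding-window analysis, which is what
makes ground-truth basis recovery checkable. Trial-to-trial amplitude
variability is lognormal with a configurable coefficient of variation.

Every trial draws from its own random stream keyed by (seed, class, trial
index within class), so per-trial content is reproducible regardless of
trial ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .epochs import CLASS_LABELS, EpochSet


def _default_erd_depth() -> dict[tuple[str, str, str], float]:
    # contralateral post-cue power drop: right-hand imagery suppresses C3,
    # left-hand imagery suppresses C4; mu reacts more strongly than beta
    return {
        ("R", "C3", "mu"): 0.5,
        ("L", "C4", "mu"): 0.5,
        ("R", "C3", "beta"): 0.7,
        ("L", "C4", "beta"): 0.7,
    }


def _default_band_amplitudes() -> dict[str, float]:
    return {"mu": 1.0, "beta": 0.6}


@dataclass
class SyntheticConfig:
    """Generator settings; defaults emulate a 9 s cued motor-imagery trial."""

    sampling_rate: float = 128.0
    n_trials_per_class: int = 70
    trial_duration: float = 9.0
    cue_time: float = 3.0
    channel_names: tuple[str, ...] = ("C3", "C4")
    mu_band: tuple[float, float] = (8.0, 13.0)
    beta_band: tuple[float, float] = (18.0, 30.0)
    band_amplitudes: dict[str, float] = field(default_factory=_default_band_amplitudes)
    erd_depth: dict[tuple[str, str, str], float] = field(default_factory=_default_erd_depth)
    noise_sigma: float = 1.0
    amplitude_cv: float = 0.25
    ramp_duration: float = 0.5
    phase_locking: float = 0.0
    template_period: float = 0.25
    noise_model: str = "white"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def bands(self) -> dict[str, tuple[float, float]]:
        return {"mu": self.mu_band, "beta": self.beta_band}

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration * self.sampling_rate))

    def validate(self) -> None:
        if not self.trial_duration > self.cue_time > 0:
            raise ValueError(
                f"require trial_duration > cue_time > 0; got "
                f"{self.trial_duration}, {self.cue_time}"
            )
        active = [b for b, (lo, hi) in self.bands.items() if self.band_amplitudes.get(b, 0) > 0]
        top = max((self.bands[b][1] for b in active), default=0.0)
        if self.sampling_rate <= 2 * top:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} violates Nyquist for band edge {top} Hz"
            )
        for (lo, hi) in self.bands.values():
            if not 0 < lo < hi:
                raise ValueError(f"invalid band ({lo}, {hi})")
        for key, depth in self.erd_depth.items():
            if depth < 0:
                raise ValueError(f"erd_depth{key} must be >= 0; got {depth}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.amplitude_cv < 0:
            raise ValueError("amplitude_cv must be >= 0")
        if not 0 <= self.phase_locking <= 1:
            raise ValueError("phase_locking must lie in [0, 1]")
        if self.noise_model not in ("white", "pink"):
            raise ValueError("noise_model must be 'white' or 'pink'")
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1")
        if self.ramp_duration < 0 or self.cue_time + self.ramp_duration > self.trial_duration:
            raise ValueError("ramp must fit between cue and trial end")


@dataclass
class GroundTruth:
    """What was planted: labels, per-(class, channel, band) envelopes, seed."""

    labels: np.ndarray
    envelopes: dict[tuple[str, str, str], np.ndarray]
    seed: int


def envelope(config: SyntheticConfig, depth: float) -> np.ndarray:
    """Unit envelope before the cue, raised-cosine ramp to ``depth`` after."""
    t = np.arange(config.n_samples) / config.sampling_rate
    env = np.ones(config.n_samples)
    if config.ramp_duration > 0:
        in_ramp = (t >= config.cue_time) & (t < config.cue_time + config.ramp_duration)
        phase = (t[in_ramp] - config.cue_time) / config.ramp_duration
        env[in_ramp] = 1 + (depth - 1) * (1 - np.cos(np.pi * phase)) / 2
        env[t >= config.cue_time + config.ramp_duration] = depth
    else:
        env[t >= config.cue_time] = depth
    return env


def band_limited_noise(
    rng: np.random.Generator, n: int, sampling_rate: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance Gaussian noise confined to ``band`` (FFT brick wall)."""
    lo, hi = band
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError(f"band {band} contains no FFT bin at n={n}, fs={sampling_rate}")
    spec[~mask] = 0.0
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    return x / x.std()


def rhythm_template(config: SyntheticConfig, channel: str, band: str) -> np.ndarray:
    """Trial-invariant rhythm waveform: in-band harmonics of 1/template_period.

    Drawn once per (channel, band) from the config seed; unit variance.
    Returns zeros when no harmonic falls inside the band.
    """
    lo, hi = config.bands[band]
    f0 = 1.0 / config.template_period
    freqs = np.arange(np.ceil(lo / f0), np.floor(hi / f0) + 1) * f0
    freqs = freqs[(freqs >= lo) & (freqs <= hi)]
    t = np.arange(config.n_samples) / config.sampling_rate
    if len(freqs) == 0:
        return np.zeros(config.n_samples)
    key = [config.seed, 7, config.channel_names.index(channel), list(config.bands).index(band)]
    rng = np.random.default_rng(np.random.SeedSequence(key))
    amps = rng.uniform(0.5, 1.0, size=len(freqs))
    phases = rng.uniform(0, 2 * np.pi, size=len(freqs))
    s = np.sum([a * np.cos(2 * np.pi * f * t + p) for a, f, p in zip(amps, freqs, phases)], axis=0)
    return s / s.std()


def _trial_rng(config: SyntheticConfig, label: str, index_in_class: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, 2, CLASS_LABELS.index(label), index_in_class])
    )


def generate_trial(
    config: SyntheticConfig, label: str, rng: np.random.Generator
) -> np.ndarray:
    """One trial (channels x samples) for the given class, from ``rng``."""
    config.validate()
    if label not in CLASS_LABELS:
        raise ValueError(f"label must be one of {CLASS_LABELS}; got {label!r}")
    n = config.n_samples
    out = np.zeros((len(config.channel_names), n))
    p = config.phase_locking
    for ci, channel in enumerate(config.channel_names):
        sig = np.zeros(n)
        for band, amp0 in config.band_amplitudes.items():
            if amp0 <= 0:
                continue
            depth = config.erd_depth.get((label, channel, band), 1.0)
            env = envelope(config, depth)
            if config.amplitude_cv > 0:
                s2 = np.log1p(config.amplitude_cv**2)
                amp = amp0 * rng.lognormal(mean=-s2 / 2, sigma=np.sqrt(s2))
            else:
                amp = amp0
            osc = np.zeros(n)
            if p > 0:
                osc += p * rhythm_template(config, channel, band)
            if p < 1:
                osc += np.sqrt(1 - p**2) * band_limited_noise(
                    rng, n, config.sampling_rate, config.bands[band]
                )
            sig += amp * env * osc
        if config.noise_sigma > 0:
            if config.noise_model == "white":
                sig += config.noise_sigma * rng.standard_normal(n)
            else:
                sig += config.noise_sigma * _pink_noise(rng, n)
        out[ci] = sig
    return out


def generate_dataset(config: SyntheticConfig) -> tuple[EpochSet, GroundTruth]:
    """Balanced, randomly ordered EpochSet plus the planted ground truth."""
    config.validate()
    n_per = config.n_trials_per_class
    order_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    slots = [(lab, j) for lab in CLASS_LABELS for j in range(n_per)]
    order = order_rng.permutation(len(slots))
    data = np.empty((len(slots), len(config.channel_names), config.n_samples))
    labels = np.empty(len(slots), dtype=object)
    for pos, slot in enumerate(order):
        label, j = slots[slot]
        data[pos] = generate_trial(config, label, _trial_rng(config, label, j))
        labels[pos] = label
    epochs = EpochSet(
        data=data,
        sampling_rate=config.sampling_rate,
        cue_time=config.cue_time,
        labels=labels,
        channel_names=config.channel_names,
    )
    envelopes = {
        (label, channel, band): envelope(
            config, config.erd_depth.get((label, channel, band), 1.0)
        )
        for label in CLASS_LABELS
        for channel in config.channel_names
        for band in config.bands
    }
    truth = GroundTruth(labels=labels.copy(), envelopes=envelopes, seed=config.seed)
    return epochs, truth


def oracle_direction(
    config: SyntheticConfig,
    channel: str,
    window_length: float = 1.0,
    step: float = 0.25,
) -> np.ndarray:
    """Dominant direction of the noiseless planted rhythm for one channel.

    Regenerates the dataset without broadband noise, pools all post-cue
    windows of the channel across both classes, and returns the leading
    eigenvector of their average outer product (unit norm, sign-fixed).
    Serves as the independent reference that a fitted projective base
    should align with on strong-effect data.
    """
    from .epochs import SegmentationScheme, segment_trials
    from .features import _fix_sign

    clean = replace(config, noise_sigma=0.0)
    epochs, _ = generate_dataset(clean)
    scheme = SegmentationScheme(window_length=window_length, step=step)
    seg = segment_trials(epochs, scheme)
    mask = seg.start_times >= config.cue_time - 1e-9
    ch = epochs.channel_index(channel)
    block = seg.data[:, mask, ch, :].reshape(-1, scheme.window_samples(config.sampling_rate))
    r = block.T @ block / block.shape[0]
    w, v = np.linalg.eigh(r)
    u = v[:, -1]
    return _fix_sign(u / np.linalg.norm(u))
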