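"""Synthetic EEG-like data with controllable artifact separation.

Generators emulate the shape of the mobile-EEG study the scoring methods are
aimed at: 100 Hz sampling, 58-channel (unimodal study) or 20-channel
(multimodal study) montages, ~6-minute sessions, sparse large blink-like EOG
transients, and rhythmic gait artifacts with harmonics.

Clean EEG is modelled per channel as 1/f-coloured Gaussian noise plus a
band-limited alpha oscillation at 10 Hz.  Ocular noise is a 4-channel EOG
surrogate: raised-cosine blink pulses at a Poisson rate with alternating
polarity across the above/below-eye channels, on top of a slow drift.  Raw
(contaminated) EEG is the clean signal plus a fixed spatial gain matrix times
the noise channels — a stand-in for volume conduction that weights frontal
channels more heavily.  Motion artifacts are sums of gait harmonics whose
fundamental rises with walking speed.

All generators are pure functions of (config, seed): identical inputs give
bit-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import Epoch, Recording, segment_epochs

__all__ = [
    "SyntheticConfig",
    "generate_clean_eeg",
    "generate_eog_noise",
    "mix_recordings",
    "default_gain_matrix",
    "make_unimodal_study",
    "generate_motion_dataset",
    "gait_fundamental_hz",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study; defaults mirror the target data shape.

    Amplitudes are in microvolts.  ``seed`` is mandatory for reproducibility;
    per-subject/session streams are derived from it with
    ``numpy.random.default_rng([seed, ...])`` spawn keys.
    """

    seed: int = 0
    # -- unimodal (ocular-artifact) study layout --
    n_subjects: int = 8
    n_channels: int = 58
    n_eog_channels: int = 4
    duration_s: float = 360.0
    rate_hz: float = 100.0
    # -- clean-EEG background --
    one_over_f_exponent: float = 1.0
    background_rms_uv: float = 10.0
    alpha_freq_hz: float = 10.0
    alpha_amplitude_uv: float = 5.0
    # -- ocular artifact --
    blink_rate_per_s: float = 0.25
    blink_amplitude_uv: float = 150.0
    blink_width_s: float = 0.4
    drift_rms_uv: float = 3.0
    mixing_gain: float = 0.5
    # -- multimodal (motion-artifact) study layout --
    n_channels_multimodal: int = 20
    n_treadmill_subjects: int = 11
    treadmill_speeds_mph: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
    treadmill_duration_s: float = 360.0
    n_ambulatory_subjects: int = 20
    baseline_duration_s: float = 60.0
    walking_duration_s: float = 420.0
    epoch_seconds_multimodal: float = 30.0
    gait_frequency_hz: float = 2.0
    gait_amplitude_uv: float = 30.0

    def __post_init__(self) -> None:
        non_negative = (
            self.blink_rate_per_s, self.blink_amplitude_uv, self.blink_width_s,
            self.gait_frequency_hz, self.gait_amplitude_uv, self.mixing_gain,
            self.alpha_amplitude_uv, self.background_rms_uv, self.drift_rms_uv,
        )
        if any(v < 0 for v in non_negative):
            raise ValueError("rates and amplitudes must be >= 0")
        if self.rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("rate and duration must be > 0")

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


def _rng(cfg: SyntheticConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), *map(int, stream)])


def _one_over_f_noise(rng: np.random.Generator, n_channels: int,
                      n_samples: int, rate: float, exponent: float,
                      rms: float) -> np.ndarray:
    """Per-channel coloured noise with power spectrum proportional to 1/f^exp."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    coeffs = (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    ) * shape
    x = np.fft.irfft(coeffs, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd * rms


def generate_clean_eeg(cfg: SyntheticConfig, seed_stream: tuple[int, ...] = (),
                       n_channels: int | None = None,
                       duration_s: float | None = None) -> Recording:
    """Clean EEG surrogate: 1/f background plus an alpha-band oscillation."""
    n_channels = cfg.n_channels if n_channels is None else n_channels
    duration_s = cfg.duration_s if duration_s is None else duration_s
    rng = _rng(cfg, 0, *seed_stream)
    n = int(round(duration_s * cfg.rate_hz))
    data = _one_over_f_noise(
        rng, n_channels, n, cfg.rate_hz, cfg.one_over_f_exponent,
        cfg.background_rms_uv,
    )
    if cfg.alpha_amplitude_uv > 0:
        t = np.arange(n) / cfg.rate_hz
        phases = rng.uniform(0, 2 * np.pi, size=n_channels)
        data = data + cfg.alpha_amplitude_uv * np.sin(
            2 * np.pi * cfg.alpha_freq_hz * t[None, :] + phases[:, None]
        )
    return Recording(
        channel_labels=[f"EEG{i:03d}" for i in range(n_channels)],
        sampling_rate=cfg.rate_hz,
        data=data,
        metadata={"kind": "clean_eeg"},
    )


def generate_eog_noise(cfg: SyntheticConfig,
                       seed_stream: tuple[int, ...] = (),
                       duration_s: float | None = None) -> Recording:
    """EOG surrogate: Poisson raised-cosine blink pulses plus slow drift.

    Channels alternate polarity (electrodes above/below the eyes); power is
    dominated by the sub-4 Hz range, mirroring real ocular artifacts.
    """
    duration_s = cfg.duration_s if duration_s is None else duration_s
    rng = _rng(cfg, 1, *seed_stream)
    n = int(round(duration_s * cfg.rate_hz))
    t_pulse = np.arange(int(round(cfg.blink_width_s * cfg.rate_hz)))
    pulse = 0.5 * (1 - np.cos(2 * np.pi * t_pulse / max(t_pulse.size - 1, 1)))
    n_blinks = rng.poisson(cfg.blink_rate_per_s * duration_s)
    starts = np.sort(rng.integers(0, max(n - t_pulse.size, 1), size=n_blinks))
    train = np.zeros(n)
    if cfg.blink_amplitude_uv > 0:
        for s in starts:
            train[s:s + t_pulse.size] += (
                cfg.blink_amplitude_uv * rng.uniform(0.8, 1.2) * pulse
            )
    gains = np.array([1.0, -0.7, 0.95, -0.65])[: cfg.n_eog_channels]
    data = gains[:, None] * train[None, :]
    # slow drift: low-passed random walk, standardised to drift_rms
    walk = np.cumsum(rng.standard_normal((cfg.n_eog_channels, n)), axis=1)
    walk = walk - walk.mean(axis=1, keepdims=True)
    sd = walk.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    data = data + walk / sd * cfg.drift_rms_uv
    return Recording(
        channel_labels=[f"EOG{i}" for i in range(cfg.n_eog_channels)],
        sampling_rate=cfg.rate_hz,
        data=data,
        metadata={"kind": "eog_noise", "n_blinks": int(n_blinks)},
    )


def mix_recordings(clean: Recording, noise: Recording,
                   gain_matrix: np.ndarray) -> Recording:
    """Raw = clean + gain_matrix @ noise, channel-wise and exactly linear."""
    if clean.sampling_rate != noise.sampling_rate:
        raise ValueError("sampling rates differ")
    if clean.n_samples != noise.n_samples:
        raise ValueError("durations differ")
    gain_matrix = np.asarray(gain_matrix, dtype=float)
    if gain_matrix.shape != (clean.n_channels, noise.n_channels):
        raise ValueError(
            f"gain matrix shape {gain_matrix.shape} does not match "
            f"({clean.n_channels}, {noise.n_channels})"
        )
    return Recording(
        channel_labels=list(clean.channel_labels),
        sampling_rate=clean.sampling_rate,
        data=clean.data + gain_matrix @ noise.data,
        metadata={**clean.metadata, "kind": "raw_eeg"},
    )


def default_gain_matrix(n_channels: int, n_noise_channels: int,
                        rng: np.random.Generator,
                        gain: float) -> np.ndarray:
    """Random artifact-propagation weights, decaying front-to-back.

    Mimics volume conduction without modelling geometry: channel i receives
    the noise channels scaled by gain * exp(-3 i / n) * U(0.5, 1).
    """
    decay = np.exp(-3.0 * np.arange(n_channels) / n_channels)
    u = rng.uniform(0.5, 1.0, size=(n_channels, n_noise_channels))
    return gain * decay[:, None] * u


def make_unimodal_study(cfg: SyntheticConfig) -> list[dict]:
    """One clean/raw/noise recording triple per subject.

    Raw is the clean EEG with the EOG surrogate propagated through a fixed
    per-subject spatial gain matrix.
    """
    study = []
    for s in range(cfg.n_subjects):
        clean = generate_clean_eeg(cfg, seed_stream=(s,))
        noise = generate_eog_noise(cfg, seed_stream=(s,))
        g = default_gain_matrix(
            cfg.n_channels, cfg.n_eog_channels, _rng(cfg, 2, s),
            cfg.mixing_gain,
        )
        raw = mix_recordings(clean, noise, g)
        for rec in (clean, raw, noise):
            rec.metadata["subject"] = f"S{s:02d}"
        study.append({
            "subject": f"S{s:02d}", "clean": clean, "raw": raw,
            "noise": noise, "gain_matrix": g,
        })
    return study


def gait_fundamental_hz(speed_mph: float) -> float:
    """Step frequency of the treadmill gait artifact at a given belt speed."""
    return 0.5 + 0.375 * speed_mph


def _gait_artifact(rng: np.random.Generator, n_channels: int, n_samples: int,
                   rate: float, fundamental: float,
                   amplitude: float) -> np.ndarray:
    """Rhythmic artifact: three gait harmonics with per-channel gain/phase."""
    t = np.arange(n_samples) / rate
    gains = amplitude * (0.3 + 0.7 * np.exp(
        -2.0 * np.arange(n_channels) / n_channels
    )) * rng.uniform(0.7, 1.0, size=n_channels)
    art = np.zeros((n_channels, n_samples))
    for h, rel in ((1, 1.0), (2, 0.5), (3, 0.25)):
        phases = rng.uniform(0, 2 * np.pi, size=n_channels)
        art += (gains * rel)[:, None] * np.sin(
            2 * np.pi * h * fundamental * t[None, :] + phases[:, None]
        )
    return art


def generate_motion_dataset(cfg: SyntheticConfig
                            ) -> tuple[list[Epoch], list[Epoch]]:
    """Clean and motion-contaminated multichannel segments.

    Emulates the two-source motion study: treadmill subjects walk at each
    speed for ``treadmill_duration_s`` (clean = artifact-removed EEG, raw =
    EEG plus gait harmonics at the speed's fundamental), and ambulatory
    subjects contribute a still baseline (clean) plus a free-walking period
    (raw, fundamental ``gait_frequency_hz``).  All sessions are cut into
    ``epoch_seconds_multimodal`` segments.  With the default layout this
    yields 12*4*11 + 2*20 = 568 clean and 12*4*11 + 14*20 = 808 raw segments.
    """
    clean_epochs: list[Epoch] = []
    raw_epochs: list[Epoch] = []
    n_ch = cfg.n_channels_multimodal

    for s in range(cfg.n_treadmill_subjects):
        for j, mph in enumerate(cfg.treadmill_speeds_mph):
            clean = generate_clean_eeg(
                cfg, seed_stream=(10, s, j), n_channels=n_ch,
                duration_s=cfg.treadmill_duration_s,
            )
            clean.metadata.update(subject=f"T{s:02d}", speed_mph=mph)
            art = _gait_artifact(
                _rng(cfg, 11, s, j), n_ch, clean.n_samples, cfg.rate_hz,
                gait_fundamental_hz(mph),
                cfg.gait_amplitude_uv * (0.6 + 0.1 * mph),
            )
            raw = Recording(
                channel_labels=list(clean.channel_labels),
                sampling_rate=cfg.rate_hz,
                data=clean.data + art,
                metadata={**clean.metadata, "kind": "raw_eeg"},
            )
            clean_epochs += segment_epochs(
                clean, cfg.epoch_seconds_multimodal, mode="multichannel")
            raw_epochs += segment_epochs(
                raw, cfg.epoch_seconds_multimodal, mode="multichannel")

    for s in range(cfg.n_ambulatory_subjects):
        baseline = generate_clean_eeg(
            cfg, seed_stream=(20, s), n_channels=n_ch,
            duration_s=cfg.baseline_duration_s,
        )
        baseline.metadata.update(subject=f"A{s:02d}", condition="baseline")
        clean_epochs += segment_epochs(
            baseline, cfg.epoch_seconds_multimodal, mode="multichannel")

        walk_clean = generate_clean_eeg(
            cfg, seed_stream=(21, s), n_channels=n_ch,
            duration_s=cfg.walking_duration_s,
        )
        art = _gait_artifact(
            _rng(cfg, 22, s), n_ch, walk_clean.n_samples, cfg.rate_hz,
            cfg.gait_frequency_hz, cfg.gait_amplitude_uv,
        )
        walk = Recording(
            channel_labels=list(walk_clean.channel_labels),
            sampling_rate=cfg.rate_hz,
            data=walk_clean.data + art,
            metadata={"subject": f"A{s:02d}", "condition": "walking",
                      "kind": "raw_eeg"},
        )
        raw_epochs += segment_epochs(
            walk, cfg.epoch_seconds_multimodal, mode="multichannel")

    return clean_epochs, raw_epochs
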