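"""Two-state multichannel EEG-like simulator.

Each recording is a sum of (i) spatially mixed 1/f-coloured background
sources shared across channels, (ii) one narrowband 8-13 Hz oscillation with
slow random amplitude modulation (spindle-like, not phase-locked) whose
per-channel gain follows a posterior-emphasis profile and is scaled up by
``1 + effect_size`` in the fatigue state, and (iii) independent white sensor
noise. Subject-level draws (base amplitude, source mixing) are shared
between the two states of a subject so that, at ``effect_size = 0``, the
states are statistically identical.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .types import Recording


@dataclass
class SimulationConfig:
    n_subjects: int = 6
    channels: int = 32
    rate: float = 500.0
    duration_per_state: float = 1200.0
    alpha_band: tuple = (8.0, 13.0)
    effect_size: float = 1.0  # multiplicative alpha-amplitude gain in fatigue
    background_exponent: float = 1.0  # background power ~ f^-exponent
    n_background_sources: int = 6
    n_alpha_sources: int = 4
    alpha_amplitude: float = 2.0
    background_sd: float = 1.0
    noise_sd: float = 0.2
    subject_sigma: float = 0.2  # log-normal spread of per-subject amplitude
    envelope_depth: float = 0.3
    envelope_cutoff_hz: float = 1.0
    posterior_weight_profile: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.rate <= 2 * self.alpha_band[1]:
            raise ValueError("rate must exceed twice the alpha upper edge")
        if self.posterior_weight_profile is None:
            # smooth front-to-back gain gradient standing in for a montage
            self.posterior_weight_profile = np.linspace(0.3, 1.5, self.channels)
        else:
            self.posterior_weight_profile = np.asarray(
                self.posterior_weight_profile, dtype=float
            )
            if self.posterior_weight_profile.shape != (self.channels,):
                raise ValueError("posterior profile length must equal channel count")


def _colored_noise(rng: np.random.Generator, n: int, rate: float, exponent: float) -> np.ndarray:
    """Unit-variance noise with power spectral density ~ f^-exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    f = np.maximum(f, 0.1)  # flatten below 0.1 Hz to avoid DC blow-up
    spec *= f ** (-exponent / 2.0)
    spec[0] = 0.0
    out = np.fft.irfft(spec, n=n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _alpha_source(rng: np.random.Generator, n: int, rate: float, cfg: SimulationConfig) -> np.ndarray:
    """Unit-RMS narrowband oscillation with slow amplitude modulation."""
    lo, hi = cfg.alpha_band
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    carrier = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sos_env = sps.butter(2, cfg.envelope_cutoff_hz, btype="lowpass", fs=rate, output="sos")
    slow = sps.sosfiltfilt(sos_env, rng.standard_normal(n))
    sd = slow.std()
    if sd > 0:
        slow = slow / sd
    env = np.clip(1.0 + cfg.envelope_depth * slow, 0.05, None)
    out = carrier * env
    # normalize to unit *in-band* variance so the class power ratio is set by
    # the configured amplitudes, not by the envelope realization
    spec = np.fft.rfft(out)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    m = (f >= lo) & (f <= hi)
    band_var = 2.0 * np.sum(np.abs(spec[m]) ** 2) / n**2
    return out / np.sqrt(band_var)


def _subject_rng(cfg: SimulationConfig, subject_index: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, 1000 + subject_index])


def generate_recording(cfg: SimulationConfig, subject_index: int, state: int) -> Recording:
    """One state recording for one subject; deterministic in (seed, subject, state)."""
    if state not in (0, 1):
        raise ValueError("state must be 0 (alert) or 1 (fatigue)")
    n = int(round(cfg.duration_per_state * cfg.rate))
    srng = _subject_rng(cfg, subject_index)
    subj_factor = float(np.exp(srng.normal(0.0, cfg.subject_sigma)))
    mixing = srng.standard_normal((cfg.channels, cfg.n_background_sources))
    mixing /= np.sqrt(cfg.n_background_sources)
    # per-source spatial jitter on top of the shared posterior profile; drawn
    # at the subject level so both states of a subject share the topography
    jitter = np.exp(srng.normal(0.0, 0.3, (cfg.channels, cfg.n_alpha_sources)))

    rng = np.random.default_rng([cfg.seed, 1000 + subject_index, state])
    sources = np.vstack(
        [_colored_noise(rng, n, cfg.rate, cfg.background_exponent)
         for _ in range(cfg.n_background_sources)]
    )
    data = cfg.background_sd * (mixing @ sources)

    base = (
        cfg.alpha_amplitude
        * subj_factor
        * (1.0 + cfg.effect_size * state)
        / np.sqrt(cfg.n_alpha_sources)
    )
    for s in range(cfg.n_alpha_sources):
        alpha = _alpha_source(rng, n, cfg.rate, cfg)
        gain = base * cfg.posterior_weight_profile * jitter[:, s]
        data += np.outer(gain, alpha)
    data += cfg.noise_sd * rng.standard_normal((cfg.channels, n))

    names = [f"Ch{i + 1:02d}" for i in range(cfg.channels)]
    return Recording(
        data=data,
        rate=cfg.rate,
        channel_names=names,
        label=state,
        subject_id=f"S{subject_index + 1:02d}",
    )


def generate_study(cfg: SimulationConfig):
    """All subjects x both states.

    Returns ``(recordings, manifest)`` where the manifest lists one row per
    recording: subject_id, state name, label, rate, channels, duration.
    """
    recordings, manifest = [], []
    for s in range(cfg.n_subjects):
        for state in (0, 1):
            rec = generate_recording(cfg, s, state)
            recordings.append(rec)
            manifest.append(
                {
                    "subject_id": rec.subject_id,
                    "state": "fatigue" if state == 1 else "alert",
                    "label": state,
                    "rate": cfg.rate,
                    "channels": cfg.channels,
                    "duration_s": cfg.duration_per_state,
                }
            )
    return recordings, manifest
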