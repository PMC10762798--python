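"""Synthetic single-channel 500 Hz EEG cohorts with controlled group structure.

The generator emulates the group- and condition-dependent structure reported
for frontal single-channel EEG in early Parkinson's disease (PD) versus
healthy controls:

* healthy subjects show higher broadband and especially Delta-band activity;
* healthy subjects carry a latent slow (1.5-4 Hz) component whose power
  tracks the ordinal cognitive load of the current task, while in PD
  subjects the component sits at a constant, load-insensitive level — the
  elevated resting activity reported for that group;
* PD subjects additionally show a stronger slow global amplitude
  co-modulation of their neural components, giving them uniformly higher
  correlations among component time courses.

Each recording is a sum of a 1/f background, five band-limited Gaussian
processes (4th-order Butterworth band-passed white noise) with group- and
condition-dependent amplitude gains, the latent load-tracking component, and
white measurement noise.  Condition gain changes are ramped with a 1 s raised
cosine at block boundaries so analysis windows straddling a boundary see no
discontinuity, and zero-phase filters run on guard-padded noise so their
edge transients never reach the session.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .protocol import CONDITIONS, ProtocolSchedule, load_level

GROUPS = ("PD", "healthy")

#: Analysis band edges in Hz (shared with the decomposition stage).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 15.0),
    "beta": (16.0, 31.0),
    "gamma": (32.0, 45.0),
}


def _default_band_gains() -> dict[str, dict[str, dict[str, float]]]:
    """group -> condition -> band -> amplitude multiplier.

    Healthy subjects get a Delta advantage (x1.25) and a slight broadband
    advantage (x1.03) in every condition.  Multipliers are amplitudes, so
    power ratios are their squares.
    """
    gains: dict[str, dict[str, dict[str, float]]] = {}
    for group in GROUPS:
        gains[group] = {}
        for cond in CONDITIONS:
            per_band = {}
            for band in BANDS:
                g = 1.0
                if group == "healthy":
                    g = 1.25 if band == "delta" else 1.03
                per_band[band] = g
            gains[group][cond] = per_band
    return gains


@dataclass
class GeneratorConfig:
    """Tunable parameters of the synthetic cohort generator.

    Default effect sizes are calibrated so that, at the study's 26-vs-26
    cohort size, the mixed-model stage detects the group effect on Delta
    power with power around 0.9 and the healthy-only load modulation of the
    latent component is recoverable; they are deliberately modest rather
    than caricatural.

    Attributes
    ----------
    fs : int
        Sampling rate in Hz.
    one_over_f_exponent : float
        Spectral exponent of the pink background (power ~ 1/f^exponent).
    background_scale : float
        RMS amplitude (uV) of the 1/f background.
    band_amplitudes : dict
        Baseline RMS amplitude (uV) of each band-limited process.
    band_gains : dict
        group -> condition -> band amplitude multipliers.
    latent_load_gain : dict
        group -> uV amplitude scale of the latent slow (1.5-4 Hz) component;
        its power grows linearly with load (amplitude = gain * sqrt(load)).
    latent_baseline : dict
        group -> constant uV amplitude of the same latent component in every
        condition.  The PD default carries the elevated, load-insensitive
        resting activity of that group: at rest PD subjects have more slow
        activity than healthy ones, and it does not move with load.
    resting_elevation : dict
        group -> broadband amplitude multiplier applied during rest blocks
        (a configuration knob; defaults are 1.0 because the resting
        elevation is carried by ``latent_baseline``).
    global_mod_sd : dict
        group -> log-amplitude SD of a slow (< ~0.1 Hz) multiplicative
        modulation shared by all neural components.  Stronger common
        modulation in the PD group yields uniformly elevated correlations
        among its component time courses — the connectivity signature the
        classifier exploits, in line with reports of increased resting
        synchrony and slowing in PD.  Normalized to unit mean-square, so it
        leaves expected band powers nearly unchanged.
    global_mod_cutoff_hz : float
        Low-pass cutoff of the shared modulation process.
    subject_gain_sd : float
        SD of the per-subject log-normal jitter on band and latent gains
        (between-subject variability; drives the mixed-model random effects).
    noise_sd : float
        White measurement noise SD in uV.
    seed : int
        Base seed; per-subject streams are spawned from it.
    """

    fs: int = 500
    one_over_f_exponent: float = 1.0
    background_scale: float = 3.0
    band_amplitudes: dict = field(default_factory=lambda: {
        "delta": 8.0, "theta": 4.0, "alpha": 3.0, "beta": 2.0, "gamma": 1.0,
    })
    band_gains: dict = field(default_factory=_default_band_gains)
    latent_load_gain: dict = field(default_factory=lambda: {
        "PD": 0.0, "healthy": 3.5,
    })
    latent_baseline: dict = field(default_factory=lambda: {
        "PD": 2.5, "healthy": 0.0,
    })
    latent_band: tuple = (1.5, 4.0)
    resting_elevation: dict = field(default_factory=lambda: {
        "PD": 1.0, "healthy": 1.0,
    })
    global_mod_sd: dict = field(default_factory=lambda: {
        "PD": 0.30, "healthy": 0.12,
    })
    global_mod_cutoff_hz: float = 0.1
    subject_gain_sd: float = 0.18
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for group in self.band_gains:
            for cond in self.band_gains[group]:
                for band, g in self.band_gains[group][cond].items():
                    if g < 0:
                        raise ValueError("band gains must be non-negative")

    def to_json(self, path: str | Path | None = None) -> str:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        text = json.dumps(d, indent=1, default=list)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass(frozen=True)
class SubjectSpec:
    subject_id: str
    group: str
    seed: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")


@dataclass
class SyntheticRecording:
    """One subject's simulated session."""

    samples: np.ndarray          # uV at config.fs
    fs: int
    labels: list[str]            # per-second condition labels
    subject_id: str
    group: str
    truth: dict                  # generator parameters actually applied

    def __post_init__(self) -> None:
        if np.any(~np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")


def _condition_envelope(labels_per_s, values_per_cond, fs, n, ramp_s=1.0):
    """Per-sample envelope from per-second condition values with cosine ramps.

    The envelope is piecewise constant per block; each value change is
    replaced by a raised-cosine crossfade of width ``ramp_s`` centred on the
    boundary, so analysis windows straddling a boundary see no discontinuity.
    """
    per_s = np.array([values_per_cond[c] for c in labels_per_s], dtype=float)
    env = np.repeat(per_s, fs)[:n].copy()
    if env.size < n:  # pad trailing partial second
        env = np.pad(env, (0, n - env.size), mode="edge")
    ramp = int(ramp_s * fs)
    if ramp > 1:
        half = ramp // 2
        fade = 0.5 * (1.0 - np.cos(np.linspace(0.0, np.pi, ramp)))
        changes = np.flatnonzero(np.diff(per_s)) + 1  # in seconds
        for sec in changes:
            p = sec * fs
            lo, hi = p - half, p - half + ramp
            if lo < 0 or hi > n:
                continue
            left, right = env[max(lo - 1, 0)], env[min(hi, n - 1)]
            env[lo:hi] = left + (right - left) * fade
    return env


def _pink_noise(rng, n, exponent, fs):
    """FFT-synthesized 1/f^(exponent/2)-amplitude Gaussian background, unit RMS."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    spec = amp * np.exp(1j * phases)
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_noise(rng, n, fs, lo, hi, guard_s: float = 16.0):
    """Unit-RMS band-limited Gaussian process (4th-order Butterworth).

    The filter is run on a guard-padded stretch of noise and the pads are
    discarded: zero-phase filtering has an edge transient of several seconds
    at low frequencies, and the session's resting blocks sit exactly at the
    recording edges, so without the guard the transient would masquerade as
    condition-dependent power.
    """
    pad = int(guard_s * fs)
    white = rng.standard_normal(n + 2 * pad)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)[pad:pad + n]
    sd = x.std()
    return x / sd if sd > 0 else x


def _slow_noise(rng, n, fs, cutoff_hz, guard_s: float = 60.0):
    """Unit-RMS low-pass Gaussian process for slow amplitude modulation."""
    pad = int(guard_s * fs)
    white = rng.standard_normal(n + 2 * pad)
    sos = signal.butter(2, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)[pad:pad + n]
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_subject(spec: SubjectSpec, schedule: ProtocolSchedule,
                     config: GeneratorConfig) -> SyntheticRecording:
    """Simulate one subject's single-channel recording over ``schedule``."""
    if not schedule.blocks:
        raise ValueError("schedule is empty")
    if config.fs <= 0:
        raise ValueError("fs must be positive")

    fs = config.fs
    duration = schedule.total_duration_s
    n = int(round(duration * fs))
    labels = [b for b in _per_second_labels(schedule)]
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, spec.seed & 0x7FFFFFFF])

    # per-subject multiplicative jitter (between-subject variability)
    jitter = {band: float(np.exp(rng.normal(0.0, config.subject_gain_sd)))
              for band in BANDS}
    latent_jitter = float(np.exp(rng.normal(0.0, config.subject_gain_sd)))

    neural = np.zeros(n)
    rest_mult = {c: (config.resting_elevation[spec.group] if c == "rest" else 1.0)
                 for c in CONDITIONS}
    for band, (lo, hi) in BANDS.items():
        base = config.band_amplitudes[band] * jitter[band]
        if base == 0:
            continue
        gains = {c: base * config.band_gains[spec.group][c][band] * rest_mult[c]
                 for c in CONDITIONS}
        if all(g == 0 for g in gains.values()):
            continue
        env = _condition_envelope(labels, gains, fs, n)
        neural += env * _band_noise(rng, n, fs, lo, hi)

    gain = config.latent_load_gain[spec.group] * latent_jitter
    base = config.latent_baseline[spec.group] * latent_jitter
    # latent power grows linearly with load on top of a constant baseline
    load_values = {c: np.hypot(gain * np.sqrt(load_level(c)), base)
                   for c in CONDITIONS}
    if any(v != 0 for v in load_values.values()):
        env = _condition_envelope(labels, load_values, fs, n)
        neural += env * _band_noise(rng, n, fs, *config.latent_band)

    mod_sd = config.global_mod_sd[spec.group] * \
        float(np.exp(rng.normal(0.0, 2.0 * config.subject_gain_sd)))
    if mod_sd > 0:
        slow = _slow_noise(rng, n, fs, config.global_mod_cutoff_hz)
        # zero log-mean: leaves log-scale (dB) outcomes unbiased by group
        neural *= np.exp(mod_sd * slow)

    x = neural
    if config.background_scale > 0:
        x = x + config.background_scale * _pink_noise(
            rng, n, config.one_over_f_exponent, fs)
    if config.noise_sd > 0:
        x = x + rng.normal(0.0, config.noise_sd, size=n)

    truth = {
        "group": spec.group,
        "jitter": jitter,
        "latent_gain": gain,
        "latent_baseline": base,
        "config_seed": config.seed,
        "subject_seed": spec.seed,
    }
    return SyntheticRecording(samples=x, fs=fs, labels=labels,
                              subject_id=spec.subject_id, group=spec.group,
                              truth=truth)


def _per_second_labels(schedule: ProtocolSchedule) -> list[str]:
    from .protocol import label_timeline
    return label_timeline(schedule, hop_s=1.0)


def generate_cohort(n_per_group: int, schedule: ProtocolSchedule,
                    config: GeneratorConfig
                    ) -> tuple[list[SyntheticRecording], pd.DataFrame]:
    """Simulate a two-group cohort (default study size: 26 per group).

    Returns the ``2 * n_per_group`` recordings and a metadata table with
    subject_id, group, age and seed.  Ages are drawn from Normal(65, 10)
    truncated to [45, 90] for metadata realism; no age effect is injected.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    meta_rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 424242])
    recordings: list[SyntheticRecording] = []
    rows = []
    idx = 0
    for group in GROUPS:
        for i in range(n_per_group):
            sid = f"{group.lower()}_{i:03d}"
            seed = int(meta_rng.integers(0, 2**31 - 1))
            age = float(np.clip(meta_rng.normal(65.0, 10.0), 45.0, 90.0))
            spec = SubjectSpec(subject_id=sid, group=group, seed=seed)
            recordings.append(generate_subject(spec, schedule, config))
            rows.append((sid, group, age, seed))
            idx += 1
    meta = pd.DataFrame(rows, columns=["subject_id", "group", "age", "seed"])
    return recordings, meta
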