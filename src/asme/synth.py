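"""Synthetic EEG generator for the speller paradigm.

Emulates the structure reported for this paradigm: target stimuli elicit an
N2 (frontal negativity ~0.3-0.5 s), a P300 (centro-parietal positivity
~0.5-0.8 s) and a late N700 negativity (~0.9-1.0 s); every stimulus drives a
steady-state response phase-locked to the stimulation rate (1/SOA); on top of
this sits spatially mixed 1/f background noise and, optionally, slow frontal
blink artifacts with matching EOG channels.

Templates are raised-cosine bumps with named channel-weight topographies (no
head model); everything superposes additively, so with the 0.2 s SOA being
shorter than the template extent, epochs neighbouring a target carry shifted
target-like waveforms, as in real recordings.  All randomness derives from a
single seed; regenerating with the same config is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .paradigm import SessionPlan, TrialSchedule

DEFAULT_CHANNELS = ("Fz", "FCz", "Cz", "CPz", "Pz", "Oz", "C3", "C4")

# named channel-weight maps (unitless, max |weight| = 1); channels absent
# from a map get weight 0
TOPOGRAPHIES: dict[str, dict[str, float]] = {
    "frontal": {"Fz": 1.0, "FCz": 0.8, "Cz": 0.5, "C3": 0.25, "C4": 0.25},
    "centroparietal": {
        "Pz": 1.0, "CPz": 0.9, "Cz": 0.7, "FCz": 0.35, "Oz": 0.4,
        "C3": 0.3, "C4": 0.3,
    },
    "central": {"Cz": 1.0, "CPz": 0.8, "FCz": 0.7, "Pz": 0.5, "C3": 0.4, "C4": 0.4},
    "auditory": {"Cz": 1.0, "FCz": 0.8, "Fz": 0.6, "C3": 0.5, "C4": 0.5, "CPz": 0.5},
}


@dataclass(frozen=True)
class ErpComponent:
    """A raised-cosine evoked component added at each target onset."""

    name: str
    center_s: float
    width_s: float
    amplitude_uV: float
    topography: str | dict[str, float] = "central"

    def weights(self, channels: Sequence[str]) -> np.ndarray:
        topo = TOPOGRAPHIES[self.topography] if isinstance(self.topography, str) else self.topography
        return np.array([float(topo.get(ch, 0.0)) for ch in channels])


def default_components() -> list[ErpComponent]:
    return [
        ErpComponent("N2", center_s=0.40, width_s=0.20, amplitude_uV=-2.0, topography="frontal"),
        ErpComponent("P300", center_s=0.65, width_s=0.30, amplitude_uV=4.0, topography="centroparietal"),
        ErpComponent("N700", center_s=0.95, width_s=0.15, amplitude_uV=-1.5, topography="central"),
    ]


@dataclass
class SynthConfig:
    fs_hz: float = 250.0
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    components: list[ErpComponent] = field(default_factory=default_components)
    ssr_amplitude_uV: float = 1.0
    ssr_topography: str | dict[str, float] = "auditory"
    noise_sigma_uV: float = 8.0
    one_over_f_exponent: float = 1.0
    latency_jitter_sd_s: float = 0.02
    eog_blink_rate_hz: float = 0.0
    eog_amplitude_uV: float = 0.0
    snr_scale: float = 1.0  # per-participant multiplier on all component amplitudes
    trial_gap_s: float = 2.0
    run_tail_s: float = 1.0
    seed: int = 0

    def scaled(self, snr_scale: float) -> "SynthConfig":
        return replace(self, snr_scale=snr_scale)


@dataclass
class Recording:
    """Continuous multichannel EEG (microvolts) with stimulus events."""

    data: np.ndarray  # channels x samples
    fs_hz: float
    channel_labels: list[str]
    events: pd.DataFrame  # events TSV columns; onset_s in recording time

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs_hz

    def eeg(self) -> "Recording":
        """Drop auxiliary (EOG) channels."""
        keep = [i for i, ch in enumerate(self.channel_labels) if not ch.startswith("EOG")]
        return Recording(
            self.data[keep], self.fs_hz, [self.channel_labels[i] for i in keep], self.events
        )


def erp_waveform(component: ErpComponent, t: np.ndarray) -> np.ndarray:
    """Raised-cosine bump: a/2 * (1 + cos(2*pi*(t - c)/w)) for |t - c| <= w/2.

    Its time integral is amplitude * width / 2.
    """
    if component.width_s <= 0:
        raise ValueError(f"width_s must be positive, got {component.width_s}")
    t = np.asarray(t, dtype=float)
    dt = t - component.center_s
    inside = np.abs(dt) <= component.width_s / 2
    out = np.zeros_like(t)
    out[inside] = (
        component.amplitude_uV
        * 0.5
        * (1.0 + np.cos(2 * np.pi * dt[inside] / component.width_s))
    )
    return out


def _one_over_f_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int, fs: float, exponent: float
) -> np.ndarray:
    """Independent unit-RMS 1/f^exponent noise sources (channels x samples)."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    ) * shape
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms


def _mixing_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random unit-row-norm spatial mixing (diagonally dominant)."""
    a = np.eye(n) + 0.4 * rng.standard_normal((n, n))
    return a / np.linalg.norm(a, axis=1, keepdims=True)


def _add_bump(data: np.ndarray, weights: np.ndarray, wave: np.ndarray, start: int) -> None:
    """Add weights[:, None] * wave into data starting at sample `start`, clipped."""
    n = data.shape[1]
    a, b = max(start, 0), min(start + wave.size, n)
    if a >= b:
        return
    data[:, a:b] += weights[:, None] * wave[a - start : b - start]


def synthesize_run(
    schedules: Sequence[TrialSchedule],
    config: SynthConfig,
    rng: np.random.Generator,
    run_idx: int = 0,
) -> Recording:
    """Render one run: trials back to back separated by ``trial_gap_s``."""
    fs = config.fs_hz
    channels = list(config.channels)
    n_ch = len(channels)
    soa = schedules[0].soa_s if schedules else 0.2

    # trial start times within the run
    starts, t0 = [], 0.0
    for sched in schedules:
        starts.append(t0)
        t0 += len(sched) * soa + config.trial_gap_s
    duration = (starts[-1] + len(schedules[-1]) * soa if schedules else 0.0) + config.run_tail_s
    n_samples = int(round(duration * fs))
    data = np.zeros((n_ch, n_samples))

    # steady-state response: one sinusoid cycle per stimulus (tiles into a
    # continuous 1/SOA-Hz oscillation during stimulation)
    ssr_w = config.ssr_amplitude_uV * ErpComponent(
        "ssr", 0, 1, 1, config.ssr_topography
    ).weights(channels)
    n_cycle = int(round(soa * fs))
    cycle = np.sin(2 * np.pi * np.arange(n_cycle) / n_cycle)

    comps = [
        (replace(c, amplitude_uV=c.amplitude_uV * config.snr_scale), c.weights(channels))
        for c in config.components
    ]

    rows = []
    for sched, tstart in zip(schedules, starts):
        for ev in sched.events:
            onset = tstart + ev.onset_s
            start = int(round(onset * fs))
            if config.ssr_amplitude_uV != 0:
                _add_bump(data, ssr_w, cycle, start)
            if ev.is_target:
                for comp, w in comps:
                    jitter = (
                        rng.normal(0.0, config.latency_jitter_sd_s)
                        if config.latency_jitter_sd_s > 0
                        else 0.0
                    )
                    # sample the continuous template on the exact time grid
                    # (latencies are not quantized to the sample grid)
                    center = onset + comp.center_s + jitter
                    i0 = max(int(np.ceil((center - comp.width_s / 2) * fs)), 0)
                    i1 = min(int(np.floor((center + comp.width_s / 2) * fs)) + 1, n_samples)
                    if i0 >= i1:
                        continue
                    t = np.arange(i0, i1) / fs
                    data[:, i0:i1] += w[:, None] * erp_waveform(
                        replace(comp, center_s=center), t
                    )[None, :]
            rows.append(
                {
                    "onset_s": onset,
                    "run": run_idx,
                    "trial": ev.trial,
                    "sequence": ev.sequence,
                    "slot": ev.slot,
                    "class_id": ev.class_id,
                    "stream": ev.stream,
                    "is_target": ev.is_target,
                    "target": sched.target,
                }
            )

    if config.noise_sigma_uV > 0:
        sources = _one_over_f_noise(rng, n_ch, n_samples, fs, config.one_over_f_exponent)
        data += config.noise_sigma_uV * (_mixing_matrix(rng, n_ch) @ sources)

    if config.eog_blink_rate_hz > 0 and config.eog_amplitude_uV != 0:
        blink = ErpComponent(
            "blink", 0.175, 0.35, config.eog_amplitude_uV, "frontal"
        )
        wave = erp_waveform(replace(blink, center_s=blink.width_s / 2),
                            np.arange(int(blink.width_s * fs) + 1) / fs)
        w = blink.weights(channels)
        eog = np.zeros(n_samples)
        n_blinks = rng.poisson(config.eog_blink_rate_hz * duration)
        for onset in np.sort(rng.uniform(0, duration - blink.width_s, size=n_blinks)):
            start = int(round(onset * fs))
            _add_bump(data, w, wave, start)
            _add_bump(eog[None, :], np.array([1.0]), wave, start)
        data = np.vstack([data, eog + rng.normal(0, 1.0, n_samples)])
        channels = channels + ["EOGv"]

    return Recording(data=data, fs_hz=fs, channel_labels=channels, events=pd.DataFrame(rows))


def synthesize_session(
    plan: SessionPlan,
    schedules: Sequence[Sequence[TrialSchedule]],
    config: SynthConfig,
) -> list[Recording]:
    """One Recording per run of the plan, deterministic under ``config.seed``."""
    if len(schedules) != len(plan.runs):
        raise ValueError("schedules inconsistent with plan")
    recs = []
    for run_idx, run_scheds in enumerate(schedules):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2, run_idx)))
        recs.append(synthesize_run(run_scheds, config, rng, run_idx=run_idx))
    return recs
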