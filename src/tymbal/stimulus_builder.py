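"""Playback stimuli for the female-preference experiment.

Five stimulus categories are used: simulated modulation cycles at 10%, 25%
and 45% duty cycle, silence (negative control, 0% DC) and band-limited white
noise (positive control, 100% DC). Each presentation is a 600 ms acoustic
emission followed by 2.4 s of silence, and a session presents every category
at least twice in seeded random order.

The stimuli here are built from the synthetic default modulation-cycle
template rather than a field-recorded exemplar, keeping the half-cycle
durations, sweep frequencies and the 4 ms inter-cycle interval fixed while
only the click count per cycle varies with the target duty cycle. Absolute
calibration (80 dB peSPL at 20 cm) is a hardware property carried as
metadata; the digital realization maps the peak sample to a configurable
dBFS level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .tymbal_model import (
    ClickEvent,
    ModulationCycle,
    Recording,
    build_modulation_cycle,
    clicks_for_duty_cycle,
    default_mc_template,
    synthesize_click,
)
from .click_analysis import DetectionConfig, _envelope

__all__ = [
    "StimulusSpec",
    "PlaybackSchedule",
    "CATEGORIES",
    "CATEGORY_DC",
    "default_specs",
    "build_stimulus",
    "make_schedule",
    "build_session",
    "measure_emission_duration",
]

CATEGORIES = ("silence", "dc10", "dc25", "dc45", "white_noise")

#: Nominal duty cycle of each category, percent.
CATEGORY_DC = {"silence": 0.0, "dc10": 10.0, "dc25": 25.0, "dc45": 45.0, "white_noise": 100.0}


@dataclass(frozen=True)
class StimulusSpec:
    """One stimulus category and its presentation framing."""

    category: str
    emission_duration: float = 0.6
    silent_interval: float = 2.4
    target_dc: Optional[float] = None
    peak_level_dbspl: float = 80.0  # peSPL at 20 cm; metadata only
    peak_level_dbfs: float = -6.0  # digital peak level re full scale
    noise_band: tuple[float, float] = (10_000.0, 100_000.0)
    noise_seed: int = 0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}; one of {CATEGORIES}")
        if self.emission_duration <= 0:
            raise ValueError("emission_duration must be > 0")
        if self.silent_interval < 0:
            raise ValueError("silent_interval must be >= 0")
        nominal = CATEGORY_DC[self.category]
        if self.target_dc is None:
            object.__setattr__(self, "target_dc", nominal)
        elif not math.isclose(self.target_dc, nominal):
            raise ValueError(
                f"target_dc {self.target_dc} inconsistent with category "
                f"{self.category} (nominal {nominal})"
            )

    @property
    def period(self) -> float:
        """Presentation period: emission plus the silent interval, seconds."""
        return self.emission_duration + self.silent_interval

    @property
    def peak_amplitude(self) -> float:
        return 10.0 ** (self.peak_level_dbfs / 20.0)


@dataclass(frozen=True)
class PlaybackSchedule:
    """Randomized presentation order of one playback session."""

    entries: tuple[tuple[int, str, float], ...]  # (presentation_index, category, onset s)
    seed: int

    def __post_init__(self) -> None:
        onsets = [e[2] for e in self.entries]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("schedule onsets must be strictly increasing")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.entries, columns=["index", "category", "onset_s"])


def default_specs() -> list[StimulusSpec]:
    return [StimulusSpec(c) for c in CATEGORIES]


def build_stimulus(
    spec: StimulusSpec,
    template: Optional[ModulationCycle] = None,
    sample_rate: float = 250_000.0,
) -> Recording:
    """Build one presentation: the 600 ms emission plus the trailing silence.

    Duty-cycle categories tile the emission with template MCs. The click
    count for the 100 ms analysis window (the scale on which stimulus duty
    cycle is defined) comes from :func:`clicks_for_duty_cycle` and is spread
    as evenly as possible over the MCs within the window, so every window
    position sees the nominal count; the last partial cycle is truncated.
    White noise spans the whole emission; silence is all zeros. The peak
    sample maps to ``spec.peak_level_dbfs``.
    """
    if template is None:
        template = default_mc_template()
    n_total = int(round(spec.period * sample_rate))
    samples = np.zeros(n_total)

    if spec.category == "silence":
        return Recording(samples, sample_rate, ground_truth=())

    if spec.category == "white_noise":
        rng = np.random.default_rng(spec.noise_seed)
        n_emit = int(round(spec.emission_duration * sample_rate))
        noise = rng.standard_normal(n_emit)
        # Band-limit by zeroing rFFT bins outside the band (flat passband).
        spectrum = np.fft.rfft(noise)
        freqs = np.fft.rfftfreq(n_emit, 1.0 / sample_rate)
        lo, hi = spec.noise_band
        spectrum[(freqs < lo) | (freqs > hi)] = 0.0
        noise = np.fft.irfft(spectrum, n_emit)
        noise *= spec.peak_amplitude / np.max(np.abs(noise))
        samples[:n_emit] = noise
        truth = (ClickEvent(0.0, spec.emission_duration, spec.peak_amplitude),)
        return Recording(samples, sample_rate, ground_truth=truth)

    # Clicking categories: tile the emission with MCs whose counts realize
    # the window-level click budget.
    click_duration = 0.0003
    analysis_window = 0.1
    mcs_per_window = max(1, int(analysis_window / template.period))
    n_window = clicks_for_duty_cycle(
        spec.target_dc, mcs_per_window * template.period, click_duration
    )
    base, extra = divmod(n_window, mcs_per_window)
    counts = [base + (1 if j < extra else 0) for j in range(mcs_per_window)]
    mcs = [build_modulation_cycle(c, template, click_duration) for c in counts]
    n_mcs = int(spec.emission_duration / template.period)
    if n_mcs < 1:
        raise ValueError("emission shorter than one modulation cycle")

    active = synthesize_click(click_duration, template.active_sweep, sample_rate, amplitude=1.0)
    passive = synthesize_click(click_duration, template.passive_sweep, sample_rate, amplitude=1.0)
    truth: list[ClickEvent] = []
    for i in range(n_mcs):
        mc_start = i * template.period
        for ev in mcs[i % mcs_per_window].clicks:
            onset = mc_start + ev.onset
            start = int(round(onset * sample_rate))
            wave = active if ev.onset < template.active_duration else passive
            stop = min(start + len(wave), n_total)
            samples[start:stop] += wave[: stop - start]
            truth.append(ClickEvent(onset, ev.duration, 1.0))
    peak = np.max(np.abs(samples))
    if peak > 0:
        samples *= spec.peak_amplitude / peak
    truth = [ClickEvent(c.onset, c.duration, spec.peak_amplitude) for c in truth]
    return Recording(samples, sample_rate, ground_truth=tuple(truth))


def make_schedule(
    specs: Sequence[StimulusSpec], repeats: int = 2, seed: int = 0
) -> tuple[PlaybackSchedule, list[StimulusSpec]]:
    """Seeded uniform shuffle of ``repeats`` presentations per category.

    Returns the schedule and the shuffled spec order it describes.
    """
    if not specs:
        raise ValueError("at least one stimulus spec is required")
    if repeats < 2:
        raise ValueError("each category must be presented at least twice (repeats >= 2)")
    rng = np.random.default_rng(seed)
    order = [s for s in specs for _ in range(repeats)]
    rng.shuffle(order)
    entries = []
    onset = 0.0
    for i, spec in enumerate(order):
        entries.append((i, spec.category, onset))
        onset += spec.period
    return PlaybackSchedule(entries=tuple(entries), seed=seed), order


def build_session(
    specs: Sequence[StimulusSpec],
    repeats: int = 2,
    seed: int = 0,
    sample_rate: float = 250_000.0,
    template: Optional[ModulationCycle] = None,
) -> tuple[PlaybackSchedule, Recording]:
    """Concatenate a session of ``repeats`` presentations per category.

    Presentation order is a uniform seeded shuffle; every category appears
    ``repeats`` (>= 2) times. Onsets step by each presentation's period.
    """
    schedule, order = make_schedule(specs, repeats, seed)

    waves = []
    truth: list[ClickEvent] = []
    onset = 0.0
    for spec in order:
        rec = build_stimulus(spec, template, sample_rate)
        waves.append(rec.samples)
        for c in rec.ground_truth or ():
            truth.append(ClickEvent(onset + c.onset, c.duration, c.peak_amplitude))
        onset += spec.period
    return schedule, Recording(np.concatenate(waves), sample_rate, ground_truth=tuple(truth))


def measure_emission_duration(
    rec: Recording, cfg: DetectionConfig = DetectionConfig()
) -> Optional[float]:
    """Supra-threshold envelope support of one emission, seconds.

    Measures the interval between the first and last envelope samples above
    the detection threshold. Returns None for silent input.
    """
    env = _envelope(rec.samples, rec.sample_rate, cfg)
    noise_floor = max(
        float(np.quantile(env, cfg.noise_quantile)) * 1.4826, cfg.min_noise_floor
    )
    above = np.flatnonzero(env > cfg.threshold_factor * noise_floor)
    if above.size == 0:
        return None
    return float((above[-1] - above[0] + 1) / rec.sample_rate)
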