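"""Tymbal acoustics: domain types and synthesis of click trains with known ground truth.

Arctiine tiger moths produce trains of short broadband ultrasonic clicks by
buckling a striated metathoracic tymbal. One flexion-plus-relaxation of the
organ is a *modulation cycle* (MC): an "active" half-cycle of clicks on the
inward buckle, a "passive" half on the outward return, then a short silent
inter-cycle interval. The fraction of time occupied by sound inside a 100 ms
analysis window — the *duty cycle* (DC) — is the trait of interest: it drives
both sonar-jamming efficacy against bats and female mate preference.

This module holds the domain types and synthesizes click trains whose click
schedule is known exactly, so downstream detection and scoring can be validated
against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ClickEvent",
    "SweepSpec",
    "ModulationCycle",
    "IndividualProfile",
    "Recording",
    "default_mc_template",
    "default_sweeps",
    "synthesize_click",
    "build_modulation_cycle",
    "clicks_for_duty_cycle",
    "synthesize_click_train",
    "max_clicks_per_mc",
]

#: Default sampling rate of the ultrasonic recording chain, Hz.
DEFAULT_SAMPLE_RATE = 250_000

#: Default tymbal click duration, seconds (0.3 ms).
DEFAULT_CLICK_DURATION = 0.0003

#: Default silent interval between successive modulation cycles, seconds (4 ms).
DEFAULT_INTER_MC_INTERVAL = 0.004

#: Default half-modulation-cycle duration, seconds. The per-species value is
#: not published; 8 ms per half gives a 20 ms MC period (5 MCs per 100 ms
#: window) and leaves room for duty cycles up to ~78% without click overlap.
DEFAULT_HALF_DURATION = 0.008

#: Relative amplitude of synthesized ground-truth clicks (of digital full scale).
DEFAULT_CLICK_AMPLITUDE = 0.8


@dataclass(frozen=True)
class ClickEvent:
    """One tymbal click: onset and duration in seconds, peak amplitude in [0, 1]."""

    onset: float
    duration: float
    peak_amplitude: float = DEFAULT_CLICK_AMPLITUDE

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"click duration must be > 0, got {self.duration}")
        if self.onset < 0:
            raise ValueError(f"click onset must be >= 0, got {self.onset}")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class SweepSpec:
    """Linear frequency sweep of one click, Hz.

    Active half-cycle clicks sweep downward, passive half-cycle clicks sweep
    upward (qualitative spectrogram structure of the tymbal sound).
    """

    start_freq: float
    end_freq: float

    def __post_init__(self) -> None:
        if self.start_freq <= 0 or self.end_freq <= 0:
            raise ValueError("sweep frequencies must be positive")

    def validate_for_rate(self, sample_rate: float) -> None:
        nyquist = sample_rate / 2.0
        if self.start_freq >= nyquist or self.end_freq >= nyquist:
            raise ValueError(
                f"sweep {self.start_freq}-{self.end_freq} Hz exceeds Nyquist "
                f"({nyquist} Hz at {sample_rate} Hz sampling)"
            )


def default_sweeps() -> tuple[SweepSpec, SweepSpec]:
    """(active, passive) sweep defaults: 90->45 kHz down, 45->90 kHz up."""
    return SweepSpec(90_000.0, 45_000.0), SweepSpec(45_000.0, 90_000.0)


@dataclass(frozen=True)
class ModulationCycle:
    """One tymbal modulation cycle.

    Clicks in ``active_half`` and ``passive_half`` carry onsets relative to the
    MC start; all active clicks precede all passive clicks, and each click fits
    inside its half. The MC period is ``active_duration + passive_duration +
    inter_mc_interval``.
    """

    active_half: tuple[ClickEvent, ...] = ()
    passive_half: tuple[ClickEvent, ...] = ()
    active_duration: float = DEFAULT_HALF_DURATION
    passive_duration: float = DEFAULT_HALF_DURATION
    inter_mc_interval: float = DEFAULT_INTER_MC_INTERVAL
    active_sweep: SweepSpec = field(default_factory=lambda: default_sweeps()[0])
    passive_sweep: SweepSpec = field(default_factory=lambda: default_sweeps()[1])

    def __post_init__(self) -> None:
        if self.inter_mc_interval < 0:
            raise ValueError("inter_mc_interval must be >= 0")
        if self.active_duration <= 0 or self.passive_duration <= 0:
            raise ValueError("half-cycle durations must be > 0")
        for ev in self.active_half:
            if ev.offset > self.active_duration + 1e-12:
                raise ValueError("active click extends past the active half")
        for ev in self.passive_half:
            if ev.onset < self.active_duration - 1e-12:
                raise ValueError("passive click precedes the passive half")
            if ev.offset > self.active_duration + self.passive_duration + 1e-12:
                raise ValueError("passive click extends past the passive half")
        _check_non_overlap(self.clicks)

    @property
    def clicks(self) -> tuple[ClickEvent, ...]:
        return tuple(sorted(self.active_half + self.passive_half, key=lambda c: c.onset))

    @property
    def period(self) -> float:
        return self.active_duration + self.passive_duration + self.inter_mc_interval


def default_mc_template() -> ModulationCycle:
    """Empty default MC template: 8 ms + 8 ms halves, 4 ms interval (20 ms period)."""
    return ModulationCycle()


@dataclass(frozen=True)
class IndividualProfile:
    """Per-male acoustic phenotype used by the synthetic-data generator."""

    species: str
    target_max_dc: float
    click_duration: float = DEFAULT_CLICK_DURATION
    mc_template: ModulationCycle = field(default_factory=default_mc_template)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.target_max_dc <= 100:
            raise ValueError("target_max_dc must be in [0, 100]")


@dataclass
class Recording:
    """A sampled waveform plus optional ground-truth click annotations."""

    samples: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE
    ground_truth: Optional[tuple[ClickEvent, ...]] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.ground_truth is not None:
            self.ground_truth = tuple(sorted(self.ground_truth, key=lambda c: c.onset))
            _check_non_overlap(self.ground_truth)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


def _check_non_overlap(clicks: Sequence[ClickEvent]) -> None:
    ordered = sorted(clicks, key=lambda c: c.onset)
    for a, b in zip(ordered, ordered[1:]):
        if b.onset < a.offset - 1e-12:
            raise ValueError(
                f"clicks overlap: [{a.onset:.6f}, {a.offset:.6f}] and onset {b.onset:.6f}"
            )


# ---------------------------------------------------------------------------
# Synthesis
# ---------------------------------------------------------------------------

def synthesize_click(
    duration: float,
    sweep: SweepSpec,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    amplitude: float = DEFAULT_CLICK_AMPLITUDE,
    damping: float = 1500.0,
    taper_fraction: float = 0.04,
) -> np.ndarray:
    """Synthesize one tymbal click as a damped, swept, tapered transient.

    The waveform is an exponentially damped sinusoid whose instantaneous
    frequency ramps linearly from ``sweep.start_freq`` to ``sweep.end_freq``,
    under a raised-cosine on/off taper so the segment begins and ends exactly
    at zero. Only the timing and duration of clicks are load-bearing for the
    duty-cycle statistics; the waveshape is a conventional transient model.

    Parameters
    ----------
    duration:
        Click duration in seconds; must be at least two sample periods.
    damping:
        Exponential decay rate (1/s). The default leaves the click tail well
        above any realistic detection threshold so the full nominal duration
        is recoverable by an envelope detector.
    taper_fraction:
        Fraction of the duration used for each of the cosine on/off ramps.
    """
    if duration < 2.0 / sample_rate:
        raise ValueError(
            f"click duration {duration} s too short for sample rate {sample_rate} Hz"
        )
    sweep.validate_for_rate(sample_rate)
    n = int(round(duration * sample_rate))
    # Sample at bin centers: the continuous taper is zero exactly at the
    # segment boundaries (no discontinuity), while every sample - including
    # the edge ones - carries a little energy, so an envelope detector can
    # recover the full nominal duration.
    t = (np.arange(n) + 0.5) / sample_rate
    # Linear frequency ramp: phase is the integral of the instantaneous frequency.
    f0, f1 = sweep.start_freq, sweep.end_freq
    phase = 2.0 * np.pi * (f0 * t + 0.5 * (f1 - f0) * t * t / duration)
    wave = np.sin(phase + 0.5 * np.pi) * np.exp(-damping * t)
    t_taper = max(2.0 / sample_rate, taper_fraction * duration)
    env = np.ones(n)
    rising = t < t_taper
    env[rising] = 0.5 * (1.0 - np.cos(np.pi * t[rising] / t_taper))
    falling = t > duration - t_taper
    env[falling] = 0.5 * (1.0 - np.cos(np.pi * (duration - t[falling]) / t_taper))
    wave *= env
    peak = np.max(np.abs(wave))
    if peak > 0:
        wave *= amplitude / peak
    return wave


def max_clicks_per_mc(template: ModulationCycle, click_duration: float) -> int:
    """Largest click count a template MC can hold without overlap."""
    return int(template.active_duration / click_duration) + int(
        template.passive_duration / click_duration
    )


def build_modulation_cycle(
    n_clicks: int,
    template: ModulationCycle,
    click_duration: float = DEFAULT_CLICK_DURATION,
    amplitude: float = DEFAULT_CLICK_AMPLITUDE,
) -> ModulationCycle:
    """Populate a template MC with ``n_clicks`` uniformly spaced clicks.

    Clicks split as evenly as possible between the halves, with an odd
    remainder going to the active half. Within each half the k clicks start at
    multiples of ``half_duration / k``, so they never overlap as long as
    ``click_duration <= half_duration / k``. Half durations, sweeps and the
    inter-MC interval are taken unchanged from the template.
    """
    if n_clicks < 0:
        raise ValueError("n_clicks must be >= 0")
    feasible = max_clicks_per_mc(template, click_duration)
    if n_clicks > feasible:
        raise ValueError(
            f"{n_clicks} clicks of {click_duration * 1e3:.3g} ms cannot fit in this "
            f"MC template without overlap; maximum feasible count is {feasible}"
        )
    n_active = (n_clicks + 1) // 2
    n_passive = n_clicks // 2

    def _fill(k: int, half_start: float, half_duration: float) -> tuple[ClickEvent, ...]:
        if k == 0:
            return ()
        spacing = half_duration / k
        return tuple(
            ClickEvent(half_start + i * spacing, click_duration, amplitude)
            for i in range(k)
        )

    return replace(
        template,
        active_half=_fill(n_active, 0.0, template.active_duration),
        passive_half=_fill(n_passive, template.active_duration, template.passive_duration),
    )


def clicks_for_duty_cycle(
    dc: float,
    window: float = 0.1,
    click_duration: float = DEFAULT_CLICK_DURATION,
) -> int:
    """Click count giving duty cycle ``dc`` (%) over ``window`` seconds.

    Inverse of the duty-cycle formula DC = click_duration x count / window:
    returns round(dc/100 x window / click_duration).
    """
    if not 0 <= dc <= 100:
        raise ValueError("dc must be in [0, 100]")
    return int(round(dc / 100.0 * window / click_duration))


def synthesize_click_train(
    profile: IndividualProfile,
    total_duration: float = 0.4,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    scoring_window: float = 0.1,
    amplitude_jitter: float = 0.08,
) -> Recording:
    """Synthesize a click-train recording for one male.

    The train ramps up in intensity the way tactile-evoked tymbal responses
    do: per-MC click counts rise from ~40% of the target to the count that
    realizes ``profile.target_max_dc`` over the final ``scoring_window`` of
    the recording, so the *maximum* sliding-window duty cycle equals the
    target phenotype. Click amplitudes are jittered per click (seeded);
    timing is deterministic, so the ground-truth schedule scores within
    +/-1 percentage point of the target.
    """
    template = profile.mc_template
    period = template.period
    if total_duration < period:
        raise ValueError("total_duration must cover at least one modulation cycle")
    rng = np.random.default_rng(profile.seed)
    n_samples = int(round(total_duration * sample_rate))
    samples = np.zeros(n_samples)

    if profile.target_max_dc <= 0:
        return Recording(samples, sample_rate, ground_truth=())

    mcs_per_window = max(1, int(scoring_window / period))
    n_target = clicks_for_duty_cycle(
        profile.target_max_dc, mcs_per_window * period, profile.click_duration
    )
    per_mc_target = int(round(n_target / mcs_per_window))
    feasible = max_clicks_per_mc(template, profile.click_duration)
    if per_mc_target > feasible:
        raise ValueError(
            f"target_max_dc={profile.target_max_dc} needs {per_mc_target} clicks per MC "
            f"but the template fits at most {feasible}"
        )

    n_mcs = int(total_duration / period)
    # Ramp: early MCs at reduced counts, the last `mcs_per_window + 1` MCs at target.
    plateau = min(n_mcs, mcs_per_window + 1)
    counts = []
    for i in range(n_mcs):
        if i >= n_mcs - plateau:
            counts.append(per_mc_target)
        else:
            frac = 0.4 + 0.6 * i / max(1, n_mcs - plateau)
            counts.append(min(per_mc_target, int(frac * per_mc_target)))

    active_click = synthesize_click(
        profile.click_duration, template.active_sweep, sample_rate, amplitude=1.0
    )
    passive_click = synthesize_click(
        profile.click_duration, template.passive_sweep, sample_rate, amplitude=1.0
    )

    truth: list[ClickEvent] = []
    for i, count in enumerate(counts):
        if count == 0:
            continue
        mc = build_modulation_cycle(count, template, profile.click_duration)
        mc_start = i * period
        for ev in mc.clicks:
            amp = DEFAULT_CLICK_AMPLITUDE * (
                1.0 + amplitude_jitter * (2.0 * rng.random() - 1.0)
            )
            amp = min(amp, 1.0)
            onset = mc_start + ev.onset
            start = int(round(onset * sample_rate))
            in_active = ev.onset < template.active_duration
            wave = active_click if in_active else passive_click
            stop = min(start + len(wave), n_samples)
            if stop <= start:
                continue
            samples[start:stop] += amp * wave[: stop - start]
            truth.append(ClickEvent(onset, ev.duration, amp))

    return Recording(samples, sample_rate, ground_truth=tuple(truth))
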