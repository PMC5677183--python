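"""Synthetic EDA recordings emulating the two-condition picture protocol.

The generator renders what the wearable would record during the affective
picture experiment: per condition, ten 6 s pictures each preceded by a
1 s blank (a 70 s segment), with a stimulus-free distractor gap between
conditions.  Conductance is built as

    g(t) = tonic(t) + (driver * bateman)(t) + noise

where the tonic is a positive band-limited (< 0.05 Hz) random drift, the
driver places one sudomotor impulse per responded picture at a latency of
1-3 s after onset, and the Bateman biexponential kernel (a standard SCR
shape from the broader EDA literature, simulation scaffolding rather than
part of the device pipeline) turns impulses into smooth SCR waveforms.
The conductance is rendered to front-end voltage through the sensor model
and quantized, so every downstream stage sees realistic device output.

Condition effects: distress pictures elicit responses more often and with
larger amplitudes than calm ones (about a 2-2.5x mean-level ratio), while
a subject-level responsiveness factor shared by both conditions makes the
classes overlap across subjects, as they do in real cohorts.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .acquisition import EDARecording, SensorConfig, conductance_to_voltage, dequantize, quantize, skin_conductance
from .decomposition import StimulusEvent, StimulusSchedule, decompose
from .features import Segment, extract_all
from .preprocessing import design_lowpass, apply_filter

__all__ = [
    "ProtocolConfig", "EffectModel", "CohortConfig", "ConditionEffect",
    "make_schedule", "simulate_driver", "bateman_kernel",
    "simulate_recording", "simulate_cohort", "segment_bounds",
]


@dataclass(frozen=True)
class ProtocolConfig:
    """Timing of the picture protocol.

    Defaults: 10 pictures of 6 s per condition, each preceded by a 1 s
    blank, hence 70 s per condition and 140 s of stimulation in total.
    ``lead_in_s`` is a quiet settling period before the first blank (it
    also absorbs the FIR start-up transient); ``distractor_gap_s``
    separates the two conditions; ``tail_s`` keeps the recording running
    briefly after the last picture so the final SCR window is not cut off
    by the record end.
    """

    n_pictures: int = 10
    picture_duration_s: float = 6.0
    blank_duration_s: float = 1.0
    conditions: tuple[str, ...] = ("distress", "calm")
    distractor_gap_s: float = 60.0
    lead_in_s: float = 5.0
    tail_s: float = 5.0

    def __post_init__(self) -> None:
        if self.n_pictures < 1:
            raise ValueError("n_pictures must be >= 1")
        if min(self.picture_duration_s, self.blank_duration_s) <= 0:
            raise ValueError("durations must be positive")
        if self.distractor_gap_s < 0 or self.lead_in_s < 0 or self.tail_s < 0:
            raise ValueError("gaps must be non-negative")

    @property
    def segment_duration_s(self) -> float:
        """Length of one condition segment: n * (blank + picture)."""
        return self.n_pictures * (self.blank_duration_s + self.picture_duration_s)

    @property
    def total_stimulus_s(self) -> float:
        """Stimulation time over all conditions, from the first screening."""
        return self.segment_duration_s * len(self.conditions)

    @property
    def total_duration_s(self) -> float:
        """Full recording length: lead-in, stimulation, gaps and tail."""
        return (self.lead_in_s + self.total_stimulus_s
                + self.distractor_gap_s * (len(self.conditions) - 1)
                + self.tail_s)


@dataclass(frozen=True)
class ConditionEffect:
    """Response statistics of one condition."""

    response_rate: float          # probability a picture elicits an SCR
    amplitude_median_us: float    # median impulse amplitude (μS)
    amplitude_sigma: float = 0.5  # log-normal shape of impulse amplitudes


@dataclass(frozen=True)
class EffectModel:
    """Physiological effect sizes driving the generator.

    Distress responses are both larger on average and far more dispersed
    than calm ones (a few large bursts rather than uniform small
    responses): the mean phasic level comes out roughly 2-2.5x higher
    under distress, and the wider amplitude spread raises the skewness of
    the distress phasic, so shape features separate the classes on an
    axis independent of overall amplitude.  ``subject_sigma`` is the
    log-normal spread of a per-subject responsiveness multiplier applied
    to both conditions of that subject; it is what makes amplitude
    features overlap between subjects.
    """

    calm: ConditionEffect = ConditionEffect(0.70, 0.45, 0.35)
    distress: ConditionEffect = ConditionEffect(0.90, 0.60, 0.85)
    latency_range_s: tuple[float, float] = (1.0, 3.0)
    tau_rise_s: float = 0.75
    tau_decay_s: float = 2.0
    tonic_level_us: tuple[float, float] = (2.0, 8.0)   # subject baseline range
    tonic_drift_us: float = 0.3                        # rms of the < 0.05 Hz drift
    tonic_max_freq_hz: float = 0.05
    noise_sigma_us: float = 0.01
    subject_sigma: float = 0.5

    def __post_init__(self) -> None:
        if not self.tau_decay_s > self.tau_rise_s > 0:
            raise ValueError("need tau_decay > tau_rise > 0")
        if self.distress.amplitude_median_us <= self.calm.amplitude_median_us:
            raise ValueError("distress amplitude scale must exceed calm")

    def for_condition(self, condition: str) -> ConditionEffect:
        if condition == "calm":
            return self.calm
        if condition == "distress":
            return self.distress
        raise ValueError(f"no effect defined for condition '{condition}'")


@dataclass(frozen=True)
class CohortConfig:
    """Enrollment and exclusion counts of the simulated cohort."""

    n_enrolled: int = 50
    n_screening_failures: int = 4
    n_technical_failures: int = 1
    n_male: int = 28
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_valid < 1:
            raise ValueError("exclusions leave no valid participants")
        if not 0 <= self.n_male <= self.n_enrolled:
            raise ValueError("n_male out of range")

    @property
    def n_valid(self) -> int:
        return self.n_enrolled - self.n_screening_failures - self.n_technical_failures


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))


def make_schedule(cfg: ProtocolConfig = ProtocolConfig(), seed: int = 0) -> tuple[StimulusSchedule, dict[str, tuple[float, float]]]:
    """Build the event schedule and per-condition segment bounds (seconds).

    Picture identities are shuffled per seed (the shuffle permutes which
    picture is shown when; timing is fixed by the protocol).  Returns the
    schedule and a dict mapping condition to its [start, end) segment.
    """
    rng = _rng(seed, 0)
    events: list[StimulusEvent] = []
    bounds: dict[str, tuple[float, float]] = {}
    t = cfg.lead_in_s
    for ci, cond in enumerate(cfg.conditions):
        if ci > 0 and cfg.distractor_gap_s > 0:
            events.append(StimulusEvent(t, cfg.distractor_gap_s, "distractor"))
            t += cfg.distractor_gap_s
        seg_start = t
        rng.permutation(cfg.n_pictures)  # picture order; identities not modelled further
        for _ in range(cfg.n_pictures):
            events.append(StimulusEvent(t, cfg.blank_duration_s, "blank"))
            t += cfg.blank_duration_s
            events.append(StimulusEvent(t, cfg.picture_duration_s, cond))
            t += cfg.picture_duration_s
        bounds[cond] = (seg_start, t)
    return StimulusSchedule(events), bounds


def segment_bounds(bounds: dict[str, tuple[float, float]], condition: str, fs: float) -> slice:
    """Sample slice of one condition segment."""
    lo, hi = bounds[condition]
    return slice(int(round(lo * fs)), int(round(hi * fs)))


def simulate_driver(
    schedule: StimulusSchedule,
    effect: EffectModel,
    condition: str,
    fs: float,
    n_samples: int,
    seed: int = 0,
    subject_gain: float = 1.0,
) -> np.ndarray:
    """Sparse non-negative sudomotor impulse train for one condition.

    Each picture of the given condition elicits, with the condition's
    response rate, a single impulse at onset + U[1, 3] s latency with a
    log-normal amplitude, snapped to the sample grid.
    """
    rng = _rng(seed, zlib.crc32(condition.encode()) & 0x7FFFFFFF)
    eff = effect.for_condition(condition)
    driver = np.zeros(n_samples)
    lo, hi = effect.latency_range_s
    for ev in schedule.pictures():
        if ev.condition != condition:
            continue
        if rng.random() >= eff.response_rate:
            continue
        latency = rng.uniform(lo, hi)
        amp = eff.amplitude_median_us * subject_gain * rng.lognormal(0.0, eff.amplitude_sigma)
        idx = int(round((ev.onset_s + latency) * fs))
        if 0 <= idx < n_samples:
            driver[idx] += amp
    return driver


def bateman_kernel(tau_rise: float = 0.75, tau_decay: float = 2.0,
                   fs: float = 10.0, duration_s: float = 20.0) -> np.ndarray:
    """Unit-area biexponential SCR kernel exp(-t/τd) - exp(-t/τr)."""
    if not tau_decay > tau_rise > 0:
        raise ValueError("need tau_decay > tau_rise > 0")
    t = np.arange(int(round(duration_s * fs))) / fs
    k = np.exp(-t / tau_decay) - np.exp(-t / tau_rise)
    return k / (k.sum() / fs)


def _tonic_drift(n: int, fs: float, max_freq: float, rms: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Zero-mean drift synthesised strictly below ``max_freq`` Hz."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = np.zeros(len(freqs), dtype=complex)
    band = (freqs > 0) & (freqs < max_freq)
    k = int(band.sum())
    if k == 0:
        return np.zeros(n)
    spec[band] = rng.normal(size=k) + 1j * rng.normal(size=k)
    drift = np.fft.irfft(spec, n=n)
    sd = drift.std()
    return drift * (rms / sd) if sd > 0 else drift


def simulate_recording(
    schedule: StimulusSchedule,
    effect: EffectModel = EffectModel(),
    sensor: SensorConfig = SensorConfig(),
    duration_s: Optional[float] = None,
    seed: int = 0,
    subject_gain: float = 1.0,
    subject_id: Optional[str] = None,
) -> tuple[EDARecording, dict]:
    """Render one full-protocol recording as raw ADC output.

    Returns the raw recording (unit ``adc_code``) and a ground-truth dict
    with the clean conductance, tonic, driver (per condition and summed)
    and the clipped-sample count, for recovery tests.
    """
    fs = sensor.fs
    if duration_s is None:
        last = schedule.events[-1]
        duration_s = last.onset_s + last.duration_s
    n = int(round(duration_s * fs))
    rng = _rng(seed, 1)
    level = rng.uniform(*effect.tonic_level_us)
    tonic = level + _tonic_drift(n, fs, effect.tonic_max_freq_hz, effect.tonic_drift_us, rng)
    tonic = np.maximum(tonic, 0.1)

    conditions = sorted({e.condition for e in schedule.pictures()})
    drivers = {c: simulate_driver(schedule, effect, c, fs, n, seed=seed, subject_gain=subject_gain)
               for c in conditions}
    driver = np.sum(list(drivers.values()), axis=0) if drivers else np.zeros(n)
    # driver weights are SCR areas in μS·s; the unit-area kernel turns a
    # weight A into a bump of peak ~0.28*A μS at the default time constants
    kernel = bateman_kernel(effect.tau_rise_s, effect.tau_decay_s, fs)
    phasic = np.convolve(driver, kernel)[:n]
    g = tonic + phasic + rng.normal(0.0, effect.noise_sigma_us, size=n)
    g = np.maximum(g, 1e-3)

    v = np.asarray(conductance_to_voltage(g, sensor)) * sensor.gain
    raw, n_clipped = quantize(np.asarray(v), sensor)
    raw.subject_id = subject_id
    truth = {"conductance": g, "tonic": tonic, "driver": driver,
             "drivers": drivers, "phasic": phasic, "n_clipped": n_clipped}
    return raw, truth


def recording_to_conductance(raw: EDARecording, sensor: SensorConfig) -> EDARecording:
    """Convert a raw ADC recording back to conductance in μS."""
    volts = dequantize(raw, sensor)
    g = np.asarray(skin_conductance(volts.samples / sensor.gain, sensor))
    return EDARecording(samples=g, fs=raw.fs, unit="microsiemens",
                        subject_id=raw.subject_id, condition=raw.condition)


def simulate_cohort(
    cohort: CohortConfig = CohortConfig(),
    protocol: ProtocolConfig = ProtocolConfig(),
    effect: EffectModel = EffectModel(),
    sensor: SensorConfig = SensorConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the whole experiment and extract the labelled feature table.

    Enrolls ``n_enrolled`` subjects, removes the configured screening and
    technical failures (logged with reasons), then runs every valid
    subject through the full chain: raw recording -> conductance -> FIR
    filter -> decomposition -> per-condition features.  Returns the
    feature table (one row per subject x condition) and the exclusion log.
    """
    rng = _rng(cohort.seed, 2)
    sexes = np.array(["M"] * cohort.n_male + ["F"] * (cohort.n_enrolled - cohort.n_male))
    subjects = [f"S{i:03d}" for i in range(1, cohort.n_enrolled + 1)]
    n_excl = cohort.n_screening_failures + cohort.n_technical_failures
    excluded = rng.choice(cohort.n_enrolled, size=n_excl, replace=False)
    reasons = (["screening questionnaire not passed"] * cohort.n_screening_failures
               + ["technical failure during acquisition"] * cohort.n_technical_failures)
    log = pd.DataFrame({"subject_id": [subjects[i] for i in excluded],
                        "sex": sexes[excluded], "reason": reasons})
    valid = [i for i in range(cohort.n_enrolled) if i not in set(excluded)]

    filt = design_lowpass(fs=sensor.fs)
    rows = []
    for i in valid:
        sid = subjects[i]
        subj_seed = (cohort.seed * 100003 + i) % (2**31 - 1)
        schedule, bounds = make_schedule(protocol, seed=subj_seed)
        subj_rng = _rng(cohort.seed, 3, i)
        gain = float(subj_rng.lognormal(0.0, effect.subject_sigma))
        raw, _ = simulate_recording(schedule, effect, sensor,
                                    duration_s=protocol.total_duration_s,
                                    seed=subj_seed,
                                    subject_gain=gain, subject_id=sid)
        g = recording_to_conductance(raw, sensor)
        filtered = apply_filter(g, filt)
        dec = decompose(filtered, schedule)
        for cond in protocol.conditions:
            seg = Segment(dec.phasic[segment_bounds(bounds, cond, sensor.fs)],
                          fs=sensor.fs, condition=cond, subject_id=sid)
            fv = extract_all(seg)
            rows.append({"subject_id": sid, "condition": cond, "sex": sexes[i],
                         **fv.as_dict()})
    table = pd.DataFrame(rows)
    return table, log
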