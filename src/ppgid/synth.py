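"""Synthetic multi-subject PPG dataset generator.

Real PPG acquisition is replaced by a parametric beat model: each subject is
a :class:`SubjectProfile` — a draw of beat-template parameters (heart period,
landmark positions/amplitudes, baseline, timing jitter) that acts as the
biometric identity. One beat is a sum of three Gaussian bumps reproducing
the canonical PPG landmarks: the systolic peak (global maximum), the
dicrotic notch (a local minimum after systole) and the diastolic peak.
Signals concatenate jittered beats, add baseline and Gaussian sensor noise,
and quantize to 18-bit ADC counts in [0, 262143].

Determinism: one root ``SeedSequence`` per dataset, spawned per subject, so
adding subjects never perturbs previously generated ones.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .types import ADC_BITS_DEFAULT, LabelledDataset, PpgSignal, Record

__all__ = [
    "SubjectProfile",
    "GeneratorConfig",
    "make_subject_profile",
    "synth_beat",
    "synth_signal",
    "build_dataset",
]

# Uniform draw ranges for subject parameters. Wide enough that default
# sensor noise does not erase identity; narrow enough to stay physiological.
PROFILE_RANGES = {
    "heart_period": (0.65, 1.10),  # s; resting heart rate ~55-92 bpm
    "systolic_amp": (0.75, 1.00),
    "systolic_pos": (0.20, 0.30),  # fraction of beat
    "systolic_width": (0.040, 0.070),  # s
    "dicrotic_amp": (0.12, 0.32),
    "dicrotic_pos": (0.44, 0.54),
    "diastolic_amp": (0.25, 0.50),
    "diastolic_pos": (0.64, 0.78),
    "baseline_level": (50_000.0, 120_000.0),  # ADC counts
}
JITTER_SD_DEFAULT = 0.01  # s, per-beat timing jitter

MIN_SAMPLES_PER_BEAT = 10


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject beat-template parameters (the biometric identity)."""

    subject_id: str
    heart_period: float  # s
    systolic_amp: float  # relative, (0, 1]
    systolic_pos: float  # fraction of beat
    systolic_width: float  # s
    dicrotic_amp: float
    dicrotic_pos: float
    diastolic_amp: float
    diastolic_pos: float
    baseline_level: float  # ADC counts
    jitter_sd: float = JITTER_SD_DEFAULT  # s

    def __post_init__(self) -> None:
        if not (0.0 < self.systolic_pos < self.dicrotic_pos < self.diastolic_pos < 1.0):
            raise ValueError("landmark positions must satisfy 0 < sys < dicrotic < dia < 1")
        if self.systolic_amp < self.dicrotic_amp or self.systolic_amp < self.diastolic_amp:
            raise ValueError("systolic amplitude must dominate the beat")
        if not (0.5 <= self.heart_period <= 1.5):
            raise ValueError("heart_period outside physiological resting range [0.5, 1.5] s")
        if self.systolic_width <= 0 or self.jitter_sd < 0:
            raise ValueError("widths must be positive, jitter non-negative")


@dataclass(frozen=True)
class GeneratorConfig:
    """Dataset-level knobs: cardinalities, rates, noise and the seed."""

    n_subjects: int = 40
    signals_per_subject: int = 80
    signal_length: int = 300
    sampling_rate: float = 50.0  # Hz; 300 samples ~ 6 s ~ 5-8 beats
    noise_sd: float = 800.0  # ADC counts
    pulse_scale: float = 100_000.0  # ADC counts per unit relative amplitude
    adc_bits: int = ADC_BITS_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.signals_per_subject, self.signal_length) <= 0:
            raise ValueError("counts must be positive")
        if self.noise_sd < 0 or self.sampling_rate <= 0 or self.pulse_scale <= 0:
            raise ValueError("noise_sd >= 0 and positive rate/scale required")


def make_subject_profile(rng: np.random.Generator, subject_id: str = "S00") -> SubjectProfile:
    """Draw one subject's beat-template parameters from the uniform ranges.

    Parameter order of the draws is fixed, so a fixed generator state yields
    a reproducible profile.
    """
    draws = {name: rng.uniform(lo, hi) for name, (lo, hi) in PROFILE_RANGES.items()}
    # amplitude ordering is guaranteed by the ranges, position ordering too
    return SubjectProfile(subject_id=subject_id, jitter_sd=JITTER_SD_DEFAULT, **draws)


def synth_beat(profile: SubjectProfile, sampling_rate: float) -> np.ndarray:
    """Render one beat of ``round(heart_period * sampling_rate)`` samples.

    The beat is the sum of three Gaussian bumps at the systolic, dicrotic
    and diastolic landmark positions, in relative amplitude units (systolic
    bump has height ``systolic_amp``).
    """
    n = int(round(profile.heart_period * sampling_rate))
    if n < MIN_SAMPLES_PER_BEAT:
        raise ValueError(
            f"sampling rate {sampling_rate} Hz yields {n} samples/beat; "
            f"need >= {MIN_SAMPLES_PER_BEAT} to resolve the landmarks"
        )
    t = np.arange(n) / sampling_rate  # seconds within the beat
    period = profile.heart_period
    width = profile.systolic_width
    beat = np.zeros(n)
    for amp, pos, w in (
        (profile.systolic_amp, profile.systolic_pos, width),
        (profile.dicrotic_amp, profile.dicrotic_pos, width),
        (profile.diastolic_amp, profile.diastolic_pos, 1.2 * width),
    ):
        if amp > 0:
            beat += amp * np.exp(-0.5 * ((t - pos * period) / w) ** 2)
    return beat


def synth_signal(
    profile: SubjectProfile,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> PpgSignal:
    """Assemble a raw signal: jittered beats + baseline + noise, quantized.

    Beat periods are jittered per beat by ``N(0, jitter_sd)`` (truncated so a
    beat never collapses), beats are concatenated, scaled to ADC counts by
    ``config.pulse_scale``, offset by the subject baseline, contaminated with
    i.i.d. Gaussian noise of ``config.noise_sd`` counts, clipped to the ADC
    range and rounded to integers.
    """
    fs = config.sampling_rate
    length = config.signal_length
    pieces: list[np.ndarray] = []
    total = 0
    while total < length:
        jitter = rng.normal(0.0, profile.jitter_sd) if profile.jitter_sd > 0 else 0.0
        period = max(0.5, min(1.5, profile.heart_period + jitter))
        beat = synth_beat(dataclasses.replace(profile, heart_period=period), fs)
        pieces.append(beat)
        total += beat.size
    rel = np.concatenate(pieces)[:length]

    counts = profile.baseline_level + config.pulse_scale * rel
    if config.noise_sd > 0:
        counts = counts + rng.normal(0.0, config.noise_sd, size=length)
    hi = 2**config.adc_bits - 1
    counts = np.clip(np.rint(counts), 0, hi).astype(np.int64)
    return PpgSignal(
        samples=counts,
        sampling_rate=fs,
        subject_id=profile.subject_id,
        adc_bits=config.adc_bits,
        provenance="raw",
    )


def subject_rngs(config: GeneratorConfig) -> list[np.random.Generator]:
    """One independent, reproducible stream per subject."""
    root = np.random.SeedSequence(config.seed)
    return [np.random.Generator(np.random.PCG64(s)) for s in root.spawn(config.n_subjects)]


def build_dataset(config: GeneratorConfig) -> LabelledDataset:
    """Generate the full labelled dataset: n_subjects x signals_per_subject.

    The manifest records the generating configuration; record ids are
    ``<subject>_r<index>``.
    """
    records: list[Record] = []
    profiles: dict[str, SubjectProfile] = {}
    for i, rng in enumerate(subject_rngs(config)):
        sid = f"S{i:02d}"
        profile = make_subject_profile(rng, subject_id=sid)
        profiles[sid] = profile
        for j in range(config.signals_per_subject):
            sig = synth_signal(profile, config, rng)
            records.append(
                Record(
                    payload=sig,
                    subject_id=sid,
                    record_id=f"{sid}_r{j:03d}",
                    provenance="raw",
                )
            )
    manifest = {"config": dataclasses.asdict(config), "profiles": {
        sid: dataclasses.asdict(p) for sid, p in profiles.items()
    }}
    return LabelledDataset(records, manifest=manifest)
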