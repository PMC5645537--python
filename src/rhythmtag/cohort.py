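"""Synthetic EEG cohorts for rhythm-imagery frequency tagging.

This module simulates the kind of dataset produced by a visually cued
rhythm-imagery experiment: participants watch a silent movie whose events
recur at a 2.4 Hz beat rate and either simply view it (``marker_viewing``)
or imagine an unaccented beat, a binary (strong-weak) meter, or a ternary
(strong-weak-weak) meter locked to that beat.  Each imagined rhythm is
modelled as a steady-state evoked potential: a sum of sinusoids at the
meter fundamental (2.4, 1.2 or 0.8 Hz) and its harmonics, with amplitudes
decaying as ``h**-gamma`` in the harmonic number ``h``.  A visual response
at the beat rate, concentrated over occipital electrodes, and per-channel
1/f^beta background noise complete the forward model.

Per-subject log-normal gains and per-trial phase jitter provide the
between-subject and between-trial variability that the downstream rank
tests and classifiers need.  All randomness derives from a single integer
seed; a cohort is bit-reproducible from its configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DEFAULT_CHANNELS",
    "Montage",
    "StimulusTiming",
    "Condition",
    "CONDITIONS",
    "IMAGERY_CONDITIONS",
    "HarmonicTable",
    "CohortConfig",
    "TrialRecording",
    "CohortDataset",
    "make_montage",
    "condition_components",
    "generate_trial",
    "generate_cohort",
]

# 30-channel 10-10 montage used throughout; order is significant (data rows
# follow it).
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "AF3", "AF4", "F3", "F4", "F7", "F8", "Fz",
    "FC1", "FC2", "FC5", "FC6", "T7", "T8", "C3", "C4", "Cz",
    "CP1", "CP2", "CP5", "CP6", "P3", "P4", "P7", "P8",
    "PO3", "PO4", "O1", "O2",
)

_OCCIPITAL: tuple[str, ...] = ("PO3", "PO4", "O1", "O2")
_FRONTAL_PAIR: tuple[str, ...] = ("Fp1", "Fp2")
# Prefrontal/frontal rows; imagery components are emphasised here so that a
# spatial contrast survives common-average referencing (a perfectly uniform
# topography would be cancelled exactly by the reference).
_FRONTAL_REGION: tuple[str, ...] = (
    "Fp1", "Fp2", "AF3", "AF4", "F3", "F4", "F7", "F8", "Fz",
)


@dataclass(frozen=True)
class Montage:
    """Named electrode set with the channel groupings the analysis uses."""

    channel_names: tuple[str, ...]
    occipital: tuple[str, ...]
    frontal_pair: tuple[str, ...]

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def non_occipital(self) -> tuple[str, ...]:
        occ = set(self.occipital)
        return tuple(c for c in self.channel_names if c not in occ)

    def group(self, name: str) -> tuple[str, ...]:
        """Resolve a group name (``all``/``occipital``/``non_occipital``/``frontal_pair``)."""
        if name == "all":
            return self.channel_names
        if name == "occipital":
            return self.occipital
        if name == "non_occipital":
            return self.non_occipital
        if name == "frontal_pair":
            return self.frontal_pair
        raise KeyError(f"unknown channel group: {name!r}")

    def indices(self, labels: Iterable[str]) -> np.ndarray:
        """Row indices of ``labels`` in montage order."""
        pos = {c: i for i, c in enumerate(self.channel_names)}
        try:
            return np.array([pos[l] for l in labels], dtype=int)
        except KeyError as exc:
            raise KeyError(f"channel {exc.args[0]!r} not in montage") from None


def make_montage(channel_names: Sequence[str] | None = None) -> Montage:
    """Build a montage; the default is the 30-channel 10-10 layout.

    Occipital and frontal-pair groups are the intersections of the standard
    group labels with the supplied channels.
    """
    names = tuple(channel_names) if channel_names is not None else DEFAULT_CHANNELS
    if len(set(names)) != len(names):
        raise ValueError("montage channel labels must be unique")
    occ = tuple(c for c in names if c in _OCCIPITAL)
    fp = tuple(c for c in names if c in _FRONTAL_PAIR)
    return Montage(channel_names=names, occipital=occ, frontal_pair=fp)


@dataclass(frozen=True)
class StimulusTiming:
    """Timing of the pacing movie and of the analysis epoch.

    beat_frequency is exactly 2.4 Hz by default: the 416 ms inter-onset
    interval of the movie is a display rounding of 416.67 ms, and the exact
    value keeps every rhythm component centred on the 0.1 Hz analysis grid.
    """

    beat_frequency: float = 2.4          # Hz
    inter_onset_interval_ms: float = 416.0  # display value, informational
    movie_duration: float = 12.0         # s
    epoch_duration: float = 10.0         # s
    pre_roll: float = 2.0                # s of recording before the first beat

    def __post_init__(self) -> None:
        if self.beat_frequency <= 0:
            raise ValueError("beat_frequency must be positive")
        if self.epoch_duration > self.movie_duration:
            raise ValueError("epoch_duration cannot exceed movie_duration")
        if self.movie_duration <= 0 or self.pre_roll < 0:
            raise ValueError("invalid movie_duration / pre_roll")

    @property
    def trial_duration(self) -> float:
        return self.pre_roll + self.movie_duration


@dataclass(frozen=True)
class Condition:
    """A task condition: pure viewing, or imagery with a metric period.

    ``meter_period`` is the number of beats per metric cycle (1 for the
    unaccented beat, 2 binary, 3 ternary) and is None for marker viewing.
    """

    name: str
    meter_period: int | None

    @property
    def is_imagery(self) -> bool:
        return self.meter_period is not None

    def meter_frequency(self, beat_frequency: float) -> float:
        if self.meter_period is None:
            raise ValueError(f"{self.name} has no meter frequency")
        return beat_frequency / self.meter_period


CONDITIONS: dict[str, Condition] = {
    "marker_viewing": Condition("marker_viewing", None),
    "unaccented_beat": Condition("unaccented_beat", 1),
    "binary_meter": Condition("binary_meter", 2),
    "ternary_meter": Condition("ternary_meter", 3),
}
IMAGERY_CONDITIONS: tuple[str, ...] = ("unaccented_beat", "binary_meter", "ternary_meter")


def _as_condition(condition: Condition | str) -> Condition:
    if isinstance(condition, Condition):
        return condition
    try:
        return CONDITIONS[condition]
    except KeyError:
        raise ValueError(f"unknown condition: {condition!r}") from None


@dataclass(frozen=True)
class HarmonicTable:
    """Frequencies and relative amplitudes of one condition's SSEP components."""

    entries: tuple[tuple[float, float], ...]  # (frequency Hz, relative amplitude)
    decay_exponent: float = 1.0

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([f for f, _ in self.entries])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([a for _, a in self.entries])

    def amplitude_at(self, frequency: float, tol: float = 1e-9) -> float:
        for f, a in self.entries:
            if abs(f - frequency) <= tol:
                return a
        raise KeyError(f"no component at {frequency} Hz")


def condition_components(
    condition: Condition | str,
    timing: StimulusTiming,
    decay_exponent: float = 1.0,
    cutoff_hz: float = 5.0,
) -> HarmonicTable:
    """Imagery component table of a condition: harmonics of the meter frequency.

    Harmonic ``h`` of the fundamental ``f0 = beat / meter_period`` enters with
    relative amplitude ``h**-decay_exponent``, up to ``cutoff_hz``.  Marker
    viewing has no imagery component and returns an empty table.
    """
    cond = _as_condition(condition)
    if timing.beat_frequency <= 0:
        raise ValueError("beat frequency must be positive")
    if decay_exponent < 0:
        raise ValueError("decay exponent must be >= 0")
    if not cond.is_imagery:
        return HarmonicTable(entries=(), decay_exponent=decay_exponent)
    f0 = cond.meter_frequency(timing.beat_frequency)
    n_harm = int(np.floor(cutoff_hz / f0 + 1e-9))
    entries = tuple(
        (h * f0, float(h) ** (-decay_exponent)) for h in range(1, max(n_harm, 1) + 1)
    )
    return HarmonicTable(entries=entries, decay_exponent=decay_exponent)


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration.  Amplitudes in µV, frequencies in Hz.

    Defaults emulate the study design: 9 subjects x 4 conditions x 20 trials.
    Amplitude defaults place single-trial classification between chance and
    ceiling (no established µV scale exists for imagery SSEPs).
    """

    n_subjects: int = 9
    n_trials: int = 20
    sampling_rate: float = 250.0
    imagery_amplitude: float = 3.5       # µV at the meter fundamental
    visual_amplitude: float = 1.5        # µV at the beat frequency
    occipital_concentration: float = 0.6  # fraction of visual energy on occipital
    noise_amplitude: float = 10.0        # µV RMS per channel
    noise_exponent: float = 1.0          # beta of 1/f^beta
    subject_gain_sd: float = 0.3         # sd of log gain (log-normal, median 1)
    phase_jitter_sd: float = 0.2         # radians
    harmonic_decay: float = 1.0          # gamma of h**-gamma
    harmonic_cutoff_hz: float = 5.0
    frontal_emphasis: float = 1.0        # extra imagery weight on frontal channels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials < 1:
            raise ValueError("n_subjects and n_trials must be >= 1")
        for name in ("imagery_amplitude", "visual_amplitude", "noise_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.occipital_concentration <= 1.0:
            raise ValueError("occipital_concentration must be in [0, 1]")
        if self.subject_gain_sd < 0 or self.phase_jitter_sd < 0:
            raise ValueError("spread parameters must be >= 0")
        if self.harmonic_decay < 0:
            raise ValueError("harmonic_decay must be >= 0")
        if self.frontal_emphasis < 0:
            raise ValueError("frontal_emphasis must be >= 0")
        highest = max(self.harmonic_cutoff_hz, 2.4)
        if self.sampling_rate <= 2 * highest:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} Hz violates the Nyquist bound "
                f"for components up to {highest} Hz"
            )


@dataclass
class TrialRecording:
    """One trial: a channels-by-samples matrix (µV) plus its metadata.

    ``onset_index`` is the sample of the first beat onset; rhythm components
    are phase-locked to it (up to the configured jitter).
    """

    subject_id: int
    condition: str
    data: np.ndarray          # (n_channels, n_samples), float32, µV
    sampling_rate: float
    onset_index: int
    trial_index: int = 0

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("trial data must be 2-D (channels x samples)")
        if not 0 <= self.onset_index < self.data.shape[1]:
            raise ValueError("onset_index out of range")


def _visual_weights(montage: Montage, concentration: float) -> np.ndarray:
    """Per-channel weights of the visual component.

    Squared weights sum so that the occipital share of total visual energy is
    exactly ``concentration``; the mean squared weight is 1, keeping the
    configured amplitude interpretable as a typical per-channel amplitude.
    """
    n = montage.n_channels
    occ_idx = montage.indices(montage.occipital)
    n_occ = len(occ_idx)
    n_non = n - n_occ
    w = np.empty(n)
    if n_occ:
        w[:] = np.sqrt((1.0 - concentration) * n / n_non) if n_non else 0.0
        w[occ_idx] = np.sqrt(concentration * n / n_occ)
    else:
        w[:] = 1.0
    return w


def _pink_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int,
    beta: float, sampling_rate: float, rms: float,
) -> np.ndarray:
    """1/f^beta noise by spectral shaping of white Gaussian noise."""
    white = rng.standard_normal((n_channels, n_samples))
    if rms == 0:
        return np.zeros((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sampling_rate)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-beta / 2.0)  # amplitude shaping -> power 1/f^beta
    x = np.fft.irfft(spec * shape, n=n_samples, axis=1)
    std = x.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return x * (rms / std)


def generate_trial(
    subject_gain: float,
    condition: Condition | str,
    config: CohortConfig,
    timing: StimulusTiming,
    rng: np.random.Generator,
    montage: Montage | None = None,
    subject_id: int = 0,
    trial_index: int = 0,
) -> TrialRecording:
    """Simulate one trial of the experiment.

    The recording spans ``pre_roll + movie_duration`` seconds; the rhythm and
    visual components start phase-zero at the onset sample (plus a per-trial
    phase offset drawn from N(0, phase_jitter_sd^2)).
    """
    cond = _as_condition(condition)
    montage = montage or make_montage()
    fs = config.sampling_rate
    n_samples = int(round(timing.trial_duration * fs))
    onset = int(round(timing.pre_roll * fs))
    t = (np.arange(n_samples) - onset) / fs

    # rng draw order is fixed so that trials are reproducible irrespective of
    # which components are switched off
    phase_imagery = rng.normal(0.0, config.phase_jitter_sd)
    phase_visual = rng.normal(0.0, config.phase_jitter_sd)

    data = np.zeros((montage.n_channels, n_samples))

    table = condition_components(
        cond, timing, config.harmonic_decay, config.harmonic_cutoff_hz
    )
    if cond.is_imagery and config.imagery_amplitude > 0 and table.entries:
        sig = np.zeros(n_samples)
        for f, rel in table.entries:
            sig += rel * np.sin(2 * np.pi * f * t + phase_imagery)
        # widespread topography with frontal emphasis; emphasis 0 = uniform
        w_im = np.ones(montage.n_channels)
        if config.frontal_emphasis:
            frontal = [c for c in _FRONTAL_REGION if c in montage.channel_names]
            if frontal:
                w_im[montage.indices(frontal)] += config.frontal_emphasis
        data += config.imagery_amplitude * subject_gain * w_im[:, None] * sig

    if config.visual_amplitude > 0:
        w = _visual_weights(montage, config.occipital_concentration)
        vis = np.sin(2 * np.pi * timing.beat_frequency * t + phase_visual)
        data += config.visual_amplitude * subject_gain * w[:, None] * vis

    data += _pink_noise(
        rng, montage.n_channels, n_samples,
        config.noise_exponent, fs, config.noise_amplitude,
    )

    return TrialRecording(
        subject_id=subject_id,
        condition=cond.name,
        data=data.astype(np.float32),
        sampling_rate=fs,
        onset_index=onset,
        trial_index=trial_index,
    )


@dataclass
class CohortDataset:
    """A full simulated cohort: trials plus montage, timing and provenance."""

    trials: list[TrialRecording]
    montage: Montage
    timing: StimulusTiming
    config: CohortConfig
    subject_gains: dict[int, float] = field(default_factory=dict)

    @property
    def subjects(self) -> list[int]:
        return sorted({tr.subject_id for tr in self.trials})

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for tr in self.trials:
            if tr.condition not in seen:
                seen.append(tr.condition)
        return seen

    def select(
        self, subject_id: int | None = None, condition: str | None = None
    ) -> list[TrialRecording]:
        out = self.trials
        if subject_id is not None:
            out = [tr for tr in out if tr.subject_id == subject_id]
        if condition is not None:
            out = [tr for tr in out if tr.condition == condition]
        return out


# Canonical condition order; fixed so that trial RNG streams do not depend on
# which subset of conditions is simulated.
_CONDITION_INDEX = {name: i for i, name in enumerate(CONDITIONS)}


def generate_cohort(
    config: CohortConfig,
    timing: StimulusTiming | None = None,
    conditions: Sequence[str] | None = None,
    montage: Montage | None = None,
) -> CohortDataset:
    """Simulate the whole cohort: every subject x condition x trial.

    Per-subject gains are drawn once per subject (log-normal, median 1).
    Every trial has its own RNG stream keyed by (seed, subject, condition,
    trial), so a subset simulation reproduces exactly the trials it shares
    with the full one.
    """
    timing = timing or StimulusTiming()
    montage = montage or make_montage()
    names = list(conditions) if conditions is not None else list(CONDITIONS)
    for name in names:
        _as_condition(name)

    gain_rng = np.random.default_rng([config.seed, 1])
    gains = {
        s: float(np.exp(gain_rng.normal(0.0, config.subject_gain_sd)))
        for s in range(config.n_subjects)
    }

    trials: list[TrialRecording] = []
    for s in range(config.n_subjects):
        for name in names:
            c_idx = _CONDITION_INDEX[name]
            for k in range(config.n_trials):
                rng = np.random.default_rng([config.seed, 2, s, c_idx, k])
                trials.append(
                    generate_trial(
                        gains[s], name, config, timing, rng,
                        montage=montage, subject_id=s, trial_index=k,
                    )
                )
    return CohortDataset(
        trials=trials, montage=montage, timing=timing, config=config,
        subject_gains=gains,
    )
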