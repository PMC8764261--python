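"""Seeded generator of DEAP-structured synthetic affective EEG.

Each trial is a sum of band-limited oscillatory sources (filtered white
noise, one per canonical EEG band), 1/f pink background noise, and
Poisson-timed ocular (blink) pulses with a front-to-back decaying scalp
topography.  Emotion classes differ by *planted connectivity*: channel
groups named in a :class:`CouplingSpec` share a common band-limited source
with mixing weight kappa, so the ground-truth class is recoverable from
inter-channel association in the planted band — the property every
downstream stage (MI networks, graph metrics, classification) is tested
against.

Ratings are drawn around the quadrant centroid of the true class
(e.g. HVHA -> valence 7, arousal 7) with Gaussian noise and a per-subject
bias, clipped to the 1-9 scale, emulating self-assessment labels.

Determinism: every random draw derives from ``SeedSequence([seed,
subject_index, trial_index, stream])``, so regenerating a subset of
subjects never reshuffles the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .core import (
    BandSet,
    EmotionLabels,
    Montage,
    QUADRANTS,
    Recording,
    TrialSet,
    ValidationError,
)

__all__ = [
    "CouplingEntry",
    "CouplingSpec",
    "SimConfig",
    "GroundTruth",
    "default_montage",
    "default_coupling",
    "generate_trial",
    "generate_dataset",
    "write_ground_truth_json",
    "read_ground_truth_json",
]

# valence/arousal centroids of the four quadrant classes on the 1-9 scale
CLASS_CENTROIDS = {
    "HVHA": (7.0, 7.0),
    "HVLA": (7.0, 3.0),
    "LVHA": (3.0, 7.0),
    "LVLA": (3.0, 3.0),
}

# front-to-back depth used for the exponentially decaying blink topography
_REGION_DEPTH = {"frontal": 0.0, "central": 1.0, "temporal": 1.5,
                 "parietal": 2.0, "occipital": 3.0}
BLINK_DURATION_S = 0.3


@dataclass(frozen=True)
class CouplingEntry:
    """One planted coupling: channels *i* and *j* share a source in *band*.

    kappa is the shared-variance fraction: the band-limited correlation
    planted between the two channels.
    """

    i: int
    j: int
    band: str
    kappa: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ValidationError(f"coupling kappa {self.kappa} outside [0, 1]")
        if self.i == self.j:
            raise ValidationError("coupling requires two distinct channels")


@dataclass(frozen=True)
class CouplingSpec:
    """Planted coupling entries per emotion class."""

    by_class: Mapping[str, tuple[CouplingEntry, ...]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "by_class",
                           {k: tuple(v) for k, v in self.by_class.items()})

    def entries(self, klass: str) -> tuple[CouplingEntry, ...]:
        if klass not in self.by_class:
            raise ValidationError(
                f"class {klass!r} absent from coupling spec; have {sorted(self.by_class)}"
            )
        return self.by_class[klass]

    def validate_against(self, montage: Montage, bandset: BandSet) -> None:
        for klass, entries in self.by_class.items():
            for e in entries:
                if not (0 <= e.i < montage.n_channels and 0 <= e.j < montage.n_channels):
                    raise ValidationError(
                        f"coupling for {klass} references channel outside montage"
                    )
                bandset.interval(e.band)  # raises on unknown band


def default_montage() -> Montage:
    """16-channel synthetic cap covering all five scalp regions."""
    return Montage.from_names([
        "Fp1", "Fp2", "F3", "F4", "F7", "F8", "C3", "C4", "Cz",
        "P3", "P4", "Pz", "T7", "T8", "O1", "O2",
    ])


def _clique(montage: Montage, names: Sequence[str], band: str, kappa: float
            ) -> list[CouplingEntry]:
    idx = [montage.index(n) for n in names]
    return [CouplingEntry(idx[a], idx[b], band, kappa)
            for a in range(len(idx)) for b in range(a + 1, len(idx))]


def default_coupling(montage: Montage | None = None) -> CouplingSpec:
    """Arousal-dominant planted connectivity over the default montage.

    High arousal strengthens a beta-band fronto-central clique
    (kappa 0.85 vs 0.15), high valence an alpha-band prefrontal clique
    (kappa 0.70 vs 0.25).  The arousal contrast is deliberately the larger
    one: network topology should discriminate arousal better than valence.
    """
    m = montage or default_montage()
    valence = {"H": _clique(m, ["Fp1", "Fp2", "F7", "F8"], "alpha", 0.70),
               "L": _clique(m, ["Fp1", "Fp2", "F7", "F8"], "alpha", 0.25)}
    arousal = {"H": _clique(m, ["F3", "F4", "C3", "C4"], "beta", 0.85),
               "L": _clique(m, ["F3", "F4", "C3", "C4"], "beta", 0.15)}
    by_class = {}
    for klass in QUADRANTS:
        by_class[klass] = tuple(valence[klass[0]] + arousal[klass[2]])
    return CouplingSpec(by_class)


@dataclass(frozen=True)
class SimConfig:
    """Study-level simulation parameters (defaults emulate DEAP's structure:
    32 subjects x 40 music trials, 128 Hz, 60 s per trial)."""

    montage: Montage = field(default_factory=default_montage)
    n_subjects: int = 32
    trials_per_subject: int = 40
    fs: float = 128.0
    trial_duration: float = 60.0
    bandset: BandSet = field(default_factory=BandSet.default)
    coupling: CouplingSpec | None = None  # None -> default_coupling(montage)
    band_amplitude: Mapping[str, float] = field(default_factory=lambda: {
        "delta": 8.0, "theta": 7.0, "alpha": 10.0, "beta": 6.0, "gamma": 4.0,
    })  # uV RMS per band source
    noise_sd: float = 3.0             # uV RMS of the pink background
    pink_exponent: float = 1.0        # 1/f^beta spectral slope
    blink_rate: float = 12.0          # events per minute
    blink_amplitude: float = 80.0     # uV at frontal sites
    rating_noise_sd: float = 0.8      # SD of rating noise on the 1-9 scale
    subject_gain_sd: float = 0.1      # per-subject multiplicative gain spread
    subject_bias_sd: float = 0.3      # per-subject rating bias spread
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.trials_per_subject < 1:
            raise ValidationError("subject and trial counts must be >= 1")
        if self.trial_duration <= 0:
            raise ValidationError("trial duration must be positive")
        if self.fs <= 2 * self.bandset.max_edge:
            raise ValidationError(
                f"fs={self.fs} Hz too low for a band reaching "
                f"{self.bandset.max_edge} Hz (need fs > 2 x highest edge)"
            )
        for name in self.band_amplitude:
            self.bandset.interval(name)
        if self.coupling is not None:
            self.coupling.validate_against(self.montage, self.bandset)

    def resolved_coupling(self) -> CouplingSpec:
        if self.coupling is not None:
            return self.coupling
        spec = default_coupling(self.montage)
        spec.validate_against(self.montage, self.bandset)
        return spec

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration * self.fs))


@dataclass
class GroundTruth:
    """Planted truth aligned with a generated TrialSet."""

    classes: list[str]                       # per-trial true class
    coupling: list[list[CouplingEntry]]      # per-trial realized coupling
    subject_gain: dict[str, float]
    subject_bias: dict[str, float]


# ---------------------------------------------------------------------------
# Signal building blocks
# ---------------------------------------------------------------------------

def _band_sources(rng: np.random.Generator, shape: tuple[int, ...], fs: float,
                  band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS band-limited noise rows: white noise through a zero-phase
    4th-order Butterworth band-pass."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    rms = np.sqrt(np.mean(x ** 2, axis=-1, keepdims=True))
    return x / np.where(rms > 0, rms, 1.0)


def _band_source(rng: np.random.Generator, n: int, fs: float,
                 band: tuple[float, float]) -> np.ndarray:
    return _band_sources(rng, (n,), fs, band)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
                exponent: float) -> np.ndarray:
    """Unit-RMS 1/f^exponent noise rows via spectral shaping of white noise."""
    n = shape[-1]
    spec = np.fft.rfft(rng.standard_normal(shape), axis=-1)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n, axis=-1)
    return x / np.sqrt(np.mean(x ** 2, axis=-1, keepdims=True))


def _blink_pulse(fs: float) -> np.ndarray:
    n = max(int(round(BLINK_DURATION_S * fs)), 2)
    t = np.arange(n) / (n - 1)
    return 0.5 * (1 - np.cos(2 * np.pi * t))  # raised cosine, peak 1


def _blink_topography(montage: Montage) -> np.ndarray:
    return np.array([np.exp(-_REGION_DEPTH[r]) for r in montage.regions])


def _coupling_groups(entries: Sequence[CouplingEntry], band: str,
                     n_channels: int) -> list[tuple[list[int], np.ndarray]]:
    """Connected components of the coupling graph in *band*, with each
    channel's mixing weight = max kappa over its incident edges."""
    in_band = [e for e in entries if e.band == band]
    if not in_band:
        return []
    parent = list(range(n_channels))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    kappa = np.zeros(n_channels)
    for e in in_band:
        parent[find(e.i)] = find(e.j)
        kappa[e.i] = max(kappa[e.i], e.kappa)
        kappa[e.j] = max(kappa[e.j], e.kappa)
    groups: dict[int, list[int]] = {}
    for e in in_band:
        groups.setdefault(find(e.i), [])
    for ch in range(n_channels):
        if kappa[ch] > 0 or any(ch in (e.i, e.j) for e in in_band):
            groups.setdefault(find(ch), []).append(ch)
    return [(sorted(members), kappa[sorted(members)])
            for root, members in sorted(groups.items()) if members]


# ---------------------------------------------------------------------------
# Trial and dataset generation
# ---------------------------------------------------------------------------

def generate_trial(config: SimConfig, klass: str, rng: np.random.Generator,
                   subject_id: str = "s01", trial_id: str = "t001",
                   subject_gain: float = 1.0) -> Recording:
    """Synthesize one trial of the given emotion class.

    Each channel is the sum over bands of band-limited sources; a coupled
    channel mixes the group's shared source with weight sqrt(kappa) and its
    private source with sqrt(1 - kappa), so kappa is the shared-variance
    fraction and the planted pairwise correlation of two clique members in
    the band equals kappa (kappa = 1 -> identical signals).  Pink noise and
    frontal-weighted blink pulses are added on top.
    """
    coupling = config.resolved_coupling()
    entries = coupling.entries(klass)
    n, fs = config.n_samples, config.fs
    n_ch = config.montage.n_channels
    data = np.zeros((n_ch, n))

    for band_name, lo, hi in config.bandset:
        amp = float(config.band_amplitude.get(band_name, 0.0))
        if amp <= 0:
            continue
        # private sources first (fixed draw order keeps determinism simple)
        private = _band_sources(rng, (n_ch, n), fs, (lo, hi))
        band_sig = private.copy()
        for members, kappas in _coupling_groups(entries, band_name, n_ch):
            shared = _band_source(rng, n, fs, (lo, hi))
            for ch, k in zip(members, kappas):
                band_sig[ch] = np.sqrt(1.0 - k) * private[ch] + np.sqrt(k) * shared
        data += amp * band_sig

    if config.noise_sd > 0:
        data += config.noise_sd * _pink_noise(rng, (n_ch, n), config.pink_exponent)

    if config.blink_rate > 0 and config.blink_amplitude > 0:
        n_blinks = rng.poisson(config.blink_rate / 60.0 * config.trial_duration)
        pulse = _blink_pulse(fs) * config.blink_amplitude
        topo = _blink_topography(config.montage)
        for _ in range(n_blinks):
            start = rng.integers(0, max(n - len(pulse), 1))
            seg = slice(start, start + len(pulse))
            data[:, seg] += topo[:, None] * pulse[None, : data[:, seg].shape[1]]

    return Recording(subject_id, trial_id, fs, subject_gain * data, config.montage)


def _balanced_classes(trials: int, rng: np.random.Generator) -> list[str]:
    """Per-subject class sequence with counts balanced to within one."""
    reps = -(-trials // len(QUADRANTS))
    seq = (list(QUADRANTS) * reps)[:trials]
    rng.shuffle(seq)
    return seq


def _trial_rng(seed: int, subject: int, trial: int, stream: int = 0
               ) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, subject, trial, stream]))


def generate_dataset(config: SimConfig, seed: int | None = None
                     ) -> tuple[TrialSet, GroundTruth]:
    """Generate the full multi-subject study: recordings, ratings, truth.

    Class counts are balanced within each subject (to within one trial);
    ratings are the class centroid plus subject bias plus Gaussian noise,
    clipped to [1, 9].
    """
    seed = config.seed if seed is None else int(seed)
    coupling = config.resolved_coupling()
    recordings: list[Recording] = []
    rows: list[dict] = []
    truth_classes: list[str] = []
    truth_coupling: list[list[CouplingEntry]] = []
    subject_gain: dict[str, float] = {}
    subject_bias: dict[str, float] = {}

    for s in range(config.n_subjects):
        sid = f"s{s + 1:02d}"
        subj_rng = _trial_rng(seed, s, 0, stream=1)
        gain = float(np.exp(config.subject_gain_sd * subj_rng.standard_normal()))
        bias = float(config.subject_bias_sd * subj_rng.standard_normal())
        subject_gain[sid] = gain
        subject_bias[sid] = bias
        classes = _balanced_classes(config.trials_per_subject, subj_rng)
        for t, klass in enumerate(classes):
            tid = f"t{t + 1:03d}"
            rng = _trial_rng(seed, s, t + 1, stream=0)
            rec = generate_trial(config, klass, rng, subject_id=sid,
                                 trial_id=tid, subject_gain=gain)
            recordings.append(rec)
            v0, a0 = CLASS_CENTROIDS[klass]
            noise = config.rating_noise_sd * rng.standard_normal(4)
            ratings = np.clip(
                [v0 + bias + noise[0], a0 + bias + noise[1],
                 5.0 + bias + noise[2], 5.0 + bias + noise[3]], 1.0, 9.0)
            rows.append({"subject_id": sid, "trial_id": tid,
                         "valence": ratings[0], "arousal": ratings[1],
                         "dominance": ratings[2], "liking": ratings[3]})
            truth_classes.append(klass)
            truth_coupling.append(list(coupling.entries(klass)))

    labels = EmotionLabels(pd.DataFrame(rows))
    trials = TrialSet(recordings, labels, classes=np.array(truth_classes))
    truth = GroundTruth(truth_classes, truth_coupling, subject_gain, subject_bias)
    return trials, truth


# ---------------------------------------------------------------------------
# Ground-truth serialization
# ---------------------------------------------------------------------------

def write_ground_truth_json(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "classes": truth.classes,
        "coupling": [[[e.i, e.j, e.band, e.kappa] for e in trial]
                     for trial in truth.coupling],
        "subject_gain": truth.subject_gain,
        "subject_bias": truth.subject_bias,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_ground_truth_json(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    coupling = [[CouplingEntry(i, j, band, kappa) for i, j, band, kappa in trial]
                for trial in payload["coupling"]]
    return GroundTruth(payload["classes"], coupling,
                       payload["subject_gain"], payload["subject_bias"])
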