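"""Shared data model: montages, recordings, frequency bands, affective labels.

The containers here are deliberately thin wrappers over numpy arrays and
pandas frames; every downstream stage (synthesis, preprocessing,
connectivity, feature extraction, classification) speaks these types.

Affective ratings follow the DEAP convention: valence, arousal, dominance
and liking on a continuous 1-9 self-assessment scale.  Classes are derived
by splitting each axis at a midpoint (default 5), giving the four
valence-arousal quadrants HVHA / HVLA / LVHA / LVLA.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "REGIONS",
    "QUADRANTS",
    "ValidationError",
    "Montage",
    "Recording",
    "BandSet",
    "EmotionLabels",
    "TrialSet",
    "quadrantize",
    "binarize",
    "infer_region",
    "infer_pairs",
    "deap_frontal_central_montage",
    "standard_1010_62_montage",
    "read_labels_csv",
    "write_labels_csv",
    "read_montage_json",
    "write_montage_json",
    "read_recording_csv",
    "write_recording_csv",
    "read_recording_edf",
]

REGIONS = ("frontal", "central", "parietal", "temporal", "occipital")
QUADRANTS = ("HVHA", "HVLA", "LVHA", "LVLA")

RATING_MIN = 1.0
RATING_MAX = 9.0


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

# prefix -> scalp region for standard 10-20 / 10-10 electrode names.
# Order matters: longest prefixes are matched first (FC before F, CP before C).
_REGION_PREFIXES = [
    ("FPZ", "frontal"), ("FP", "frontal"), ("AF", "frontal"),
    ("FT", "temporal"), ("FCZ", "central"), ("FC", "central"),
    ("FZ", "frontal"), ("F", "frontal"),
    ("TP", "temporal"), ("T", "temporal"),
    ("CPZ", "parietal"), ("CP", "parietal"),
    ("CZ", "central"), ("C", "central"),
    ("POZ", "parietal"), ("PO", "parietal"),
    ("PZ", "parietal"), ("P", "parietal"),
    ("OZ", "occipital"), ("O", "occipital"), ("CB", "occipital"),
]


def infer_region(name: str) -> str:
    """Map a standard 10-20 / 10-10 electrode name to a scalp region tag."""
    upper = name.upper()
    for prefix, region in _REGION_PREFIXES:
        if upper.startswith(prefix):
            return region
    raise ValidationError(f"cannot infer a scalp region for electrode {name!r}")


def infer_pairs(names: Sequence[str]) -> list[tuple[int, int]]:
    """Find homologous left/right pairs among 10-20 names.

    By convention odd digits are left-hemisphere, even digits right; the
    homologue of e.g. F3 is F4 and of F7 is F8 (same prefix, digit + 1).
    """
    index = {n.upper(): i for i, n in enumerate(names)}
    pairs: list[tuple[int, int]] = []
    for i, name in enumerate(names):
        m = re.fullmatch(r"([A-Za-z]+)(\d+)", name)
        if m is None:
            continue
        digit = int(m.group(2))
        if digit % 2 == 1:  # left hemisphere
            partner = f"{m.group(1)}{digit + 1}".upper()
            if partner in index:
                pairs.append((i, index[partner]))
    return pairs


@dataclass(frozen=True)
class Montage:
    """Electrode layout: names, scalp-region tags and homologous pairs.

    Regions are explicit tags rather than being inferred at use time, so
    fully synthetic montages work; :func:`infer_region` labels standard
    10-20 names when building one from a name list.
    """

    channel_names: tuple[str, ...]
    regions: tuple[str, ...]
    pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        names = self.channel_names
        if len(set(names)) != len(names):
            raise ValidationError("montage channel names must be unique")
        if len(self.regions) != len(names):
            raise ValidationError("one region tag per channel required")
        for r in self.regions:
            if r not in REGIONS:
                raise ValidationError(f"unknown region tag {r!r}; expected one of {REGIONS}")
        seen: set[int] = set()
        for left, right in self.pairs:
            for idx in (left, right):
                if not 0 <= idx < len(names):
                    raise ValidationError(f"pair index {idx} out of range")
                if idx in seen:
                    raise ValidationError(
                        f"channel {names[idx]!r} appears in more than one pair"
                    )
                seen.add(idx)
            if left == right:
                raise ValidationError("a pair cannot contain the same channel twice")

    @classmethod
    def from_names(cls, names: Sequence[str], pairs: Sequence[tuple[int, int]] | None = None) -> "Montage":
        """Build a montage from standard 10-20 names, inferring regions and pairs."""
        regions = tuple(infer_region(n) for n in names)
        if pairs is None:
            pairs = infer_pairs(names)
        return cls(tuple(names), regions, tuple(tuple(p) for p in pairs))

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def channels_in(self, regions: Iterable[str]) -> list[int]:
        wanted = set(regions)
        return [i for i, r in enumerate(self.regions) if r in wanted]

    def index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise ValidationError(f"channel {name!r} not in montage") from None


def deap_frontal_central_montage() -> Montage:
    """The 15-electrode frontal + central subset used for reduced features.

    Nine frontal and six fronto-central/central electrodes with six
    homologous pairs; midline Fz and the FC5/FC6 temporal-leaning sites are
    left unpaired.
    """
    names = [
        "Fp1", "Fp2", "AF3", "AF4", "F3", "F4", "F7", "F8", "Fz",
        "FC1", "FC2", "FC5", "FC6", "C3", "C4",
    ]
    pairs = [(0, 1), (2, 3), (4, 5), (6, 7), (9, 10), (13, 14)]
    return Montage.from_names(names, pairs)


def standard_1010_62_montage() -> Montage:
    """A standard 62-channel extended 10-10 cap (full PSD feature scheme)."""
    names = [
        "Fp1", "Fpz", "Fp2", "AF3", "AF4",
        "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
        "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
        "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
        "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
        "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
        "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
        "CB1", "O1", "Oz", "O2", "CB2",
    ]
    return Montage.from_names(names)


# ---------------------------------------------------------------------------
# Recording
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """One subject/trial multichannel EEG epoch: channels x samples, in uV."""

    subject_id: str
    trial_id: str
    fs: float
    data: np.ndarray
    montage: Montage

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValidationError("sampling rate must be positive")
        if self.data.ndim != 2:
            raise ValidationError("data must be a channels x samples matrix")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValidationError(
                f"data has {self.data.shape[0]} rows but montage has "
                f"{self.montage.n_channels} channels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError(
                f"non-finite samples in recording {self.subject_id}/{self.trial_id}"
            )
        if self.data.shape[1] < 2 * self.fs:
            raise ValidationError(
                f"recording {self.subject_id}/{self.trial_id} shorter than 2 s"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "Recording":
        return Recording(self.subject_id, self.trial_id, self.fs, data, self.montage)


# ---------------------------------------------------------------------------
# Bands
# ---------------------------------------------------------------------------

DEFAULT_BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}


@dataclass(frozen=True)
class BandSet:
    """Named closed frequency intervals in Hz.

    The default is the canonical EEG decomposition: delta 1-4, theta 4-8,
    alpha 8-13, beta 13-30 and gamma 30-45 Hz (gamma capped below mains
    frequencies).
    """

    bands: tuple[tuple[str, float, float], ...] = tuple(
        (name, lo, hi) for name, (lo, hi) in DEFAULT_BANDS.items()
    )

    def __post_init__(self) -> None:
        names = [b[0] for b in self.bands]
        if len(set(names)) != len(names):
            raise ValidationError("band names must be unique")
        for name, lo, hi in self.bands:
            if not (0 <= lo < hi):
                raise ValidationError(f"band {name!r}: require 0 <= lo < hi, got ({lo}, {hi})")

    @classmethod
    def default(cls) -> "BandSet":
        return cls()

    @classmethod
    def from_dict(cls, d: Mapping[str, tuple[float, float]]) -> "BandSet":
        return cls(tuple((k, float(lo), float(hi)) for k, (lo, hi) in d.items()))

    @property
    def names(self) -> list[str]:
        return [b[0] for b in self.bands]

    def interval(self, name: str) -> tuple[float, float]:
        for n, lo, hi in self.bands:
            if n == name:
                return (lo, hi)
        raise ValidationError(f"unknown band {name!r}; have {self.names}")

    @property
    def max_edge(self) -> float:
        return max(hi for _, _, hi in self.bands)

    @property
    def span(self) -> tuple[float, float]:
        return (min(lo for _, lo, _ in self.bands), self.max_edge)

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)


# ---------------------------------------------------------------------------
# Labels and classes
# ---------------------------------------------------------------------------

def _check_rating(value: float, what: str, trial: str | None = None) -> float:
    value = float(value)
    if not (RATING_MIN <= value <= RATING_MAX):
        where = f" (trial {trial})" if trial else ""
        raise ValidationError(
            f"{what} rating {value} outside [{RATING_MIN:g}, {RATING_MAX:g}]{where}"
        )
    return value


def binarize(rating: float, midpoint: float = 5.0, *, trial: str | None = None) -> str:
    """Split one rating axis at *midpoint*: ``high`` iff rating >= midpoint.

    The tie goes to ``high`` so the mapping is total on [1, 9].
    """
    if not (RATING_MIN < midpoint < RATING_MAX):
        raise ValidationError(f"midpoint {midpoint} must lie strictly inside (1, 9)")
    rating = _check_rating(rating, "axis", trial)
    return "high" if rating >= midpoint else "low"


def quadrantize(valence: float, arousal: float, midpoint: float = 5.0,
                *, trial: str | None = None) -> str:
    """Map (valence, arousal) to its quadrant class HVHA/HVLA/LVHA/LVLA.

    Composes exactly with :func:`binarize` applied per axis; ties count as
    high, so the four classes partition the [1, 9] x [1, 9] rating square.
    """
    v = binarize(_check_rating(valence, "valence", trial), midpoint)
    a = binarize(_check_rating(arousal, "arousal", trial), midpoint)
    return ("H" if v == "high" else "L") + "V" + ("H" if a == "high" else "L") + "A"


@dataclass
class EmotionLabels:
    """Per-trial affective ratings on the 1-9 scale, as a pandas frame.

    Columns: subject_id, trial_id, valence, arousal, dominance, liking.
    """

    table: pd.DataFrame

    RATING_COLUMNS = ("valence", "arousal", "dominance", "liking")

    def __post_init__(self) -> None:
        required = ["subject_id", "trial_id", *self.RATING_COLUMNS]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"labels table missing columns {missing}")
        for col in self.RATING_COLUMNS:
            vals = self.table[col].to_numpy(dtype=float)
            bad = (vals < RATING_MIN) | (vals > RATING_MAX) | ~np.isfinite(vals)
            if bad.any():
                trial = self.table.loc[np.flatnonzero(bad)[0], "trial_id"]
                raise ValidationError(
                    f"{col} rating out of [1, 9] for trial {trial!r}"
                )
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def quadrant_classes(self, midpoint: float = 5.0) -> np.ndarray:
        return np.array([
            quadrantize(v, a, midpoint, trial=str(t))
            for v, a, t in zip(self.table["valence"], self.table["arousal"],
                               self.table["trial_id"])
        ])

    def binary_classes(self, axis: str, midpoint: float = 5.0) -> np.ndarray:
        if axis not in self.RATING_COLUMNS:
            raise ValidationError(f"unknown rating axis {axis!r}")
        return np.array([
            binarize(r, midpoint, trial=str(t))
            for r, t in zip(self.table[axis], self.table["trial_id"])
        ])


@dataclass
class TrialSet:
    """Aligned recordings + labels for a multi-subject, multi-trial study."""

    recordings: list[Recording]
    labels: EmotionLabels
    classes: np.ndarray | None = None  # optional per-trial class annotation

    def __post_init__(self) -> None:
        if len(self.recordings) != len(self.labels):
            raise ValidationError(
                f"{len(self.recordings)} recordings but {len(self.labels)} label rows"
            )
        if self.recordings:
            fs = self.recordings[0].fs
            montage = self.recordings[0].montage
            for rec in self.recordings:
                if rec.fs != fs:
                    raise ValidationError("all recordings must share one sampling rate")
                if rec.montage is not montage and rec.montage != montage:
                    raise ValidationError("all recordings must share one montage")
        if self.classes is not None and len(self.classes) != len(self.recordings):
            raise ValidationError("class annotations must align with recordings")

    def __len__(self) -> int:
        return len(self.recordings)

    @property
    def fs(self) -> float:
        return self.recordings[0].fs

    @property
    def montage(self) -> Montage:
        return self.recordings[0].montage

    def sample_keys(self) -> pd.DataFrame:
        return self.labels.table[["subject_id", "trial_id"]].copy()


# ---------------------------------------------------------------------------
# I/O: labels CSV, montage JSON, recordings CSV + JSON sidecar, EDF
# ---------------------------------------------------------------------------

def write_labels_csv(labels: EmotionLabels, path: str | Path) -> None:
    labels.table.to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> EmotionLabels:
    return EmotionLabels(pd.read_csv(path))


def write_montage_json(montage: Montage, path: str | Path) -> None:
    payload = {
        "channel_names": list(montage.channel_names),
        "regions": list(montage.regions),
        "pairs": [list(p) for p in montage.pairs],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_montage_json(path: str | Path) -> Montage:
    payload = json.loads(Path(path).read_text())
    return Montage(
        tuple(payload["channel_names"]),
        tuple(payload["regions"]),
        tuple(tuple(p) for p in payload["pairs"]),
    )


def write_recording_csv(rec: Recording, path: str | Path) -> None:
    """Write channels x samples matrix as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    np.savetxt(path, rec.data, delimiter=",", fmt="%.6f")
    sidecar = {
        "subject_id": rec.subject_id,
        "trial_id": rec.trial_id,
        "fs": rec.fs,
        "channel_names": list(rec.montage.channel_names),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_recording_csv(path: str | Path, montage: Montage) -> Recording:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    if list(montage.channel_names) != list(meta["channel_names"]):
        raise ValidationError(f"montage does not match sidecar of {path.name}")
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    return Recording(meta["subject_id"], meta["trial_id"], float(meta["fs"]), data, montage)


def read_recording_edf(path: str | Path, subject_id: str = "", trial_id: str = "",
                       montage: Montage | None = None) -> Recording:
    """Read a multichannel EDF file into a Recording (amplitudes in uV)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF reading requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    if montage is None:
        montage = Montage.from_names(list(raw.ch_names))
    return Recording(subject_id or Path(path).stem, trial_id or "0",
                     float(raw.info["sfreq"]), data, montage)
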