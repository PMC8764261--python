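"""High-level pipeline: simulate -> preprocess -> networks -> features -> evaluate.

These functions wire the stage modules together in memory; the command-line
interface adds on-disk artifacts around them.
"""

from __future__ import annotations

from .classify import CVScheme, EvalReport, evaluate
from .connectivity import (
    DEFAULT_DENSITY,
    DEFAULT_N_BINS,
    DEFAULT_STEP_S,
    DEFAULT_WINDOW_S,
    ConnectivityTensor,
    dynamic_network,
    network_feature_series,
)
from .core import BandSet, Recording, TrialSet
from .features import FeatureTable, mwl_index
from .preprocess import decompose_bands, remove_ocular, rereference
from .synth import SimConfig, generate_dataset

__all__ = [
    "preprocess_trials",
    "trial_tensor",
    "network_features",
    "mwl_features",
    "emotion_evaluation",
    "run_emotion_study",
]


def preprocess_trials(trials: TrialSet, ocular: str | None = "ica") -> TrialSet:
    """Common-average re-reference and (optionally) ocular cleanup per trial."""
    cleaned = []
    for rec in trials.recordings:
        rec = rereference(rec)
        if ocular:
            rec = remove_ocular(rec, method=ocular)
        cleaned.append(rec)
    return TrialSet(cleaned, trials.labels, classes=trials.classes)


def trial_tensor(rec: Recording, bandset: BandSet | None = None,
                 estimator: str = "mi", window_s: float = DEFAULT_WINDOW_S,
                 step_s: float = DEFAULT_STEP_S,
                 n_bins: int = DEFAULT_N_BINS) -> ConnectivityTensor:
    """Band-decompose one trial and build its sliding-window tensor."""
    bands = decompose_bands(rec, bandset or BandSet.default())
    return dynamic_network(bands, estimator=estimator, window_s=window_s,
                           step_s=step_s, n_bins=n_bins)


def network_features(trials: TrialSet, bandset: BandSet | None = None,
                     estimator: str = "mi", window_s: float = DEFAULT_WINDOW_S,
                     step_s: float = DEFAULT_STEP_S,
                     density: float = DEFAULT_DENSITY,
                     n_bins: int = DEFAULT_N_BINS) -> FeatureTable:
    """Dynamic-network graph-metric features for every trial."""
    rows = []
    for rec in trials.recordings:
        tensor = trial_tensor(rec, bandset, estimator, window_s, step_s, n_bins)
        rows.append(network_feature_series(tensor, density))
    return FeatureTable.from_rows(trials.sample_keys(), rows)


def mwl_features(trials: TrialSet, bandset: BandSet | None = None) -> FeatureTable:
    """Single-column mental-workload feature table."""
    rows = [{"mwl": mwl_index(rec, bandset)} for rec in trials.recordings]
    return FeatureTable.from_rows(trials.sample_keys(), rows)


def emotion_evaluation(features: FeatureTable, trials: TrialSet,
                       model: str = "lda",
                       scheme: CVScheme | None = None,
                       midpoint: float = 5.0, seed: int = 0
                       ) -> dict[str, EvalReport]:
    """Evaluate four-class quadrant and the two dichotomous tasks."""
    scheme = scheme or CVScheme("leave_one_subject_out")
    meta = features.table[["subject_id", "trial_id"]]
    labels = trials.labels
    out = {
        "quadrant": evaluate(features, labels.quadrant_classes(midpoint),
                             model, scheme, meta, seed),
        "valence": evaluate(features, labels.binary_classes("valence", midpoint),
                            model, scheme, meta, seed),
        "arousal": evaluate(features, labels.binary_classes("arousal", midpoint),
                            model, scheme, meta, seed),
    }
    return out


def run_emotion_study(config: SimConfig, seed: int, model: str = "lda",
                      ocular: str | None = "ica",
                      estimator: str = "mi",
                      window_s: float = DEFAULT_WINDOW_S,
                      step_s: float = DEFAULT_STEP_S,
                      density: float = DEFAULT_DENSITY
                      ) -> dict[str, EvalReport]:
    """Simulate one study and run the full network-feature evaluation."""
    trials, _ = generate_dataset(config, seed)
    trials = preprocess_trials(trials, ocular=ocular)
    feats = network_features(trials, config.bandset, estimator,
                             window_s, step_s, density)
    return emotion_evaluation(feats, trials, model=model, seed=seed)
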