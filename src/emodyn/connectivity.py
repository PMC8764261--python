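"""Dynamic brain networks from sliding-window association estimators.

The core of the method: each trial's band-decomposed EEG is scanned with a
sliding window; within every window an association value (mutual
information by default, Pearson correlation or phase-locking value as
alternatives) is computed for every channel pair, yielding a
(band x window x channel x channel) connectivity tensor.  Each slice is
proportionally thresholded into a binary graph whose topology (average
clustering coefficient, characteristic path length) is summarized over
time into per-trial features.

Mutual information uses a plug-in estimate over equal-frequency
(quantile) bins — default 16 — which makes MI(x, x) a stable ln(n_bins)
for continuous signals and needs no bandwidth choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .core import Recording, ValidationError
from .preprocess import analytic_phase

__all__ = [
    "DegenerateInputWarning",
    "ConnectivityTensor",
    "BrainNetwork",
    "PathLengthResult",
    "ESTIMATORS",
    "mutual_information",
    "pearson",
    "plv",
    "sliding_windows",
    "dynamic_network",
    "threshold_proportional",
    "clustering_coefficient",
    "characteristic_path_length",
    "network_feature_series",
    "write_network_csv",
    "NETWORK_METRICS",
    "NETWORK_SUMMARIES",
]

DEFAULT_N_BINS = 16
DEFAULT_WINDOW_S = 4.0
DEFAULT_STEP_S = 2.0
DEFAULT_DENSITY = 0.15
MIN_MI_SAMPLES = 64

ESTIMATORS = ("mi", "pearson", "plv")


class DegenerateInputWarning(UserWarning):
    """A constant (zero-variance) input was passed to an estimator."""


# ---------------------------------------------------------------------------
# Pairwise estimators
# ---------------------------------------------------------------------------

def _quantile_bin_indices(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin index of every sample (stable under ties)."""
    n = len(x)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return (ranks * n_bins) // n


def _plugin_mi_from_bins(bx: np.ndarray, by: np.ndarray, n_bins: int) -> float:
    joint = np.bincount(bx * n_bins + by, minlength=n_bins * n_bins)
    pxy = joint / len(bx)
    pxy = pxy.reshape(n_bins, n_bins)
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    mask = pxy > 0
    return float(np.sum(pxy[mask] * np.log(pxy[mask] / np.outer(px, py)[mask])))


def mutual_information(x: np.ndarray, y: np.ndarray,
                       n_bins: int = DEFAULT_N_BINS) -> float:
    """Plug-in mutual information (nats) over equal-frequency 2-D bins.

    Symmetric and non-negative; MI(x, x) equals the marginal entropy of
    the binning (ln n_bins for continuous x).  A constant input is
    degenerate: a :class:`DegenerateInputWarning` is issued and 0 returned.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if len(x) != len(y):
        raise ValidationError("mutual_information requires equal-length inputs")
    if len(x) < MIN_MI_SAMPLES:
        raise ValidationError(
            f"mutual_information needs >= {MIN_MI_SAMPLES} samples, got {len(x)}")
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input to mutual_information; returning 0",
                      DegenerateInputWarning, stacklevel=2)
        return 0.0
    return _plugin_mi_from_bins(_quantile_bin_indices(x, n_bins),
                                _quantile_bin_indices(y, n_bins), n_bins)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation in [-1, 1]; 0 (with warning) if degenerate."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if len(x) != len(y):
        raise ValidationError("pearson requires equal-length inputs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input to pearson; returning 0",
                      DegenerateInputWarning, stacklevel=2)
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def plv(x: np.ndarray, y: np.ndarray) -> float:
    """Phase-locking value |<exp(i (phi_x - phi_y))>| in [0, 1]."""
    px = analytic_phase(np.asarray(x, float).ravel())
    py = analytic_phase(np.asarray(y, float).ravel())
    if len(px) != len(py):
        raise ValidationError("plv requires equal-length inputs")
    return float(np.abs(np.mean(np.exp(1j * (px - py)))))


# ---------------------------------------------------------------------------
# Sliding windows and the connectivity tensor
# ---------------------------------------------------------------------------

def sliding_windows(n_samples: int, fs: float, window_s: float = DEFAULT_WINDOW_S,
                    step_s: float = DEFAULT_STEP_S) -> list[tuple[int, int]]:
    """Half-open [start, stop) sample windows; count floor((T - w)/s) + 1."""
    if window_s <= 0 or step_s <= 0:
        raise ValidationError("window and step must be positive")
    w = int(round(window_s * fs))
    s = int(round(step_s * fs))
    if n_samples < w:
        return []
    return [(k * s, k * s + w) for k in range((n_samples - w) // s + 1)]


@dataclass
class ConnectivityTensor:
    """(band x window x channel x channel) symmetric association values."""

    values: np.ndarray
    bands: tuple[str, ...]
    window_starts_s: tuple[float, ...]
    window_s: float
    step_s: float
    estimator: str

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 4 or v.shape[2] != v.shape[3]:
            raise ValidationError("tensor must be (band, window, channel, channel)")
        if v.shape[0] != len(self.bands) or v.shape[1] != len(self.window_starts_s):
            raise ValidationError("tensor axes do not match band/window metadata")

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    def band_slice(self, band: str, window: int) -> np.ndarray:
        return self.values[self.bands.index(band), window]


def _window_estimates(seg: np.ndarray, estimator: str, n_bins: int,
                      phases: np.ndarray | None = None) -> np.ndarray:
    """Symmetric channel x channel association matrix on one window."""
    c = seg.shape[0]
    out = np.zeros((c, c))
    if estimator == "pearson":
        sd = seg.std(axis=1)
        ok = sd > 0
        if ok.any():
            sub = np.corrcoef(seg[ok])
            out[np.ix_(ok, ok)] = np.atleast_2d(sub)
        np.fill_diagonal(out, 0.0)
        return out
    if estimator == "plv":
        z = np.exp(1j * phases)
        m = np.abs(z @ z.conj().T) / seg.shape[1]
        np.fill_diagonal(m, 0.0)
        return m
    # mi
    n = seg.shape[1]
    bins = np.vstack([
        _quantile_bin_indices(seg[ch], n_bins) if np.ptp(seg[ch]) > 0
        else np.full(n, -1, dtype=np.int64)
        for ch in range(c)
    ])
    for i in range(c):
        if bins[i, 0] < 0:
            continue
        for j in range(i + 1, c):
            if bins[j, 0] < 0:
                continue
            out[i, j] = out[j, i] = _plugin_mi_from_bins(bins[i], bins[j], n_bins)
    return out


def dynamic_network(band_recordings: Mapping[str, Recording | np.ndarray],
                    fs: float | None = None,
                    estimator: str = "mi",
                    window_s: float = DEFAULT_WINDOW_S,
                    step_s: float = DEFAULT_STEP_S,
                    n_bins: int = DEFAULT_N_BINS) -> ConnectivityTensor:
    """Sliding-window association tensor over band-decomposed signals.

    *band_recordings* maps band name to a Recording (or channels x samples
    array, in which case *fs* is required).  Every (band, window, pair)
    cell is filled; slices are symmetric with zero diagonal.
    """
    if estimator not in ESTIMATORS:
        raise ValidationError(
            f"unknown estimator {estimator!r}; choose one of {ESTIMATORS}")
    arrays: dict[str, np.ndarray] = {}
    for name, rec in band_recordings.items():
        if isinstance(rec, Recording):
            arrays[name] = rec.data
            fs = rec.fs
        else:
            arrays[name] = np.asarray(rec, float)
    if fs is None:
        raise ValidationError("fs required when passing raw arrays")
    shapes = {a.shape for a in arrays.values()}
    if len(shapes) != 1:
        raise ValidationError("all band signals must share one shape")
    (n_ch, n_samples), = shapes
    windows = sliding_windows(n_samples, fs, window_s, step_s)
    bands = tuple(arrays)
    values = np.zeros((len(bands), len(windows), n_ch, n_ch))
    for b, name in enumerate(bands):
        sig = arrays[name]
        phases = analytic_phase(sig) if estimator == "plv" else None
        for w, (start, stop) in enumerate(windows):
            values[b, w] = _window_estimates(
                sig[:, start:stop], estimator, n_bins,
                phases[:, start:stop] if phases is not None else None)
    return ConnectivityTensor(values, bands,
                              tuple(start / fs for start, _ in windows),
                              window_s, step_s, estimator)


# ---------------------------------------------------------------------------
# Thresholding and graph metrics
# ---------------------------------------------------------------------------

@dataclass
class BrainNetwork:
    """Binary symmetric adjacency without self-loops."""

    adjacency: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValidationError("adjacency must be square")
        if np.any(np.diag(a) != 0):
            raise ValidationError("self-loops are not allowed")
        if not np.array_equal(a, a.T):
            raise ValidationError("adjacency must be symmetric")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def density(self) -> float:
        n = self.n_nodes
        possible = n * (n - 1) // 2
        return self.n_edges / possible if possible else 0.0

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


def threshold_proportional(weights: np.ndarray, density: float) -> BrainNetwork:
    """Keep the round(density * n(n-1)/2) strongest off-diagonal weights.

    Ties are broken deterministically by ascending (i, j) index, so equal
    weights always yield the same edge set.
    """
    w = np.asarray(weights, float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValidationError("weight matrix must be square")
    if not 0 <= density <= 1:
        raise ValidationError("density must be in [0, 1]")
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    k = int(round(density * len(vals)))
    # lexsort: primary descending weight, then ascending (i, j)
    order = np.lexsort((ju, iu, -vals))
    adj = np.zeros((n, n), dtype=np.int8)
    keep = order[:k]
    adj[iu[keep], ju[keep]] = 1
    adj[ju[keep], iu[keep]] = 1
    return BrainNetwork(adj)


def clustering_coefficient(net: BrainNetwork) -> float:
    """Watts-Strogatz average clustering: mean per-node triangle density;
    nodes of degree < 2 contribute 0."""
    a = net.adjacency.astype(np.int64)
    if net.n_nodes == 0:
        return 0.0
    triangles = np.diag(a @ a @ a) / 2.0
    deg = net.degrees
    local = np.zeros(net.n_nodes)
    ok = deg >= 2
    local[ok] = 2.0 * triangles[ok] / (deg[ok] * (deg[ok] - 1))
    return float(local.mean())


@dataclass(frozen=True)
class PathLengthResult:
    """Mean shortest-path length over reachable ordered pairs.

    ``fragmented`` is set when at least one node pair is unreachable (the
    mean then covers reachable pairs only; 0.0 if none are reachable).
    """

    value: float
    fragmented: bool

    def __float__(self) -> float:
        return self.value


def characteristic_path_length(net: BrainNetwork) -> PathLengthResult:
    n = net.n_nodes
    if n < 2:
        return PathLengthResult(0.0, False)
    dist = shortest_path(net.adjacency, method="D", unweighted=True, directed=False)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    fragmented = bool(finite.sum() < off.sum())
    if not finite.any():
        return PathLengthResult(0.0, True)
    return PathLengthResult(float(dist[finite].mean()), fragmented)


# ---------------------------------------------------------------------------
# Per-trial network feature series
# ---------------------------------------------------------------------------

def write_network_csv(net: BrainNetwork, path, fmt: str = "matrix",
                      channel_names: Sequence[str] | None = None) -> None:
    """Export a single network as a square-matrix or edge-list CSV."""
    import csv
    from pathlib import Path

    names = list(channel_names) if channel_names is not None else [
        f"ch{i}" for i in range(net.n_nodes)]
    if len(names) != net.n_nodes:
        raise ValidationError("channel names do not match node count")
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        if fmt == "matrix":
            writer.writerow([""] + names)
            for i, row in enumerate(net.adjacency):
                writer.writerow([names[i]] + [int(v) for v in row])
        elif fmt == "edges":
            writer.writerow(["source", "target"])
            for i in range(net.n_nodes):
                for j in range(i + 1, net.n_nodes):
                    if net.adjacency[i, j]:
                        writer.writerow([names[i], names[j]])
        else:
            raise ValidationError(f"unknown network format {fmt!r}")


NETWORK_METRICS = ("clustering", "path_length", "density", "mean_degree")
NETWORK_SUMMARIES = ("mean", "sd", "slope")


def _summaries(series: np.ndarray) -> tuple[float, float, float]:
    mean = float(series.mean())
    sd = float(series.std())
    if len(series) < 2:
        slope = 0.0
    else:
        slope = float(np.polyfit(np.arange(len(series)), series, 1)[0])
    return mean, sd, slope


def network_feature_series(tensor: ConnectivityTensor,
                           density: float = DEFAULT_DENSITY) -> dict[str, float]:
    """Summarize each band's graph-metric time course into named features.

    Per band, the windowed graphs' (clustering, path length, achieved
    density, mean degree) series are reduced to mean, SD and linear slope:
    5 default bands x 4 metrics x 3 summaries = 60 features per trial.
    """
    features: dict[str, float] = {}
    for b, band in enumerate(tensor.bands):
        series = {m: [] for m in NETWORK_METRICS}
        for w in range(tensor.n_windows):
            net = threshold_proportional(tensor.values[b, w], density)
            series["clustering"].append(clustering_coefficient(net))
            series["path_length"].append(characteristic_path_length(net).value)
            series["density"].append(net.density)
            series["mean_degree"].append(float(net.degrees.mean()))
        for metric in NETWORK_METRICS:
            mean, sd, slope = _summaries(np.asarray(series[metric]))
            features[f"net_{band}_{metric}_mean"] = mean
            features[f"net_{band}_{metric}_sd"] = sd
            features[f"net_{band}_{metric}_slope"] = slope
    return features
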