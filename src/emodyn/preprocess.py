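"""EEG preprocessing chain.

Filtering, common-average re-referencing, ocular-artifact removal (ICA
with a regression fallback), epoching with baseline correction, band
decomposition, and empirical mode decomposition with Hilbert phase.

All filters are zero-phase (forward-backward 4th-order Butterworth), so
no stage introduces inter-band group delay — the sliding-window
association estimators downstream assume aligned signals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline
from scipy.stats import kurtosis

from .core import BandSet, Recording, ValidationError

__all__ = [
    "IMFSet",
    "bandpass",
    "rereference",
    "remove_ocular",
    "segment",
    "decompose_bands",
    "emd",
    "analytic_phase",
]

OCULAR_BAND = (0.5, 4.0)        # blink/eye-movement frequency range, Hz
OCULAR_CORR_THRESHOLD = 0.7     # |r| with the frontal slow reference
OCULAR_KURTOSIS_THRESHOLD = 10.0
MIN_ICA_CHANNELS = 8


# ---------------------------------------------------------------------------
# Filtering and referencing
# ---------------------------------------------------------------------------

def _band_sos(band: tuple[float, float], fs: float) -> np.ndarray:
    lo, hi = band
    if not (0 < lo < hi):
        raise ValidationError(f"invalid band ({lo}, {hi})")
    if hi >= fs / 2:
        raise ValidationError(
            f"band edge {hi} Hz at or above Nyquist ({fs / 2} Hz)")
    return signal.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")


def bandpass(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along the last axis.

    Forward-backward filtering doubles the effective roll-off (well beyond
    20 dB one octave outside the passband) and cancels group delay.
    """
    return signal.sosfiltfilt(_band_sos(band, fs), np.asarray(x, float), axis=-1)


def rereference(rec: Recording, mode: str = "common_average") -> Recording:
    """Re-reference a recording; common average subtracts the per-sample
    mean across channels, making every column zero-mean."""
    if mode != "common_average":
        raise ValidationError(f"unknown reference mode {mode!r}")
    return rec.copy_with(rec.data - rec.data.mean(axis=0, keepdims=True))


# ---------------------------------------------------------------------------
# Ocular artifact removal
# ---------------------------------------------------------------------------

def _frontal_slow_reference(rec: Recording) -> np.ndarray:
    frontal = rec.montage.channels_in(["frontal"])
    if not frontal:
        frontal = list(range(rec.n_channels))
    return bandpass(rec.data[frontal].mean(axis=0), rec.fs, OCULAR_BAND)


def _regress_out(data: np.ndarray, ref: np.ndarray) -> np.ndarray:
    ref = ref - ref.mean()
    denom = float(ref @ ref)
    if denom == 0:
        return data.copy()
    beta = (data - data.mean(axis=1, keepdims=True)) @ ref / denom
    return data - np.outer(beta, ref)


def remove_ocular(rec: Recording, method: str = "ica") -> Recording:
    """Remove blink/eye-movement components.

    ICA mode (default, needs >= 8 channels): FastICA components whose
    absolute correlation with a frontal 0.5-4 Hz reference reaches 0.7, or
    whose excess kurtosis exceeds 10, are zeroed before reconstruction.
    Fewer channels, or ICA failure, falls back (with a warning) to
    regressing the frontal slow reference out of every channel.
    """
    if method not in ("ica", "regression"):
        raise ValidationError(f"unknown ocular-removal method {method!r}")
    ref = _frontal_slow_reference(rec)

    if method == "regression" or rec.n_channels < MIN_ICA_CHANNELS:
        if method == "ica":
            warnings.warn(
                f"ICA needs >= {MIN_ICA_CHANNELS} channels "
                f"(got {rec.n_channels}); falling back to regression",
                stacklevel=2)
        return rec.copy_with(_regress_out(rec.data, ref))

    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    # FastICA rarely meets its convergence criterion on EEG whose background
    # is near-Gaussian (the Gaussian subspace has no preferred rotation), but
    # the spiky blink component is still extracted; use the estimate and fall
    # back only on hard failure.  Whitening must not span numerically null
    # directions (common-average referencing drops the rank by one), so the
    # component count is capped at the numerical rank.
    x = rec.data.T
    sv = np.linalg.svd(x - x.mean(axis=0), compute_uv=False)
    rank = int(np.sum(sv > sv[0] * 1e-10)) if sv[0] > 0 else 0
    if rank < 2:
        warnings.warn("ICA impossible on rank-deficient data; using regression",
                      stacklevel=2)
        return rec.copy_with(_regress_out(rec.data, ref))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            ica = FastICA(n_components=rank, whiten="unit-variance",
                          max_iter=300, tol=1e-3, random_state=0)
            sources = ica.fit_transform(x)  # samples x components
        if not np.all(np.isfinite(sources)):
            raise ValueError("non-finite ICA sources")
    except ValueError as exc:
        warnings.warn(f"ICA failed ({exc}); falling back to regression",
                      stacklevel=2)
        return rec.copy_with(_regress_out(rec.data, ref))

    ref_c = ref - ref.mean()
    ref_norm = np.sqrt(ref_c @ ref_c)
    flagged = np.zeros(sources.shape[1], dtype=bool)
    for k in range(sources.shape[1]):
        s = sources[:, k] - sources[:, k].mean()
        s_norm = np.sqrt(s @ s)
        r = abs(s @ ref_c / (s_norm * ref_norm)) if s_norm > 0 and ref_norm > 0 else 0.0
        if r >= OCULAR_CORR_THRESHOLD or kurtosis(sources[:, k]) > OCULAR_KURTOSIS_THRESHOLD:
            flagged[k] = True

    sources[:, flagged] = 0.0
    cleaned = ica.inverse_transform(sources).T
    return rec.copy_with(cleaned)


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def segment(rec: Recording, epoch_s: float, baseline_s: float = 0.5
            ) -> list[Recording]:
    """Cut into non-overlapping epochs with per-channel baseline correction.

    Each epoch's first *baseline_s* seconds define the baseline whose mean
    is subtracted channel-wise; a trailing partial epoch is dropped.
    """
    if epoch_s <= 0 or baseline_s < 0 or baseline_s > epoch_s:
        raise ValidationError("require 0 <= baseline_s <= epoch_s and epoch_s > 0")
    ep = int(round(epoch_s * rec.fs))
    nb = int(round(baseline_s * rec.fs))
    epochs = []
    for k in range(rec.n_samples // ep):
        chunk = rec.data[:, k * ep:(k + 1) * ep].copy()
        if nb > 0:
            chunk -= chunk[:, :nb].mean(axis=1, keepdims=True)
        epochs.append(Recording(rec.subject_id, f"{rec.trial_id}_e{k:03d}",
                                rec.fs, chunk, rec.montage))
    return epochs


def decompose_bands(rec: Recording, bandset: BandSet | None = None
                    ) -> dict[str, Recording]:
    """One zero-phase band-passed copy of the recording per band, in
    bandset order."""
    bandset = bandset or BandSet.default()
    return {name: rec.copy_with(bandpass(rec.data, rec.fs, (lo, hi)))
            for name, lo, hi in bandset}


# ---------------------------------------------------------------------------
# Empirical mode decomposition
# ---------------------------------------------------------------------------

@dataclass
class IMFSet:
    """Ordered intrinsic mode functions plus the monotone-ish residue.

    By construction ``imfs.sum(0) + residue`` reproduces the input to
    floating-point accuracy; a well-separated IMF has extrema and
    zero-crossing counts differing by at most one.
    """

    imfs: np.ndarray      # (n_imfs, n) — possibly empty first axis
    residue: np.ndarray   # (n,)

    @property
    def n_imfs(self) -> int:
        return self.imfs.shape[0]

    def reconstruct(self) -> np.ndarray:
        return self.imfs.sum(axis=0) + self.residue


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.diff(x)
    maxima = np.flatnonzero((d[:-1] > 0) & (d[1:] <= 0)) + 1
    minima = np.flatnonzero((d[:-1] < 0) & (d[1:] >= 0)) + 1
    return maxima, minima


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    # anchor the spline at the signal ends to tame edge swings
    n = len(x)
    knots = np.concatenate(([0], idx, [n - 1]))
    vals = x[knots]
    keep = np.concatenate(([True], np.diff(knots) > 0))
    return CubicSpline(knots[keep], vals[keep])(np.arange(n))


def _is_monotone(x: np.ndarray) -> bool:
    d = np.diff(x)
    return bool(np.all(d >= 0) or np.all(d <= 0))


def emd(x: np.ndarray, max_imfs: int = 10, sift_tol: float = 0.05,
        max_sifts: int = 64) -> IMFSet:
    """Empirical mode decomposition by sifting with cubic-spline envelopes.

    A sift stops when the RMS of the mean envelope drops below
    ``sift_tol`` times the RMS of the current component; decomposition
    stops when the residue is monotone, has too few extrema, or
    ``max_imfs`` is reached.  A signal with too few extrema to sift is
    returned unchanged as the residue with zero IMFs.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 16:
        raise ValidationError("emd expects a 1-D signal of length >= 16")
    if not np.all(np.isfinite(x)):
        raise ValidationError("emd input must be finite")

    residue = x.copy()
    imfs: list[np.ndarray] = []
    while len(imfs) < max_imfs and not _is_monotone(residue):
        maxima, minima = _local_extrema(residue)
        if len(maxima) < 2 or len(minima) < 2:
            break
        h = residue.copy()
        for _ in range(max_sifts):
            maxima, minima = _local_extrema(h)
            if len(maxima) < 2 or len(minima) < 2:
                break
            mean_env = 0.5 * (_envelope(h, maxima) + _envelope(h, minima))
            h_rms = np.sqrt(np.mean(h ** 2))
            if h_rms == 0 or np.sqrt(np.mean(mean_env ** 2)) < sift_tol * h_rms:
                h = h - mean_env
                break
            h = h - mean_env
        imfs.append(h)
        residue = residue - h

    imf_arr = np.vstack(imfs) if imfs else np.empty((0, len(x)))
    return IMFSet(imf_arr, residue)


def analytic_phase(x: np.ndarray) -> np.ndarray:
    """Instantaneous phase in (-pi, pi] via the Hilbert analytic signal."""
    x = np.asarray(x, dtype=float)
    return np.angle(signal.hilbert(x, axis=-1))
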