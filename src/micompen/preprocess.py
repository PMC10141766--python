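"""Conventional filtering and SOBI-based ICA artifact rejection.

The denoising model is linear instantaneous mixing ``x(t) = A s(t)``:
sources are estimated as ``y(t) = W x(t)`` by second-order blind
identification (SOBI, joint approximate diagonalisation of time-lagged
covariance matrices), components are flagged as ocular artifacts when
their zero-lag normalised cross-correlation with any EOG reference
channel exceeds a threshold, flagged source rows are zeroed, and the
cleaned recording is reconstructed as ``x̂(t) = A ŝ(t)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .eeg_io import RawRecording

logger = logging.getLogger(__name__)


class DegenerateSignalError(ValueError):
    """Raised when a computation is undefined on the given signal."""


# ---------------------------------------------------------------------------
# conventional filters (zero-phase: forward-backward IIR)

def _filter_recording(rec: RawRecording, b: np.ndarray, a: np.ndarray) -> RawRecording:
    out = sps.filtfilt(b, a, rec.data, axis=1)
    return rec.copy_with(out)


def notch_filter(rec: RawRecording, freq: float = 50.0, q: float = 30.0) -> RawRecording:
    """Zero-phase IIR notch (second-order, quality factor ``q``)."""
    if not 0 < freq < rec.fs / 2:
        raise ValueError(f"notch frequency {freq} outside (0, Nyquist)")
    b, a = sps.iirnotch(freq, q, fs=rec.fs)
    return _filter_recording(rec, b, a)


def bandpass_filter(rec: RawRecording, low: float = 8.0, high: float = 30.0,
                    order: int = 4) -> RawRecording:
    """Zero-phase Butterworth band-pass (default 8-30 Hz, order 4)."""
    if not 0 < low < high < rec.fs / 2:
        raise ValueError(f"invalid band ({low}, {high}) for fs={rec.fs}")
    b, a = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs)
    return _filter_recording(rec, b, a)


# ---------------------------------------------------------------------------
# zero-lag normalised cross-correlation

def xcorr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson-form normalised cross-correlation at zero lag.

    Σ(x−x̄)(y−ȳ) / sqrt(Σ(x−x̄)² · Σ(y−ȳ)²), in [−1, 1].
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("xcorr needs two equal-length series of length >= 2")
    xd, yd = x - x.mean(), y - y.mean()
    denom = np.sqrt((xd @ xd) * (yd @ yd))
    if denom == 0:
        raise DegenerateSignalError("xcorr undefined for zero-variance input")
    return float((xd @ yd) / denom)


# ---------------------------------------------------------------------------
# SOBI

@dataclass
class ICDecomposition:
    """Result of a blind source separation of the EEG channels."""

    mixing: np.ndarray        # channels x components (A)
    unmixing: np.ndarray      # components x channels (W)
    sources: np.ndarray       # components x samples (y)
    channel_indices: np.ndarray   # rows of the recording the BSS was fit on
    xcorr_scores: np.ndarray | None = None   # components x eog channels, |r|
    artifact_flags: np.ndarray | None = None
    low_confidence: bool = False

    @property
    def n_components(self) -> int:
        return self.sources.shape[0]


def _joint_diagonalize(mats: np.ndarray, tol: float = 1e-8,
                       max_sweeps: int = 100) -> np.ndarray:
    """Orthogonal joint approximate diagonalisation (Jacobi rotations).

    Given symmetric matrices ``mats[k]``, returns orthogonal V maximising
    the sum of squared diagonals of Vᵀ mats[k] V (Cardoso & Souloumiac's
    Givens-angle update specialised to the real symmetric case).
    """
    K, n, _ = mats.shape
    M = mats.copy()
    V = np.eye(n)
    for _ in range(max_sweeps):
        rotated = False
        for p in range(n - 1):
            for q in range(p + 1, n):
                # 2x2 subproblem over all K matrices
                h1 = M[:, p, p] - M[:, q, q]
                h2 = M[:, p, q] + M[:, q, p]
                G = np.array([[h1 @ h1, h1 @ h2], [h2 @ h1, h2 @ h2]])
                evals, evecs = np.linalg.eigh(G)
                x, y = evecs[:, -1]
                if x < 0:
                    x, y = -x, -y
                r = np.hypot(x, y)
                c = np.sqrt((x + r) / (2 * r))
                s = y / (2 * c * r)
                if abs(s) > tol:
                    rotated = True
                    rot = np.array([[c, -s], [s, c]])
                    idx = [p, q]
                    M[:, idx, :] = np.einsum("ij,kjl->kil", rot.T, M[:, idx, :])
                    M[:, :, idx] = np.einsum("kij,jl->kil", M[:, :, idx], rot)
                    V[:, idx] = V[:, idx] @ rot
        if not rotated:
            break
    return V


def sobi(rec: RawRecording, n_lags: int = 100,
         rank_tol: float = 1e-10) -> ICDecomposition:
    """Second-order blind identification of the EEG channels.

    Channels are zero-meaned and whitened (PCA), time-lagged covariance
    matrices at lags 1..``n_lags`` are jointly diagonalised by Jacobi
    rotations, and the unmixing matrix is the composition of the rotation
    and the whitener.  EOG channels are excluded from the decomposition;
    they serve only as artifact references downstream.

    If the channel covariance is rank deficient the decomposition is
    reduced to the numerical rank, with a warning.  If the data carry no
    temporal structure (all lagged covariances ≈ 0, e.g. i.i.d. white
    sources) the result is flagged ``low_confidence`` — SOBI's
    identifiability assumption is violated and the rotation is arbitrary.
    """
    eeg_idx = rec.eeg_indices
    X = rec.data[eeg_idx] - rec.data[eeg_idx].mean(axis=1, keepdims=True)
    n_ch, T = X.shape
    if T < 10 * n_ch:
        raise ValueError(f"too few samples ({T}) for {n_ch} channels")
    if not 1 <= n_lags < T:
        raise ValueError("n_lags must be in [1, n_samples)")

    C0 = (X @ X.T) / T
    evals, evecs = np.linalg.eigh(C0)
    keep = evals > rank_tol * evals.max()
    if not keep.all():
        warnings.warn(f"rank-deficient covariance: keeping {keep.sum()}/{n_ch} "
                      "dimensions", RuntimeWarning, stacklevel=2)
    evals, evecs = evals[keep], evecs[:, keep]
    whitener = evecs / np.sqrt(evals)          # n_ch x rank
    Z = whitener.T @ X                         # rank x T

    lags = range(1, n_lags + 1)
    R = np.stack([
        0.5 * (Z[:, :-tau] @ Z[:, tau:].T + Z[:, tau:] @ Z[:, :-tau].T) / (T - tau)
        for tau in lags])
    off_energy = float(np.sum(R ** 2))
    low_conf = off_energy < 1e-3 * len(R) * Z.shape[0]
    if low_conf:
        warnings.warn("lagged covariances are near zero: sources lack temporal "
                      "structure, SOBI rotation is not identifiable",
                      RuntimeWarning, stacklevel=2)

    V = _joint_diagonalize(R)
    unmixing = V.T @ whitener.T                # comps x n_ch
    mixing = np.linalg.pinv(unmixing)          # n_ch x comps
    sources = unmixing @ X
    return ICDecomposition(mixing=mixing, unmixing=unmixing, sources=sources,
                           channel_indices=eeg_idx, low_confidence=low_conf)


# ---------------------------------------------------------------------------
# artifact flagging and reconstruction

def score_components(dec: ICDecomposition, eog: np.ndarray) -> np.ndarray:
    """|XCorr| of every component against every EOG channel."""
    eog = np.atleast_2d(np.asarray(eog, dtype=float))
    scores = np.empty((dec.n_components, eog.shape[0]))
    for i in range(dec.n_components):
        for j in range(eog.shape[0]):
            try:
                scores[i, j] = abs(xcorr(dec.sources[i], eog[j]))
            except DegenerateSignalError:
                scores[i, j] = 0.0
    return scores


def flag_and_zero(dec: ICDecomposition, rec: RawRecording,
                  threshold: float = 0.5) -> tuple[ICDecomposition, RawRecording]:
    """Flag EOG-correlated components, zero them, reconstruct the EEG.

    A component is flagged iff its maximum |XCorr| over the recording's
    EOG channels is >= ``threshold``.  Flagged source rows are set to
    zero and the EEG channels are rebuilt as ``x̂ = A ŝ``; EOG channels
    are passed through unchanged.  Refuses to run if every component
    would be flagged (cleaning would null the data).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    eog_idx = rec.eog_indices
    if len(eog_idx) == 0:
        raise ValueError("recording has no EOG channels to reference against")
    eog = rec.data[eog_idx]
    if eog.shape[1] != dec.sources.shape[1]:
        raise ValueError("EOG channels and sources are not time-aligned")

    scores = score_components(dec, eog)
    flags = scores.max(axis=1) >= threshold
    if flags.all():
        raise RuntimeError("all components flagged as artifacts; refusing to "
                           "zero the entire recording (raise the threshold)")
    logger.info("flagged %d/%d components at threshold %.2f",
                int(flags.sum()), dec.n_components, threshold)

    s_hat = dec.sources.copy()
    s_hat[flags] = 0.0
    flagged_dec = ICDecomposition(
        mixing=dec.mixing, unmixing=dec.unmixing, sources=s_hat,
        channel_indices=dec.channel_indices, xcorr_scores=scores,
        artifact_flags=flags, low_confidence=dec.low_confidence)

    cleaned = rec.data.copy()
    eeg_idx = dec.channel_indices
    means = rec.data[eeg_idx].mean(axis=1, keepdims=True)
    cleaned[eeg_idx] = dec.mixing @ s_hat + means
    return flagged_dec, rec.copy_with(cleaned)


def denoise(rec: RawRecording, notch: float | None = 50.0,
            band: tuple[float, float] | None = (8.0, 30.0),
            n_lags: int = 100, threshold: float = 0.5,
            ) -> tuple[RawRecording, ICDecomposition]:
    """Full conventional + ICA denoising chain on a continuous recording.

    Order: notch, then SOBI artifact zeroing on the wideband data, then
    band-pass.  The ICA step runs before the band-pass because ocular
    activity is concentrated below 8 Hz — band-passing first would strip
    most of the very energy the EOG-correlation criterion needs to
    identify blink components.
    """
    out = rec
    if notch is not None:
        out = notch_filter(out, notch)
    dec = sobi(out, n_lags=n_lags)
    dec, out = flag_and_zero(dec, out, threshold=threshold)
    if band is not None:
        out = bandpass_filter(out, *band)
    return out, dec
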