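"""Complexity features: Higuchi fractal dimension and rescaled-range Hurst.

Both are defined on fixed-length windows (default 1500 samples = 6 s at
250 Hz).  The Higuchi dimension measures how reconstructed curve length
L(k) scales with the coarse-graining interval k; the Hurst exponent
measures long-range persistence via the scaling of the rescaled range
R/S with block length n.  For a fractional-Brownian-motion trace with
Hurst exponent H the two are linked by FD = 2 − H.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import DegenerateSignalError

__all__ = ["HiguchiConfig", "HurstConfig", "higuchi_fd", "hurst_rs"]


@dataclass
class HiguchiConfig:
    kmax: int = 20
    window_samples: int = 1500

    def __post_init__(self) -> None:
        if not 2 <= self.kmax < self.window_samples / 2:
            raise ValueError("need 2 <= kmax < window_samples/2")


@dataclass
class HurstConfig:
    window_samples: int = 1500
    min_subset: int = 16
    use_log_returns: bool = False

    def __post_init__(self) -> None:
        if self.min_subset < 8:
            raise ValueError("min_subset must be >= 8")
        if self.window_samples < 4 * self.min_subset:
            raise ValueError("window_samples must be >= 4 * min_subset")


def higuchi_fd(x: np.ndarray, cfg: HiguchiConfig | None = None, *,
               kmax: int | None = None) -> float:
    """Higuchi fractal dimension of a 1-D window.

    For each interval k = 1..kmax and offset m = 1..k, the decimated
    sub-series x[m], x[m+k], ... yields a curve length

        L_m(k) = [ Σ |x[m+ik] − x[m+(i−1)k]| · (N−1)/(⌊(N−m)/k⌋·k) ] / k,

    averaged over m to L(k); the estimate is the least-squares slope of
    ln L(k) against ln(1/k).  A value outside [1, 2] is reported as-is
    with a warning (never silently clipped).
    """
    x = np.asarray(x, dtype=float).ravel()
    if cfg is None:
        cfg = HiguchiConfig(window_samples=len(x),
                            kmax=20 if kmax is None else kmax)
    elif len(x) != cfg.window_samples:
        raise ValueError(f"window length {len(x)} != configured "
                         f"{cfg.window_samples}")
    if not np.isfinite(x).all():
        raise ValueError("window contains non-finite values")
    N = len(x)
    if np.ptp(x) == 0:
        raise DegenerateSignalError("constant window: curve length is zero")

    L = np.empty(cfg.kmax)
    for k in range(1, cfg.kmax + 1):
        Lm = np.empty(k)
        for m in range(1, k + 1):
            sub = x[m - 1::k]
            n_int = (N - m) // k  # intervals in the decimated series
            d = np.abs(np.diff(sub[:n_int + 1])).sum()
            Lm[m - 1] = d * (N - 1) / (n_int * k) / k
        L[k - 1] = Lm.mean()
    k_arr = np.arange(1, cfg.kmax + 1)
    ok = L > 0
    if not ok.all():
        warnings.warn(f"curve length zero at {int((~ok).sum())} interval(s); "
                      "excluded from the log-log fit", RuntimeWarning,
                      stacklevel=2)
        if ok.sum() < 2:
            raise DegenerateSignalError("too few usable intervals for the fit")
    slope = np.polynomial.polynomial.polyfit(np.log(1.0 / k_arr[ok]),
                                             np.log(L[ok]), 1)[1]
    fd = float(slope)
    # estimates jitter a hair past the theoretical range on finite noise;
    # only a substantive excursion is worth flagging (value is never clipped)
    if not 1.0 - 0.05 <= fd <= 2.0 + 0.05:
        warnings.warn(f"Higuchi FD {fd:.4f} outside [1, 2]; reporting unclipped",
                      RuntimeWarning, stacklevel=2)
    return fd


def _dyadic_block_lengths(N: int, n_min: int) -> list[int]:
    out, n = [], n_min
    while n <= N // 2:
        out.append(n)
        n *= 2
    return out


def hurst_rs(x: np.ndarray, cfg: HurstConfig | None = None) -> float:
    """Rescaled-range (R/S) Hurst exponent of a 1-D window.

    For each block length n on a dyadic grid (min_subset, 2·min_subset,
    ... <= N/2) the window is split into m = ⌊N/n⌋ adjacent blocks
    (remainder samples discarded).  Per block: mean, cumulative
    deviations X_k, range R = max X_k − min X_k, standard deviation S;
    blocks with S = 0 are excluded with a warning.  The estimate is the
    least-squares slope of log mean(R/S) against log n.

    With ``use_log_returns`` the window is first transformed to
    log(x[i+1]/x[i]) (requires strictly positive values); the default
    analyses the signal directly, since band-passed EEG crosses zero.
    """
    if cfg is None:
        cfg = HurstConfig(window_samples=len(np.asarray(x).ravel()))
    x = np.asarray(x, dtype=float).ravel()
    if len(x) != cfg.window_samples:
        raise ValueError(f"window length {len(x)} != configured "
                         f"{cfg.window_samples}")
    if cfg.use_log_returns:
        if np.any(x <= 0):
            raise ValueError("log-returns transform requires positive values")
        x = np.log(x[1:] / x[:-1])
    if np.ptp(x) == 0:
        raise DegenerateSignalError("constant window: R/S undefined")

    N = len(x)
    log_n, log_rs = [], []
    n_excluded = 0
    for n in _dyadic_block_lengths(N, cfg.min_subset):
        m = N // n
        blocks = x[:m * n].reshape(m, n)
        dev = np.cumsum(blocks - blocks.mean(axis=1, keepdims=True), axis=1)
        R = dev.max(axis=1) - dev.min(axis=1)
        S = blocks.std(axis=1)
        ok = S > 0
        n_excluded += int((~ok).sum())
        if not ok.any():
            continue
        log_n.append(np.log(n))
        log_rs.append(np.log((R[ok] / S[ok]).mean()))
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} zero-variance blocks from R/S",
                      RuntimeWarning, stacklevel=2)
    if len(log_n) < 2:
        raise DegenerateSignalError("fewer than two usable block lengths")
    slope = np.polynomial.polynomial.polyfit(log_n, log_rs, 1)[1]
    return float(slope)
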