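"""Irregularity features: Tsallis entropy and dispersion entropy.

Tsallis entropy generalises Shannon entropy with a non-extensivity
parameter q; for signals it is evaluated either from an amplitude
histogram (Eq.-15 form on bin probabilities) or through Sneddon's
critical-point approximation for q = 2, which scores how much of the
signal's variance is explained by segmentation at its local extrema:

    S_T ≈ 1 − (1/N) Σ_i s_i² / σ²

with N bins delimited by critical points of the discrete derivative,
s_i² the within-bin variance and σ² the whole-window variance.

Dispersion entropy is the Shannon entropy of coarse-grained "dispersion
patterns": samples are mapped to c integer classes (normal-CDF mapping
by default), embedded into length-m vectors at delay d, and the pattern
distribution is entropied.  It is bounded by ln(c^m).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .preprocess import DegenerateSignalError

__all__ = ["TsallisConfig", "DispersionConfig", "tsallis_q",
           "tsallis_sneddon", "tsallis_histogram", "dispersion_entropy"]


@dataclass
class TsallisConfig:
    q: float = 2.0
    mode: str = "sneddon"          # "sneddon" | "histogram"
    n_bins: int = 16               # histogram mode only

    def __post_init__(self) -> None:
        if self.q <= 0:
            raise ValueError("q must be positive")
        if self.mode not in ("sneddon", "histogram"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass
class DispersionConfig:
    m: int = 2                     # embedding dimension
    c: int = 2                     # number of classes
    d: int = 1                     # time delay
    mapping: str = "ncdf"          # "ncdf" | "identity"

    def __post_init__(self) -> None:
        if self.m < 2 or self.c < 2 or self.d < 1:
            raise ValueError("need m >= 2, c >= 2, d >= 1")
        if self.mapping not in ("ncdf", "identity"):
            raise ValueError(f"unknown mapping {self.mapping!r}")


def tsallis_q(p: np.ndarray, q: float) -> float:
    """Tsallis entropy (1 − Σ pᵢ^q)/(q − 1) of a probability vector.

    q = 1 dispatches to the Shannon limit −Σ pᵢ ln pᵢ (natural log),
    which is the continuous limit of the q-logarithm form.
    """
    p = np.asarray(p, dtype=float).ravel()
    if np.any(p < -1e-12):
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {p.sum()}, not 1")
    p = p[p > 0]
    if q == 1.0:
        return float(-(p * np.log(p)).sum())
    return float((1.0 - (p ** q).sum()) / (q - 1.0))


def _critical_points(x: np.ndarray) -> np.ndarray:
    """Indices where the discrete derivative is zero or changes sign.

    The derivative d[i] = x[i+1] − x[i] is examined left to right; index
    i (1 <= i <= N−2) is critical when d[i] = 0 or sign(d[i]) differs
    from the sign of the most recent nonzero derivative (local extrema
    and plateau onsets).
    """
    d = np.diff(x)
    crit = []
    prev_sign = 0
    for i, di in enumerate(d):
        s = int(np.sign(di))
        if i > 0 and (s == 0 or (prev_sign != 0 and s != prev_sign)):
            crit.append(i)
        if s != 0:
            prev_sign = s
    return np.asarray(crit, dtype=int)


def tsallis_sneddon(x: np.ndarray) -> float:
    """Sneddon critical-point approximation of Tsallis entropy (q = 2).

    Returns 1 − (1/N)·Σ s_i²/σ² over the N bins delimited by consecutive
    critical points of the signal (bin i spans samples [c_i, c_{i+1});
    the window edges act as outer boundaries).  Bounded above by 1;
    equals 1 when every bin is internally constant, 0 when every bin's
    variance equals the global variance.
    """
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < 3:
        raise ValueError("window must have at least 3 samples")
    sigma2 = x.var()
    if sigma2 == 0:
        raise DegenerateSignalError("zero global variance")
    crit = _critical_points(x)
    if len(crit) < 2:
        warnings.warn("fewer than 2 critical points: single-bin result",
                      RuntimeWarning, stacklevel=2)
    bounds = np.concatenate([[0], crit, [len(x)]])
    bounds = np.unique(bounds)
    ratios = [x[a:b].var() / sigma2
              for a, b in zip(bounds[:-1], bounds[1:]) if b - a >= 1]
    return float(1.0 - np.mean(ratios))


def tsallis_histogram(x: np.ndarray, cfg: TsallisConfig | None = None) -> float:
    """Tsallis entropy of the amplitude histogram of a window."""
    if cfg is None:
        cfg = TsallisConfig(mode="histogram")
    x = np.asarray(x, dtype=float).ravel()
    if np.ptp(x) == 0:
        raise DegenerateSignalError("zero global variance")
    counts, _ = np.histogram(x, bins=cfg.n_bins)
    return tsallis_q(counts / counts.sum(), cfg.q)


def _map_to_classes(x: np.ndarray, c: int) -> np.ndarray:
    """Normal-CDF mapping of a signal to integer classes 1..c.

    y = Φ((x − μ)/σ), class = round(c·y + 0.5) clipped into [1, c]; the
    mapping adapts to the signal's own location and scale, making the
    pattern distribution invariant to positive affine transforms.
    """
    mu, sd = x.mean(), x.std()
    if sd == 0:
        return np.ones(len(x), dtype=int)
    y = ndtr((x - mu) / sd)
    z = np.round(c * y + 0.5).astype(int)
    return np.clip(z, 1, c)


def dispersion_entropy(x: np.ndarray, cfg: DispersionConfig | None = None) -> float:
    """Dispersion entropy of a window, in [0, ln(c^m)].

    With N samples, delay d and embedding m there are N − (m−1)·d
    dispersion patterns; their relative frequencies p(π) give
    DispEn = −Σ p(π) ln p(π).  A constant signal maps to a single class
    and returns 0 with a warning.
    """
    if cfg is None:
        cfg = DispersionConfig()
    x = np.asarray(x, dtype=float).ravel()
    N = len(x)
    if N <= (cfg.m - 1) * cfg.d + 1:
        raise ValueError(f"window too short (N={N}) for m={cfg.m}, d={cfg.d}")
    if cfg.c ** cfg.m >= N:
        warnings.warn(f"c^m = {cfg.c ** cfg.m} >= N = {N}: pattern "
                      "probabilities will be undersampled", RuntimeWarning,
                      stacklevel=2)
    if cfg.mapping == "identity":
        u = np.asarray(np.round(x), dtype=int)
        if u.min() < 1 or u.max() > cfg.c:
            raise ValueError("identity mapping requires classes in 1..c")
    else:
        if np.ptp(x) == 0:
            warnings.warn("constant signal: dispersion entropy is 0",
                          RuntimeWarning, stacklevel=2)
            return 0.0
        u = _map_to_classes(x, cfg.c)

    n_pat = N - (cfg.m - 1) * cfg.d
    emb = np.stack([u[j * cfg.d: j * cfg.d + n_pat] for j in range(cfg.m)], axis=1)
    codes = emb @ (cfg.c ** np.arange(cfg.m))   # injective pattern encoding
    _, counts = np.unique(codes, return_counts=True)
    p = counts / n_pat
    return float(-(p * np.log(p)).sum())
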