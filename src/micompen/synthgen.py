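"""Synthetic four-class motor-imagery EEG with known ground truth.

The generator emulates the phenomenology the analysis pipeline targets:

* a Graz-style trial schedule (fixation 0-2 s, cue at 2 s, imagery 2-6 s,
  configurable inter-trial gap),
* class-dependent signal complexity — during the imagery window the
  designated channels carry fractional Gaussian noise (fGn) with a
  class-specific Hurst exponent, plus a 10 Hz mu oscillation whose
  amplitude is attenuated by the class's ERD depth,
* ocular artifacts — smooth biphasic blink pulses written to the EOG
  channels and propagated to frontal EEG channels,
* 50 Hz line interference on all channels,
* linear instantaneous mixing of the EEG sources by a random full-rank
  matrix, recorded in the ground truth so blind-source-separation
  recovery can be scored.

fGn is synthesised by exact-autocovariance circulant embedding
(Davies-Harte), so the Hurst exponent of every source is known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .eeg_io import (
    CLASS_ORDER,
    DEFAULT_CLASS_EVENT_CODES,
    DEFAULT_EEG_LABELS,
    DEFAULT_EOG_LABELS,
    RawRecording,
)

__all__ = [
    "ClassSignature",
    "ArtifactSpec",
    "GroundTruth",
    "generate_fgn",
    "generate_fbm",
    "generate_recording",
    "default_signatures",
]


@dataclass
class ClassSignature:
    """Per-class signal signature planted during the imagery window."""

    class_label: str
    hurst: float
    erd_depth: float = 0.5
    erd_channels: tuple[str, ...] = ()
    osc_amplitude: float = 10.0  # µV, 10 Hz mu rhythm at rest

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_ORDER:
            raise ValueError(f"unknown class {self.class_label!r}")
        if not 0.0 < self.hurst < 1.0:
            raise ValueError("hurst must lie strictly in (0, 1)")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must lie in [0, 1]")


@dataclass
class ArtifactSpec:
    """Blink and line-noise parameters."""

    blink_rate: float = 12.0          # events per minute
    blink_amplitude: float = 80.0     # µV at the EOG channels
    blink_frontal_gain: dict[str, float] = field(default_factory=dict)
    line_freq: float = 50.0           # Hz
    line_amplitude: float = 2.0       # µV

    def __post_init__(self) -> None:
        if min(self.blink_rate, self.blink_amplitude, self.line_amplitude) < 0:
            raise ValueError("rates and amplitudes must be non-negative")
        if self.line_freq <= 0:
            raise ValueError("line_freq must be positive")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    mixing_matrix: np.ndarray          # EEG channels x sources (incl. artifact col)
    source_signals: np.ndarray         # sources x samples
    artifact_source_indices: tuple[int, ...]
    class_labels: np.ndarray           # per trial
    trial_onsets: np.ndarray           # sample index of each trial start
    hurst_per_class: dict[str, float]
    blink_onsets: np.ndarray           # sample indices of blink centres


def _fgn_autocov(n: int, hurst: float) -> np.ndarray:
    k = np.arange(n, dtype=float)
    return 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst)
                  + np.abs(k - 1) ** (2 * hurst))


def generate_fgn(n: int, hurst: float, seed: int | np.random.Generator) -> np.ndarray:
    """Exact-covariance fractional Gaussian noise via circulant embedding.

    The returned series has unit variance and autocovariance
    γ(k) = ½(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}) by construction
    (Davies-Harte synthesis: the circulant embedding of γ is diagonalised
    by the FFT and sampled in the spectral domain).
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError("hurst must lie strictly in (0, 1)")
    if n < 16:
        # embed in a longer series; exactness is unaffected by truncation
        return generate_fgn(16, hurst, seed)[:n]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gamma = _fgn_autocov(n, hurst)
    circ = np.concatenate([gamma, gamma[-2:0:-1]])   # length m = 2n - 2
    m = len(circ)
    lam = np.fft.rfft(circ).real
    if lam.min() < -1e-8 * lam.max():
        raise RuntimeError(
            f"circulant embedding not positive semi-definite for H={hurst} "
            f"(min eigenvalue {lam.min():.3e}); increase n")
    lam = np.clip(lam, 0.0, None)
    z = rng.standard_normal(m // 2 + 1) + 1j * rng.standard_normal(m // 2 + 1)
    z[0] = np.sqrt(2.0) * z[0].real
    z[-1] = np.sqrt(2.0) * z[-1].real
    x = np.fft.irfft(z * np.sqrt(lam * m / 2.0), n=m)
    return x[:n]


def generate_fbm(n: int, hurst: float, seed: int | np.random.Generator) -> np.ndarray:
    """Fractional Brownian motion trace: cumulative sum of exact fGn.

    The graph of fBm with Hurst exponent H has fractal dimension 2 − H,
    which makes this the ground-truth process for fractal-dimension
    estimator checks (raw fGn itself is dimension ≈ 2 for every H).
    """
    return np.cumsum(generate_fgn(n, hurst, seed))


def default_signatures(montage_eeg: tuple[str, ...] = DEFAULT_EEG_LABELS,
                       hurst_gap: float | None = None) -> dict[str, ClassSignature]:
    """Well-separated per-class signatures on disjoint channel groups.

    The four classes carry Hurst exponents 0.35 / 0.50 / 0.65 / 0.80 on
    disjoint quarters of the montage, with ERD depths 0.6 / 0.5 / 0.4 / 0.3.
    ``hurst_gap`` optionally rescales the spread around 0.575 (gap = the
    difference between consecutive class exponents) for separability
    sweeps; ``hurst_gap=0`` collapses all classes onto H = 0.575.
    """
    hursts = np.array([0.35, 0.50, 0.65, 0.80])
    if hurst_gap is not None:
        hursts = 0.575 + (hursts - 0.575) * (hurst_gap / 0.15)
    depths = [0.6, 0.5, 0.4, 0.3]
    n = len(montage_eeg)
    groups = [tuple(montage_eeg[i * n // 4:(i + 1) * n // 4]) for i in range(4)]
    return {
        cls: ClassSignature(class_label=cls, hurst=float(h), erd_depth=d,
                            erd_channels=grp)
        for cls, h, d, grp in zip(CLASS_ORDER, hursts, depths, groups)
    }


def _blink_pulse(fs: float, width_s: float = 0.3, lobe_s: float = 0.03,
                 sep_s: float = 0.06) -> np.ndarray:
    """Gaussian-windowed biphasic pulse of ``width_s`` total extent.

    Two opposite-sign Gaussian lobes (sigma ``lobe_s``, centres ``sep_s``
    apart) under a Gaussian envelope: smooth ocular-artifact morphology
    whose rise time is sharp enough that part of its energy (~1/3 RMS)
    survives an 8-30 Hz band-pass, as eye blinks do.
    """
    n = int(round(width_s * fs))
    t = np.linspace(-width_s / 2, width_s / 2, n)
    env = np.exp(-0.5 * (t / (width_s / 4)) ** 2)
    pulse = env * (np.exp(-0.5 * ((t + sep_s / 2) / lobe_s) ** 2)
                   - np.exp(-0.5 * ((t - sep_s / 2) / lobe_s) ** 2))
    return pulse / np.abs(pulse).max()


def generate_recording(
    montage_eeg: tuple[str, ...] = DEFAULT_EEG_LABELS,
    montage_eog: tuple[str, ...] = DEFAULT_EOG_LABELS,
    n_trials: int = 8,
    signatures: dict[str, ClassSignature] | None = None,
    artifacts: ArtifactSpec | None = None,
    fs: float = 250.0,
    seed: int | np.random.Generator = 0,
    intertrial_gap_s: float = 1.5,
    background_rms: float = 8.0,
) -> tuple[RawRecording, GroundTruth]:
    """Generate a continuous recording with ``n_trials`` balanced trials.

    Trial timing: fixation 0-2 s, cue at 2 s, imagery 2-6 s, then
    ``intertrial_gap_s`` of rest.  One trial-onset event per trial is
    emitted with the Graz class codes (769-772).  EEG sources are mixed
    by a random full-rank matrix; the blink source is propagated to the
    frontal EEG channels and to the EOG channels unmixed.
    """
    if len(montage_eeg) < 2 or len(montage_eog) < 1:
        raise ValueError("need at least 2 EEG channels and 1 EOG channel")
    if n_trials % len(CLASS_ORDER):
        raise ValueError(f"n_trials={n_trials} not divisible by {len(CLASS_ORDER)} "
                         "(balanced classes required)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if signatures is None:
        signatures = default_signatures(montage_eeg)
    if artifacts is None:
        artifacts = ArtifactSpec()
    for sig in signatures.values():
        unknown = set(sig.erd_channels) - set(montage_eeg)
        if unknown:
            raise ValueError(f"erd_channels not in montage: {sorted(unknown)}")

    n_eeg, n_eog = len(montage_eeg), len(montage_eog)
    trial_len = int(round((6.0 + intertrial_gap_s) * fs))
    imagery = slice(int(round(2.0 * fs)), int(round(6.0 * fs)))
    n_samples = n_trials * trial_len
    t = np.arange(n_samples) / fs

    # balanced, shuffled class sequence
    labels = np.repeat(CLASS_ORDER, n_trials // 4)
    rng.shuffle(labels)
    onsets = np.arange(n_trials) * trial_len

    # neural sources: one per EEG channel slot; background fGn (H=0.5) with
    # a continuous mu rhythm, overwritten in imagery windows on ERD channels
    sources = np.empty((n_eeg, n_samples))
    osc_amp = np.empty((n_eeg, n_samples))
    for i, ch in enumerate(montage_eeg):
        sources[i] = background_rms * generate_fgn(n_samples, 0.5, rng)
        amp = next((s.osc_amplitude for s in signatures.values()
                    if ch in s.erd_channels), 10.0)
        osc_amp[i] = amp
    for trial, (onset, cls) in enumerate(zip(onsets, labels)):
        sig = signatures[cls]
        win = slice(onset + imagery.start, onset + imagery.stop)
        n_win = win.stop - win.start
        for i, ch in enumerate(montage_eeg):
            if ch in sig.erd_channels:
                sources[i, win] = background_rms * generate_fgn(n_win, sig.hurst, rng)
                osc_amp[i, win] = sig.osc_amplitude * (1.0 - sig.erd_depth)
    phases = rng.uniform(0, 2 * np.pi, n_eeg)
    sources += osc_amp * np.sin(2 * np.pi * 10.0 * t[None, :] + phases[:, None])

    # blink artifact source
    blink = np.zeros(n_samples)
    blink_onsets = np.array([], dtype=int)
    if artifacts.blink_rate > 0 and artifacts.blink_amplitude > 0:
        pulse = _blink_pulse(fs)
        n_blinks = max(1, int(round(artifacts.blink_rate * n_samples / fs / 60.0)))
        lo, hi = len(pulse), n_samples - len(pulse)
        blink_onsets = np.sort(rng.integers(lo, hi, size=n_blinks))
        for c in blink_onsets:
            start = c - len(pulse) // 2
            blink[start:start + len(pulse)] += artifacts.blink_amplitude * pulse
    sources_all = np.vstack([sources, blink[None, :]])

    # mixing: near-identity + random spread, checked full rank
    mix_eeg = np.eye(n_eeg) + 0.15 * rng.standard_normal((n_eeg, n_eeg))
    if np.linalg.matrix_rank(mix_eeg) < n_eeg:  # pragma: no cover
        mix_eeg += 0.05 * np.eye(n_eeg)
    frontal_gain = np.array([
        artifacts.blink_frontal_gain.get(
            ch, 0.35 if ch.upper().startswith(("F", "AF")) else 0.02)
        for ch in montage_eeg])
    mixing = np.hstack([mix_eeg, frontal_gain[:, None]])  # n_eeg x (n_eeg + 1)

    eeg = mixing @ sources_all
    eog = np.empty((n_eog, n_samples))
    for j in range(n_eog):
        eog[j] = blink + 3.0 * rng.standard_normal(n_samples)

    data = np.vstack([eeg, eog])
    if artifacts.line_amplitude > 0:
        line = artifacts.line_amplitude * np.sin(2 * np.pi * artifacts.line_freq * t)
        data += line[None, :]

    events = [(int(s), DEFAULT_CLASS_EVENT_CODES[cls])
              for s, cls in zip(onsets, labels)]
    rec = RawRecording(
        data=data, fs=fs,
        channel_labels=list(montage_eeg) + list(montage_eog),
        channel_roles=["EEG"] * n_eeg + ["EOG"] * n_eog,
        events=events)
    truth = GroundTruth(
        mixing_matrix=mixing, source_signals=sources_all,
        artifact_source_indices=(n_eeg,),
        class_labels=np.array(labels), trial_onsets=onsets,
        hurst_per_class={c: s.hurst for c, s in signatures.items()},
        blink_onsets=blink_onsets)
    return rec, truth
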