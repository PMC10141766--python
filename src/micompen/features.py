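"""The CompEn integrated feature set: FD, Hur, TsEn and DispEn per channel.

Every trial and EEG channel contributes four scalars — Higuchi fractal
dimension, rescaled-range Hurst exponent, Tsallis entropy (Sneddon
form) and dispersion entropy — concatenated into one row per trial with
``<channel>__<feature>`` column names.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .complexity import HiguchiConfig, HurstConfig, higuchi_fd, hurst_rs
from .eeg_io import EpochSet
from .entropy import DispersionConfig, TsallisConfig, dispersion_entropy, \
    tsallis_histogram, tsallis_sneddon

FEATURE_NAMES = ("FD", "Hur", "TsEn", "DispEn")


@dataclass
class FeatureTable:
    """Trials x (channels x 4 features) matrix with per-trial labels."""

    matrix: pd.DataFrame
    labels: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.matrix):
            raise ValueError("labels length must equal row count")
        if self.matrix.isna().any().any():
            raise ValueError("feature table contains missing values")

    @property
    def values(self) -> np.ndarray:
        return self.matrix.to_numpy()

    def to_tsv(self, path) -> None:
        out = self.matrix.copy()
        out.insert(0, "class", self.labels)
        out.to_csv(path, sep="\t", index=False)


class CompEnExtractor(BaseEstimator, TransformerMixin):
    """Stateless transformer: EpochSet -> trials x features array.

    Parameters follow the per-feature configs; ``transform`` also
    accepts a plain (trials, channels, samples) array.  Column names are
    exposed as ``feature_names_`` after the first transform.
    """

    def __init__(self, kmax: int = 20, hurst_min_subset: int = 16,
                 tsallis_mode: str = "sneddon", dispersion_m: int = 2,
                 dispersion_c: int = 2, dispersion_d: int = 1):
        self.kmax = kmax
        self.hurst_min_subset = hurst_min_subset
        self.tsallis_mode = tsallis_mode
        self.dispersion_m = dispersion_m
        self.dispersion_c = dispersion_c
        self.dispersion_d = dispersion_d

    def fit(self, X, y=None):  # nothing to learn
        return self

    def _window_features(self, w: np.ndarray, n: int) -> tuple[float, ...]:
        hcfg = HiguchiConfig(kmax=self.kmax, window_samples=n)
        rcfg = HurstConfig(window_samples=n, min_subset=self.hurst_min_subset)
        dcfg = DispersionConfig(m=self.dispersion_m, c=self.dispersion_c,
                                d=self.dispersion_d)
        if self.tsallis_mode == "sneddon":
            ts = tsallis_sneddon(w)
        else:
            ts = tsallis_histogram(w, TsallisConfig(mode="histogram"))
        return (higuchi_fd(w, hcfg), hurst_rs(w, rcfg), ts,
                dispersion_entropy(w, dcfg))

    def transform(self, X) -> np.ndarray:
        if isinstance(X, EpochSet):
            idx = X.eeg_indices
            data = X.data[:, idx, :]
            ch_names = [X.channel_labels[i] for i in idx]
        else:
            data = np.asarray(X, dtype=float)
            ch_names = [f"ch{i}" for i in range(data.shape[1])]
        n_trials, n_ch, n_samp = data.shape
        out = np.empty((n_trials, n_ch * len(FEATURE_NAMES)))
        for t in range(n_trials):
            for c in range(n_ch):
                out[t, c * 4:(c + 1) * 4] = self._window_features(
                    data[t, c], n_samp)
        self.feature_names_ = [f"{ch}__{f}" for ch in ch_names
                               for f in FEATURE_NAMES]
        return out


def extract_features(epochs: EpochSet, subject_id: str = "",
                     **params) -> FeatureTable:
    """Batch entry point: EpochSet -> :class:`FeatureTable`."""
    ext = CompEnExtractor(**params)
    mat = ext.transform(epochs)
    df = pd.DataFrame(mat, columns=ext.feature_names_)
    return FeatureTable(matrix=df, labels=np.asarray(epochs.labels),
                        subject_id=subject_id)
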