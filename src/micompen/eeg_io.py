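"""Reading, epoching and in-memory containers for continuous EEG recordings.

The on-disk layout follows the Graz four-class motor-imagery convention:
22 EEG channels plus 3 EOG channels sampled at 250 Hz, stored as GDF or
EDF(+) with trial events encoded as annotations.  Reading goes through
:mod:`mne`; epoching is done here so window semantics (0-based, half-open
sample slices) are fully pinned down.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: canonical class order used everywhere (confusion matrices, reports)
CLASS_ORDER = ("left_hand", "right_hand", "foot", "tongue")

#: Graz-style annotation codes for the four imagery classes
DEFAULT_CLASS_EVENT_CODES = {
    "left_hand": 769,
    "right_hand": 770,
    "foot": 771,
    "tongue": 772,
}

#: 22-channel motor-cortex montage plus 3 EOG references
DEFAULT_EEG_LABELS = (
    "Fz", "FC3", "FC1", "FCz", "FC2", "FC4",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP3", "CP1", "CPz", "CP2", "CP4",
    "P1", "Pz", "P2", "POz",
)
DEFAULT_EOG_LABELS = ("EOG-left", "EOG-central", "EOG-right")


class FormatError(RuntimeError):
    """Raised when a recording file cannot be parsed."""


class EmptyEpochSetError(RuntimeError):
    """Raised when epoching yields zero usable trials."""


@dataclass
class RawRecording:
    """Continuous multichannel recording in microvolts.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
    channel_roles : list of str
        ``"EEG"`` or ``"EOG"`` per channel, same order as ``data`` rows.
    events : list of (int, int)
        ``(sample_index, event_code)`` pairs, sample indices 0-based.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    channel_roles: list[str]
    events: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        n_ch = self.data.shape[0]
        if len(self.channel_labels) != n_ch or len(self.channel_roles) != n_ch:
            raise ValueError("channel_labels/channel_roles length must equal row count")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for s, _code in self.events:
            if not 0 <= s < self.data.shape[1]:
                raise ValueError(f"event sample index {s} out of range")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def eeg_indices(self) -> np.ndarray:
        return np.flatnonzero([r == "EEG" for r in self.channel_roles])

    @property
    def eog_indices(self) -> np.ndarray:
        return np.flatnonzero([r == "EOG" for r in self.channel_roles])

    def copy_with(self, data: np.ndarray) -> "RawRecording":
        return RawRecording(
            data=np.array(data, dtype=float),
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            channel_roles=list(self.channel_roles),
            events=list(self.events),
        )


@dataclass
class EpochSet:
    """Trials x channels x samples array with per-trial class labels."""

    data: np.ndarray
    labels: np.ndarray
    fs: float
    window: tuple[float, float]
    channel_labels: list[str]
    channel_roles: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def eeg_indices(self) -> np.ndarray:
        return np.flatnonzero([r == "EEG" for r in self.channel_roles])


def _infer_role(label: str) -> str:
    return "EOG" if "eog" in label.lower() else "EEG"


def read_recording(path: str | Path, format: str | None = None) -> RawRecording:
    """Read a GDF or EDF(+) recording into a :class:`RawRecording`.

    Channels keep their stored order; channels whose label contains "EOG"
    (case-insensitive) are flagged with the EOG role.  Events are taken
    from the file's annotations; descriptions that parse as integers are
    used verbatim as event codes, anything else is ignored with a count.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    if format is None:
        format = path.suffix.lstrip(".").lower()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if format == "gdf":
                raw = mne.io.read_raw_gdf(str(path), preload=True, verbose="error")
            elif format == "edf":
                raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
            else:
                raise FormatError(f"unsupported format: {format!r}")
    except FormatError:
        raise
    except Exception as exc:  # mne raises assorted errors on malformed files
        raise FormatError(f"cannot parse {path.name} as {format}: {exc}") from exc

    data_uv = raw.get_data() * 1e6  # mne holds volts internally
    labels = list(raw.ch_names)
    roles = [_infer_role(lbl) for lbl in labels]
    fs = float(raw.info["sfreq"])

    events: list[tuple[int, int]] = []
    n_ignored = 0
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        try:
            code = int(str(desc).strip())
        except ValueError:
            n_ignored += 1
            continue
        sample = int(np.floor(onset * fs))
        if 0 <= sample < data_uv.shape[1]:
            events.append((sample, code))
    if n_ignored:
        logger.info("ignored %d non-integer annotation descriptions", n_ignored)
    if not events:
        logger.warning("recording %s has no usable events", path.name)

    return RawRecording(data=data_uv, fs=fs, channel_labels=labels,
                        channel_roles=roles, events=events)


def epoch(
    rec: RawRecording,
    window: tuple[float, float] = (0.0, 6.0),
    class_event_codes: dict[str, int] | None = None,
) -> EpochSet:
    """Slice one epoch per trial-onset event.

    ``window`` is (start_s, end_s) relative to the trial-onset event,
    realised as a half-open 0-based sample slice ``[floor(start*fs),
    floor(end*fs))``.  Trials with any sample out of range are dropped
    (and counted in a log message).  Event codes not in
    ``class_event_codes`` are ignored.
    """
    if class_event_codes is None:
        class_event_codes = dict(DEFAULT_CLASS_EVENT_CODES)
    start_s, end_s = window
    if end_s <= start_s:
        raise ValueError(f"degenerate window {window}")
    code_to_class = {v: k for k, v in class_event_codes.items()}

    off0 = int(np.floor(start_s * rec.fs))
    off1 = int(np.floor(end_s * rec.fs))
    n_win = off1 - off0

    epochs, labels = [], []
    n_dropped = n_unknown = 0
    for sample, code in rec.events:
        if code not in code_to_class:
            n_unknown += 1
            continue
        lo, hi = sample + off0, sample + off1
        if lo < 0 or hi > rec.n_samples:
            n_dropped += 1
            continue
        epochs.append(rec.data[:, lo:hi])
        labels.append(code_to_class[code])
    if n_unknown:
        logger.info("ignored %d events with unknown codes", n_unknown)
    if n_dropped:
        logger.warning("dropped %d trials with out-of-range samples", n_dropped)
    if not epochs:
        raise EmptyEpochSetError("no usable trials after epoching")

    data = np.stack(epochs)
    assert data.shape[2] == n_win
    return EpochSet(data=data, labels=np.array(labels), fs=rec.fs, window=window,
                    channel_labels=list(rec.channel_labels),
                    channel_roles=list(rec.channel_roles))
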