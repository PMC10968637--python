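"""Containers and I/O for continuous and epoched EEG.

The two in-memory containers are :class:`ContinuousRecording` (channels x
samples with press-event markers) and :class:`EpochSet` (trials x channels x
samples with per-trial labels).  Standard formats (EDF, BrainVision) are read
through :mod:`mne`; epoched data round-trips bit-exactly through a plain
array-container + JSON-sidecar store.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from errpkit.errors import (
    CorruptStoreError,
    EmptyEpochsError,
    UnknownMarkerError,
    UnsupportedFormatError,
)

logger = logging.getLogger(__name__)

#: Event codes carried on press markers.
PRESS_CORRECT = "press_correct"
PRESS_ERROR = "press_error"
PRESS_TIMEOUT = "press_timeout"
EVENT_CODES = (PRESS_CORRECT, PRESS_ERROR, PRESS_TIMEOUT)

#: Trial labels used everywhere downstream.
LABEL_ERROR = "error"
LABEL_CORRECT = "correct"


def _check_unique_names(names: Sequence[str]) -> None:
    lowered = [n.lower() for n in names]
    if len(set(lowered)) != len(lowered):
        raise ValueError("channel names must be unique (case-insensitive)")


@dataclass
class ContinuousRecording:
    """Multichannel continuous EEG with press-event markers.

    Parameters
    ----------
    signal
        channels x samples array, arbitrary units.
    fs
        Sampling rate in Hz.
    channel_names
        Ordered 10-20 labels; cerebellar electrodes are CB1, CBZ, CB2.
        Matching elsewhere is case-insensitive ("CBz" == "CBZ").
    events
        List of ``(sample_index, event_code)`` with codes drawn from
        :data:`EVENT_CODES`.
    """

    signal: np.ndarray
    fs: float
    channel_names: list[str]
    events: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels x samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError("channel_names length must equal signal row count")
        _check_unique_names(self.channel_names)
        n = self.signal.shape[1]
        for s, code in self.events:
            if not 0 <= s < n:
                raise ValueError(f"event sample {s} outside [0, {n})")
            if code not in EVENT_CODES:
                raise ValueError(f"unknown event code {code!r}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


@dataclass
class EpochSet:
    """Press-locked epoched EEG.

    ``data`` is trials x channels x samples; ``t0_offset`` is the time of the
    first sample in seconds relative to the press (negative = pre-press).
    ``labels`` holds ``"error"`` / ``"correct"`` per trial.
    """

    data: np.ndarray
    fs: float
    t0_offset: float
    labels: np.ndarray
    channel_names: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal trial count")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must equal channel count")
        _check_unique_names(self.channel_names)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds relative to the press."""
        return self.t0_offset + np.arange(self.n_samples) / self.fs

    def channel_index(self, name: str) -> int:
        """Index of a channel, matched case-insensitively."""
        lowered = [c.lower() for c in self.channel_names]
        try:
            return lowered.index(name.lower())
        except ValueError:
            raise KeyError(f"channel {name!r} not present") from None

    def select_channels(self, names: Sequence[str]) -> "EpochSet":
        """Return a new EpochSet restricted (and reordered) to ``names``."""
        idx = [self.channel_index(n) for n in names]
        return replace(self, data=self.data[:, idx, :], channel_names=[self.channel_names[i] for i in idx])

    def class_data(self, label: str) -> np.ndarray:
        return self.data[self.labels == label]


#: Default map from marker descriptions to event codes: identity on the three
#: codes. BrainVision annotations arrive as "<type>/<description>"; the part
#: after the final "/" is matched.
DEFAULT_CODE_MAP = {c: c for c in EVENT_CODES}


def read_continuous(
    path: str | Path,
    format: str | None = None,
    code_map: dict[str, str] | None = None,
    strict: bool = True,
) -> ContinuousRecording:
    """Read a continuous EEG file (EDF or BrainVision) into a recording.

    Parameters
    ----------
    path
        The ``.edf`` file or BrainVision ``.vhdr`` header.
    format
        ``"edf"`` or ``"brainvision"``; inferred from the suffix when None.
    code_map
        Maps marker descriptions to event codes.  Unknown descriptions raise
        :class:`UnknownMarkerError` when ``strict``, otherwise they are
        skipped with a warning.
    """
    import mne

    path = Path(path)
    if format is None:
        format = {".edf": "edf", ".vhdr": "brainvision"}.get(path.suffix.lower(), "")
    if format == "edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif format == "brainvision":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise UnsupportedFormatError(f"unsupported format {format!r} for {path.name}")

    # mne rescales to SI volts; recover the native microvolt-scale values for
    # voltage channels so synthetic "a.u." data round-trips.
    try:
        signal = raw.get_data(units="uV")
    except (ValueError, KeyError):
        signal = raw.get_data()

    fs = float(raw.info["sfreq"])
    code_map = DEFAULT_CODE_MAP if code_map is None else code_map
    events: list[tuple[int, str]] = []
    for ann in raw.annotations:
        desc = ann["description"].split("/")[-1].strip()
        if desc.lower() in ("new segment", "") or desc.startswith("New Segment"):
            continue
        if desc not in code_map:
            if strict:
                raise UnknownMarkerError(f"marker description {desc!r} not in code map")
            warnings.warn(f"skipping unmapped marker {desc!r}", stacklevel=2)
            continue
        sample = int(round((ann["onset"] - raw.first_time) * fs))
        events.append((sample, code_map[desc]))

    return ContinuousRecording(
        signal=signal,
        fs=fs,
        channel_names=list(raw.ch_names),
        events=events,
    )


def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Write an EpochSet to ``path/`` as ``data.npy`` + ``meta.json``.

    The round trip through :func:`read_epochs` is bit-exact.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "data.npy", epochs.data)
    meta = {
        "fs": epochs.fs,
        "t0_offset": epochs.t0_offset,
        "labels": [str(l) for l in epochs.labels],
        "channel_names": list(epochs.channel_names),
        "subject_id": epochs.subject_id,
        "shape": list(epochs.data.shape),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


def read_epochs(path: str | Path) -> EpochSet:
    """Read an EpochSet written by :func:`write_epochs`."""
    path = Path(path)
    try:
        meta = json.loads((path / "meta.json").read_text())
        data = np.load(path / "data.npy")
    except (OSError, json.JSONDecodeError) as exc:
        raise CorruptStoreError(f"cannot read epoch store at {path}: {exc}") from exc
    if list(data.shape) != meta.get("shape") or len(meta["labels"]) != data.shape[0]:
        raise CorruptStoreError(f"sidecar/array shape mismatch in {path}")
    if len(meta["channel_names"]) != data.shape[1]:
        raise CorruptStoreError(f"sidecar channel count mismatch in {path}")
    return EpochSet(
        data=data,
        fs=meta["fs"],
        t0_offset=meta["t0_offset"],
        labels=np.array(meta["labels"], dtype=object),
        channel_names=meta["channel_names"],
        subject_id=meta.get("subject_id", ""),
    )


def split_epochs(epochs: EpochSet, test_fraction: float = 0.4, seed: int = 0) -> tuple[EpochSet, EpochSet]:
    """Stratified within-subject train/test split of an EpochSet.

    Classification is calibrated per subject, so train and test trials come
    from the same recording; the split preserves the class ratio.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for label in np.unique(epochs.labels.astype(str)):
        idx = np.flatnonzero(epochs.labels.astype(str) == label)
        n_test = int(round(test_fraction * len(idx)))
        test_idx.extend(rng.permutation(idx)[:n_test])
    mask = np.zeros(epochs.n_trials, dtype=bool)
    mask[test_idx] = True

    def take(sel: np.ndarray) -> EpochSet:
        return replace(epochs, data=epochs.data[sel], labels=epochs.labels[sel])

    return take(~mask), take(mask)


#: Press-event codes that become epochs, with their trial labels.
_EPOCHED_CODES = {PRESS_CORRECT: LABEL_CORRECT, PRESS_ERROR: LABEL_ERROR}


def epoch(
    recording: ContinuousRecording,
    window: tuple[float, float] = (-0.5, 0.5),
    subject_id: str = "",
) -> EpochSet:
    """Cut press-locked epochs out of a continuous recording.

    The press sample is t = 0.  Windows are half-open sample ranges
    ``[round(start*fs), round(start*fs) + N)`` with
    ``N = round((end - start) * fs)``, so every trial has the same length.
    Timeout events are excluded; events whose window leaves the recording are
    dropped (count logged).
    """
    start_s, end_s = window
    if not start_s < end_s:
        raise ValueError("window start must precede end")
    fs = recording.fs
    off = int(round(start_s * fs))
    n = int(round((end_s - start_s) * fs))

    trials, labels = [], []
    dropped = 0
    for sample, code in recording.events:
        if code not in _EPOCHED_CODES:
            continue
        s0 = sample + off
        if s0 < 0 or s0 + n > recording.n_samples:
            dropped += 1
            continue
        trials.append(recording.signal[:, s0 : s0 + n])
        labels.append(_EPOCHED_CODES[code])
    if dropped:
        logger.info("epoch(): dropped %d out-of-bounds events", dropped)
    if not trials:
        raise EmptyEpochsError("no usable press events inside the recording")

    return EpochSet(
        data=np.stack(trials),
        fs=fs,
        t0_offset=off / fs,
        labels=np.array(labels, dtype=object),
        channel_names=list(recording.channel_names),
        subject_id=subject_id,
    )
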