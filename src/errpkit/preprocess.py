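"""Signal conditioning for press-locked ErrP analysis.

Pipeline order: bandpass the continuous signal (1-30 Hz zero-phase
Butterworth), common average reference, epoch, subtract the pre-press
baseline mean, then keep the post-press analysis window with its own mean
removed per trial and channel.  Filtering happens on the continuous record,
before epoching, so filter edge transients never sit inside an epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.signal

from errpkit.errors import ConfigError, EmptyClassError, ReferenceError_
from errpkit.io import ContinuousRecording, EpochSet


@dataclass
class PreprocessConfig:
    """Conditioning parameters.

    band
        Butterworth passband in Hz.
    filter_order
        Order per pass; applied forward-backward (zero phase), so the
        effective attenuation is doubled.
    baseline_window, analysis_window
        Seconds relative to the press.  The baseline mean is subtracted from
        the whole epoch; classification and screening consume only the
        zero-meaned analysis window.
    """

    band: tuple[float, float] = (1.0, 30.0)
    filter_order: int = 4
    baseline_window: tuple[float, float] = (-0.5, 0.0)
    analysis_window: tuple[float, float] = (0.0, 0.5)

    def validate(self, fs: float) -> None:
        low, high = self.band
        if not 0 < low < high:
            raise ConfigError(f"invalid band {self.band}")
        if high >= fs / 2:
            raise ConfigError(f"band edge {high} Hz >= Nyquist ({fs / 2} Hz)")
        if self.filter_order < 1:
            raise ConfigError("filter_order must be >= 1")


def bandpass(recording: ContinuousRecording | EpochSet, cfg: PreprocessConfig | None = None):
    """Zero-phase Butterworth bandpass of every channel.

    Preferred on the continuous signal before epoching, where edge
    transients fall outside the trials; pre-epoched data is filtered
    trial-wise (reflect-padded), a close approximation for epochs much
    longer than the filter's impulse response.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate(recording.fs)
    sos = scipy.signal.butter(cfg.filter_order, cfg.band, btype="bandpass", fs=recording.fs, output="sos")
    if isinstance(recording, EpochSet):
        return replace(recording, data=scipy.signal.sosfiltfilt(sos, recording.data, axis=2))
    filtered = scipy.signal.sosfiltfilt(sos, recording.signal, axis=1)
    return ContinuousRecording(
        signal=filtered,
        fs=recording.fs,
        channel_names=list(recording.channel_names),
        events=list(recording.events),
    )


def average_reference(x: ContinuousRecording | EpochSet):
    """Re-reference to the common average: subtract the cross-channel mean at
    every sample.  Works on continuous recordings (channel axis 0) and epoch
    sets (channel axis 1)."""
    if isinstance(x, ContinuousRecording):
        if x.n_channels < 2:
            raise ReferenceError_("average reference needs >= 2 channels")
        sig = x.signal - x.signal.mean(axis=0, keepdims=True)
        return ContinuousRecording(sig, x.fs, list(x.channel_names), list(x.events))
    if isinstance(x, EpochSet):
        if x.n_channels < 2:
            raise ReferenceError_("average reference needs >= 2 channels")
        return replace(x, data=x.data - x.data.mean(axis=1, keepdims=True))
    raise TypeError(f"cannot re-reference {type(x).__name__}")


def _window_slice(epochs: EpochSet, window: tuple[float, float]) -> slice:
    start, end = window
    i0 = int(round((start - epochs.t0_offset) * epochs.fs))
    i1 = int(round((end - epochs.t0_offset) * epochs.fs))
    if i0 < 0 or i1 > epochs.n_samples or i0 >= i1:
        raise ConfigError(f"window {window} outside epoch span")
    return slice(i0, i1)


def baseline_correct(epochs: EpochSet, cfg: PreprocessConfig | None = None) -> EpochSet:
    """Subtract the pre-press baseline mean per trial and channel, keeping
    the full epoch.  This is the conditioning used for waveform morphology
    (ERN/Pe peak measurement); classification additionally zero-means the
    analysis window via :func:`baseline_zero_mean`."""
    cfg = cfg or PreprocessConfig()
    base = _window_slice(epochs, cfg.baseline_window)
    return replace(epochs, data=epochs.data - epochs.data[:, :, base].mean(axis=2, keepdims=True))


def baseline_zero_mean(epochs: EpochSet, cfg: PreprocessConfig | None = None) -> EpochSet:
    """Baseline-correct and extract the zero-meaned analysis window.

    Per trial and channel: subtract the mean over ``baseline_window`` from the
    whole epoch, cut out ``analysis_window``, and remove that segment's own
    mean.  Returns the analysis-window EpochSet, whose every trial-channel
    trace has zero mean.
    """
    cfg = cfg or PreprocessConfig()
    base = _window_slice(epochs, cfg.baseline_window)
    ana = _window_slice(epochs, cfg.analysis_window)
    data = epochs.data - epochs.data[:, :, base].mean(axis=2, keepdims=True)
    seg = data[:, :, ana]
    seg = seg - seg.mean(axis=2, keepdims=True)
    return replace(epochs, data=seg, t0_offset=cfg.analysis_window[0])


def class_average(epochs: EpochSet, label: str) -> np.ndarray:
    """Mean over trials of one class; channels x samples."""
    sel = epochs.class_data(label)
    if sel.shape[0] == 0:
        raise EmptyClassError(f"no trials with label {label!r}")
    return sel.mean(axis=0)
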