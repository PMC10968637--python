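"""The standard conditioning chain applied before classification/screening.

Bandpass (1-30 Hz zero-phase Butterworth) -> common average reference ->
baseline correction against the pre-press window -> zero-meaned 0-500 ms
analysis segment.  Classification, screening indices and channel ranking
all consume the output of this chain.
"""

from __future__ import annotations

from errpkit.io import ContinuousRecording, EpochSet, epoch
from errpkit.preprocess import PreprocessConfig, average_reference, bandpass, baseline_zero_mean


def condition_epochs(epochs: EpochSet, cfg: PreprocessConfig | None = None) -> EpochSet:
    """Full conditioning of pre-epoched trials (filtering done trial-wise)."""
    cfg = cfg or PreprocessConfig()
    return baseline_zero_mean(average_reference(bandpass(epochs, cfg)), cfg)


def condition_recording(
    recording: ContinuousRecording,
    cfg: PreprocessConfig | None = None,
    window: tuple[float, float] = (-0.5, 0.5),
) -> EpochSet:
    """Full conditioning starting from a continuous recording: filter the
    continuous signal (no edge transients inside trials), re-reference,
    epoch around the presses, then baseline/zero-mean."""
    cfg = cfg or PreprocessConfig()
    return baseline_zero_mean(epoch(average_reference(bandpass(recording, cfg)), window), cfg)
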