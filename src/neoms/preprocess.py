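"""Preprocessing: bandpass filtering, resampling, re-referencing, epoching.

The analysis chain is filter -> resample -> re-reference, applied to raw
multichannel recordings before any microstate computation.  Filtering is
zero-phase (forward-backward Butterworth): microstate boundaries are
timing-sensitive and a causal filter would shift every label by the
group delay.  Resampling uses a polyphase rational-factor method with a
built-in anti-alias filter.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal

from neoms.epoch import EEGEpoch

#: Default analysis band (Hz) and Butterworth design order.
DEFAULT_BAND = (0.2, 25.0)
DEFAULT_ORDER = 7
#: Rate (Hz) the EEG is brought to before microstate analysis.
DEFAULT_FS_ANALYSIS = 100.0


def bandpass_filter(
    epoch: EEGEpoch,
    low_hz: float = DEFAULT_BAND[0],
    high_hz: float = DEFAULT_BAND[1],
    order: int = DEFAULT_ORDER,
) -> EEGEpoch:
    """Zero-phase Butterworth bandpass, applied per channel.

    The nominal design order is ``order``; forward-backward application
    doubles the effective attenuation.  Epochs shorter than three
    high-pass time constants are rejected: the filter transient would
    dominate the output.
    """
    if not (0 < low_hz < high_hz < epoch.fs / 2):
        raise ValueError(
            f"need 0 < low ({low_hz}) < high ({high_hz}) < Nyquist ({epoch.fs / 2})"
        )
    tau = 1.0 / (2 * np.pi * low_hz)  # high-pass edge time constant, s
    if epoch.duration_s < 3 * tau:
        raise ValueError(
            f"epoch of {epoch.duration_s:.2f} s is shorter than 3 filter "
            f"time constants ({3 * tau:.2f} s)"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=epoch.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, epoch.data, axis=1)
    return epoch.copy_with(data=filtered)


def resample(epoch: EEGEpoch, fs_new: float) -> EEGEpoch:
    """Downsample to ``fs_new`` Hz by polyphase rational-factor resampling.

    Only downsampling (or the identity) is supported; the anti-alias
    filter of :func:`scipy.signal.resample_poly` guards the new Nyquist.
    """
    if fs_new > epoch.fs:
        raise ValueError(f"upsampling {epoch.fs} -> {fs_new} Hz not supported")
    if fs_new <= 0:
        raise ValueError("fs_new must be positive")
    if fs_new == epoch.fs:
        return epoch.copy_with()
    frac = Fraction(fs_new / epoch.fs).limit_denominator(1000)
    data = signal.resample_poly(epoch.data, frac.numerator, frac.denominator, axis=1)
    n_expected = round(epoch.duration_s * fs_new)
    data = data[:, :n_expected]  # polyphase may emit a trailing partial sample
    return epoch.copy_with(data=data, fs=fs_new)


def rereference_common_average(epoch: EEGEpoch) -> EEGEpoch:
    """Subtract the per-sample channel mean (common-average reference).

    Idempotent; requires at least two channels (with one channel the
    average reference annihilates the signal).
    """
    if epoch.n_channels < 2:
        raise ValueError("common-average reference needs >= 2 channels")
    data = epoch.data - epoch.data.mean(axis=0, keepdims=True)
    return epoch.copy_with(data=data, reference="common_average")


def extract_epoch(
    recording: EEGEpoch,
    start_s: float,
    duration_s: float,
    sleep_label: str,
) -> EEGEpoch:
    """Cut a contiguous window out of a recording and tag its sleep state.

    Sleep labels (QS / non-QS) are caller-provided: the pipeline does not
    stage sleep itself.
    """
    if sleep_label not in ("QS", "NQS"):
        raise ValueError(f"sleep_label must be 'QS' or 'NQS', got {sleep_label!r}")
    i0 = round(start_s * recording.fs)
    n = round(duration_s * recording.fs)
    if start_s < 0 or i0 + n > recording.n_samples:
        raise ValueError(
            f"window [{start_s}, {start_s + duration_s}] s outside recording "
            f"of {recording.duration_s} s"
        )
    return recording.copy_with(data=recording.data[:, i0 : i0 + n], sleep_state=sleep_label)


def preprocess_epoch(
    epoch: EEGEpoch,
    low_hz: float = DEFAULT_BAND[0],
    high_hz: float = DEFAULT_BAND[1],
    order: int = DEFAULT_ORDER,
    fs_new: float = DEFAULT_FS_ANALYSIS,
) -> EEGEpoch:
    """Full chain: bandpass filter, downsample, common-average reference."""
    out = bandpass_filter(epoch, low_hz, high_hz, order)
    out = resample(out, fs_new)
    return rereference_common_average(out)
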