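"""Amplitude-threshold artifact handling.

Fixed pipeline order: (1) detect consistently noisy channels and substitute
each with the unweighted mean of its six nearest good neighbors, (2)
re-reference to the common average, (3) cut the trial into contiguous 1.1-s
bins, discarding the first and last, (4) reject whole bins (more than 5% of
channels exceeding 60 µV) and individual channel-bins (more than 10% of
samples exceeding 30 µV).

All exceedance tests use absolute value (EEG is bipolar about its reference)
and all percentage comparisons are strict (">"), so a channel at exactly the
15% mark is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .protocol import ProtocolConfig
from .simulate import Montage, SensorTrial

__all__ = [
    "RejectionMask",
    "detect_bad_channels",
    "interpolate_bad_channels",
    "rereference_common_average",
    "bandpass_filter",
    "bin_trial",
    "reject_bins",
    "preprocess_trial",
]

BAD_CHANNEL_THRESHOLD_UV = 30.0
BAD_CHANNEL_FRACTION = 0.15
WHOLE_BIN_THRESHOLD_UV = 60.0
WHOLE_BIN_CHANNEL_FRACTION = 0.05
CHANNEL_BIN_THRESHOLD_UV = 30.0
CHANNEL_BIN_SAMPLE_FRACTION = 0.10
N_NEIGHBORS = 6


@dataclass
class RejectionMask:
    """Boolean rejection flags; ``True`` means rejected.

    The first and last bins of a trial are always flagged.  Whole-bin
    rejection implies rejection of every channel-bin in that bin.
    """

    bad_channels: np.ndarray  # (n_channels,)
    rejected_bins: np.ndarray  # (n_bins,)
    rejected_channel_bins: np.ndarray  # (n_bins, n_channels)

    @property
    def usable_bins(self) -> np.ndarray:
        return ~self.rejected_bins

    def channel_bin_valid(self) -> np.ndarray:
        """(n_bins, n_channels) validity: not whole-bin and not channel-bin rejected."""
        return ~(self.rejected_channel_bins | self.rejected_bins[:, None])


def detect_bad_channels(trial: SensorTrial) -> np.ndarray:
    """Flag channels where strictly more than 15% of samples exceed 30 µV."""
    if trial.data.size == 0:
        raise ValueError("empty trial")
    frac = np.mean(np.abs(trial.data) > BAD_CHANNEL_THRESHOLD_UV, axis=1)
    return frac > BAD_CHANNEL_FRACTION


def interpolate_bad_channels(
    trial: SensorTrial, flags: np.ndarray, montage: Montage | None = None
) -> SensorTrial:
    """Replace each flagged channel by the unweighted mean of its six nearest
    unflagged channels (Euclidean distance on the montage)."""
    montage = montage or trial.montage
    if montage is None:
        raise ValueError("montage required for interpolation")
    flags = np.asarray(flags, dtype=bool)
    good = np.flatnonzero(~flags)
    if good.size < N_NEIGHBORS + 1:
        raise ValueError(
            f"only {good.size} good channels; need at least {N_NEIGHBORS + 1} to interpolate"
        )
    data = trial.data.copy()
    for ch in np.flatnonzero(flags):
        nbrs = montage.nearest_neighbors(ch, N_NEIGHBORS, candidates=good)
        data[ch] = trial.data[nbrs].mean(axis=0)
    return replace(trial, data=data)


def rereference_common_average(trial: SensorTrial) -> SensorTrial:
    return replace(trial, data=trial.data - trial.data.mean(axis=0, keepdims=True))


def bandpass_filter(trial: SensorTrial, low_hz: float = 0.3, high_hz: float = 50.0, order: int = 4) -> SensorTrial:
    """Optional zero-phase Butterworth bandpass (the acquisition chain applies
    0.3–50 Hz in hardware; the simulator already emits band-limited signals,
    so this is off by default in the pipeline)."""
    sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=trial.sampling_rate, output="sos")
    return replace(trial, data=sosfiltfilt(sos, trial.data, axis=1))


def bin_trial(trial: SensorTrial, protocol: ProtocolConfig) -> np.ndarray:
    """Cut into ``n_bins`` contiguous non-overlapping bins.

    Returns an array (n_bins, n_channels, samples_per_bin).  Edge-bin
    rejection is recorded by :func:`reject_bins`.
    """
    m = protocol.samples_per_bin
    need = protocol.n_bins * m
    if trial.data.shape[1] < need:
        raise ValueError(
            f"trial has {trial.data.shape[1]} samples; need at least {need}"
        )
    chunk = trial.data[:, :need]
    return chunk.reshape(trial.data.shape[0], protocol.n_bins, m).transpose(1, 0, 2)


def reject_bins(bins: np.ndarray, bad_channels: np.ndarray | None = None) -> RejectionMask:
    """Two-level amplitude rejection on binned data (n_bins, n_channels, m)."""
    n_bins, n_channels, _ = bins.shape
    absmax = np.abs(bins)
    channel_exceeds_60 = (absmax > WHOLE_BIN_THRESHOLD_UV).any(axis=2)  # (bins, ch)
    whole = channel_exceeds_60.mean(axis=1) > WHOLE_BIN_CHANNEL_FRACTION
    frac30 = (absmax > CHANNEL_BIN_THRESHOLD_UV).mean(axis=2)  # (bins, ch)
    channel_bins = frac30 > CHANNEL_BIN_SAMPLE_FRACTION
    # first and last bins always discarded
    whole = whole.copy()
    whole[0] = True
    whole[-1] = True
    channel_bins = channel_bins | whole[:, None]
    if bad_channels is None:
        bad_channels = np.zeros(n_channels, dtype=bool)
    return RejectionMask(
        bad_channels=np.asarray(bad_channels, dtype=bool),
        rejected_bins=whole,
        rejected_channel_bins=channel_bins,
    )


def preprocess_trial(
    trial: SensorTrial,
    protocol: ProtocolConfig,
    montage: Montage | None = None,
    bandpass: bool = False,
) -> tuple[np.ndarray, RejectionMask]:
    """Full per-trial chain; returns (bins, mask)."""
    montage = montage or trial.montage
    if bandpass:
        trial = bandpass_filter(trial)
    bad = detect_bad_channels(trial)
    if bad.any():
        trial = interpolate_bad_channels(trial, bad, montage)
    trial = rereference_common_average(trial)
    bins = bin_trial(trial, protocol)
    return bins, reject_bins(bins, bad_channels=bad)
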