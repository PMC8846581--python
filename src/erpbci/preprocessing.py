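"""Continuous EEG -> cleaned epochs -> interval-mean feature vectors.

The pipeline is the standard one for ERP classification: zero-phase
band-pass filtering, stimulus-locked epoching with pre-stimulus baseline
correction, peak-to-peak artefact rejection, and mean amplitudes over a
set of post-stimulus intervals per channel as features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .paradigm import Role, StimulusEvent
from .simulate import ContinuousEEG

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_BAND_HZ",
    "DEFAULT_WINDOW_MS",
    "DEFAULT_BASELINE_MS",
    "DEFAULT_INTERVALS_MS",
    "DEFAULT_REJECT_UV",
    "EpochSet",
    "FeatureMatrix",
    "bandpass_filter",
    "epoch",
    "reject_artifacts",
    "extract_features",
]

DEFAULT_BAND_HZ = (0.5, 8.0)
DEFAULT_WINDOW_MS = (-200.0, 800.0)
DEFAULT_BASELINE_MS = (-200.0, 0.0)
# six half-open windows covering the N200 and the broad P300 range
DEFAULT_INTERVALS_MS = (
    (50.0, 150.0),
    (150.0, 250.0),
    (250.0, 350.0),
    (350.0, 450.0),
    (450.0, 600.0),
    (600.0, 800.0),
)
DEFAULT_REJECT_UV = 150.0


@dataclass
class EpochSet:
    """Stimulus-locked epochs with labels and rejection mask.

    data: epochs x channels x time (microvolts); times_ms relative to
    stimulus onset; labels 1 = target, 0 = non-target.  ``kept_mask``
    marks epochs surviving artefact rejection; ``kept()`` materialises
    the surviving subset.
    """

    data: np.ndarray
    times_ms: np.ndarray
    labels: np.ndarray
    channel_names: tuple[str, ...]
    word_ids: np.ndarray
    trial_ids: np.ndarray
    kept_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    fs_hz: float = 0.0

    def __post_init__(self) -> None:
        if self.kept_mask is None:
            self.kept_mask = np.ones(len(self.data), dtype=bool)
        if len(self.labels) != len(self.data):
            raise ValueError("labels length must equal epoch count")
        if np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("times_ms must be strictly increasing")

    def __len__(self) -> int:
        return len(self.data)

    def kept(self) -> "EpochSet":
        m = self.kept_mask
        return EpochSet(
            data=self.data[m],
            times_ms=self.times_ms,
            labels=self.labels[m],
            channel_names=self.channel_names,
            word_ids=self.word_ids[m],
            trial_ids=self.trial_ids[m],
            fs_hz=self.fs_hz,
        )


@dataclass
class FeatureMatrix:
    """Interval-mean ERP features: epochs x (intervals x channels).

    Column (i, c) holds the mean amplitude of channel ``channel_names[c]``
    over ``intervals_ms[i]``; columns are ordered interval-major.
    """

    values: np.ndarray
    intervals_ms: tuple[tuple[float, float], ...]
    channel_names: tuple[str, ...]
    labels: np.ndarray

    def __post_init__(self) -> None:
        expected = len(self.intervals_ms) * len(self.channel_names)
        if self.values.shape[1] != expected:
            raise ValueError(
                f"column count {self.values.shape[1]} != intervals x channels = {expected}"
            )
        if len(self.labels) != len(self.values):
            raise ValueError("labels length must equal row count")

    def __len__(self) -> int:
        return len(self.values)


def bandpass_filter(
    eeg: ContinuousEEG,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
    order: int = 4,
) -> ContinuousEEG:
    """Zero-phase Butterworth band-pass per channel; markers unchanged."""
    nyq = eeg.fs_hz / 2.0
    if not 0 <= low_hz < high_hz < nyq:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz invalid for Nyquist {nyq} Hz"
        )
    if low_hz == 0:
        sos = signal.butter(order, high_hz, btype="low", fs=eeg.fs_hz, output="sos")
    else:
        sos = signal.butter(
            order, [low_hz, high_hz], btype="band", fs=eeg.fs_hz, output="sos"
        )
    filtered = signal.sosfiltfilt(sos, eeg.data, axis=1)
    return ContinuousEEG(
        data=filtered,
        fs_hz=eeg.fs_hz,
        channel_names=tuple(eeg.channel_names),
        markers=list(eeg.markers),
    )


def epoch(
    eeg: ContinuousEEG,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    baseline_ms: tuple[float, float] | None = DEFAULT_BASELINE_MS,
) -> EpochSet:
    """Cut one epoch per marker and subtract the pre-stimulus baseline.

    The epoch grid is [window_ms[0], window_ms[1]) at the recording's
    sampling rate, with t = 0 falling on the marker sample.  Markers too
    close to the recording edges are dropped with a warning.  When
    ``baseline_ms`` is given, the per-channel mean over that (half-open)
    window is subtracted from each epoch.
    """
    fs = eeg.fs_hz
    i0 = round(window_ms[0] * fs / 1000.0)
    i1 = round(window_ms[1] * fs / 1000.0)
    times_ms = np.arange(i0, i1) / fs * 1000.0
    n_samples = eeg.data.shape[1]

    epochs, labels, word_ids, trial_ids = [], [], [], []
    n_dropped = 0
    for idx, ev in eeg.markers:
        lo, hi = idx + i0, idx + i1
        if lo < 0 or hi > n_samples:
            n_dropped += 1
            continue
        epochs.append(eeg.data[:, lo:hi])
        labels.append(1 if Role(ev.role) is Role.TARGET else 0)
        word_ids.append(ev.word_id)
        trial_ids.append(ev.trial_id)
    if n_dropped:
        logger.warning("dropped %d markers too close to the recording edge", n_dropped)
    if not epochs:
        raise ValueError("no marker yields a complete epoch")

    data = np.stack(epochs)
    if baseline_ms is not None:
        bmask = (times_ms >= baseline_ms[0]) & (times_ms < baseline_ms[1])
        if not bmask.any():
            raise ValueError(f"baseline window {baseline_ms} outside epoch grid")
        data = data - data[:, :, bmask].mean(axis=2, keepdims=True)

    return EpochSet(
        data=data,
        times_ms=times_ms,
        labels=np.asarray(labels),
        channel_names=tuple(eeg.channel_names),
        word_ids=np.asarray(word_ids),
        trial_ids=np.asarray(trial_ids),
        fs_hz=fs,
    )


def reject_artifacts(
    epochs: EpochSet, peak_to_peak_uv_max: float = DEFAULT_REJECT_UV
) -> EpochSet:
    """Mask out epochs whose peak-to-peak amplitude on any channel exceeds
    the threshold.  Data of kept epochs is untouched."""
    if peak_to_peak_uv_max <= 0:
        raise ValueError("peak_to_peak_uv_max must be > 0")
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # epochs x channels
    ok = (ptp <= peak_to_peak_uv_max).all(axis=1)
    out = replace(epochs, kept_mask=epochs.kept_mask & ok)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("artefact rejection masked %d of %d epochs", n_bad, len(epochs))
    return out


def extract_features(
    epochs: EpochSet,
    intervals_ms: tuple[tuple[float, float], ...] = DEFAULT_INTERVALS_MS,
    *,
    kept_only: bool = True,
) -> FeatureMatrix:
    """Mean amplitude per (interval, channel); rows preserve epoch order.

    Intervals are half-open [a, b) on the epoch's time grid.  By default
    only epochs surviving artefact rejection contribute rows.
    """
    src = epochs.kept() if kept_only else epochs
    t = src.times_ms
    cols = []
    for a, b in intervals_ms:
        mask = (t >= a) & (t < b)
        if not mask.any():
            raise ValueError(f"interval [{a}, {b}) ms outside epoch window")
        cols.append(src.data[:, :, mask].mean(axis=2))  # epochs x channels
    values = np.concatenate(cols, axis=1)
    return FeatureMatrix(
        values=values,
        intervals_ms=tuple(tuple(iv) for iv in intervals_ms),
        channel_names=tuple(src.channel_names),
        labels=src.labels.copy(),
    )
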