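"""Offline ERP characterization: grand averages, bootstrap peak
amplitude/latency estimation, P300 onset detection and interval
topographies.

Peaks are read from bootstrap-averaged waveforms: 80% of the epochs are
resampled 10 times, the resample averages are scanned for the signed
extremum in a component-specific window, and the readouts are averaged.
The P300 onset is the first post-stimulus time point at which target and
non-target epochs differ in a two-sided t-test at alpha = 0.05; if no
sample is significant the onset is reported as 1000 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocessing import EpochSet

__all__ = [
    "ERPStats",
    "N200_WINDOW_MS",
    "P300_WINDOW_MS",
    "grand_average",
    "bootstrap_peak",
    "p300_onset",
    "p300_onset_from_epochs",
    "interval_topography",
    "erp_stats",
]

# default peak-search windows (channel is fixed by convention: N200 at Fz,
# P300 at Cz)
N200_WINDOW_MS = (150.0, 300.0)
P300_WINDOW_MS = (250.0, 800.0)
ONSET_FALLBACK_MS = 1000.0


@dataclass(frozen=True)
class ERPStats:
    """The six summary readouts of an ERP dataset."""

    p300_amp_uv: float
    p300_latency_ms: float
    p300_onset_ms: float
    n200_amp_uv: float
    n200_latency_ms: float
    auc: float


def _channel_index(epochs: EpochSet, channel: str) -> int:
    try:
        return epochs.channel_names.index(channel)
    except ValueError as err:
        raise ValueError(f"channel {channel!r} not in epoch set") from err


def grand_average(epochs: EpochSet) -> dict[str, np.ndarray]:
    """Per-class sample-wise mean waveforms (channels x time), keyed by
    'target' and 'nontarget'."""
    out = {}
    for name, lab in (("target", 1), ("nontarget", 0)):
        mask = epochs.labels == lab
        if not mask.any():
            raise ValueError(f"no {name} epochs to average")
        out[name] = epochs.data[mask].mean(axis=0)
    return out


def bootstrap_peak(
    epochs: EpochSet,
    channel: str,
    window_ms: tuple[float, float],
    polarity: int,
    n_boot: int = 10,
    frac: float = 0.8,
    rng: np.random.Generator | None = None,
    *,
    label: int = 1,
) -> tuple[float, float]:
    """Bootstrap peak estimate on one channel: (amplitude_uv, latency_ms).

    For each of ``n_boot`` resamples, ``frac`` of the class-``label``
    epochs are drawn without replacement, averaged, and the signed
    extremum (maximum for polarity +1, minimum for -1) within
    ``window_ms`` is read out; the readouts are averaged.  The amplitude
    is returned as the signed value at the extremum.
    """
    if rng is None:
        rng = np.random.default_rng()
    tmask = (epochs.times_ms >= window_ms[0]) & (epochs.times_ms <= window_ms[1])
    if not tmask.any():
        raise ValueError(f"window {window_ms} outside the epoch grid")
    ch = _channel_index(epochs, channel)
    X = epochs.data[epochs.labels == label][:, ch, :][:, tmask]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 epochs for the bootstrap")
    times = epochs.times_ms[tmask]
    n_draw = max(1, int(round(frac * X.shape[0])))
    amps, lats = [], []
    for _ in range(n_boot):
        pick = rng.choice(X.shape[0], size=n_draw, replace=False)
        avg = X[pick].mean(axis=0)
        i = int(np.argmax(avg)) if polarity > 0 else int(np.argmin(avg))
        amps.append(avg[i])
        lats.append(times[i])
    return float(np.mean(amps)), float(np.mean(lats))


def p300_onset(
    target_epochs: np.ndarray,
    nontarget_epochs: np.ndarray,
    times_ms: np.ndarray,
    alpha: float = 0.05,
) -> float:
    """First post-stimulus time at which the classes differ significantly.

    Inputs are single-channel epoch matrices (epochs x time).  A
    two-sided two-sample t-test is run at every sample in (0, 1000] ms;
    the onset is the first significant sample's time, or 1000 ms if none
    is.  Zero-variance degenerate samples count as significant exactly
    when the class means differ.
    """
    target_epochs = np.atleast_2d(np.asarray(target_epochs, dtype=float))
    nontarget_epochs = np.atleast_2d(np.asarray(nontarget_epochs, dtype=float))
    if target_epochs.shape[0] < 2 or nontarget_epochs.shape[0] < 2:
        raise ValueError("need at least 2 epochs per class")
    scan = (times_ms > 0) & (times_ms <= ONSET_FALLBACK_MS)
    t_idx = np.flatnonzero(scan)
    tt, pp = stats.ttest_ind(
        target_epochs[:, t_idx], nontarget_epochs[:, t_idx], axis=0, equal_var=False
    )
    for j, (t, p) in enumerate(zip(tt, pp)):
        if np.isnan(t):
            mt = target_epochs[:, t_idx[j]].mean()
            mn = nontarget_epochs[:, t_idx[j]].mean()
            if mt != mn:
                return float(times_ms[t_idx[j]])
            continue
        if p < alpha:
            return float(times_ms[t_idx[j]])
    return ONSET_FALLBACK_MS


def p300_onset_from_epochs(
    epochs: EpochSet, channel: str = "Cz", alpha: float = 0.05
) -> float:
    """Convenience wrapper running :func:`p300_onset` on one channel of a
    labelled epoch set."""
    ch = _channel_index(epochs, channel)
    return p300_onset(
        epochs.data[epochs.labels == 1][:, ch, :],
        epochs.data[epochs.labels == 0][:, ch, :],
        epochs.times_ms,
        alpha=alpha,
    )


def interval_topography(
    epochs: EpochSet, interval_ms: tuple[float, float]
) -> np.ndarray:
    """Per-channel mean target amplitude over a time interval (the scalp
    maps of the four canonical windows 191-240 / 301-420 / 421-670 /
    671-800 ms)."""
    tmask = (epochs.times_ms >= interval_ms[0]) & (epochs.times_ms <= interval_ms[1])
    if not tmask.any():
        raise ValueError(f"interval {interval_ms} outside the epoch grid")
    targets = epochs.data[epochs.labels == 1]
    if targets.shape[0] == 0:
        raise ValueError("no target epochs")
    return targets[:, :, tmask].mean(axis=(0, 2))


def erp_stats(
    epochs: EpochSet,
    auc_value: float,
    rng: np.random.Generator | None = None,
    *,
    p300_channel: str = "Cz",
    n200_channel: str = "Fz",
) -> ERPStats:
    """Bundle the six standard readouts for one dataset."""
    if rng is None:
        rng = np.random.default_rng()
    p_amp, p_lat = bootstrap_peak(epochs, p300_channel, P300_WINDOW_MS, +1, rng=rng)
    n_amp, n_lat = bootstrap_peak(epochs, n200_channel, N200_WINDOW_MS, -1, rng=rng)
    onset = p300_onset_from_epochs(epochs, channel=p300_channel)
    return ERPStats(
        p300_amp_uv=p_amp,
        p300_latency_ms=p_lat,
        p300_onset_ms=onset,
        n200_amp_uv=n_amp,
        n200_latency_ms=n_lat,
        auc=float(auc_value),
    )
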