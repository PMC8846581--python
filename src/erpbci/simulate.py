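"""Synthetic multichannel EEG with stimulus-locked ERPs.

The simulator renders rank-1 space-time ERP templates (Gaussian temporal
envelope x fixed scalp topography) into pink-noise background activity at
scheduled stimulus onsets.  Target stimuli carry the full component set;
non-targets carry only the components shared by both classes (by default
the N200, while the P300 is target-specific).  A ``SubjectProfile``
degrades the target response the way severely impaired listeners do:
attenuation, delayed latencies, a fraction of missed targets that evoke
no target-specific response at all, and high-amplitude artefact bursts.

Amplitudes, latencies and noise levels of the default profiles are
simulator fixtures chosen to be physiologically plausible; they are not
measured patient values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .paradigm import Role, StimulusEvent, TrialSpec

__all__ = [
    "MONTAGE_31",
    "ERPComponentParams",
    "SubjectProfile",
    "ContinuousEEG",
    "scalp_topography",
    "default_components",
    "healthy_profile",
    "patient_profile",
    "render_erp",
    "make_noise",
    "simulate_session",
]

# 31-channel 10-20 subset (the montage size used online); approximate 2-D
# scalp positions in head-radius units, x = right, y = anterior.
MONTAGE_31: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.55, 0.48), "Fz": (0.0, 0.40),
    "F4": (0.55, 0.48), "F8": (0.81, 0.59),
    "FC5": (-0.75, 0.25), "FC1": (-0.30, 0.20), "FC2": (0.30, 0.20),
    "FC6": (0.75, 0.25),
    "T7": (-1.0, 0.0), "C3": (-0.5, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.5, 0.0), "T8": (1.0, 0.0),
    "CP5": (-0.75, -0.25), "CP1": (-0.30, -0.20), "CP2": (0.30, -0.20),
    "CP6": (0.75, -0.25),
    "P7": (-0.81, -0.59), "P3": (-0.55, -0.48), "Pz": (0.0, -0.40),
    "P4": (0.55, -0.48), "P8": (0.81, -0.59),
    "PO3": (-0.35, -0.75), "PO4": (0.35, -0.75),
    "O1": (-0.31, -0.95), "Oz": (0.0, -1.0), "O2": (0.31, -0.95),
    "FCz": (0.0, 0.20),
}


def scalp_topography(
    peak_channel: str,
    channel_names: list[str] | tuple[str, ...],
    spread: float = 0.6,
    shift_x: float = 0.0,
) -> np.ndarray:
    """Gaussian spatial falloff around a peak electrode.

    Weight of channel c is exp(-d^2 / (2 spread^2)) with d the planar
    distance to the (optionally laterally shifted) peak position; the
    maximum weight is 1 by construction at zero shift.
    """
    positions = np.array([MONTAGE_31[c] for c in channel_names])
    px, py = MONTAGE_31[peak_channel]
    px += shift_x
    d2 = (positions[:, 0] - px) ** 2 + (positions[:, 1] - py) ** 2
    return np.exp(-d2 / (2.0 * spread**2))


@dataclass(frozen=True)
class ERPComponentParams:
    """One ERP component as a rank-1 space-time template.

    ``amplitude_uv`` is the peak amplitude (in microvolts, before applying
    ``polarity``); ``width_ms`` is the standard deviation of the Gaussian
    temporal envelope; ``topography`` holds per-channel weights with
    max |weight| = 1 at ``peak_channel``.  ``nontarget_scale`` multiplies
    the amplitude for non-target stimuli (0 makes the component
    target-specific, 1 class-unspecific).  ``target_specific`` components
    are the ones modulated by the subject profile (attenuation, delay,
    misses).
    """

    name: str
    polarity: int
    amplitude_uv: float
    latency_ms: float
    width_ms: float
    peak_channel: str
    topography: np.ndarray
    nontarget_scale: float = 0.0
    target_specific: bool = True

    def __post_init__(self) -> None:
        if self.amplitude_uv < 0:
            raise ValueError("amplitude_uv must be >= 0")
        if self.width_ms <= 0:
            raise ValueError("width_ms must be > 0")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")


@dataclass(frozen=True)
class SubjectProfile:
    """Signal-quality regime of a simulated subject.

    attenuation: gain in (0, 1] applied to target-specific components.
    latency_delay_ms: added to target-specific component latencies.
    miss_probability: fraction of target stimuli that evoke no
        target-specific response (attention lapses).
    artefact_rate_per_min: expected high-amplitude burst count per minute.
    lateralization_shift: rightward shift (head-radius units) of all
        topography centres, emulating peri-lesional reorganisation.
    noise_rms_uv: per-channel RMS of the continuous background activity.
    """

    attenuation: float = 1.0
    latency_delay_ms: float = 0.0
    miss_probability: float = 0.0
    artefact_rate_per_min: float = 0.0
    lateralization_shift: float = 0.0
    noise_rms_uv: float = 4.0

    def __post_init__(self) -> None:
        if not 0.0 < self.attenuation <= 1.0:
            raise ValueError("attenuation must be in (0, 1]")
        if self.latency_delay_ms < 0:
            raise ValueError("latency_delay_ms must be >= 0")
        if not 0.0 <= self.miss_probability <= 1.0:
            raise ValueError("miss_probability must be in [0, 1]")
        if self.artefact_rate_per_min < 0 or self.noise_rms_uv < 0:
            raise ValueError("rates and RMS must be >= 0")


@dataclass
class ContinuousEEG:
    """Continuous multichannel recording plus stimulus markers.

    data: channels x samples, microvolts.
    markers: (sample_index, StimulusEvent) pairs, chronological.
    """

    data: np.ndarray
    fs_hz: float
    channel_names: tuple[str, ...]
    markers: list[tuple[int, StimulusEvent]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be > 0")
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ValueError("data must be channels x samples matching channel_names")
        n = self.data.shape[1]
        for idx, _ in self.markers:
            if not 0 <= idx < n:
                raise ValueError(f"marker sample {idx} outside recording of {n} samples")

    def copy(self) -> "ContinuousEEG":
        return ContinuousEEG(
            data=self.data.copy(),
            fs_hz=self.fs_hz,
            channel_names=tuple(self.channel_names),
            markers=list(self.markers),
        )


def default_components(
    channel_names: list[str] | tuple[str, ...] | None = None,
    lateralization_shift: float = 0.0,
) -> list[ERPComponentParams]:
    """Healthy-like component set: N200 (-3 uV, 200 ms, Fz-max, both
    classes) and a target-specific P300 (+5 uV, 400 ms, Cz-max)."""
    names = tuple(channel_names) if channel_names else tuple(MONTAGE_31)
    return [
        ERPComponentParams(
            name="N200", polarity=-1, amplitude_uv=3.0, latency_ms=200.0,
            width_ms=40.0, peak_channel="Fz",
            topography=scalp_topography("Fz", names, shift_x=lateralization_shift),
            nontarget_scale=1.0, target_specific=False,
        ),
        ERPComponentParams(
            name="P300", polarity=1, amplitude_uv=5.0, latency_ms=400.0,
            width_ms=90.0, peak_channel="Cz",
            topography=scalp_topography("Cz", names, shift_x=lateralization_shift),
            nontarget_scale=0.0, target_specific=True,
        ),
    ]


def healthy_profile(**overrides) -> SubjectProfile:
    return SubjectProfile(**overrides)


def patient_profile(**overrides) -> SubjectProfile:
    """Impaired regime: attenuated, delayed, frequently missed target
    responses with artefact bursts."""
    defaults = dict(
        attenuation=0.5,
        latency_delay_ms=150.0,
        miss_probability=0.2,
        artefact_rate_per_min=2.0,
        lateralization_shift=0.3,
        noise_rms_uv=6.0,
    )
    defaults.update(overrides)
    return SubjectProfile(**defaults)


def render_erp(
    components: list[ERPComponentParams],
    role: Role | str,
    fs_hz: float,
    epoch_window_ms: tuple[float, float] = (-200.0, 800.0),
) -> np.ndarray:
    """Noise-free single-epoch waveform (channels x time) for one class.

    Components superpose linearly; each contributes
    polarity * amplitude * topography (x) Gaussian(latency, width).
    Non-target epochs use each component's ``nontarget_scale``.
    """
    role = Role(role)
    t0, t1 = epoch_window_ms
    times = np.arange(round(t0 * fs_hz / 1000.0), round(t1 * fs_hz / 1000.0)) / fs_hz * 1000.0
    n_ch = len(components[0].topography) if components else 0
    out = np.zeros((n_ch, times.size))
    for comp in components:
        if not t0 <= comp.latency_ms <= t1:
            raise ValueError(
                f"component {comp.name} latency {comp.latency_ms} ms outside "
                f"epoch window {epoch_window_ms}"
            )
        scale = 1.0 if role is Role.TARGET else comp.nontarget_scale
        envelope = np.exp(-0.5 * ((times - comp.latency_ms) / comp.width_ms) ** 2)
        out += (
            comp.polarity * comp.amplitude_uv * scale
        ) * np.outer(comp.topography, envelope)
    return out


def make_noise(
    fs_hz: float,
    n_samples: int,
    n_channels: int,
    noise_rms_uv: float,
    rng: np.random.Generator,
    alpha_fraction: float = 0.3,
) -> np.ndarray:
    """Pink (1/f) background noise plus a 10 Hz alpha oscillation.

    White Gaussian noise is spectrally shaped by 1/sqrt(f); an alpha
    sinusoid with per-channel random phase contributes ``alpha_fraction``
    of the total variance.  The output is rescaled per channel to the
    requested RMS exactly.
    """
    if noise_rms_uv < 0:
        raise ValueError("noise_rms_uv must be >= 0")
    if n_samples <= 0:
        raise ValueError("n_samples must be > 0")
    if noise_rms_uv == 0:
        return np.zeros((n_channels, n_samples))

    white = rng.standard_normal((n_channels, n_samples))
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    shaping[0] = 0.0  # no DC drift
    pink = np.fft.irfft(np.fft.rfft(white, axis=1) * shaping, n=n_samples, axis=1)
    pink /= np.sqrt(np.mean(pink**2, axis=1, keepdims=True))

    t = np.arange(n_samples) / fs_hz
    phases = rng.uniform(0, 2 * np.pi, size=n_channels)
    alpha = np.sqrt(2.0) * np.sin(2 * np.pi * 10.0 * t[None, :] + phases[:, None])

    mix = np.sqrt(1.0 - alpha_fraction) * pink + np.sqrt(alpha_fraction) * alpha
    mix /= np.sqrt(np.mean(mix**2, axis=1, keepdims=True))
    return noise_rms_uv * mix


def _insert_artefacts(
    data: np.ndarray,
    fs_hz: float,
    rate_per_min: float,
    channel_names: tuple[str, ...],
    rng: np.random.Generator,
) -> None:
    """Add Poisson-timed 100-500 ms bursts of +-100-500 uV low-frequency
    deflections on frontal channels, in place."""
    if rate_per_min <= 0:
        return
    n_samples = data.shape[1]
    duration_min = n_samples / fs_hz / 60.0
    n_bursts = rng.poisson(rate_per_min * duration_min)
    frontal = [i for i, c in enumerate(channel_names) if c.startswith(("Fp", "F"))]
    if not frontal:
        frontal = list(range(data.shape[0]))
    for _ in range(n_bursts):
        width_s = rng.uniform(0.1, 0.5)
        amp = rng.uniform(100.0, 500.0) * rng.choice([-1.0, 1.0])
        centre = rng.integers(0, n_samples)
        half = int(width_s * fs_hz / 2)
        lo, hi = max(0, centre - half), min(n_samples, centre + half)
        if hi <= lo:
            continue
        t = np.arange(lo, hi)
        burst = amp * np.hanning(hi - lo)
        gains = rng.uniform(0.5, 1.0, size=len(frontal))
        for g, ch in zip(gains, frontal):
            data[ch, t] += g * burst


def simulate_session(
    schedule: list[TrialSpec] | TrialSpec,
    profile: SubjectProfile,
    components: list[ERPComponentParams] | None = None,
    fs_hz: float = 100.0,
    rng: np.random.Generator | None = None,
    *,
    tail_s: float = 2.0,
) -> ContinuousEEG:
    """Render a full session of scheduled trials into continuous EEG.

    Every scheduled stimulus becomes a marker.  Class-unspecific
    components are inserted at every onset; target-specific components are
    inserted at target onsets only, scaled by the profile's attenuation,
    delayed by its latency delay, and dropped altogether for a
    Bernoulli(miss_probability) subset of targets.  Background noise and
    artefact bursts are added on top.
    """
    if isinstance(schedule, TrialSpec):
        schedule = [schedule]
    if not schedule:
        raise ValueError("schedule must contain at least one trial")
    if rng is None:
        rng = np.random.default_rng()
    channel_names = tuple(MONTAGE_31)
    if components is None:
        components = default_components(channel_names, profile.lateralization_shift)

    min_width = min(c.width_ms for c in components) if components else np.inf
    # envelope bandwidth ~ 1/(2 pi sigma); require a few samples per sigma
    if components and fs_hz < 3.0 / (min_width / 1000.0):
        raise ValueError(
            f"fs_hz={fs_hz} too low to resolve a {min_width} ms-wide envelope"
        )

    events = [ev for trial in schedule for ev in trial.events]
    events.sort(key=lambda e: e.onset_s)
    t_end = events[-1].onset_s + tail_s
    n_samples = int(np.ceil(t_end * fs_hz)) + 1
    data = make_noise(fs_hz, n_samples, len(channel_names), profile.noise_rms_uv, rng)

    # profile-modulated target-specific components
    shifted = [
        dataclasses.replace(
            c,
            amplitude_uv=c.amplitude_uv * profile.attenuation,
            latency_ms=c.latency_ms + profile.latency_delay_ms,
        )
        if c.target_specific
        else c
        for c in components
    ]
    window = (0.0, 1000.0)
    for c in shifted:
        if not window[0] <= c.latency_ms <= window[1]:
            raise ValueError(
                f"profile-delayed latency {c.latency_ms} ms of {c.name} exceeds "
                "the 1000 ms insertion window"
            )
    shared = [c for c in shifted if not c.target_specific]
    target_only = [c for c in shifted if c.target_specific]
    template_shared = (
        render_erp(shared, Role.TARGET, fs_hz, window) if shared else None
    )
    template_shared_nt = (
        render_erp(shared, Role.NONTARGET, fs_hz, window) if shared else None
    )
    template_target_extra = (
        render_erp(target_only, Role.TARGET, fs_hz, window) if target_only else None
    )
    template_nt_extra = (
        render_erp(target_only, Role.NONTARGET, fs_hz, window) if target_only else None
    )
    tpl_len = next(
        (
            t.shape[1]
            for t in (template_shared, template_target_extra)
            if t is not None
        ),
        0,
    )

    markers: list[tuple[int, StimulusEvent]] = []
    for ev in events:
        idx = int(round(ev.onset_s * fs_hz))
        markers.append((idx, ev))
        hi = min(idx + tpl_len, n_samples)
        span = hi - idx
        if span <= 0:
            continue
        if ev.role is Role.TARGET:
            if template_shared is not None:
                data[:, idx:hi] += template_shared[:, :span]
            if template_target_extra is not None and rng.random() >= profile.miss_probability:
                data[:, idx:hi] += template_target_extra[:, :span]
        else:
            if template_shared_nt is not None:
                data[:, idx:hi] += template_shared_nt[:, :span]
            if template_nt_extra is not None:
                data[:, idx:hi] += template_nt_extra[:, :span]

    _insert_artefacts(data, fs_hz, profile.artefact_rate_per_min, channel_names, rng)
    return ContinuousEEG(data=data, fs_hz=fs_hz, channel_names=channel_names, markers=markers)
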