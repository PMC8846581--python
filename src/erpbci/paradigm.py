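"""Stimulus schedule generation for the auditory word-oddball training task.

A session is organised into runs of six trials.  Each trial is cued by a
sentence whose missing final word is the target; the six words of the set
are then played in a pseudo-random sequence of 15 blocks, each block a
permutation of all six words, so every word occurs exactly
``repetitions_per_word`` times (default 15 targets + 75 non-targets = 90
stimuli).  Within a run the target role rotates over the six words in a
balanced way.  A separate non-verbal tone-oddball schedule (rare high
tones among frequent low tones at a fixed SOA) serves as control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

N_WORDS = 6

__all__ = [
    "Condition",
    "Role",
    "SessionConfig",
    "StimulusEvent",
    "TrialSpec",
    "RunSpec",
    "generate_trial",
    "generate_run",
    "generate_oddball_run",
]


class Condition(str, Enum):
    """Stimulus presentation mode: six spatial loudspeakers or mono headphones."""

    LOUDSPEAKER = "loudspeaker"
    HEADPHONE = "headphone"


class Role(str, Enum):
    TARGET = "target"
    NONTARGET = "nontarget"


@dataclass(frozen=True)
class SessionConfig:
    """Parameters of one training session.

    Parameters
    ----------
    soa_ms:
        Stimulus onset asynchrony in milliseconds; the task supports
        250-1000 ms.
    condition:
        Loudspeaker (spatial) or headphone (mono) presentation.
    n_runs:
        Number of six-trial runs in the session.
    words, sentences:
        Six opaque identifiers each; sentence *i* cues word *i*.
    repetitions_per_word:
        Presentations of every word per trial (default 15).
    lead_in_s:
        Silence before the first stimulus of each trial, seconds.
    inter_trial_gap_s:
        Gap between the last stimulus of a trial and the lead-in of the
        next (sentence cue + feedback time in the real system).
    """

    soa_ms: float = 350.0
    condition: Condition = Condition.LOUDSPEAKER
    n_runs: int = 1
    words: tuple[str, ...] = tuple(f"word{i}" for i in range(N_WORDS))
    sentences: tuple[str, ...] = tuple(f"sentence{i}" for i in range(N_WORDS))
    repetitions_per_word: int = 15
    lead_in_s: float = 2.0
    inter_trial_gap_s: float = 5.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (250.0 <= self.soa_ms <= 1000.0):
            raise ValueError(f"soa_ms must be within [250, 1000], got {self.soa_ms}")
        if len(self.words) != N_WORDS or len(self.sentences) != N_WORDS:
            raise ValueError("exactly 6 words and 6 sentences are required")
        if self.repetitions_per_word < 1:
            raise ValueError("repetitions_per_word must be >= 1")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        object.__setattr__(self, "condition", Condition(self.condition))


@dataclass(frozen=True)
class StimulusEvent:
    """One scheduled stimulus presentation."""

    onset_s: float
    word_id: int
    role: Role
    direction: int  # loudspeaker index 1-6, or 0 for mono
    trial_id: int
    run_id: int
    duration_s: float = 0.3  # nominal stimulus duration, not modelled further


@dataclass(frozen=True)
class TrialSpec:
    """One trial: a sentence cue, a target word and the stimulus sequence."""

    sentence_id: int
    target_word_id: int
    word_to_direction: tuple[int, ...]
    events: tuple[StimulusEvent, ...]
    trial_id: int = 0
    run_id: int = 0

    @property
    def n_blocks(self) -> int:
        return len(self.events) // N_WORDS


@dataclass(frozen=True)
class RunSpec:
    """Six trials in which each word serves as target exactly once."""

    trials: tuple[TrialSpec, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        targets = sorted(t.target_word_id for t in self.trials)
        if targets != list(range(N_WORDS)):
            raise ValueError("run must use each word as target exactly once")


def _blockwise_sequence(n_blocks: int, rng: np.random.Generator) -> np.ndarray:
    """Concatenate n_blocks random permutations of the 6 words such that no
    two adjacent elements (across block boundaries included) coincide."""
    seq = np.empty(n_blocks * N_WORDS, dtype=np.int64)
    prev = -1
    for b in range(n_blocks):
        while True:
            perm = rng.permutation(N_WORDS)
            if perm[0] != prev:
                break
        seq[b * N_WORDS : (b + 1) * N_WORDS] = perm
        prev = perm[-1]
    return seq


def generate_trial(
    config: SessionConfig,
    sentence_id: int,
    rng: np.random.Generator,
    *,
    trial_id: int = 0,
    run_id: int = 0,
    start_s: float | None = None,
) -> TrialSpec:
    """Generate the stimulus schedule of one trial.

    The sentence uniquely cues its paired word (``target_word_id ==
    sentence_id``).  The sequence consists of ``repetitions_per_word``
    blocks, each a fresh permutation of the six words, with no word
    repeated back to back; onsets advance by the configured SOA.  In the
    loudspeaker condition a fresh word-to-direction permutation is drawn
    per trial; the headphone condition maps every word to mono (0).
    """
    if not 0 <= sentence_id < N_WORDS:
        raise ValueError(f"sentence_id must be in 0-5, got {sentence_id}")
    if start_s is None:
        start_s = config.lead_in_s

    seq = _blockwise_sequence(config.repetitions_per_word, rng)
    if config.condition is Condition.LOUDSPEAKER:
        word_to_direction = tuple(int(d) + 1 for d in rng.permutation(N_WORDS))
    else:
        word_to_direction = (0,) * N_WORDS

    target_word_id = sentence_id
    soa_s = config.soa_ms / 1000.0
    events = tuple(
        StimulusEvent(
            onset_s=start_s + i * soa_s,
            word_id=int(w),
            role=Role.TARGET if w == target_word_id else Role.NONTARGET,
            direction=word_to_direction[int(w)],
            trial_id=trial_id,
            run_id=run_id,
        )
        for i, w in enumerate(seq)
    )
    return TrialSpec(
        sentence_id=sentence_id,
        target_word_id=target_word_id,
        word_to_direction=word_to_direction,
        events=events,
        trial_id=trial_id,
        run_id=run_id,
    )


def generate_run(
    config: SessionConfig,
    rng: np.random.Generator,
    *,
    run_id: int = 0,
    start_s: float = 0.0,
) -> RunSpec:
    """Generate six trials with the target role balanced over the words.

    The order in which the six sentences (and hence targets) appear is a
    uniformly random permutation, so every word is the target of exactly
    one trial per run.
    """
    order = rng.permutation(N_WORDS)
    trials = []
    t0 = start_s
    trial_dur = (
        config.lead_in_s
        + (config.repetitions_per_word * N_WORDS - 1) * config.soa_ms / 1000.0
    )
    for k, sid in enumerate(order):
        trial = generate_trial(
            config,
            int(sid),
            rng,
            trial_id=k,
            run_id=run_id,
            start_s=t0 + config.lead_in_s,
        )
        trials.append(trial)
        t0 += trial_dur + config.inter_trial_gap_s
    return RunSpec(trials=tuple(trials))


def generate_oddball_run(
    n_targets: int = 50,
    n_nontargets: int = 250,
    soa_s: float = 1.0,
    rng: np.random.Generator | None = None,
    *,
    lead_in_s: float = 2.0,
) -> TrialSpec:
    """Generate the non-verbal tone-oddball control schedule.

    Defaults to 50 rare high-pitched target tones among 250 low-pitched
    non-targets, one tone per second.  Tone classes are coded as word_id 1
    (high/target) and 0 (low/non-target); the order is a uniformly random
    shuffle of the class multiset.
    """
    if n_targets < 0 or n_nontargets < 0:
        raise ValueError("tone counts must be non-negative")
    if rng is None:
        rng = np.random.default_rng()
    labels = np.concatenate(
        [np.ones(n_targets, dtype=np.int64), np.zeros(n_nontargets, dtype=np.int64)]
    )
    rng.shuffle(labels)
    events = tuple(
        StimulusEvent(
            onset_s=lead_in_s + i * soa_s,
            word_id=int(c),
            role=Role.TARGET if c == 1 else Role.NONTARGET,
            direction=0,
            trial_id=0,
            run_id=0,
        )
        for i, c in enumerate(labels)
    )
    return TrialSpec(
        sentence_id=0,
        target_word_id=1,
        word_to_direction=(0,) * N_WORDS,
        events=events,
    )
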