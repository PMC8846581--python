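"""Trial-level word decoding with dynamic stopping and graded feedback.

During a trial the decoder scores every stimulus epoch and the outputs
are accumulated separately per word (up to 15 per word).  The attended
word is the one with the highest mean output.  After each complete
presentation block the stopping rule may end the sequence early: once at
least ``min_iterations`` blocks are in, a one-sided Welch t-test of the
current best word's outputs against the pooled outputs of the other five
words triggers a stop at p < ``p_threshold``.

Feedback is graded in three levels: *very positive* when the selection
is correct and the trial stopped early, *positive* when correct at full
length with a clear output separation, and *neutral* when the selection
is wrong or the separation (best-vs-rest AUC) stays below
``separation_threshold``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .decoder import LDAClassifier, auc, decision_values
from .paradigm import N_WORDS, TrialSpec
from .preprocessing import (
    DEFAULT_BASELINE_MS,
    DEFAULT_INTERVALS_MS,
    DEFAULT_WINDOW_MS,
)
from .simulate import ContinuousEEG

__all__ = [
    "TrialDecodingState",
    "StoppingPolicy",
    "FeedbackLevel",
    "FeedbackResult",
    "update_state",
    "select_word",
    "should_stop",
    "grade_feedback",
    "run_trial",
]


@dataclass
class TrialDecodingState:
    """Per-word classifier-output accumulators for one trial."""

    per_word_outputs: list[list[float]] = field(
        default_factory=lambda: [[] for _ in range(N_WORDS)]
    )
    repetitions_per_word: int = 15
    stopped_early: bool = False

    @property
    def iteration_count(self) -> int:
        """Completed presentation blocks = min output count over words."""
        return min(len(o) for o in self.per_word_outputs)

    @property
    def n_outputs(self) -> int:
        return sum(len(o) for o in self.per_word_outputs)


class FeedbackLevel:
    VERY_POSITIVE = "very_positive"
    POSITIVE = "positive"
    NEUTRAL = "neutral"


@dataclass(frozen=True)
class StoppingPolicy:
    """Dynamic-stopping and feedback-grading thresholds."""

    min_iterations: int = 5
    p_threshold: float = 0.01
    separation_threshold: float = 0.65

    def __post_init__(self) -> None:
        if self.min_iterations < 1:
            raise ValueError("min_iterations must be >= 1")
        if not (0.0 < self.p_threshold < 1.0 and 0.0 < self.separation_threshold < 1.0):
            raise ValueError("thresholds must lie in (0, 1)")


@dataclass(frozen=True)
class FeedbackResult:
    """Outcome of one trial: the selected word and the feedback grade."""

    selected_word_id: int
    target_word_id: int
    correct: bool
    level: str
    stimuli_presented: int
    separation_score: float
    stopped_early: bool


def update_state(
    state: TrialDecodingState, word_id: int, output: float
) -> TrialDecodingState:
    """Append one classifier output to the word's accumulator (in place,
    also returned for chaining)."""
    if not 0 <= word_id < N_WORDS:
        raise ValueError(f"word_id must be in 0-5, got {word_id}")
    if len(state.per_word_outputs[word_id]) >= state.repetitions_per_word:
        raise ValueError(
            f"word {word_id} already has {state.repetitions_per_word} outputs"
        )
    state.per_word_outputs[word_id].append(float(output))
    return state


def select_word(state: TrialDecodingState) -> int:
    """Word with the highest mean classifier output; ties break toward
    the lowest word id (argmax convention)."""
    if any(len(o) == 0 for o in state.per_word_outputs):
        raise ValueError("every word needs at least one output before selection")
    means = np.array([np.mean(o) for o in state.per_word_outputs])
    return int(np.argmax(means))


def _best_vs_rest(state: TrialDecodingState) -> tuple[int, np.ndarray, np.ndarray]:
    best = select_word(state)
    best_out = np.asarray(state.per_word_outputs[best])
    rest = np.concatenate(
        [np.asarray(o) for w, o in enumerate(state.per_word_outputs) if w != best]
    )
    return best, best_out, rest


def should_stop(state: TrialDecodingState, policy: StoppingPolicy) -> bool:
    """One-sided Welch t-test of the best word's outputs vs the pooled
    rest; stop once p < p_threshold after the minimum block count."""
    if state.iteration_count < policy.min_iterations:
        return False
    _, best_out, rest = _best_vs_rest(state)
    if best_out.size < 2 or rest.size < 2:
        return False
    if np.var(best_out) == 0 and np.var(rest) == 0:
        # degenerate: identical-variance-free samples; stop only on a
        # strict mean separation
        return float(best_out.mean()) > float(rest.mean())
    t, p_two = stats.ttest_ind(best_out, rest, equal_var=False)
    if not np.isfinite(t):
        return False
    p_one = p_two / 2.0 if t > 0 else 1.0 - p_two / 2.0
    return bool(p_one < policy.p_threshold)


def grade_feedback(
    state: TrialDecodingState,
    target_word_id: int,
    policy: StoppingPolicy = StoppingPolicy(),
) -> FeedbackResult:
    """Map the finished trial to a feedback level.

    neutral: wrong selection or best-vs-rest AUC below the separation
    threshold; very_positive: correct and stopped early; positive:
    correct at full length with sufficient separation.
    """
    selected, best_out, rest = _best_vs_rest(state)
    sep_labels = np.concatenate([np.ones(best_out.size), np.zeros(rest.size)])
    separation = auc(np.concatenate([best_out, rest]), sep_labels)
    correct = selected == target_word_id
    if not correct or separation < policy.separation_threshold:
        level = FeedbackLevel.NEUTRAL
    elif state.stopped_early:
        level = FeedbackLevel.VERY_POSITIVE
    else:
        level = FeedbackLevel.POSITIVE
    return FeedbackResult(
        selected_word_id=selected,
        target_word_id=target_word_id,
        correct=correct,
        level=level,
        stimuli_presented=state.n_outputs,
        separation_score=float(separation),
        stopped_early=state.stopped_early,
    )


def run_trial(
    clf: LDAClassifier,
    eeg_stream: ContinuousEEG,
    trial: TrialSpec,
    policy: StoppingPolicy = StoppingPolicy(),
    *,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    baseline_ms: tuple[float, float] = DEFAULT_BASELINE_MS,
    intervals_ms=DEFAULT_INTERVALS_MS,
) -> FeedbackResult:
    """Decode one trial online-style from a (filtered) continuous stream.

    Epochs are cut marker by marker in presentation order, featurized,
    scored and accumulated; the stopping rule is evaluated after every
    complete presentation block.  The stream must contain a marker for
    every scheduled stimulus of the trial.
    """
    marker_by_onset = {
        round(ev.onset_s, 6): idx for idx, ev in eeg_stream.markers
    }
    fs = eeg_stream.fs_hz
    i0 = round(window_ms[0] * fs / 1000.0)
    i1 = round(window_ms[1] * fs / 1000.0)
    times_ms = np.arange(i0, i1) / fs * 1000.0
    bmask = (times_ms >= baseline_ms[0]) & (times_ms < baseline_ms[1])
    ivmasks = [(times_ms >= a) & (times_ms < b) for a, b in intervals_ms]

    n_blocks = trial.n_blocks
    state = TrialDecodingState(repetitions_per_word=n_blocks)
    for i, ev in enumerate(trial.events):
        key = round(ev.onset_s, 6)
        if key not in marker_by_onset:
            raise ValueError(f"stream is missing a marker at onset {ev.onset_s:.3f} s")
        idx = marker_by_onset[key]
        lo, hi = idx + i0, idx + i1
        if lo < 0 or hi > eeg_stream.data.shape[1]:
            raise ValueError(f"stream too short for the epoch at {ev.onset_s:.3f} s")
        ep = eeg_stream.data[:, lo:hi]
        ep = ep - ep[:, bmask].mean(axis=1, keepdims=True)
        feats = np.concatenate([ep[:, m].mean(axis=1) for m in ivmasks])
        out = float(decision_values(clf, feats[None, :])[0])
        update_state(state, ev.word_id, out)
        block_done = (i + 1) % N_WORDS == 0
        if block_done and should_stop(state, policy):
            state.stopped_early = state.iteration_count < n_blocks
            break
    return grade_feedback(state, trial.target_word_id, policy)
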