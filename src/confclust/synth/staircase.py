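"""Adaptive 1-up-2-down staircase on motion coherence.

Difficulty increases (coherence steps down) after two consecutive correct
responses and decreases (coherence steps up) after every error.  With equal
up/down steps the procedure converges to the accuracy p solving p^2 = 0.5,
i.e. ~0.707.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .specs import ObserverSpec


@dataclass
class StaircaseResult:
    coherence: np.ndarray   # coherence presented on each trial
    correct: np.ndarray     # bool per trial
    steps: np.ndarray       # +1 up (easier), -1 down (harder), 0 hold, applied AFTER the trial

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.correct))

    def final_half_accuracy(self) -> float:
        half = len(self.correct) // 2
        return float(np.mean(self.correct[half:]))


def simulate_staircase(
    observer: ObserverSpec,
    n_trials: int,
    initial_coherence: float = 1.0,
    step: float = 0.05,
    floor: float = 1e-3,
    ceiling: float = 4.0,
    rng: np.random.Generator | None = None,
    p_correct=None,
) -> StaircaseResult:
    """Run a 1-up-2-down staircase with multiplicative (log-additive) steps.

    ``p_correct`` may override the observer's psychometric function (callable
    coherence -> probability); used for degenerate-observer tests.
    """
    if n_trials < 50:
        raise ValueError("staircase needs at least 50 trials")
    if initial_coherence <= 0:
        raise ValueError("initial coherence must be positive")
    if rng is None:
        rng = np.random.default_rng()
    if p_correct is None:
        p_correct = observer.p_correct

    log_c = np.log(initial_coherence)
    log_floor, log_ceil = np.log(floor), np.log(ceiling)

    coherence = np.empty(n_trials)
    correct = np.zeros(n_trials, dtype=bool)
    steps = np.zeros(n_trials, dtype=int)
    consecutive_correct = 0
    for i in range(n_trials):
        c = float(np.exp(log_c))
        coherence[i] = c
        ok = bool(rng.random() < float(p_correct(c)))
        correct[i] = ok
        if ok:
            consecutive_correct += 1
            if consecutive_correct == 2:   # two in a row -> harder
                steps[i] = -1
                consecutive_correct = 0
        else:
            steps[i] = +1                  # every error -> easier
            consecutive_correct = 0
        log_c = float(np.clip(log_c + steps[i] * step, log_floor, log_ceil))

    return StaircaseResult(coherence=coherence, correct=correct, steps=steps)


def reconstruct_coherence(result: StaircaseResult, initial_coherence: float,
                          step: float = 0.05, floor: float = 1e-3,
                          ceiling: float = 4.0) -> np.ndarray:
    """Replay the recorded up/down steps; must reproduce the coherence trace."""
    log_c = np.log(initial_coherence)
    lo, hi = np.log(floor), np.log(ceiling)
    out = np.empty(len(result.steps))
    for i, s in enumerate(result.steps):
        out[i] = np.exp(log_c)
        log_c = float(np.clip(log_c + s * step, lo, hi))
    return out
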