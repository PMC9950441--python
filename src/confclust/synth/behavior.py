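"""Behavioral trial simulation: staircase-matched accuracy, confidence read-out,
movement onsets and generative change-of-mind / exclusion truth."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .specs import CohortSpec, ObserverSpec

TRIAL_COLUMNS = [
    "participant", "group", "trial", "stimulus", "response", "correct",
    "coherence", "evidence", "confidence", "onset", "com_pre",
    "true_exclusion",
]


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def simulate_participant(
    observer: ObserverSpec,
    n_trials: int,
    rng: np.random.Generator,
    initial_coherence: float = 1.0,
    step: float = 0.05,
    com_pre_rate: float = 0.07,
) -> pd.DataFrame:
    """Simulate one participant's trials with an embedded 1-up-2-down staircase.

    Evidence follows an equal-variance SDT model: x ~ N(stim * slope * c, 1),
    response = sign(x), so p(correct) = Phi(slope * c) before lapses.
    Confidence is a clipped linear read-out of response-consistent evidence,
    coupled to the standardized movement onset.
    """
    if n_trials == 0:
        return pd.DataFrame(columns=TRIAL_COLUMNS[2:])

    log_c = np.log(initial_coherence)
    lo, hi = np.log(1e-3), np.log(4.0)
    consecutive = 0

    stimulus = rng.choice([-1, 1], size=n_trials)
    coherence = np.empty(n_trials)
    evidence = np.empty(n_trials)
    response = np.empty(n_trials, dtype=int)
    correct = np.zeros(n_trials, dtype=bool)

    for i in range(n_trials):
        c = float(np.exp(log_c))
        coherence[i] = c
        x = rng.normal(stimulus[i] * observer.slope * c, 1.0)
        evidence[i] = x
        if rng.random() < observer.lapse:
            resp = int(rng.choice([-1, 1]))
        else:
            resp = 1 if x > 0 else -1
        response[i] = resp
        ok = resp == stimulus[i]
        correct[i] = ok
        if ok:
            consecutive += 1
            if consecutive == 2:
                log_c = float(np.clip(log_c - step, lo, hi))
                consecutive = 0
        else:
            log_c = float(np.clip(log_c + step, lo, hi))
            consecutive = 0

    mu, sigma = _lognormal_params(observer.mean_onset, observer.onset_sd)
    onset = rng.lognormal(mu, sigma, size=n_trials)
    z_onset = (onset - onset.mean()) / max(onset.std(), 1e-12)

    signed_evidence = evidence * response
    confidence = (
        observer.confidence_bias
        + observer.confidence_gain * signed_evidence
        + 100.0 * observer.confidence_rt_coupling * z_onset
        + rng.normal(0.0, observer.confidence_noise_sd, size=n_trials)
    )
    confidence = np.clip(confidence, 0.0, 100.0)

    com_pre = rng.random(n_trials) < com_pre_rate

    true_excl = np.full(n_trials, "none", dtype=object)
    true_excl[confidence < 50.0] = "com_post"
    true_excl[com_pre] = "com_pre"
    true_excl[onset > 6.0] = "late"
    true_excl[onset < 0.1] = "early"

    return pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "stimulus": stimulus,
            "response": response,
            "correct": correct.astype(int),
            "coherence": coherence,
            "evidence": evidence,
            "confidence": confidence,
            "onset": onset,
            "com_pre": com_pre,
            "true_exclusion": true_excl,
        }
    )


def simulate_behavior(
    cohort: CohortSpec,
    observer_a: ObserverSpec,
    observer_b: ObserverSpec | None = None,
    rng: np.random.Generator | None = None,
    com_pre_rate: float = 0.07,
) -> pd.DataFrame:
    """Simulate the full two-group cohort; one row per trial.

    Group a uses ``observer_a`` (control), group b ``observer_b`` (ssd);
    if ``observer_b`` is omitted both groups share ``observer_a``.
    """
    if observer_b is None:
        observer_b = observer_a
    if rng is None:
        rng = np.random.default_rng(cohort.seed)

    frames = []
    for pid in cohort.participant_ids():
        group = cohort.group_of(pid)
        obs = observer_a if group == "control" else observer_b
        df = simulate_participant(obs, cohort.trials_per_participant, rng,
                                  com_pre_rate=com_pre_rate)
        df.insert(0, "participant", pid)
        df.insert(1, "group", group)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out[TRIAL_COLUMNS]
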