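"""Synthetic mouse trajectories on a normalized [0,1]x[0,1] screen.

Start point bottom-center (0.5, 0.05); response targets at the top corners
(0.1, 0.9) and (0.9, 0.9); the midline is x = 0.5.  Movements follow a
minimal-jerk profile beginning at the generative onset.  With the default
movement duration (0.65 s) the speed crosses 20% of its peak ~83 ms after the
generative onset, so the detector's five-frame offset approximately cancels.
"""

from __future__ import annotations

import numpy as np

from ..kinematics import Trajectory

START = (0.5, 0.05)
TARGET_LEFT = (0.1, 0.9)
TARGET_RIGHT = (0.9, 0.9)
TARGET_RADIUS = 0.12

#: Fixed display frame rate implied by the five-frame (~83 ms) onset offset.
FRAME_RATE = 60.0


def _minimal_jerk(tau: np.ndarray) -> np.ndarray:
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def minimal_jerk_peak_speed(distance: float, duration: float) -> float:
    """Analytic peak speed of a minimal-jerk reach: 1.875 * d / T."""
    return 1.875 * distance / duration


def simulate_trajectory(
    onset: float,
    target_side: str,
    com: bool = False,
    frame_rate: float = FRAME_RATE,
    movement_duration: float = 0.65,
    trial_id: int = 0,
    rng: np.random.Generator | None = None,
    jitter_sd: float = 0.0,
) -> Trajectory:
    """Generate a single mouse trajectory.

    The cursor is stationary at the start point until ``onset`` seconds, then
    reaches the chosen target.  If ``com`` is set, the path first heads toward
    the opposite target (switching 40% into the movement), producing a midline
    crossing after 20% of travel toward the target's y-projection.
    """
    if onset >= 6.0 + movement_duration:
        raise ValueError("onset must precede the response deadline")
    if target_side not in ("left", "right"):
        raise ValueError("target_side must be 'left' or 'right'")

    target = np.array(TARGET_LEFT if target_side == "left" else TARGET_RIGHT)
    wrong = np.array(TARGET_RIGHT if target_side == "left" else TARGET_LEFT)
    start = np.array(START)

    duration = movement_duration * (1.25 if com else 1.0)
    t_end = onset + duration + 0.15
    t = np.arange(0.0, t_end, 1.0 / frame_rate)
    xy = np.tile(start, (t.size, 1))

    moving = t >= onset
    if com:
        switch = 0.4
        t_switch = onset + switch * duration
        seg1 = moving & (t < t_switch)
        tau1 = (t[seg1] - onset) / duration
        xy[seg1] = start + np.outer(_minimal_jerk(tau1), wrong - start)
        # position reached at the switch point
        p_switch = start + _minimal_jerk(np.array([switch]))[0] * (wrong - start)
        seg2 = t >= t_switch
        tau2 = (t[seg2] - t_switch) / (duration * (1 - switch))
        xy[seg2] = p_switch + np.outer(_minimal_jerk(tau2), target - p_switch)
    else:
        tau = (t[moving] - onset) / duration
        xy[moving] = start + np.outer(_minimal_jerk(tau), target - start)

    if jitter_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        xy = xy + rng.normal(0.0, jitter_sd, size=xy.shape)

    return Trajectory(t=t, x=xy[:, 0], y=xy[:, 1], trial_id=trial_id)


def trajectories_for_trials(
    trials,
    frame_rate: float = FRAME_RATE,
    rng: np.random.Generator | None = None,
) -> list[Trajectory]:
    """One trajectory per row of a behavioral trial table."""
    out = []
    for i, row in trials.reset_index(drop=True).iterrows():
        side = "right" if row["response"] > 0 else "left"
        onset = float(min(row["onset"], 6.4))
        out.append(
            simulate_trajectory(
                onset=onset,
                target_side=side,
                com=bool(row.get("com_pre", False)),
                frame_rate=frame_rate,
                trial_id=int(i),
                rng=rng,
            )
        )
    return out
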