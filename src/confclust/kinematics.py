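"""Mouse-trajectory kinematics: velocity, movement onset, changes of mind and
trial exclusion decisions.

Movement onset is the time the speed first reaches 20% of the trial's peak
speed (restricted to the movement containing the global peak, so sub-threshold
micro-movements are ignored), minus a fixed five-frame offset (~83 ms at
60 Hz), floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MIDLINE_X = 0.5
ONSET_THRESHOLD_FRACTION = 0.20
ONSET_OFFSET_FRAMES = 5
DEFAULT_FRAME_RATE = 60.0
EARLY_CUTOFF = 0.100        # seconds
LATE_CUTOFF = 6.0           # seconds
COM_TRAVEL_FRACTION = 0.20
COM_POST_CONFIDENCE = 50.0  # strictly below -> post-response change of mind

EXCLUSION_LABELS = ("none", "early", "late", "com_pre", "com_post", "no_movement")


def onset_offset_seconds(frames: int = ONSET_OFFSET_FRAMES,
                         frame_rate: float = DEFAULT_FRAME_RATE) -> float:
    """Fixed offset subtracted from the threshold-crossing time, seconds."""
    return frames / frame_rate


def onset_offset_ms(frames: int = ONSET_OFFSET_FRAMES,
                    frame_rate: float = DEFAULT_FRAME_RATE) -> int:
    """The offset in milliseconds, rounded to the nearest integer (~83 ms)."""
    return int(round(1000.0 * frames / frame_rate))


@dataclass
class Trajectory:
    """Timestamped 2-D mouse samples at the display frame rate."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    trial_id: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.size == self.x.size == self.y.size):
            raise ValueError("t, x, y must have equal length")
        if self.t.size < 2:
            raise ValueError("trajectory needs at least 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def smoothed(self, window: int = 3) -> "Trajectory":
        """Optional moving-average smoothing for noisy real recordings."""
        kernel = np.ones(window) / window
        pad = window // 2
        xs = np.convolve(np.pad(self.x, pad, mode="edge"), kernel, mode="valid")
        ys = np.convolve(np.pad(self.y, pad, mode="edge"), kernel, mode="valid")
        return Trajectory(t=self.t, x=xs[: self.t.size], y=ys[: self.t.size],
                          trial_id=self.trial_id)


@dataclass
class KinematicResult:
    onset: float | None
    peak_velocity: float
    com_pre: bool
    com_post: bool
    exclusion: str

    def __post_init__(self) -> None:
        if self.exclusion not in EXCLUSION_LABELS:
            raise ValueError(f"unknown exclusion label {self.exclusion!r}")
        if self.onset is not None and self.onset < 0:
            raise ValueError("onset must be >= 0 when present")


def compute_velocity(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Speed series (units/s) between consecutive samples.

    Returns (t_mid, speed): length n-1, mapped to interval midpoints.
    """
    dt = np.diff(traj.t)
    if np.any(dt == 0):
        raise ValueError("duplicate timestamps in trajectory")
    disp = np.hypot(np.diff(traj.x), np.diff(traj.y))
    speed = disp / dt
    t_mid = (traj.t[:-1] + traj.t[1:]) / 2.0
    return t_mid, speed


def _threshold_crossing_index(speed: np.ndarray,
                              fraction: float = ONSET_THRESHOLD_FRACTION) -> int | None:
    """Index of the first speed sample >= fraction*max within the movement
    containing the global peak (sub-threshold peaks are non-decisional)."""
    vmax = speed.max()
    if vmax <= 0:
        return None
    threshold = fraction * vmax
    peak = int(np.argmax(speed))
    # walk back from the peak to the start of its supra-threshold run
    i = peak
    while i > 0 and speed[i - 1] >= threshold:
        i -= 1
    return i


def detect_movement_onset(
    traj: Trajectory,
    threshold_fraction: float = ONSET_THRESHOLD_FRACTION,
    offset_frames: int = ONSET_OFFSET_FRAMES,
    frame_rate: float = DEFAULT_FRAME_RATE,
) -> float | None:
    """Movement onset in seconds from stimulus onset, or None if no movement."""
    t_mid, speed = compute_velocity(traj)
    idx = _threshold_crossing_index(speed, threshold_fraction)
    if idx is None:
        return None
    onset = float(t_mid[idx]) - offset_frames / frame_rate
    return max(onset, 0.0)  # the offset may not push onset before stimulus onset


def detect_change_of_mind(
    traj: Trajectory,
    target_side: str,
    travel_fraction: float = COM_TRAVEL_FRACTION,
    midline: float | None = None,
    target_y: float | None = None,
) -> bool:
    """Pre-response change of mind: midline crossing after 20% of travel.

    Travel progress is measured toward the y-projection of the target position
    from the initial mouse position.  Restricted to samples at/after the first
    sample reaching ``travel_fraction`` progress, the flag is raised when the
    x-coordinate is found strictly on the non-target side of the midline.

    By default the midline is the starting x (the start point sits between the
    two targets) and the target's y-projection is the trajectory endpoint, so
    the decision is invariant to uniform rescaling of the screen coordinates.
    """
    if target_side not in ("left", "right"):
        raise ValueError("target_side must be 'left' or 'right'")
    if midline is None:
        midline = float(traj.x[0])
    if target_y is None:
        target_y = float(traj.y[-1])
    y0 = traj.y[0]
    total = target_y - y0
    if total == 0:
        return False
    progress = (traj.y - y0) / total
    reached = np.flatnonzero(progress >= travel_fraction)
    if reached.size == 0:
        return False
    seg = slice(int(reached[0]), None)
    dx = traj.x[seg] - midline
    if target_side == "right":
        return bool(np.any(dx < 0))
    return bool(np.any(dx > 0))


def analyze_trajectory(
    traj: Trajectory,
    target_side: str,
    confidence: float | None = None,
    frame_rate: float = DEFAULT_FRAME_RATE,
) -> KinematicResult:
    """Full per-trial kinematic analysis including the exclusion decision."""
    t_mid, speed = compute_velocity(traj)
    peak = float(speed.max())
    onset = detect_movement_onset(traj, frame_rate=frame_rate)
    com_pre = detect_change_of_mind(traj, target_side) if onset is not None else False
    com_post = confidence is not None and confidence < COM_POST_CONFIDENCE
    label = exclusion_label(onset=onset, com_pre=com_pre, confidence=confidence)
    return KinematicResult(onset=onset, peak_velocity=peak, com_pre=com_pre,
                           com_post=com_post, exclusion=label)


def exclusion_label(
    onset: float | None,
    com_pre: bool = False,
    confidence: float | None = None,
) -> str:
    """Exclusion decision with precedence
    no_movement > early > late > com_pre > com_post > none."""
    if confidence is not None and not (0.0 <= confidence <= 100.0):
        raise ValueError("confidence must lie in [0, 100]")
    if onset is None:
        return "no_movement"
    if onset < EARLY_CUTOFF:
        return "early"
    if onset > LATE_CUTOFF:
        return "late"
    if com_pre:
        return "com_pre"
    if confidence is not None and confidence < COM_POST_CONFIDENCE:
        return "com_post"
    return "none"


def apply_trial_exclusions(trials: pd.DataFrame) -> pd.DataFrame:
    """Attach exclusion labels to a trial table carrying onset/com_pre/confidence.

    ``onset`` may contain NaN for absent onsets (no movement detected).
    """
    labels = []
    for _, row in trials.iterrows():
        onset = row.get("onset")
        onset = None if onset is None or (isinstance(onset, float) and np.isnan(onset)) else float(onset)
        labels.append(
            exclusion_label(
                onset=onset,
                com_pre=bool(row.get("com_pre", False)),
                confidence=float(row["confidence"]) if "confidence" in row else None,
            )
        )
    out = trials.copy()
    out["exclusion"] = labels
    return out


# -- CSV interfaces ---------------------------------------------------------

def read_trajectories_csv(path) -> list[Trajectory]:
    """Long-format CSV (trial_id, t, x, y) -> list of Trajectory."""
    df = pd.read_csv(path)
    required = {"trial_id", "t", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory CSV must have columns {sorted(required)}")
    out = []
    for tid, g in df.groupby("trial_id", sort=True):
        g = g.sort_values("t")
        out.append(Trajectory(t=g["t"].to_numpy(), x=g["x"].to_numpy(),
                              y=g["y"].to_numpy(), trial_id=int(tid)))
    return out


def write_trajectories_csv(trajectories: list[Trajectory], path) -> None:
    frames = [
        pd.DataFrame({"trial_id": tr.trial_id, "t": tr.t, "x": tr.x, "y": tr.y})
        for tr in trajectories
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def results_to_frame(results: dict[int, KinematicResult]) -> pd.DataFrame:
    rows = []
    for tid, r in results.items():
        rows.append(
            {
                "trial_id": tid,
                "onset": np.nan if r.onset is None else r.onset,
                "peak_velocity": r.peak_velocity,
                "com_pre": r.com_pre,
                "com_post": r.com_post,
                "exclusion": r.exclusion,
            }
        )
    return pd.DataFrame(rows)
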