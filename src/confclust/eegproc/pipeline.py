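"""Deterministic EEG preprocessing.

Canonical order: filter -> epoch -> common-average reference -> artifact
surrogate -> participant-level baseline -> percentile trimming.  ICA-based
artifact classification is deliberately replaced by a documented surrogate
(peak-to-peak / EOG amplitude rejection); hooks allow a real-data user to plug
in an external implementation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from ..epochs import EpochArray, default_times
from .edf import ContinuousRecording

TARGET_FS = 128.0
HIGHPASS_HZ = 0.5
LOWPASS_HZ = 45.0
BASELINE_WINDOW = (-0.700, -0.200)
PTP_THRESHOLD_UV = 150.0
EOG_THRESHOLD_UV = 120.0


# -- continuous-domain steps -------------------------------------------------

def bandpass_fir(n_samples: int, fs: float, lo: float = HIGHPASS_HZ,
                 hi: float = LOWPASS_HZ) -> np.ndarray:
    """Zero-phase-ready linear-phase FIR band-pass taps (Hamming window)."""
    transition = lo  # narrowest transition is set by the high-pass edge
    numtaps = int(3.3 * fs / transition)
    numtaps = min(numtaps, max((n_samples - 2) // 3, 11))
    if numtaps % 2 == 0:
        numtaps -= 1
    return signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs)


def preprocess_continuous(
    rec: ContinuousRecording,
    montage: list[str] | None = None,
    target_fs: float = TARGET_FS,
    lo: float = HIGHPASS_HZ,
    hi: float = LOWPASS_HZ,
) -> ContinuousRecording:
    """Downsample to 128 Hz, then zero-phase band-pass filter 0.5-45 Hz."""
    if rec.fs < 256:
        raise ValueError("input sampling rate must be >= 256 Hz")
    if montage is not None:
        missing = set(montage) - set(rec.channels)
        if missing:
            raise ValueError(f"recording is missing montage channels: {sorted(missing)}")
    up, down = (np.array([target_fs, rec.fs]) /
                math.gcd(int(round(target_fs)), int(round(rec.fs)))).astype(int)
    data = signal.resample_poly(rec.data, up, down, axis=1)
    taps = bandpass_fir(data.shape[1], target_fs, lo, hi)
    data = signal.filtfilt(taps, [1.0], data, axis=1)
    return ContinuousRecording(data=data, fs=target_fs, channels=list(rec.channels))


def derive_eog(rec: ContinuousRecording) -> tuple[np.ndarray, np.ndarray]:
    """hEOG = AF8 - AF7; vEOG = Fpz - AFz."""
    needed = ("AF7", "AF8", "AFz", "Fpz")
    missing = [ch for ch in needed if ch not in rec.channels]
    if missing:
        raise ValueError(f"EOG derivation needs channels {needed}, missing {missing}")
    idx = {ch: rec.channels.index(ch) for ch in needed}
    heog = rec.data[idx["AF8"]] - rec.data[idx["AF7"]]
    veog = rec.data[idx["Fpz"]] - rec.data[idx["AFz"]]
    return heog, veog


def extract_epochs(
    rec: ContinuousRecording,
    onsets: np.ndarray,
    metadata: pd.DataFrame | None = None,
    window: tuple[float, float] = (-1.0, 2.0),
) -> EpochArray:
    """Cut epochs time-locked to movement onsets (seconds into the recording)."""
    times = default_times(rec.fs, window)
    rel = np.round(times * rec.fs).astype(int)
    keep, slabs = [], []
    for i, onset in enumerate(np.asarray(onsets, dtype=float)):
        center = int(round(onset * rec.fs))
        lo_i, hi_i = center + rel[0], center + rel[-1]
        if lo_i < 0 or hi_i >= rec.n_samples:
            continue
        keep.append(i)
        slabs.append(rec.data[:, lo_i : hi_i + 1])
    data = np.stack(slabs) if slabs else np.empty((0, len(rec.channels), times.size))
    if metadata is not None:
        meta = metadata.iloc[keep].reset_index(drop=True)
    else:
        meta = pd.DataFrame(index=range(len(keep)))
    return EpochArray(data=data, times=times, channels=list(rec.channels), metadata=meta)


# -- epoch-domain steps ------------------------------------------------------

def rereference_common_average(epochs: EpochArray,
                               scalp_channels: list[str] | None = None) -> EpochArray:
    """Subtract the mean over scalp channels at every (trial, sample)."""
    out = epochs.copy()
    if scalp_channels is None:
        idx = np.arange(len(epochs.channels))
    else:
        idx = np.array([epochs.channel_index(c) for c in scalp_channels])
    mean = out.data[:, idx, :].mean(axis=1, keepdims=True)
    out.data = out.data - mean
    return out


def baseline_correct(epochs: EpochArray,
                     window: tuple[float, float] = BASELINE_WINDOW) -> EpochArray:
    """Subtract one scalar per participant and channel: the mean over the
    baseline window across ALL of that participant's retained trials."""
    mask = epochs.time_mask(window[0], window[1])
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    out = epochs.copy()
    if "participant" in epochs.metadata.columns:
        groups = epochs.metadata["participant"].astype(str).to_numpy()
    else:
        groups = np.repeat("all", epochs.n_trials)
    for p in np.unique(groups):
        rows = np.flatnonzero(groups == p)
        # (channels,) scalar per channel, pooled over this participant's trials
        scalars = out.data[np.ix_(rows)][:, :, mask].mean(axis=(0, 2))
        out.data[rows] -= scalars[None, :, None]
    return out


def trim_amplitude_percentiles(epochs: EpochArray, tail: float = 0.01) -> tuple[EpochArray, dict]:
    """Drop, per participant, the ceil(n*tail) trials with the lowest and the
    highest maximum absolute amplitude (ties broken by trial index)."""
    if "participant" in epochs.metadata.columns:
        groups = epochs.metadata["participant"].astype(str).to_numpy()
    else:
        groups = np.repeat("all", epochs.n_trials)
    metric = np.max(np.abs(epochs.data), axis=(1, 2))
    keep_mask = np.ones(epochs.n_trials, dtype=bool)
    dropped: dict[str, int] = {}
    for p in np.unique(groups):
        rows = np.flatnonzero(groups == p)
        n = rows.size
        k = math.ceil(n * tail)
        if n < 3 or 2 * k >= n:
            dropped[str(p)] = 0
            continue
        order = np.argsort(metric[rows], kind="stable")
        drop = np.concatenate([order[:k], order[-k:]])
        keep_mask[rows[drop]] = False
        dropped[str(p)] = int(drop.size)
    return epochs.select_trials(keep_mask), dropped


def reject_artifact_epochs(
    epochs: EpochArray,
    ptp_threshold: float = PTP_THRESHOLD_UV,
    eog: np.ndarray | None = None,
    eog_threshold: float = EOG_THRESHOLD_UV,
) -> tuple[EpochArray, dict]:
    """Surrogate for ICA/ADJUST artifact handling (documented deviation):
    drop epochs whose peak-to-peak exceeds ``ptp_threshold`` or whose EOG
    magnitude exceeds ``eog_threshold``."""
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)
    bad = (ptp > ptp_threshold).any(axis=1)
    n_eog = 0
    if eog is not None:
        eog = np.atleast_2d(np.asarray(eog))
        bad_eog = (np.abs(eog) > eog_threshold).any(axis=tuple(range(1, eog.ndim)))
        n_eog = int((bad_eog & ~bad).sum())
        bad = bad | bad_eog
    report = {
        "rule": "amplitude-surrogate (ICA/ADJUST out of scope)",
        "n_ptp": int((ptp > ptp_threshold).any(axis=1).sum()),
        "n_eog": n_eog,
        "n_dropped": int(bad.sum()),
    }
    return epochs.select_trials(~bad), report


def exclude_participants_by_variance(
    epochs_by_participant: dict[str, EpochArray],
    n_sd: float = 2.0,
    max_bad_channels: int = 10,
) -> list[str]:
    """Exclude participants with MORE THAN ``max_bad_channels`` channels whose
    variance exceeds the across-participant pool mean by ``n_sd`` pooled SDs."""
    pids = list(epochs_by_participant)
    if len(pids) < 2:
        return []
    first = next(iter(epochs_by_participant.values()))
    n_ch = len(first.channels)
    variances = np.empty((len(pids), n_ch))
    for i, pid in enumerate(pids):
        ep = epochs_by_participant[pid]
        variances[i] = ep.data.transpose(1, 0, 2).reshape(n_ch, -1).var(axis=1)
    mean = variances.mean(axis=0)
    sd = variances.std(axis=0, ddof=1)
    threshold = mean + n_sd * sd
    bad_counts = (variances > threshold[None, :]).sum(axis=1)
    return [pid for pid, c in zip(pids, bad_counts) if c > max_bad_channels]


# -- orchestration -----------------------------------------------------------

@dataclass
class RetentionLog:
    participant: str
    n_input: int
    n_artifact: int = 0
    n_trimmed: int = 0
    n_retained: int = 0
    notes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "participant": self.participant,
            "n_input": self.n_input,
            "n_artifact": self.n_artifact,
            "n_trimmed": self.n_trimmed,
            "n_retained": self.n_retained,
            "notes": self.notes,
        }

    def check(self) -> None:
        if self.n_input != self.n_retained + self.n_artifact + self.n_trimmed:
            raise AssertionError("retention accounting does not balance")


def preprocess_epochs(
    epochs: EpochArray,
    scalp_channels: list[str] | None = None,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    ptp_threshold: float = PTP_THRESHOLD_UV,
    eog: np.ndarray | None = None,
    trim_tail: float = 0.01,
) -> tuple[EpochArray, list[dict]]:
    """Epoch-domain part of the canonical pipeline (reref -> artifact ->
    baseline -> trim) with per-participant retention accounting."""
    if "participant" in epochs.metadata.columns:
        input_counts = epochs.metadata.groupby("participant").size().to_dict()
    else:
        input_counts = {"all": epochs.n_trials}

    out = rereference_common_average(epochs, scalp_channels)
    out, art_report = reject_artifact_epochs(out, ptp_threshold, eog=eog)
    out = baseline_correct(out, baseline_window)
    out, trimmed = trim_amplitude_percentiles(out, trim_tail)

    logs = []
    if "participant" in out.metadata.columns:
        retained_counts = out.metadata.groupby("participant").size().to_dict()
    else:
        retained_counts = {"all": out.n_trials}
    for pid, n_in in input_counts.items():
        n_ret = int(retained_counts.get(pid, 0))
        n_trim = int(trimmed.get(str(pid), 0))
        log = RetentionLog(
            participant=str(pid),
            n_input=int(n_in),
            n_artifact=int(n_in) - n_ret - n_trim,
            n_trimmed=n_trim,
            n_retained=n_ret,
            notes=[art_report["rule"]],
        )
        try:
            log.check()
        except AssertionError:
            warnings.warn(f"retention accounting mismatch for {pid}")
        logs.append(log.as_dict())
    return out, logs
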