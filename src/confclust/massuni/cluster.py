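"""Step 2: cluster-level regressions with nested random effects, contiguity
filtering (> 50 ms), peak-window effect amplitudes and confidence tertiles."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..epochs import EpochArray
from .design import CLUSTER_FORMULA_BY_TERM, build_design, participant_codes
from .fastlmm import reml_scan
from .fdr import benjamini_hochberg

CLUSTER_WINDOW = (-0.2, 0.75)   # step-2 scan window (may start pre-onset)
MIN_CLUSTER_SECONDS = 0.050     # strictly greater than 50 ms
PEAK_HALF_WINDOW = 0.025        # 50 ms window centered on the peak


@dataclass
class ClusterResult:
    """A spatio-temporal cluster of a genuine effect."""

    term: str
    electrodes: list[str]
    t_start: float
    t_end: float
    peak_time: float
    peak_stat: float
    n_samples: int
    amplitude: float | None = None
    amplitude_sd: float | None = None

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def as_dict(self) -> dict:
        return {
            "term": self.term, "electrodes": ",".join(self.electrodes),
            "t_start": self.t_start, "t_end": self.t_end,
            "peak_time": self.peak_time, "peak_stat": self.peak_stat,
            "n_samples": self.n_samples, "amplitude": self.amplitude,
            "amplitude_sd": self.amplitude_sd,
        }


@dataclass
class ClusterScan:
    term: str
    electrodes: list[str]
    times: np.ndarray
    coef: np.ndarray
    tstat: np.ndarray
    pval: np.ndarray
    qval: np.ndarray
    reject: np.ndarray
    clusters: list[ClusterResult] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.term, "time": self.times, "coef": self.coef,
            "tstat": self.tstat, "p": self.pval, "q": self.qval,
            "significant": self.reject,
        })


def significant_runs(reject: np.ndarray, times: np.ndarray, fs: float,
                     min_seconds: float = MIN_CLUSTER_SECONDS) -> list[tuple[int, int]]:
    """Maximal runs of significant adjacent samples strictly longer than 50 ms.

    A run of k samples at rate fs counts as k/fs seconds (7 samples at 128 Hz
    = 54.7 ms qualifies; 6 samples = 46.9 ms does not).
    """
    runs = []
    in_run = False
    start = 0
    for i, flag in enumerate(np.asarray(reject, dtype=bool)):
        if flag and not in_run:
            in_run, start = True, i
        elif not flag and in_run:
            runs.append((start, i - 1))
            in_run = False
    if in_run:
        runs.append((start, len(reject) - 1))
    return [(a, b) for a, b in runs if (b - a + 1) / fs > min_seconds]


def extract_clusters(
    reject: np.ndarray,
    tstat: np.ndarray,
    times: np.ndarray,
    fs: float,
    term: str,
    electrodes: list[str],
    min_seconds: float = MIN_CLUSTER_SECONDS,
) -> list[ClusterResult]:
    """Turn a per-sample significance mask into contiguity-filtered clusters."""
    out = []
    for a, b in significant_runs(reject, times, fs, min_seconds):
        seg = np.abs(tstat[a : b + 1])
        peak = a + int(np.argmax(seg))
        out.append(
            ClusterResult(
                term=term, electrodes=list(electrodes),
                t_start=float(times[a]), t_end=float(times[b]),
                peak_time=float(times[peak]), peak_stat=float(tstat[peak]),
                n_samples=int(b - a + 1),
            )
        )
    return out


def cluster_regression(
    epochs: EpochArray,
    term: str,
    electrodes: list[str],
    window: tuple[float, float] = CLUSTER_WINDOW,
    alpha: float = 0.05,
    formula: str | None = None,
    min_seconds: float = MIN_CLUSTER_SECONDS,
) -> ClusterScan:
    """Per-sample regression over the selected electrodes with participant and
    electrode-within-participant random intercepts; FDR over samples."""
    if not electrodes:
        return ClusterScan(term=term, electrodes=[], times=np.array([]),
                           coef=np.array([]), tstat=np.array([]),
                           pval=np.array([]), qval=np.array([]),
                           reject=np.array([], dtype=bool))
    if formula is None:
        formula = CLUSTER_FORMULA_BY_TERM[term]

    tmask = epochs.time_mask(*window)
    times = epochs.times[tmask]
    e_idx = [epochs.channel_index(ch) for ch in electrodes]
    E = len(e_idx)
    n_tr = epochs.n_trials
    # rows = trial x electrode (electrode fastest), columns = samples
    Y = epochs.data[np.ix_(np.arange(n_tr), e_idx, np.flatnonzero(tmask))]
    Y = Y.transpose(0, 1, 2).reshape(n_tr * E, times.size)

    X_trial, names = build_design(epochs.metadata, formula)
    X = np.repeat(X_trial, E, axis=0)
    part = participant_codes(epochs.metadata)
    part_rows = np.repeat(part, E)
    pe_rows = part_rows * E + np.tile(np.arange(E), n_tr)
    # recode participant/electrode levels densely
    pe_rows = pd.factorize(pe_rows)[0]

    factors = [part_rows, pe_rows] if E > 1 else [part_rows]
    fit = reml_scan(X, Y, factors, names)
    ti = fit.term_index(term)
    coef, tstat, pval = fit.beta[ti], fit.tstat[ti], fit.pval[ti]
    reject, qval = benjamini_hochberg(pval, alpha)
    fs = epochs.fs
    clusters = extract_clusters(reject, tstat, times, fs, term, electrodes,
                                min_seconds)
    return ClusterScan(term=term, electrodes=list(electrodes), times=times,
                       coef=coef, tstat=tstat, pval=pval, qval=qval,
                       reject=reject, clusters=clusters)


# -- effect amplitude and tertiles ------------------------------------------

def assign_tertiles(values) -> np.ndarray:
    """Labels {low, mid, high} with empirical tertile boundaries; ties go to
    the lower bin.  Boundary convention: the low and mid bins take floor(n/3)
    order statistics each, the high bin the remainder."""
    v = np.asarray(values, dtype=float)
    n = v.size
    labels = np.full(n, "low", dtype=object)
    if n < 3:
        return labels
    k = n // 3
    srt = np.sort(v, kind="stable")
    t1, t2 = srt[k - 1], srt[2 * k - 1]
    labels[(v > t1) & (v <= t2)] = "mid"
    labels[v > t2] = "high"
    return labels


def effect_amplitude(
    epochs: EpochArray,
    cluster: ClusterResult,
    contrast: str = "correctness",
) -> tuple[float, float, pd.Series]:
    """Mean condition difference over the cluster electrodes and the 50 ms
    peak-centered window (symmetric truncation at epoch edges).

    correctness: correct minus incorrect trials.  confidence: top minus bottom
    per-participant confidence tertile.  movementRT: fastest minus slowest
    onset tertile.  Returns (mean across participants, sd, per-participant).
    """
    half = min(PEAK_HALF_WINDOW,
               cluster.peak_time - epochs.times[0],
               epochs.times[-1] - cluster.peak_time)
    tmask = epochs.time_mask(cluster.peak_time - half, cluster.peak_time + half)
    e_idx = [epochs.channel_index(ch) for ch in cluster.electrodes]
    window_mean = epochs.data[np.ix_(np.arange(epochs.n_trials), e_idx,
                                     np.flatnonzero(tmask))].mean(axis=(1, 2))
    meta = epochs.metadata
    per_participant = {}
    for pid, rows in meta.groupby("participant").groups.items():
        idx = meta.index.get_indexer(rows)
        sub = meta.iloc[idx]
        vals = window_mean[idx]
        if contrast == "correctness":
            a = vals[sub["correct"].to_numpy() == 1]
            b = vals[sub["correct"].to_numpy() == 0]
        elif contrast in ("confidence", "movementRT"):
            col = "confidence" if contrast == "confidence" else "onset"
            tert = assign_tertiles(sub[col].to_numpy())
            hi, lo = ("high", "low")
            if contrast == "movementRT":
                hi, lo = ("low", "high")  # faster onsets vs slowest
            a, b = vals[tert == hi], vals[tert == lo]
        else:
            raise ValueError(f"unknown contrast {contrast!r}")
        if a.size and b.size:
            per_participant[pid] = float(a.mean() - b.mean())
    series = pd.Series(per_participant, name="effect")
    return float(series.mean()), float(series.std(ddof=1)), series
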