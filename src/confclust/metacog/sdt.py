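"""Signal-detection primitives: rating counts and type-1 sensitivity."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm


@dataclass
class SDTCounts:
    """Per-participant counts of stimulus x response x confidence bin.

    Shapes are (2 stimulus, 2 response, k bins); axis order is
    (stimulus in {left, right}, response in {left, right}, bin 0..k-1 from
    least to most confident).
    """

    counts: np.ndarray
    n_bins: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (2, 2, self.n_bins):
            raise ValueError("counts must be 2 x 2 x n_bins")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def correct_by_bin(self) -> np.ndarray:
        """Confidence-bin counts pooled over correct trials (response-collapsed)."""
        return self.counts[0, 0] + self.counts[1, 1]

    def incorrect_by_bin(self) -> np.ndarray:
        return self.counts[0, 1] + self.counts[1, 0]

    def hit_false_alarm(self) -> tuple[float, float, float, float]:
        """(hits, signal trials, false alarms, noise trials) treating 'right'
        as the signal response."""
        signal = self.counts[1].sum()
        noise = self.counts[0].sum()
        hits = self.counts[1, 1].sum()
        fas = self.counts[0, 1].sum()
        return hits, signal, fas, noise


def bin_confidence(confidence: np.ndarray, n_bins: int = 4) -> np.ndarray:
    """Equal-quantile confidence bins (0..n_bins-1) within a participant."""
    conf = np.asarray(confidence, dtype=float)
    if conf.size == 0:
        return np.array([], dtype=int)
    qs = np.quantile(conf, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(qs, conf, side="left").astype(int)


def counts_from_trials(trials: pd.DataFrame, n_bins: int = 4,
                       exclude_low_confidence: bool = True) -> SDTCounts:
    """Build rating counts for one participant's trial table.

    Trials with confidence < 50 are excluded first (mirroring the
    post-response change-of-mind exclusion), so bins span the [50, 100] range.
    """
    t = trials
    if exclude_low_confidence:
        t = t[t["confidence"] >= 50.0]
    stim = (t["stimulus"].to_numpy() > 0).astype(int)
    resp = (t["response"].to_numpy() > 0).astype(int)
    bins = bin_confidence(t["confidence"].to_numpy(), n_bins)
    counts = np.zeros((2, 2, n_bins))
    np.add.at(counts, (stim, resp, bins), 1.0)
    return SDTCounts(counts=counts, n_bins=n_bins)


def corrected_rate(count: float, n: float) -> float:
    """Rate with the 1/(2N) correction applied to extreme values only."""
    if n <= 0:
        raise ValueError("no trials for rate computation")
    rate = count / n
    if rate == 0.0:
        return 1.0 / (2.0 * n)
    if rate == 1.0:
        return 1.0 - 1.0 / (2.0 * n)
    return rate


def compute_dprime(counts: SDTCounts) -> tuple[float, float]:
    """Type-1 d' and criterion c from hit / false-alarm rates.

    d' = z(hit) - z(fa); c = -(z(hit) + z(fa)) / 2, with extreme rates pulled
    in by 1/(2N).
    """
    hits, n_sig, fas, n_noise = counts.hit_false_alarm()
    hr = corrected_rate(hits, n_sig)
    far = corrected_rate(fas, n_noise)
    zh, zf = norm.ppf(hr), norm.ppf(far)
    return float(zh - zf), float(-(zh + zf) / 2.0)
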