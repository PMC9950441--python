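"""Parameter specifications for the synthetic cohort generator."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GROUP_LABELS = ("control", "ssd")


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort layout: group a = control, group b = ssd."""

    n_group_a: int = 19
    n_group_b: int = 14
    trials_per_participant: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a < 1 or self.n_group_b < 1:
            raise ValueError("group sizes must be >= 1")
        if self.trials_per_participant < 0:
            raise ValueError("trials_per_participant must be >= 0")

    @property
    def n_total(self) -> int:
        return self.n_group_a + self.n_group_b

    def participant_ids(self) -> list[str]:
        a = [f"c{i:02d}" for i in range(self.n_group_a)]
        b = [f"s{i:02d}" for i in range(self.n_group_b)]
        return a + b

    def group_of(self, pid: str) -> str:
        return "control" if pid.startswith("c") else "ssd"


@dataclass(frozen=True)
class ObserverSpec:
    """Generative observer: psychometric sensitivity plus confidence read-out.

    ``confidence_rt_coupling`` is the slope (on the 0-1 confidence scale) per
    standardized movement onset; it is typically negative (earlier movements,
    higher confidence) and can be set weaker for one group.
    """

    slope: float = 2.2                 # sensitivity d' per unit coherence
    lapse: float = 0.02
    confidence_noise_sd: float = 12.0  # on the 0-100 scale
    confidence_rt_coupling: float = -0.04
    mean_onset: float = 1.3            # seconds
    onset_sd: float = 0.65             # seconds
    confidence_gain: float = 28.0      # 0-100 points per unit |evidence|
    confidence_bias: float = 52.0      # 0-100 baseline confidence

    def __post_init__(self) -> None:
        if not (0.0 <= self.lapse <= 0.1):
            raise ValueError("lapse must lie in [0, 0.1]")
        if self.confidence_noise_sd < 0:
            raise ValueError("confidence noise sd must be >= 0")
        if self.mean_onset <= 0 or self.onset_sd < 0:
            raise ValueError("onset parameters must be positive")

    def p_correct(self, coherence: float | np.ndarray) -> np.ndarray:
        """Accuracy as a function of motion coherence (0.5 at zero evidence)."""
        from scipy.stats import norm

        c = np.asarray(coherence, dtype=float)
        base = norm.cdf(self.slope * c)          # in [0.5, 1) for c >= 0
        return self.lapse * 0.5 + (1.0 - self.lapse) * base


@dataclass(frozen=True)
class ErpComponentSpec:
    """One ERP component: topography x Gaussian temporal kernel x modulator."""

    name: str
    topography: dict[str, float]        # channel -> spatial weight
    peak_latency: float                 # seconds relative to movement onset
    width: float                        # Gaussian kernel sd, seconds
    modulator: str = "constant"         # correctness | confidence | movementRT | constant
    gain: float = 1.0                   # microvolts per modulator unit

    _MODULATORS = ("correctness", "confidence", "movementRT", "constant")

    def __post_init__(self) -> None:
        if self.modulator not in self._MODULATORS:
            raise ValueError(f"unknown modulator {self.modulator!r}")
        if not np.isfinite(self.gain):
            raise ValueError("gain must be finite")
        if self.width <= 0:
            raise ValueError("kernel width must be positive")

    def normalized_topography(self, channels: list[str]) -> np.ndarray:
        w = np.array([self.topography.get(ch, 0.0) for ch in channels], dtype=float)
        peak = np.max(np.abs(w))
        if peak > 0:
            w = w / peak  # unit peak so gain is in microvolts at the peak channel
        return w

    def kernel(self, times: np.ndarray) -> np.ndarray:
        return np.exp(-0.5 * ((times - self.peak_latency) / self.width) ** 2)


@dataclass(frozen=True)
class ErpTemplateSpec:
    components: tuple[ErpComponentSpec, ...] = ()

    def check_support(self, times: np.ndarray) -> None:
        for comp in self.components:
            if not (times[0] <= comp.peak_latency <= times[-1]):
                raise ValueError(
                    f"component {comp.name!r} peaks at {comp.peak_latency}s, "
                    f"outside the epoch window [{times[0]}, {times[-1]}]s"
                )


@dataclass(frozen=True)
class NoiseSpec:
    pink_sd: float = 2.0        # microvolts, 1/f-shaped
    white_sd: float = 1.5       # microvolts
    intercept_sd: float = 1.0   # per-participant offset sd, microvolts
    artifact_rate: float = 0.0  # probability of a high-amplitude artifact trial
    artifact_amplitude: float = 250.0
    bad_channel_count: int = 0
    bad_channel_sd: float = 40.0

    def __post_init__(self) -> None:
        for name in ("pink_sd", "white_sd", "intercept_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.artifact_rate <= 1.0):
            raise ValueError("artifact_rate must be a probability")


def study_templates(channels: list[str], car_neutral: bool = True) -> ErpTemplateSpec:
    """Default study-calibrated components (peaks at 266/102/133 ms).

    Gains are chosen so the generated contrasts land near the magnitudes the
    analysis is expected to recover (correct-incorrect = -0.34 uV at the Cz
    peak, positive confidence and movement-onset modulations fronto-centrally).

    With ``car_neutral`` the topography is made zero-mean over the montage
    (counterweights spread over the remaining channels) and rescaled to keep a
    unit weight at the peak channel, so the common-average reference leaves
    the calibrated peak amplitude untouched.
    """

    from ..montage import frontocentral_roi

    roi = set(frontocentral_roi(tuple(channels)))

    def topo(center: dict[str, float]) -> dict[str, float]:
        w = {ch: float(v) for ch, v in center.items() if ch in channels}
        if not car_neutral or not w:
            return w
        # balance the field on distant (off-ROI) channels so the common
        # average reference does not shift the calibrated peak amplitude;
        # needs enough sink channels to keep |sink| below the source peak
        sinks = [ch for ch in channels if ch not in w and ch not in roi]
        if not sinks:
            return w
        sink_weight = -sum(w.values()) / len(sinks)
        full = dict(w)
        full.update({ch: sink_weight for ch in sinks})
        return full

    central = {"Cz": 1.0, "C1": 0.95, "C2": 0.95}
    frontocentral = {
        "FCz": 1.0, "FC1": 0.9, "FC2": 0.9, "Fz": 0.8, "F1": 0.7, "F2": 0.7,
        "Cz": 0.75, "C1": 0.6, "C2": 0.6, "F3": 0.45, "FC3": 0.5,
    }
    comps = (
        ErpComponentSpec(
            name="correctness_central",
            topography=topo(central),
            peak_latency=0.266, width=0.055,
            modulator="correctness", gain=-0.34,
        ),
        ErpComponentSpec(
            name="confidence_frontocentral",
            topography=topo(frontocentral),
            peak_latency=0.102, width=0.05,
            modulator="confidence", gain=0.8,
        ),
        ErpComponentSpec(
            name="onset_frontocentral",
            topography=topo(frontocentral),
            peak_latency=0.133, width=0.06,
            modulator="movementRT", gain=0.4,
        ),
    )
    return ErpTemplateSpec(components=comps)
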