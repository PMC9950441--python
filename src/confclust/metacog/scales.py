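"""Clinical-scale arithmetic: the cognitive-insight composite."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BcisScores:
    """Beck Cognitive Insight Scale subscale scores (points)."""

    self_reflectiveness: float
    self_certainty: float

    @property
    def composite(self) -> float:
        return bcis_composite(self.self_reflectiveness, self.self_certainty)


def bcis_composite(self_reflectiveness: float, self_certainty: float) -> float:
    """Composite cognitive-insight index: self-reflectiveness minus
    self-certainty.  Exact arithmetic, no tolerance."""
    return self_reflectiveness - self_certainty
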