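"""Channel naming for the 64-electrode 10-10 montage and scalp regions of interest.

Only channel *names* are needed by the pipeline (no topographic rendering), so
the montage is a plain ordered list.  The region-of-interest helper returns the
central / fronto-central rows used for cluster analyses.
"""

from __future__ import annotations

# 64 labels of the extended international 10-10 system (g.tec HIamp-style cap).
CHANNELS_64: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
    "Iz", "FT9", "FT10",
)

assert len(CHANNELS_64) == 64
assert len(set(CHANNELS_64)) == 64

# Channels used to derive EOG signals (bipolar subtractions).
EOG_SOURCE_CHANNELS: tuple[str, ...] = ("AF7", "AF8", "AFz", "Fpz")

# Central and fronto-central rows (frontal row included: F* electrodes can
# respond to confidence and are part of the scalp region of interest).
_ROI_ROWS = ("F", "FC", "C")
_ROI_EXCLUDE = {"FT7", "FT8", "FT9", "FT10", "T7", "T8", "Fp1", "Fpz", "Fp2"}


def frontocentral_roi(channels: tuple[str, ...] | list[str] = CHANNELS_64) -> list[str]:
    """Return the central / fronto-central subset of *channels*, montage order."""
    roi = []
    for ch in channels:
        if ch in _ROI_EXCLUDE:
            continue
        row = ch.rstrip("0123456789z")
        # strip the trailing hemisphere digit or 'z'; e.g. FC1 -> FC, Cz -> C
        base = ch[: len(row)] if row else ch
        if base in _ROI_ROWS:
            roi.append(ch)
    return roi


def validate_channels(channels: list[str]) -> None:
    """Reject duplicate or empty channel name lists."""
    if not channels:
        raise ValueError("channel list is empty")
    if len(set(channels)) != len(channels):
        raise ValueError("duplicate channel names in montage")
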