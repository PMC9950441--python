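"""Synthetic EEG epoch generation: linear ERP templates + 1/f and white noise."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .. import montage as montage_mod
from ..epochs import EpochArray, default_times
from .specs import ErpTemplateSpec, NoiseSpec


def pink_noise(rng: np.random.Generator, shape: tuple[int, ...], fs: float,
               sd: float) -> np.ndarray:
    """1/f-shaped noise along the last axis, scaled to the requested sd."""
    if sd == 0:
        return np.zeros(shape)
    n = shape[-1]
    white = rng.standard_normal(shape)
    spectrum = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    shaped = np.fft.irfft(spectrum * shaping, n=n, axis=-1)
    scale = shaped.std(axis=-1, keepdims=True)
    scale[scale == 0] = 1.0
    return sd * shaped / scale


def modulator_values(trials: pd.DataFrame, modulator: str) -> np.ndarray:
    """Per-trial modulator on the scale used by the generative model.

    confidence enters on the 0-1 scale (single conversion site from the 0-100
    rating scale); movementRT is the per-participant standardized onset.
    """
    if modulator == "constant":
        return np.ones(len(trials))
    if modulator == "correctness":
        return trials["correct"].to_numpy(dtype=float)
    if modulator == "confidence":
        return trials["confidence"].to_numpy(dtype=float) / 100.0
    if modulator == "movementRT":
        z = trials.groupby("participant")["onset"].transform(
            lambda s: (s - s.mean()) / max(s.std(ddof=0), 1e-12)
        )
        return z.to_numpy(dtype=float)
    raise ValueError(f"unknown modulator {modulator!r}")


def simulate_epochs(
    trials: pd.DataFrame,
    templates: ErpTemplateSpec,
    noise: NoiseSpec,
    channels: list[str],
    fs: float = 128.0,
    window: tuple[float, float] = (-1.0, 2.0),
    rng: np.random.Generator | None = None,
) -> EpochArray:
    """Generate epochs for every row of ``trials``.

    Expected value at (trial, channel, time) is the participant intercept plus
    the sum over components of gain * modulator * topography * kernel.
    """
    montage_mod.validate_channels(channels)
    for comp in templates.components:
        unknown = set(comp.topography) - set(channels)
        if unknown:
            raise ValueError(
                f"component {comp.name!r} references channels missing from the "
                f"montage: {sorted(unknown)}"
            )
    if rng is None:
        rng = np.random.default_rng()

    times = default_times(fs, window)
    templates.check_support(times)
    trials = trials.reset_index(drop=True)
    n_tr, n_ch, n_t = len(trials), len(channels), times.size
    data = np.zeros((n_tr, n_ch, n_t))

    # deterministic per-participant structure: intercept and bad channels
    participants = trials["participant"].astype(str)
    unique_p = list(dict.fromkeys(participants))
    intercepts = {p: rng.normal(0.0, noise.intercept_sd) for p in unique_p}
    bad_channels: dict[str, np.ndarray] = {}
    for p in unique_p:
        if noise.bad_channel_count > 0:
            bad_channels[p] = rng.choice(n_ch, size=min(noise.bad_channel_count, n_ch),
                                         replace=False)
        else:
            bad_channels[p] = np.array([], dtype=int)

    p_index = participants.map({p: i for i, p in enumerate(unique_p)}).to_numpy()
    data += np.array([intercepts[p] for p in unique_p])[p_index][:, None, None]

    for comp in templates.components:
        topo = comp.normalized_topography(channels)
        kern = comp.kernel(times)
        mod = modulator_values(trials, comp.modulator)
        data += comp.gain * mod[:, None, None] * topo[None, :, None] * kern[None, None, :]

    if noise.pink_sd > 0:
        data += pink_noise(rng, (n_tr, n_ch, n_t), fs, noise.pink_sd)
    if noise.white_sd > 0:
        data += rng.normal(0.0, noise.white_sd, size=(n_tr, n_ch, n_t))

    for p, chans in bad_channels.items():
        if chans.size:
            mask = (participants == p).to_numpy()
            data[np.ix_(np.flatnonzero(mask), chans)] += rng.normal(
                0.0, noise.bad_channel_sd, size=(int(mask.sum()), chans.size, n_t)
            )

    if noise.artifact_rate > 0:
        hit = rng.random(n_tr) < noise.artifact_rate
        for i in np.flatnonzero(hit):
            center = rng.integers(0, n_t)
            width = max(int(0.1 * fs), 2)
            kern = np.exp(-0.5 * ((np.arange(n_t) - center) / width) ** 2)
            data[i] += noise.artifact_amplitude * kern[None, :]

    meta = trials.copy()
    meta["z_confidence"] = meta.groupby("participant")["confidence"].transform(
        lambda s: (s - s.mean()) / max(s.std(ddof=0), 1e-12)
    )
    meta["z_onset"] = meta.groupby("participant")["onset"].transform(
        lambda s: (s - s.mean()) / max(s.std(ddof=0), 1e-12)
    )
    return EpochArray(data=data, times=times, channels=list(channels), metadata=meta)
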