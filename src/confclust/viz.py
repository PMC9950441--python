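"""Quick-look plots (optional; requires matplotlib).

Publication-grade topographies are out of scope — these are diagnostic ERP
trace plots by condition or tertile, averaged over a set of electrodes.
"""

from __future__ import annotations

import numpy as np

from .epochs import EpochArray
from .massuni import assign_tertiles


def _require_matplotlib():
    try:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("quick-look plots need matplotlib "
                          "(pip install confclust[plots])") from exc
    return plt


def plot_erp_by_tertile(
    epochs: EpochArray,
    electrodes: list[str],
    by: str = "confidence",
    ax=None,
):
    """Grand-average ERP traces split by per-participant tertiles of ``by``
    (confidence or onset), or by correctness when ``by='correct'``."""
    plt = _require_matplotlib()
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    e_idx = [epochs.channel_index(ch) for ch in electrodes]
    traces = epochs.data[:, e_idx, :].mean(axis=1)
    meta = epochs.metadata

    if by == "correct":
        groups = {"incorrect": meta["correct"].to_numpy() == 0,
                  "correct": meta["correct"].to_numpy() == 1}
    else:
        labels = np.concatenate([
            assign_tertiles(sub[by].to_numpy())
            for _, sub in meta.groupby("participant", sort=False)
        ])
        order = np.concatenate([
            meta.index.get_indexer(sub.index)
            for _, sub in meta.groupby("participant", sort=False)
        ])
        full = np.empty(len(meta), dtype=object)
        full[order] = labels
        groups = {name: full == name for name in ("low", "mid", "high")}

    for name, mask in groups.items():
        if mask.sum() == 0:
            continue
        ax.plot(epochs.times, traces[mask].mean(axis=0), label=name)
    ax.axvline(0.0, color="k", lw=0.5)
    ax.axvspan(-0.7, -0.2, color="0.9", zorder=0)  # baseline window
    ax.set_xlabel("time from movement onset (s)")
    ax.set_ylabel("amplitude (uV)")
    ax.set_title(f"{'+'.join(electrodes)} by {by}")
    ax.legend()
    return ax
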