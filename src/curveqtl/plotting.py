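"""Basic figures: genome-scan curves, per-QTL profiles, effect curves."""

from __future__ import annotations

import numpy as np


def _chrom_offsets(scan, gap=10.0):
    offsets, x0 = {}, 0.0
    for ci in range(len(scan.chrom_names)):
        sel = scan.grid_chrom == ci
        offsets[ci] = x0 - scan.grid_pos[sel].min()
        x0 = offsets[ci] + scan.grid_pos[sel].max() + gap
    return offsets


def plot_scan(scan, methods=None, thresholds=None, ax=None):
    """LOD-type curves along the genome, one panel, chromosomes concatenated."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3.2))
    methods = methods or [m for m in ("sl", "ml", "hklod", "slod", "mlod") if getattr(scan, m) is not None]
    offsets = _chrom_offsets(scan)
    for m in methods:
        y = scan.statistic(m)
        for ci in range(len(scan.chrom_names)):
            sel = scan.grid_chrom == ci
            x = scan.grid_pos[sel] + offsets[ci]
            ax.plot(x, y[sel], color=f"C{methods.index(m)}", label=m.upper() if ci == 0 else None)
    if thresholds:
        for m, t in thresholds.items():
            if m in methods:
                ax.axhline(t, color=f"C{methods.index(m)}", ls=":", lw=0.8)
    for ci, name in enumerate(scan.chrom_names):
        sel = scan.grid_chrom == ci
        ax.text(np.median(scan.grid_pos[sel]) + offsets[ci], -0.04, name, ha="center", va="top",
                transform=ax.get_xaxis_transform())
    ax.set_xticks([])
    ax.set_ylabel("LOD")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_profiles(profiles, ax=None):
    """Per-QTL profile LOD curves over their chromosomes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3.2))
    x0 = 0.0
    for k in range(len(profiles.qtl)):
        pos, curve = profiles.pos_cM[k], np.maximum(profiles.curves[k], 0.0)
        ax.plot(pos + x0 - pos.min(), curve, label=f"{profiles.chrom[k]}@{profiles.qtl[k][1]:g}")
        x0 += pos.max() - pos.min() + 10.0
    ax.set_xticks([])
    ax.set_ylabel("profile LOD")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_effects(effects, times=None, ax=None):
    """Baseline curve and per-QTL high-minus-low allele effect curves."""
    import matplotlib.pyplot as plt

    t = effects.times if effects.times is not None else times
    if ax is None:
        _, axes = plt.subplots(1, 2, figsize=(9, 3.2))
    else:
        axes = ax
    axes[0].plot(t, effects.baseline, "k-")
    axes[0].set_title("baseline curve")
    for k, (ch, p) in enumerate(effects.qtl):
        axes[1].plot(t, effects.effects[k], label=f"{ch}@{p:g}")
    axes[1].axhline(0, color="grey", lw=0.6)
    axes[1].set_title("QTL effects (high - low allele)")
    axes[1].legend(frameon=False, fontsize=8)
    return axes
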