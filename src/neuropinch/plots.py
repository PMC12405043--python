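"""Summary figures: pooled coherence grids and cluster overlays."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .coherence import BANDS, PooledCoherence

__all__ = ["plot_pooled_coherence", "plot_clusters"]

_BAND_SHADE = {"alpha": 0.08, "beta": 0.14, "gamma": 0.20}


def _shade_bands(ax):
    for name, (lo, hi) in BANDS.items():
        ax.axvspan(lo, hi, color="0.5", alpha=_BAND_SHADE[name], lw=0)


def plot_pooled_coherence(pooled_by_key: dict[tuple[str, float], PooledCoherence],
                          path, fmax: float = 80.0):
    """One panel per force level: pooled coherence per group with its
    confidence limit dashed; alpha/beta/gamma bands shaded."""
    levels = sorted({lv for _, lv in pooled_by_key})
    groups = sorted({g for g, _ in pooled_by_key})
    fig, axes = plt.subplots(1, max(len(levels), 1),
                             figsize=(3.2 * max(len(levels), 1), 3.0),
                             sharey=True, squeeze=False)
    for ax, level in zip(axes[0], levels):
        _shade_bands(ax)
        for g in groups:
            p = pooled_by_key.get((g, level))
            if p is None:
                continue
            m = p.freqs <= fmax
            ax.plot(p.freqs[m], p.r2[m], label=g, lw=1.2)
            ax.axhline(p.cl, ls="--", lw=0.8, color="0.3")
        ax.set_title(f"{level:.0%} MVC")
        ax.set_xlabel("frequency (Hz)")
    axes[0][0].set_ylabel("pooled coherence")
    axes[0][0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_clusters(envelopes, model, path, target: np.ndarray | None = None):
    """Members as thin lines per cluster, centroid bold, optional target
    profile overlaid (scaled to the centroid range)."""
    X = [np.asarray(getattr(e, "samples", e), dtype=float) for e in envelopes]
    k = model.k
    fig, axes = plt.subplots(1, k, figsize=(3.2 * k, 3.0), squeeze=False)
    for c in range(k):
        ax = axes[0][c]
        members = [X[i] for i in np.flatnonzero(model.assignments == c)]
        for m in members:
            z = (m - m.mean()) / (m.std() or 1.0)
            ax.plot(z, lw=0.5, alpha=0.6)
        ax.plot(model.centroids[c], "k-", lw=2.0)
        if target is not None:
            t = (target - target.mean()) / (target.std() or 1.0)
            ax.plot(np.linspace(0, len(model.centroids[c]) - 1, t.size), t,
                    "--", color="0.4", lw=1.0)
        ax.set_title(f"cluster {c} (n={len(members)})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
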