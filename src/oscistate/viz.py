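"""Topographic rendering of microstate maps (plotting only).

Maps are drawn as interpolated sensor-space fields on a disc.  When the
optional ``mne`` dependency is present the true planar sensor layout is
used; otherwise channels are placed on concentric rings, which preserves
the left/right and anterior/posterior structure of synthetic maps well
enough for visual inspection.
"""

from __future__ import annotations

import numpy as np


def _ring_positions(n: int) -> np.ndarray:
    pos = []
    remaining = n
    ring = 0
    while remaining > 0:
        count = min(remaining, max(6 * ring, 1))
        radius = 0.15 + 0.8 * ring / max(1, int(np.ceil(n / 12)))
        ang = np.linspace(0, 2 * np.pi, count, endpoint=False)
        pos.extend(zip(radius * np.cos(ang), radius * np.sin(ang)))
        remaining -= count
        ring += 1
    return np.asarray(pos[:n])


def _layout_positions(channel_names: list[str]) -> np.ndarray:
    try:
        import mne

        layout = mne.channels.read_layout("Vectorview-all")
        lut = {n.replace(" ", ""): p[:2] for n, p in zip(layout.names, layout.pos)}
        pos = [lut.get(str(n).replace(" ", "")) for n in channel_names]
        if all(p is not None for p in pos):
            arr = np.asarray(pos, float)
            arr -= arr.mean(axis=0)
            arr /= np.abs(arr).max() or 1.0
            return arr
    except Exception:  # pragma: no cover - layout fallback
        pass
    return _ring_positions(len(channel_names))


def plot_maps(maps: np.ndarray, channel_names, out_png: str, titles=None) -> None:
    """Render K microstate maps side by side to a PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    maps = np.asarray(maps, float)
    K = maps.shape[0]
    pos = _layout_positions(list(channel_names))
    fig, axes = plt.subplots(1, K, figsize=(3 * K, 3))
    if K == 1:
        axes = [axes]
    for k, ax in enumerate(axes):
        v = maps[k]
        lim = np.abs(v).max() or 1.0
        ax.tricontourf(pos[:, 0], pos[:, 1], v, levels=21, cmap="RdBu_r",
                       vmin=-lim, vmax=lim)
        ax.scatter(pos[:, 0], pos[:, 1], s=2, c="k", alpha=0.3)
        ax.set_title(titles[k] if titles else f"MS{k + 1}")
        ax.set_aspect("equal")
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)
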