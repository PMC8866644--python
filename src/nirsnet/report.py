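"""Figure rendering for pipeline reports.

Two figure analogues: a strong-connectivity diagram (channels on a circle,
line thickness by connection strength class) and metric-versus-sparsity
curves per hemisphere and session. Rendering is optional; the data behind
both figures live in the report JSON.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def plot_strong_edges(edges: list[dict], n_channels: int, path: str | Path,
                      title: str = "") -> None:
    """Channels on a circle; edges drawn with thickness by strength class."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    theta = 2 * np.pi * np.arange(n_channels) / n_channels
    xy = np.column_stack([np.cos(theta), np.sin(theta)])
    fig, ax = plt.subplots(figsize=(5, 5))
    for e in edges:
        a, b = e["ch_a"] - 1, e["ch_b"] - 1
        ax.plot([xy[a, 0], xy[b, 0]], [xy[a, 1], xy[b, 1]],
                lw=e.get("thickness", 1), color="tab:red", alpha=0.7)
    ax.scatter(xy[:, 0], xy[:, 1], s=60, color="tab:green", zorder=3)
    for k in range(n_channels):
        ax.annotate(str(k + 1), xy[k] * 1.12, ha="center", va="center", fontsize=7)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_profiles(profiles: dict, path: str | Path) -> None:
    """Mean metric-vs-sparsity curves; one panel per hemisphere x metric."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hemis = sorted({k.split("/")[1] for k in profiles})
    fig, axes = plt.subplots(2, len(hemis), figsize=(5 * len(hemis), 7),
                             squeeze=False)
    for col, hemi in enumerate(hemis):
        for key, prof in sorted(profiles.items()):
            session, h = key.split("/")
            if h != hemi:
                continue
            grid = prof["grid"]
            axes[0][col].plot(grid, prof["mean_clustering"], label=session)
            axes[1][col].plot(grid, prof["mean_efficiency"], label=session)
        axes[0][col].set_title(f"{hemi} hemisphere")
        axes[0][col].set_ylabel("clustering coefficient")
        axes[1][col].set_ylabel("global efficiency")
        axes[1][col].set_xlabel("sparsity")
        axes[0][col].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
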