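"""Optional matplotlib views: silhouette maps and MSW-vs-k curves."""

from __future__ import annotations

import numpy as np

from .powermean import format_exponent

__all__ = ["silhouette_map", "msw_curves"]


def silhouette_map(pattern, table, ax=None):
    """Scatter a 2-D pattern, circling objects with negative silhouette."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    xy = pattern.coords
    for lab in np.unique(pattern.labels):
        m = pattern.labels == lab
        ax.scatter(xy[m, 0], xy[m, 1], s=14, label=str(lab))
    bad = table["s"].to_numpy() < 0
    if bad.any():
        ax.scatter(
            xy[bad, 0], xy[bad, 1], s=90, facecolors="none",
            edgecolors="k", linewidths=0.9,
        )
    p = table.attrs.get("p", float("nan"))
    msw = table["s"].mean()
    mr = float(np.mean(bad))
    ax.set_title(f"p = {format_exponent(p)}   MSW = {msw:.3f}   MR = {mr:.3f}")
    ax.set_aspect("equal")
    ax.legend(frameon=False, fontsize=8)
    return ax


def msw_curves(grid, by: str = "p", ax=None):
    """MSW against cluster number, one panel line per method or per p.

    ``by="p"`` draws one line per exponent for each method frame passed;
    ``by="method"`` draws one line per method at fixed p.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    key = "p" if by == "p" else "method"
    for val, sub in grid.groupby(key, sort=True):
        sub = sub.sort_values("k")
        lbl = format_exponent(val) if key == "p" else str(val)
        ax.plot(sub["k"], sub["msw"], marker="o", ms=3, label=lbl)
    ax.set_xlabel("number of clusters k")
    ax.set_ylabel("mean silhouette width")
    ax.legend(frameon=False, fontsize=8, title=key)
    return ax
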