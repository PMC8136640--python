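"""Congruence diagrams: threshold interval vs depth, one panel per chorotype."""

from __future__ import annotations

import warnings
from pathlib import Path

from .core import Chorotype

__all__ = ["plot_congruence_diagram"]


def plot_congruence_diagram(chorotype: Chorotype, path: str | Path | None = None):
    """Draw a chorotype's partials as threshold intervals against depth.

    Each partial chorotype is a vertical bar spanning its threshold
    interval, placed at its closure depth and annotated with its
    richness.  Non-informative chorotypes produce a warning and no
    figure.  Returns the matplotlib figure (or None).
    """
    if not chorotype.informative:
        warnings.warn(
            f"reference {chorotype.reference!r} is not informative; nothing to plot"
        )
        return None
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for p in chorotype.partials:
        lo, hi = p.ct_min, p.ct_max
        hi = hi if hi > lo else lo + 1e-3  # zero-width interval still visible
        ax.plot([p.depth, p.depth], [lo, hi], lw=6, solid_capstyle="butt", alpha=0.7)
        ax.annotate(
            str(p.richness),
            (p.depth, (lo + hi) / 2),
            textcoords="offset points",
            xytext=(8, 0),
            fontsize=9,
        )
    ax.set_xlabel("closure depth")
    ax.set_ylabel("congruence threshold $C_T$")
    ax.set_title(f"Chorotype of {chorotype.reference}")
    ax.set_xlim(left=0)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
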