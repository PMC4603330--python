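"""Minimal log-scale plot of f(B) with its exponential tail fits."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .superblocks import MultiplicityDistribution
from .tailfit import ExponentialFit

__all__ = ["plot_multiplicity_fit"]


def plot_multiplicity_fit(
    dist: MultiplicityDistribution,
    fits: Iterable[ExponentialFit],
    path: str | Path,
) -> None:
    """Plot empirical f(B) (log y-axis) and the fitted exponentials.

    Multiplicities with zero counts are drawn as open markers at f = 1 for
    visibility, matching the display convention of the analysis; they are
    never used in fitting.
    """
    fits = [f for f in fits if f is not None]
    b_max = max(dist.counts, default=4)
    fig, ax = plt.subplots(figsize=(5, 4))
    bs = list(range(2, b_max + 1))
    pos = [(b, dist.counts[b]) for b in bs if dist.counts.get(b, 0) > 0]
    zero = [b for b in bs if dist.counts.get(b, 0) == 0]
    if pos:
        ax.semilogy(*zip(*pos), "ko", label="f(B)")
    if zero:
        ax.semilogy(zero, [1] * len(zero), "o", mfc="none", mec="grey",
                    label="f(B)=0 (shown as 1)")
    grid = np.linspace(2, max(b_max, 3), 100)
    for fit in fits:
        ax.semilogy(grid, fit.a * np.exp(-fit.c * grid),
                    label=f"B>={fit.B_min}: c={fit.c:.2f}")
    ax.set_xlabel("multiplicity B")
    ax.set_ylabel("f(B)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
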