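"""Exponential tail fits to the multiplicity distribution f(B).

The signature statistic is the decay rate c of the log-linear fit
f(B) = a * exp(-c * B) over the tail B >= B_min of the multiplicity
distribution.  Three tails are fitted per distribution — B >= 2 (all B),
B >= 3, and B >= 4 — the last giving the most weight to high
multiplicities.  Only c is retained downstream: it is much more stable
than the amplitude a under changes of tail definition, and a larger c
means a faster-decaying (less persistent) tail, i.e. less inferred WGD.

Fitting is unweighted ordinary least squares of ln f(B) on B over the
multiplicities with positive counts; zero counts carry no information
about the density on a log scale and are excluded, not imputed.  The
closed-form OLS solution makes the fit fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .superblocks import MultiplicityDistribution

__all__ = [
    "ExponentialFit",
    "FitUndefinedError",
    "fit_exponential_tail",
    "fit_all_cutoffs",
    "DEFAULT_CUTOFFS",
]

DEFAULT_CUTOFFS: tuple[int, ...] = (2, 3, 4)


class FitUndefinedError(ValueError):
    """Fewer than two positive-count multiplicities at/above the cutoff."""


@dataclass(frozen=True)
class ExponentialFit:
    """Result of fitting f(B) = a * exp(-c * B) to a tail B >= B_min.

    ``c > 0`` is a decaying tail; ``n_points`` counts the positive-count
    multiplicities the regression used.
    """

    a: float
    c: float
    B_min: int
    n_points: int
    provenance: tuple = ()

    def predict(self, B: float) -> float:
        return self.a * math.exp(-self.c * B)


def fit_exponential_tail(
    dist: MultiplicityDistribution | Mapping[int, int], B_min: int
) -> ExponentialFit:
    """OLS of ln f(B) on B over {B >= B_min : f(B) > 0}.

    Returns a = e^intercept and c = -slope.  Raises
    :class:`FitUndefinedError` when fewer than two usable points exist
    (callers in the panel sweep record such cells as missing).
    """
    if isinstance(dist, MultiplicityDistribution):
        counts, provenance = dist.counts, dist.provenance
    else:
        counts, provenance = dist, ()
    pts = sorted((b, n) for b, n in counts.items() if b >= B_min and n > 0)
    if len(pts) < 2:
        raise FitUndefinedError(
            f"need >= 2 positive-count multiplicities at B >= {B_min}, "
            f"have {len(pts)}"
        )
    x = np.array([b for b, _ in pts], dtype=float)
    y = np.log([n for _, n in pts])
    slope, intercept = np.polyfit(x, y, 1)
    return ExponentialFit(
        a=float(np.exp(intercept)),
        c=float(-slope),
        B_min=B_min,
        n_points=len(pts),
        provenance=tuple(provenance) + (B_min,) if provenance else (B_min,),
    )


def fit_all_cutoffs(
    dist: MultiplicityDistribution | Mapping[int, int],
    cutoffs: tuple[int, ...] = DEFAULT_CUTOFFS,
) -> dict[int, ExponentialFit | None]:
    """Fit every tail cutoff; undefined fits are recorded as None, not raised."""
    out: dict[int, ExponentialFit | None] = {}
    for b_min in cutoffs:
        try:
            out[b_min] = fit_exponential_tail(dist, b_min)
        except FitUndefinedError:
            out[b_min] = None
    return out
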