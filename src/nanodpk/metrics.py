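"""Dose-profile comparison metrics.

The headline metric is the mean absolute percentage error between a
reference dose series G (e.g. the transport oracle or a full Monte Carlo
run) and a test series S (e.g. an EPA-rescaled profile):

    MAPE = (100 / N) * sum_i |G_i - S_i| / G_i

over the N aligned distance bins with G_i > 0; zero-reference bins are
excluded from the sum and reported separately (the ratio is undefined
there, and dose tails legitimately reach zero at the electron range).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernels import RadialDoseProfile

__all__ = ["MapeResult", "mape", "align_profiles", "mape_profiles"]


@dataclass(frozen=True)
class MapeResult:
    """MAPE value in percent plus bin bookkeeping."""

    value: float
    n_used: int
    n_excluded: int

    def __post_init__(self) -> None:
        if self.n_used < 1:
            raise ValueError("MAPE needs at least one usable bin")
        if self.value < 0:
            raise ValueError("MAPE is non-negative")


def mape(reference, test) -> MapeResult:
    """MAPE (percent) of ``test`` against ``reference`` on aligned bins."""
    g = np.asarray(reference, dtype=float)
    s = np.asarray(test, dtype=float)
    if g.shape != s.shape or g.ndim != 1 or g.size < 1:
        raise ValueError("series must be 1D, equal length, non-empty")
    used = g > 0
    n_excluded = int((~used).sum())
    if not used.any():
        raise ValueError("all reference bins are zero")
    rel = np.abs(g[used] - s[used]) / g[used]
    return MapeResult(
        value=float(100.0 * rel.mean()),
        n_used=int(used.sum()),
        n_excluded=n_excluded,
    )


def align_profiles(a: RadialDoseProfile, b: RadialDoseProfile):
    """Pair two profiles on exactly matching distance bins.

    Returns ``(dose_a, dose_b, edges)`` over the common bins; raises if
    the binnings differ in width or the ranges do not overlap.
    """
    wa = a.distance_edges[1] - a.distance_edges[0]
    wb = b.distance_edges[1] - b.distance_edges[0]
    if not np.isclose(wa, wb, rtol=1e-9):
        raise ValueError(f"bin widths differ: {wa} vs {wb} nm")
    # both start at 0 with uniform width, so the overlap is the first
    # min(n_a, n_b) bins
    n = min(a.dose.size, b.dose.size)
    if n < 1:
        raise ValueError("profiles have no common bins")
    return a.dose[:n], b.dose[:n], a.distance_edges[: n + 1]


def mape_profiles(
    reference: RadialDoseProfile, test: RadialDoseProfile, d_max: float | None = None
) -> MapeResult:
    """MAPE of ``test`` vs ``reference`` over common bins up to ``d_max`` nm."""
    g, s, edges = align_profiles(reference, test)
    if d_max is not None:
        n = int(np.searchsorted(edges, d_max, side="right")) - 1
        if n < 1:
            raise ValueError("d_max below the first bin")
        g, s = g[:n], s[:n]
    return mape(g, s)
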