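"""Photon source spectra and simplified secondary-electron spectra.

A :class:`PhotonSpectrum` is a discrete line spectrum, (energy, yield per
disintegration).  The bundled Yb-169 spectrum lists all lines with yield
above 0.1% — the workhorse keV brachytherapy source for gold-nanoparticle
dose-enhancement studies.

:func:`secondary_electron_spectrum` turns a photon line spectrum into a
binned photoelectron + Auger kinetic-energy spectrum under a deliberately
simple model: every sampled photon undergoes photoelectric absorption on a
user-supplied set of atomic shells (photoelectron energy ``E_gamma - B``),
optionally followed by fixed-energy Auger emission per vacancy.  Compton
scattering and pair production are not modelled; for gold at keV photon
energies the photoelectric channel dominates.  A spectrum computed by an
external transport code can be loaded from CSV instead.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "PhotonSpectrum",
    "ElectronSpectrum",
    "builtin_yb169",
    "total_yield",
    "secondary_electron_spectrum",
    "read_photon_spectrum",
    "write_photon_spectrum",
    "read_electron_spectrum",
    "write_electron_spectrum",
    "GOLD_SHELLS",
    "GOLD_AUGER",
]

# Yb-169 photon lines (energy in MeV exactly as tabulated, yield per
# disintegration); lines with yields > 0.1%.  Converted to keV on load.
_YB169_LINES_MEV = (
    (0.04977, 0.532),
    (0.05074, 0.940),
    (0.05730, 0.0993),
    (0.05751, 0.192),
    (0.05790, 0.00379),
    (0.05903, 0.0647),
    (0.05921, 0.0172),
    (0.06312, 0.442),
    (0.09362, 0.0261),
    (0.10978, 0.1747),
    (0.11819, 0.01869),
    (0.13052, 0.1131),
    (0.17721, 0.2216),
    (0.19796, 0.358),
    (0.26108, 0.01715),
    (0.30774, 0.1005),
)

# Gold atomic shells for the simplified photoelectric sampler:
# (binding energy keV, relative photo-ionisation probability when allowed).
# Binding energies from standard X-ray data tables; the relative weights are
# a fixed coarse split (K-dominant above the K edge) — see docs/methods.md.
GOLD_SHELLS: tuple[tuple[float, float], ...] = (
    (80.725, 0.80),   # K
    (14.353, 0.06),   # L1
    (13.734, 0.04),   # L2
    (11.919, 0.05),   # L3
    (2.743, 0.04),    # M (grouped)
    (0.759, 0.01),    # N (grouped)
)

# Simplified gold Auger lines: (electron energy keV, yield per vacancy).
# KLL ~55 keV (rare, gold K fluorescence yield ~0.96), LMM ~8 keV, MNN ~2 keV.
GOLD_AUGER: tuple[tuple[float, float], ...] = (
    (55.0, 0.04),
    (8.0, 0.7),
    (2.0, 1.0),
)


@dataclass(frozen=True)
class PhotonSpectrum:
    """Discrete photon line spectrum.

    Parameters
    ----------
    lines : sequence of (energy_keV, yield)
        Line energies (keV, strictly positive) with yields per
        disintegration (>= 0).  Stored sorted by energy.
    name : str
        Human-readable label.
    """

    lines: tuple[tuple[float, float], ...]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.lines) < 1:
            raise ValueError("spectrum needs at least one line")
        lines = tuple(sorted((float(e), float(y)) for e, y in self.lines))
        energies = [e for e, _ in lines]
        if any(e <= 0 for e in energies):
            raise ValueError("line energies must be strictly positive")
        if any(b <= a for a, b in zip(energies, energies[1:])):
            raise ValueError("line energies must be distinct")
        if any(y < 0 for _, y in lines):
            raise ValueError("line yields must be non-negative")
        object.__setattr__(self, "lines", lines)

    @property
    def energies(self) -> np.ndarray:
        return np.array([e for e, _ in self.lines])

    @property
    def yields(self) -> np.ndarray:
        return np.array([y for _, y in self.lines])


@dataclass(frozen=True)
class ElectronSpectrum:
    """Binned electron kinetic-energy spectrum.

    ``weights[i]`` is the expected number of electrons per incident photon
    with energy in ``[bin_edges[i], bin_edges[i+1])``.  Bin edges are
    uniform (default width 0.1 keV for keV sources).
    """

    bin_edges: np.ndarray
    weights: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("need at least two bin edges")
        if weights.shape != (edges.size - 1,):
            raise ValueError("len(weights) must equal len(bin_edges) - 1")
        d = np.diff(edges)
        if np.any(d <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if not np.allclose(d, d[0], rtol=1e-9, atol=1e-12):
            raise ValueError("bin edges must be uniform")
        if np.any(weights < 0) or not np.all(np.isfinite(weights)):
            raise ValueError("weights must be finite and non-negative")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "weights", weights)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


def builtin_yb169() -> PhotonSpectrum:
    """The bundled Yb-169 line spectrum (16 lines), energies in keV."""
    return PhotonSpectrum(
        lines=tuple((e * 1000.0, y) for e, y in _YB169_LINES_MEV),
        name="Yb-169",
    )


def total_yield(s: PhotonSpectrum) -> float:
    """Total photons emitted per disintegration (sum of line yields)."""
    return float(s.yields.sum())


def secondary_electron_spectrum(
    s: PhotonSpectrum,
    shells: Sequence[tuple[float, float]] = GOLD_SHELLS,
    auger: Sequence[tuple[float, float]] | None = GOLD_AUGER,
    n_samples: int = 100_000,
    seed: int = 0,
    bin_width: float = 0.1,
) -> ElectronSpectrum:
    """Monte-Carlo photoelectron (+ Auger) spectrum per incident photon.

    For each sampled photon a line is drawn with probability proportional
    to its yield and a shell is drawn among those energetically allowed
    (binding energy below the line energy), weighted by the shells'
    relative probabilities.  The photoelectron carries ``E_gamma - B``;
    each vacancy additionally emits the ``auger`` lines with their yields.
    The histogram is normalised to electrons per incident photon, so
    uniformly rescaling all line yields leaves the result unchanged.

    Raises
    ------
    ValueError
        If no (line, shell) pair is energetically allowed, ``n_samples``
        < 1 or ``bin_width`` <= 0.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    shells = [(float(b), float(p)) for b, p in shells]
    if not shells:
        raise ValueError("need at least one shell")
    e_lines = s.energies
    y_lines = s.yields
    bindings = np.array([b for b, _ in shells])
    shell_p = np.array([p for _, p in shells])
    # allowed[i, j]: shell j ionisable by line i
    allowed = e_lines[:, None] > bindings[None, :]
    if not allowed.any():
        raise ValueError("no energetically allowed (line, shell) pair")

    rng = np.random.default_rng(seed)
    line_prob = y_lines / y_lines.sum()
    line_idx = rng.choice(e_lines.size, size=n_samples, p=line_prob)

    # Per-line shell distribution restricted to allowed shells.
    shell_cdf = np.where(allowed, shell_p[None, :], 0.0)
    norm = shell_cdf.sum(axis=1)
    interacting = norm[line_idx] > 0
    shell_cdf = np.cumsum(shell_cdf, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        shell_cdf = shell_cdf / norm[:, None]
    u = rng.random(n_samples)
    shell_idx = np.empty(n_samples, dtype=np.intp)
    for i in range(e_lines.size):
        m = line_idx == i
        if norm[i] > 0:
            shell_idx[m] = np.searchsorted(shell_cdf[i], u[m], side="right")
        else:
            shell_idx[m] = -1

    pe_energies = np.where(
        interacting, e_lines[line_idx] - bindings[np.clip(shell_idx, 0, None)], np.nan
    )
    pe_energies = pe_energies[interacting]
    n_vac = pe_energies.size

    e_max = float(e_lines.max())
    n_bins = int(np.ceil(e_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(pe_energies, bins=edges)
    weights = counts.astype(float)
    if auger:
        for e_a, y_a in auger:
            if e_a <= 0 or y_a < 0:
                raise ValueError("Auger lines need positive energy, yield >= 0")
            if e_a >= e_max:
                continue
            k = int(e_a / bin_width)
            weights[k] += y_a * n_vac
    weights /= n_samples  # electrons per incident photon
    return ElectronSpectrum(bin_edges=edges, weights=weights, name=f"{s.name} electrons")


# ---------------------------------------------------------------------------
# CSV I/O

def write_photon_spectrum(s: PhotonSpectrum, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["energy_keV", "weight"])
        for e, y in s.lines:
            w.writerow([repr(e), repr(y)])


def read_photon_spectrum(path: str | Path, name: str | None = None) -> PhotonSpectrum:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or rows[0][:2] != ["energy_keV", "weight"]:
        raise ValueError(f"{path}: missing 'energy_keV,weight' header")
    lines = tuple((float(r[0]), float(r[1])) for r in rows[1:] if r)
    return PhotonSpectrum(lines=lines, name=name or Path(path).stem)


def write_electron_spectrum(es: ElectronSpectrum, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["bin_lo_keV", "bin_hi_keV", "weight"])
        for lo, hi, wt in zip(es.bin_edges[:-1], es.bin_edges[1:], es.weights):
            w.writerow([repr(float(lo)), repr(float(hi)), repr(float(wt))])


def read_electron_spectrum(path: str | Path, name: str | None = None) -> ElectronSpectrum:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or rows[0][:3] != ["bin_lo_keV", "bin_hi_keV", "weight"]:
        raise ValueError(f"{path}: missing 'bin_lo_keV,bin_hi_keV,weight' header")
    lo = np.array([float(r[0]) for r in rows[1:] if r])
    hi = np.array([float(r[1]) for r in rows[1:] if r])
    wt = np.array([float(r[2]) for r in rows[1:] if r])
    if lo.size == 0:
        raise ValueError(f"{path}: no data rows")
    if not np.allclose(lo[1:], hi[:-1]):
        raise ValueError(f"{path}: bins are not contiguous")
    edges = np.append(lo, hi[-1])
    return ElectronSpectrum(bin_edges=edges, weights=wt, name=name or Path(path).stem)
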