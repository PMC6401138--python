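"""Dose point kernels: construction from deposition events, evaluation, I/O.

A dose point kernel (DPK) is the radial absorbed-dose distribution around
an isotropic point source of electrons in an infinite homogeneous medium,
scored in thin concentric spherical shells (1 nm by default) and divided
by each shell's mass.  Kernels here are normalised per *source electron*;
multiply by electrons-per-photon (``ElectronSpectrum.total_weight``) to
recover a per-incident-photon normalisation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "DosePointKernel",
    "RadialDoseProfile",
    "shell_mass",
    "kernel_from_deposits",
    "kernel_value",
    "read_kernel",
    "write_kernel",
    "read_profile",
    "write_profile",
]

_NM3_TO_CM3 = 1e-21


def _check_uniform_edges(edges: np.ndarray, start_at_zero: bool) -> None:
    if edges.ndim != 1 or edges.size < 2:
        raise ValueError("need at least two bin edges")
    d = np.diff(edges)
    if np.any(d <= 0):
        raise ValueError("bin edges must be strictly increasing")
    if not np.allclose(d, d[0], rtol=1e-9, atol=1e-12):
        raise ValueError("bin edges must be uniform")
    if start_at_zero and abs(edges[0]) > 1e-12:
        raise ValueError("bin edges must start at 0")


@dataclass(frozen=True)
class DosePointKernel:
    """Radial dose table around a point source, keV/g per source electron."""

    medium: str
    bin_edges: np.ndarray  # nm, uniform, starting at 0
    dose: np.ndarray       # keV/g per source electron, one per shell
    n_source: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        dose = np.asarray(self.dose, dtype=float)
        _check_uniform_edges(edges, start_at_zero=True)
        if dose.shape != (edges.size - 1,):
            raise ValueError("one dose value per shell required")
        if np.any(dose < 0) or not np.all(np.isfinite(dose)):
            raise ValueError("dose must be finite and non-negative")
        if self.n_source < 1:
            raise ValueError("n_source must be >= 1")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "dose", dose)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def r_max(self) -> float:
        return float(self.bin_edges[-1])


@dataclass(frozen=True)
class RadialDoseProfile:
    """Dose vs distance from a particle *surface*, keV/g per source electron."""

    distance_edges: np.ndarray  # nm from the surface, uniform, starting at 0
    dose: np.ndarray
    n_samples: np.ndarray
    meta: dict | None = None

    def __post_init__(self) -> None:
        edges = np.asarray(self.distance_edges, dtype=float)
        dose = np.asarray(self.dose, dtype=float)
        n = np.asarray(self.n_samples, dtype=np.int64)
        _check_uniform_edges(edges, start_at_zero=True)
        if dose.shape != (edges.size - 1,) or n.shape != dose.shape:
            raise ValueError("dose and n_samples must have one entry per bin")
        if np.any(dose < 0):
            raise ValueError("dose must be non-negative")
        object.__setattr__(self, "distance_edges", edges)
        object.__setattr__(self, "dose", dose)
        object.__setattr__(self, "n_samples", n)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.distance_edges[:-1] + self.distance_edges[1:])


def shell_mass(r_in: float, r_out: float, rho: float) -> float:
    """Mass (g) of the spherical shell between radii r_in and r_out (nm).

    ``rho`` is the shell material density in g/cm^3.
    """
    if not (0 <= r_in < r_out):
        raise ValueError("need 0 <= r_in < r_out")
    if rho <= 0:
        raise ValueError("density must be positive")
    return (4.0 / 3.0) * math.pi * (r_out**3 - r_in**3) * _NM3_TO_CM3 * rho


def kernel_from_deposits(
    events,
    bin_width: float = 1.0,
    r_max: float = 1000.0,
    rho: float = 1.0,
    n_source: int = 1,
    medium: str = "water",
) -> DosePointKernel:
    """Histogram deposition events into a shell-mass-normalised kernel.

    ``events`` is any pair-iterable of (radius nm, deposited energy keV) or
    a 2-tuple of arrays ``(r, e_dep)``.  Events at ``r >= r_max`` are
    dropped (their count is reported via the returned kernel's conservation
    deficit, not an error).  By construction
    ``sum(dose_k * mass_k) * n_source == sum(e_dep kept)``.
    """
    if n_source < 1:
        raise ValueError("n_source must be >= 1")
    if bin_width <= 0 or r_max <= 0:
        raise ValueError("bin_width and r_max must be positive")
    if hasattr(events, "r") and hasattr(events, "e_dep"):
        r = np.asarray(events.r, dtype=float)
        e_dep = np.asarray(events.e_dep, dtype=float)
    elif isinstance(events, tuple) and len(events) == 2:
        r, e_dep = (np.asarray(a, dtype=float) for a in events)
    else:
        arr = np.asarray(list(events), dtype=float)
        if arr.size == 0:
            r = np.empty(0)
            e_dep = np.empty(0)
        else:
            r, e_dep = arr[:, 0], arr[:, 1]
    if np.any(r < 0):
        raise ValueError("event radii must be >= 0")
    n_bins = int(round(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    kept = r < edges[-1]
    n_dropped = int((~kept).sum())
    if n_dropped:
        logger.info("kernel_from_deposits: dropped %d events at r >= %g nm",
                    n_dropped, edges[-1])
    energy, _ = np.histogram(r[kept], bins=edges, weights=e_dep[kept])
    masses = np.array(
        [shell_mass(edges[i], edges[i + 1], rho) for i in range(n_bins)]
    )
    return DosePointKernel(
        medium=medium, bin_edges=edges, dose=energy / masses / n_source,
        n_source=n_source,
    )


def kernel_value(k: DosePointKernel, r):
    """Kernel dose at radius ``r`` (nm), scalar or array.

    Linear interpolation between shell-centre values; below the first
    centre the first shell's value is used, beyond the last centre the
    kernel is zero (electrons have finite range).
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0):
        raise ValueError("radius must be >= 0")
    out = np.interp(r_arr, k.bin_centers, k.dose, left=k.dose[0], right=0.0)
    return out if r_arr.ndim else float(out)


# ---------------------------------------------------------------------------
# CSV I/O

def write_kernel(k: DosePointKernel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# medium={k.medium}\n")
        fh.write(f"# n_source={k.n_source}\n")
        fh.write("r_lo_nm,r_hi_nm,dose_keV_per_g_per_src\n")
        for lo, hi, d in zip(k.bin_edges[:-1], k.bin_edges[1:], k.dose):
            fh.write(f"{float(lo)!r},{float(hi)!r},{float(d)!r}\n")


def read_kernel(path: str | Path) -> DosePointKernel:
    medium = "water"
    n_source = None
    lo, hi, dose = [], [], []
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                if key.strip() == "medium":
                    medium = val.strip()
                elif key.strip() == "n_source":
                    n_source = int(val)
                continue
            if not header_seen:
                if line != "r_lo_nm,r_hi_nm,dose_keV_per_g_per_src":
                    raise ValueError(f"{path}:{lineno}: missing kernel header")
                header_seen = True
                continue
            parts = line.split(",")
            try:
                lo.append(float(parts[0]))
                hi.append(float(parts[1]))
                dose.append(float(parts[2]))
            except (IndexError, ValueError):
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from None
    if not header_seen:
        raise ValueError(f"{path}: missing kernel header")
    if n_source is None:
        raise ValueError(f"{path}: missing '# n_source=' comment")
    lo_a, hi_a = np.array(lo), np.array(hi)
    if lo_a.size == 0:
        raise ValueError(f"{path}: no data rows")
    if not np.allclose(lo_a[1:], hi_a[:-1]):
        raise ValueError(f"{path}: bins are not contiguous")
    edges = np.append(lo_a, hi_a[-1])
    return DosePointKernel(
        medium=medium, bin_edges=edges, dose=np.array(dose), n_source=n_source
    )


def write_profile(p: RadialDoseProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        for key, val in (p.meta or {}).items():
            fh.write(f"# {key}={val}\n")
        fh.write("d_lo_nm,d_hi_nm,dose_keV_per_g_per_src,n_samples\n")
        for lo, hi, d, n in zip(
            p.distance_edges[:-1], p.distance_edges[1:], p.dose, p.n_samples
        ):
            fh.write(f"{float(lo)!r},{float(hi)!r},{float(d)!r},{int(n)}\n")


def read_profile(path: str | Path) -> RadialDoseProfile:
    meta: dict = {}
    lo, hi, dose, n = [], [], [], []
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
                continue
            if not header_seen:
                if line != "d_lo_nm,d_hi_nm,dose_keV_per_g_per_src,n_samples":
                    raise ValueError(f"{path}:{lineno}: missing profile header")
                header_seen = True
                continue
            parts = line.split(",")
            try:
                lo.append(float(parts[0]))
                hi.append(float(parts[1]))
                dose.append(float(parts[2]))
                n.append(int(parts[3]))
            except (IndexError, ValueError):
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from None
    if not header_seen or not lo:
        raise ValueError(f"{path}: missing header or data")
    edges = np.append(np.array(lo), hi[-1])
    return RadialDoseProfile(
        distance_edges=edges, dose=np.array(dose), n_samples=np.array(n), meta=meta
    )
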