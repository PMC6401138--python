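"""Material stopping-power/CSDA tables and the four path-rescaling factors.

The equivalent-path-length approximation replaces the segment of an
electron path inside a dense heterogeneity (here gold) by an equivalent
water path, ``alpha`` times longer.  Four choices of the dimensionless
factor ``alpha >= 1`` are provided:

unity
    No rescaling (geometry-only): ``alpha = 1``.
tsp
    Spectrum-weighted ratio of *linear* total stopping powers,
    ``alpha = sum(w_i E_i S_Au(E_i)) / sum(w_i E_i S_w(E_i))``.
lrr
    Spectrum-weighted ratio of *linear* CSDA ranges, water over gold.
pdr
    Physical density ratio, 19.3 for gold/water.

Stopping quantities are tabulated per material as (energy keV, mass total
stopping power MeV cm^2/g, mass CSDA range g/cm^2) with the density held
alongside; interpolation is log-log (standard practice for stopping-power
tables) with no extrapolation.  The builtin gold/water tables are computed
from the Berger–Seltzer (Moller) collision stopping-power formula with a
Z*E/800 radiative correction and CSDA by numerical integration of 1/S.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np

from .spectra import ElectronSpectrum

__all__ = [
    "MaterialTable",
    "RescalingFactor",
    "linear_tsp",
    "linear_csda",
    "factor_unity",
    "factor_pdr",
    "factor_tsp",
    "factor_lrr",
    "builtin_material_table",
    "read_material_table",
    "write_material_table",
    "RHO_GOLD",
    "RHO_WATER",
]

RHO_GOLD = 19.3   # g/cm^3
RHO_WATER = 1.0

# unit conversions
_MEV_PER_CM_TO_KEV_PER_NM = 1e3 / 1e7   # 1 MeV/cm = 1e-4 keV/nm
_CM_TO_NM = 1e7


@dataclass(frozen=True)
class MaterialTable:
    """Columnar electron stopping data for one material.

    ``rows`` hold (energy keV, mass TSP MeV cm^2/g, mass CSDA g/cm^2) on a
    strictly increasing energy grid; mass CSDA must itself be strictly
    increasing with energy.
    """

    material: str
    density: float  # g/cm^3
    energy: np.ndarray
    mass_tsp: np.ndarray
    mass_csda: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energy, dtype=float)
        s = np.asarray(self.mass_tsp, dtype=float)
        r = np.asarray(self.mass_csda, dtype=float)
        if self.density <= 0:
            raise ValueError("density must be positive")
        if e.size < 2 or s.shape != e.shape or r.shape != e.shape:
            raise ValueError("need >= 2 aligned rows")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(s <= 0) or np.any(r <= 0):
            raise ValueError("stopping power and CSDA must be positive")
        if np.any(np.diff(r) <= 0):
            raise ValueError("mass CSDA must be strictly increasing with energy")
        object.__setattr__(self, "energy", e)
        object.__setattr__(self, "mass_tsp", s)
        object.__setattr__(self, "mass_csda", r)


@dataclass(frozen=True)
class RescalingFactor:
    """Named EPA rescaling factor, ``alpha >= 1``."""

    name: str
    alpha: float

    def __post_init__(self) -> None:
        if self.name not in {"unity", "tsp", "lrr", "pdr"}:
            raise ValueError(f"unknown factor name {self.name!r}")
        if not (self.alpha >= 1.0):
            raise ValueError(f"alpha must be >= 1, got {self.alpha}")


def _loglog_interp(t: MaterialTable, e, column: np.ndarray):
    e_arr = np.asarray(e, dtype=float)
    if np.any(e_arr < t.energy[0]) or np.any(e_arr > t.energy[-1]):
        raise ValueError(
            f"energy outside {t.material} table grid "
            f"[{t.energy[0]}, {t.energy[-1]}] keV (no extrapolation)"
        )
    out = np.exp(np.interp(np.log(e_arr), np.log(t.energy), np.log(column)))
    return out if e_arr.ndim else float(out)


def linear_tsp(t: MaterialTable, e):
    """Linear total stopping power at energy ``e`` (keV), in keV/nm.

    Log-log interpolated mass TSP times density; errors outside the grid.
    Accepts a scalar or an array of energies.
    """
    return _loglog_interp(t, e, t.mass_tsp) * t.density * _MEV_PER_CM_TO_KEV_PER_NM


def linear_csda(t: MaterialTable, e):
    """Linear CSDA range at energy ``e`` (keV), in nm."""
    return _loglog_interp(t, e, t.mass_csda) / t.density * _CM_TO_NM


def factor_unity() -> RescalingFactor:
    """Geometry-only rescaling: alpha = 1."""
    return RescalingFactor("unity", 1.0)


def factor_pdr(rho_medium: float = RHO_GOLD, rho_water: float = RHO_WATER) -> RescalingFactor:
    """Physical density ratio medium/water (19.3 for gold)."""
    if rho_water <= 0:
        raise ValueError("water density must be positive")
    if rho_medium < rho_water:
        raise ValueError("rho_medium < rho_water would give alpha < 1")
    return RescalingFactor("pdr", rho_medium / rho_water)


def _spectrum_weighted_ratio(
    es: ElectronSpectrum, num: np.ndarray, den: np.ndarray
) -> float:
    centers = es.bin_centers
    w = es.weights * centers  # E_i-weighted
    return float(np.sum(w * num) / np.sum(w * den))


def _support(es: ElectronSpectrum) -> np.ndarray:
    mask = es.weights > 0
    if not mask.any():
        raise ValueError("electron spectrum has no weight")
    return mask


def factor_tsp(es: ElectronSpectrum, gold: MaterialTable, water: MaterialTable) -> RescalingFactor:
    """Energy-spectrum-weighted linear total-stopping-power ratio gold/water."""
    mask = _support(es)
    centers = es.bin_centers[mask]
    s_au = linear_tsp(gold, centers)
    s_w = linear_tsp(water, centers)
    w = es.weights[mask] * centers
    alpha = float(np.sum(w * s_au) / np.sum(w * s_w))
    return RescalingFactor("tsp", alpha)


def factor_lrr(es: ElectronSpectrum, water: MaterialTable, gold: MaterialTable) -> RescalingFactor:
    """Energy-spectrum-weighted linear CSDA-range ratio water/gold."""
    mask = _support(es)
    centers = es.bin_centers[mask]
    r_w = linear_csda(water, centers)
    r_au = linear_csda(gold, centers)
    w = es.weights[mask] * centers
    alpha = float(np.sum(w * r_w) / np.sum(w * r_au))
    return RescalingFactor("lrr", alpha)


# ---------------------------------------------------------------------------
# Builtin tables from the Berger–Seltzer formula

_MEC2_KEV = 510.99895  # electron rest energy

_MATERIAL_CONST = {
    # Z/A (electrons per u), mean excitation energy I (eV), density, Z for
    # the radiative correction (effective Z for water).
    "water": dict(z_over_a=0.55509, i_ev=75.0, density=RHO_WATER, z=7.42),
    "gold": dict(z_over_a=0.40108, i_ev=790.0, density=RHO_GOLD, z=79.0),
}


def _mass_collision_sp(e_kev: np.ndarray, z_over_a: float, i_ev: float) -> np.ndarray:
    """Moller/Berger–Seltzer mass collision stopping power, MeV cm^2/g.

    Density-effect correction omitted (negligible below ~1 MeV for the
    energies this package targets).
    """
    tau = e_kev / _MEC2_KEV
    beta2 = 1.0 - 1.0 / (1.0 + tau) ** 2
    i_rel = (i_ev / 1000.0) / _MEC2_KEV
    f_minus = (
        1.0
        - beta2
        + (tau**2 / 8.0 - (2.0 * tau + 1.0) * np.log(2.0)) / (tau + 1.0) ** 2
    )
    bracket = np.log(tau**2 * (tau + 2.0) / (2.0 * i_rel**2)) + f_minus
    return 0.153536 * z_over_a / beta2 * bracket


@lru_cache(maxsize=None)
def builtin_material_table(
    material: str, e_min: float = 1.0, e_max: float = 1000.0, n: int = 200
) -> MaterialTable:
    """Gold or water stopping table computed from the Bethe formula.

    The grid is log-spaced on ``[e_min, e_max]`` keV.  Radiative stopping
    is approximated as ``S_col * Z * E[MeV] / 800``; the mass CSDA range
    is the cumulative integral of ``1/S_total`` with ``r(e_min) =
    e_min / S(e_min)``.  Below a few keV the Bethe formula degrades
    (especially for gold, I = 790 eV); keep ``e_min >= 1`` keV.
    """
    try:
        c = _MATERIAL_CONST[material]
    except KeyError:
        raise ValueError(f"no builtin table for {material!r}") from None
    e = np.geomspace(e_min, e_max, n)
    s_col = _mass_collision_sp(e, c["z_over_a"], c["i_ev"])
    if np.any(s_col <= 0):
        raise ValueError(f"Bethe formula invalid at e_min={e_min} keV for {material}")
    s_tot = s_col * (1.0 + c["z"] * (e / 1000.0) / 800.0)
    # mass CSDA: integrate dE/S on a fine grid, sample back onto e
    e_fine = np.geomspace(e_min, e_max, 4000)
    s_fine = _mass_collision_sp(e_fine, c["z_over_a"], c["i_ev"])
    s_fine *= 1.0 + c["z"] * (e_fine / 1000.0) / 800.0
    r_fine = np.concatenate(
        ([0.0], np.cumsum(np.diff(e_fine / 1000.0) / (0.5 * (s_fine[1:] + s_fine[:-1]))))
    )
    r_fine += (e_min / 1000.0) / s_fine[0]
    r = np.interp(e, e_fine, r_fine)
    return MaterialTable(
        material=material, density=c["density"], energy=e, mass_tsp=s_tot, mass_csda=r
    )


# ---------------------------------------------------------------------------
# CSV I/O: columns energy_keV, mass_tsp_MeV_cm2_per_g, mass_csda_g_per_cm2,
# density as a "# density_g_per_cm3=..." comment, material as "# material=...".

def write_material_table(t: MaterialTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# material={t.material}\n")
        fh.write(f"# density_g_per_cm3={t.density!r}\n")
        fh.write("energy_keV,mass_tsp_MeV_cm2_per_g,mass_csda_g_per_cm2\n")
        for e, s, r in zip(t.energy, t.mass_tsp, t.mass_csda):
            fh.write(f"{float(e)!r},{float(s)!r},{float(r)!r}\n")


def read_material_table(path: str | Path) -> MaterialTable:
    material = Path(path).stem
    density = None
    body = io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                if key.strip() == "density_g_per_cm3":
                    density = float(val)
                elif key.strip() == "material":
                    material = val.strip()
            else:
                body.write(line)
    body.seek(0)
    header = body.readline().strip()
    if header != "energy_keV,mass_tsp_MeV_cm2_per_g,mass_csda_g_per_cm2":
        raise ValueError(f"{path}: unexpected or missing header {header!r}")
    if density is None:
        raise ValueError(f"{path}: missing '# density_g_per_cm3=' comment")
    data = np.loadtxt(body, delimiter=",", ndmin=2)
    return MaterialTable(
        material=material,
        density=density,
        energy=data[:, 0],
        mass_tsp=data[:, 1],
        mass_csda=data[:, 2],
    )
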