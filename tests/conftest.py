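import numpy as np
import pytest

from nanodpk import DosePointKernel, ElectronSpectrum, MaterialTable


def constant_stopping_table(material: str, density: float, s_linear: float) -> MaterialTable:
    """Toy table with a constant linear stopping power (keV/nm).

    mass TSP = S_lin / (rho * 1e-4) MeV cm^2/g, mass CSDA = E/S_lin in nm
    converted to g/cm^2; CSDA is then exactly E / S.
    """
    e = np.array([0.1, 1000.0])
    mass_tsp = np.full(2, s_linear * 1e4 / density)
    mass_csda = e / s_linear * 1e-7 * density
    return MaterialTable(material, density, e, mass_tsp, mass_csda)


@pytest.fixture
def toy_water():
    return constant_stopping_table("water", 1.0, 0.005)


@pytest.fixture
def toy_gold():
    # modest stopping contrast (alpha = 1.3 vs toy_water), proportional at
    # all energies so the EPA factor is energy-independent
    return constant_stopping_table("gold", 19.3, 0.0065)


@pytest.fixture
def two_row_table():
    """Hand-checkable 2-row table for log-log interpolation tests."""
    return MaterialTable(
        material="toy",
        density=2.0,
        energy=np.array([10.0, 1000.0]),
        mass_tsp=np.array([8.0, 2.0]),
        mass_csda=np.array([0.001, 0.1]),
    )


@pytest.fixture
def mono_8kev():
    """Narrow electron line at 8 keV (range 1600 nm in toy water)."""
    return ElectronSpectrum(np.array([7.95, 8.05]), np.array([1.0]))


@pytest.fixture
def smooth_kernel():
    """Analytic exponentially decaying kernel, 1500 nm support."""
    edges = np.arange(0.0, 1501.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DosePointKernel(
        medium="water",
        bin_edges=edges,
        dose=100.0 * np.exp(-centers / 300.0),
        n_source=1,
    )


@pytest.fixture
def zero_kernel():
    edges = np.arange(0.0, 101.0)
    return DosePointKernel(
        medium="water", bin_edges=edges, dose=np.zeros(100), n_source=1
    )
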