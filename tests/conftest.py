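import numpy as np
import pytest

from pyritize import NonDimensionalParams, SolverOptions, solve_profile
from pyritize.grid import synthesize_grid


@pytest.fixture(scope="session")
def fast_options():
    """Looser tolerance for bulk test runs; accuracy checks tighten it."""
    return SolverOptions(tol=1.0e-6)


@pytest.fixture(scope="session")
def glacial_solution(fast_options):
    """High-OC-delivery, low-Da* shelf endmember (closed-system)."""
    p = NonDimensionalParams(gamma0=25.2, da_star=3.7, psi0=10.0)
    return p, solve_profile(p, fast_options)


@pytest.fixture(scope="session")
def interglacial_solution(fast_options):
    """Low-OC-delivery, high-Da* shelf endmember (open-system)."""
    p = NonDimensionalParams(gamma0=3.9, da_star=11.4, psi0=10.0)
    return p, solve_profile(p, fast_options)


@pytest.fixture(scope="session")
def midrange_solution(fast_options):
    p = NonDimensionalParams(gamma0=5.0, da_star=2.0, psi0=5.0)
    return p, solve_profile(p, fast_options)


@pytest.fixture(scope="session")
def small_grid():
    return synthesize_grid(seed=42, n_cells=48)


def representative_scenarios():
    """Six shelf/slope/abyss scenarios with high and low OC delivery.

    Built from per-regime 95th/5th-percentile OC contents of a synthetic
    grid with regime-average values for the other boundary conditions.
    """
    grid = synthesize_grid(seed=7, n_cells=600)
    from pyritize.params import SiteConditions

    scenarios = []
    for regime in ("shelf", "slope", "abyss"):
        sub = grid[grid["regime"] == regime]
        base = {
            "water_depth": sub["water_depth"].median(),
            "temperature": sub["temperature"].mean(),
            "porosity": sub["porosity"].mean(),
            "sed_rate": sub["sed_rate"].median(),
            "oc_reactivity_swi": sub["oc_reactivity_swi"].median(),
            "fe_swi": sub["fe_swi"].mean(),
            "onset_depth": sub["onset_depth"].median(),
        }
        for label, q in (("high_oc", 0.95), ("low_oc", 0.05)):
            site = SiteConditions(**base, oc_swi=sub["oc_swi"].quantile(q))
            scenarios.append((f"{regime}_{label}", site))
    return scenarios


@pytest.fixture(scope="session")
def scenario_sites():
    return representative_scenarios()
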