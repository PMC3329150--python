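"""Shared fixtures: the toy phototroph and a chemostat-like reference state.

All fixtures are session-scoped; analysis functions only touch models inside
cobra contexts, so the shared instances stay pristine.
"""

from __future__ import annotations

import pytest
from cobra import Metabolite, Model, Reaction

from cyanoflux.energetics import EnergyParameters, apply_energy_parameters
from cyanoflux.fba import minimize_flux_norm
from cyanoflux.synth import make_toy_network


@pytest.fixture(scope="session")
def toy():
    return make_toy_network()


@pytest.fixture(scope="session")
def energized(toy):
    """Toy with GAR=50, NGAR=1 installed (the generator's true values)."""
    return apply_energy_parameters(toy, EnergyParameters(gar=50.0, ngar=1.0))


@pytest.fixture(scope="session")
def chemostat(energized):
    """Measured-rate constraint set and the reference flux state at balanced
    light (25/25), the toy analogue of a light-limited chemostat.

    The 'measurements' are rounded the way real rate data are: growth to
    four decimals (slightly below the true optimum), O2 evolution to the
    midpoint of its feasible interval at that growth — mutually consistent
    numbers of finite precision.
    """
    import math

    from cyanoflux.fba import run_fva

    psii = psi = 25.0
    with energized as m:
        m.reactions.EX_photon_psii_e.bounds = (psii, psii)
        m.reactions.EX_photon_psi_e.bounds = (psi, psi)
        growth = m.slim_optimize()
    growth_m = math.floor(growth * 1e4) / 1e4
    base = {"EX_photon_psii_e": psii, "EX_photon_psi_e": psi,
            "BIOMASS": growth_m}
    o2 = run_fva(energized, constraints=base, reactions=["EX_o2_e"]).ranges
    o2_m = float(o2.mean(axis=1).iloc[0])
    measured = dict(base, EX_o2_e=o2_m)
    state = minimize_flux_norm(energized, constraints=measured)
    return {"measured": measured, "growth": growth_m, "state": state}


def build_chain_model(n: int = 3, uptake: float = 5.0) -> Model:
    """Linear chain EX -> A -> B -> ... with the uptake fixed; every internal
    flux is then pinned by conservation."""
    m = Model("chain")
    mets = [Metabolite(f"m{i}_c", compartment="c") for i in range(n)]
    ex = Reaction("EX_m0_e", lower_bound=uptake, upper_bound=uptake)
    m.add_reactions([ex])
    ex.add_metabolites({mets[0]: 1})
    for i in range(n - 1):
        r = Reaction(f"R{i}", lower_bound=0, upper_bound=1000)
        m.add_reactions([r])
        r.add_metabolites({mets[i]: -1, mets[i + 1]: 1})
    dm = Reaction("DM_end", lower_bound=0, upper_bound=1000)
    m.add_reactions([dm])
    dm.add_metabolites({mets[-1]: -1})
    m.objective = "DM_end"
    return m
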