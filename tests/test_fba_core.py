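"""FBA/FVA core against independent scipy oracles and structural invariants."""

import numpy as np
import pytest
from cobra import Metabolite, Model, Reaction
from hypothesis import given, settings, strategies as st
from scipy.optimize import linprog, minimize

from cyanoflux.fba import (FvaResult, classify_usage, flux_span_summary,
                           minimize_flux_norm, run_fva, solve_fba)
from conftest import build_chain_model

import pandas as pd


def _dense_lp(model, sense="max"):
    """Independent LP oracle: hand-assembled S matrix + scipy linprog."""
    mets = [m.id for m in model.metabolites]
    rxns = [r.id for r in model.reactions]
    S = np.zeros((len(mets), len(rxns)))
    for j, r in enumerate(model.reactions):
        for met, c in r.metabolites.items():
            S[mets.index(met.id), j] = c
    from cobra.util.solver import linear_reaction_coefficients
    obj = next(iter(linear_reaction_coefficients(model))).id
    c = np.zeros(len(rxns))
    c[rxns.index(obj)] = -1.0 if sense == "max" else 1.0
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    res = linprog(c, A_eq=S, b_eq=np.zeros(len(mets)), bounds=bounds,
                  method="highs")
    assert res.status == 0
    return -res.fun if sense == "max" else res.fun


def test_fba_matches_dense_lp_oracle(toy):
    """Toy growth optimum equals an independently assembled scipy LP."""
    cons = {"EX_photon_psii_e": 10.0, "EX_photon_psi_e": 10.0}
    dist = solve_fba(toy, constraints=cons)
    with toy as m:
        m.reactions.EX_photon_psii_e.bounds = (10, 10)
        m.reactions.EX_photon_psi_e.bounds = (10, 10)
        oracle = _dense_lp(m)
    assert dist.status == "optimal"
    assert dist.objective_value == pytest.approx(oracle, rel=1e-7)


def test_no_photons_no_growth(toy):
    dist = solve_fba(toy, constraints={"EX_photon_psii_e": 0.0,
                                       "EX_photon_psi_e": 0.0})
    assert dist.status == "optimal"
    assert dist.objective_value == pytest.approx(0.0, abs=1e-9)


def test_infeasible_reported_not_silent(toy):
    """Contradictory constraints yield status='infeasible', never zeros."""
    dist = solve_fba(toy, constraints={"EX_photon_psii_e": 0.0,
                                       "EX_photon_psi_e": 0.0,
                                       "BIOMASS": 1.0})
    assert dist.status == "infeasible"
    assert np.isnan(dist.objective_value)


def test_unknown_constraint_reaction_raises(toy):
    with pytest.raises(KeyError, match="NOPE"):
        solve_fba(toy, constraints={"NOPE": 1.0})


def test_chain_fva_conservation():
    """A -> B -> C with the uptake fixed at 5: every range is [5, 5]."""
    chain = build_chain_model(n=3, uptake=5.0)
    fva = run_fva(chain)
    for rid in fva.ranges.index:
        assert fva.ranges.loc[rid, "minimum"] == pytest.approx(5.0, abs=1e-8)
        assert fva.ranges.loc[rid, "maximum"] == pytest.approx(5.0, abs=1e-8)


def test_blocked_downstream_of_closed_exchange(toy):
    """Closing the only nitrogen sources blocks the nitrogen-fixing route."""
    fva = run_fva(toy, constraints={"EX_n2_e": 0.0, "EX_photon_psii_e": 0.0,
                                    "EX_photon_psi_e": 0.0},
                  reactions=["NIF"])
    assert fva.ranges.loc["NIF", "minimum"] == pytest.approx(0.0, abs=1e-9)
    assert fva.ranges.loc["NIF", "maximum"] == pytest.approx(0.0, abs=1e-9)


def test_fva_brackets_fba_optimum(toy):
    """Any FBA optimum lies inside the FVA ranges computed under identical
    constraints."""
    cons = {"EX_photon_psii_e": 20.0, "EX_photon_psi_e": 20.0}
    dist = solve_fba(toy, constraints=cons)
    cons_fixed = dict(cons, BIOMASS=dist.objective_value - 1e-9)
    fva = run_fva(toy, constraints={**cons,
                                    "BIOMASS": (dist.objective_value - 1e-9,
                                                1000.0)})
    for rid in fva.ranges.index:
        lo, hi = fva.ranges.loc[rid]
        assert lo - 1e-6 <= dist.values[rid] <= hi + 1e-6, rid


def test_fva_infeasible_names_context(toy):
    with pytest.raises(RuntimeError, match="BIOMASS"):
        run_fva(toy, constraints={"EX_photon_psii_e": 0.0,
                                  "EX_photon_psi_e": 0.0,
                                  "BIOMASS": 1.0}, reactions=["BIOMASS"])


def test_classify_usage_examples_and_partition():
    ranges = pd.DataFrame({"minimum": [2.0, -3.0, 0.0, -1e-12],
                           "maximum": [5.0, 4.0, 0.0, 1e-12]},
                          index=["a", "b", "c", "d"])
    labels = classify_usage(FvaResult(ranges=ranges))
    assert labels == {"a": "required", "b": "optional",
                      "c": "inactive", "d": "inactive"}
    assert len(labels) == len(ranges)  # exhaustive


def test_flux_span_summary_constant_ranges():
    ranges = pd.DataFrame({"minimum": [1.0, -2.0], "maximum": [1.0, -2.0]},
                          index=["a", "b"])
    spans, mean = flux_span_summary(FvaResult(ranges=ranges))
    assert (spans == 0).all() and mean == 0.0
    with pytest.raises(ValueError, match="empty"):
        flux_span_summary(FvaResult(ranges=ranges), subset=[])


# ---------------------------------------------------------------------------
# flux-norm minimization
# ---------------------------------------------------------------------------

def _cycle_model():
    """One productive path A -> B plus a 2-reaction futile cycle B <-> A."""
    m = Model("cycle")
    a = Metabolite("A_c", compartment="c")
    b = Metabolite("B_c", compartment="c")
    for rid, stoich, lb, ub in [
            ("EX_a", {a: 1}, 3, 3),
            ("PATH", {a: -1, b: 1}, 0, 1000),
            ("CYC_F", {a: -1, b: 1}, 0, 1000),
            ("CYC_R", {b: -1, a: 1}, 0, 1000),
            ("DM_b", {b: -1}, 0, 1000)]:
        r = Reaction(rid, lower_bound=lb, upper_bound=ub)
        m.add_reactions([r])
        r.add_metabolites(stoich)
    m.objective = "DM_b"
    return m


@pytest.mark.parametrize("norm", ["l2", "l1"])
def test_norm_minimization_kills_futile_cycle(norm):
    m = _cycle_model()
    dist = minimize_flux_norm(m, objective_value=3.0, norm=norm)
    # the A->B conversion splits over the parallel routes, but the
    # backwards leg of the cycle carries nothing
    assert abs(dist.values["CYC_R"]) < 1e-6
    assert dist.values["DM_b"] == pytest.approx(3.0, abs=1e-6)


def test_zero_objective_all_zero_fluxes(toy):
    dist = minimize_flux_norm(toy, objective_value=0.0,
                              constraints={"EX_photon_psii_e": (0, 0),
                                           "EX_photon_psi_e": (0, 0)})
    assert float(dist.values.abs().max()) < 1e-7


def test_qp_matches_dense_kkt_oracle():
    """Least-norm flux on the chain equals the exact KKT solution of the
    equality-constrained quadratic program (dense, hand-assembled)."""
    chain = build_chain_model(n=4, uptake=2.0)
    dist = minimize_flux_norm(chain, objective_value=2.0)
    mets = [m.id for m in chain.metabolites]
    rxns = [r.id for r in chain.reactions]
    S = np.zeros((len(mets), len(rxns)))
    for j, r in enumerate(chain.reactions):
        for met, c in r.metabolites.items():
            S[mets.index(met.id), j] = c
    # equality constraints: S v = 0, v_uptake = 2, v_demand = 2; the box
    # bounds are slack at the optimum, so the KKT system is linear:
    # [2I A^T; A 0] [v; lam] = [0; b]
    fix = np.zeros((2, len(rxns)))
    fix[0, rxns.index("EX_m0_e")] = 1.0
    fix[1, rxns.index("DM_end")] = 1.0
    A = np.vstack([S, fix])
    b = np.concatenate([np.zeros(len(mets)), [2.0, 2.0]])
    n, m = len(rxns), A.shape[0]
    kkt = np.block([[2 * np.eye(n), A.T], [A, np.zeros((m, m))]])
    rhs = np.concatenate([np.zeros(n), b])
    v = np.linalg.lstsq(kkt, rhs, rcond=None)[0][:n]
    assert (v > -1e-9).all()  # bounds indeed inactive
    np.testing.assert_allclose(dist.values[rxns].to_numpy(), v, atol=1e-6)


def test_l1_l2_same_support_loop_free():
    """On a loop-free instance both norms activate the same reactions."""
    chain = build_chain_model(n=4, uptake=2.0)
    l2 = minimize_flux_norm(chain, objective_value=2.0, norm="l2")
    l1 = minimize_flux_norm(chain, objective_value=2.0, norm="l1")
    s2 = set(l2.values[l2.values.abs() > 1e-6].index)
    s1 = set(l1.values[l1.values.abs() > 1e-6].index)
    assert s1 == s2


def test_infeasible_objective_fixation_raises(toy):
    with pytest.raises(RuntimeError):
        minimize_flux_norm(toy, objective_value=10.0,
                           constraints={"EX_photon_psii_e": 0.0,
                                        "EX_photon_psi_e": 0.0})


# ---------------------------------------------------------------------------
# structural invariants
# ---------------------------------------------------------------------------

@settings(max_examples=10, deadline=None, derandomize=True)
@given(st.floats(min_value=0.1, max_value=4.0))
def test_homogeneous_scaling(toy, k):
    """Scaling all fixed rates by k scales the LP optimum by k."""
    base = solve_fba(toy, constraints={"EX_photon_psii_e": 10.0,
                                       "EX_photon_psi_e": 10.0})
    scaled = solve_fba(toy, constraints={"EX_photon_psii_e": 10.0 * k,
                                         "EX_photon_psi_e": 10.0 * k})
    assert scaled.objective_value == pytest.approx(
        k * base.objective_value, rel=1e-6)


@pytest.mark.parametrize("removed", [("QOX",), ("FDPQ", "NDH2"),
                                     ("COX", "QOX", "MEHLER_NADPH",
                                      "MEHLER_FD")])
def test_deletion_never_increases_objective(toy, removed):
    cons = {"EX_photon_psii_e": 30.0, "EX_photon_psi_e": 20.0}
    full = solve_fba(toy, constraints=cons).objective_value
    cons_del = dict(cons, **{r: 0.0 for r in removed})
    smaller = solve_fba(toy, constraints=cons_del)
    if smaller.status == "optimal":
        assert smaller.objective_value <= full + 1e-8
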