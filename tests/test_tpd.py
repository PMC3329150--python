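"""Expression-evidence integration: set construction, MIQP fit, TPD FVA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cyanoflux.fba import classify_usage, minimize_flux_norm, run_fva
from cyanoflux.synth import SyntheticExpressionSpec, simulate_expression
from cyanoflux.tpd import (ExpressionEvidence, ReactionEvidenceSets,
                           build_reaction_sets, epsilon_sensitivity,
                           fit_tpd_flux, tpd_constrained_fva)


def _relaxed(measured, tol=1e-6):
    """Measured rates with the same numerical half-width the TPD stages
    apply; plain-vs-TPD comparisons need identical R_E treatment."""
    return {rid: (v - tol, v + tol) for rid, v in measured.items()}


def _evidence(detected, mrna=None, threshold=8.0):
    return ExpressionEvidence(protein_detected=frozenset(detected),
                              mrna_log2=mrna or {}, mrna_threshold=threshold)


# ---------------------------------------------------------------------------
# reaction-set construction
# ---------------------------------------------------------------------------

def test_and_rule_needs_all_subunits(toy):
    """PSII carries '(psbA1 or psbA2) and psbB': one isozyme alone is not
    enough without the shared core subunit."""
    sets = build_reaction_sets(toy, _evidence({"tg_psbA1"}), measured={})
    assert "PSII" not in sets.r_h
    sets = build_reaction_sets(toy, _evidence({"tg_psbA1", "tg_psbB"}),
                               measured={})
    assert "PSII" in sets.r_h
    sets = build_reaction_sets(toy, _evidence({"tg_psbA2", "tg_psbB"}),
                               measured={})
    assert "PSII" in sets.r_h  # isozyme OR


def test_nothing_detected_everything_low(toy):
    genes = {g.id: 3.0 for g in toy.genes}  # all below the log2 threshold 8
    sets = build_reaction_sets(toy, _evidence(set(), genes), measured={})
    assert not sets.r_h
    gene_bearing = {r.id for r in toy.reactions if r.genes}
    assert sets.r_l == gene_bearing


def test_high_mrna_keeps_reaction_out_of_low_set(toy):
    genes = {g.id: 3.0 for g in toy.genes}
    genes["tg_petH"] = 12.0  # FNR transcribed though protein undetected
    sets = build_reaction_sets(toy, _evidence(set(), genes), measured={})
    assert "FNR" not in sets.r_l
    assert "FNR" not in sets.r_h


def test_data_driven_threshold(toy):
    """'Low' can mean below the weakest mRNA among detected proteins."""
    mrna = {g.id: 5.0 for g in toy.genes}
    mrna["tg_petH"] = 6.5
    sets = build_reaction_sets(
        toy, _evidence({"tg_petH"}, mrna), measured={},
        mrna_mode="data_driven")
    # threshold becomes 6.5; everything at 5.0 and undetected is low
    assert "FNR" in sets.r_h
    assert "PSII" in sets.r_l


def test_measured_reactions_excluded_from_evidence_sets(toy):
    detected = {g.id for g in toy.reactions.CBB.genes}
    sets = build_reaction_sets(toy, _evidence(detected),
                               measured={"CBB": 1.0})
    assert "CBB" not in sets.r_h and "CBB" not in sets.r_l
    assert sets.r_e == {"CBB": 1.0}


def test_overlap_validation():
    with pytest.raises(ValueError, match="overlap"):
        ReactionEvidenceSets(r_e={}, r_h=frozenset({"A"}),
                             r_l=frozenset({"A"}))
    with pytest.raises(ValueError, match="epsilon"):
        ReactionEvidenceSets(r_e={}, r_h=frozenset(), r_l=frozenset(),
                             epsilon=0.0)


def test_generator_roundtrip_recovers_sets(energized, chemostat):
    """Noise-free evidence from a known flux state reproduces the evidence
    sets implied by that state exactly."""
    spec = SyntheticExpressionSpec(true_flux=dict(chemostat["state"].values),
                                   detect_prob_active=1.0,
                                   detect_prob_inactive=0.0, mrna_sd=0.0,
                                   seed=0)
    ev = simulate_expression(energized, spec)
    sets = build_reaction_sets(energized, ev, chemostat["measured"])
    active_genes = ev.protein_detected
    for rxn in energized.reactions:
        genes = {g.id for g in rxn.genes}
        if not genes or rxn.id in chemostat["measured"]:
            continue
        functional = rxn.gpr.eval(
            knockouts={g.id for g in energized.genes} - active_genes)
        assert (rxn.id in sets.r_h) == functional


# ---------------------------------------------------------------------------
# the evidence MIQP
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def toy_sets(energized, chemostat):
    ev = simulate_expression(
        energized,
        SyntheticExpressionSpec(true_flux=dict(chemostat["state"].values),
                                seed=3))
    return build_reaction_sets(energized, ev, chemostat["measured"])


@pytest.fixture(scope="module")
def toy_fit(energized, toy_sets):
    return fit_tpd_flux(energized, toy_sets)


def test_empty_evidence_reduces_to_norm_minimization(energized, chemostat):
    sets = ReactionEvidenceSets(r_e=dict(chemostat["measured"]),
                                r_h=frozenset(), r_l=frozenset())
    fit = fit_tpd_flux(energized, sets)
    plain = minimize_flux_norm(energized,
                               constraints=_relaxed(chemostat["measured"]))
    assert fit.evidence_score == 0
    pd.testing.assert_series_equal(fit.flux.values, plain.values,
                                   atol=1e-6, rtol=0, check_names=False)


def test_fit_respects_indicator_semantics(energized, toy_sets, toy_fit):
    eps = toy_sets.epsilon
    v = toy_fit.flux.values
    for rid in toy_sets.r_h:
        x, y = toy_fit.x[rid], toy_fit.y[rid]
        assert x + y <= 1
        if y:
            assert v[rid] >= eps - 1e-6
        elif x:
            assert v[rid] <= -eps + 1e-6
        else:
            assert abs(v[rid]) <= 1e-6
    for rid in toy_sets.r_l:
        if toy_fit.z[rid]:
            assert abs(v[rid]) <= 1e-6


def test_lexicographic_fit_matches_enumeration_oracle(energized, chemostat):
    """On a trimmed instance (4 high + 3 low evidence reactions) the MILP
    evidence score equals the exhaustively enumerated maximum, and no
    score-optimal assignment admits a smaller flux norm."""
    r_h = ["PSII", "COX", "NDH1", "TRANSH"]
    r_l = ["QOX", "MEHLER_NADPH", "FDPQ"]
    sets = ReactionEvidenceSets(r_e=dict(chemostat["measured"]),
                                r_h=frozenset(r_h), r_l=frozenset(r_l))
    fit = fit_tpd_flux(energized, sets)

    eps = sets.epsilon
    best_score, best_norm = -1, np.inf
    for states in itertools.product(("zero", "pos", "neg"), repeat=len(r_h)):
        for zbits in itertools.product((0, 1), repeat=len(r_l)):
            cons = dict(chemostat["measured"])
            for rid, s in zip(r_h, states):
                rxn = energized.reactions.get_by_id(rid)
                if s == "pos":
                    cons[rid] = (max(rxn.lower_bound, eps), rxn.upper_bound)
                elif s == "neg":
                    cons[rid] = (rxn.lower_bound, min(rxn.upper_bound, -eps))
                else:
                    cons[rid] = (0.0, 0.0)
            for rid, zb in zip(r_l, zbits):
                if zb:
                    cons[rid] = (0.0, 0.0)
            try:
                dist = minimize_flux_norm(energized, constraints=cons)
            except (RuntimeError, ValueError):
                continue  # assignment infeasible (or bounds cannot reach it)
            score = sum(s != "zero" for s in states) + sum(zbits)
            norm = float((dist.values ** 2).sum())
            if score > best_score or (score == best_score
                                      and norm < best_norm - 1e-6):
                best_score, best_norm = score, norm
    assert fit.evidence_score == best_score
    assert fit.flux_norm == pytest.approx(best_norm, rel=1e-4)


def test_infeasible_measured_rates_reported(energized, toy_sets):
    bad = ReactionEvidenceSets(
        r_e=dict(toy_sets.r_e, EX_photon_psii_e=0.0, BIOMASS=1.0),
        r_h=toy_sets.r_h, r_l=toy_sets.r_l)
    with pytest.raises(RuntimeError, match="feasib"):
        fit_tpd_flux(energized, bad)


def test_weighted_mode_runs(energized, toy_sets):
    fit = fit_tpd_flux(energized, toy_sets, weight=1e-4)
    assert fit.evidence_score >= 0


# ---------------------------------------------------------------------------
# TPD-constrained FVA
# ---------------------------------------------------------------------------

def test_tpd_shrinks_ranges_and_raises_required(energized, chemostat,
                                                toy_sets, toy_fit):
    plain = run_fva(energized, constraints=_relaxed(chemostat["measured"]))
    tpd = tpd_constrained_fva(energized, toy_sets, toy_fit)
    wide, narrow = plain.ranges, tpd.ranges.loc[plain.ranges.index]
    assert (narrow["minimum"] >= wide["minimum"] - 1e-6).all()
    assert (narrow["maximum"] <= wide["maximum"] + 1e-6).all()
    before = pd.Series(classify_usage(plain)).value_counts()
    after = pd.Series(classify_usage(tpd)).value_counts()
    assert after.get("required", 0) >= before.get("required", 0)
    assert after.get("optional", 0) <= before.get("optional", 0)


def test_z_one_reactions_have_zero_range(energized, toy_sets, toy_fit):
    tpd = tpd_constrained_fva(energized, toy_sets, toy_fit)
    forced = [rid for rid, zb in toy_fit.z.items() if zb]
    assert forced  # the instance does pin some low-evidence reactions
    for rid in forced:
        assert tpd.ranges.loc[rid, "minimum"] == pytest.approx(0, abs=1e-9)
        assert tpd.ranges.loc[rid, "maximum"] == pytest.approx(0, abs=1e-9)


def test_active_set_recovery_jaccard(energized, chemostat):
    """With 90% detection of active enzymes the fitted active set overlaps
    the generative truth with Jaccard >= 0.8."""
    truth = {r.id for r in energized.reactions
             if r.genes and abs(chemostat["state"].values.get(r.id, 0)) > 1e-6
             and r.id not in chemostat["measured"]}
    ev = simulate_expression(
        energized,
        SyntheticExpressionSpec(true_flux=dict(chemostat["state"].values),
                                detect_prob_active=0.9,
                                detect_prob_inactive=0.05, seed=5))
    sets = build_reaction_sets(energized, ev, chemostat["measured"])
    fit = fit_tpd_flux(energized, sets)
    fitted_active = {rid for rid in sets.r_h
                     if fit.x[rid] or fit.y[rid]}
    fitted_active |= {rid for rid in sets.r_l if not fit.z[rid]
                      and abs(fit.flux.values[rid]) > 1e-6}
    inter = len(truth & fitted_active)
    union = len(truth | fitted_active)
    assert inter / union >= 0.8


def test_epsilon_sensitivity_report(energized, chemostat, toy_sets):
    ev_df = epsilon_sensitivity(
        energized,
        simulate_expression(
            energized,
            SyntheticExpressionSpec(true_flux=dict(chemostat["state"].values),
                                    seed=3)),
        chemostat["measured"], epsilons=(0.01, 0.1, 1.0))
    assert list(ev_df["epsilon"]) == [0.01, 0.1, 1.0]
    total = len(energized.reactions)
    assert (ev_df[["required", "optional", "inactive"]].sum(axis=1)
            == total).all()
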