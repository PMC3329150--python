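"""Integration of transcriptome/proteome data (TPD) into flux prediction.

Following the iMAT family of methods, gene-level evidence is lifted to
reaction evidence sets through the boolean gene-protein-reaction rules:

* R_E — reactions with experimentally measured fluxes (biomass, O2, photon
  exchanges), imposed as equality constraints;
* R_H — reactions whose enzymes were detected in the proteome (flux is
  favoured): binary indicators y (active positive, flux >= epsilon) and x
  (active negative, flux <= -epsilon); with x = y = 0 the flux is zero;
* R_L — reactions all of whose genes are undetected and weakly transcribed
  (flux is disfavoured): binary z forces zero flux when set.

The fit maximizes the number of satisfied evidence indicators
(sum over R_H of x+y plus sum over R_L of z) and, lexicographically second,
minimizes the sum of squared fluxes so alternate optima do not hide in
futile cycles.  Stage 1 is a MILP (GLPK, big-M indicators); with the optimal
binaries fixed the disjunctions collapse to bounds, so stage 2 and the
TPD-constrained FVA are continuous problems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cobra import Model

from .fba import (FvaResult, FluxDistribution, classify_usage,
                  minimize_flux_norm, run_fva)

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionEvidence",
    "ReactionEvidenceSets",
    "TpdFitResult",
    "build_reaction_sets",
    "fit_tpd_flux",
    "tpd_constrained_fva",
    "epsilon_sensitivity",
]

#: default biological activity threshold epsilon (mmol/gAFDW/h); well above
#: solver noise, well below typical central-metabolic fluxes
DEFAULT_EPSILON = 0.1

#: numerical half-width applied to the measured-rate (R_E) equalities --
#: measurements carry finite precision, and razor-edge equalities make the
#: mixed-integer stage brittle at solver tolerance
MEASURED_TOL = 1e-6


def _measured_constraints(r_e: dict[str, float]) -> dict:
    return {rid: (v - MEASURED_TOL, v + MEASURED_TOL)
            for rid, v in r_e.items()}


@dataclass(frozen=True)
class ExpressionEvidence:
    """Gene-level evidence: protein detection calls and log2 mRNA levels."""

    protein_detected: frozenset[str]
    mrna_log2: dict[str, float]
    mrna_threshold: float = 8.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.mrna_threshold):
            raise ValueError("mrna_threshold must be finite")


@dataclass(frozen=True)
class ReactionEvidenceSets:
    """Reaction-level evidence: R_E measured fluxes, R_H high, R_L low."""

    r_e: dict[str, float]
    r_h: frozenset[str]
    r_l: frozenset[str]
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.r_h & self.r_l:
            raise ValueError("R_H and R_L overlap: "
                             f"{sorted(self.r_h & self.r_l)}")
        overlap = set(self.r_e) & (self.r_h | self.r_l)
        if overlap:
            raise ValueError(f"measured reactions also in R_H/R_L: {overlap}")


def build_reaction_sets(network: Model, evidence: ExpressionEvidence,
                        measured: dict[str, float],
                        epsilon: float = DEFAULT_EPSILON,
                        mrna_mode: str = "threshold") -> ReactionEvidenceSets:
    """Lift gene evidence to reaction sets through the GPR rules.

    A reaction joins R_H if its GPR evaluates true with undetected genes
    knocked out (AND = complex requires all subunits, OR = isozymes).  It
    joins R_L if every associated gene is undetected *and* weakly
    transcribed (below the threshold; ``mrna_mode='data_driven'`` uses the
    lowest mRNA level among detected genes as the threshold).  Reactions
    qualifying for both get R_H precedence (conflict logged); reactions
    without genes or in R_E are left out.
    """
    model_genes = {g.id for g in network.genes}
    unmatched = (set(evidence.mrna_log2) | set(evidence.protein_detected)) \
        - model_genes
    if unmatched:
        logger.info("expression evidence for %d gene(s) not in the model "
                    "ignored: %s", len(unmatched), sorted(unmatched)[:10])
    if mrna_mode == "data_driven":
        detected_levels = [evidence.mrna_log2[g]
                           for g in evidence.protein_detected
                           if g in evidence.mrna_log2]
        threshold = min(detected_levels) if detected_levels \
            else evidence.mrna_threshold
    elif mrna_mode == "threshold":
        threshold = evidence.mrna_threshold
    else:
        raise ValueError("mrna_mode must be 'threshold' or 'data_driven'")

    def gene_low(gid: str) -> bool:
        return (gid not in evidence.protein_detected
                and gid in evidence.mrna_log2
                and evidence.mrna_log2[gid] < threshold)

    undetected = model_genes - set(evidence.protein_detected)
    r_h, r_l = set(), set()
    for rxn in network.reactions:
        genes = {g.id for g in rxn.genes}
        if not genes or rxn.id in measured:
            continue
        in_high = rxn.gpr.eval(knockouts=undetected)
        in_low = all(gene_low(g) for g in genes)
        if in_high and in_low:
            logger.info("reaction %s qualifies for both R_H and R_L; "
                        "keeping R_H", rxn.id)
            in_low = False
        if in_high:
            r_h.add(rxn.id)
        elif in_low:
            r_l.add(rxn.id)
    return ReactionEvidenceSets(r_e=dict(measured), r_h=frozenset(r_h),
                                r_l=frozenset(r_l), epsilon=epsilon)


@dataclass
class TpdFitResult:
    """Outcome of the evidence-constrained flux fit."""

    flux: FluxDistribution
    x: dict[str, int]  # active-negative indicators (R_H)
    y: dict[str, int]  # active-positive indicators (R_H)
    z: dict[str, int]  # inactive indicators (R_L)
    evidence_score: int
    flux_norm: float


def _binary_bounds(network: Model, sets: ReactionEvidenceSets,
                   fit: "TpdFitResult") -> dict[str, tuple[float, float]]:
    """Translate fixed indicator values into the equivalent flux bounds."""
    eps = sets.epsilon
    bounds: dict[str, tuple[float, float]] = {}
    for rid in sorted(sets.r_h):
        rxn = network.reactions.get_by_id(rid)
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if fit.y.get(rid):
            bounds[rid] = (max(lb, eps), ub)
        elif fit.x.get(rid):
            bounds[rid] = (lb, min(ub, -eps))
        else:
            bounds[rid] = (0.0, 0.0)
    for rid in sorted(sets.r_l):
        if fit.z.get(rid):
            bounds[rid] = (0.0, 0.0)
    return bounds


def fit_tpd_flux(network: Model, sets: ReactionEvidenceSets,
                 weight: float | None = None, norm: str = "l2",
                 big_m: float = 1000.0) -> TpdFitResult:
    """Flux distribution best matching the evidence, of minimal magnitude.

    Lexicographic by default: stage 1 maximizes the evidence score by MILP;
    stage 2 fixes the stage-1-optimal binaries and minimizes the flux norm.
    ``weight`` switches to a single-stage weighted trade-off
    (score - weight * sum |v|), kept linear so it remains a MILP.
    """
    with network as model:
        for rid, value in sorted(sets.r_e.items()):
            try:
                model.reactions.get_by_id(rid).bounds = (
                    value - MEASURED_TOL, value + MEASURED_TOL)
            except KeyError:
                raise KeyError(f"measured reaction {rid!r} not in model")
        prob = model.problem
        try:
            # default MIP tolerances let epsilon-sized indicator violations
            # slip through big-M rows; tighten them to the solver's floor
            model.solver.configuration.tolerances.feasibility = 1e-9
            model.solver.configuration.tolerances.integrality = 1e-9
        except AttributeError:
            pass
        new_vars, new_cons, obj_terms = [], [], []
        xs, ys, zs = {}, {}, {}
        for rid in sorted(sets.r_h):
            rxn = model.reactions.get_by_id(rid)
            v = rxn.flux_expression
            # indicator branches that the bounds cannot reach are fixed to 0
            # structurally (also keeps tiny-epsilon terms out of big-M rows
            # where MIP feasibility tolerances could let them slip)
            can_pos = rxn.upper_bound >= sets.epsilon
            can_neg = rxn.lower_bound <= -sets.epsilon
            x = prob.Variable(f"x_{rid}", type="binary") if can_neg else None
            y = prob.Variable(f"y_{rid}", type="binary") if can_pos else None
            xs[rid], ys[rid] = x, y
            x_expr = x if x is not None else 0
            y_expr = y if y is not None else 0
            new_vars += [b for b in (x, y) if b is not None]
            new_cons += [
                prob.Constraint(v - sets.epsilon * y_expr + big_m * x_expr,
                                lb=0, name=f"tpd_pos_{rid}"),
                prob.Constraint(v + sets.epsilon * x_expr - big_m * y_expr,
                                ub=0, name=f"tpd_neg_{rid}"),
            ]
            if x is not None and y is not None:
                new_cons.append(prob.Constraint(x + y, ub=1,
                                                name=f"tpd_xor_{rid}"))
            obj_terms += [b for b in (x, y) if b is not None]
        for rid in sorted(sets.r_l):
            rxn = model.reactions.get_by_id(rid)
            v = rxn.flux_expression
            z = prob.Variable(f"z_{rid}", type="binary")
            zs[rid] = z
            new_vars.append(z)
            new_cons += [
                prob.Constraint(v + big_m * z, ub=big_m, name=f"tpd_lo_u_{rid}"),
                prob.Constraint(v - big_m * z, lb=-big_m, name=f"tpd_lo_l_{rid}"),
            ]
            obj_terms.append(z)
        model.add_cons_vars(new_vars + new_cons)
        expr = sum(obj_terms) if obj_terms else 0
        if weight is not None:
            flux_l1 = sum(r.forward_variable + r.reverse_variable
                          for r in model.reactions)
            expr = expr - weight * flux_l1
        model.objective = prob.Objective(expr, direction="max")
        model.solver.update()
        status = model.solver.optimize()
        if status != "optimal":
            raise RuntimeError(f"evidence MILP not optimal: {status}; check "
                               "feasibility of the measured-flux constraints")
        score = int(round(model.objective.value)) if weight is None else None
        if weight is None and obj_terms:
            # tiebreak among alternate score-optimal binary assignments:
            # pin the score and pick the assignment of least L1 flux norm,
            # so the quadratic stage starts from a cycle-poor interpretation
            pin = prob.Constraint(sum(obj_terms), lb=score, ub=score,
                                  name="tpd_score_pin")
            model.add_cons_vars([pin])
            flux_l1 = sum(r.forward_variable + r.reverse_variable
                          for r in model.reactions)
            model.objective = prob.Objective(flux_l1, direction="min")
            model.solver.update()
            status = model.solver.optimize()
            if status != "optimal":
                raise RuntimeError(f"evidence tiebreak MILP failed: {status}")
        x_opt = {rid: (int(round(var.primal)) if var is not None else 0)
                 for rid, var in xs.items()}
        y_opt = {rid: (int(round(var.primal)) if var is not None else 0)
                 for rid, var in ys.items()}
        z_opt = {rid: int(round(var.primal)) for rid, var in zs.items()}
        score = sum(x_opt.values()) + sum(y_opt.values()) + sum(z_opt.values())

    fit = TpdFitResult(flux=None, x=x_opt, y=y_opt, z=z_opt,  # type: ignore
                       evidence_score=score, flux_norm=float("nan"))
    # stage 2: binaries fixed -> the disjunctions become plain bounds
    stage2 = _measured_constraints(sets.r_e)
    stage2.update(_binary_bounds(network, sets, fit))
    dist = minimize_flux_norm(network, constraints=stage2, norm=norm)
    fit.flux = dist
    fit.flux_norm = float((dist.values ** 2).sum())
    return fit


def tpd_constrained_fva(network: Model, sets: ReactionEvidenceSets,
                        fit: TpdFitResult,
                        reactions=None) -> FvaResult:
    """FVA under the measured rates with the fit's binaries held fixed."""
    constraints = _measured_constraints(sets.r_e)
    constraints.update(_binary_bounds(network, sets, fit))
    result = run_fva(network, constraints=constraints, reactions=reactions)
    result.context["tpd"] = {"epsilon": sets.epsilon,
                             "evidence_score": fit.evidence_score}
    return result


def epsilon_sensitivity(network: Model, evidence: ExpressionEvidence,
                        measured: dict[str, float],
                        epsilons=(0.01, 0.1, 1.0)) -> pd.DataFrame:
    """Usage-class counts as a function of the activity threshold epsilon.

    The required/optional/inactive tallies depend on the (unobservable)
    choice of epsilon; this report makes that sensitivity explicit.
    """
    rows = []
    for eps in epsilons:
        sets = build_reaction_sets(network, evidence, measured, epsilon=eps)
        fit = fit_tpd_flux(network, sets)
        fva = tpd_constrained_fva(network, sets, fit)
        labels = pd.Series(classify_usage(fva))
        counts = labels.value_counts()
        rows.append({"epsilon": eps,
                     "evidence_score": fit.evidence_score,
                     "required": int(counts.get("required", 0)),
                     "optional": int(counts.get("optional", 0)),
                     "inactive": int(counts.get("inactive", 0))})
    return pd.DataFrame(rows)


def fit_report(network: Model, sets: ReactionEvidenceSets,
               fit: TpdFitResult, path) -> pd.DataFrame:
    """Tab-separated fit report (reaction, flux, x, y, z, set membership)."""
    rows = []
    for rid in [r.id for r in network.reactions]:
        member = ("R_E" if rid in sets.r_e else
                  "R_H" if rid in sets.r_h else
                  "R_L" if rid in sets.r_l else "")
        rows.append({"reaction": rid,
                     "flux": float(fit.flux.values.get(rid, 0.0)),
                     "x": fit.x.get(rid, ""), "y": fit.y.get(rid, ""),
                     "z": fit.z.get(rid, ""), "set": member})
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
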