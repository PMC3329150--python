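"""Linear/quadratic optimisation over the flux cone.

Flux balance analysis (FBA) maximizes or minimizes an objective over the
steady-state polytope {v : S v = 0, lb <= v <= ub}; flux variability analysis
(FVA) minimizes and maximizes each flux individually under the same
constraints; flux-norm minimization picks, among the optima, the distribution
of least overall flux magnitude (sum of squared fluxes by default, so that
futile cycles carry no avoidable flux).

LPs are solved through cobrapy's GLPK backend.  The quadratic least-norm
problem is assembled as sparse matrices and handed to OSQP directly; an L1
fallback (minimize sum |v| via the forward/reverse variable split) is
available where a quadratic solve is not wanted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from cobra import Model
from cobra.util.array import create_stoichiometric_matrix
from cobra.util.solver import linear_reaction_coefficients

__all__ = [
    "FluxDistribution",
    "FvaResult",
    "Constraints",
    "apply_constraints",
    "load_constraints",
    "solve_fba",
    "minimize_flux_norm",
    "run_fva",
    "classify_usage",
    "flux_span_summary",
    "add_flux_sum_constraint",
    "ZERO_TOL",
]

#: default numerical zero for "carries no flux" decisions (solver noise scale;
#: distinct from the much larger biological activity threshold epsilon used by
#: the expression-evidence integration)
ZERO_TOL = 1e-9

#: reaction id -> fixed value, or -> (lb, ub) pair
Constraints = Mapping[str, "float | tuple[float, float]"]


@dataclass
class FluxDistribution:
    """A single flux vector v (mmol/gAFDW/h) with its objective value."""

    values: pd.Series
    objective_value: float
    status: str = "optimal"

    def __getitem__(self, rxn_id: str) -> float:
        return float(self.values[rxn_id])


@dataclass
class FvaResult:
    """Per-reaction [min, max] flux ranges under a fixed constraint set."""

    ranges: pd.DataFrame  # index: reaction id; columns: minimum, maximum
    context: dict = field(default_factory=dict)

    def span(self, rxn_id: str) -> float:
        row = self.ranges.loc[rxn_id]
        return float(row["maximum"] - row["minimum"])


def apply_constraints(model: Model, constraints: Constraints | None) -> None:
    """Tighten reaction bounds in place (use inside a ``with model:`` block).

    A scalar fixes the flux (equality); a pair sets (lb, ub).  Unknown
    reaction ids raise ``KeyError`` naming the offender.
    """
    if not constraints:
        return
    for rid, val in constraints.items():
        try:
            rxn = model.reactions.get_by_id(rid)
        except KeyError:
            raise KeyError(f"constraint references unknown reaction {rid!r}")
        if isinstance(val, (tuple, list)):
            lb, ub = float(val[0]), float(val[1])
        else:
            lb = ub = float(val)
        if lb > ub:
            raise ValueError(f"constraint on {rid}: lb {lb} > ub {ub}")
        rxn.bounds = (lb, ub)


def load_constraints(path) -> dict:
    """Read a YAML constraint list: items {reaction, fixed} or {reaction, lb, ub}."""
    with open(path) as fh:
        entries = yaml.safe_load(fh) or []
    out: dict = {}
    for item in entries:
        rid = item["reaction"]
        if "fixed" in item:
            out[rid] = float(item["fixed"])
        else:
            out[rid] = (float(item.get("lb", -np.inf)),
                        float(item.get("ub", np.inf)))
    return out


def add_flux_sum_constraint(model: Model, rxn_ids: Sequence[str],
                            total: float, name: str = "flux_sum") -> None:
    """Constrain the sum of several fluxes to a fixed total (e.g. the total
    photon uptake over both photosystems when only the sum was measured)."""
    expr = sum(model.reactions.get_by_id(r).flux_expression for r in rxn_ids)
    cons = model.problem.Constraint(expr, lb=total, ub=total, name=name)
    model.add_cons_vars([cons])


def _objective_reaction_id(model: Model) -> str:
    coeffs = linear_reaction_coefficients(model)
    if len(coeffs) != 1:
        raise ValueError("expected a single-reaction linear objective, got "
                         f"{[r.id for r in coeffs]}")
    return next(iter(coeffs)).id


def solve_fba(network: Model, constraints: Constraints | None = None,
              sense: str = "max", objective: str | None = None,
              ) -> FluxDistribution:
    """FBA: optimize an objective flux subject to S v = 0 and bounds.

    Infeasibility or unboundedness is reported in ``status``, never as a
    silent zero vector.
    """
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    with network as model:
        apply_constraints(model, constraints)
        if objective is not None:
            model.objective = model.reactions.get_by_id(objective)
        model.objective_direction = "max" if sense == "max" else "min"
        solution = model.optimize()
        status = solution.status
        if status != "optimal":
            return FluxDistribution(values=pd.Series(dtype=float),
                                    objective_value=float("nan"),
                                    status=status)
        return FluxDistribution(values=solution.fluxes.copy(),
                                objective_value=float(solution.objective_value),
                                status="optimal")


def _qp_min_norm(model: Model) -> pd.Series:
    """Minimize sum v_i^2 over {S v = 0, lb <= v <= ub} with OSQP."""
    import osqp
    from scipy import sparse

    S = sparse.csc_matrix(create_stoichiometric_matrix(model))
    n = S.shape[1]
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    A = sparse.vstack([S, sparse.identity(n, format="csc")], format="csc")
    l = np.concatenate([np.zeros(S.shape[0]), lb])
    u = np.concatenate([np.zeros(S.shape[0]), ub])
    prob = osqp.OSQP()
    prob.setup(P=sparse.identity(n, format="csc") * 2.0, q=np.zeros(n),
               A=A, l=l, u=u, verbose=False, polishing=True,
               eps_abs=1e-9, eps_rel=1e-9, max_iter=200_000)
    res = prob.solve(raise_error=False)
    if res.info.status not in ("solved", "solved inaccurate"):
        raise RuntimeError(f"quadratic flux-norm solve failed: {res.info.status}")
    return pd.Series(res.x, index=[r.id for r in model.reactions])


def _l1_min_norm(model: Model) -> pd.Series:
    """Minimize sum |v| via the forward/reverse split (pFBA-style LP)."""
    from optlang.symbolics import Zero

    model.objective = model.problem.Objective(Zero, direction="min")
    coeffs = {}
    for rxn in model.reactions:
        coeffs[rxn.forward_variable] = 1.0
        coeffs[rxn.reverse_variable] = 1.0
    model.objective.set_linear_coefficients(coeffs)
    solution = model.optimize()
    if solution.status != "optimal":
        raise RuntimeError(f"L1 flux-norm solve failed: {solution.status}")
    return solution.fluxes.copy()


def minimize_flux_norm(network: Model, objective_value: float | None = None,
                       constraints: Constraints | None = None,
                       norm: str = "l2") -> FluxDistribution:
    """Representative flux distribution of minimal overall magnitude.

    If ``objective_value`` is given, the model's objective flux is first
    fixed to it (the measured-rate convention); otherwise only
    ``constraints`` delimit the polytope.  ``norm='l2'`` minimizes the sum of
    squared fluxes (quadratic, OSQP); ``norm='l1'`` the sum of absolute
    fluxes (LP).
    """
    if norm not in ("l2", "l1"):
        raise ValueError("norm must be 'l2' or 'l1'")
    with network as model:
        apply_constraints(model, constraints)
        obj_value = objective_value
        if obj_value is not None:
            obj_id = _objective_reaction_id(model)
            model.reactions.get_by_id(obj_id).bounds = (obj_value, obj_value)
        fluxes = _qp_min_norm(model) if norm == "l2" else _l1_min_norm(model)
    fluxes = fluxes.where(fluxes.abs() > ZERO_TOL, 0.0)
    return FluxDistribution(values=fluxes,
                            objective_value=(float("nan") if obj_value is None
                                             else float(obj_value)),
                            status="optimal")


def run_fva(network: Model, constraints: Constraints | None = None,
            reactions: Iterable[str] | None = None) -> FvaResult:
    """Flux variability analysis: min and max of each flux individually.

    The constraint set is taken as given (measured rates enter as
    equalities); no fraction-of-optimum objective fixation is applied here —
    callers that want the objective pinned put it in ``constraints``.
    """
    with network as model:
        apply_constraints(model, constraints)
        if reactions is None:
            targets = [r.id for r in model.reactions]
        else:
            targets = list(reactions)
        mins, maxs = {}, {}
        for rid in targets:
            rxn = model.reactions.get_by_id(rid)
            model.objective = model.problem.Objective(rxn.flux_expression,
                                                      direction="min")
            lo = model.slim_optimize(error_value=np.nan)
            model.objective_direction = "max"
            hi = model.slim_optimize(error_value=np.nan)
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise RuntimeError(
                    f"FVA infeasible or unbounded when optimizing {rid!r} "
                    f"under constraints {dict(constraints or {})}")
            # guard against solver noise inverting the pair
            mins[rid], maxs[rid] = min(lo, hi), max(lo, hi)
    ranges = pd.DataFrame({"minimum": pd.Series(mins), "maximum": pd.Series(maxs)})
    ranges = ranges.loc[targets]
    return FvaResult(ranges=ranges, context={"constraints": dict(constraints or {})})


def classify_usage(fva: FvaResult, zero_tol: float = ZERO_TOL
                   ) -> dict[str, str]:
    """Partition reactions into required / optional / inactive.

    required: zero lies outside [min, max]; inactive: min = max = 0;
    optional: everything else — exhaustive and exclusive by construction.
    """
    labels = {}
    for rid, row in fva.ranges.iterrows():
        lo, hi = row["minimum"], row["maximum"]
        if lo > zero_tol or hi < -zero_tol:
            labels[rid] = "required"
        elif abs(lo) <= zero_tol and abs(hi) <= zero_tol:
            labels[rid] = "inactive"
        else:
            labels[rid] = "optional"
    return labels


def flux_span_summary(fva: FvaResult, subset: Iterable[str] | None = None
                      ) -> tuple[pd.Series, float]:
    """Per-reaction flux spans (max - min) and their mean over a subset."""
    ids = list(subset) if subset is not None else list(fva.ranges.index)
    if not ids:
        raise ValueError("empty reaction subset")
    spans = (fva.ranges.loc[ids, "maximum"] - fva.ranges.loc[ids, "minimum"])
    spans.name = "span"
    return spans, float(spans.mean())


def fva_report(fva: FvaResult, path, zero_tol: float = ZERO_TOL) -> pd.DataFrame:
    """Write the tab-separated FVA report (id, min, max, span, class)."""
    labels = classify_usage(fva, zero_tol)
    df = fva.ranges.copy()
    df["span"] = df["maximum"] - df["minimum"]
    df["class"] = pd.Series(labels)
    df.index.name = "reaction"
    df.to_csv(path, sep="\t")
    return df
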