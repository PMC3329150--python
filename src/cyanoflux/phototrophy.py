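"""Photon-resolved analyses over the two photosystems.

A phenotypic phase plane (PhPP) maps optimal growth over a grid of PSII and
PSI photon uptake fluxes and partitions it into regions by which photon
constraint has marginal value (positive reduced cost): PSII-only (region 1),
both (region 2), PSI-only (region 3).  Within a region, PhPP FVA classifies
each reaction as active (nonzero, same sign at every sampled
maximal-growth point), blocked (zero everywhere), or optional, extending
point-wise FVA to entire regions.  Limitation diagnosis distinguishes
reductant- from energy-limited growth by offering the model a small
artificial ATP- or NADPH-generating reaction and checking which one buys
growth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cobra import Model, Reaction

from .fba import ZERO_TOL, minimize_flux_norm
from .network import DEFAULT_SPECIES

__all__ = [
    "PhotonRegime",
    "PhppGrid",
    "compute_phpp",
    "diagnose_limitation",
    "phpp_fva",
    "region_usage",
    "scenario_scan",
]

#: capacity of the artificial ATP/NADPH generators used for diagnosis
#: (mmol/gAFDW/h); small so it probes the marginal, not the optimum
ARTIFICIAL_CAPACITY = 0.1
#: growth increase counted as a strict improvement (1/h)
GROWTH_INCREASE_TOL = 1e-8
#: reduced-cost tolerance for "this photon constraint has marginal value"
DUAL_TOL = 1e-6

DEFAULT_PSII_EXCHANGE = "EX_photon_psii_e"
DEFAULT_PSI_EXCHANGE = "EX_photon_psi_e"


@dataclass(frozen=True)
class PhotonRegime:
    """Photon uptake bounds for both photosystems (mmol/gAFDW/h).

    ``mode='fixed'`` pins uptake to the value (equality, the controlled-
    illumination convention); ``mode='upper_bound'`` caps it, letting the
    model absorb less than offered.
    """

    psii_uptake: float
    psi_uptake: float
    mode: str = "fixed"

    def __post_init__(self) -> None:
        if self.psii_uptake < 0 or self.psi_uptake < 0:
            raise ValueError("photon uptakes must be nonnegative")
        if self.mode not in ("fixed", "upper_bound"):
            raise ValueError("mode must be 'fixed' or 'upper_bound'")


def _apply_regime(model: Model, regime: PhotonRegime,
                  psii_exchange: str, psi_exchange: str) -> None:
    for rid, u in [(psii_exchange, regime.psii_uptake),
                   (psi_exchange, regime.psi_uptake)]:
        rxn = model.reactions.get_by_id(rid)
        rxn.bounds = (u, u) if regime.mode == "fixed" else (0.0, u)


@dataclass
class PhppGrid:
    """Growth surface and region partition over the photon-uptake grid."""

    psii_values: np.ndarray
    psi_values: np.ndarray
    growth: np.ndarray        # shape (len(psii), len(psi)), 1/h
    region: np.ndarray        # int labels: 0 none, 1 PSII, 2 both, 3 PSI
    boundary: np.ndarray      # True where a 4-neighbour has another region
    limitation: dict[int, str] = field(default_factory=dict)
    mode: str = "fixed"

    def region_points(self, region_id: int,
                      interior_only: bool = True) -> list[tuple[float, float]]:
        mask = self.region == region_id
        if interior_only and (mask & ~self.boundary).any():
            mask = mask & ~self.boundary
        ii, jj = np.nonzero(mask)
        return [(float(self.psii_values[i]), float(self.psi_values[j]))
                for i, j in zip(ii, jj)]


def compute_phpp(network: Model,
                 psii_range: tuple[float, float] = (0.0, 60.0),
                 psi_range: tuple[float, float] = (0.0, 60.0),
                 step: float = 5.0, mode: str = "fixed",
                 psii_exchange: str = DEFAULT_PSII_EXCHANGE,
                 psi_exchange: str = DEFAULT_PSI_EXCHANGE,
                 species: dict[str, str] = DEFAULT_SPECIES,
                 diagnose: bool = True,
                 dual_tol: float = DUAL_TOL) -> PhppGrid:
    """Phenotypic phase plane of maximal growth over photon uptakes.

    Each grid cell is an FBA solve under its photon regime; regions follow
    the sign pattern of the photon-constraint reduced costs (falling back to
    finite differences of one grid step when the duals are degenerate at a
    vertex).  Cells adjacent to another region are flagged as boundary and,
    when duals tie, keep the lower-numbered label.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    for rid in (psii_exchange, psi_exchange):
        if rid not in network.reactions:
            raise KeyError(f"network lacks photon exchange {rid!r}")
    psii_vals = np.arange(psii_range[0], psii_range[1] + step / 2, step)
    psi_vals = np.arange(psi_range[0], psi_range[1] + step / 2, step)
    growth = np.zeros((len(psii_vals), len(psi_vals)))
    region = np.zeros_like(growth, dtype=int)

    def solve(psii: float, psi: float):
        with network as m:
            _apply_regime(m, PhotonRegime(psii, psi, mode),
                          psii_exchange, psi_exchange)
            sol = m.optimize()
            if sol.status != "optimal":
                return np.nan, np.nan, np.nan
            return (sol.objective_value,
                    sol.reduced_costs[psii_exchange],
                    sol.reduced_costs[psi_exchange])

    for i, u2 in enumerate(psii_vals):
        for j, u1 in enumerate(psi_vals):
            g, rc2, rc1 = solve(u2, u1)
            growth[i, j] = max(g, 0.0) if np.isfinite(g) else np.nan
            if not np.isfinite(g) or g <= ZERO_TOL:
                # non-growing cells (e.g. a dark photosystem) carry no
                # phenotype region
                region[i, j] = 0
                continue
            a, b = rc2 > dual_tol, rc1 > dual_tol
            if not (a or b):
                # degenerate duals: one-grid-step finite differences
                ga, *_ = solve(u2 + step, u1)
                gb, *_ = solve(u2, u1 + step)
                a = np.isfinite(ga) and ga - g > GROWTH_INCREASE_TOL
                b = np.isfinite(gb) and gb - g > GROWTH_INCREASE_TOL
            region[i, j] = 1 if (a and not b) else 2 if (a and b) \
                else 3 if b else 0

    boundary = np.zeros_like(region, dtype=bool)
    for i in range(region.shape[0]):
        for j in range(region.shape[1]):
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if 0 <= ni < region.shape[0] and 0 <= nj < region.shape[1] \
                        and region[ni, nj] != region[i, j]:
                    boundary[i, j] = True
                    break

    grid = PhppGrid(psii_values=psii_vals, psi_values=psi_vals,
                    growth=growth, region=region, boundary=boundary,
                    mode=mode)
    if diagnose:
        for rid in sorted({int(r) for r in region.flat} - {0}):
            pts = grid.region_points(rid)
            if not pts:
                continue
            psii, psi = pts[len(pts) // 2]
            if psii == 0 or psi == 0:
                continue
            grid.limitation[rid] = diagnose_limitation(
                network, PhotonRegime(psii, psi, mode),
                psii_exchange=psii_exchange, psi_exchange=psi_exchange,
                species=species)
    return grid


def diagnose_limitation(network: Model, regime: PhotonRegime,
                        species: dict[str, str] = DEFAULT_SPECIES,
                        delta: float = ARTIFICIAL_CAPACITY,
                        increase_tol: float = GROWTH_INCREASE_TOL,
                        psii_exchange: str = DEFAULT_PSII_EXCHANGE,
                        psi_exchange: str = DEFAULT_PSI_EXCHANGE) -> str:
    """Is growth under this regime limited by energy (ATP) or reductant
    (NADPH)?

    Adds, one at a time, a capacity-``delta`` artificial generator
    (ADP + Pi + H -> ATP + H2O, or NADP + H -> NADPH) and labels by which
    addition strictly raises optimal growth: 'energy_limited',
    'reductant_limited', 'mixed' (both), or 'neither' (e.g. carbon-limited).
    """
    def met(key):
        return network.metabolites.get_by_id(species[key])

    def growth_with(extra_stoich) -> float:
        with network as m:
            _apply_regime(m, regime, psii_exchange, psi_exchange)
            if extra_stoich is not None:
                rxn = Reaction("ARTIFICIAL_GEN", lower_bound=0.0,
                               upper_bound=delta)
                m.add_reactions([rxn])
                rxn.add_metabolites(extra_stoich)
            return m.slim_optimize(error_value=np.nan)

    base = growth_with(None)
    if not np.isfinite(base):
        raise RuntimeError("photon regime infeasible")
    atp_gain = growth_with({met("adp"): -1, met("pi"): -1, met("h"): -1,
                            met("atp"): 1, met("h2o"): 1}) - base
    nadph_gain = growth_with({met("nadp"): -1, met("h"): -1,
                              met("nadph"): 1}) - base
    atp_up = np.isfinite(atp_gain) and atp_gain > increase_tol
    nadph_up = np.isfinite(nadph_gain) and nadph_gain > increase_tol
    if atp_up and nadph_up:
        return "mixed"
    if atp_up:
        return "energy_limited"
    if nadph_up:
        return "reductant_limited"
    return "neither"


def phpp_fva(network: Model, grid: PhppGrid, region_id: int,
             reactions, sample_density: int = 5,
             growth_slack: float = 1e-9,
             zero_tol: float = 1e-6,
             psii_exchange: str = DEFAULT_PSII_EXCHANGE,
             psi_exchange: str = DEFAULT_PSI_EXCHANGE) -> dict[str, str]:
    """Region-wide reaction usage: active / optional / blocked.

    At up to ``sample_density``^2 points of the region, growth is fixed to
    its point-wise maximum (minus an absolute slack of ``growth_slack`` to
    absorb solver noise) and FVA is run over ``reactions``; a reaction is
    *active* if min and max share a nonzero sign at every sampled point,
    *blocked* if its range is [0, 0] at every point, *optional* otherwise.
    ``zero_tol`` sits well above the flux wiggle the growth slack admits.
    """
    from .fba import run_fva

    pts = grid.region_points(region_id)
    if not pts:
        raise ValueError(f"region {region_id} has no grid points")
    if len(pts) == 1:
        warnings.warn(f"region {region_id} is a single grid point; "
                      "region-wide labels degenerate to point FVA",
                      stacklevel=2)
    limit = max(1, sample_density ** 2)
    if len(pts) > limit:
        idx = np.linspace(0, len(pts) - 1, limit).round().astype(int)
        pts = [pts[i] for i in sorted(set(idx))]

    reactions = list(reactions)
    per_point = []
    for psii, psi in pts:
        i = int(np.argmin(np.abs(grid.psii_values - psii)))
        j = int(np.argmin(np.abs(grid.psi_values - psi)))
        gmax = grid.growth[i, j]
        if not np.isfinite(gmax):
            continue
        with network as m:
            _apply_regime(m, PhotonRegime(psii, psi, grid.mode),
                          psii_exchange, psi_exchange)
            from .fba import _objective_reaction_id
            obj = m.reactions.get_by_id(_objective_reaction_id(m))
            obj.lower_bound = gmax - growth_slack
            per_point.append(run_fva(m, reactions=reactions).ranges)
    labels = {}
    for rid in reactions:
        act = blk = True
        for ranges in per_point:
            lo, hi = ranges.loc[rid, "minimum"], ranges.loc[rid, "maximum"]
            point_active = (lo > zero_tol and hi > zero_tol) or \
                           (lo < -zero_tol and hi < -zero_tol)
            point_blocked = abs(lo) <= zero_tol and abs(hi) <= zero_tol
            act &= point_active
            blk &= point_blocked
        labels[rid] = "active" if act else "blocked" if blk else "optional"
    return labels


def region_usage(network: Model, grid: PhppGrid, reactions,
                 **kwargs) -> dict[int, dict[str, str]]:
    """PhPP FVA labels for every region of the grid."""
    return {rid: phpp_fva(network, grid, rid, reactions, **kwargs)
            for rid in sorted({int(r) for r in grid.region.flat} - {0})}


def scenario_scan(network: Model, removed_sets: dict[str, list[str]],
                  psii_fixed: float, psi_values,
                  psii_exchange: str = DEFAULT_PSII_EXCHANGE,
                  psi_exchange: str = DEFAULT_PSI_EXCHANGE,
                  secretion_ignore: tuple[str, ...] = (
                      "EX_h2o_e", "EX_h_e", "EX_o2_e", "EX_co2_e",
                      "EX_nh3_e", "EX_n2_e", "EX_pi_e"),
                  secretion_tol: float = 1e-6) -> pd.DataFrame:
    """Electron-route knockout scan: growth and secreted products vs PSI
    photon uptake at fixed PSII uptake.

    ``removed_sets`` maps scenario labels (e.g. 'cyclic', 'sinks') to
    reaction-id lists; their union is disabled.  At each feasible point the
    secreted products are read off the minimal-flux-norm optimum, so only
    secretion the objective actually needs (or costs nothing to avoid) is
    reported.
    """
    removed: list[str] = []
    for name, ids in removed_sets.items():
        unknown = [r for r in ids if r not in network.reactions
                   and r not in removed]
        known = [r for r in ids if r in network.reactions]
        if unknown:
            warnings.warn(f"scenario set {name!r}: ids not in model ignored: "
                          f"{unknown}", stacklevel=2)
        removed.extend(known)
    rows = []
    any_feasible = False
    for psi in psi_values:
        with network as m:
            for rid in removed:
                m.reactions.get_by_id(rid).bounds = (0.0, 0.0)
            m.reactions.get_by_id(psii_exchange).bounds = (psii_fixed,
                                                           psii_fixed)
            m.reactions.get_by_id(psi_exchange).bounds = (psi, psi)
            g = m.slim_optimize(error_value=np.nan)
            if not np.isfinite(g):
                rows.append({"psi_uptake": psi, "growth": np.nan,
                             "status": "infeasible", "secreted": ""})
                continue
            any_feasible = True
            dist = minimize_flux_norm(m, objective_value=g)
        secreted = sorted(
            rid for rid in (r.id for r in network.reactions if r.boundary)
            if rid not in (psii_exchange, psi_exchange)
            and rid not in secretion_ignore
            and float(dist.values.get(rid, 0.0)) > secretion_tol)
        rows.append({"psi_uptake": psi, "growth": float(g),
                     "status": "optimal", "secreted": ";".join(secreted)})
    if not any_feasible:
        warnings.warn("scenario scan infeasible at every PSI value",
                      stacklevel=2)
    return pd.DataFrame(rows)
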