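"""ATP-requirement estimation, dark N2-fixation energetics, and photon units.

The growth-associated (GAR) and non-growth-associated (NGAR) ATP requirements
are estimated from batch observations by fixing measured growth and photon
uptake rates, maximizing the ATP-maintenance hydrolysis flux by LP for each
batch, and fitting max-ATP-hydrolysis vs growth rate by ordinary least
squares: the slope is GAR (mmol ATP per g AFDW, i.e. per unit growth in 1/h)
and the intercept is NGAR (mmol/gAFDW/h).

Dark N2 fixation is modelled as a static snapshot: photon uptakes are zero,
glycogen is supplied through a bounded source reaction, and cyanophycin
production is maximized; nitrogenase stoichiometry ties H2 co-production to
fixed N2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cobra import Model

from .fba import minimize_flux_norm
from .network import DEFAULT_SPECIES

__all__ = [
    "EnergyParameters",
    "BatchObservation",
    "DarkFixationResult",
    "estimate_atp_requirements",
    "apply_energy_parameters",
    "predict_batch_growth",
    "dark_n2_fixation",
    "photon_flux_from_irradiance",
]


@dataclass(frozen=True)
class EnergyParameters:
    """GAR (slope, mmol ATP/gAFDW) and NGAR (intercept, mmol/gAFDW/h)."""

    gar: float
    ngar: float

    def __post_init__(self) -> None:
        if self.gar < 0 or self.ngar < 0:
            raise ValueError("GAR and NGAR must be nonnegative")


@dataclass(frozen=True)
class BatchObservation:
    """One batch experiment: photon uptakes by wavelength and growth rate.

    630 nm photons are absorbed by phycobilisomes (PSII channel); 680 nm by
    chlorophyll a (PSI channel).  All rates in mmol/gAFDW/h (growth in 1/h).
    """

    photon_uptake_630: float
    photon_uptake_680: float
    growth_rate: float

    def __post_init__(self) -> None:
        if min(self.photon_uptake_630, self.photon_uptake_680,
               self.growth_rate) < 0:
            raise ValueError("batch observations must be nonnegative")


def estimate_atp_requirements(network: Model,
                              batches: list[BatchObservation],
                              maintenance_id: str = "ATPM",
                              psii_exchange: str = "EX_photon_psii_e",
                              psi_exchange: str = "EX_photon_psi_e",
                              biomass_id: str | None = None,
                              ) -> EnergyParameters:
    """Estimate (GAR, NGAR) by the max-ATP-hydrolysis regression.

    The network should carry a polymerization-only biomass equation (no GAR
    folded in) and an unconstrained maintenance reaction.  Requires at least
    two batches with distinct growth rates.
    """
    if len(batches) < 2 or len({b.growth_rate for b in batches}) < 2:
        raise ValueError("need >= 2 batches with distinct growth rates")
    if biomass_id is None:
        from .fba import _objective_reaction_id
        biomass_id = _objective_reaction_id(network)
    growths, atpm = [], []
    for i, b in enumerate(batches):
        with network as m:
            m.reactions.get_by_id(biomass_id).bounds = (b.growth_rate,
                                                        b.growth_rate)
            m.reactions.get_by_id(psii_exchange).bounds = (
                b.photon_uptake_630, b.photon_uptake_630)
            m.reactions.get_by_id(psi_exchange).bounds = (
                b.photon_uptake_680, b.photon_uptake_680)
            m.objective = m.reactions.get_by_id(maintenance_id)
            m.objective_direction = "max"
            val = m.slim_optimize(error_value=np.nan)
        if not np.isfinite(val):
            raise RuntimeError(f"batch {i} (growth {b.growth_rate}, photons "
                               f"{b.photon_uptake_630}/{b.photon_uptake_680}) "
                               "is infeasible")
        growths.append(b.growth_rate)
        atpm.append(val)
    slope, intercept = np.polyfit(growths, atpm, 1)
    if intercept < 0:
        warnings.warn(f"fitted NGAR {intercept:.3g} < 0; clamped to 0",
                      stacklevel=2)
        intercept = 0.0
    return EnergyParameters(gar=float(max(slope, 0.0)),
                            ngar=float(intercept))


def apply_energy_parameters(network: Model, params: EnergyParameters,
                            maintenance_id: str = "ATPM",
                            biomass_id: str | None = None,
                            species: dict[str, str] = DEFAULT_SPECIES,
                            ) -> Model:
    """Install (GAR, NGAR) into a copy of the network.

    NGAR becomes the lower bound of the maintenance hydrolysis flux; GAR is
    folded into the biomass reaction's ATP hydrolysis terms.  Apply to a
    polymerization-only biomass equation (the function adds, it does not
    replace).
    """
    out = network.copy()
    try:
        atpm = out.reactions.get_by_id(maintenance_id)
    except KeyError:
        raise KeyError(f"network has no maintenance reaction {maintenance_id!r}")
    atpm.lower_bound = params.ngar
    if biomass_id is None:
        from .fba import _objective_reaction_id
        biomass_id = _objective_reaction_id(out)
    biomass = out.reactions.get_by_id(biomass_id)
    if params.gar:
        mets = {out.metabolites.get_by_id(species["atp"]): -params.gar,
                out.metabolites.get_by_id(species["h2o"]): -params.gar,
                out.metabolites.get_by_id(species["adp"]): params.gar,
                out.metabolites.get_by_id(species["pi"]): params.gar,
                out.metabolites.get_by_id(species["h"]): params.gar}
        biomass.add_metabolites(mets, combine=True)
    return out


def predict_batch_growth(network: Model, batch: BatchObservation,
                         mode: str = "split",
                         psii_exchange: str = "EX_photon_psii_e",
                         psi_exchange: str = "EX_photon_psi_e") -> float:
    """Maximal growth under a batch's photon constraints.

    ``mode='split'`` fixes each photosystem's uptake to its wavelength
    channel; ``mode='total'`` constrains only the summed photon uptake (the
    convention for single-wavelength experiments, where one lamp still
    drives both photosystems).
    """
    from .fba import add_flux_sum_constraint

    with network as m:
        if mode == "split":
            m.reactions.get_by_id(psii_exchange).bounds = (
                batch.photon_uptake_630, batch.photon_uptake_630)
            m.reactions.get_by_id(psi_exchange).bounds = (
                batch.photon_uptake_680, batch.photon_uptake_680)
        elif mode == "total":
            total = batch.photon_uptake_630 + batch.photon_uptake_680
            add_flux_sum_constraint(m, [psii_exchange, psi_exchange], total,
                                    name="total_photon_uptake")
        else:
            raise ValueError("mode must be 'split' or 'total'")
        growth = m.slim_optimize(error_value=np.nan)
    return float(growth)


@dataclass
class DarkFixationResult:
    """Yields of the dark N2-fixation snapshot (all per mol glycogen unit)."""

    n2_per_glycogen: float
    h2_per_glycogen: float
    o2_per_n2: float
    cyanophycin_per_glycogen: float
    #: N2 fixation implied by cyanophycin nitrogen content (cross-check
    #: against the nitrogenase-flux-based yield above)
    n2_per_glycogen_from_cyanophycin: float
    pathway_fluxes: dict[str, float] = field(default_factory=dict)


def dark_n2_fixation(network: Model, glycogen_flux_cap: float,
                     remove_hydrogenases: bool = True,
                     ngar: float = 0.0,
                     objective: str = "cyanophycin",
                     photon_exchanges: tuple[str, ...] = (
                         "EX_photon_psii_e", "EX_photon_psi_e"),
                     glycogen_source: str = "GLYC_SRC",
                     cyanophycin_demand: str = "DM_cph_c",
                     nitrogenase: str = "NIF",
                     hydrogenase_ids: tuple[str, ...] = (
                         "HDH_1", "HDH_2", "UPHYDR"),
                     h2_exchange: str = "EX_h2_e",
                     o2_exchange: str = "EX_o2_e",
                     nh3_exchange: str = "EX_nh3_e",
                     maintenance_id: str = "ATPM",
                     n_per_cyanophycin: float = 2.0,
                     pathway_reactions: tuple[str, ...] = (
                         "COX", "QOX", "MEHLER_NADPH", "MEHLER_FD",
                         "NDH1", "NDH2", "FDPQ"),
                     ) -> DarkFixationResult:
    """Dark, N2-fixing snapshot: maximize cyanophycin (or N2 fixation)
    from a capped glycogen supply.

    Photon uptakes and growth are zero, ammonium uptake is closed so all
    nitrogen comes through nitrogenase, and maintenance hydrolysis runs at
    ``ngar``.  With hydrogenases present the nitrogenase-produced H2 is
    recycled; removing them forces H2 export at the nitrogenase ratio.
    """
    if glycogen_flux_cap < 0:
        raise ValueError("glycogen_flux_cap must be >= 0")
    with network as m:
        for rid in photon_exchanges:
            m.reactions.get_by_id(rid).bounds = (0.0, 0.0)
        m.reactions.get_by_id(nh3_exchange).lower_bound = 0.0
        from .fba import _objective_reaction_id
        m.reactions.get_by_id(_objective_reaction_id(m)).bounds = (0.0, 0.0)
        m.reactions.get_by_id(glycogen_source).bounds = (0.0, glycogen_flux_cap)
        atpm = m.reactions.get_by_id(maintenance_id)
        atpm.bounds = (ngar, max(ngar, atpm.upper_bound))
        if remove_hydrogenases:
            for rid in hydrogenase_ids:
                if rid in m.reactions:
                    m.reactions.get_by_id(rid).bounds = (0.0, 0.0)
        target = (cyanophycin_demand if objective == "cyanophycin"
                  else nitrogenase)
        m.objective = m.reactions.get_by_id(target)
        m.objective_direction = "max"
        best = m.slim_optimize(error_value=np.nan)
        if not np.isfinite(best):
            raise RuntimeError(
                f"dark N2-fixing condition infeasible at NGAR={ngar}")
        # representative distribution at the optimum, without avoidable cycles
        m.reactions.get_by_id(target).bounds = (best, best)
        dist = minimize_flux_norm(m)
    v = dist.values
    glyc = float(v.get(glycogen_source, 0.0))
    if glyc <= 1e-12:
        zero = 0.0
        return DarkFixationResult(zero, zero, float("nan"), zero, zero,
                                  {r: 0.0 for r in pathway_reactions
                                   if r in v.index})
    n2 = float(v.get(nitrogenase, 0.0))
    h2 = float(v.get(h2_exchange, 0.0))
    cph = float(v.get(cyanophycin_demand, 0.0))
    o2_uptake = max(0.0, -float(v.get(o2_exchange, 0.0)))
    return DarkFixationResult(
        n2_per_glycogen=n2 / glyc,
        h2_per_glycogen=h2 / glyc,
        o2_per_n2=(o2_uptake / n2) if n2 > 1e-12 else float("nan"),
        cyanophycin_per_glycogen=cph / glyc,
        n2_per_glycogen_from_cyanophycin=cph * n_per_cyanophycin / 2.0 / glyc,
        pathway_fluxes={r: float(v.get(r, 0.0)) for r in pathway_reactions
                        if r in v.index})


def photon_flux_from_irradiance(consumption_rate: float, area: float,
                                biomass: float) -> float:
    """Convert a light consumption rate to a biomass-specific photon flux.

    consumption_rate [umol photon/m2/s] x area [m2] / biomass [g AFDW],
    converted to mmol/gAFDW/h (x3600 s/h, /1000 umol/mmol).
    """
    if biomass <= 0 or area <= 0:
        raise ValueError("area and biomass must be positive")
    if consumption_rate < 0:
        raise ValueError("consumption rate must be nonnegative")
    return consumption_rate * area * 3600.0 / 1000.0 / biomass


def batches_to_table(batches: list[BatchObservation]) -> pd.DataFrame:
    """Tab-separated-ready frame mirroring the batch-experiment layout."""
    return pd.DataFrame(
        [{"batch": i + 1, "uptake_630": b.photon_uptake_630,
          "uptake_680": b.photon_uptake_680, "growth": b.growth_rate}
         for i, b in enumerate(batches)])


def batches_from_table(df: pd.DataFrame) -> list[BatchObservation]:
    return [BatchObservation(photon_uptake_630=row["uptake_630"],
                             photon_uptake_680=row["uptake_680"],
                             growth_rate=row["growth"])
            for _, row in df.iterrows()]
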