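"""Desk-scale synthetic fixtures.

Three generators with the structure the analyses assume:

* :func:`make_toy_network` -- a ~40-reaction phototroph with two photosystems,
  linear and cyclic electron transport, terminal oxidases, Mehler reactions,
  nitrogenase and hydrogenases, and glycogen/cyanophycin storage.  The
  topology follows the canonical cyanobacterial thylakoid chain
  (PSII -> Pq -> cyt b6f -> Pc -> PSI -> Fd -> FNR -> NADPH, with FdPq cyclic
  return, NDH-1/NDH-2 feeding the quinone pool, and COX/QOX reducing O2).
* :func:`simulate_expression` -- per-gene protein detection calls and log2
  mRNA levels correlated with a known flux state.
* :func:`simulate_batches` -- batch growth/photon-uptake observations
  generated from known ATP-requirement parameters plus multiplicative noise.

The toy is a structural analogue, not a quantitative surrogate, of a
genome-scale cyanobacterial model: proton stoichiometries are textbook-like
integers chosen so that the qualitative orderings (COX pumps more than QOX,
NDH-1 pumps while NDH-2 does not, cyclic flow trades reductant for ATP) hold.

Electron bookkeeping uses metabolite charges: a reduced carrier differs from
its oxidized form by -1 charge (Pc, Fd) or by one H and the matching charge
(NAD(P)H, PqH2), so every internal reaction is element- and charge-balanced
and can be audited.  Photons are massless, chargeless species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from cobra import Metabolite, Model, Reaction

from .energetics import BatchObservation, EnergyParameters, apply_energy_parameters
from .tpd import ExpressionEvidence

__all__ = [
    "ToyNetworkSpec",
    "ToyIncludeFlags",
    "SyntheticExpressionSpec",
    "SyntheticBatchSpec",
    "UnviableSpecError",
    "make_toy_network",
    "simulate_expression",
    "simulate_batches",
    "TOY_SPECIES",
    "TOY_ETC_REACTIONS",
    "TOY_CENTRAL_REACTIONS",
    "TOY_HYDROGENASES",
    "TOY_CYCLIC_SET",
    "TOY_SINK_SET",
]


class UnviableSpecError(ValueError):
    """The requested feature-flag combination admits no path to biomass."""


@dataclass(frozen=True)
class ToyIncludeFlags:
    """Feature switches for optional electron routes and storage pools."""

    cyclic_fdpq: bool = True
    ndh2: bool = True
    qox: bool = True
    mehler: bool = True
    nitrogenase: bool = True
    hydrogenases: bool = True
    glycogen: bool = True
    cyanophycin: bool = True


@dataclass(frozen=True)
class ToyNetworkSpec:
    """Stoichiometric knobs of the toy phototroph.

    Proton numbers are H+ translocated into the thylakoid lumen per two
    electrons; ``protons_per_atp`` is the ATP-synthase coupling ratio.
    """

    proton_per_psii: float = 2.0
    proton_per_cytb6f: float = 4.0
    proton_per_ndh1: float = 4.0
    proton_per_cox: float = 4.0
    proton_per_qox: float = 2.0
    protons_per_atp: float = 4.0
    include: ToyIncludeFlags = field(default_factory=ToyIncludeFlags)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "proton_per_psii",
            "proton_per_cytb6f",
            "proton_per_ndh1",
            "proton_per_cox",
            "proton_per_qox",
            "protons_per_atp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.proton_per_cytb6f < 2:
            raise ValueError("proton_per_cytb6f must be >= 2 (quinol protons)")


#: canonical metabolite ids of the toy, used as the default species map
TOY_SPECIES = {
    "atp": "atp_c",
    "adp": "adp_c",
    "pi": "pi_c",
    "h": "h_c",
    "h2o": "h2o_c",
    "nadp": "nadp_c",
    "nadph": "nadph_c",
}

#: photosynthetic/respiratory electron-transport reactions of the toy
TOY_ETC_REACTIONS = (
    "PSII",
    "CYTB6F",
    "PSI",
    "FNR",
    "FDPQ",
    "NDH1",
    "NDH2",
    "COX",
    "QOX",
    "MEHLER_NADPH",
    "MEHLER_FD",
    "ATPASE",
)

#: central carbon metabolism of the toy (flux-span reporting set)
TOY_CENTRAL_REACTIONS = (
    "CBB",
    "BM_OX",
    "TRANSH",
    "GLYCSYN",
    "GLYCDEG",
    "ORGSEC",
    "CPHSYN",
)

TOY_HYDROGENASES = ("HDH_1", "HDH_2", "UPHYDR")
#: cyclic electron-transport routes (analogue of the NDH/FdPq removal set)
TOY_CYCLIC_SET = ("FDPQ", "NDH1", "NDH2")
#: alternative reductant sinks (H2 production, oxidases, Mehler)
TOY_SINK_SET = ("COX", "QOX", "MEHLER_NADPH", "MEHLER_FD",
                "HDH_1", "HDH_2", "UPHYDR", "EX_h2_e")

#: biomass demand per gram ash-free dry weight (mmol/g)
_BIOMASS_BM = 30.0
_BIOMASS_NH3 = 5.0
_BIOMASS_ATP_POLY = 20.0  # polymerization-only cost; GAR is added separately
_BIOMASS_NADPH = 10.0


def _metabolites() -> dict[str, Metabolite]:
    spec = [
        # id, name, formula, charge
        ("photon_psii_e", "photon (PSII-absorbed)", "", 0),
        ("photon_psi_e", "photon (PSI-absorbed)", "", 0),
        ("h2o_c", "water", "H2O", 0),
        ("o2_c", "oxygen", "O2", 0),
        ("co2_c", "carbon dioxide", "CO2", 0),
        ("n2_c", "dinitrogen", "N2", 0),
        ("h2_c", "dihydrogen", "H2", 0),
        ("nh3_c", "ammonia", "H3N", 0),
        ("pi_c", "phosphate", "HO4P", 0),
        ("h_c", "proton (cytoplasm)", "H", 1),
        ("h_t", "proton (thylakoid lumen)", "H", 1),
        ("pq_c", "plastoquinone", "Pq", 0),
        ("pqh2_c", "plastoquinol", "PqH2", 0),
        ("pcox_c", "plastocyanin (oxidized)", "Pc", 0),
        ("pcred_c", "plastocyanin (reduced)", "Pc", -1),
        ("fdox_c", "ferredoxin (oxidized)", "Fd", 0),
        ("fdred_c", "ferredoxin (reduced)", "Fd", -1),
        ("nad_c", "NAD+", "Xn", 1),
        ("nadh_c", "NADH", "XnH", 0),
        ("nadp_c", "NADP+", "Xp", 1),
        ("nadph_c", "NADPH", "XpH", 0),
        ("adp_c", "ADP", "Xa", -1),
        ("atp_c", "ATP", "XaO3P", 0),
        ("bm_c", "fixed-carbon precursor", "CH2O", 0),
        ("org_c", "organic by-product", "C2H4O2", 0),
        ("glycogen_c", "glycogen (glucosyl unit)", "C6H10O5", 0),
        ("cph_c", "cyanophycin (monomer unit)", "C4H10N2O2", 0),
    ]
    mets = {}
    for mid, name, formula, charge in spec:
        compartment = "t" if mid.endswith("_t") else ("e" if mid.endswith("_e") else "c")
        m = Metabolite(mid, name=name, formula=formula, charge=charge,
                       compartment=compartment)
        mets[mid] = m
    return mets


def _rxn(model: Model, mets: dict[str, Metabolite], rid: str, name: str,
         stoich: dict[str, float], lb: float, ub: float,
         gpr: str = "", subsystem: str = "") -> Reaction:
    r = Reaction(rid, name=name, lower_bound=lb, upper_bound=ub)
    r.subsystem = subsystem
    model.add_reactions([r])
    r.add_metabolites({mets[k]: v for k, v in stoich.items() if v != 0})
    if gpr:
        r.gene_reaction_rule = gpr
    return r


def make_toy_network(spec: ToyNetworkSpec | None = None) -> Model:
    """Build the toy phototroph as a :class:`cobra.Model`.

    The returned model grows photoautotrophically when both photon exchanges
    are open and shows a three-region phenotypic phase plane over the two
    photon uptake fluxes for the default coefficients.

    Raises
    ------
    UnviableSpecError
        if the feature-flag combination leaves no route to biomass.
    """
    spec = spec or ToyNetworkSpec()
    inc = spec.include
    model = Model("toy_phototroph")
    mets = _metabolites()

    p2, pb6f = spec.proton_per_psii, spec.proton_per_cytb6f
    pndh, pcox, pqox = spec.proton_per_ndh1, spec.proton_per_cox, spec.proton_per_qox
    natp = spec.protons_per_atp

    # --- photon supply (import-positive exchanges) ---
    _rxn(model, mets, "EX_photon_psii_e", "PSII photon supply",
         {"photon_psii_e": 1}, 0, 1000, subsystem="Exchange")
    _rxn(model, mets, "EX_photon_psi_e", "PSI photon supply",
         {"photon_psi_e": 1}, 0, 1000, subsystem="Exchange")

    # --- electron transport chain (per 2 e-) ---
    _rxn(model, mets, "PSII", "photosystem II (water-splitting)",
         {"photon_psii_e": -2, "h2o_c": -1, "pq_c": -1, "h_c": -p2,
          "o2_c": 0.5, "pqh2_c": 1, "h_t": p2},
         0, 1000, gpr="(tg_psbA1 or tg_psbA2) and tg_psbB", subsystem="ETC")
    _rxn(model, mets, "CYTB6F", "cytochrome b6f complex",
         {"pqh2_c": -1, "pcox_c": -2, "h_c": -(pb6f - 2),
          "pq_c": 1, "pcred_c": 2, "h_t": pb6f},
         0, 1000, gpr="tg_petB and tg_petD", subsystem="ETC")
    _rxn(model, mets, "PSI", "photosystem I",
         {"photon_psi_e": -2, "pcred_c": -2, "fdox_c": -2,
          "pcox_c": 2, "fdred_c": 2},
         0, 1000, gpr="tg_psaA and tg_psaB", subsystem="ETC")
    _rxn(model, mets, "FNR", "ferredoxin:NADP+ reductase",
         {"fdred_c": -2, "nadp_c": -1, "h_c": -1, "fdox_c": 2, "nadph_c": 1},
         -1000, 1000, gpr="tg_petH", subsystem="ETC")
    if inc.cyclic_fdpq:
        _rxn(model, mets, "FDPQ", "ferredoxin-plastoquinone reductase (cyclic)",
             {"fdred_c": -2, "pq_c": -1, "h_c": -2, "fdox_c": 2, "pqh2_c": 1},
             0, 1000, gpr="tg_pgr5", subsystem="ETC")
    _rxn(model, mets, "NDH1", "NADH dehydrogenase type 1 (proton-pumping)",
         {"nadh_c": -1, "pq_c": -1, "h_c": -(1 + pndh),
          "nad_c": 1, "pqh2_c": 1, "h_t": pndh},
         0, 1000, gpr="tg_ndhF and tg_ndhD", subsystem="ETC")
    if inc.ndh2:
        _rxn(model, mets, "NDH2", "NADH dehydrogenase type 2 (non-pumping)",
             {"nadh_c": -1, "pq_c": -1, "h_c": -1, "nad_c": 1, "pqh2_c": 1},
             0, 1000, gpr="tg_ndbA", subsystem="ETC")
    _rxn(model, mets, "COX", "cytochrome c oxidase",
         {"pcred_c": -2, "o2_c": -0.5, "h_c": -(pcox + 2),
          "pcox_c": 2, "h2o_c": 1, "h_t": pcox},
         0, 1000, gpr="tg_coxA and tg_coxB", subsystem="ETC")
    if inc.qox:
        _rxn(model, mets, "QOX", "quinol oxidase",
             {"pqh2_c": -1, "o2_c": -0.5, "h_c": -pqox,
              "pq_c": 1, "h2o_c": 1, "h_t": pqox},
             0, 1000, gpr="tg_cydA or tg_qoxA", subsystem="ETC")
    if inc.mehler:
        _rxn(model, mets, "MEHLER_NADPH", "Mehler reaction (NADPH-dependent)",
             {"nadph_c": -1, "o2_c": -0.5, "h_c": -1, "nadp_c": 1, "h2o_c": 1},
             0, 1000, gpr="tg_flv1", subsystem="ETC")
        _rxn(model, mets, "MEHLER_FD", "Mehler reaction (ferredoxin-dependent)",
             {"fdred_c": -2, "o2_c": -0.5, "h_c": -2, "fdox_c": 2, "h2o_c": 1},
             0, 1000, gpr="tg_flv3", subsystem="ETC")
    _rxn(model, mets, "ATPASE", "ATP synthase",
         {"adp_c": -1, "pi_c": -1, "h_t": -natp,
          "atp_c": 1, "h2o_c": 1, "h_c": natp - 1},
         0, 1000, gpr="tg_atpA and tg_atpB", subsystem="ETC")
    _rxn(model, mets, "ATPM", "ATP maintenance hydrolysis",
         {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1},
         0, 1000, subsystem="Maintenance")

    # --- carbon and nitrogen metabolism (lumped) ---
    _rxn(model, mets, "CBB", "Calvin-Benson cycle (lumped CO2 fixation)",
         {"co2_c": -1, "atp_c": -3, "nadph_c": -2, "h2o_c": -2,
          "bm_c": 1, "adp_c": 3, "pi_c": 3, "nadp_c": 2, "h_c": 1},
         0, 1000, gpr="tg_rbcL and tg_prkB", subsystem="Central")
    _rxn(model, mets, "BM_OX", "precursor oxidation (lumped glycolysis+TCA)",
         {"bm_c": -1, "h2o_c": -1, "nad_c": -2,
          "co2_c": 1, "nadh_c": 2, "h_c": 2},
         0, 1000, gpr="tg_gapA", subsystem="Central")
    _rxn(model, mets, "TRANSH", "transhydrogenase",
         {"nadph_c": -1, "nad_c": -1, "nadp_c": 1, "nadh_c": 1},
         -1000, 1000, gpr="tg_pntA", subsystem="Central")
    _rxn(model, mets, "ORGSEC", "substrate-level organic by-product formation",
         {"bm_c": -2, "adp_c": -1, "pi_c": -1, "h_c": -1,
          "org_c": 1, "atp_c": 1, "h2o_c": 1},
         0, 1000, subsystem="Central")
    if inc.glycogen:
        _rxn(model, mets, "GLYCSYN", "glycogen synthesis",
             {"bm_c": -6, "atp_c": -1,
              "glycogen_c": 1, "adp_c": 1, "pi_c": 1, "h_c": 1},
             0, 1000, gpr="tg_glgA", subsystem="Central")
        _rxn(model, mets, "GLYCDEG", "glycogen mobilization",
             {"glycogen_c": -1, "h2o_c": -1, "bm_c": 6},
             0, 1000, gpr="tg_glgP", subsystem="Central")
        # demand/source pair used by the dark N2-fixation analysis; the
        # source stays closed unless an analysis opens it
        _rxn(model, mets, "DM_glycogen_c", "glycogen accumulation (demand)",
             {"glycogen_c": -1}, 0, 1000, subsystem="Storage")
        _rxn(model, mets, "GLYC_SRC", "glycogen mobilization source",
             {"glycogen_c": 1}, 0, 0, subsystem="Storage")
    if inc.cyanophycin:
        _rxn(model, mets, "CPHSYN", "cyanophycin synthetase (lumped)",
             {"bm_c": -4, "nh3_c": -2, "atp_c": -2,
              "cph_c": 1, "adp_c": 2, "pi_c": 2, "h_c": 2},
             0, 1000, gpr="tg_cphA", subsystem="Storage")
        _rxn(model, mets, "DM_cph_c", "cyanophycin accumulation (demand)",
             {"cph_c": -1}, 0, 1000, subsystem="Storage")
    if inc.nitrogenase:
        _rxn(model, mets, "NIF", "nitrogenase (Mo-Fe)",
             {"n2_c": -1, "fdred_c": -8, "atp_c": -16, "h2o_c": -16,
              "nh3_c": 2, "h2_c": 1, "fdox_c": 8, "adp_c": 16, "pi_c": 16,
              "h_c": 8},
             0, 1000, gpr="tg_nifH and tg_nifD", subsystem="Nitrogen")
    if inc.hydrogenases:
        _rxn(model, mets, "HDH_1", "bidirectional hydrogenase (NAD)",
             {"h2_c": -1, "nad_c": -1, "nadh_c": 1, "h_c": 1},
             -1000, 1000, gpr="tg_hoxH", subsystem="Nitrogen")
        _rxn(model, mets, "HDH_2", "bidirectional hydrogenase (NADP)",
             {"h2_c": -1, "nadp_c": -1, "nadph_c": 1, "h_c": 1},
             -1000, 1000, gpr="tg_hoxY", subsystem="Nitrogen")
        _rxn(model, mets, "UPHYDR", "uptake hydrogenase (ferredoxin)",
             {"h2_c": -1, "fdox_c": -2, "fdred_c": 2, "h_c": 2},
             0, 1000, gpr="tg_hupL", subsystem="Nitrogen")

    # --- biomass (polymerization-only ATP; GAR is installed separately) ---
    _rxn(model, mets, "BIOMASS", "biomass production",
         {"bm_c": -_BIOMASS_BM, "nh3_c": -_BIOMASS_NH3,
          "atp_c": -_BIOMASS_ATP_POLY, "h2o_c": -_BIOMASS_ATP_POLY,
          "nadph_c": -_BIOMASS_NADPH,
          "adp_c": _BIOMASS_ATP_POLY, "pi_c": _BIOMASS_ATP_POLY,
          "h_c": _BIOMASS_ATP_POLY, "nadp_c": _BIOMASS_NADPH},
         0, 1000, subsystem="Biomass")

    # --- inorganic exchanges (cobra convention: uptake negative) ---
    for rid, mid, lb, ub in [
        ("EX_co2_e", "co2_c", -1000, 1000),
        ("EX_o2_e", "o2_c", -1000, 1000),
        ("EX_nh3_e", "nh3_c", -1000, 1000),
        ("EX_n2_e", "n2_c", -1000, 1000),
        ("EX_h2_e", "h2_c", 0, 1000),
        ("EX_h2o_e", "h2o_c", -1000, 1000),
        ("EX_pi_e", "pi_c", -1000, 1000),
        ("EX_h_e", "h_c", -1000, 1000),
        ("EX_org_e", "org_c", 0, 1000),
    ]:
        if mid == "h2_c" and not (inc.nitrogenase or inc.hydrogenases):
            continue
        _rxn(model, mets, rid, f"{mets[mid].name} exchange",
             {mid: -1}, lb, ub, subsystem="Exchange")

    model.objective = "BIOMASS"

    with model:
        growth = model.slim_optimize(error_value=0.0)
    if not np.isfinite(growth) or growth <= 1e-9:
        raise UnviableSpecError(
            "toy network spec admits no photoautotrophic growth "
            f"(flags: {inc})")
    return model


# ---------------------------------------------------------------------------
# expression evidence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticExpressionSpec:
    """Generative model for protein-detection calls and log2 mRNA levels.

    Genes of reactions carrying flux in ``true_flux`` are detected with
    probability ``detect_prob_active`` and their mRNA is drawn around
    ``mrna_mean_active``; genes of silent reactions use the inactive
    parameters.  Defaults emulate high-coverage proteomics (90% detection of
    expressed enzymes, 5% spurious detection) with well-separated mRNA modes
    on the log2 scale.
    """

    true_flux: dict[str, float]
    detect_prob_active: float = 0.9
    detect_prob_inactive: float = 0.05
    mrna_mean_active: float = 11.0
    mrna_mean_inactive: float = 5.0
    mrna_sd: float = 1.0
    active_flux_threshold: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.detect_prob_active, self.detect_prob_inactive):
            if not 0.0 <= p <= 1.0:
                raise ValueError("detection probabilities must be in [0, 1]")
        if self.mrna_sd < 0:
            raise ValueError("mrna_sd must be >= 0")


def simulate_expression(network: Model,
                        spec: SyntheticExpressionSpec) -> ExpressionEvidence:
    """Draw gene-level evidence from a known flux state (seeded)."""
    rng = np.random.default_rng(spec.seed)
    active_genes: set[str] = set()
    for rxn in network.reactions:
        if abs(spec.true_flux.get(rxn.id, 0.0)) > spec.active_flux_threshold:
            active_genes.update(g.id for g in rxn.genes)
    detected: set[str] = set()
    mrna: dict[str, float] = {}
    for gene in sorted(g.id for g in network.genes):
        is_active = gene in active_genes
        p = spec.detect_prob_active if is_active else spec.detect_prob_inactive
        if rng.random() < p:
            detected.add(gene)
        mean = spec.mrna_mean_active if is_active else spec.mrna_mean_inactive
        mrna[gene] = float(mean + spec.mrna_sd * rng.standard_normal())
    return ExpressionEvidence(protein_detected=frozenset(detected),
                              mrna_log2=mrna, mrna_threshold=8.0)


# ---------------------------------------------------------------------------
# batch observations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticBatchSpec:
    """Generative model for batch growth observations.

    ``photon_grid`` pairs are (PSII, PSI) uptakes in mmol/gAFDW/h; the default
    grid stays in the dual-limitation regime of the toy phase plane, where
    photon supply translates tightly into ATP so the requirement parameters
    are identifiable.  ``noise_cv`` is the coefficient of variation of a
    batch-level multiplicative measurement error applied to the whole
    observation vector (growth and both photon uptakes) — emulating the
    shared ash-free-dry-weight normalization error that dominates
    per-biomass rate measurements.
    """

    true_gar: float = 50.0
    true_ngar: float = 1.0
    n_batches: int = 8
    photon_grid: tuple[tuple[float, float], ...] = ()
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_batches < 2:
            raise ValueError("need at least two batches")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not self.photon_grid:
            # equal PSII/PSI uptakes from 10 to 60: inside the toy's
            # dual-limited phase-plane region
            levels = np.linspace(10.0, 60.0, self.n_batches)
            object.__setattr__(
                self, "photon_grid",
                tuple((float(v), float(v)) for v in levels))


def simulate_batches(spec: SyntheticBatchSpec,
                     network: Model) -> list[BatchObservation]:
    """FBA-generated batch observations under known (GAR, NGAR) + noise.

    The 630 nm channel maps to PSII (phycobilisome absorption) and the
    680 nm channel to PSI (chlorophyll a), as in the photobioreactor
    convention the analyses assume.
    """
    rng = np.random.default_rng(spec.seed)
    params = EnergyParameters(gar=spec.true_gar, ngar=spec.true_ngar)
    energized = apply_energy_parameters(network, params)
    out: list[BatchObservation] = []
    for psii, psi in spec.photon_grid[: spec.n_batches]:
        with energized as m:
            m.reactions.EX_photon_psii_e.bounds = (psii, psii)
            m.reactions.EX_photon_psi_e.bounds = (psi, psi)
            growth = m.slim_optimize(error_value=np.nan)
        if not np.isfinite(growth):
            warnings.warn(f"photon pair ({psii}, {psi}) infeasible; skipped")
            continue
        scale = max(0.0, 1.0 + spec.noise_cv * rng.standard_normal())
        out.append(BatchObservation(photon_uptake_630=float(psii * scale),
                                    photon_uptake_680=float(psi * scale),
                                    growth_rate=float(growth * scale)))
    return out
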