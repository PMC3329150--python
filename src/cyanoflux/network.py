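"""Model I/O, validation, and biomass-equation construction.

The in-memory network container is :class:`cobra.Model` (stoichiometry,
bounds, reversibility, boolean gene-protein-reaction rules, objective);
SBML is read and written through cobrapy/libSBML, which accepts both the
legacy Level 2 dialect (bounds in kinetic-law parameters) and Level 3 with
the fbc extension, and always emits Level 3 + fbc.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import cobra
import pandas as pd
import yaml
from cobra import Metabolite, Model, Reaction
from cobra.io import read_sbml_model, write_sbml_model

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_SPECIES",
    "BiomassComposition",
    "read_sbml",
    "write_sbml",
    "validate_network",
    "mass_balance_audit",
    "reaction_counts",
    "delete_reactions",
    "build_biomass_equation",
    "load_biomass_composition",
    "save_biomass_composition",
    "load_monomer_table",
    "write_reaction_table",
    "write_metabolite_table",
]

#: energy/redox currency metabolite ids assumed by biomass construction and
#: the artificial-reaction diagnostics; override for models with other ids
DEFAULT_SPECIES = {
    "atp": "atp_c",
    "adp": "adp_c",
    "pi": "pi_c",
    "h": "h_c",
    "h2o": "h2o_c",
    "nadp": "nadp_c",
    "nadph": "nadph_c",
}


def read_sbml(path) -> Model:
    """Read an SBML model (L2 kinetic-law bounds or L3+fbc).

    Missing flux bounds are defaulted by libSBML/cobra to the conventional
    big-M box ([0, 1000] irreversible, [-1000, 1000] reversible) and the
    defaulting is logged.
    """
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model = read_sbml_model(str(path))
        for w in caught:
            logger.info("SBML read: %s", w.message)
    except Exception as exc:  # libSBML reports the offending line in its log
        raise ValueError(f"could not parse SBML file {path}: {exc}") from exc
    return model


def write_sbml(network: Model, path) -> None:
    """Write the network as SBML Level 3 + fbc."""
    problems = validate_network(network)
    if problems:
        raise ValueError("refusing to write invalid network: "
                         + "; ".join(problems))
    write_sbml_model(network, str(path))


def validate_network(network: Model) -> list[str]:
    """Check container invariants; returns a list of problems (empty = ok)."""
    problems = []
    for rxn in network.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            problems.append(f"{rxn.id}: lower bound exceeds upper bound")
    from cobra.util.solver import linear_reaction_coefficients
    if not linear_reaction_coefficients(network):
        problems.append("no objective reaction set")
    return problems


def mass_balance_audit(network: Model, tol: float = 1e-6,
                       exempt: tuple[str, ...] = ()) -> pd.DataFrame:
    """Elemental/charge balance of internal reactions with full formulas.

    Exchange, demand/sink, and biomass (objective) reactions are exempt, as
    are reactions touching a metabolite with no formula.  Returns a tidy
    frame of violations (reaction, element, imbalance); empty means clean.
    """
    from cobra.util.solver import linear_reaction_coefficients
    objective_ids = {r.id for r in linear_reaction_coefficients(network)}
    rows = []
    for rxn in network.reactions:
        if rxn.boundary or rxn.id in exempt or rxn.id in objective_ids:
            continue
        if any(m.formula is None for m in rxn.metabolites):
            continue
        for element, imbalance in rxn.check_mass_balance().items():
            if abs(imbalance) > tol:
                rows.append({"reaction": rxn.id, "element": str(element),
                             "imbalance": float(imbalance)})
    return pd.DataFrame(rows, columns=["reaction", "element", "imbalance"])


def reaction_counts(network: Model) -> dict[str, int]:
    """Reaction totals with and without exchange (boundary) reactions."""
    n_exchange = sum(1 for r in network.reactions if r.boundary)
    return {
        "total": len(network.reactions),
        "exchange": n_exchange,
        "metabolic_and_transport": len(network.reactions) - n_exchange,
        "genes": len(network.genes),
    }


def delete_reactions(network: Model, ids) -> Model:
    """Copy of the network lacking the given reactions; original untouched."""
    ids = list(ids)
    missing = [i for i in ids if i not in network.reactions]
    if missing:
        raise KeyError(f"unknown reaction id(s): {missing}")
    from cobra.util.solver import linear_reaction_coefficients
    objective_ids = {r.id for r in linear_reaction_coefficients(network)}
    out = network.copy()
    if objective_ids & set(ids):
        warnings.warn("deleting the objective reaction; network left without "
                      "an objective", stacklevel=2)
    out.remove_reactions([out.reactions.get_by_id(i) for i in ids])
    return out


# ---------------------------------------------------------------------------
# biomass equation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiomassComposition:
    """Macromolecular mass fractions of ash-free dry weight.

    ``fractions`` maps macromolecule name (protein, carbohydrate, lipid,
    RNA, DNA, cyanophycin, pigment, ...) to g per g AFDW; the closure must
    lie within [0.95, 1.05] to absorb measurement error.
    """

    fractions: dict[str, float]
    amino_acid_profile: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError("fractions must be nonnegative")
        total = sum(self.fractions.values())
        if not 0.95 <= total <= 1.05:
            raise ValueError(f"composition closure {total:.3f} outside "
                             "[0.95, 1.05]")


def build_biomass_equation(composition: BiomassComposition,
                           monomer_table: dict[str, dict[str, float]],
                           gar: float = 0.0,
                           species: dict[str, str] = DEFAULT_SPECIES,
                           network: Model | None = None,
                           reaction_id: str = "BIOMASS") -> Reaction:
    """Assemble a biomass drain from measured composition.

    ``monomer_table`` maps each macromolecule to its precursor demand in
    mmol per g of that macromolecule (positive = consumed, negative =
    released, e.g. ADP from polymerization ATP already spent elsewhere).
    Precursor coefficients scale linearly (degree-1 homogeneous) with the
    fractions; the growth-associated ATP requirement ``gar``
    (mmol ATP per g AFDW) is added as an ATP -> ADP + Pi + H hydrolysis term.
    """
    coeffs: dict[str, float] = {}
    for macro, frac in composition.fractions.items():
        if frac == 0:
            continue
        if macro not in monomer_table:
            raise KeyError(f"monomer table lacks an entry for {macro!r} "
                           f"(fraction {frac})")
        for met_id, per_gram in monomer_table[macro].items():
            coeffs[met_id] = coeffs.get(met_id, 0.0) - frac * per_gram
    if gar:
        for key, sign in [("atp", -1), ("h2o", -1),
                          ("adp", 1), ("pi", 1), ("h", 1)]:
            mid = species[key]
            coeffs[mid] = coeffs.get(mid, 0.0) + sign * gar

    def _resolve(mid: str) -> Metabolite:
        if network is not None:
            return network.metabolites.get_by_id(mid)
        return Metabolite(mid, compartment=mid.rsplit("_", 1)[-1])

    rxn = Reaction(reaction_id, name="biomass production",
                   lower_bound=0.0, upper_bound=1000.0)
    rxn.add_metabolites({_resolve(m): c for m, c in coeffs.items() if c != 0})
    return rxn


# ---------------------------------------------------------------------------
# tabular / YAML interfaces
# ---------------------------------------------------------------------------

def load_biomass_composition(path) -> BiomassComposition:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return BiomassComposition(
        fractions={k: float(v) for k, v in data["fractions"].items()},
        amino_acid_profile=data.get("amino_acid_profile"))


def save_biomass_composition(composition: BiomassComposition, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"fractions": composition.fractions,
                        "amino_acid_profile": composition.amino_acid_profile},
                       fh)


def load_monomer_table(path) -> dict[str, dict[str, float]]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return {macro: {m: float(c) for m, c in entry.items()}
            for macro, entry in data.items()}


def write_reaction_table(network: Model, path) -> pd.DataFrame:
    """Tab-separated reaction listing (id, name, equation, GPR, subsystem)."""
    rows = [{"id": r.id, "name": r.name,
             "equation": r.build_reaction_string(),
             "gpr": r.gene_reaction_rule, "subsystem": r.subsystem or ""}
            for r in network.reactions]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def write_metabolite_table(network: Model, path) -> pd.DataFrame:
    rows = [{"id": m.id, "name": m.name, "formula": m.formula or "",
             "charge": m.charge if m.charge is not None else "",
             "compartment": m.compartment}
            for m in network.metabolites]
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
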