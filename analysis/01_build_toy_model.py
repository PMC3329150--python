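#!/usr/bin/env python
"""Build the toy phototroph network, audit it, and export its artefacts.

Writes the SBML file plus tab-separated reaction/metabolite listings to
results/, and reports the network size and the elemental/charge audit.
"""

from pathlib import Path

from cyanoflux.network import (mass_balance_audit, reaction_counts,
                               write_metabolite_table, write_reaction_table,
                               write_sbml)
from cyanoflux.synth import make_toy_network

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    toy = make_toy_network()
    write_sbml(toy, OUT / "toy_phototroph.xml")
    write_reaction_table(toy, OUT / "toy_reactions.tsv")
    write_metabolite_table(toy, OUT / "toy_metabolites.tsv")

    counts = reaction_counts(toy)
    audit = mass_balance_audit(toy)
    print(f"toy phototroph: {counts['total']} reactions "
          f"({counts['metabolic_and_transport']} metabolic/transport, "
          f"{counts['exchange']} exchange/demand), {counts['genes']} genes")
    if len(audit):
        print("BALANCE PROBLEMS:\n", audit.to_string(index=False))
    else:
        print("all internal reactions element- and charge-balanced")
    print(f"artefacts in {OUT}")


if __name__ == "__main__":
    main()
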