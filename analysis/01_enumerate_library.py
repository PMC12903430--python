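"""Enumerate the dendrimer library and audit the mass calculus.

Builds every layer sequence over {AB3, AB6} for generations 1-3 (the 14
structural analogs), tabulates peripheral-group counts, formulae and
masses for both terminal forms, and prints the desk-scale checkpoints:
Pascal-class multiplicities, module masses, the G2-3-6-N theoretical MW,
the generation-3 mass extremes and the first-generation separation mass
ratio.  Writes results/library.csv and results/pg_classes.csv.
"""

from pathlib import Path

import pandas as pd

from pamcas.grammar import (
    Registry,
    activated_ester_composition,
    average_mass,
    elemental_composition,
    enumerate_sequences,
    parse_name,
    peripheral_group_count,
    pg_class_histogram,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    registry = Registry.default()
    RESULTS.mkdir(exist_ok=True)

    rows = []
    for generation in (1, 2, 3):
        for form in ("allyl", "ammonium"):
            for spec in enumerate_sequences(
                generation,
                registry.branch_blocks,
                core=registry.core,
                cap=registry.cap,
                terminal_form=form,
            ):
                comp = elemental_composition(spec)
                rows.append(
                    {
                        "name": spec.name,
                        "generation": generation,
                        "n_pg": peripheral_group_count(spec),
                        "formula": comp.hill_formula,
                        "average_mass": round(comp.average_mass, 2),
                        "monoisotopic_mass": round(comp.monoisotopic_mass, 4),
                    }
                )
    library = pd.DataFrame(rows)
    library.to_csv(RESULTS / "library.csv", index=False)

    sequences = library[library.name.str.endswith("N")]
    print(f"{len(sequences)} layer sequences over generations 1-3 "
          f"(expected 14: 2 + 4 + 8)")

    classes = []
    for generation in (1, 2, 3):
        hist = pg_class_histogram(
            generation, registry.branch_blocks, core=registry.core
        )
        for n_pg, multiplicity in hist.items():
            classes.append(
                {"generation": generation, "n_pg": n_pg,
                 "sequences": multiplicity}
            )
        print(f"G{generation} peripheral-group classes: {hist}")
    pd.DataFrame(classes).to_csv(RESULTS / "pg_classes.csv", index=False)
    print("G3 multiplicities follow Pascal's 1:3:3:1 row; extremes 108/864.\n")

    ab3, ab6 = registry["AB3"], registry["AB6"]
    print(f"module masses: AB3 {ab3.average_mass:.1f} g/mol "
          f"(reported 330), AB6 {ab6.average_mass:.1f} g/mol (reported 539)")

    g2_3_6 = parse_name("G2-3-6-N", registry)
    print(f"G2-3-6-N theoretical MW {average_mass(g2_3_6):.1f} g/mol "
          f"(reported 17,107)")

    small = average_mass(parse_name("G3-3-3-3-N", registry)) / 1000
    large = average_mass(parse_name("G3-6-6-6-N", registry)) / 1000
    print(f"G3 ammonium mass range {small:.1f} - {large:.1f} kDa "
          f"(reported 32 to >200 kDa)")

    g1_3a = parse_name("G1-3-A", registry)
    bto = activated_ester_composition(ab3)
    print(f"G1-3-A : BtO-AB3 mass ratio "
          f"{average_mass(g1_3a) / bto.average_mass:.2f} (reported 3.9:1)")
    g1_6a = parse_name("G1-6-A", registry)
    print(f"G1-6-A : AB6 mass ratio "
          f"{average_mass(g1_6a) / ab6.average_mass:.2f} "
          f"(reported 4.9:1; the reconstructed compositions give 4.80)")


if __name__ == "__main__":
    main()
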