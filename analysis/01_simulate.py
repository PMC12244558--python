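#!/usr/bin/env python
"""Step 1: generate the synthetic study landscape and occurrence records.

Builds the default virtual-species scenario (a 100x100 coastal-shelf
grid, 15 spatially autocorrelated environmental layers, 20 species with
known Gaussian niches, 60 presence-only draws each) and serialises it as
text artifacts under the results directory: one .asc file per layer plus
a manifest, the occurrence table, the per-species truth table and a
provenance JSON.
"""

import argparse
from pathlib import Path

from stacksdm.pipeline import substream
from stacksdm.synthetic_data import build_scenario, coastal_shelf_grid, write_scenario


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--results", type=str, default="results")
    parser.add_argument("--n-species", type=int, default=20)
    parser.add_argument("--n-layers", type=int, default=15)
    parser.add_argument("--records-per-species", type=int, default=60)
    parser.add_argument("--grid-side", type=int, default=100)
    args = parser.parse_args()

    scenario = build_scenario(
        spec=coastal_shelf_grid(args.grid_side, args.grid_side),
        n_species=args.n_species,
        n_layers=args.n_layers,
        records_per_species=args.records_per_species,
        seed=substream(args.seed, "simulate"),
    )
    out = Path(args.results) / "scenario"
    write_scenario(scenario, out)
    print(f"scenario written to {out}")
    print(f"  species: {len(scenario.species)}")
    print(f"  occurrence records: {len(scenario.occurrences)}")
    print(f"  layers: {len(scenario.stack.layers)}")


if __name__ == "__main__":
    main()
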