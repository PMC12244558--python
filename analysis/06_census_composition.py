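#!/usr/bin/env python
"""Step 6: taxonomic composition of the reference census.

Summarises the bundled synthetic species-level census (which matches the
published order, genus and wall-type tallies of the Arabian Gulf benthic
foraminifera compilation: 492 species) into percentage shares per order,
genus and wall type, and writes the tidy table.
"""

import argparse
from pathlib import Path

from stacksdm.datasets import synthetic_gulf_census
from stacksdm.occurrences import summarize_composition


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=str, default="results")
    args = parser.parse_args()

    results = Path(args.results)
    results.mkdir(parents=True, exist_ok=True)
    records, taxonomy = synthetic_gulf_census()
    comp = summarize_composition(records, taxonomy)
    comp.to_csv(results / "census_composition.csv", index=False)

    total = records["taxon"].nunique()
    print(f"census: {total} species")
    for rank in ("order", "wall_type"):
        sub = comp[comp["rank"] == rank].sort_values("n_species", ascending=False)
        print(f"\nby {rank}:")
        for _, row in sub.iterrows():
            print(f"  {row['group']:<16} {row['n_species']:>4}  {row['share_pct']:>5.1f}%")


if __name__ == "__main__":
    main()
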