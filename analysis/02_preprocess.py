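#!/usr/bin/env python
"""Step 2: clean and thin occurrences, screen collinear layers.

Reads the scenario written by step 1, applies the cleaning cascade
(synonym standardisation, deduplication, coordinate checks, off-grid and
nodata removal, species-level filter), thins to one record per species
per cell, drops species with fewer than four records, and removes
collinear layers (|r| > 0.85, keeping the higher-priority layer of each
offending pair). Writes the analysis-ready occurrence table and the
retained layer list.
"""

import argparse
from pathlib import Path

import pandas as pd

from stacksdm.pipeline import preprocess
from stacksdm.raster_io import read_stack


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=str, default="results")
    args = parser.parse_args()

    results = Path(args.results)
    stack, priority = read_stack(results / "scenario" / "layers" / "manifest.yaml")
    records = pd.read_csv(results / "scenario" / "occurrences.csv")

    clean_records, retained = preprocess(records, stack, priority=priority)

    clean_records.to_csv(results / "occurrences_clean.csv", index=False)
    (results / "retained_layers.txt").write_text("\n".join(retained) + "\n")
    print(f"records in: {len(records)}, retained: {len(clean_records)}")
    print(f"species retained: {clean_records['taxon'].nunique()}")
    print(f"layers retained ({len(retained)}/{len(stack.layers)}): {', '.join(retained)}")


if __name__ == "__main__":
    main()
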