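#!/usr/bin/env python
"""Step 5: cluster species by environmental-importance profiles.

Runs PCA on the species x layer permutation-importance matrix from step
3 (correlation-matrix convention) and Ward hierarchical clustering on
the retained component scores, choosing the cluster count at the largest
relative drop in within-cluster inertia. Writes the cluster assignments
and a per-cluster characterisation (mean importances, top variables,
representative species).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from stacksdm import niche_clusters as nc


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=str, default="results")
    parser.add_argument("--k", default="auto")
    args = parser.parse_args()

    results = Path(args.results)
    imp = pd.read_csv(results / "importance_matrix.csv", index_col=0)
    nonzero = imp[imp.sum(axis=1) > 0]
    variable_cols = nonzero.columns[nonzero.std(ddof=1) > 0]

    p = nc.pca(nonzero[variable_cols])
    n_comp = nc.retained_components(p)
    k = args.k if args.k == "auto" else int(args.k)
    assignment = nc.hcpc(p, n_components=n_comp, k=k)

    assignment.labels.rename("cluster").to_csv(results / "clusters.csv")
    summary = nc.characterize_clusters(assignment, nonzero[variable_cols])
    summary.to_csv(results / "cluster_summary.csv")
    with open(results / "cluster_report.json", "w") as fh:
        json.dump(
            {
                "k": assignment.k,
                "n_components": n_comp,
                "explained_variance_ratio": p.explained_variance_ratio[:n_comp].tolist(),
                "inertia_gain": assignment.inertia_gain,
            },
            fh, indent=2, default=float,
        )

    print(f"PCA: {n_comp} components retained "
          f"({100 * p.explained_variance_ratio[:n_comp].sum():.1f}% of variance)")
    print(f"clusters: k = {assignment.k}")
    for c, row in summary.iterrows():
        print(f"  cluster {c}: n = {row['n_species']}, "
              f"top variables {row['top_variables'][:2]}, "
              f"representative {row['representative_species']}")


if __name__ == "__main__":
    main()
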