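"""Per-species ensembles: combining algorithm members, searching algorithm
combinations, and inter-algorithm agreement."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .sdm_fit import EvalMetrics, FittedSDM, metrics_at_threshold, select_threshold


@dataclass
class EnsembleSDM:
    """Weighted ensemble of per-algorithm models for one species.

    The ensemble suitability is the weighted mean of member suitability
    surfaces, so it lies cellwise within the members' range. The
    presence threshold is recomputed on the combined predictions at the
    training cells, and ``metrics`` evaluates those combined training
    predictions at that threshold.
    """

    species: str
    members: list[FittedSDM]
    weights: np.ndarray
    suitability: np.ndarray
    threshold: float
    metrics: EvalMetrics
    importance: pd.Series  # weight-averaged member importances (percent)

    @property
    def binary(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(np.isfinite(self.suitability), self.suitability >= self.threshold, False)

    @property
    def member_names(self) -> list[str]:
        return [m.algorithm for m in self.members]


def combine(members: list[FittedSDM], weighting: str = "auc") -> EnsembleSDM:
    """Combine >= 2 fitted algorithm models of one species.

    ``weighting="auc"`` (default) weights members proportionally to their
    cross-validated AUC; ``"uniform"`` weights them equally.
    """
    if len(members) < 2:
        raise ValueError("an ensemble needs at least two members")
    species = members[0].species
    shape = members[0].suitability.shape
    for m in members[1:]:
        if m.species != species:
            raise ValueError("all members must model the same species")
        if m.suitability.shape != shape:
            raise ValueError("member suitability grids differ in shape")
        if m.train_cells != members[0].train_cells:
            raise ValueError("members were trained on different cells")

    if weighting == "uniform":
        w = np.ones(len(members))
    elif weighting == "auc":
        w = np.array([m.cv_metrics.auc for m in members], dtype=float)
        if not np.all(np.isfinite(w)) or w.sum() <= 0:
            w = np.ones(len(members))
    else:
        raise ValueError(f"unknown weighting '{weighting}'")
    w = w / w.sum()

    suit = np.tensordot(w, np.stack([m.suitability for m in members]), axes=1)
    # threshold and metrics from the combined *out-of-fold* predictions at
    # the training cells; resubstitution predictions would bias the
    # threshold high (see sdm_fit.fit_species). One threshold per CV
    # replicate, averaged; metrics averaged over replicates likewise.
    y = members[0].y
    cv_pred = np.tensordot(
        w, np.stack([np.atleast_2d(m.cv_predictions) for m in members]), axes=1
    )
    rep_thresholds = [select_threshold(row, y) for row in cv_pred]
    threshold = float(np.mean(rep_thresholds))
    rep_metrics = pd.DataFrame(
        [metrics_at_threshold(row, y, t).as_dict() for row, t in zip(cv_pred, rep_thresholds)]
    )
    metrics = EvalMetrics(**rep_metrics.mean().to_dict())
    imp = sum(wi * m.importance for wi, m in zip(w, members))
    return EnsembleSDM(
        species=species,
        members=list(members),
        weights=w,
        suitability=suit,
        threshold=threshold,
        metrics=metrics,
        importance=imp,
    )


@dataclass
class CombinationResult:
    """Mean +/- SD evaluation of one algorithm combination over species."""

    combo: tuple[str, ...]
    mean: dict[str, float]
    sd: dict[str, float]
    n_species: int


def search_combinations(
    fitted: dict[str, dict[str, FittedSDM]],
    algorithms: list[str],
    sizes: tuple[int, ...] = (3, 4, 5),
    subset_size: int | None = 50,
    seed: int = 0,
    weighting: str = "auc",
) -> list[CombinationResult]:
    """Evaluate every algorithm combination of the given sizes.

    ``fitted`` maps species -> algorithm -> fitted model; every species in
    the evaluated subset must carry all candidate algorithms. A random
    species subset of ``subset_size`` (seeded) keeps the search tractable
    on large assemblages. Combinations are ranked by mean Jaccard, with
    ties broken by prediction success (proportion correct); the ranking
    does not depend on the order species are supplied in.
    """
    species = sorted(fitted)
    for s in species:
        missing = set(algorithms) - set(fitted[s])
        if missing:
            raise ValueError(f"species '{s}' lacks fitted models for {sorted(missing)}")
    if subset_size is not None and subset_size < len(species):
        rng = np.random.default_rng(seed)
        species = sorted(rng.choice(species, size=subset_size, replace=False).tolist())

    results: list[CombinationResult] = []
    for size in sorted(sizes):
        for combo in combinations(sorted(algorithms), size):
            rows = []
            for s in species:
                ens = combine([fitted[s][a] for a in combo], weighting=weighting)
                rows.append(ens.metrics.as_dict())
            df = pd.DataFrame(rows)
            results.append(
                CombinationResult(
                    combo=combo,
                    mean=df.mean().to_dict(),
                    sd=df.std(ddof=1).fillna(0.0).to_dict() if len(df) > 1 else {k: 0.0 for k in df},
                    n_species=len(species),
                )
            )
    results.sort(key=lambda r: (-r.mean["jaccard"], -r.mean["prop_correct"], r.combo))
    return results


def leaderboard(results: list[CombinationResult]) -> pd.DataFrame:
    """Tabulate a combination search as a tidy leaderboard."""
    rows = []
    for r in results:
        row = {"combo": "-".join(r.combo), "n_species": r.n_species}
        for key in ("jaccard", "prop_correct", "kappa", "specificity", "sensitivity", "tss"):
            row[f"{key}_mean"] = r.mean[key]
            row[f"{key}_sd"] = r.sd[key]
        rows.append(row)
    return pd.DataFrame(rows)


def inter_algorithm_correlation(ensemble: EnsembleSDM) -> pd.DataFrame:
    """Pairwise Pearson correlation between member suitability maps.

    Computed over cells valid in all members. A constant member map makes
    its correlations undefined (NaN), which is reported rather than
    coerced.
    """
    if len(ensemble.members) < 2:
        raise ValueError("need at least two members")
    maps = [m.suitability.ravel() for m in ensemble.members]
    names = ensemble.member_names
    joint = np.logical_and.reduce([np.isfinite(v) for v in maps])
    n = len(maps)
    out = np.full((n, n), np.nan)
    for i in range(n):
        out[i, i] = 1.0
        for j in range(i + 1, n):
            xi, xj = maps[i][joint], maps[j][joint]
            if np.std(xi) == 0 or np.std(xj) == 0:
                continue
            out[i, j] = out[j, i] = float(np.corrcoef(xi, xj)[0, 1])
    return pd.DataFrame(out, index=names, columns=names)
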