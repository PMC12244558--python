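"""Pipeline orchestration: configuration, stage drivers, end-to-end runs.

The stages mirror the analysis workflow: prepare (load or simulate the
landscape and occurrences) -> clean/thin/filter -> per-species fits ->
ensembles -> stacking -> diversity statistics -> importance clustering.
All randomness flows from one root seed through named substreams, so a
re-run with the same configuration reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ensemble as ens
from . import niche_clusters as nc
from . import occurrences as occ
from . import sdm_fit
from . import spatial_diversity as sdiv
from . import stack as stk
from .envgrid import EnvStack, pairwise_correlation, screen_collinear
from .sdm_fit import BUILTIN_ALGORITHMS, FittedSDM, get_adapter

logger = logging.getLogger(__name__)

#: pseudo-absence conventions per algorithm family: regression-style
#: algorithms get a large fixed background, classification-style ones a
#: background equal to the presence count (both capped at eligibility).
REGRESSION_FAMILY = {"GLM", "GAM", "MARS"}
DEFAULT_REGRESSION_ABSENCES = 1000


def substream(seed: int, stage: str) -> int:
    """Derive a named, stable substream seed below 2**31 from a root seed."""
    h = int(seed) & 0xFFFFFFFF
    for ch in stage:
        h = (h * 31 + ord(ch)) & 0xFFFFFFFF
    return h % (2**31 - 1)


@dataclass
class RunConfig:
    """Validated run configuration (see ``validate_config``)."""

    # paths
    occurrences_path: str | None = None
    taxonomy_path: str | None = None
    layer_manifest: str | None = None
    output_dir: str = "results/run"
    # synthetic fallback when no paths are given
    simulate: bool = True
    n_species: int = 20
    n_layers: int = 15
    records_per_species: int = 60
    grid_rows: int = 100
    grid_cols: int = 100
    # preprocessing
    min_occurrences: int = 4
    collinearity_threshold: float = 0.85
    priority: list[str] | None = None
    # modelling
    algorithms: list[str] = field(default_factory=lambda: ["CTA", "RF", "SVM"])
    k: int = 20
    n_reps: int = 10
    n_strata: int = 5
    buffer_cells: int = 3
    weighting: str = "auc"
    # stacking / analysis
    uncertainty: bool = True
    endemism: bool = True
    gradient_axes: list[str] = field(default_factory=lambda: ["latitude", "longitude"])
    moran_subsample: int | None = 2500
    cluster_k: int | str = "auto"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def validate_config(config: RunConfig) -> list[str]:
    """Schema and cross-field checks; returns problems, empty when valid."""
    problems: list[str] = []
    if config.k < 2:
        problems.append(f"k must be >= 2, got {config.k}")
    if not 0 < config.collinearity_threshold <= 1:
        problems.append(
            f"collinearity_threshold must lie in (0, 1], got {config.collinearity_threshold}"
        )
    if config.n_reps < 1:
        problems.append("n_reps must be >= 1")
    for algo in config.algorithms:
        if algo not in BUILTIN_ALGORITHMS:
            problems.append(f"unknown algorithm '{algo}'")
    if config.weighting not in {"auc", "uniform"}:
        problems.append(f"unknown weighting '{config.weighting}'")
    if not config.simulate:
        for label, p in (
            ("occurrences_path", config.occurrences_path),
            ("layer_manifest", config.layer_manifest),
        ):
            if p is None:
                problems.append(f"{label} is required when simulate is false")
            elif not Path(p).exists():
                problems.append(f"{label} does not exist: {p}")
    if isinstance(config.cluster_k, int) and config.cluster_k < 1:
        problems.append("cluster_k must be >= 1 or 'auto'")
    return problems


def preprocess(
    records: pd.DataFrame,
    stack: EnvStack,
    priority: list[str] | None = None,
    collinearity_threshold: float = 0.85,
    min_occurrences: int = 4,
    synonyms: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Clean, thin and rare-filter occurrences; screen collinear layers.

    Returns the analysis-ready records and the retained layer names in
    priority order.
    """
    cleaned = occ.clean(records, stack, synonyms=synonyms)
    thinned = occ.spatial_thin(cleaned, stack.spec)
    filtered = occ.filter_rare(thinned, min_occurrences=min_occurrences)
    priority = priority or stack.names
    corr = pairwise_correlation(stack)
    retained = screen_collinear(corr.matrix, priority, threshold=collinearity_threshold)
    return filtered, retained


def fit_assemblage(
    records: pd.DataFrame,
    stack: EnvStack,
    retained_layers: list[str],
    algorithms: list[str] = ("CTA", "RF", "SVM"),
    k: int = 20,
    n_reps: int = 10,
    n_strata: int = 5,
    buffer_cells: int = 3,
    seed: int = 0,
) -> dict[str, dict[str, FittedSDM]]:
    """Fit every algorithm to every species; returns species -> algo -> fit.

    Pseudo-absence counts follow the per-family convention: a fixed
    large background for regression-style algorithms, presence-matched
    for classification-style ones, each capped at the number of eligible
    cells and drawn once per (species, family). The default 3-cell
    Chebyshev exclusion buffer keeps the background away from presence
    neighbourhoods, which are likely occupied-but-unsampled habitat;
    background points drawn there act as false absences and bias the
    TSS threshold upward.
    """
    spec = stack.spec
    species_list = sorted(records["taxon"].unique())
    fitted: dict[str, dict[str, FittedSDM]] = {}
    families = {a: ("regression" if a in REGRESSION_FAMILY else "classification") for a in algorithms}
    n_valid = int(spec.valid_mask.sum())
    for si, species in enumerate(species_list):
        presences = occ.presence_cells_for(records, species, spec)
        pa_by_family = {}
        for family in set(families.values()):
            if family == "regression":
                n_abs = min(DEFAULT_REGRESSION_ABSENCES, n_valid - len(presences))
            else:
                n_abs = min(len(presences), n_valid - len(presences))
            pa_by_family[family] = occ.generate_pseudo_absences(
                species,
                records,
                stack,
                n_absences=n_abs,
                n_strata=n_strata,
                buffer_cells=buffer_cells,
                seed=substream(seed, f"absences/{family}/{species}"),
                layer_names=retained_layers,
            )
        fitted[species] = {}
        for algo_name in algorithms:
            pa = pa_by_family[families[algo_name]]
            adapter = get_adapter(algo_name)
            fitted[species][algo_name] = sdm_fit.fit_species(
                pa,
                adapter,
                stack,
                k=k,
                n_reps=n_reps,
                seed=substream(seed, f"fit/{algo_name}/{species}"),
            )
        logger.info("fitted %s (%d/%d)", species, si + 1, len(species_list))
    return fitted


def ensemble_assemblage(
    fitted: dict[str, dict[str, FittedSDM]],
    weighting: str = "auc",
) -> dict[str, ens.EnsembleSDM]:
    """Combine each species' algorithm fits into its ensemble."""
    return {
        species: ens.combine(list(by_algo.values()), weighting=weighting)
        for species, by_algo in sorted(fitted.items())
    }


def importance_matrix(ensembles: dict[str, ens.EnsembleSDM]) -> pd.DataFrame:
    """Species x layer matrix of ensemble importances (percent rows)."""
    return pd.DataFrame({s: e.importance for s, e in ensembles.items()}).T


def recovery_study(
    seed: int = 0,
    n_species: int = 20,
    n_layers: int = 15,
    grid_rows: int = 100,
    grid_cols: int = 100,
    records_per_species: int = 60,
    algorithms: tuple[str, ...] = ("CTA", "RF", "SVM"),
    k: int = 5,
    n_reps: int = 1,
) -> dict:
    """Fit the full pipeline on a synthetic scenario and score recovery.

    Builds the default virtual-species study (known niches and true
    richness), runs cleaning, pseudo-absence generation, per-algorithm
    fits, ensembling and stacking, then measures how well the known
    truth is recovered. The cross-validation problem size (k folds,
    replicates) is kept modest here because the study is re-fit from
    scratch on every call.

    Returns a dict with: ``richness_truth_pearson_r``, the correlation
    between predicted and true richness over valid cells;
    ``importance_top1_rate``, the fraction of single-layer-niche species
    whose true niche layer ranks first in ensemble permutation
    importance; ``mean_cv_auc``, the mean cross-validated AUC over all
    species x algorithms; plus the fitted objects for further analysis.
    """
    from .synthetic_data import build_scenario, coastal_shelf_grid

    scenario = build_scenario(
        spec=coastal_shelf_grid(grid_rows, grid_cols),
        n_species=n_species,
        n_layers=n_layers,
        records_per_species=records_per_species,
        seed=substream(seed, "simulate"),
    )
    records, retained = preprocess(scenario.occurrences, scenario.stack)
    fitted = fit_assemblage(
        records,
        scenario.stack,
        retained,
        algorithms=list(algorithms),
        k=k,
        n_reps=n_reps,
        seed=substream(seed, "fit"),
    )
    ensembles = ensemble_assemblage(fitted)
    richness = stk.stack_binary(list(ensembles.values()), scenario.stack.spec)

    truth = scenario.true_richness.values
    pred = richness.values
    ok = np.isfinite(truth) & np.isfinite(pred)
    r = float(np.corrcoef(truth[ok], pred[ok])[0, 1])

    singles = [
        vs for vs in scenario.species
        if len(vs.niche.responses) == 1 and vs.name in ensembles
    ]
    hits = 0
    for vs in singles:
        true_layer = next(iter(vs.niche.responses))
        imp = ensembles[vs.name].importance
        if imp.idxmax() == true_layer:
            hits += 1
    top1 = hits / len(singles) if singles else float("nan")

    aucs = [f.cv_metrics.auc for by_algo in fitted.values() for f in by_algo.values()]
    return {
        "richness_truth_pearson_r": r,
        "importance_top1_rate": top1,
        "n_single_layer_species": len(singles),
        "mean_cv_auc": float(np.mean(aucs)),
        "scenario": scenario,
        "fitted": fitted,
        "ensembles": ensembles,
        "richness": richness,
        "records": records,
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and write maps, tables and JSON reports.

    Raises on the first stage failure, naming the stage. Returns the
    output directory.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .raster_io import read_stack, write_ascii_grid

    stage = "prepare"
    try:
        if config.simulate:
            from .synthetic_data import build_scenario, coastal_shelf_grid

            scenario = build_scenario(
                spec=coastal_shelf_grid(config.grid_rows, config.grid_cols),
                n_species=config.n_species,
                n_layers=config.n_layers,
                records_per_species=config.records_per_species,
                seed=substream(config.seed, "simulate"),
            )
            stack, records = scenario.stack, scenario.occurrences
            priority = config.priority or stack.names
        else:
            stack, priority = read_stack(config.layer_manifest)
            records = pd.read_csv(config.occurrences_path)
            priority = config.priority or priority

        stage = "clean"
        records, retained = preprocess(
            records,
            stack,
            priority=priority,
            collinearity_threshold=config.collinearity_threshold,
            min_occurrences=config.min_occurrences,
        )

        stage = "fit"
        fitted = fit_assemblage(
            records,
            stack,
            retained,
            algorithms=config.algorithms,
            k=config.k,
            n_reps=config.n_reps,
            n_strata=config.n_strata,
            buffer_cells=config.buffer_cells,
            seed=substream(config.seed, "fit"),
        )
        metrics_rows = [
            {"species": s, "algorithm": a, **f.cv_metrics.as_dict(), "threshold": f.threshold}
            for s, by_algo in sorted(fitted.items())
            for a, f in sorted(by_algo.items())
        ]
        pd.DataFrame(metrics_rows).to_csv(out / "sdm_metrics.csv", index=False)

        stage = "ensemble"
        ensembles = ensemble_assemblage(fitted, weighting=config.weighting)
        ens_rows = [
            {"species": s, **e.metrics.as_dict(), "threshold": e.threshold}
            for s, e in ensembles.items()
        ]
        pd.DataFrame(ens_rows).to_csv(out / "ensemble_metrics.csv", index=False)

        stage = "stack"
        spec = stack.spec
        ens_list = list(ensembles.values())
        richness = stk.stack_binary(ens_list, spec)
        write_ascii_grid(out / "richness.asc", richness.values, spec)
        if config.uncertainty:
            unc = stk.uncertainty_map(ens_list, spec)
            write_ascii_grid(out / "uncertainty.asc", unc.values, spec)
        if config.endemism:
            end = stk.endemism_map(ens_list, spec)
            write_ascii_grid(out / "endemism.asc", end.values, spec)
        observed = stk.observed_assemblages(records, spec)
        community = stk.evaluate_community(ens_list, observed)
        community.per_site.to_csv(out / "community_eval.csv")

        stage = "diversity"
        diversity_report = {}
        for axis in config.gradient_axes:
            fit = sdiv.gradient_regression(
                richness, axis=axis, seed=substream(config.seed, f"gradient/{axis}")
            )
            diversity_report[f"gradient_{axis}"] = asdict(fit)
        moran = sdiv.morans_i_grid(
            richness, subsample=config.moran_subsample, seed=substream(config.seed, "moran")
        )
        diversity_report["morans_i"] = asdict(moran)
        diversity_report["community_eval_mean"] = community.mean
        diversity_report["community_eval_sd"] = community.sd

        stage = "clusters"
        imp = importance_matrix(ensembles)
        nonzero = imp[imp.sum(axis=1) > 0]
        cluster_report = {}
        if len(nonzero) >= 3:
            variable_cols = nonzero.columns[nonzero.std(ddof=1) > 0]
            p = nc.pca(nonzero[variable_cols])
            assignment = nc.hcpc(p, k=config.cluster_k)
            assignment.labels.rename("cluster").to_csv(out / "clusters.csv")
            nc.characterize_clusters(assignment, nonzero[variable_cols]).to_csv(
                out / "cluster_summary.csv"
            )
            cluster_report = {"k": assignment.k, "inertia_gain": assignment.inertia_gain}

        report = {
            "seed": config.seed,
            "n_species": len(ensembles),
            "retained_layers": retained,
            "diversity": diversity_report,
            "clusters": cluster_report,
        }
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=float)
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return out
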