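"""Occurrence handling: cleaning, thinning, rare-species filtering,
pseudo-absence generation and taxonomic composition summaries.

Occurrence tables are pandas DataFrames with columns
``taxon, lon, lat, depth_m, source_id`` (``depth_m`` optional, metres below
sea level as negative numbers). Taxonomy tables carry
``species, genus, family, superfamily, order, wall_type``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .envgrid import EnvStack, GridSpec

logger = logging.getLogger(__name__)

OCCURRENCE_COLUMNS = ["taxon", "lon", "lat", "depth_m", "source_id"]
_NON_SPECIES_EPITHETS = {"sp", "sp.", "spp", "spp.", "indet", "indet.", "cf", "cf."}


@dataclass
class PresenceAbsenceSet:
    """Training data for one species: presence cells, pseudo-absence cells,
    and the extracted environmental design matrix.

    ``X`` rows correspond to ``cells`` (presences first), ``y`` is 1 for
    presence and 0 for pseudo-absence. Presence and absence sets are
    disjoint by construction.
    """

    species: str
    presence_cells: list[tuple[int, int]]
    absence_cells: list[tuple[int, int]]
    X: np.ndarray
    y: np.ndarray
    layer_names: list[str]

    def __post_init__(self) -> None:
        if set(self.presence_cells) & set(self.absence_cells):
            raise ValueError("presence and absence cells overlap")
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")

    @property
    def cells(self) -> list[tuple[int, int]]:
        return list(self.presence_cells) + list(self.absence_cells)


def _is_binomial(name: str) -> bool:
    parts = str(name).strip().split()
    if len(parts) < 2:
        return False
    return parts[1].lower() not in _NON_SPECIES_EPITHETS


def clean(
    records: pd.DataFrame,
    stack: EnvStack,
    synonyms: pd.DataFrame | None = None,
    return_report: bool = False,
):
    """Clean an occurrence table against an environmental stack.

    Applies, in order: synonym standardisation (local ``old_name ->
    accepted_name`` table, no network), removal of exact duplicates,
    removal of records with missing or out-of-range coordinates, removal
    of records falling outside the stack extent or on nodata cells, and
    removal of taxa not resolvable to species level (non-binomial names).
    Drops are logged with reasons and counts; pass ``return_report=True``
    to also get the counts as a dict.
    """
    df = records.copy()
    report: dict[str, int] = {"input": len(df)}

    if synonyms is not None and len(synonyms):
        mapping = dict(zip(synonyms["old_name"], synonyms["accepted_name"]))
        df["taxon"] = df["taxon"].map(lambda t: mapping.get(t, t))

    before = len(df)
    df = df.drop_duplicates()
    report["duplicates"] = before - len(df)

    before = len(df)
    coord_ok = (
        df["lon"].notna() & df["lat"].notna()
        & df["lon"].between(-180, 180) & df["lat"].between(-90, 90)
    )
    df = df[coord_ok]
    report["bad_coordinates"] = before - len(df)

    spec = stack.spec
    before = len(df)
    on_grid = []
    for lon, lat in zip(df["lon"], df["lat"]):
        cell = spec.point_to_cell(lon, lat)
        on_grid.append(cell is not None and bool(spec.valid_mask[cell]))
    df = df[np.asarray(on_grid, dtype=bool)]
    report["off_grid_or_nodata"] = before - len(df)

    before = len(df)
    df = df[df["taxon"].map(_is_binomial)]
    report["not_species_level"] = before - len(df)
    report["retained"] = len(df)

    for reason in ("duplicates", "bad_coordinates", "off_grid_or_nodata", "not_species_level"):
        if report[reason]:
            logger.info("clean: dropped %d records (%s)", report[reason], reason)
    df = df.reset_index(drop=True)
    return (df, report) if return_report else df


def spatial_thin(records: pd.DataFrame, spec: GridSpec) -> pd.DataFrame:
    """Keep at most one record per species per grid cell.

    Records are first sorted by (source_id, original row order) so the
    result is stable under reshuffling of the input; the first record of
    each (species, cell) group is kept.
    """
    df = records.copy()
    df["_order"] = np.arange(len(df))
    df = df.sort_values(["source_id", "_order"], kind="stable")
    cells = [spec.point_to_cell(lon, lat) for lon, lat in zip(df["lon"], df["lat"])]
    df["_cell"] = cells
    df = df.drop_duplicates(subset=["taxon", "_cell"], keep="first")
    df = df.sort_values("_order").drop(columns=["_order", "_cell"])
    return df.reset_index(drop=True)


def filter_rare(records: pd.DataFrame, min_occurrences: int = 4) -> pd.DataFrame:
    """Drop species with fewer than ``min_occurrences`` thinned records.

    The default of 4 removes species with three or fewer occurrences,
    which cannot support cross-validated model fitting.
    """
    counts = records["taxon"].value_counts()
    keep = counts[counts >= min_occurrences].index
    out = records[records["taxon"].isin(keep)].reset_index(drop=True)
    dropped = records["taxon"].nunique() - out["taxon"].nunique() if len(records) else 0
    if dropped:
        logger.info("filter_rare: removed %d species with < %d occurrences", dropped, min_occurrences)
    return out


def presence_cells_for(records: pd.DataFrame, species: str, spec: GridSpec) -> list[tuple[int, int]]:
    """Unique grid cells holding at least one record of ``species``."""
    sub = records[records["taxon"] == species]
    cells: list[tuple[int, int]] = []
    seen = set()
    for lon, lat in zip(sub["lon"], sub["lat"]):
        cell = spec.point_to_cell(lon, lat)
        if cell is not None and cell not in seen:
            seen.add(cell)
            cells.append(cell)
    return cells


def _stratum_blocks(spec: GridSpec, n_strata: int) -> np.ndarray:
    """Label each cell with its stratum id in an n_strata x n_strata partition."""
    row_edges = np.linspace(0, spec.n_rows, n_strata + 1)
    col_edges = np.linspace(0, spec.n_cols, n_strata + 1)
    rows, cols = np.indices(spec.shape)
    rb = np.clip(np.searchsorted(row_edges, rows, side="right") - 1, 0, n_strata - 1)
    cb = np.clip(np.searchsorted(col_edges, cols, side="right") - 1, 0, n_strata - 1)
    return rb * n_strata + cb


def allocate_proportional(eligible_per_block: np.ndarray, n_total: int) -> np.ndarray:
    """Proportional allocation of draws across strata.

    Each block receives ``floor(n_total * e_b / E)`` draws; leftover draws
    go one-by-one to the blocks with the largest eligibility that still
    have spare cells. Allocations never exceed a block's eligibility.
    """
    e = np.asarray(eligible_per_block, dtype=int)
    E = int(e.sum())
    if n_total > E:
        raise ValueError(f"requested {n_total} draws but only {E} eligible cells")
    alloc = (n_total * e) // E if E else np.zeros_like(e)
    alloc = np.minimum(alloc, e)
    remaining = n_total - int(alloc.sum())
    # hand out remainders by descending eligibility, stable on ties
    order = np.argsort(-e, kind="stable")
    while remaining > 0:
        progressed = False
        for b in order:
            if remaining == 0:
                break
            if alloc[b] < e[b]:
                alloc[b] += 1
                remaining -= 1
                progressed = True
        if not progressed:
            raise RuntimeError("allocation failed to progress")  # pragma: no cover
    return alloc


def generate_pseudo_absences(
    species: str,
    records: pd.DataFrame,
    stack: EnvStack,
    n_absences: int,
    n_strata: int = 5,
    buffer_cells: int = 0,
    seed: int = 0,
    layer_names: list[str] | None = None,
) -> PresenceAbsenceSet:
    """Draw spatially stratified random pseudo-absences for one species.

    Eligible cells are valid cells that are neither presence cells nor
    within a Chebyshev (chessboard) distance of ``buffer_cells`` of any
    presence. Draws are without replacement, allocated proportionally
    across an ``n_strata`` x ``n_strata`` partition of the grid so that
    background points follow the geography of the available habitat
    rather than clustering by chance. Deterministic under ``seed``.
    """
    spec = stack.spec
    presences = presence_cells_for(records, species, spec)
    if not presences:
        raise ValueError(f"species '{species}' has no presence cells")

    eligible = spec.valid_mask.copy()
    pres_mask = np.zeros(spec.shape, dtype=bool)
    pr = np.array([c[0] for c in presences])
    pc = np.array([c[1] for c in presences])
    pres_mask[pr, pc] = True
    if buffer_cells > 0:
        rows, cols = np.indices(spec.shape)
        cheb = np.min(
            np.maximum(
                np.abs(rows[..., None] - pr[None, None, :]),
                np.abs(cols[..., None] - pc[None, None, :]),
            ),
            axis=-1,
        )
        eligible &= cheb > buffer_cells
    else:
        eligible &= ~pres_mask

    n_eligible = int(eligible.sum())
    if n_eligible < n_absences:
        raise ValueError(
            f"species '{species}': {n_absences} pseudo-absences requested but only "
            f"{n_eligible} eligible cells (shortfall {n_absences - n_eligible})"
        )

    blocks = _stratum_blocks(spec, n_strata)
    n_blocks = n_strata * n_strata
    elig_flat = eligible.ravel()
    block_flat = blocks.ravel()
    e_per_block = np.bincount(block_flat[elig_flat], minlength=n_blocks)
    alloc = allocate_proportional(e_per_block, n_absences)

    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    flat_idx = np.arange(spec.n_rows * spec.n_cols)
    for b in range(n_blocks):
        if alloc[b] == 0:
            continue
        pool = flat_idx[elig_flat & (block_flat == b)]
        chosen.extend(rng.choice(pool, size=alloc[b], replace=False).tolist())
    absences = [(int(i) // spec.n_cols, int(i) % spec.n_cols) for i in chosen]

    names = layer_names or stack.names
    sub = stack.select(names)
    all_cells = presences + absences
    rows_idx = np.array([c[0] for c in all_cells])
    cols_idx = np.array([c[1] for c in all_cells])
    X = sub.extract(rows_idx, cols_idx)
    y = np.concatenate([np.ones(len(presences)), np.zeros(len(absences))]).astype(int)
    return PresenceAbsenceSet(
        species=species,
        presence_cells=presences,
        absence_cells=absences,
        X=X,
        y=y,
        layer_names=names,
    )


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_composition(
    records: pd.DataFrame,
    taxonomy: pd.DataFrame,
    ranks: tuple[str, ...] = ("order", "family", "genus", "wall_type"),
) -> pd.DataFrame:
    """Species counts and percentage shares by taxonomic rank and wall type.

    The share of a group is ``100 * n_species_in_group / n_species_total``,
    rounded half-up to one decimal. Counts per rank always sum to the
    total; raw shares sum to 100 before rounding.

    Returns a tidy DataFrame with columns ``rank, group, n_species,
    share_pct``.
    """
    species = pd.unique(records["taxon"])
    missing = sorted(set(species) - set(taxonomy["species"]))
    if missing:
        raise ValueError(f"species missing from taxonomy: {missing}")
    tax = taxonomy.set_index("species").loc[species]
    total = len(species)
    rows = []
    for rank in ranks:
        counts = tax[rank].value_counts()
        for group, n in counts.items():
            rows.append(
                {
                    "rank": rank,
                    "group": group,
                    "n_species": int(n),
                    "share_pct": _round_half_up(100.0 * n / total),
                }
            )
    return pd.DataFrame(rows, columns=["rank", "group", "n_species", "share_pct"])
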