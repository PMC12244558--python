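"""Virtual landscapes and virtual species with known niches.

Every pipeline stage is testable against ground truth by simulating what
a basin-scale occurrence compilation provides: a stack of spatially
autocorrelated environmental layers over a coastal-shelf grid, species
whose occupancy is driven by unimodal (Gaussian) niche responses of
varying breadth, and presence-only samples drawn from the occupied cells.
Detection is perfect by default; an optional flip rate can corrupt
occupancy for robustness experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .envgrid import EnvLayer, EnvStack, GridSpec
from .stack import RichnessMap

#: layer names, units and value ranges emulating a shallow subtropical
#: shelf sea (depth in negative metres, temperatures in deg C, salinity in
#: permille, nutrients in umol/l, oxygen in ml/l, chlorophyll-a in mg/m3).
DEFAULT_LAYER_RANGES: dict[str, tuple[float, float, str]] = {
    "bathymetry": (-127.0, -2.0, "m"),
    "sst_mean": (24.23, 29.45, "degC"),
    "sst_min": (13.09, 24.0, "degC"),
    "sst_max": (30.0, 37.6, "degC"),
    "bottom_temp_mean": (20.0, 30.0, "degC"),
    "salinity": (37.04, 37.46, "permille"),
    "chlorophyll_a": (0.73, 12.99, "mg/m3"),
    "dissolved_oxygen": (4.51, 5.02, "ml/l"),
    "iron": (5e-4, 2e-3, "umol/l"),
    "silicate": (1.80, 2.79, "umol/l"),
    "phosphate": (0.15, 0.42, "umol/l"),
    "nitrate": (0.81, 2.58, "umol/l"),
    "ph": (8.13, 8.14, "pH"),
    "calcite": (1.61e-4, 5.6e-2, "mol/m3"),
    "light_attenuation": (0.05, 0.5, "1/m"),
}


@dataclass
class NicheDefinition:
    """Gaussian niche responses per layer; layers absent are flat.

    ``responses`` maps layer name -> (optimum, breadth). Suitability is
    the product of per-layer Gaussian responses, so adding active layers
    narrows the realised niche.
    """

    responses: dict[str, tuple[float, float]]
    prevalence_target: float = 0.2

    def __post_init__(self) -> None:
        if not self.responses:
            raise ValueError("niche needs at least one non-flat response")
        for name, (_, breadth) in self.responses.items():
            if breadth <= 0:
                raise ValueError(f"breadth for '{name}' must be > 0")
        if not 0 < self.prevalence_target <= 1:
            raise ValueError("prevalence_target must lie in (0, 1]")


@dataclass
class VirtualSpecies:
    name: str
    niche: NicheDefinition
    suitability: np.ndarray  # [0, 1], max 1 at the optimum cell(s)
    true_binary: np.ndarray

    @property
    def range_size(self) -> int:
        return int(self.true_binary.sum())


@dataclass
class SyntheticScenario:
    stack: EnvStack
    species: list[VirtualSpecies]
    occurrences: pd.DataFrame
    true_richness: RichnessMap
    seed: int
    provenance: dict = field(default_factory=dict)


def coastal_shelf_grid(
    n_rows: int = 100,
    n_cols: int = 100,
    cell_size: float = 0.02,
    origin_x: float = 48.0,
    origin_y: float = 30.0,
    land_frac: float = 0.12,
) -> GridSpec:
    """A shelf grid with a diagonal land margin along the south-west corner."""
    rows, cols = np.indices((n_rows, n_cols))
    # land where the anti-diagonal coordinate falls below a cutoff
    coast = (n_rows - 1 - rows) + cols
    cutoff = np.quantile(coast, land_frac)
    mask = coast > cutoff
    return GridSpec(
        n_rows=n_rows, n_cols=n_cols, cell_size=cell_size,
        origin_x=origin_x, origin_y=origin_y, valid_mask=mask,
    )


def generate_env_stack(
    spec: GridSpec,
    n_layers: int = 15,
    autocorr_range_cells: float = 8.0,
    gradient_weight: float = 0.4,
    value_ranges: dict[str, tuple[float, float, str]] | None = None,
    seed: int = 0,
) -> EnvStack:
    """Generate spatially autocorrelated environmental layers.

    Each layer is ``gradient_weight`` parts deterministic ramp (N-S for
    even layers, E-W for odd ones) and the rest Gaussian-smoothed white
    noise with kernel radius ``autocorr_range_cells``, affinely rescaled
    to the layer's value range. Deterministic under ``seed``.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    ranges = value_ranges or DEFAULT_LAYER_RANGES
    names = list(ranges)[:n_layers]
    if len(names) < n_layers:
        names += [f"layer_{i}" for i in range(len(names), n_layers)]
    rng = np.random.default_rng(seed)
    rows, cols = np.indices(spec.shape)
    layers = []
    for i, name in enumerate(names):
        lo, hi, units = ranges.get(name, (0.0, 1.0, ""))
        if lo >= hi:
            raise ValueError(f"layer '{name}': invalid range ({lo}, {hi})")
        ramp = rows / max(spec.n_rows - 1, 1) if i % 2 == 0 else cols / max(spec.n_cols - 1, 1)
        noise = rng.standard_normal(spec.shape)
        if autocorr_range_cells > 0:
            noise = gaussian_filter(noise, sigma=autocorr_range_cells)
        # rescale both parts to [0, 1] before mixing so the weight is meaningful
        if noise.max() > noise.min():
            noise = (noise - noise.min()) / (noise.max() - noise.min())
        field_ = gradient_weight * ramp + (1 - gradient_weight) * noise
        span = field_.max() - field_.min()
        if span > 0:
            field_ = (field_ - field_.min()) / span
        values = lo + field_ * (hi - lo)
        values = np.where(spec.valid_mask, values, np.nan)
        layers.append(EnvLayer(name=name, spec=spec, values=values, units=units))
    return EnvStack(layers)


def define_virtual_species(
    niche: NicheDefinition,
    stack: EnvStack,
    name: str = "virtual",
) -> VirtualSpecies:
    """Realise a niche on a landscape.

    Suitability is the product over active layers of
    ``exp(-0.5 ((x - optimum)/breadth)^2)``, normalised to a maximum of 1
    over valid cells. Occupancy thresholds suitability at the quantile
    that makes the occupied fraction of valid cells match the prevalence
    target.
    """
    spec = stack.spec
    missing = set(niche.responses) - set(stack.names)
    if missing:
        raise ValueError(f"niche references unknown layers: {sorted(missing)}")
    suit = np.ones(spec.shape)
    for layer_name, (opt, breadth) in niche.responses.items():
        x = stack[layer_name].values
        suit = suit * np.exp(-0.5 * ((x - opt) / breadth) ** 2)
    suit = np.where(spec.valid_mask, suit, np.nan)
    m = np.nanmax(suit)
    if not np.isfinite(m) or m <= 0:
        raise ValueError("suitability vanished everywhere; niche optimum too far outside the landscape")
    suit = suit / m
    valid_vals = suit[spec.valid_mask]
    cutoff = np.quantile(valid_vals, 1 - niche.prevalence_target)
    with np.errstate(invalid="ignore"):
        binary = np.where(spec.valid_mask, suit >= cutoff, False)
    if not binary.any():
        raise ValueError("empty occupied set")
    return VirtualSpecies(name=name, niche=niche, suitability=suit, true_binary=binary)


def sample_occurrences(
    vs: VirtualSpecies,
    spec: GridSpec,
    n: int = 60,
    seed: int = 0,
    source_id: str = "synthetic",
) -> pd.DataFrame:
    """Presence-only samples drawn proportionally to suitability.

    ``n`` cells are drawn with replacement from the occupied cells with
    probability proportional to suitability, then deduplicated to the
    cell level; record coordinates are cell centers. Every record lies
    inside the species' true range by construction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    occ_rows, occ_cols = np.where(vs.true_binary)
    if occ_rows.size == 0:
        raise ValueError("no occupied cells to sample")
    probs = vs.suitability[occ_rows, occ_cols]
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    draws = rng.choice(occ_rows.size, size=n, replace=True, p=probs)
    chosen = np.unique(draws)
    lon = spec.origin_x + (occ_cols[chosen] + 0.5) * spec.cell_size
    lat = spec.origin_y - (occ_rows[chosen] + 0.5) * spec.cell_size
    return pd.DataFrame(
        {
            "taxon": vs.name,
            "lon": lon,
            "lat": lat,
            "depth_m": np.nan,
            "source_id": source_id,
        }
    )


def sample_niche(
    stack: EnvStack,
    rng: np.random.Generator,
    n_active_choices: tuple[int, ...] = (1, 1, 2, 3),
    breadth_frac_range: tuple[float, float] = (0.08, 0.25),
    prevalence_range: tuple[float, float] = (0.08, 0.25),
) -> NicheDefinition:
    """Draw a random niche: active layers, optima within layer ranges,
    breadths as a fraction of each range. Half the draws are single-layer
    specialists by default."""
    n_active = int(rng.choice(n_active_choices))
    names = list(rng.choice(stack.names, size=n_active, replace=False))
    responses = {}
    for name in names:
        vals = stack[name].values[stack.spec.valid_mask]
        lo, hi = float(vals.min()), float(vals.max())
        opt = float(rng.uniform(lo, hi))
        breadth = float(rng.uniform(*breadth_frac_range) * (hi - lo))
        responses[name] = (opt, breadth)
    prevalence = float(rng.uniform(*prevalence_range))
    return NicheDefinition(responses=responses, prevalence_target=prevalence)


def build_scenario(
    spec: GridSpec | None = None,
    n_species: int = 20,
    n_layers: int = 15,
    records_per_species: int = 60,
    seed: int = 0,
    autocorr_range_cells: float = 8.0,
    gradient_weight: float = 0.4,
    niche_kwargs: dict | None = None,
) -> SyntheticScenario:
    """Build a full synthetic study: landscape, species, samples, truth.

    Defaults emulate the study conditions exercised throughout the test
    suite: a 100x100 shelf grid, 15 autocorrelated layers, 20 virtual
    species with Gaussian niches, 60 presence-only draws each.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if spec is None:
        spec = coastal_shelf_grid()
    rng = np.random.default_rng(seed)
    stack = generate_env_stack(
        spec,
        n_layers=n_layers,
        autocorr_range_cells=autocorr_range_cells,
        gradient_weight=gradient_weight,
        seed=int(rng.integers(2**31 - 1)),
    )
    species: list[VirtualSpecies] = []
    tables = []
    for i in range(n_species):
        niche = sample_niche(stack, rng, **(niche_kwargs or {}))
        vs = define_virtual_species(niche, stack, name=f"Virtualis species{i:03d}")
        occ = sample_occurrences(
            vs, spec, n=records_per_species, seed=int(rng.integers(2**31 - 1))
        )
        # construction invariant: presence-only samples stay in the true range
        for lon, lat in zip(occ["lon"], occ["lat"]):
            cell = spec.point_to_cell(lon, lat)
            assert cell is not None and vs.true_binary[cell]
        species.append(vs)
        tables.append(occ)
    counts = np.sum([vs.true_binary.astype(int) for vs in species], axis=0)
    counts[~spec.valid_mask] = -1
    provenance = {
        "seed": seed,
        "n_species": n_species,
        "n_layers": n_layers,
        "records_per_species": records_per_species,
        "niches": {
            vs.name: {
                "responses": vs.niche.responses,
                "prevalence_target": vs.niche.prevalence_target,
                "range_size": vs.range_size,
            }
            for vs in species
        },
    }
    return SyntheticScenario(
        stack=stack,
        species=species,
        occurrences=pd.concat(tables, ignore_index=True),
        true_richness=RichnessMap(spec=spec, counts=counts),
        seed=seed,
        provenance=provenance,
    )


def write_scenario(scenario: SyntheticScenario, directory: str | Path) -> None:
    """Serialise a scenario: .asc layers, occurrences CSV, truth CSV, provenance JSON."""
    from .raster_io import write_stack

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_stack(directory / "layers", scenario.stack)
    scenario.occurrences.to_csv(directory / "occurrences.csv", index=False)
    truth = pd.DataFrame(
        [
            {
                "species": vs.name,
                "n_niche_layers": len(vs.niche.responses),
                "niche_layers": ";".join(vs.niche.responses),
                "prevalence_target": vs.niche.prevalence_target,
                "range_size": vs.range_size,
            }
            for vs in scenario.species
        ]
    )
    truth.to_csv(directory / "truth.csv", index=False)
    with open(directory / "provenance.json", "w") as fh:
        json.dump(scenario.provenance, fh, indent=2, default=str)
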