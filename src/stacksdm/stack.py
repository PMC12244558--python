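"""Stacking per-species binary maps into community surfaces.

Richness is the cellwise sum of TSS-thresholded binary maps; uncertainty
is the mean (over species) of the between-algorithm standard deviation of
member suitabilities; endemism is the weighted endemism index (WEI), the
cellwise sum of inverse range sizes. ``evaluate_community`` scores
predicted assemblages against observed ones at occurrence sites.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import EnsembleSDM
from .envgrid import GridSpec
from .sdm_fit import ConfusionCounts, confusion_metrics

logger = logging.getLogger(__name__)


@dataclass
class RichnessMap:
    spec: GridSpec
    counts: np.ndarray  # int grid; -1 outside valid mask

    @property
    def values(self) -> np.ndarray:
        """Counts as float with NaN outside the valid mask."""
        out = self.counts.astype(float)
        out[~self.spec.valid_mask] = np.nan
        return out


@dataclass
class UncertaintyMap:
    spec: GridSpec
    values: np.ndarray


@dataclass
class EndemismMap:
    spec: GridSpec
    values: np.ndarray
    method: str = "WEI"


@dataclass
class CommunityEval:
    """Mean +/- SD of site-level assemblage metrics.

    ``prediction_success`` is percent correct over the species roster;
    ``species_richness_error`` is the absolute difference between
    predicted and observed richness at a site.
    """

    mean: dict[str, float]
    sd: dict[str, float]
    n_sites: int
    per_site: pd.DataFrame


def stack_binary(ensembles: list[EnsembleSDM], spec: GridSpec) -> RichnessMap:
    """Sum thresholded per-species binary maps into a richness surface."""
    shape = spec.shape
    for e in ensembles:
        if e.suitability.shape != shape:
            raise ValueError(f"species '{e.species}' grid differs from stack grid")
    counts = np.zeros(shape, dtype=int)
    for e in ensembles:
        counts += e.binary.astype(int)
    counts[~spec.valid_mask] = -1
    return RichnessMap(spec=spec, counts=counts)


def uncertainty_map(ensembles: list[EnsembleSDM], spec: GridSpec) -> UncertaintyMap:
    """Mean over species of the SD across member suitability maps per cell."""
    for e in ensembles:
        if len(e.members) < 2:
            raise ValueError(f"species '{e.species}' ensemble has a single member")
    sds = []
    for e in ensembles:
        member_stack = np.stack([m.suitability for m in e.members])
        sds.append(np.std(member_stack, axis=0, ddof=0))
    values = np.mean(np.stack(sds), axis=0)
    values = np.where(spec.valid_mask, values, np.nan)
    return UncertaintyMap(spec=spec, values=values)


def endemism_map(ensembles: list[EnsembleSDM], spec: GridSpec, method: str = "WEI") -> EndemismMap:
    """Weighted endemism: WEI(cell) = sum over species of binary/range size.

    Range-restricted species contribute more per occupied cell; a species
    with an empty predicted range is excluded with a warning.
    """
    if method != "WEI":
        raise ValueError("only the WEI endemism method is implemented")
    values = np.zeros(spec.shape, dtype=float)
    for e in ensembles:
        rng_size = int(e.binary.sum())
        if rng_size == 0:
            warnings.warn(f"species '{e.species}' has an empty predicted range; excluded from WEI")
            continue
        values += e.binary.astype(float) / rng_size
    values = np.where(spec.valid_mask, values, np.nan)
    return EndemismMap(spec=spec, values=values, method=method)


def observed_assemblages(records: pd.DataFrame, spec: GridSpec) -> dict[tuple[int, int], set[str]]:
    """Observed species sets per occupied grid cell (evaluation sites)."""
    sites: dict[tuple[int, int], set[str]] = {}
    for taxon, lon, lat in zip(records["taxon"], records["lon"], records["lat"]):
        cell = spec.point_to_cell(lon, lat)
        if cell is not None and spec.valid_mask[cell]:
            sites.setdefault(cell, set()).add(taxon)
    return sites


def evaluate_community(
    ensembles: list[EnsembleSDM],
    observed: dict[tuple[int, int], set[str]],
) -> CommunityEval:
    """Score predicted against observed assemblages at evaluation sites.

    At each site the species roster (all modelled species) is scored as a
    confusion table: TP = predicted and observed, FP = predicted only,
    FN = observed only, TN = neither. Observed absence of unrecorded
    roster species is assumed — the unavoidable convention with
    presence-only data. Sites whose observed set contains no roster
    species are skipped with a warning. Degenerate per-site metrics
    (e.g. specificity at a site observing the full roster) are NaN and
    excluded from the means.
    """
    roster = [e.species for e in ensembles]
    binaries = {e.species: e.binary for e in ensembles}
    rows = []
    for cell, obs in observed.items():
        obs_in_roster = obs & set(roster)
        if not obs_in_roster:
            warnings.warn(f"site {cell}: no roster species observed; skipped")
            continue
        predicted = {s for s in roster if binaries[s][cell]}
        tp = len(predicted & obs_in_roster)
        fp = len(predicted - obs_in_roster)
        fn = len(obs_in_roster - predicted)
        tn = len(roster) - tp - fp - fn
        row = {
            "site": cell,
            "species_richness_error": abs(len(predicted) - len(obs_in_roster)),
            "prediction_success": 100.0 * (tp + tn) / len(roster),
        }
        try:
            m = confusion_metrics(ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn))
            row.update(
                kappa=m.kappa, specificity=m.specificity,
                sensitivity=m.sensitivity, jaccard=m.jaccard, tss=m.tss,
            )
        except ValueError:
            row.update(kappa=np.nan, specificity=np.nan, sensitivity=np.nan,
                       jaccard=np.nan, tss=np.nan)
        rows.append(row)
    if not rows:
        raise ValueError("no usable evaluation sites")
    per_site = pd.DataFrame(rows).set_index("site")
    mean = per_site.mean().to_dict()
    sd = per_site.std(ddof=1).fillna(0.0).to_dict() if len(per_site) > 1 else {k: 0.0 for k in per_site}
    return CommunityEval(mean=mean, sd=sd, n_sites=len(per_site), per_site=per_site)
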