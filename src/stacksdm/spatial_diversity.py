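"""Regional and gradient statistics on richness surfaces.

One-way ANOVA with Tukey HSD across user-defined regions, ordinary
least-squares richness gradients along latitude/longitude, and global
Moran's I under binary rook-contiguity weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .envgrid import GridSpec
from .stack import RichnessMap


@dataclass
class AnovaResult:
    """Classical one-way ANOVA table plus Tukey HSD pairwise comparisons."""

    f_stat: float
    p: float
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    group_means: pd.Series
    tukey: pd.DataFrame  # group1, group2, meandiff, lower, upper, reject


@dataclass
class GradientFit:
    """OLS fit of richness on a single coordinate axis."""

    axis: str
    beta: float
    intercept: float
    t_stat: float
    r_squared: float
    f_stat: float
    p: float
    n: int


@dataclass
class MoranResult:
    I: float
    expected: float
    z: float
    p: float
    n: int


def regional_anova(richness: RichnessMap, labels: np.ndarray) -> AnovaResult:
    """One-way ANOVA of per-cell richness across labelled regions.

    ``labels`` is a per-cell array of region names (object/str dtype) over
    the richness grid; cells labelled None/empty or outside the valid
    mask are excluded. Tukey HSD intervals use alpha = 0.05.
    """
    vals = richness.values
    lab = np.asarray(labels, dtype=object)
    if lab.shape != vals.shape:
        raise ValueError("labels shape differs from richness grid")
    ok = np.isfinite(vals) & np.array([[bool(x) for x in row] for row in lab])
    v = vals[ok]
    g = lab[ok].astype(str)
    groups = pd.unique(g)
    if len(groups) < 2:
        raise ValueError("need at least 2 regions")
    for name in groups:
        if (g == name).sum() < 2:
            raise ValueError(f"region '{name}' has fewer than 2 cells")
    samples = [v[g == name] for name in groups]
    f_stat, p = stats.f_oneway(*samples)
    grand = v.mean()
    ss_between = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    tuk = pairwise_tukeyhsd(v, g, alpha=0.05)
    tukey = pd.DataFrame(
        tuk.summary().data[1:], columns=[c.strip() for c in tuk.summary().data[0]]
    )
    return AnovaResult(
        f_stat=float(f_stat),
        p=float(p),
        df_between=len(groups) - 1,
        df_within=len(v) - len(groups),
        ss_between=float(ss_between),
        ss_within=float(ss_within),
        group_means=pd.Series({name: s.mean() for name, s in zip(groups, samples)}),
        tukey=tukey,
    )


def gradient_regression(
    richness: RichnessMap,
    axis: str = "latitude",
    subsample: int | None = None,
    seed: int = 0,
) -> GradientFit:
    """OLS of cell richness on the cell-center coordinate along one axis.

    ``beta`` is species per unit coordinate (per degree on geographic
    grids). ``subsample`` draws a seeded random subset of valid cells for
    very large grids.
    """
    if axis not in {"latitude", "longitude"}:
        raise ValueError("axis must be 'latitude' or 'longitude'")
    cx, cy = richness.spec.cell_centers()
    coord = cy if axis == "latitude" else cx
    vals = richness.values
    ok = np.isfinite(vals)
    x = coord[ok]
    y = vals[ok]
    if subsample is not None and subsample < len(x):
        idx = np.random.default_rng(seed).choice(len(x), size=subsample, replace=False)
        x, y = x[idx], y[idx]
    if len(x) < 3 or np.std(x) == 0:
        raise ValueError("need >= 3 cells with coordinate variance")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return GradientFit(
        axis=axis,
        beta=float(fit.params[1]),
        intercept=float(fit.params[0]),
        t_stat=float(fit.tvalues[1]),
        r_squared=float(fit.rsquared),
        f_stat=float(fit.fvalue),
        p=float(fit.pvalues[1]),
        n=int(fit.nobs),
    )


def rook_weights(spec: GridSpec) -> tuple[sp.csr_matrix, np.ndarray]:
    """Binary rook-contiguity weights over the valid cells of a grid.

    Returns (W, flat indices of the valid cells W is indexed by). Weights
    are symmetric 0/1 and not row-standardised.
    """
    mask = spec.valid_mask
    idx_grid = np.full(spec.shape, -1, dtype=int)
    rows, cols = np.where(mask)
    idx_grid[rows, cols] = np.arange(len(rows))
    src, dst = [], []
    for dr, dc in ((0, 1), (1, 0)):
        r2, c2 = rows + dr, cols + dc
        ok = (r2 < spec.n_rows) & (c2 < spec.n_cols)
        ok[ok] &= mask[r2[ok], c2[ok]]
        a = idx_grid[rows[ok], cols[ok]]
        b = idx_grid[r2[ok], c2[ok]]
        src.extend([a, b])
        dst.extend([b, a])
    n = len(rows)
    src = np.concatenate(src) if src else np.array([], dtype=int)
    dst = np.concatenate(dst) if dst else np.array([], dtype=int)
    W = sp.csr_matrix((np.ones(len(src)), (src, dst)), shape=(n, n))
    return W, rows * spec.n_cols + cols


def morans_i(values: np.ndarray, W: sp.spmatrix) -> MoranResult:
    """Global Moran's I with z-score and p under the normality approximation.

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z the centred
    values and S0 the total weight. E[I] = -1/(n-1).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0:
        raise ValueError("Moran's I undefined for a constant surface")
    W = sp.csr_matrix(W)
    s0 = W.sum()
    if s0 <= 0:
        raise ValueError("need at least one positive weight")
    z = x - x.mean()
    num = float(z @ (W @ z))
    den = float((z**2).sum())
    I = (n / s0) * num / den

    expected = -1.0 / (n - 1)
    # variance under normality (symmetric W assumed)
    s1 = 0.5 * float(((W + W.T).power(2)).sum())
    row_sums = np.asarray(W.sum(axis=1)).ravel()
    col_sums = np.asarray(W.sum(axis=0)).ravel()
    s2 = float(((row_sums + col_sums) ** 2).sum())
    var = (n**2 * s1 - n * s2 + 3 * s0**2) / ((n**2 - 1) * s0**2) - expected**2
    zscore = (I - expected) / np.sqrt(var) if var > 0 else np.nan
    p = 2 * stats.norm.sf(abs(zscore)) if np.isfinite(zscore) else np.nan
    return MoranResult(I=float(I), expected=float(expected), z=float(zscore), p=float(p), n=n)


def morans_i_grid(
    richness: RichnessMap,
    subsample: int | None = None,
    seed: int = 0,
) -> MoranResult:
    """Moran's I of a richness surface under rook weights on its grid.

    Subsampling, when requested, crops to a seeded random rectangular
    window rather than scattering points (scattered subsets lose
    contiguity and hence all weights).
    """
    spec = richness.spec
    vals = richness.values
    if subsample is not None and int(spec.valid_mask.sum()) > subsample:
        side = max(3, int(np.sqrt(subsample)))
        rng = np.random.default_rng(seed)
        r0 = int(rng.integers(0, max(1, spec.n_rows - side)))
        c0 = int(rng.integers(0, max(1, spec.n_cols - side)))
        window = np.zeros(spec.shape, dtype=bool)
        window[r0 : r0 + side, c0 : c0 + side] = True
        from dataclasses import replace

        spec = replace(spec, valid_mask=spec.valid_mask & window)
    W, flat = rook_weights(spec)
    x = vals.ravel()[flat]
    keep = np.isfinite(x)
    if not keep.all():
        W = W[keep][:, keep]
        x = x[keep]
    return morans_i(x, W)
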