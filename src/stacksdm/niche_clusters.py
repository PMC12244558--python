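"""Clustering species by environmental-importance profiles.

PCA on the species x variable importance matrix followed by Ward
hierarchical clustering on the retained principal-component scores (the
HCPC idiom, without the optional k-means consolidation step).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage


@dataclass
class PCAResult:
    """Eigendecomposition of the (standardised) importance matrix.

    ``scores @ loadings.T`` reproduces the centred/scaled data when all
    components are retained; eigenvalues sum to the number of columns
    when ``scale=True`` (correlation-matrix PCA).
    """

    eigenvalues: np.ndarray
    loadings: pd.DataFrame  # variables x components
    scores: pd.DataFrame  # rows x components
    center: np.ndarray
    scale_: np.ndarray | None

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total == 0:  # degenerate case: no variance at all
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total


@dataclass
class ClusterAssignment:
    labels: pd.Series  # species -> cluster id in 1..k
    k: int
    linkage: str = "ward"
    inertia_gain: dict[int, float] = field(default_factory=dict)


def pca(matrix: pd.DataFrame, center: bool = True, scale: bool = True) -> PCAResult:
    """Principal component analysis via SVD.

    With ``scale=True`` (default) columns are standardised (sd with one
    delta degree of freedom), so the decomposition is that of the
    correlation matrix. Zero-variance columns cannot be scaled and raise
    an error naming them.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    if not np.isfinite(X).all():
        raise ValueError("matrix contains missing or non-finite entries")
    mu = X.mean(axis=0) if center else np.zeros(X.shape[1])
    Xc = X - mu
    sd = None
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        dead = [str(c) for c, s in zip(matrix.columns, sd) if s == 0]
        if dead:
            raise ValueError(f"zero-variance columns cannot be scaled: {dead}")
        Xc = Xc / sd
    n = X.shape[0]
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-magnitude loading of each component positive
    for j in range(Vt.shape[0]):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    eigenvalues = s**2 / (n - 1)
    comps = [f"PC{i + 1}" for i in range(len(s))]
    loadings = pd.DataFrame(Vt.T, index=matrix.columns, columns=comps)
    scores = pd.DataFrame(Xc @ Vt.T, index=matrix.index, columns=comps)
    return PCAResult(
        eigenvalues=eigenvalues, loadings=loadings, scores=scores, center=mu, scale_=sd
    )


def _within_inertia(scores: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(labels):
        pts = scores[labels == c]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def retained_components(p: PCAResult, var_target: float = 0.8, cap: int = 5) -> int:
    """Smallest component count explaining >= var_target, capped."""
    cum = np.cumsum(p.explained_variance_ratio)
    k = int(np.searchsorted(cum, var_target) + 1)
    return min(k, cap, len(p.eigenvalues))


def hcpc(p: PCAResult, n_components: int | None = None, k: int | str = "auto") -> ClusterAssignment:
    """Ward clustering on retained principal-component scores.

    ``k="auto"`` picks the candidate in [2, 10] with the largest relative
    drop in within-cluster inertia between consecutive cuts — the elbow
    of the dendrogram. Deterministic: ward linkage has no random state.
    """
    if n_components is None:
        n_components = retained_components(p)
    if n_components > p.scores.shape[1]:
        raise ValueError("n_components exceeds available components")
    S = p.scores.values[:, :n_components]
    n = S.shape[0]
    if isinstance(k, int) and k > n:
        raise ValueError(f"fewer species ({n}) than requested clusters ({k})")

    total = _within_inertia(S, np.zeros(n, dtype=int))
    if total == 0:
        warnings.warn("all profiles identical; returning a single cluster")
        return ClusterAssignment(
            labels=pd.Series(1, index=p.scores.index), k=1, inertia_gain={}
        )

    Z = linkage(S, method="ward")
    gains: dict[int, float] = {}
    prev = total
    within: dict[int, float] = {}
    max_k = min(10, n - 1)
    for kk in range(2, max_k + 1):
        lab = fcluster(Z, t=kk, criterion="maxclust")
        within[kk] = _within_inertia(S, lab)
        gains[kk] = (prev - within[kk]) / prev if prev > 0 else 0.0
        prev = within[kk]

    if k == "auto":
        k = max(gains, key=lambda kk: gains[kk]) if gains else 1
    labels = fcluster(Z, t=int(k), criterion="maxclust")
    return ClusterAssignment(
        labels=pd.Series(labels, index=p.scores.index), k=int(k), inertia_gain=gains
    )


def characterize_clusters(
    assignment: ClusterAssignment, matrix: pd.DataFrame
) -> pd.DataFrame:
    """Per-cluster mean importances, variable ranking and representatives.

    Variables are ranked within each cluster by their standardised
    contrast (cluster mean minus grand mean, in units of the variable's
    overall SD); the representative species is the member closest to the
    cluster centroid in standardised importance space.
    """
    labels = assignment.labels
    grand_mean = matrix.mean()
    grand_sd = matrix.std(ddof=1).replace(0, np.nan)
    Z = (matrix - grand_mean) / grand_sd
    rows = []
    for c in sorted(labels.unique()):
        members = labels.index[labels == c]
        sub = matrix.loc[members]
        contrast = ((sub.mean() - grand_mean) / grand_sd).fillna(0.0)
        top = contrast.sort_values(ascending=False).index.tolist()
        centroid = Z.loc[members].mean()
        dists = ((Z.loc[members] - centroid) ** 2).sum(axis=1)
        rows.append(
            {
                "cluster": int(c),
                "n_species": len(members),
                "top_variables": top[:4],
                "representative_species": dists.idxmin(),
                **{f"mean_{v}": sub[v].mean() for v in matrix.columns},
            }
        )
    return pd.DataFrame(rows).set_index("cluster")
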