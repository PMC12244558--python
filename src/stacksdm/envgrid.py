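"""Environmental raster stack: grid geometry, resampling, cropping, collinearity.

The analysis grid is a north-up regular grid. Row 0 is the northernmost row,
columns increase eastward, and cells own the half-open interval
``[x, x + cell_size)`` in easting and the corresponding half-open interval
downward from the northern edge. ``origin_x``/``origin_y`` locate the
*north-west corner* of the grid.

Layers are plain 2-D float arrays with NaN-free values wherever the shared
validity mask is true; invalid cells carry NaN. A stack is an ordered,
name-unique collection of layers sharing one :class:`GridSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class ExtentError(ValueError):
    """Raised when two grids or a grid and a bounding box do not overlap."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular north-up analysis grid.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape; row 0 is the northernmost row.
    cell_size
        Cell edge length in map units (degrees or metres), > 0.
    origin_x, origin_y
        Easting / northing of the grid's north-west corner.
    crs_id
        Free-text identifier of the coordinate reference system
        (e.g. ``"EPSG:4326"``). Only recorded, never reprojected.
    valid_mask
        Boolean array of shape ``(n_rows, n_cols)``; True marks analysable
        cells (e.g. sea, not land).
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_x: float
    origin_y: float
    crs_id: str = "EPSG:4326"
    valid_mask: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid shape must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        mask = self.valid_mask
        if mask is None:
            mask = np.ones((self.n_rows, self.n_cols), dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.n_rows, self.n_cols):
            raise ValueError(
                f"valid_mask shape {mask.shape} != ({self.n_rows}, {self.n_cols})"
            )
        object.__setattr__(self, "valid_mask", mask)

    # -- geometry helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid extent."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinate arrays of shape (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def point_to_cell(self, x: float, y: float) -> tuple[int, int] | None:
        """Map a point to its owning (row, col), or None if off-grid.

        Ownership is half-open: a point exactly on a cell's western edge
        belongs to that cell; one on the eastern edge belongs to the
        neighbour. Same convention top-down from the northern edge.
        """
        col = int(np.floor((x - self.origin_x) / self.cell_size))
        row = int(np.floor((self.origin_y - y) / self.cell_size))
        # the exact southern/eastern boundary of the grid closes the last cell
        if x == self.origin_x + self.n_cols * self.cell_size:
            col = self.n_cols - 1
        if y == self.origin_y - self.n_rows * self.cell_size:
            row = self.n_rows - 1
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return row, col
        return None

    def same_geometry(self, other: "GridSpec") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.isclose(self.origin_x, other.origin_x)
            and np.isclose(self.origin_y, other.origin_y)
        )


@dataclass
class EnvLayer:
    """A single named environmental predictor grid (one variable, one unit)."""

    name: str
    spec: GridSpec
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"layer '{self.name}': values shape {self.values.shape} "
                f"!= grid {self.spec.shape}"
            )
        bad = self.spec.valid_mask & ~np.isfinite(self.values)
        if bad.any():
            raise ValueError(
                f"layer '{self.name}': {int(bad.sum())} non-finite values on valid cells"
            )


@dataclass
class EnvStack:
    """Ordered collection of co-registered environmental layers."""

    layers: list[EnvLayer]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("stack must contain at least one layer")
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate layer names: {names}")
        spec = self.layers[0].spec
        for layer in self.layers[1:]:
            if not layer.spec.same_geometry(spec):
                raise ValueError(f"layer '{layer.name}' geometry differs from stack")

    @property
    def spec(self) -> GridSpec:
        return self.layers[0].spec

    @property
    def names(self) -> list[str]:
        return [l.name for l in self.layers]

    def __getitem__(self, name: str) -> EnvLayer:
        for layer in self.layers:
            if layer.name == name:
                return layer
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.layers)

    def to_array(self) -> np.ndarray:
        """Stack values as an array of shape (n_layers, n_rows, n_cols)."""
        return np.stack([l.values for l in self.layers])

    def extract(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Extract the per-layer values at cells, shape (n_cells, n_layers)."""
        return np.column_stack([l.values[rows, cols] for l in self.layers])

    def select(self, names: list[str]) -> "EnvStack":
        return EnvStack([self[n] for n in names])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def resample_bilinear(layer: EnvLayer, target: GridSpec) -> EnvLayer:
    """Resample a layer onto a new grid by bilinear interpolation.

    Each target cell center is interpolated from the four enclosing source
    cell centers. If *any* of the four contributing corners is nodata the
    output cell is nodata — a conservative rule that avoids fabricating
    values along coastlines. Target centers that fall inside the source
    extent but outside the hull of source centers (the half-cell border)
    are clamped to the nearest edge of the center lattice.
    """
    src = layer.spec
    if src.n_rows < 2 or src.n_cols < 2:
        raise ValueError("source layer needs at least 2x2 cells")
    sxmin, symin, sxmax, symax = src.bounds
    txmin, tymin, txmax, tymax = target.bounds
    if txmin >= sxmax or txmax <= sxmin or tymin >= symax or tymax <= symin:
        raise ExtentError("target grid does not overlap source layer extent")

    tx, ty = target.cell_centers()
    # fractional position in source *center* coordinates
    gx = (tx - src.origin_x) / src.cell_size - 0.5
    gy = (src.origin_y - ty) / src.cell_size - 0.5
    inside = (gx >= -0.5) & (gx <= src.n_cols - 0.5) & (gy >= -0.5) & (gy <= src.n_rows - 0.5)
    gx = np.clip(gx, 0.0, src.n_cols - 1.0)
    gy = np.clip(gy, 0.0, src.n_rows - 1.0)

    c0 = np.floor(gx).astype(int)
    r0 = np.floor(gy).astype(int)
    c0 = np.minimum(c0, src.n_cols - 2)
    r0 = np.minimum(r0, src.n_rows - 2)
    fx = gx - c0
    fy = gy - r0

    vals = np.where(src.valid_mask, layer.values, np.nan)
    v00 = vals[r0, c0]
    v01 = vals[r0, c0 + 1]
    v10 = vals[r0 + 1, c0]
    v11 = vals[r0 + 1, c0 + 1]
    out = (
        v00 * (1 - fx) * (1 - fy)
        + v01 * fx * (1 - fy)
        + v10 * (1 - fx) * fy
        + v11 * fx * fy
    )
    out[~inside] = np.nan
    mask = target.valid_mask & np.isfinite(out)
    out = np.where(mask, out, np.nan)
    new_spec = replace(target, valid_mask=mask)
    return EnvLayer(name=layer.name, spec=new_spec, values=out, units=layer.units)


def crop(stack: EnvStack, bbox: tuple[float, float, float, float]) -> EnvStack:
    """Crop a stack to the cells whose centers fall inside ``bbox``.

    ``bbox`` is (xmin, ymin, xmax, ymax). Layer order is preserved.
    """
    xmin, ymin, xmax, ymax = bbox
    spec = stack.spec
    cx, cy = spec.cell_centers()
    keep = (cx >= xmin) & (cx <= xmax) & (cy >= ymin) & (cy <= ymax)
    if not keep.any():
        raise ExtentError("bbox contains no cell centers")
    rows = np.where(keep.any(axis=1))[0]
    cols = np.where(keep.any(axis=0))[0]
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    new_spec = GridSpec(
        n_rows=r1 - r0,
        n_cols=c1 - c0,
        cell_size=spec.cell_size,
        origin_x=spec.origin_x + c0 * spec.cell_size,
        origin_y=spec.origin_y - r0 * spec.cell_size,
        crs_id=spec.crs_id,
        valid_mask=spec.valid_mask[r0:r1, c0:c1],
    )
    layers = [
        EnvLayer(name=l.name, spec=new_spec, values=l.values[r0:r1, c0:c1], units=l.units)
        for l in stack.layers
    ]
    return EnvStack(layers)


@dataclass
class CorrelationResult:
    """Pairwise Pearson correlations between layers, pairwise-complete."""

    matrix: pd.DataFrame
    undefined: list[str]  # zero-variance layers whose rows/cols are NaN


def pairwise_correlation(stack: EnvStack) -> CorrelationResult:
    """Pearson correlation between all layer pairs over jointly valid cells.

    Correlations use only cells valid in both layers of a pair. A layer
    with zero variance over the joint support yields NaN entries and is
    reported in ``undefined`` rather than silently coerced to 0.
    """
    names = stack.names
    arrs = [np.where(l.spec.valid_mask, l.values, np.nan).ravel() for l in stack.layers]
    n = len(names)
    mat = np.full((n, n), np.nan)
    undefined: set[str] = set()
    for i in range(n):
        mat[i, i] = 1.0
        for j in range(i + 1, n):
            joint = np.isfinite(arrs[i]) & np.isfinite(arrs[j])
            if joint.sum() < 3:
                raise ValueError(
                    f"layers '{names[i]}'/'{names[j]}': fewer than 3 jointly valid cells"
                )
            xi, xj = arrs[i][joint], arrs[j][joint]
            if np.std(xi) == 0:
                undefined.add(names[i])
            if np.std(xj) == 0:
                undefined.add(names[j])
            if np.std(xi) == 0 or np.std(xj) == 0:
                continue
            mat[i, j] = mat[j, i] = np.corrcoef(xi, xj)[0, 1]
    for name in undefined:
        k = names.index(name)
        mat[k, :] = np.nan
        mat[:, k] = np.nan
        mat[k, k] = 1.0
    return CorrelationResult(
        matrix=pd.DataFrame(mat, index=names, columns=names),
        undefined=sorted(undefined),
    )


def screen_collinear(
    corr: pd.DataFrame,
    priority: list[str],
    threshold: float = 0.85,
) -> list[str]:
    """Greedy collinearity screen retaining the most ecologically relevant layer.

    Layers are scanned in ``priority`` order (rank 1 = most relevant). A
    layer is dropped iff its absolute correlation with an already-retained
    layer exceeds ``threshold``. The retained list preserves priority order,
    so the result does not depend on how layers were stored.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    known = set(corr.columns)
    if set(priority) != known or len(priority) != len(known):
        missing = known.symmetric_difference(priority)
        raise ValueError(f"priority list must name every layer exactly once; mismatch: {sorted(missing)}")
    retained: list[str] = []
    for name in priority:
        r_with_kept = [abs(corr.loc[name, kept]) for kept in retained]
        if any(np.isfinite(r) and r > threshold for r in r_with_kept):
            continue
        retained.append(name)
    return retained
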