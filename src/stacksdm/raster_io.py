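"""Read/write environmental layers as ESRI ASCII grids plus a YAML manifest.

One ``.asc`` file per layer (plain text, portable, diff-able); the stack
manifest is a YAML file listing, per layer: file, name, units and priority
rank for the collinearity screen. Only north-up square-cell grids are
supported, which matches the analysis grid convention.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .envgrid import EnvLayer, EnvStack, GridSpec

_NODATA = -9999.0


def write_ascii_grid(path: str | Path, values: np.ndarray, spec: GridSpec) -> None:
    """Write one grid as an ESRI ASCII raster (xllcorner/yllcorner form)."""
    path = Path(path)
    vals = np.where(spec.valid_mask & np.isfinite(values), values, _NODATA)
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {spec.origin_x!r}\n"
        f"yllcorner {spec.origin_y - spec.n_rows * spec.cell_size!r}\n"
        f"cellsize {spec.cell_size!r}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path: str | Path, crs_id: str = "EPSG:4326") -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII raster; returns (values with NaN nodata, GridSpec)."""
    path = Path(path)
    header: dict[str, float] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
                "yllcenter", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
                n_header += 1
            else:
                break
    if "ncols" not in header or "nrows" not in header:
        raise ValueError(f"{path}: not an ESRI ASCII grid (missing ncols/nrows)")
    values = np.loadtxt(path, skiprows=n_header)
    values = np.atleast_2d(values)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: data shape {values.shape} != header ({n_rows}, {n_cols})")
    cell = header["cellsize"]
    if "xllcorner" in header:
        x0 = header["xllcorner"]
        y1 = header["yllcorner"] + n_rows * cell
    else:  # center-registered variant
        x0 = header["xllcenter"] - cell / 2
        y1 = header["yllcenter"] - cell / 2 + n_rows * cell
    nodata = header.get("nodata_value", _NODATA)
    mask = values != nodata
    values = np.where(mask, values, np.nan)
    spec = GridSpec(
        n_rows=n_rows, n_cols=n_cols, cell_size=cell,
        origin_x=x0, origin_y=y1, crs_id=crs_id, valid_mask=mask,
    )
    return values, spec


def write_stack(directory: str | Path, stack: EnvStack, priority: list[str] | None = None) -> Path:
    """Write all layers of a stack plus a ``manifest.yaml``; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    priority = priority or stack.names
    entries = []
    for layer in stack.layers:
        fname = f"{layer.name}.asc"
        write_ascii_grid(directory / fname, layer.values, layer.spec)
        entries.append(
            {
                "file": fname,
                "name": layer.name,
                "units": layer.units,
                "priority": priority.index(layer.name) + 1,
            }
        )
    manifest = {"crs_id": stack.spec.crs_id, "layers": entries}
    manifest_path = directory / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


def read_stack(manifest_path: str | Path) -> tuple[EnvStack, list[str]]:
    """Read a stack from its manifest; returns (stack, priority-ordered names).

    The shared validity mask is the intersection of per-layer masks, so a
    cell is analysable only where every predictor has data.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    crs_id = manifest.get("crs_id", "EPSG:4326")
    raw = []
    for entry in sorted(manifest["layers"], key=lambda e: e.get("priority", 1)):
        values, spec = read_ascii_grid(manifest_path.parent / entry["file"], crs_id=crs_id)
        raw.append((entry["name"], entry.get("units", ""), values, spec))
    joint_mask = np.logical_and.reduce([spec.valid_mask for *_, spec in raw])
    from dataclasses import replace

    shared = replace(raw[0][3], valid_mask=joint_mask)
    layers = [
        EnvLayer(name=name, spec=shared, values=np.where(joint_mask, vals, np.nan), units=units)
        for name, units, vals, _ in raw
    ]
    stack = EnvStack(layers)
    return stack, [l.name for l in layers]
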