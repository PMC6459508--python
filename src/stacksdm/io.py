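"""Plain-text raster, table and model serialization.

Rasters travel as ESRI ASCII grids (one file per layer; float values,
nodata -9999), a text format every GIS reads, with a small JSON manifest
carrying the layer names and scenario id for a stack. Occurrences and
result tables are CSV; fitted models are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .grid import ClimateStack, GridSpec
from .models import FittedModel
from .synthetic import OccurrenceSet

NODATA = -9999.0


def write_ascii_grid(path: str | Path, arr: np.ndarray, grid: GridSpec
                     ) -> None:
    """Write one layer as an ESRI ASCII grid (row 0 = northern edge)."""
    arr = np.asarray(arr, dtype=float)
    if arr.shape != grid.shape:
        raise ValueError(f"array shape {arr.shape} != grid {grid.shape}")
    x0, y0 = grid.origin
    out = np.where(np.isfinite(arr), arr, NODATA)
    header = (f"ncols {grid.n_cols}\n"
              f"nrows {grid.n_rows}\n"
              f"xllcorner {x0}\n"
              f"yllcorner {y0}\n"
              f"cellsize {grid.cell_size_km}\n"
              f"NODATA_value {NODATA}\n")
    with open(path, "w") as fh:
        fh.write(header)
        # ASCII grids are written north-to-south; our row 0 is the south
        np.savetxt(fh, out[::-1], fmt="%.8g")


def read_ascii_grid(path: str | Path) -> Tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid back into (array, GridSpec)."""
    header: Dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            line = fh.readline()
            try:
                key, val = line.split()
                header[key.lower()] = float(val)
            except ValueError:
                raise ValueError(
                    f"malformed ASCII grid header line: {line!r}") from None
        body = np.loadtxt(fh)
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value"}
    missing = required - set(header)
    if missing:
        raise ValueError(f"ASCII grid header missing fields: {missing}")
    grid = GridSpec(n_rows=int(header["nrows"]), n_cols=int(header["ncols"]),
                    cell_size_km=header["cellsize"],
                    origin=(header["xllcorner"], header["yllcorner"]))
    arr = np.atleast_2d(body)[::-1].copy()
    arr[arr == header["nodata_value"]] = np.nan
    if arr.shape != grid.shape:
        raise ValueError(f"body shape {arr.shape} != header {grid.shape}")
    return arr, grid


def write_stack(directory: str | Path, stack: ClimateStack) -> None:
    """One ASCII grid per layer plus a manifest.json."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for name, arr in stack.layers.items():
        write_ascii_grid(d / f"{name}.asc", arr, stack.grid)
    manifest = {"scenario_id": stack.scenario_id,
                "layers": stack.layer_names}
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_stack(directory: str | Path) -> ClimateStack:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    layers = {}
    grid = None
    for name in manifest["layers"]:
        arr, g = read_ascii_grid(d / f"{name}.asc")
        if grid is None:
            grid = g
        elif g != grid:
            raise ValueError(f"layer {name!r} grid differs from stack grid")
        layers[name] = arr
    return ClimateStack(grid=grid, scenario_id=manifest["scenario_id"],
                        layers=layers)


def write_occurrences(path: str | Path, occ: OccurrenceSet) -> None:
    rows = [{"species": s, "x_km": x, "y_km": y,
             "guild": occ.species_meta.get(s, ("", ""))[0],
             "habitat": occ.species_meta.get(s, ("", ""))[1]}
            for s, x, y in occ.records]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_occurrences(path: str | Path) -> OccurrenceSet:
    df = pd.read_csv(path)
    required = {"species", "x_km", "y_km"}
    if not required <= set(df.columns):
        raise ValueError(f"occurrence CSV missing columns "
                         f"{required - set(df.columns)}")
    records = [(str(r.species), float(r.x_km), float(r.y_km))
               for r in df.itertuples()]
    meta = {}
    if {"guild", "habitat"} <= set(df.columns):
        for r in df.drop_duplicates("species").itertuples():
            meta[str(r.species)] = (str(r.guild), str(r.habitat))
    return OccurrenceSet(records=records, species_meta=meta)


def write_models(path: str | Path, models: List[FittedModel]) -> None:
    payload = [m.to_dict() for m in models]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_models(path: str | Path) -> List[FittedModel]:
    payload = json.loads(Path(path).read_text())
    return [FittedModel.from_dict(d) for d in payload]


def write_mask(path: str | Path, mask: np.ndarray, grid: GridSpec) -> None:
    write_ascii_grid(path, np.asarray(mask, dtype=float), grid)


def read_mask(path: str | Path) -> Tuple[np.ndarray, GridSpec]:
    arr, grid = read_ascii_grid(path)
    return np.nan_to_num(arr, nan=0.0).astype(int), grid
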