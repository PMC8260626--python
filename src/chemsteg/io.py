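"""File formats: picklist CSV, spectral-grid HDF5, plan files, mzML intake.

The picklist is an Echo-style dispense instruction table with pinned
columns.  Spectral grids are stored in a simple HDF5 layout::

    /meta                    attrs: lock_mass, pitch, rows, cols, seed
    /locations/{i}/mz        float64, ascending
    /locations/{i}/intensity float64
    /locations/{i}/grid_index  (row, col)

Plan files are flat ``key = value`` text documents so a reader can
reconstruct the framing (including pad length and seeds) without this
package's config machinery.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .chemchannel import SpectrumGrid
from .framing import PICKLIST_COLUMNS, FramePlan
from .geometry import GridGeometry

__all__ = [
    "write_picklist",
    "read_picklist",
    "write_grid",
    "read_grid",
    "write_plan",
    "read_plan",
    "read_mzml_peaks",
]


def write_picklist(picklist: pd.DataFrame, path) -> None:
    missing = [c for c in PICKLIST_COLUMNS if c not in picklist.columns]
    if missing:
        raise ValueError(f"picklist missing columns {missing}")
    picklist[PICKLIST_COLUMNS].to_csv(path, index=False)


def read_picklist(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PICKLIST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"picklist file missing columns {missing}")
    return df[PICKLIST_COLUMNS]


def write_grid(grid: SpectrumGrid, path) -> None:
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["lock_mass"] = grid.lock_mass
        meta.attrs["pitch"] = grid.geometry.pitch_mm
        meta.attrs["rows"] = grid.geometry.rows
        meta.attrs["cols"] = grid.geometry.cols
        meta.attrs["seed"] = int(grid.meta.get("seed", -1))
        locs = f.create_group("locations")
        for i in range(grid.n_locations):
            g = locs.create_group(str(i))
            g.create_dataset("mz", data=grid.mz[i], dtype="f8")
            g.create_dataset("intensity", data=grid.intensity[i], dtype="f8")
            g.create_dataset("grid_index", data=grid.cells[i], dtype="i8")


def read_grid(path) -> SpectrumGrid:
    with h5py.File(path, "r") as f:
        meta = f["meta"].attrs
        geometry = GridGeometry(
            rows=int(meta["rows"]), cols=int(meta["cols"]), pitch_mm=float(meta["pitch"])
        )
        locs = f["locations"]
        order = sorted(locs.keys(), key=int)
        mz = [np.asarray(locs[k]["mz"]) for k in order]
        inten = [np.asarray(locs[k]["intensity"]) for k in order]
        cells = np.stack([np.asarray(locs[k]["grid_index"]) for k in order])
        grid = SpectrumGrid(
            geometry=geometry,
            cells=cells,
            mz=mz,
            intensity=inten,
            lock_mass=float(meta["lock_mass"]),
            meta={"seed": int(meta.get("seed", -1))},
        )
    return grid


def write_plan(plan: FramePlan, path, extra: dict | None = None) -> None:
    """Serialize a frame plan (plus optional seeds/metadata) as key = value."""
    lines = [
        f"n_extracts = {plan.n_extracts}",
        f"n_locations = {plan.n_locations}",
        f"levels = {plan.levels}",
        f"repetitions = {plan.repetitions}",
        f"interleaver_seed = {plan.interleaver_seed}",
        f"pad_length = {plan.pad_length}",
    ]
    for k, v in (extra or {}).items():
        lines.append(f"{k} = {v}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_plan(path) -> tuple[FramePlan, dict]:
    """Parse a plan file; unknown keys are returned in the extras dict."""
    fields = {}
    extra = {}
    known = {
        "n_extracts",
        "n_locations",
        "levels",
        "repetitions",
        "interleaver_seed",
        "pad_length",
    }
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"bad plan line: {line!r}")
        k, v = (s.strip() for s in line.split("=", 1))
        if k in known:
            fields[k] = int(v)
        else:
            extra[k] = v
    missing = known - fields.keys()
    if missing:
        raise ValueError(f"plan file missing keys {sorted(missing)}")
    return FramePlan(**fields), extra


def read_mzml_peaks(path) -> list:
    """Best-effort centroided mzML intake: list of (mz, intensity) arrays.

    Spectra are returned in file order; mapping them onto grid cells is
    the caller's responsibility (acquisition order is instrument
    specific).
    """
    from pyteomics import mzml  # optional dependency, imported lazily

    out = []
    with mzml.read(str(path)) as reader:
        for spec in reader:
            mz = np.asarray(spec["m/z array"], dtype=np.float64)
            inten = np.asarray(spec["intensity array"], dtype=np.float64)
            order = np.argsort(mz)
            out.append((mz[order], inten[order]))
    return out
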