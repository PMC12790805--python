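"""MRC volume/stack and STAR metadata input/output.

Volumes and image stacks travel as MRC/CCP4 maps (mode 2, pixel size in the
header) via gemmi; particle metadata travels as STAR tables with
RELION-style column names (``rlnAngleRot``, ``rlnAngleTilt``,
``rlnAnglePsi``, ``rlnOriginXAngst``, ``rlnOriginYAngst``, ``rlnDefocusU``,
``rlnImageName``) plus ``tl_*`` extension columns carrying simulator ground
truth.  In memory a particle table is a plain pandas DataFrame.

Image stacks are stored as 3D MRC grids of shape (n, N, N); the pixel size
recorded in the header is the in-plane pixel size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import gemmi

from .geometry import DensityVolume

__all__ = [
    "read_mrc",
    "write_mrc",
    "read_volume",
    "write_volume",
    "read_star",
    "write_star",
]

# Canonical metadata columns; everything numeric except the image reference
# and the categorical ground-truth state label.
_STRING_COLUMNS = {"rlnImageName", "tl_state"}


def write_mrc(path, data: np.ndarray, pixel_size: float) -> None:
    """Write a 3D array (volume ``[z, y, x]`` or stack ``[i, y, x]``)."""
    data = np.ascontiguousarray(np.asarray(data, dtype=np.float32))
    if data.ndim != 3:
        raise ValueError("expected a 3D array")
    m = gemmi.Ccp4Map()
    # gemmi grids index (nu, nv, nw) fastest-first; transpose so the file
    # round-trips to the same numpy layout.
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(data.transpose(2, 1, 0)))
    nz, ny, nx = data.shape
    m.grid.set_unit_cell(
        gemmi.UnitCell(nx * pixel_size, ny * pixel_size, nz * pixel_size, 90, 90, 90)
    )
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_mrc(path):
    """Read an MRC map; returns ``(data, pixel_size)`` with data ``[z, y, x]``."""
    m = gemmi.read_ccp4_map(str(path))
    arr = np.array(m.grid, copy=True).transpose(2, 1, 0)
    return arr, float(m.grid.spacing[0])


def write_volume(path, volume: DensityVolume) -> None:
    write_mrc(path, volume.voxels, volume.pixel_size)


def read_volume(path) -> DensityVolume:
    data, apix = read_mrc(path)
    return DensityVolume(data.astype(np.float64), apix)


def write_star(path, records: pd.DataFrame, block_name: str = "particles") -> None:
    """Write a particle table as a single-block STAR loop."""
    doc = gemmi.cif.Document()
    block = doc.add_new_block(block_name)
    cols = list(records.columns)
    loop = block.init_loop("_", cols)
    for row in records.itertuples(index=False):
        cells = []
        for col, v in zip(cols, row):
            if col in _STRING_COLUMNS:
                cells.append(str(v))
            else:
                cells.append(f"{float(v):.10g}")
        loop.add_row(cells)
    doc.write_file(str(path))


def read_star(path, block_name: str | None = None) -> pd.DataFrame:
    """Read a STAR particle table back into a DataFrame.

    Numeric columns are parsed as floats; ``rlnImageName`` and ``tl_state``
    stay strings.
    """
    doc = gemmi.cif.read_file(str(path))
    block = doc.sole_block() if block_name is None else doc.find_block(block_name)
    if block is None:
        raise ValueError(f"block {block_name!r} not found in {path}")
    data = {}
    for item in block:
        loop = item.loop
        if loop is None:
            continue
        width = loop.width()
        values = np.array(loop.values, dtype=object).reshape(-1, width)
        for j, tag in enumerate(loop.tags):
            col = tag.lstrip("_")
            if col in _STRING_COLUMNS:
                data[col] = [str(v) for v in values[:, j]]
            else:
                data[col] = values[:, j].astype(float)
    if not data:
        raise ValueError(f"no loop data in {path}")
    return pd.DataFrame(data)
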