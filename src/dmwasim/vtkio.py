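"""Legacy-ASCII VTK structured-points export for visual inspection.

Writes voxel grids and scalar fields in the legacy VTK ``STRUCTURED_POINTS``
format (readable by ParaView/VisIt).  Kept deliberately minimal: point data
only, one file per time snapshot.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Union

import numpy as np

from .phantom import LabelGrid

__all__ = ["export_vtk", "export_temperature_series"]


def export_vtk(path: Union[str, Path], grid: LabelGrid,
               fields: Dict[str, np.ndarray]) -> None:
    """Write scalar per-voxel ``fields`` (each of ``grid.shape``) to ``path``.

    Values are attached as point data at voxel centers.
    """
    nx, ny, nz = grid.shape
    ox, oy, oz = (o + grid.spacing / 2 for o in grid.origin)
    lines = [
        "# vtk DataFile Version 3.0",
        "dmwasim voxel field",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        f"ORIGIN {ox:.9g} {oy:.9g} {oz:.9g}",
        f"SPACING {grid.spacing:.9g} {grid.spacing:.9g} {grid.spacing:.9g}",
        f"POINT_DATA {nx * ny * nz}",
    ]
    for name, values in fields.items():
        arr = np.asarray(values)
        if arr.shape != grid.shape:
            raise ValueError(f"field {name!r} shape {arr.shape} != grid shape")
        safe = name.replace(" ", "_")
        lines.append(f"SCALARS {safe} float 1")
        lines.append("LOOKUP_TABLE default")
        # VTK expects x fastest: transpose to (z, y, x) then ravel
        flat = arr.transpose(2, 1, 0).ravel()
        lines.extend(" ".join(f"{v:.6g}" for v in flat[i:i + 9])
                     for i in range(0, flat.size, 9))
    Path(path).write_text("\n".join(lines) + "\n")


def export_temperature_series(directory: Union[str, Path], field,
                              stem: str = "temperature") -> None:
    """One VTK file per stored snapshot of a temperature field."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, t in enumerate(field.times):
        export_vtk(
            directory / f"{stem}_{i:04d}_t{t:.0f}s.vtk",
            field.grid,
            {"temperature_C": field.values[i],
             "label": field.grid.label_ids.astype(float)},
        )
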