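"""Result serialisation: tidy CSV summaries, run metadata and VTK snapshots.

Every run can emit (i) a tidy CSV of the recorded time series, (ii) a
metadata JSON echoing the full configuration, the seed and the package
version — enough to re-execute the run exactly — and (iii) optional legacy
VTK point snapshots of the temperature field for external rendering.
Outputs are bit-stable for identical inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .solver import SimulationResult

__all__ = ["result_frame", "run_metadata", "write_outputs", "write_vtk_points"]

_T0C = 273.15


def result_frame(result: SimulationResult) -> pd.DataFrame:
    """Recorded time series as a tidy frame (temperatures in degC)."""
    return pd.DataFrame(
        {
            "time_s": result.times,
            "T_mean_C": result.T_mean - _T0C,
            "T_min_C": result.T_min - _T0C,
            "T_max_C": result.T_max - _T0C,
            "T_centre_C": result.centre_T - _T0C,
            "T_sunny_mean_C": result.side_mean["sunny"] - _T0C,
            "T_shaded_mean_C": result.side_mean["shaded"] - _T0C,
            "transp_sunny_L_m2_h": result.transp_rate["sunny"] * 3600.0,
            "transp_shaded_L_m2_h": result.transp_rate["shaded"] * 3600.0,
            "cum_water_kg": result.cum_water,
        }
    )


def run_metadata(cfg=None, seed: int | None = None, extra: dict | None = None) -> dict:
    """Metadata sufficient to re-execute a run: config echo, seed, version."""
    from . import __version__

    meta: dict = {"package": "fruittherm", "version": __version__}
    if cfg is not None:
        meta["config"] = cfg.model_dump(mode="json")
    if seed is not None:
        meta["seed"] = seed
    if extra:
        meta.update(extra)
    return meta


def write_outputs(
    result: SimulationResult,
    outdir: str | Path,
    formats: set[str] = frozenset({"csv"}),
    metadata: dict | None = None,
    prefix: str = "run",
) -> list[Path]:
    """Write the run summary (and optional VTK snapshots) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if "csv" in formats:
        path = outdir / f"{prefix}_summary.csv"
        # 17 significant digits: exact float64 round trip on re-read
        result_frame(result).to_csv(path, index=False, float_format="%.17g")
        written.append(path)

    meta_path = outdir / f"{prefix}_metadata.json"
    meta_path.write_text(json.dumps(metadata or {}, indent=2, sort_keys=True))
    written.append(meta_path)

    if "vtk" in formats:
        if result.T_fields is None:
            raise ValueError("VTK output requires stored fields")
        centres = result.mesh.centres
        for i, (t, field) in enumerate(zip(result.times, result.T_fields)):
            path = outdir / f"{prefix}_T_{i:04d}.vtk"
            write_vtk_points(path, centres, field - _T0C, name="temperature_C")
            written.append(path)
    return written


def write_vtk_points(
    path: str | Path, centres: np.ndarray, values: np.ndarray, name: str = "field"
) -> None:
    """Legacy-format VTK point cloud (cell centres) with one scalar field."""
    n = centres.shape[0]
    if values.shape[0] != n:
        raise ValueError("field length does not match point count")
    lines = [
        "# vtk DataFile Version 3.0",
        "fruittherm snapshot",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n} double",
    ]
    lines += [f"{x:.9e} {y:.9e} {z:.9e}" for x, y, z in centres]
    lines.append(f"CELLS {n} {2 * n}")
    lines += [f"1 {i}" for i in range(n)]
    lines.append(f"CELL_TYPES {n}")
    lines += ["1"] * n  # VTK_VERTEX
    lines += [
        f"POINT_DATA {n}",
        f"SCALARS {name} double 1",
        "LOOKUP_TABLE default",
    ]
    lines += [f"{v:.9e}" for v in values]
    Path(path).write_text("\n".join(lines) + "\n")
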