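"""Snapshot and report writers: HDF5 state containers, VTK volume export,
CSV record and classification reports.  Every file embeds the config hash
and the replica seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def save_snapshot(state, path, seed=None, config_hash=None):
    """Write the full simulation state to an HDF5 container."""
    import h5py

    n = state.n_cells + 1
    with h5py.File(path, "w") as f:
        f.attrs["clock_hours"] = state.clock
        f.attrs["voxel_size_um"] = state.voxel_size
        if seed is not None:
            f.attrs["seed"] = int(seed)
        if config_hash is not None:
            f.attrs["config_hash"] = config_hash
        f.create_dataset("site_map", data=state.site.astype(np.uint32),
                         compression="gzip")
        cells = f.create_group("cells")
        cells.create_dataset("id", data=np.arange(n, dtype=np.int64))
        cells.create_dataset("type", data=state.ctype[:n])
        cells.create_dataset("volume", data=state.volume[:n])
        cells.create_dataset("target_volume", data=state.target_volume[:n])
        com = np.zeros((n, 3))
        for c in range(1, n):
            if state.volume[c] > 0:
                com[c] = state.com(c) * state.voxel_size
        cells.create_dataset("com_um", data=com)
        cells.create_dataset("alive", data=state.alive[:n])
        cells.create_dataset("frozen", data=state.frozen[:n])
        cells.create_dataset("birth_time", data=state.birth_time[:n])
        links = f.create_group("links")
        links.create_dataset("a", data=state.link_a)
        links.create_dataset("b", data=state.link_b)
        links.create_dataset("lambda", data=state.link_lambda)
        links.create_dataset("rest_length", data=state.link_rest)
        links.create_dataset("active", data=state.link_active)
        fg = f.create_group("fields")
        for name, grid in state.fields.items():
            fg.create_dataset(name, data=grid, compression="gzip")


def load_snapshot(path):
    """Read a snapshot back as a dict of arrays (bit-identical round trip)."""
    import h5py

    out = {"cells": {}, "links": {}, "fields": {}}
    with h5py.File(path, "r") as f:
        out["clock_hours"] = float(f.attrs["clock_hours"])
        out["voxel_size_um"] = float(f.attrs["voxel_size_um"])
        for key in ("seed", "config_hash"):
            if key in f.attrs:
                out[key] = f.attrs[key]
        out["site_map"] = f["site_map"][...]
        for k in f["cells"]:
            out["cells"][k] = f["cells"][k][...]
        for k in f["links"]:
            out["links"][k] = f["links"][k][...]
        for k in f["fields"]:
            out["fields"][k] = f["fields"][k][...]
    return out


# ---------------------------------------------------------------------------
# VTK legacy structured-points export (plain text, openable by volume viewers)


def write_vtk_image(path, arrays, voxel_size=1.0, title="cnvsim snapshot"):
    """Write 3D arrays as a legacy ASCII VTK STRUCTURED_POINTS file."""
    arrays = dict(arrays)
    first = next(iter(arrays.values()))
    nx, ny, nz = first.shape
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} {nz}",
        "ORIGIN 0 0 0",
        f"SPACING {voxel_size} {voxel_size} {voxel_size}",
        f"POINT_DATA {nx * ny * nz}",
    ]
    for name, arr in arrays.items():
        if arr.shape != (nx, ny, nz):
            raise ValueError("all arrays must share one shape")
        if np.issubdtype(arr.dtype, np.integer):
            vtype, fmt = "int", "%d"
        else:
            vtype, fmt = "float", "%.6g"
        lines.append(f"SCALARS {name} {vtype} 1")
        lines.append("LOOKUP_TABLE default")
        flat = arr.ravel(order="F")
        for i in range(0, flat.size, 9):
            lines.append(" ".join(fmt % v for v in flat[i:i + 9]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vtk_header(path):
    """Parse the header of a legacy VTK file (format-conformance check)."""
    info = {"scalars": []}
    with open(path) as fh:
        lines = [fh.readline().rstrip("\n") for _ in range(4)]
        if not lines[0].startswith("# vtk DataFile Version"):
            raise ValueError("not a legacy VTK file")
        info["title"] = lines[1]
        info["format"] = lines[2]
        info["dataset"] = lines[3].split()[-1]
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "DIMENSIONS":
                info["dimensions"] = tuple(int(v) for v in parts[1:4])
            elif parts[0] == "SPACING":
                info["spacing"] = tuple(float(v) for v in parts[1:4])
            elif parts[0] == "POINT_DATA":
                info["n_points"] = int(parts[1])
            elif parts[0] == "SCALARS":
                info["scalars"].append(parts[1])
    return info


# ---------------------------------------------------------------------------
# CSV reports


def _header_comment(seed, config_hash):
    return f"# seed={seed} config_hash={config_hash}\n"


def write_records_csv(records, path, seed=0, config_hash=""):
    """One row per storage cadence tick of the morphometric record stream."""
    from .morphometry import records_to_frame

    df = records_to_frame(records)
    with open(path, "w") as fh:
        fh.write(_header_comment(seed, config_hash))
        df.to_csv(fh, index=False)


def read_records_csv(path):
    from .morphometry import records_from_frame

    df = pd.read_csv(path, comment="#")
    return records_from_frame(df)


def write_classification_csv(rows, path, seed=0, config_hash=""):
    """Per-replica classification report (replica, onset, types, dynamics)."""
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(_header_comment(seed, config_hash))
        df.to_csv(fh, index=False)


def write_profile_csv(depths, values, path, value_name="PO2_mmHg"):
    pd.DataFrame({"depth_um": depths, value_name: values}).to_csv(
        path, index=False)
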