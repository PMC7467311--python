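"""Reading and writing trajectories, umbrella windows and surfaces.

Trajectories are exchanged as TSV (one header line, one row per frame) or
GROMACS-style XVG (``#``/``@`` prefixed metadata lines), with a JSON
sidecar carrying metadata. These are the formats real MD post-processing
tools emit, so the analysis layer is agnostic to the data source.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .lattice import RiseTrajectory, UmbrellaWindow

__all__ = [
    "write_trajectory_tsv", "read_trajectory_tsv",
    "write_trajectory_xvg", "read_trajectory_xvg",
    "write_windows_tsv", "read_windows_tsv",
]

_SERIES = ("L_x", "L_y", "L_z", "P_xx", "P_yy", "P_zz")


def _frame(traj: RiseTrajectory) -> pd.DataFrame:
    cols = {f"rise_{i + 1}": traj.rise[:, i] for i in range(traj.n_pf)}
    for key in ("L_x", "L_y", "L_z"):
        cols[key] = traj.box[key]
    for key in ("P_xx", "P_yy", "P_zz"):
        cols[key] = traj.pressure[key]
    return pd.DataFrame(cols)


def _from_frame(df: pd.DataFrame, meta: dict) -> RiseTrajectory:
    rise_cols = sorted(c for c in df.columns if c.startswith("rise_"))
    rise = df[rise_cols].to_numpy()
    box = {k: df[k].to_numpy() for k in ("L_x", "L_y", "L_z")}
    pressure = {k: df[k].to_numpy() for k in ("P_xx", "P_yy", "P_zz")}
    return RiseTrajectory(rise=rise, box=box, pressure=pressure, meta=meta)


def write_trajectory_tsv(traj: RiseTrajectory, path) -> None:
    path = Path(path)
    _frame(traj).to_csv(path, sep="\t", index=False, float_format="%.8g")
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(traj.meta, default=float, indent=1))


def read_trajectory_tsv(path) -> RiseTrajectory:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return _from_frame(df, meta)


def write_trajectory_xvg(traj: RiseTrajectory, path) -> None:
    """XVG with a leading frame-index column; metadata in ``@``/``#`` lines."""
    df = _frame(traj)
    lines = ["# pflattice rise trajectory"]
    for k, v in traj.meta.items():
        lines.append(f"# {k} = {v}")
    lines.append('@    xaxis  label "frame"')
    lines.append("@ legend: " + " ".join(df.columns))
    data = np.column_stack([np.arange(len(df)), df.to_numpy()])
    for row in data:
        lines.append(" ".join(f"{x:.8g}" for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory_xvg(path) -> RiseTrajectory:
    meta, legend, rows = {}, None, []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "=" in line:
                k, _, v = line[1:].partition("=")
                meta[k.strip()] = v.strip()
            continue
        if line.startswith("@"):
            if "legend:" in line:
                legend = line.split("legend:")[1].split()
            continue
        rows.append([float(x) for x in line.split()])
    arr = np.asarray(rows)
    if legend is None:
        raise ValueError("XVG file lacks a legend line naming the columns")
    df = pd.DataFrame(arr[:, 1:], columns=legend)
    return _from_frame(df, meta)


def write_windows_tsv(windows: list[UmbrellaWindow], path) -> None:
    """All windows in one long-format TSV: window, center, k_bias, sample."""
    recs = []
    for i, w in enumerate(windows):
        for s in w.samples:
            recs.append((i, w.center, w.k_bias, s))
    pd.DataFrame(recs, columns=["window", "center", "k_bias", "sample"]).to_csv(
        path, sep="\t", index=False, float_format="%.8g")


def read_windows_tsv(path) -> list[UmbrellaWindow]:
    df = pd.read_csv(path, sep="\t")
    windows = []
    for _, grp in df.groupby("window", sort=True):
        windows.append(UmbrellaWindow(
            center=float(grp["center"].iloc[0]),
            k_bias=float(grp["k_bias"].iloc[0]),
            samples=grp["sample"].to_numpy()))
    return windows
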