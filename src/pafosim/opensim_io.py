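"""Readers/writers for OpenSim-dialect text formats (.trc, .sto, .mot).

These are small line-oriented tab-separated dialects: .trc carries marker
trajectories (header with DataRate/NumFrames/NumMarkers/Units, one X/Y/Z
triple per marker), .sto/.mot carry named time series behind a header
terminated by ``endheader``.  The planar model writes Z = 0 and ignores Z
on read.  Joint angles are written in degrees per the usual motion-file
convention; everything is radians in memory.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ._fk import JOINT_NAMES

_ANGLE_COORDS = ("pelvis_tilt", "hip", "knee", "ankle")


def write_trc(path, markers: dict, data_rate: float, units: str = "m") -> None:
    """Write planar marker trajectories as a .trc file (Z = 0)."""
    names = list(markers)
    n = len(next(iter(markers.values())))
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
        fh.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                 "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
        fh.write(f"{data_rate:g}\t{data_rate:g}\t{n}\t{len(names)}\t{units}\t"
                 f"{data_rate:g}\t1\t{n}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t\t\n")
        sub = "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(len(names)))
        fh.write(f"\t\t{sub}\n\n")
        for f in range(n):
            t = f / data_rate
            row = [f"{f + 1}", f"{t:.6f}"]
            for nm in names:
                x, y = markers[nm][f]
                row += [f"{x:.8f}", f"{y:.8f}", "0.00000000"]
            fh.write("\t".join(row) + "\n")


def read_trc(path) -> tuple[dict, float]:
    """Read a .trc file; returns (marker name → (n, 2) array, data rate)."""
    lines = Path(path).read_text().splitlines()
    meta = dict(zip(lines[1].split("\t"), lines[2].split("\t")))
    rate = float(meta["DataRate"])
    names = [c for c in lines[3].split("\t")[2:] if c.strip()]
    rows = []
    for ln in lines[5:]:
        parts = ln.split("\t")
        if len(parts) < 3 or not parts[0].strip():
            continue
        rows.append([float(v) for v in parts[2:] if v.strip() != ""])
    data = np.asarray(rows)
    markers = {}
    for i, nm in enumerate(names):
        markers[nm] = data[:, 3 * i:3 * i + 2]
    return markers, rate


def write_sto(path, columns: dict, name: str = "pafosim",
              in_degrees: bool = False) -> None:
    """Write named time series as an .sto/.mot-dialect file.

    ``columns`` maps column name → series; must include ``time`` first.
    """
    cols = list(columns)
    if cols[0] != "time":
        raise ValueError("first column must be 'time'")
    n = len(columns["time"])
    with open(path, "w") as fh:
        fh.write(f"{name}\nversion=1\nnRows={n}\nnColumns={len(cols)}\n")
        fh.write(f"inDegrees={'yes' if in_degrees else 'no'}\nendheader\n")
        fh.write("\t".join(cols) + "\n")
        for f in range(n):
            fh.write("\t".join(f"{np.asarray(columns[c])[f]:.8f}"
                               for c in cols) + "\n")


def read_sto(path) -> pd.DataFrame:
    """Read an .sto/.mot file into a DataFrame (header in ``df.attrs``)."""
    lines = Path(path).read_text().splitlines()
    attrs = {}
    for i, ln in enumerate(lines):
        if ln.strip().lower() == "endheader":
            break
        if "=" in ln:
            k, v = ln.split("=", 1)
            attrs[k.strip()] = v.strip()
    header = lines[i + 1].split("\t")
    data = [[float(v) for v in ln.split("\t")]
            for ln in lines[i + 2:] if ln.strip()]
    df = pd.DataFrame(data, columns=[h.strip() for h in header])
    df.attrs.update(attrs)
    return df


def write_motion(path, angles: dict, cycle_duration: float,
                 name: str = "coordinates") -> None:
    """Write coordinate series as a .mot file, rotations in degrees."""
    n = len(angles["hip"])
    cols = {"time": np.linspace(0.0, cycle_duration, n)}
    for k, v in angles.items():
        cols[k] = np.rad2deg(v) if k in _ANGLE_COORDS else np.asarray(v)
    write_sto(path, cols, name=name, in_degrees=True)


def read_motion(path) -> tuple[dict, float]:
    """Read a .mot written by :func:`write_motion` back to radians."""
    df = read_sto(path)
    t = df["time"].to_numpy()
    in_deg = df.attrs.get("inDegrees", "no") == "yes"
    angles = {}
    for c in df.columns:
        if c == "time":
            continue
        v = df[c].to_numpy()
        angles[c] = np.deg2rad(v) if (in_deg and c in _ANGLE_COORDS) else v
    return angles, float(t[-1] - t[0])


def write_moments(path, series, cycle_duration: float) -> None:
    """Write net joint moments as .sto columns ``<joint>_moment``."""
    n = series.n_frames
    cols = {"time": np.linspace(0.0, cycle_duration, n)}
    cols.update({f"{j}_moment": series.moments[j] for j in JOINT_NAMES})
    write_sto(path, cols, name="net_joint_moments")


def write_muscle_series(path, forces, cycle_duration: float,
                        kind: str = "force") -> None:
    """Write muscle forces or activations as .sto columns.

    ``kind`` selects ``_force`` (N) or ``_activation`` columns; the reserve
    torque is written as ``reserve_force``/``reserve_activation``.
    """
    if kind not in ("force", "activation"):
        raise ValueError("kind must be 'force' or 'activation'")
    data = forces.forces if kind == "force" else forces.activations
    n = data.shape[0]
    cols = {"time": np.linspace(0.0, cycle_duration, n)}
    for i, nm in enumerate(forces.muscle_names):
        cols[f"{nm}_{kind}"] = data[:, i]
    cols[f"reserve_{kind}"] = forces.reserve
    write_sto(path, cols, name=f"muscle_{kind}s")
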