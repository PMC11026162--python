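"""Plain-text trajectory and table I/O.

Trajectories and observation sets are written as extended XYZ (one block per
frame, comment line carrying time and box) or long-format CSV
(frame, id, x_um, y_um, radius_um); g(r) curves as CSV (r_nm, g, n_pairs).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bd import Trajectory
from .rdf import RDF
from .synth import ObservationSet

__all__ = ["write_xyz", "read_xyz", "write_csv_trajectory", "write_rdf_csv",
           "read_rdf_csv", "write_potential_csv"]


def _frame_iter(obj):
    if isinstance(obj, Trajectory):
        for k in range(obj.n_frames):
            yield obj.times[k], obj.frames[k], obj.radii
    elif isinstance(obj, ObservationSet):
        for k, (f, r) in enumerate(zip(obj.frames, obj.radii_per_frame)):
            yield k / obj.frame_rate, f, r
    else:
        raise TypeError("expected Trajectory or ObservationSet")


def write_xyz(obj, path):
    """Extended-XYZ: N / comment(time, box) / one 'P x y r' line per particle."""
    box = obj.box
    with open(path, "w") as fh:
        for t, pos, radii in _frame_iter(obj):
            fh.write(f"{pos.shape[0]}\n")
            fh.write(f'time={t:.9g} box="{box[0]:.9g} {box[1]:.9g}" '
                     f'columns=species:x:y:radius units=m\n')
            for (x, y), r in zip(pos, radii):
                fh.write(f"P {x:.9e} {y:.9e} {r:.9e}\n")


def read_xyz(path):
    """Read frames written by write_xyz.

    Returns (frames, radii_per_frame, times, box).
    """
    frames, radii, times = [], [], []
    box = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        n = int(lines[i])
        comment = lines[i + 1]
        t = float(comment.split("time=")[1].split()[0])
        bx = comment.split('box="')[1].split('"')[0].split()
        box = (float(bx[0]), float(bx[1]))
        block = lines[i + 2:i + 2 + n]
        arr = np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        frames.append(arr[:, :2])
        radii.append(arr[:, 2])
        times.append(t)
        i += 2 + n
    return frames, radii, np.array(times), box


def write_csv_trajectory(obj, path):
    rows = []
    for k, (t, pos, radii) in enumerate(_frame_iter(obj)):
        for i, ((x, y), r) in enumerate(zip(pos, radii)):
            rows.append((k, i, x * 1e6, y * 1e6, r * 1e6))
    pd.DataFrame(rows, columns=["frame", "id", "x_um", "y_um", "radius_um"]) \
        .to_csv(path, index=False)


def write_rdf_csv(rdf: RDF, path):
    df = pd.DataFrame({"r_nm": rdf.r * 1e9, "g": rdf.g})
    if rdf.n_pairs is not None:
        df["n_pairs"] = rdf.n_pairs
    df.to_csv(path, index=False)


def read_rdf_csv(path, density: float = 0.0, box=None) -> RDF:
    df = pd.read_csv(path)
    r = df["r_nm"].to_numpy() * 1e-9
    dr = float(np.median(np.diff(r)))
    return RDF(r=r, g=df["g"].to_numpy(dtype=float), dr=dr, n_frames=1,
               density=density,
               n_pairs=df["n_pairs"].to_numpy() if "n_pairs" in df else None,
               metadata={"box": box, "source": str(path)})


def write_potential_csv(params, x, path, temperature: float = 298.0):
    """CSV of the potential decomposition along a grid (nm / kBT units)."""
    from .constants import kBT
    from .potential import vdw_energy
    kT = kBT(temperature)
    x = np.asarray(x, dtype=float)
    u_el = params.A * np.exp(-params.kappa1 * x) / kT
    u_int = params.B * np.exp(-params.kappa2 * x) / kT
    u_vdw = (vdw_energy(x, params.A_H, params.R1, params.R2) / kT
             if params.include_vdw else np.zeros_like(x))
    pd.DataFrame({"x_nm": x * 1e9, "U_el_kBT": u_el, "U_int_kBT": u_int,
                  "U_vdw_kBT": u_vdw,
                  "U_tot_kBT": u_el + u_int + u_vdw}).to_csv(path, index=False)
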