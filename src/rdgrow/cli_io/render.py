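"""Result serialization (HDF5/CSV) and deterministic plotting."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from rdgrow.sim1d import SimResult1D
from rdgrow.sim2d import SimResult2D

__all__ = [
    "save_result_hdf5",
    "kymograph_raster",
    "write_kymograph_csv",
    "write_boundary_csv",
    "render_outputs",
]

_FLOAT_FMT = "%.17g"


def save_result_hdf5(result, path) -> None:
    """Layout: /snapshots/<idx>/{t, X, x, u, mu} (1D) or
    {t, coords, triangles, u, boundary} (2D), plus /series arrays."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["config_hash"] = result.config_hash
        f.attrs["seed"] = -1 if result.seed is None else result.seed
        grp = f.create_group("snapshots")
        for i, snap in enumerate(result.snapshots):
            g = grp.create_group(str(i))
            for key, val in snap.items():
                if np.isscalar(val):
                    g.attrs[key] = val
                else:
                    g.create_dataset(key, data=np.asarray(val))
        ser = f.create_group("series")
        if isinstance(result, SimResult1D):
            ser.create_dataset("t", data=result.t_series)
            ser.create_dataset("L", data=result.L_series)
        else:
            for key, val in result.series.items():
                ser.create_dataset(key, data=np.asarray(val))


def kymograph_raster(
    result: SimResult1D,
    species: int = 0,
    n_columns: int = 400,
    anchor: str = "midpoint",
):
    """Space-time raster of a species on a common Eulerian axis.

    anchor="zero" keeps x(t, 0) = 0; "midpoint" recentres each profile at
    the domain midpoint (the visualization convention for patterned runs).
    Returns (times, x_axis, raster) with NaN outside the domain.
    """
    snaps = result.snapshots
    times = np.array([s["t"] for s in snaps])
    half = max(s["x"][-1] - s["x"][0] for s in snaps) / 2.0
    if anchor == "midpoint":
        lo, hi = -half, half
    else:
        lo, hi = 0.0, 2 * half
    axis = np.linspace(lo, hi, n_columns)
    raster = np.full((len(snaps), n_columns), np.nan)
    for i, s in enumerate(snaps):
        x = s["x"]
        if anchor == "midpoint":
            x = x - (x[0] + x[-1]) / 2.0
        inside = (axis >= x[0]) & (axis <= x[-1])
        raster[i, inside] = np.interp(axis[inside], x, s["u"][species])
    return times, axis, raster


def write_kymograph_csv(result: SimResult1D, path, species: int = 0, **kw) -> None:
    times, axis, raster = kymograph_raster(result, species, **kw)
    header = "t," + ",".join(_FLOAT_FMT % v for v in axis)
    rows = np.column_stack([times, raster])
    np.savetxt(path, rows, delimiter=",", header=header, comments="", fmt=_FLOAT_FMT)


def write_boundary_csv(result: SimResult2D, path) -> None:
    """One row block per snapshot: t, vertex index, x1, x2."""
    with open(path, "w") as f:
        f.write("t,vertex,x1,x2\n")
        for snap in result.snapshots:
            t = snap["t"]
            for i, (x1, x2) in enumerate(snap["boundary"]):
                f.write(
                    f"{_FLOAT_FMT % t},{i},{_FLOAT_FMT % x1},{_FLOAT_FMT % x2}\n"
                )


def render_outputs(result, out_dir, formats=("h5", "csv", "png")) -> list[Path]:
    """Write the standard artifact set for a result; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    is_1d = isinstance(result, SimResult1D)
    if "h5" in formats:
        p = out_dir / "result.h5"
        save_result_hdf5(result, p)
        written.append(p)
    if "csv" in formats:
        if is_1d:
            for anchor in ("midpoint", "zero"):
                p = out_dir / f"kymograph_{anchor}.csv"
                write_kymograph_csv(result, p, anchor=anchor)
                written.append(p)
            p = out_dir / "length.csv"
            np.savetxt(
                p,
                np.column_stack([result.t_series, result.L_series]),
                delimiter=",",
                header="t,L",
                comments="",
                fmt=_FLOAT_FMT,
            )
            written.append(p)
        else:
            p = out_dir / "boundary.csv"
            write_boundary_csv(result, p)
            written.append(p)
            p = out_dir / "series.csv"
            keys = list(result.series)
            np.savetxt(
                p,
                np.column_stack([result.series[k] for k in keys]),
                delimiter=",",
                header=",".join(keys),
                comments="",
                fmt=_FLOAT_FMT,
            )
            written.append(p)
    if "png" in formats:
        written.append(_render_png(result, out_dir, is_1d))
    return written


def _render_png(result, out_dir: Path, is_1d: bool) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4), dpi=120)
    if is_1d:
        times, axis, raster = kymograph_raster(result)
        pcm = ax.pcolormesh(axis, times, raster, shading="auto", cmap="viridis")
        fig.colorbar(pcm, ax=ax, label="u")
        ax.set_xlabel("x (midpoint-anchored)")
        ax.set_ylabel("t")
        path = out_dir / "kymograph.png"
    else:
        for snap in result.snapshots:
            ring = np.vstack([snap["boundary"], snap["boundary"][:1]])
            ax.plot(ring[:, 0], ring[:, 1], lw=0.8)
        ax.set_aspect("equal")
        ax.set_xlabel("x1")
        ax.set_ylabel("x2")
        path = out_dir / "boundaries.png"
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
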