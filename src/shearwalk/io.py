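"""On-disk formats: trajectory TSV, distribution parameter files, result CSV.

All files are UTF-8 text with '#'-prefixed comment lines and SI units.
Trajectory files are tab-separated with columns platelet_id, t, y; the
sampling interval and domain height are recorded in header comments so a
file is self-describing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .trajectory_analysis import TrajectorySet
from .velocity_model import VelocityDistribution, _mass_mean, solve_normalization

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "read_distribution",
    "write_distribution",
    "write_result_csv",
]

_TRAJ_COLUMNS = ("platelet_id", "t", "y")


class FormatError(ValueError):
    """Malformed input file."""


def write_trajectories(traj: TrajectorySet, path, extra_comments: dict | None = None) -> None:
    """Write a trajectory ensemble as tab-separated text.

    Header comments record dt_sample and L (plus any ``extra_comments``);
    values are written at full double precision so read(write(x)) round-trips
    exactly.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# dt_sample = {traj.dt_sample!r}\n")
        fh.write(f"# L = {traj.L!r}\n")
        for key, val in (extra_comments or {}).items():
            fh.write(f"# {key} = {val}\n")
        fh.write("\t".join(_TRAJ_COLUMNS) + "\n")
        for pid, t, yy in zip(traj.ids, traj.times, traj.y):
            frame = pd.DataFrame({"platelet_id": pid, "t": t, "y": yy})
            frame.to_csv(fh, sep="\t", header=False, index=False, float_format="%.17g")


def _parse_header_comments(path: Path) -> dict:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    return meta


def read_trajectories(path) -> TrajectorySet:
    """Read a trajectory TSV into a :class:`TrajectorySet`.

    Comment lines (leading '#') may appear anywhere.  Malformed rows are
    reported with their 1-based line numbers; non-uniform time spacing is
    rejected naming the offending platelet.
    """
    path = Path(path)
    meta = _parse_header_comments(path)
    for key in ("dt_sample", "L"):
        if key not in meta:
            raise FormatError(f"{path}: missing '# {key} = ...' header comment")
    dt_sample, L = float(meta["dt_sample"]), float(meta["L"])

    ids_col, t_col, y_col = [], [], []
    bad = []
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if not header_seen:
                if tuple(p.strip() for p in parts) != _TRAJ_COLUMNS:
                    raise FormatError(
                        f"{path}:{lineno}: expected header {'/'.join(_TRAJ_COLUMNS)}, "
                        f"got {line!r}"
                    )
                header_seen = True
                continue
            if len(parts) != 3:
                bad.append(lineno)
                continue
            try:
                t_val, y_val = float(parts[1]), float(parts[2])
            except ValueError:
                bad.append(lineno)
                continue
            ids_col.append(parts[0])
            t_col.append(t_val)
            y_col.append(y_val)
    if bad:
        shown = ", ".join(str(n) for n in bad[:10])
        more = "" if len(bad) <= 10 else f" (+{len(bad) - 10} more)"
        raise FormatError(f"{path}: malformed rows at lines {shown}{more}")
    if not header_seen or not ids_col:
        raise FormatError(f"{path}: no trajectory data")

    ids_arr = np.asarray(ids_col)
    t_arr = np.asarray(t_col)
    y_arr = np.asarray(y_col)
    # records in order of first appearance; a platelet id restarting later in
    # the file is treated as the same record only if contiguous
    change = np.r_[True, ids_arr[1:] != ids_arr[:-1]]
    starts = np.flatnonzero(change)
    stops = np.r_[starts[1:], ids_arr.size]
    ids, times, ys = [], [], []
    for a, b in zip(starts, stops):
        ids.append(str(ids_arr[a]))
        times.append(t_arr[a:b])
        ys.append(y_arr[a:b])
    return TrajectorySet(ids=ids, times=times, y=ys, dt_sample=dt_sample, L=L)


def write_distribution(dist: VelocityDistribution, path) -> None:
    """Write distribution parameters as flat key/value text.

    Always emits the solved (p0, lam) and records the residuals of the
    unit-mass and mean constraints as comments.
    """
    mass, mean = _mass_mean(dist.p0, dist.lam, dist.alpha, dist.v_min)
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# exponential-bulk / power-law-tail velocity distribution (SI units)\n")
        fh.write(f"# mass residual = {mass - 1.0:.3e}\n")
        fh.write(f"# mean residual = {mean / dist.v_moy - 1.0:.3e} (relative)\n")
        for key in ("alpha", "v_min", "v_moy", "p0", "lam"):
            fh.write(f"{key} = {getattr(dist, key)!r}\n")


def read_distribution(path) -> VelocityDistribution:
    """Read a parameter file; solves for (p0, lam) when they are absent."""
    path = Path(path)
    values = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, _, val = line.partition("=")
            try:
                values[key.strip()] = float(val)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric value {val!r}") from exc
    for key in ("alpha", "v_min", "v_moy"):
        if key not in values:
            raise FormatError(f"{path}: missing required key {key!r}")
    if "p0" in values and "lam" in values:
        return VelocityDistribution(**{k: values[k] for k in ("alpha", "v_min", "v_moy", "p0", "lam")})
    p0, lam = solve_normalization(values["alpha"], values["v_min"], values["v_moy"])
    return VelocityDistribution(
        alpha=values["alpha"], v_min=values["v_min"], v_moy=values["v_moy"], p0=p0, lam=lam
    )


def write_result_csv(df: pd.DataFrame, path, params: dict | None = None) -> None:
    """Write a result table as CSV preceded by a '#'-prefixed parameter echo."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in (params or {}).items():
            fh.write(f"# {key} = {val}\n")
        df.to_csv(fh, index=False)


def read_result_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
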