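"""Diffusion metrics: mean square displacement, D estimates, finite-size
effects, and the Zydney-Colton shear-induced diffusivity reference.

The MSD is taken from the trajectory origin, MSD(t) = <(y_i(t) - y_i(0))^2>,
with two censoring modes mirroring how wall-bounded observations are usually
analysed: 'in' keeps only platelets that never leave the observation domain,
'in_and_out' lets every platelet contribute until its first exit.  For a 1D
diffusive process MSD(t) = 2 D t, and for the iid-step walk the exact value
is D = <v^2> * dt_step / 2 — the analytic oracle the estimators are checked
against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory_analysis import TrajectorySet

__all__ = [
    "MsdCurve",
    "DiffusionEstimate",
    "ZcParams",
    "msd",
    "diffusion_coefficient",
    "finite_size_scan",
    "zydney_colton",
]


@dataclass(frozen=True)
class MsdCurve:
    """Lag-indexed mean square displacement (m^2 vs s) with censoring mode."""

    lags: np.ndarray
    msd: np.ndarray
    contributing: np.ndarray
    mode: str


@dataclass(frozen=True)
class DiffusionEstimate:
    """Diffusion coefficient (m^2/s) with the estimator and window used."""

    D: float
    method: str
    fit_window: tuple


@dataclass(frozen=True)
class ZcParams:
    """Inputs of the Zydney-Colton shear-induced diffusivity.

    D_PRP: platelet diffusivity in platelet-rich plasma (no red cells), m^2/s;
    d_RBC: red-blood-cell diameter, m; H: hematocrit (RBC volume fraction);
    gamma_dot: shear rate, 1/s.
    """

    D_PRP: float = 1e-13
    d_RBC: float = 9e-6
    H: float = 0.35
    gamma_dot: float = 100.0

    def __post_init__(self) -> None:
        if min(self.D_PRP, self.d_RBC, self.H, self.gamma_dot) < 0:
            raise ValueError("all parameters must be non-negative")
        if self.H >= 1:
            raise ValueError("hematocrit must be below 1")


def msd(traj: TrajectorySet, mode: str = "in_and_out", domain=None) -> MsdCurve:
    """Mean square displacement from the origin with domain censoring.

    mode 'in': only records inside ``domain`` for their whole duration
    contribute.  mode 'in_and_out': each record contributes to lags strictly
    before its first exit from ``domain``.
    """
    if mode not in ("in", "in_and_out"):
        raise ValueError("mode must be 'in' or 'in_and_out'")
    lo, hi = (0.0, traj.L) if domain is None else domain
    cutoffs = []
    records = []
    for yy in traj.y:
        yy = np.asarray(yy, dtype=float)
        outside = (yy < lo) | (yy > hi)
        if mode == "in":
            cut = 0 if outside.any() else yy.size
        else:
            cut = int(np.argmax(outside)) if outside.any() else yy.size
        if cut > 0:
            records.append(yy)
            cutoffs.append(cut)
    if not records:
        raise ValueError("no eligible record at lag 0")
    max_len = max(cutoffs)
    total = np.zeros(max_len)
    count = np.zeros(max_len, dtype=np.intp)
    for yy, cut in zip(records, cutoffs):
        d2 = (yy[:cut] - yy[0]) ** 2
        total[:cut] += d2
        count[:cut] += 1
    lags = np.arange(max_len) * traj.dt_sample
    with np.errstate(invalid="ignore"):
        values = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return MsdCurve(lags=lags, msd=values, contributing=count, mode=mode)


def diffusion_coefficient(
    curve: MsdCurve, method: str = "slope", fit_window=None
) -> DiffusionEstimate:
    """Estimate D from an MSD curve.

    'ratio': mean of MSD(t) / (2 t) over the window.  'slope': zero-intercept
    least-squares slope of MSD on t over the window, divided by 2 (default
    window: [t_max/5, t_max], chosen away from the lag-0 end).
    """
    if method not in ("slope", "ratio"):
        raise ValueError("method must be 'slope' or 'ratio'")
    if fit_window is None:
        fit_window = (curve.lags[-1] / 5.0, curve.lags[-1])
    lo, hi = fit_window
    sel = (curve.lags >= lo) & (curve.lags <= hi) & (curve.lags > 0) & np.isfinite(curve.msd)
    if sel.sum() < 2:
        raise ValueError("fit window must contain at least 2 lags")
    t = curve.lags[sel]
    m = curve.msd[sel]
    if method == "ratio":
        d = float(np.mean(m / (2.0 * t)))
    else:
        d = float(np.sum(m * t) / np.sum(t * t) / 2.0)
    return DiffusionEstimate(D=d, method=method, fit_window=(float(lo), float(hi)))


def finite_size_scan(dist, L_values, protocol=None):
    """Diffusion coefficient versus confining box height.

    For each L, walkers start uniformly in a fully reflecting box of height L
    and D is estimated from the mode-'in' MSD (slope over
    [t_end/10, t_end/2]).  Small boxes saturate the MSD and underestimate D;
    the unconfined limit is <v^2> * dt_step / 2.

    ``protocol`` overrides dict(N=200, dt_step=5e-4, t_end=20.0, seeds=(0,)).

    Returns a pandas DataFrame (L, D, D_sd) sorted by L.
    """
    import pandas as pd

    from .stochastic_sim import WalkConfig, simulate_walk

    p = dict(N=200, dt_step=5e-4, t_end=20.0, seeds=(0,))
    if protocol:
        p.update(protocol)
    L_values = sorted(float(L) for L in L_values)
    if any(L <= 0 for L in L_values):
        raise ValueError("L values must be positive")
    rows = []
    for L in L_values:
        d_vals = []
        for seed in p["seeds"]:
            cfg = WalkConfig(
                L=L,
                N=p["N"],
                dt_step=p["dt_step"],
                t_end=p["t_end"],
                seed=seed,
                bottom="reflecting",
                top="reflecting",
            )
            traj, _ = simulate_walk(cfg, dist, record="positions")
            curve = msd(traj, mode="in", domain=(0.0, L))
            est = diffusion_coefficient(
                curve, method="slope", fit_window=(p["t_end"] / 10, p["t_end"] / 2)
            )
            d_vals.append(est.D)
        rows.append(dict(L=L, D=float(np.mean(d_vals)), D_sd=float(np.std(d_vals))))
    return pd.DataFrame(rows)


def zydney_colton(params: ZcParams) -> float:
    """Zydney-Colton shear-induced platelet diffusivity, m^2/s:

    D_ZC = D_PRP (1 - H) + 0.15 (d_RBC^2 / 4) H gamma_dot (1 - H)^1.8
    """
    h = params.H
    return float(
        params.D_PRP * (1.0 - h)
        + 0.15 * (params.d_RBC**2 / 4.0) * h * params.gamma_dot * (1.0 - h) ** 1.8
    )
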