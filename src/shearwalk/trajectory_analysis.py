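"""Trajectory statistics for wall-bounded platelet transport.

Operates on ensembles of vertical (cross-flow) platelet positions sampled at
a uniform interval: finite-difference velocities, ensemble mean speed,
log-binned velocity densities, Clauset-style power-law tail fits (KS-minimizing
threshold + continuous MLE exponent), the velocity autocorrelation function
and its power-law fit, the decorrelation (velocity memory) time, and per-height
velocity profiles with near-wall exclusion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TrajectorySet",
    "TailFit",
    "VacfCurve",
    "VacfFit",
    "DecorrelationResult",
    "WallProfiles",
    "extract_velocities",
    "mean_abs_velocity",
    "exclusion_filter",
    "log_binned_density",
    "fit_tail",
    "vacf",
    "fit_vacf_powerlaw",
    "decorrelation_time",
    "wall_profiles",
]

_TIME_TOL = 1e-9  # uniform-spacing tolerance, s


@dataclass
class TrajectorySet:
    """Ensemble of uniformly sampled vertical platelet positions.

    Each record is one contiguous position series (a platelet, or an in-band
    segment of one after filtering).  ``ids`` may repeat when a platelet was
    split into several segments.

    Attributes
    ----------
    ids : list of str
        Record labels.
    times : list of ndarray
        Sampling instants per record, s; strictly increasing, uniform spacing
        ``dt_sample`` to within 1 ns.
    y : list of ndarray
        Vertical positions per record, m.
    dt_sample : float
        Sampling interval, s.
    L : float
        Domain height, m.
    """

    ids: list
    times: list
    y: list
    dt_sample: float
    L: float

    def __post_init__(self) -> None:
        if self.L <= 0:
            raise ValueError("domain height L must be positive")
        if self.dt_sample <= 0:
            raise ValueError("dt_sample must be positive")
        if not (len(self.ids) == len(self.times) == len(self.y)):
            raise ValueError("ids, times and y must have equal length")
        for pid, t, yy in zip(self.ids, self.times, self.y):
            t = np.asarray(t, dtype=float)
            yy = np.asarray(yy, dtype=float)
            if t.shape != yy.shape:
                raise ValueError(f"platelet {pid!r}: times and y differ in length")
            if not np.all(np.isfinite(yy)):
                raise ValueError(f"platelet {pid!r}: non-finite positions")
            if t.size >= 2:
                dt = np.diff(t)
                if np.any(dt <= 0) or np.any(np.abs(dt - self.dt_sample) > _TIME_TOL):
                    raise ValueError(
                        f"platelet {pid!r}: non-uniform sampling "
                        f"(expected spacing {self.dt_sample} s)"
                    )

    @property
    def n_records(self) -> int:
        return len(self.ids)

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class TailFit:
    """Power-law tail fit: KS-minimizing threshold + continuous-MLE exponent.

    ``alpha_hat`` follows the convention in which the tail density decays as
    ``v**-(1+alpha)`` (i.e. the MLE density exponent minus one).
    """

    alpha_hat: float
    v_min_hat: float
    ks_stat: float
    n_tail: int
    degenerate: bool = False


@dataclass(frozen=True)
class VacfCurve:
    """Velocity autocorrelation values on a grid of lags (m^2/s^2 vs s)."""

    lags: np.ndarray
    values: np.ndarray
    n_pairs: np.ndarray


@dataclass(frozen=True)
class VacfFit:
    """Power-law fit VACF(tau) = a * (tau/1 ms)**-b with OLS standard errors."""

    a: float
    b: float
    sd_a: float
    sd_b: float


@dataclass(frozen=True)
class DecorrelationResult:
    """Velocity memory time: first lag at which the VACF falls to the noise floor."""

    delta_t: float
    sigma_tail: float
    tail_window: tuple


@dataclass(frozen=True)
class WallProfiles:
    """Per-height mean and variance of the signed velocity."""

    y_centers: np.ndarray
    mean_v: np.ndarray
    var_v: np.ndarray
    counts: np.ndarray
    global_mean: float
    global_var: float


# ---------------------------------------------------------------------------
# velocities


def extract_velocities(traj: TrajectorySet, stride: int = 1):
    """Forward-difference signed velocities at an effective interval ``stride*dt``.

    v(t) = (y(t + stride*dt) - y(t)) / (stride*dt); the last ``stride``
    samples of each record yield no velocity.

    Returns
    -------
    series : list of ndarray
        Signed velocity series per record, m/s.
    dt_eff : float
        Effective sampling interval ``stride * dt_sample``, s.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    dt_eff = stride * traj.dt_sample
    series = []
    for pid, yy in zip(traj.ids, traj.y):
        yy = np.asarray(yy, dtype=float)
        if yy.size < stride + 1:
            raise ValueError(
                f"platelet {pid!r}: needs at least {stride + 1} samples for stride {stride}"
            )
        series.append((yy[stride:] - yy[:-stride]) / dt_eff)
    return series, dt_eff


def mean_abs_velocity(series) -> float:
    """Mean absolute velocity: time average per record, then record average.

    Records of unequal length carry equal weight (this is not the pooled mean).
    """
    series = list(series)
    if not series or any(np.asarray(s).size == 0 for s in series):
        raise ValueError("mean_abs_velocity requires non-empty velocity series")
    return float(np.mean([np.mean(np.abs(s)) for s in series]))


def exclusion_filter(traj: TrajectorySet, margin: float = 1e-5) -> TrajectorySet:
    """Restrict records to the band ``margin <= y <= L - margin``.

    Near-wall samples are discarded (margination traps platelets within about
    one red-blood-cell diameter of each wall, where the transport statistics
    are not representative of the bulk).  Each contiguous in-band run becomes
    an independent record.
    """
    if 2 * margin >= traj.L:
        raise ValueError("exclusion band is empty: 2*margin >= L")
    lo, hi = margin, traj.L - margin
    ids, times, ys = [], [], []
    for pid, t, yy in zip(traj.ids, traj.times, traj.y):
        t = np.asarray(t, dtype=float)
        yy = np.asarray(yy, dtype=float)
        inside = (yy >= lo) & (yy <= hi)
        if not inside.any():
            continue
        # contiguous runs of in-band samples
        edges = np.flatnonzero(np.diff(inside.astype(np.int8)))
        starts = np.r_[0, edges + 1]
        stops = np.r_[edges + 1, inside.size]
        for a, b in zip(starts, stops):
            if inside[a]:
                ids.append(pid)
                times.append(t[a:b])
                ys.append(yy[a:b])
    return TrajectorySet(ids=ids, times=times, y=ys, dt_sample=traj.dt_sample, L=traj.L)


# ---------------------------------------------------------------------------
# densities and tail fitting


def log_binned_density(velocities, bins_per_decade: int = 8, vrange=(1e-5, 0.3)):
    """Empirical density of velocity magnitudes on logarithmically spaced bins.

    Densities are counts divided by (total sample count x linear bin width),
    so that sum(density * width) equals the fraction of samples inside
    ``vrange``.

    Returns
    -------
    centers : ndarray
        Geometric bin centers, m/s.
    densities : ndarray
        Estimated density per bin, s/m (0 for empty bins).
    """
    lo, hi = vrange
    if lo <= 0 or hi <= lo:
        raise ValueError("vrange must satisfy 0 < lo < hi")
    v = np.asarray(velocities, dtype=float).ravel()
    n_bins = max(1, int(math.ceil(bins_per_decade * math.log10(hi / lo))))
    edges = np.geomspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(v, bins=edges)
    widths = np.diff(edges)
    densities = counts / (v.size * widths)
    centers = np.sqrt(edges[:-1] * edges[1:])
    return centers, densities


def _candidate_thresholds(v_sorted: np.ndarray, max_candidates: int = 200) -> np.ndarray:
    """Unique observed values between the 50th and 99.9th percentile, thinned
    to at most ``max_candidates`` log-spaced values."""
    lo = np.quantile(v_sorted, 0.5)
    hi = np.quantile(v_sorted, 0.999)
    cand = np.unique(v_sorted[(v_sorted >= lo) & (v_sorted <= hi)])
    if cand.size > max_candidates:
        targets = np.geomspace(cand[0], cand[-1], max_candidates)
        idx = np.unique(np.searchsorted(cand, targets).clip(0, cand.size - 1))
        cand = cand[idx]
    return cand


def fit_tail(
    velocities,
    v_min_grid=None,
    min_tail: int = 50,
    max_ks_points: int = 2000,
) -> TailFit:
    """Joint threshold/exponent estimate of a power-law tail.

    For each candidate threshold, the tail exponent is the continuous MLE
    ``1 + n / sum(ln(v/v_min))`` (density convention) and the goodness of fit
    is the KS distance between the tail sample and the fitted Pareto; the
    selected threshold minimizes the KS distance.  The returned ``alpha_hat``
    is the MLE density exponent minus one.

    For large tails the KS distance is evaluated on up to ``max_ks_points``
    evenly spaced order statistics (exact when the tail is smaller).

    A fit is flagged ``degenerate`` when the optimal threshold sits at either
    extreme of the candidate grid, or when even the best candidate is
    rejected by a KS test at the 1% level (critical value 1.63/sqrt(n_tail))
    — both typical of data with no power-law tail.
    """
    v = np.asarray(velocities, dtype=float).ravel()
    v = v[v > 0]
    v.sort()
    if v_min_grid is None:
        cand = _candidate_thresholds(v)
    else:
        cand = np.sort(np.asarray(v_min_grid, dtype=float))
    if cand.size == 0:
        raise ValueError("no candidate thresholds")

    log_v = np.log(v)
    suffix = np.concatenate([np.cumsum(log_v[::-1])[::-1], [0.0]])

    best = None
    for j, vm in enumerate(cand):
        i0 = np.searchsorted(v, vm, side="left")
        n_tail = v.size - i0
        if n_tail < min_tail:
            continue
        sum_log = suffix[i0] - n_tail * math.log(vm)
        if sum_log <= 0:
            continue
        a_density = 1.0 + n_tail / sum_log
        # KS against the fitted Pareto, on (a subset of) the tail order stats
        if n_tail > max_ks_points:
            ranks = np.unique(np.linspace(0, n_tail - 1, max_ks_points).astype(np.intp))
        else:
            ranks = np.arange(n_tail, dtype=np.intp)
        tail_vals = v[i0 + ranks]
        f_model = 1.0 - (tail_vals / vm) ** (-(a_density - 1.0))
        d = np.maximum(
            np.abs(f_model - ranks / n_tail), np.abs(f_model - (ranks + 1) / n_tail)
        ).max()
        if best is None or d < best[0]:
            best = (float(d), float(vm), float(a_density), int(n_tail), j)
    if best is None:
        raise ValueError(f"tail smaller than min_tail={min_tail} at every candidate threshold")
    ks, vm, a_density, n_tail, j = best
    return TailFit(
        alpha_hat=a_density - 1.0,
        v_min_hat=vm,
        ks_stat=ks,
        n_tail=n_tail,
        degenerate=(j == 0 or j == cand.size - 1 or ks > 1.63 / math.sqrt(n_tail)),
    )


# ---------------------------------------------------------------------------
# autocorrelation


def vacf(series, dt: float, lags=None) -> VacfCurve:
    """Velocity autocorrelation VACF(tau) = <v(t+tau) v(t)> of signed velocities.

    Averages over all records and admissible time origins; pairs never
    straddle record boundaries (so pre-segmented, exclusion-filtered input is
    handled correctly).  Requested lags must be integer multiples of ``dt``;
    lags with no contributing pair in any record are dropped with a warning.
    """
    series = [np.asarray(s, dtype=float) for s in series]
    if not series:
        raise ValueError("empty ensemble")
    max_len = max(s.size for s in series)
    if lags is None:
        ks = np.arange(0, max_len)
    else:
        lags = np.asarray(lags, dtype=float)
        ks = np.rint(lags / dt).astype(np.intp)
        if np.any(np.abs(ks * dt - lags) > 1e-9):
            raise ValueError("lags must be integer multiples of the sampling interval")
    keep, vals, pairs = [], [], []
    dropped = 0
    for k in ks:
        total = 0.0
        count = 0
        for s in series:
            if s.size > k:
                total += float(np.dot(s[: s.size - k], s[k:]))
                count += s.size - k
        if count == 0:
            dropped += 1
            continue
        keep.append(k * dt)
        vals.append(total / count)
        pairs.append(count)
    if dropped:
        warnings.warn(f"dropped {dropped} lag(s) beyond the longest series", stacklevel=2)
    return VacfCurve(
        lags=np.asarray(keep), values=np.asarray(vals), n_pairs=np.asarray(pairs, dtype=np.intp)
    )


def fit_vacf_powerlaw(curve: VacfCurve, fit_window) -> VacfFit:
    """Least-squares power-law fit of the VACF on log-log axes.

    Fits ln VACF against ln(tau / 1 ms) over ``fit_window`` (s, s), using only
    strictly positive VACF values; returns the amplitude ``a`` (the VACF value
    at tau = 1 ms), the decay exponent ``b`` and their standard errors.
    """
    lo, hi = fit_window
    sel = (curve.lags >= lo) & (curve.lags <= hi) & (curve.values > 0) & (curve.lags > 0)
    if sel.sum() < 3:
        raise ValueError("need at least 3 strictly positive VACF values in the fit window")
    x = np.log(curve.lags[sel] / 1e-3)
    yv = np.log(curve.values[sel])
    res = stats.linregress(x, yv)
    a = math.exp(res.intercept)
    return VacfFit(
        a=a,
        b=-res.slope,
        sd_a=a * res.intercept_stderr,
        sd_b=res.stderr,
    )


def decorrelation_time(curve: VacfCurve, tail_window=None) -> DecorrelationResult:
    """Velocity memory time from the VACF noise floor.

    ``sigma_tail`` is the standard deviation of the VACF values inside
    ``tail_window`` (default: the last quarter of the lag range); the memory
    time is the smallest lag at which VACF(tau) <= sigma_tail.
    """
    if tail_window is None:
        lo = curve.lags[0] + 0.75 * (curve.lags[-1] - curve.lags[0])
        tail_window = (float(lo), float(curve.lags[-1]))
    lo, hi = tail_window
    sel = (curve.lags >= lo) & (curve.lags <= hi)
    if sel.sum() < 5:
        raise ValueError("tail window must contain at least 5 lags")
    sigma = float(np.std(curve.values[sel]))
    below = curve.values <= sigma
    if not below.any():
        raise ValueError(
            "VACF never falls below the noise floor; extend the lag range"
        )
    return DecorrelationResult(
        delta_t=float(curve.lags[np.argmax(below)]),
        sigma_tail=sigma,
        tail_window=(float(lo), float(hi)),
    )


# ---------------------------------------------------------------------------
# wall profiles


def wall_profiles(
    traj: TrajectorySet,
    bin_width: float = 1e-7,
    min_freq: float = 1e-3,
    margin: float = 1e-5,
) -> WallProfiles:
    """Mean and variance of the signed velocity as a function of height.

    Velocities (stride-1 forward differences) are attributed to the height at
    the start of each interval and binned in ``bin_width`` slabs across
    [0, L].  Bins visited by fewer than ``min_freq`` of all samples are
    masked out.  The global mean/variance are computed over the
    exclusion-filtered band [margin, L - margin].
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    series, _ = extract_velocities(traj, stride=1)
    v_all = np.concatenate(series)
    y_all = np.concatenate([np.asarray(yy, dtype=float)[:-1] for yy in traj.y])
    n_bins = max(1, int(math.ceil(traj.L / bin_width)))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    idx = np.clip(np.digitize(y_all, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=v_all, minlength=n_bins)
    sq = np.bincount(idx, weights=v_all**2, minlength=n_bins)
    visible = counts >= max(1, int(math.ceil(min_freq * v_all.size)))
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts
        var = sq / counts - mean**2
    centers = 0.5 * (edges[:-1] + edges[1:])
    band = (y_all >= margin) & (y_all <= traj.L - margin)
    return WallProfiles(
        y_centers=centers[visible],
        mean_v=mean[visible],
        var_v=var[visible],
        counts=counts[visible],
        global_mean=float(np.mean(v_all[band])) if band.any() else float("nan"),
        global_var=float(np.var(v_all[band])) if band.any() else float("nan"),
    )
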