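"""Piecewise exponential / power-law model of platelet transverse velocities.

In a sheared red-blood-cell suspension, the marginal distribution of the
platelet velocity magnitude perpendicular to the flow is well described by an
exponentially decaying bulk joined continuously, at a threshold ``v_min``, to
a Pareto (power-law) tail::

    P(v) = p0 * exp(-lam * v)                              for v <= v_min
    P(v) = p0 * exp(-lam * v_min) * (v / v_min)**-(1+alpha) for v >= v_min

Five parameters describe the law: the tail exponent ``alpha`` (density decays
as ``v**-(1+alpha)``), the bulk/tail threshold ``v_min`` (m/s), the mean
magnitude ``v_moy`` (m/s), and the derived pair ``(p0, lam)`` fixed by
requiring unit mass and mean ``v_moy``.  This module solves for ``(p0, lam)``,
evaluates the density/CDF in closed form, inverts the CDF exactly, draws
sign-symmetric velocity samples, and provides closed-form moments used as
analytic oracles for diffusion estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

__all__ = [
    "VelocityDistribution",
    "solve_normalization",
    "NormalizationError",
]

# r values this close to 1 are clamped before CDF inversion; beyond it the
# tail expression's bracket can underflow to <= 0.
_R_CLAMP = 1.0 - 1e-12


class NormalizationError(RuntimeError):
    """Raised when the (p0, lam) root solve fails to reach tolerance."""


def _mass_mean(p0: float, lam: float, alpha: float, v_min: float) -> tuple[float, float]:
    """Exact zeroth and first moments of the piecewise law."""
    e = math.exp(-lam * v_min)
    mass = p0 / lam * (1.0 - e) + p0 * e * v_min / alpha
    mean = p0 * e * (v_min**2 / (alpha - 1.0) - v_min / lam - 1.0 / lam**2) + p0 / lam**2
    return mass, mean


def solve_normalization(
    alpha: float, v_min: float, v_moy: float, *, rtol: float = 1e-12
) -> tuple[float, float]:
    """Solve the unit-mass and mean constraints for ``(p0, lam)``.

    The two constraints are the exact integrals of the piecewise density:
    total mass 1 and mean ``v_moy`` (the mean constraint includes the bulk
    term ``p0/lam**2``).  The solve is initialized at the pure-exponential
    limit ``p0 = lam = 1/v_moy``, which is exact when the tail carries no
    mass (``lam*v_min >> 1``) and within a few percent otherwise.

    Parameters
    ----------
    alpha : float
        Tail exponent, must exceed 1 for the tail mean to be finite.
    v_min : float
        Bulk/tail threshold velocity, m/s.
    v_moy : float
        Target mean velocity magnitude, m/s.
    rtol : float
        Maximum admissible relative residual of both constraints.

    Returns
    -------
    (p0, lam) : tuple of float
        Density normalization (s/m) and bulk decay rate (s/m).
    """
    if alpha <= 1.0:
        raise ValueError(f"alpha must exceed 1 (tail mean diverges); got {alpha}")
    if v_min <= 0.0 or v_moy <= 0.0:
        raise ValueError("v_min and v_moy must be positive")

    def residuals(x: np.ndarray) -> list[float]:
        p0, lam = np.exp(x)
        mass, mean = _mass_mean(p0, lam, alpha, v_min)
        return [mass - 1.0, mean / v_moy - 1.0]

    x0 = np.log([1.0 / v_moy, 1.0 / v_moy])
    sol = optimize.root(residuals, x0, method="hybr", tol=1e-14)
    p0, lam = np.exp(sol.x)
    r_mass, r_mean = residuals(sol.x)
    if not (abs(r_mass) <= rtol and abs(r_mean) <= rtol):
        raise NormalizationError(
            "normalization solve did not converge: "
            f"mass residual {r_mass:.3e}, mean residual {r_mean:.3e} "
            f"(alpha={alpha}, v_min={v_min}, v_moy={v_moy})"
        )
    return float(p0), float(lam)


@dataclass(frozen=True)
class VelocityDistribution:
    """Exponential-bulk / power-law-tail distribution of velocity magnitudes.

    Attributes
    ----------
    alpha : float
        Dimensionless tail exponent; tail density decays as ``v**-(1+alpha)``.
    v_min : float
        Threshold separating bulk from tail, m/s.
    v_moy : float
        Mean velocity magnitude, m/s.
    p0 : float
        Density at v=0, s/m.
    lam : float
        Bulk exponential decay rate, s/m.
    """

    alpha: float
    v_min: float
    v_moy: float
    p0: float
    lam: float

    def __post_init__(self) -> None:
        if self.alpha <= 1.0:
            raise ValueError("alpha must exceed 1")
        for name in ("v_min", "v_moy", "p0", "lam"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_constraints(cls, alpha: float, v_min: float, v_moy: float) -> "VelocityDistribution":
        """Build a distribution by solving the normalization constraints."""
        p0, lam = solve_normalization(alpha, v_min, v_moy)
        return cls(alpha=alpha, v_min=v_min, v_moy=v_moy, p0=p0, lam=lam)

    # -- closed-form pieces -------------------------------------------------

    @property
    def _tail_amp(self) -> float:
        """Density value at the threshold, p0*exp(-lam*v_min)."""
        return self.p0 * math.exp(-self.lam * self.v_min)

    @property
    def r_c(self) -> float:
        """CDF value at v_min: mass of the exponential bulk."""
        return self.p0 / self.lam * (1.0 - math.exp(-self.lam * self.v_min))

    def pdf(self, v):
        """Probability density of the velocity magnitude, s/m."""
        v = np.asarray(v, dtype=float)
        if np.any(v < 0):
            raise ValueError("velocity magnitudes must be non-negative")
        bulk = self.p0 * np.exp(-self.lam * v)
        with np.errstate(divide="ignore"):
            tail = self._tail_amp * (v / self.v_min) ** (-1.0 - self.alpha)
        out = np.where(v <= self.v_min, bulk, tail)
        return out if out.ndim else float(out)

    def cdf(self, v):
        """Cumulative distribution of the magnitude, closed form on both branches."""
        v = np.asarray(v, dtype=float)
        if np.any(v < 0):
            raise ValueError("velocity magnitudes must be non-negative")
        bulk = self.p0 / self.lam * (1.0 - np.exp(-self.lam * v))
        tail = self.r_c + self._tail_amp * self.v_min / self.alpha * (
            1.0 - (np.maximum(v, self.v_min) / self.v_min) ** (-self.alpha)
        )
        out = np.where(v <= self.v_min, bulk, tail)
        return out if out.ndim else float(out)

    def inverse_cdf(self, r):
        """Exact functional inverse of :meth:`cdf`.

        Bulk branch for r below r_c, Pareto branch above; r values at or
        above ``1 - 1e-12`` are clamped to avoid the tail bracket reaching 0.
        """
        r = np.asarray(r, dtype=float)
        scalar = r.ndim == 0
        if np.any((r < 0) | (r >= 1)):
            raise ValueError("r must lie in [0, 1)")
        r = np.minimum(r, _R_CLAMP)
        r_c = self.r_c
        in_bulk = r < r_c
        arg = 1.0 - self.lam * np.where(in_bulk, r, 0.0) / self.p0
        bulk = -np.log(arg) / self.lam
        bracket = 1.0 - self.alpha * np.where(in_bulk, 0.0, r - r_c) / (
            self._tail_amp * self.v_min
        )
        tail = self.v_min * bracket ** (-1.0 / self.alpha)
        out = np.where(in_bulk, bulk, tail)
        return float(out) if scalar else out

    # -- sampling -----------------------------------------------------------

    def sample_magnitudes(self, n: int, rng: np.random.Generator, cap: float | None = None):
        """Draw ``n`` velocity magnitudes by inverse-CDF sampling.

        Consumes uniforms in (magnitude, sign) pairs even though the sign
        column is discarded here, so that magnitude draws coincide with
        those of :meth:`sample_signed` at the same generator state.
        """
        u = rng.random((n, 2))
        v = self.inverse_cdf(u[:, 0])
        if cap is not None:
            if cap <= 0:
                raise ValueError("cap must be positive")
            bad = v > cap
            while np.any(bad):
                u = rng.random((int(bad.sum()), 2))
                v[bad] = self.inverse_cdf(u[:, 0])
                bad = v > cap
        return v

    def sample_signed(self, n: int, seed=None, cap: float | None = None, rng=None):
        """Draw ``n`` signed velocities: inverse-CDF magnitude, then a ±1 sign
        with probability 1/2 each from a second uniform per velocity."""
        if n < 1:
            raise ValueError("n must be >= 1")
        if rng is None:
            rng = np.random.default_rng(seed)
        u = rng.random((n, 2))
        v = self.inverse_cdf(u[:, 0])
        signs = np.where(u[:, 1] < 0.5, -1.0, 1.0)
        if cap is not None:
            if cap <= 0:
                raise ValueError("cap must be positive")
            bad = v > cap
            while np.any(bad):
                u2 = rng.random((int(bad.sum()), 2))
                v[bad] = self.inverse_cdf(u2[:, 0])
                signs[bad] = np.where(u2[:, 1] < 0.5, -1.0, 1.0)
                bad = v > cap
        return v * signs

    # -- moments ------------------------------------------------------------

    def moment(self, k: int) -> float:
        """Closed-form k-th moment of the magnitude, k in {0, 1, 2}.

        Bulk contribution via the lower incomplete gamma function, tail via
        the Pareto integral; the second moment requires alpha > 2.
        """
        if k not in (0, 1, 2):
            raise ValueError("k must be 0, 1 or 2")
        if k == 2 and self.alpha <= 2.0:
            raise ValueError(
                f"second moment diverges for alpha <= 2 (Levy regime); alpha={self.alpha}"
            )
        lam, v_min, alpha = self.lam, self.v_min, self.alpha
        # bulk: p0 * int_0^vmin v^k exp(-lam v) dv = p0 * gamma_lower(k+1, lam*vmin) / lam^(k+1)
        bulk = self.p0 * special.gammainc(k + 1, lam * v_min) * math.gamma(k + 1) / lam ** (k + 1)
        tail = self._tail_amp * v_min ** (k + 1) / (alpha - k)
        return float(bulk + tail)


# Thin functional wrappers (module-level verbs mirroring the class surface).

def pdf(dist: VelocityDistribution, v):
    return dist.pdf(v)


def cdf(dist: VelocityDistribution, v):
    return dist.cdf(v)


def inverse_cdf(dist: VelocityDistribution, r):
    return dist.inverse_cdf(r)


def sample_signed(dist: VelocityDistribution, n: int, seed=None, cap=None):
    return dist.sample_signed(n, seed=seed, cap=cap)


def moment(dist: VelocityDistribution, k: int) -> float:
    return dist.moment(k)
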