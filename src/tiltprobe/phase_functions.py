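"""Single-scattering phase functions for turbid-tissue optics.

Three azimuthally symmetric phase-function families are provided:

* Henyey–Greenstein (HG) — the classic one-parameter function whose
  Legendre moments are ``g_n = g**n``.
* Modified Henyey–Greenstein (MHG) — a mixture ``alpha * HG + (1 - alpha)
  * (3/2) mu^2`` that decouples the second Legendre moment ``g2`` from the
  anisotropy ``g1``.
* Modified power of cosines (MPC) — a mixture of ``(1 + mu)**N`` and the
  same ``cos^2`` term.  MHG and MPC can be solved to share (g1, g2) while
  differing in every higher moment, which is exactly what makes the pair
  useful for quantifying the influence of moments above order 2 on
  subdiffusive reflectance.

Density convention
------------------
All densities here are per unit *cosine* of the polar scattering angle,
``p(mu)`` with ``mu = cos(theta)`` on [-1, 1] and ``∫ p(mu) d(mu) = 1``.
The per-solid-angle forms found in the literature carry an extra
``1/(2 pi)`` azimuthal factor that is divided out; single scattering in an
isotropic medium is azimuthally uniform.  Legendre moments are

    g_n = ∫_{-1}^{1} P_n(mu) p(mu) d(mu).

The ``cos^2`` admixture has moments g1 = 0, g2 = 2/5, g_n = 0 otherwise,
which is where the ``(2/5)(1 - alpha)`` terms in the mixture moments come
from.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence, Union

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import brentq
from scipy.special import eval_legendre

__all__ = [
    "MomentSet",
    "HenyeyGreenstein",
    "ModifiedHenyeyGreenstein",
    "ModifiedPowerOfCosines",
    "PhaseFunction",
    "InfeasibleMomentsError",
    "evaluate_pdf",
    "analytic_moments",
    "numeric_moments",
    "sample_cos_theta",
    "solve_params_from_moments",
    "spec_for_gamma",
    "mpc_pure_moments",
    "representable",
]

#: second Legendre moment of the (3/2) mu^2 admixture
_COS2_G2 = 0.4

#: tolerance for snapping (g1, g2) targets onto a family boundary
_BOUNDARY_EPS = 1e-9


class InfeasibleMomentsError(ValueError):
    """Raised when a (g1, g2) target lies outside a family's representable
    region (would require alpha outside [0, 1] or a negative density)."""


@dataclasses.dataclass(frozen=True)
class MomentSet:
    """First two Legendre moments of a phase function.

    ``gamma = (1 - g2) / (1 - g1)`` is the subdiffusive parameter: it
    controls the phase-function dependence of reflectance at short
    source–detector separations and is sensitive to the scatterer size
    distribution.
    """

    g1: float
    g2: float

    def __post_init__(self) -> None:
        if not -1.0 < self.g1 < 1.0:
            raise ValueError(f"g1 must lie in (-1, 1), got {self.g1}")
        if not -0.5 <= self.g2 < 1.0:
            raise ValueError(f"g2 must lie in [-0.5, 1), got {self.g2}")

    @property
    def gamma(self) -> float:
        return (1.0 - self.g2) / (1.0 - self.g1)

    @classmethod
    def from_gamma(cls, gamma: float, g1: float = 0.9) -> "MomentSet":
        """Moment pair with the requested gamma at a fixed anisotropy g1."""
        return cls(g1, 1.0 - gamma * (1.0 - g1))

    def decayed(self, s: int) -> "MomentSet":
        """Moments of the effective phase function after ``s`` scattering
        events (Legendre moments multiply under composed rotations)."""
        if s < 1:
            raise ValueError("s must be >= 1")
        return MomentSet(self.g1**s, self.g2**s)


def _hg_pdf(g: float, mu: np.ndarray) -> np.ndarray:
    if abs(g) < 1e-12:
        return np.full_like(mu, 0.5)
    return 0.5 * (1.0 - g * g) / (1.0 + g * g - 2.0 * g * mu) ** 1.5


def _cos2_pdf(mu: np.ndarray) -> np.ndarray:
    return 1.5 * mu * mu


@dataclasses.dataclass(frozen=True)
class HenyeyGreenstein:
    """HG phase function; ``g`` is the anisotropy factor g1."""

    g: float
    family = "hg"

    def __post_init__(self) -> None:
        if not 0.0 <= self.g < 1.0:
            raise ValueError(f"HG g must lie in [0, 1), got {self.g}")

    def pdf(self, mu):
        mu = np.asarray(mu, dtype=float)
        _check_mu(mu)
        return _hg_pdf(self.g, mu)

    def moments(self, n_max: int) -> np.ndarray:
        _check_nmax(n_max)
        return self.g ** np.arange(1, n_max + 1, dtype=float)

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        xi = rng.random(size)
        return _hg_invcdf(self.g, xi)


@dataclasses.dataclass(frozen=True)
class ModifiedHenyeyGreenstein:
    """MHG: ``alpha * HG(g) + (1 - alpha) * (3/2) mu^2`` per unit cosine."""

    alpha: float
    g: float
    family = "mhg"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"MHG alpha must lie in [0, 1], got {self.alpha}")
        if not 0.0 <= self.g < 1.0:
            raise ValueError(f"MHG g must lie in [0, 1), got {self.g}")

    def pdf(self, mu):
        mu = np.asarray(mu, dtype=float)
        _check_mu(mu)
        return self.alpha * _hg_pdf(self.g, mu) + (1.0 - self.alpha) * _cos2_pdf(mu)

    def moments(self, n_max: int) -> np.ndarray:
        _check_nmax(n_max)
        gn = self.alpha * self.g ** np.arange(1, n_max + 1, dtype=float)
        if n_max >= 2:
            gn[1] += _COS2_G2 * (1.0 - self.alpha)
        return gn

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        xi = rng.random(size)
        comp = rng.random(size) < self.alpha
        out = np.where(comp, _hg_invcdf(self.g, xi), _cos2_invcdf(xi))
        return out if size is not None else float(out)


@dataclasses.dataclass(frozen=True)
class ModifiedPowerOfCosines:
    """MPC: ``alpha * PC(N) + (1 - alpha) * (3/2) mu^2`` where the pure
    power-of-cosines density is ``(N + 1) / 2**(N + 1) * (1 + mu)**N``.

    ``n_pc`` (the exponent N) may be any nonnegative real; the moment
    recursion ``gPC_n = gPC_{n-1} (N - n + 1) / (N + n + 1)`` remains valid
    for non-integer N, and matching arbitrary (g1, g2) generally requires
    it.
    """

    alpha: float
    n_pc: float
    family = "mpc"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"MPC alpha must lie in [0, 1], got {self.alpha}")
        if not self.n_pc >= 0.0:
            raise ValueError(f"MPC exponent must be >= 0, got {self.n_pc}")

    def pdf(self, mu):
        mu = np.asarray(mu, dtype=float)
        _check_mu(mu)
        n = self.n_pc
        pc = 0.5 * (n + 1.0) * ((1.0 + mu) / 2.0) ** n
        return self.alpha * pc + (1.0 - self.alpha) * _cos2_pdf(mu)

    def moments(self, n_max: int) -> np.ndarray:
        _check_nmax(n_max)
        gn = self.alpha * mpc_pure_moments(self.n_pc, n_max)
        if n_max >= 2:
            gn[1] += _COS2_G2 * (1.0 - self.alpha)
        return gn

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        xi = rng.random(size)
        comp = rng.random(size) < self.alpha
        pc = 2.0 * xi ** (1.0 / (self.n_pc + 1.0)) - 1.0
        out = np.where(comp, pc, _cos2_invcdf(xi))
        return out if size is not None else float(out)


PhaseFunction = Union[HenyeyGreenstein, ModifiedHenyeyGreenstein, ModifiedPowerOfCosines]


def _check_mu(mu: np.ndarray) -> None:
    if np.any(mu < -1.0) or np.any(mu > 1.0):
        raise ValueError("mu must lie in [-1, 1]")


def _check_nmax(n_max: int) -> None:
    if n_max < 1:
        raise ValueError("n_max must be >= 1")


def _hg_invcdf(g: float, xi) -> np.ndarray:
    """Standard HG inverse CDF on the per-cosine density."""
    xi = np.asarray(xi, dtype=float)
    if abs(g) < 1e-12:
        return 2.0 * xi - 1.0
    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    return (1.0 + g * g - t * t) / (2.0 * g)


def _cos2_invcdf(xi) -> np.ndarray:
    """Inverse CDF of (3/2) mu^2: mu = cbrt(2 xi - 1)."""
    return np.cbrt(2.0 * np.asarray(xi, dtype=float) - 1.0)


def mpc_pure_moments(n_pc: float, n_max: int) -> np.ndarray:
    """Legendre moments of the pure power-of-cosines density.

    gPC_1 = N / (N + 2); gPC_n = gPC_{n-1} (N - n + 1) / (N + n + 1).
    """
    _check_nmax(n_max)
    gn = np.empty(n_max, dtype=float)
    gn[0] = n_pc / (n_pc + 2.0)
    for n in range(2, n_max + 1):
        gn[n - 1] = gn[n - 2] * (n_pc - n + 1.0) / (n_pc + n + 1.0)
    return gn


def evaluate_pdf(spec: PhaseFunction, mu) -> np.ndarray:
    """Evaluate the per-cosine density of ``spec`` at ``mu``."""
    return spec.pdf(mu)


def analytic_moments(spec: PhaseFunction, n_max: int) -> np.ndarray:
    """Closed-form Legendre moments g_1..g_{n_max} of ``spec``."""
    return spec.moments(n_max)


def sample_cos_theta(spec: PhaseFunction, rng: np.random.Generator, size=None):
    """Draw exact samples of the scattering-angle cosine."""
    return spec.sample(rng, size)


def numeric_moments(pdf, n_max: int, n_quad: int = 512) -> np.ndarray:
    """Legendre moments of an arbitrary per-cosine density by Gauss–Legendre
    quadrature.

    Parameters
    ----------
    pdf
        Callable ``pdf(mu)`` returning the density, or an array of density
        values tabulated on the ``n_quad``-point Gauss–Legendre nodes.
    n_max
        Highest moment order to return.

    Raises
    ------
    ValueError
        If the density is negative somewhere or not normalized to 1 within
        1e-6.
    """
    _check_nmax(n_max)
    nodes, weights = leggauss(n_quad)
    p = np.asarray(pdf(nodes) if callable(pdf) else pdf, dtype=float)
    if p.shape != nodes.shape:
        raise ValueError("tabulated pdf must be given on the quadrature nodes")
    if np.any(p < -1e-12):
        raise ValueError("pdf must be nonnegative")
    norm = float(weights @ p)
    if abs(norm - 1.0) > 1e-6:
        raise ValueError(f"pdf integrates to {norm:.8f}, expected 1 within 1e-6")
    return np.array(
        [float(weights @ (eval_legendre(n, nodes) * p)) for n in range(1, n_max + 1)]
    )


# ---------------------------------------------------------------------------
# Solving family parameters from target (g1, g2)
# ---------------------------------------------------------------------------

def _mhg_bounds(g1: float) -> tuple[float, float]:
    # alpha = 1 lower boundary (pure HG); alpha -> g1 as g -> 1 upper boundary
    return g1 * g1, g1 + _COS2_G2 * (1.0 - g1)


def _mpc_bounds(g1: float) -> tuple[float, float]:
    n_min = 2.0 * g1 / (1.0 - g1)  # alpha = 1 boundary
    g2_lo = g1 * (n_min - 1.0) / (n_min + 3.0)
    return g2_lo, g1 + _COS2_G2 * (1.0 - g1)


def representable(family: str, g1: float, g2: float) -> bool:
    """Whether the (g1, g2) pair is reachable by the family with
    alpha in [0, 1] and a nonnegative density."""
    if not 0.0 < g1 < 1.0:
        return False
    lo, hi = _mhg_bounds(g1) if family == "mhg" else _mpc_bounds(g1)
    return lo - _BOUNDARY_EPS <= g2 <= hi + _BOUNDARY_EPS


def _solve_mhg(g1: float, g2: float) -> ModifiedHenyeyGreenstein:
    lo, hi = _mhg_bounds(g1)
    if g2 < lo - _BOUNDARY_EPS:
        raise InfeasibleMomentsError(
            f"MHG requires g2 >= g1^2 = {lo:.6g} (alpha <= 1); got g2 = {g2:.6g}"
        )
    if g2 > hi + _BOUNDARY_EPS:
        raise InfeasibleMomentsError(
            f"MHG requires g2 <= g1 + 0.4(1 - g1) = {hi:.6g} (alpha >= 0 with "
            f"g < 1); got g2 = {g2:.6g}"
        )
    if g1 < 1e-12:  # isotropic limit: g = 0, alpha set by g2 alone
        return ModifiedHenyeyGreenstein(1.0 - g2 / _COS2_G2, 0.0)
    if g2 <= lo:  # boundary within tolerance: pure HG
        return ModifiedHenyeyGreenstein(1.0, g1)
    # eliminate alpha = g1/g:  g1 g^2 + (0.4 - g2) g - 0.4 g1 = 0
    # (conjugate form of the positive root, stable for small g1)
    b = _COS2_G2 - g2
    g = 2.0 * _COS2_G2 * g1 / (b + math.sqrt(b * b + 4.0 * _COS2_G2 * g1 * g1))
    g = min(g, 1.0 - 1e-15)
    alpha = min(g1 / g, 1.0)
    return ModifiedHenyeyGreenstein(alpha, g)


def _solve_mpc(g1: float, g2: float) -> ModifiedPowerOfCosines:
    lo, hi = _mpc_bounds(g1)
    if g2 < lo - _BOUNDARY_EPS:
        raise InfeasibleMomentsError(
            f"MPC requires g2 >= {lo:.6g} at g1 = {g1:.6g} (alpha <= 1); "
            f"got g2 = {g2:.6g}"
        )
    if g2 > hi + _BOUNDARY_EPS:
        raise InfeasibleMomentsError(
            f"MPC requires g2 <= g1 + 0.4(1 - g1) = {hi:.6g} (alpha >= 0); "
            f"got g2 = {g2:.6g}"
        )
    if g1 < 1e-12:  # isotropic limit: N = 0 (flat), alpha set by g2 alone
        return ModifiedPowerOfCosines(1.0 - g2 / _COS2_G2, 0.0)
    n_min = 2.0 * g1 / (1.0 - g1)
    if g2 <= lo:
        return ModifiedPowerOfCosines(1.0, n_min)

    def f(n: float) -> float:
        # g2 as a function of N with alpha eliminated (alpha = g1 (N+2)/N);
        # strictly increasing in N
        return (
            g1 * (n - 1.0) / (n + 3.0)
            + _COS2_G2 * (1.0 - g1 * (n + 2.0) / n)
            - g2
        )

    n_hi = max(1e4, 10.0 * n_min)
    if f(n_hi) < 0.0:
        raise InfeasibleMomentsError(
            f"MPC exponent exceeds the search bracket for (g1, g2) = "
            f"({g1:.6g}, {g2:.6g})"
        )
    n = brentq(f, n_min, n_hi, xtol=1e-12, rtol=8.882e-16)
    alpha = min(g1 * (n + 2.0) / n, 1.0)
    return ModifiedPowerOfCosines(alpha, n)


def solve_params_from_moments(family: str, target: MomentSet) -> PhaseFunction:
    """Solve MHG or MPC parameters reproducing the target (g1, g2).

    The mixture weight alpha is eliminated in closed form and the remaining
    shape parameter found on its unique monotone branch; the returned
    parameters reproduce the targets to ~1e-10.  Targets outside the
    representable region raise :class:`InfeasibleMomentsError` naming the
    violated constraint.
    """
    if family == "mhg":
        return _solve_mhg(target.g1, target.g2)
    if family == "mpc":
        return _solve_mpc(target.g1, target.g2)
    raise ValueError(f"unknown family {family!r}; expected 'mhg' or 'mpc'")


def spec_for_gamma(
    family: str, gamma: float, g1: float = 0.9
) -> PhaseFunction:
    """Phase function of the given family with subdiffusive parameter gamma.

    (mus', gamma) alone do not pin down a phase function; following common
    practice the anisotropy is fixed (default g1 = 0.9) and g2 is derived
    from gamma.
    """
    return solve_params_from_moments(family, MomentSet.from_gamma(gamma, g1))
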