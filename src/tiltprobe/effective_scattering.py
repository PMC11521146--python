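"""Effective (multiply-scattered) phase functions and the Ws weights.

After ``s`` scattering events the angular distribution of a photon's
direction relative to its initial direction — the *effective* phase
function — tends to isotropy.  Its Legendre moments decay geometrically,

    g_{n,s} = g_n ** s,

because Legendre moments multiply under composition of independent
rotations.  Two phase functions sharing (g1, g2) but differing in higher
moments therefore converge onto each other as ``s`` grows; the integrated
absolute difference between the s-scattered MHG and MPC effective
densities,

    W_s = ∫ |p_MHG(g1^s, g2^s, mu) - p_MPC(g1^s, g2^s, mu)| d(mu),

quantifies how much the moments above order 2 can still influence a
photon that has scattered ``s`` times.  W_s is the per-order ingredient of
the detector criterion F = sum_s p_s W_s (see :mod:`tiltprobe.criterion`).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import eval_legendre

from .phase_functions import (
    InfeasibleMomentsError,
    MomentSet,
    PhaseFunction,
    analytic_moments,
    sample_cos_theta,
    solve_params_from_moments,
)

__all__ = [
    "compose_cosines",
    "effective_samples",
    "effective_pdf_mc",
    "moment_decay",
    "mean_square_decay",
    "EffectiveMoments",
    "ws_weight",
    "WsTable",
    "ws_table",
]


def compose_cosines(mu1, mu2, phi):
    """Cosine of the angle between the initial direction and the direction
    after a further deflection.

    ``mu1`` is the cosine accumulated so far, ``mu2`` the cosine of the new
    polar deflection and ``phi`` its azimuth relative to the previous
    scattering plane:

        cos(theta_n) = cos(theta_1) cos(theta_2)
                       + sin(theta_1) sin(theta_2) cos(phi).

    The result is clipped to [-1, 1] against floating-point rounding.
    """
    mu1 = np.asarray(mu1, dtype=float)
    mu2 = np.asarray(mu2, dtype=float)
    s1 = np.sqrt(np.clip(1.0 - mu1 * mu1, 0.0, None))
    s2 = np.sqrt(np.clip(1.0 - mu2 * mu2, 0.0, None))
    return np.clip(mu1 * mu2 + s1 * s2 * np.cos(phi), -1.0, 1.0)


def effective_samples(
    spec: PhaseFunction, s: int, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Monte Carlo samples of the s-scattered effective deflection cosine.

    The composition is iterated: the accumulated cosine is combined with a
    fresh single-scattering cosine and a uniform azimuth at each of the
    ``s - 1`` subsequent events.
    """
    if s < 1:
        raise ValueError("s must be >= 1")
    mu = sample_cos_theta(spec, rng, n_samples)
    for _ in range(s - 1):
        mu2 = sample_cos_theta(spec, rng, n_samples)
        phi = rng.uniform(0.0, 2.0 * np.pi, n_samples)
        mu = compose_cosines(mu, mu2, phi)
    return mu


def effective_pdf_mc(
    spec: PhaseFunction,
    s: int,
    n_samples: int,
    rng: np.random.Generator,
    bins: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram estimate (density per unit cosine) of the s-scattered
    effective phase function.  Returns ``(bin_edges, density)``."""
    mu = effective_samples(spec, s, n_samples, rng)
    hist, edges = np.histogram(mu, bins=bins, range=(-1.0, 1.0), density=True)
    return edges, hist


@dataclasses.dataclass(frozen=True)
class EffectiveMoments:
    """Legendre moments of the effective phase function at order ``s``."""

    s: int
    moments: np.ndarray


def moment_decay(g_initial, s: int) -> EffectiveMoments:
    """Analytic decay law ``g_{n,s} = g_n ** s``.

    ``s = 0`` is the identity (all moments 1, i.e. a forward delta —
    no scattering has occurred).
    """
    if s < 0:
        raise ValueError("s must be >= 0")
    g = np.atleast_1d(np.asarray(g_initial, dtype=float))
    if np.any(np.abs(g) > 1.0):
        raise ValueError("|g_n| must be <= 1")
    return EffectiveMoments(s, g**s)


def mean_square_decay(cos2_mean: float, s: int) -> float:
    """Decay of the raw second moment <cos^2 theta> with scattering order.

    With g2 = (3 <cos^2> - 1)/2 this is <cos^2>_s = 1/3 + (2/3) g2^s,
    reaching the isotropic value 1/3 as s -> infinity.
    """
    if s < 0:
        raise ValueError("s must be >= 0")
    g2 = (3.0 * cos2_mean - 1.0) / 2.0
    return 1.0 / 3.0 + (2.0 / 3.0) * g2**s


# ---------------------------------------------------------------------------
# Ws weights
# ---------------------------------------------------------------------------

_QUAD_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _quad(n_quad: int) -> tuple[np.ndarray, np.ndarray]:
    if n_quad not in _QUAD_CACHE:
        _QUAD_CACHE[n_quad] = leggauss(n_quad)
    return _QUAD_CACHE[n_quad]


def _ws_area(pair: MomentSet, s: int, n_quad: int) -> float:
    decayed = pair.decayed(s)
    mhg = solve_params_from_moments("mhg", decayed)
    mpc = solve_params_from_moments("mpc", decayed)
    nodes, weights = _quad(n_quad)
    return float(weights @ np.abs(mhg.pdf(nodes) - mpc.pdf(nodes)))


def _ws_series(
    pair: MomentSet, s: int, n_quad: int, tail_tol: float = 1e-8
) -> float:
    mhg = solve_params_from_moments("mhg", pair)
    mpc = solve_params_from_moments("mpc", pair)
    # choose the truncation order so the geometric tail of the series is
    # negligible: |g_n| <= r**n with r the slowest-decaying moment ratio,
    # and the term magnitude is bounded by (2n+1)/2 |g_n|**s
    r_mpc = (mpc.n_pc - 1.0) / (mpc.n_pc + 3.0) if mpc.n_pc > 1.0 else 0.0
    r = min(max(mhg.g, r_mpc, 0.3), 1.0 - 1e-9)
    n_max = 8
    while n_max < 4096 and (n_max + 0.5) * r ** (s * n_max) > tail_tol:
        n_max *= 2
    d = (analytic_moments(mhg, n_max) ** s) - (analytic_moments(mpc, n_max) ** s)
    nodes, weights = _quad(n_quad)
    acc = np.zeros_like(nodes)
    for n in range(3, n_max + 1):
        # per-cosine Legendre series: p(mu) = sum (2n+1)/2 g_n P_n(mu)
        acc += (2.0 * n + 1.0) / 2.0 * d[n - 1] * eval_legendre(n, nodes)
    return float(weights @ np.abs(acc))


def ws_weight(
    pair: MomentSet, s: int, n_quad: int = 512, force_branch: str | None = None
) -> tuple[float, str]:
    """Residual higher-order-moment weight W_s for a matched MHG/MPC pair.

    Both families are re-solved at the decayed moments (g1^s, g2^s) and the
    absolute density difference integrated (the convention-free area form).
    If the decayed moments fall outside a family's representable region the
    truncated Legendre-series form — built from the original families'
    analytic moments raised to the power s — is used instead.

    Returns ``(value, branch)`` with branch in {"area", "series"}.
    """
    if s < 1:
        raise ValueError("s must be >= 1")
    if force_branch not in (None, "area", "series"):
        raise ValueError("force_branch must be None, 'area' or 'series'")
    if force_branch != "series":
        try:
            return _ws_area(pair, s, n_quad), "area"
        except InfeasibleMomentsError:
            if force_branch == "area":
                raise
    return _ws_series(pair, s, n_quad), "series"


@dataclasses.dataclass(frozen=True)
class WsTable:
    """W_s tabulated for s = 1..s_max, with the moment pair it refers to.

    ``ws[0]`` corresponds to s = 1.  Orders beyond ``s_max`` contribute
    W_s ~ 0 and are treated as zero by consumers.
    """

    moments: MomentSet
    ws: np.ndarray
    branches: tuple[str, ...]

    @property
    def s_max(self) -> int:
        return len(self.ws)

    def value(self, s) -> np.ndarray:
        """W_s for integer order(s) ``s``; 0 beyond the table."""
        s = np.asarray(s, dtype=int)
        out = np.zeros(s.shape, dtype=float)
        ok = (s >= 1) & (s <= self.s_max)
        out[ok] = self.ws[s[ok] - 1]
        return out

    def to_text(self, path) -> None:
        """Two-column delimited export (s, Ws)."""
        data = np.column_stack([np.arange(1, self.s_max + 1), self.ws])
        header = (
            f"Ws table for g1={self.moments.g1:.6g} g2={self.moments.g2:.6g} "
            f"(gamma={self.moments.gamma:.6g})\ns\tWs"
        )
        np.savetxt(path, data, fmt=("%d", "%.8e"), delimiter="\t", header=header)


def ws_table(
    pair: MomentSet,
    tol: float = 1e-4,
    s_cap: int = 300,
    n_quad: int = 512,
) -> WsTable:
    """Tabulate W_s from s = 1 up to the first order with W_s < ``tol``
    (capped at ``s_cap``); beyond that the criterion contributions are
    negligible at the 10% validity threshold."""
    ws: list[float] = []
    branches: list[str] = []
    for s in range(1, s_cap + 1):
        w, branch = ws_weight(pair, s, n_quad=n_quad)
        ws.append(w)
        branches.append(branch)
        if w < tol:
            break
    return WsTable(pair, np.asarray(ws), tuple(branches))
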