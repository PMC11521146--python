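"""Monte Carlo photon transport for a semi-infinite turbid medium probed by
tilted optical fibers.

Model summary
-------------
Photon packets start with weight 1 on the source-fiber footprint (a circle
on the surface z = 0), directed uniformly within the in-tissue acceptance
cone of half-angle ``asin(NA / n_in)`` about the tilted fiber axis.
Steps are sampled from the scattering mean free path (``-ln(xi)/mu_s``);
deflection cosines come from the medium's single-scattering phase function
with uniform azimuth.  Absorption is applied as continuous Beer–Lambert
weight attenuation ``exp(-mu_a * L)`` along the path — there are no
discrete absorption events, so the per-photon scattering count ``s``
counts scattering only.  The surface is a uniform tissue–air Fresnel
boundary (unpolarized coefficients, total internal reflection included).
Detection depends on the fiber–tissue coupling mode: with index-matched
faces (default) the tilt acts un-refracted in the tissue and a photon is
collected when it reaches a detector footprint with its *internal*
direction inside the acceptance cone, before any boundary lottery; with
air coupling the axis refracts at the surface and acceptance is tested on
the refracted external direction of transmitted photons.  Photons are
terminated unbiasedly by Russian roulette once their weight falls below
1e-4 (survival 0.1), or cut off by generous geometric caps that only
matter in zero-absorption runs.

For fully perpendicular layouts the tally uses ring-averaged
(arc-fraction) scoring — the azimuthal symmetry makes a detector's
expected signal equal to the exit-ring arc fraction covered by its
footprint times the rotation-invariant cone test — which cuts the
variance by one to two orders of magnitude.  Tilted layouts use direct
footprint detection.

Coordinates: z >= 0 into the tissue, source footprint centred at the
origin, detectors along +x, all lengths in mm.  Both fibers tilt in the
x–z plane toward each other ("opposite directions"): the source beam
leans toward +x, a detector accepts photons exiting up-and-toward +x.

Tallies per detector: collected weight fraction (reflectance) with a
batch-means standard error, the weighted distribution ``p_s`` of the
number of scattering events of collected photons, and a weighted histogram
of the depths (z) of their scattering events from which the ``zv80``
sampling-depth quantile derives.  Optionally, per-photon path lengths are
recorded so a single ``mu_a = 0`` run can be reweighted to any absorption
coefficient (the look-up-table shortcut).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .phase_functions import (
    HenyeyGreenstein,
    ModifiedHenyeyGreenstein,
    ModifiedPowerOfCosines,
    PhaseFunction,
    analytic_moments,
    spec_for_gamma,
)

__all__ = [
    "Medium",
    "FiberSpec",
    "ProbeLayout",
    "DetectionTally",
    "propagate",
    "launch_photons",
    "detect",
    "sampling_depth_zv80",
    "reflectance_uncertainty",
    "reweight_reflectance",
]

# termination constants (see module docstring)
_W_MIN = 1e-4
_P_SURVIVE = 0.1
_Z_CAP = 12.0  # mm
_R_CAP = 30.0  # mm
_S_CAP = 30000
_DBUF = 16384  # per-photon scattering-depth buffer

DEPTH_BIN = 0.01  # mm, resolves zv80 well below the 0.1 mm design grid
N_DEPTH_BINS = 600  # 6 mm range; deeper events land in the last bin
N_S_BINS = 3000  # scattering-count histogram; higher orders share last bin


@dataclasses.dataclass(frozen=True)
class Medium:
    """Semi-infinite homogeneous medium (half-space z >= 0).

    ``mu_s``/``mu_a`` in 1/mm; ``phase`` is the single-scattering phase
    function; ``n_in`` the tissue refractive index (1.43 is the usual
    soft-tissue assumption) and ``n_out`` the external index (air).
    """

    mu_s: float
    mu_a: float
    phase: PhaseFunction
    n_in: float = 1.43
    n_out: float = 1.0

    def __post_init__(self) -> None:
        if not self.mu_s > 0:
            raise ValueError("mu_s must be > 0")
        if self.mu_a < 0:
            raise ValueError("mu_a must be >= 0")
        if self.n_in < 1.0 or self.n_out < 1.0:
            raise ValueError("refractive indices must be >= 1")

    @property
    def g1(self) -> float:
        return float(analytic_moments(self.phase, 1)[0])

    @property
    def mus_prime(self) -> float:
        """Reduced scattering coefficient mu_s (1 - g1), 1/mm."""
        return self.mu_s * (1.0 - self.g1)

    @classmethod
    def from_reduced(
        cls,
        mus_prime: float,
        gamma: float,
        mu_a: float,
        family: str = "mhg",
        g1: float = 0.9,
        n_in: float = 1.43,
        n_out: float = 1.0,
    ) -> "Medium":
        """Build a medium from the intrinsic optical properties
        (mus', gamma, mu_a), disaggregating with a fixed anisotropy g1."""
        phase = spec_for_gamma(family, gamma, g1)
        return cls(mus_prime / (1.0 - g1), mu_a, phase, n_in, n_out)


@dataclasses.dataclass(frozen=True)
class FiberSpec:
    """One fiber: core diameter (mm), numerical aperture, tilt from the
    surface normal (degrees) in the source–detector plane."""

    diameter: float = 0.1
    na: float = 0.4
    tilt_deg: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tilt_deg < 90.0:
            raise ValueError("tilt must lie in [0, 90) degrees")
        if not 0.0 < self.na:
            raise ValueError("numerical aperture must be positive")
        if not self.diameter > 0:
            raise ValueError("fiber diameter must be positive")


@dataclasses.dataclass(frozen=True)
class ProbeLayout:
    """Source fiber at the origin plus detector fibers at separations rho.

    ``detectors`` is a sequence of (rho_mm, FiberSpec).  The paper-default
    constructor :meth:`linear` tilts source and detectors by the same
    angle in opposite directions (toward each other).
    """

    source: FiberSpec
    detectors: tuple

    def __post_init__(self) -> None:
        rhos = [r for r, _ in self.detectors]
        if len(rhos) == 0:
            raise ValueError("layout needs at least one detector")
        if any(r <= 0 for r in rhos):
            raise ValueError("all detector separations must be > 0")
        specs = [f for _, f in self.detectors]
        for i in range(len(rhos)):
            for j in range(i + 1, len(rhos)):
                if (
                    abs(rhos[i] - rhos[j])
                    < (specs[i].diameter + specs[j].diameter) / 2 - 1e-9
                ):
                    raise ValueError(
                        f"detector footprints at rho={rhos[i]} and rho={rhos[j]} "
                        "overlap"
                    )

    @property
    def rhos(self) -> np.ndarray:
        return np.array([r for r, _ in self.detectors], dtype=float)

    @classmethod
    def linear(
        cls,
        rhos: Sequence[float],
        tilt_deg: float = 0.0,
        diameter: float = 0.1,
        na: float = 0.4,
    ) -> "ProbeLayout":
        src = FiberSpec(diameter, na, tilt_deg)
        det = FiberSpec(diameter, na, tilt_deg)
        return cls(src, tuple((float(r), det) for r in rhos))

    def subset(self, indices: Sequence[int]) -> "ProbeLayout":
        return ProbeLayout(self.source, tuple(self.detectors[i] for i in indices))


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------


_U11 = np.uint64(11)
_U17 = np.uint64(17)
_U23 = np.uint64(23)
_U26 = np.uint64(26)
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(inline="always")
def _rng_u(state):
    """xorshift128+ uniform in [0, 1); state is a 2-element uint64 array."""
    x = state[0]
    y = state[1]
    state[0] = y
    x ^= x << _U23
    x ^= x >> _U17
    x ^= y ^ (y >> _U26)
    state[1] = x
    return float((x + y) >> _U11) * _INV53


@njit(cache=True)
def _seed_state(seed):
    """splitmix64 expansion of a 32-bit seed into the xorshift state."""
    state = np.empty(2, dtype=np.uint64)
    z = np.uint64(seed)
    for i in range(2):
        z += np.uint64(0x9E3779B97F4A7C15)
        t = z
        t = (t ^ (t >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        t = (t ^ (t >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        state[i] = t ^ (t >> np.uint64(31))
    return state


@njit(inline="always")
def _sample_mu(fam, alpha, shape, state):
    if _rng_u(state) < alpha:
        if fam == 2:  # power of cosines
            return 2.0 * _rng_u(state) ** (1.0 / (shape + 1.0)) - 1.0
        g = shape
        if g < 1e-12:
            return 2.0 * _rng_u(state) - 1.0
        t = (1.0 - g * g) / (1.0 - g + 2.0 * g * _rng_u(state))
        return (1.0 + g * g - t * t) / (2.0 * g)
    # (3/2) mu^2 admixture
    return np.cbrt(2.0 * _rng_u(state) - 1.0)


@njit(cache=True, fastmath=True)
def _transport_kernel(
    seed,
    n_photons,
    n_batches,
    mu_s,
    mu_a,
    n_rel,  # n_in / n_out
    fam,
    alpha,
    shape,
    src_r,
    sax_x,
    sax_z,  # source axis in tissue (y = 0)
    cos_cone_src,
    det_x,
    det_r,
    dax_x,
    dax_z,  # detector external axes (y = 0)
    cos_acc,
    symmetric,  # ring-averaged scoring (valid only for untilted layouts)
    matched,  # index-matched fiber faces (in-tissue acceptance)
    z_bin,
    n_zbins,
    n_sbins,
    record,
    rec_cap,
):
    state = _seed_state(seed)
    nd = det_x.shape[0]
    refl = np.zeros(nd)
    batch = np.zeros((n_batches, nd))
    ps = np.zeros((nd, n_sbins))
    psc = np.zeros((nd, n_sbins))  # raw-count (unweighted) variant
    depth = np.zeros((nd, n_zbins))
    ndet = np.zeros(nd, dtype=np.int64)
    # conservation channels: exited, absorbed, cap-killed, roulette net
    cons = np.zeros(4)
    rec_det = np.empty(rec_cap, dtype=np.int32)
    rec_len = np.empty(rec_cap, dtype=np.float64)
    rec_w = np.empty(rec_cap, dtype=np.float64)
    rec_s = np.empty(rec_cap, dtype=np.int32)
    n_rec = 0
    rec_overflow = False

    zbuf = np.empty(_DBUF)
    inv_zbin = 1.0 / z_bin
    inv_mu_s = 1.0 / mu_s
    # absorption is deterministic in path length, so the roulette trigger
    # is a precomputed path-length threshold instead of a per-step weight
    # update: w = wr * exp(-mu_a * L) < _W_MIN  <=>  L > l_thresh
    if mu_a > 0.0:
        l_thresh0 = math.log(1.0 / _W_MIN) / mu_a
        dl_boost = math.log(1.0 / _P_SURVIVE) / mu_a
    else:
        l_thresh0 = 1e300
        dl_boost = 0.0
    # orthonormal frame around the source axis (axis x z-hat)
    if sax_x > 1e-12:
        e1x, e1y, e1z = 0.0, -1.0, 0.0
        e2x, e2y, e2z = sax_z, 0.0, -sax_x
    else:
        e1x, e1y, e1z = 1.0, 0.0, 0.0
        e2x, e2y, e2z = 0.0, 1.0, 0.0

    for i in range(n_photons):
        # --- launch ---
        rr = src_r * math.sqrt(_rng_u(state))
        ang = 2.0 * math.pi * _rng_u(state)
        x = rr * math.cos(ang)
        y = rr * math.sin(ang)
        z = 0.0
        cb = 1.0 - _rng_u(state) * (1.0 - cos_cone_src)
        sb = math.sqrt(max(0.0, 1.0 - cb * cb))
        ph = 2.0 * math.pi * _rng_u(state)
        cp = math.cos(ph)
        sp = math.sin(ph)
        ux = cb * sax_x + sb * (cp * e1x + sp * e2x)
        uy = sb * (cp * e1y + sp * e2y)
        uz = cb * sax_z + sb * (cp * e1z + sp * e2z)

        wr = 1.0  # roulette multiplier; physical weight = wr*exp(-mu_a*L)
        created = 0.0  # weight created by roulette survivals (bookkeeping)
        removed = 0.0  # weight leaving by exit / roulette death / caps
        path_len = 0.0
        l_thresh = l_thresh0
        s = 0
        alive = True
        while alive:
            t = -math.log(1.0 - _rng_u(state)) * inv_mu_s
            while t > 0.0:
                if uz < 0.0:
                    d = -z / uz
                    if d <= t:
                        # advance to the surface
                        x += ux * d
                        y += uy * d
                        z = 0.0
                        path_len += d
                        t -= d
                        if matched:
                            # index-matched fiber faces: detection happens on
                            # the internal direction at the footprint, before
                            # the boundary lottery
                            if symmetric:
                                r_exit = math.sqrt(x * x + y * y)
                                scored = False
                                for j in range(nd):
                                    if -uz < cos_acc[j]:
                                        continue
                                    if abs(r_exit - det_x[j]) > det_r[j]:
                                        continue
                                    arg = (
                                        r_exit * r_exit
                                        + det_x[j] * det_x[j]
                                        - det_r[j] * det_r[j]
                                    ) / (2.0 * r_exit * det_x[j])
                                    if arg > 1.0:
                                        arg = 1.0
                                    elif arg < -1.0:
                                        arg = -1.0
                                    w = wr * math.exp(-mu_a * path_len)
                                    wd = w * math.acos(arg) / math.pi
                                    b = i * n_batches // n_photons
                                    refl[j] += wd
                                    batch[b, j] += wd
                                    ndet[j] += 1
                                    si = s if s < n_sbins else n_sbins - 1
                                    ps[j, si] += wd
                                    psc[j, si] += math.acos(arg) / math.pi
                                    m = s if s < _DBUF else _DBUF
                                    for k in range(m):
                                        idx = int(zbuf[k] * inv_zbin)
                                        if idx >= n_zbins:
                                            idx = n_zbins - 1
                                        depth[j, idx] += wd
                                    if record:
                                        if n_rec < rec_cap:
                                            rec_det[n_rec] = j
                                            rec_len[n_rec] = path_len
                                            rec_w[n_rec] = wd
                                            rec_s[n_rec] = s
                                            n_rec += 1
                                        else:
                                            rec_overflow = True
                                # scored photons continue through the normal
                                # boundary lottery (expected-value scoring)
                            else:
                                det = -1
                                for j in range(nd):
                                    dx = x - det_x[j]
                                    if dx * dx + y * y <= det_r[j] * det_r[j]:
                                        if (
                                            ux * dax_x[j] + uz * dax_z[j]
                                            >= cos_acc[j]
                                        ):
                                            det = j
                                        break  # footprints are disjoint
                                if det >= 0:
                                    w = wr * math.exp(-mu_a * path_len)
                                    cons[0] += w
                                    removed += w
                                    b = i * n_batches // n_photons
                                    refl[det] += w
                                    batch[b, det] += w
                                    ndet[det] += 1
                                    si = s if s < n_sbins else n_sbins - 1
                                    ps[det, si] += w
                                    psc[det, si] += 1.0
                                    m = s if s < _DBUF else _DBUF
                                    for k in range(m):
                                        idx = int(zbuf[k] * inv_zbin)
                                        if idx >= n_zbins:
                                            idx = n_zbins - 1
                                        depth[det, idx] += w
                                    if record:
                                        if n_rec < rec_cap:
                                            rec_det[n_rec] = det
                                            rec_len[n_rec] = path_len
                                            rec_w[n_rec] = w
                                            rec_s[n_rec] = s
                                            n_rec += 1
                                        else:
                                            rec_overflow = True
                                    alive = False
                                    break
                        cosi = -uz
                        sint = n_rel * math.sqrt(max(0.0, 1.0 - cosi * cosi))
                        if sint >= 1.0:
                            uz = -uz  # total internal reflection
                            continue
                        cost = math.sqrt(1.0 - sint * sint)
                        rs = (n_rel * cosi - cost) / (n_rel * cosi + cost)
                        rp = (n_rel * cost - cosi) / (n_rel * cost + cosi)
                        refl_prob = 0.5 * (rs * rs + rp * rp)
                        if _rng_u(state) < refl_prob:
                            uz = -uz
                            continue
                        # transmission: external direction (Snell)
                        uxe = ux * n_rel
                        uze = -cost
                        w = wr * math.exp(-mu_a * path_len)
                        cons[0] += w
                        removed += w
                        b = i * n_batches // n_photons
                        if matched:
                            pass  # matched-mode detection happened pre-lottery
                        elif symmetric:
                            # ring-averaged scoring: for an azimuthally
                            # symmetric layout a detector expected signal
                            # is the arc fraction of the exit ring covered
                            # by its footprint, times the (rotation-
                            # invariant) cone acceptance
                            r_exit = math.sqrt(x * x + y * y)
                            for j in range(nd):
                                if -uze < cos_acc[j]:
                                    continue
                                if abs(r_exit - det_x[j]) > det_r[j]:
                                    continue
                                arg = (
                                    r_exit * r_exit
                                    + det_x[j] * det_x[j]
                                    - det_r[j] * det_r[j]
                                ) / (2.0 * r_exit * det_x[j])
                                if arg > 1.0:
                                    arg = 1.0
                                elif arg < -1.0:
                                    arg = -1.0
                                wd = w * math.acos(arg) / math.pi
                                refl[j] += wd
                                batch[b, j] += wd
                                ndet[j] += 1
                                si = s if s < n_sbins else n_sbins - 1
                                ps[j, si] += wd
                                psc[j, si] += math.acos(arg) / math.pi
                                m = s if s < _DBUF else _DBUF
                                for k in range(m):
                                    idx = int(zbuf[k] * inv_zbin)
                                    if idx >= n_zbins:
                                        idx = n_zbins - 1
                                    depth[j, idx] += wd
                                if record:
                                    if n_rec < rec_cap:
                                        rec_det[n_rec] = j
                                        rec_len[n_rec] = path_len
                                        rec_w[n_rec] = wd
                                        rec_s[n_rec] = s
                                        n_rec += 1
                                    else:
                                        rec_overflow = True
                        else:
                            det = -1
                            for j in range(nd):
                                dx = x - det_x[j]
                                if dx * dx + y * y <= det_r[j] * det_r[j]:
                                    if uxe * dax_x[j] + uze * dax_z[j] >= cos_acc[j]:
                                        det = j
                                    break  # footprints are disjoint
                            if det >= 0:
                                refl[det] += w
                                batch[b, det] += w
                                ndet[det] += 1
                                si = s if s < n_sbins else n_sbins - 1
                                ps[det, si] += w
                                psc[det, si] += 1.0
                                m = s if s < _DBUF else _DBUF
                                for k in range(m):
                                    idx = int(zbuf[k] * inv_zbin)
                                    if idx >= n_zbins:
                                        idx = n_zbins - 1
                                    depth[det, idx] += w
                                if record:
                                    if n_rec < rec_cap:
                                        rec_det[n_rec] = det
                                        rec_len[n_rec] = path_len
                                        rec_w[n_rec] = w
                                        rec_s[n_rec] = s
                                        n_rec += 1
                                    else:
                                        rec_overflow = True
                        alive = False
                        break
                # free propagation over the remaining step
                x += ux * t
                y += uy * t
                z += uz * t
                path_len += t
                t = 0.0
            if not alive:
                break
            # --- scattering event ---
            if s < _DBUF:
                zbuf[s] = z
            s += 1
            mu = _sample_mu(fam, alpha, shape, state)
            sint = math.sqrt(max(0.0, 1.0 - mu * mu))
            # Marsaglia polar draw of the azimuth (cos, sin without trig)
            while True:
                aa = 2.0 * _rng_u(state) - 1.0
                bb = 2.0 * _rng_u(state) - 1.0
                mm = aa * aa + bb * bb
                if 1e-12 < mm < 1.0:
                    break
            cp = (aa * aa - bb * bb) / mm
            sp = 2.0 * aa * bb / mm
            if abs(uz) > 0.99999:
                ux = sint * cp
                uy = sint * sp
                uz = mu if uz > 0.0 else -mu
            else:
                tmp = math.sqrt(1.0 - uz * uz)
                nx = sint * (ux * uz * cp - uy * sp) / tmp + ux * mu
                ny = sint * (uy * uz * cp + ux * sp) / tmp + uy * mu
                nz = -sint * cp * tmp + uz * mu
                ux, uy, uz = nx, ny, nz
            # geometric caps (matter only when mu_a = 0)
            if z > _Z_CAP or x * x + y * y > _R_CAP * _R_CAP or s >= _S_CAP:
                w = wr * math.exp(-mu_a * path_len)
                cons[2] += w
                removed += w
                break
            # Russian roulette on the physical weight
            if path_len > l_thresh:
                w = wr * math.exp(-mu_a * path_len)
                if _rng_u(state) < _P_SURVIVE:
                    gain = w * (1.0 / _P_SURVIVE - 1.0)
                    cons[3] -= gain
                    created += gain
                    wr /= _P_SURVIVE
                    l_thresh += dl_boost
                else:
                    cons[3] += w
                    removed += w
                    break
        # weight balance of this photon: whatever was neither removed nor
        # still pending was absorbed along the path
        cons[1] += 1.0 + created - removed

    return (
        refl,
        batch,
        ps,
        psc,
        depth,
        ndet,
        cons,
        rec_det[:n_rec],
        rec_len[:n_rec],
        rec_w[:n_rec],
        rec_s[:n_rec],
        rec_overflow,
    )


# ---------------------------------------------------------------------------
# wrappers
# ---------------------------------------------------------------------------


def _phase_params(phase: PhaseFunction) -> tuple[int, float, float]:
    if isinstance(phase, HenyeyGreenstein):
        return 0, 1.0, phase.g
    if isinstance(phase, ModifiedHenyeyGreenstein):
        return 1, phase.alpha, phase.g
    if isinstance(phase, ModifiedPowerOfCosines):
        return 2, phase.alpha, phase.n_pc
    raise TypeError(f"unsupported phase function {type(phase).__name__}")


def _source_axis(
    layout: ProbeLayout, medium: Medium, coupling: str
) -> tuple[float, float, float]:
    """In-tissue source axis (x, z components) and launch-cone cosine.

    With index-matched coupling the fiber axis continues un-refracted into
    the tissue; with air coupling it refracts toward the normal.  In both
    cases the in-tissue cone half-angle is asin(NA / n_in).
    """
    src = layout.source
    sin_tilt = math.sin(math.radians(src.tilt_deg))
    sin_in = sin_tilt if coupling == "matched" else sin_tilt * medium.n_out / medium.n_in
    ax = sin_in
    az = math.sqrt(1.0 - sin_in * sin_in)
    if src.na >= medium.n_in:
        raise ValueError("source NA must be below the tissue index")
    cos_cone = math.sqrt(1.0 - (src.na / medium.n_in) ** 2)
    return ax, az, cos_cone


def _detector_arrays(layout: ProbeLayout, medium: Medium, coupling: str):
    nd = len(layout.detectors)
    det_x = np.empty(nd)
    det_r = np.empty(nd)
    dax_x = np.empty(nd)
    dax_z = np.empty(nd)
    cos_acc = np.empty(nd)
    for j, (rho, f) in enumerate(layout.detectors):
        det_x[j] = rho
        det_r[j] = f.diameter / 2.0
        # detector tilted opposite to the source: accepts photons exiting
        # up-and-toward +x
        tilt = math.radians(f.tilt_deg)
        dax_x[j] = math.sin(tilt)
        dax_z[j] = -math.cos(tilt)
        if coupling == "matched":
            # acceptance on the internal direction at the footprint
            if f.na >= medium.n_in:
                raise ValueError("detector NA must be below the tissue index")
            cos_acc[j] = math.sqrt(1.0 - (f.na / medium.n_in) ** 2)
        else:
            # acceptance on the refracted external direction
            if f.na >= medium.n_out:
                raise ValueError("detector NA must be below the external index")
            cos_acc[j] = math.sqrt(1.0 - (f.na / medium.n_out) ** 2)
    return det_x, det_r, dax_x, dax_z, cos_acc


@dataclasses.dataclass
class DetectionTally:
    """Per-detector tallies of one transport run."""

    rhos: np.ndarray
    n_photons: int
    n_batches: int
    reflectance: np.ndarray  # collected weight fraction per detector
    reflectance_se: np.ndarray  # batch-means standard error
    ps: np.ndarray  # (n_det, N_S_BINS) detected weight per scattering count
    ps_counts: np.ndarray  # unweighted variant of ps (sensitivity analysis)
    depth_hist: np.ndarray  # (n_det, N_DEPTH_BINS) weighted event depths
    depth_bin: float
    n_detected: np.ndarray
    conservation: dict
    seed: int
    records: Optional[dict] = None

    def ps_pdf(self, det: int) -> np.ndarray:
        """Normalized weight distribution over the scattering count s for
        one detector (index 0 corresponds to s = 0 and is always empty)."""
        total = self.ps[det].sum()
        if total <= 0:
            raise ValueError(f"detector {det} collected no photons")
        return self.ps[det] / total


def propagate(
    medium: Medium,
    layout: ProbeLayout,
    n_photons: int,
    seed: int,
    n_batches: int = 10,
    record_paths: bool = False,
    coupling: str = "matched",
) -> DetectionTally:
    """Run the transport simulation and return per-detector tallies.

    ``seed`` fully determines the photon stream: identical arguments give
    byte-identical tallies.  With ``record_paths`` the per-photon path
    lengths of detected photons are kept so the run can be reweighted to
    other absorption coefficients (see :func:`reweight_reflectance`).

    ``coupling`` selects the fiber–tissue interface model: "matched"
    (default) treats the fiber face as index-matched to the tissue, so the
    tilt acts un-refracted in-tissue and detection is decided on the
    internal direction at the footprint; "air" refracts the axis at the
    surface and accepts on the refracted external direction after the
    Fresnel lottery.  The boundary outside detection events is uniform
    tissue–air Fresnel in both modes.
    """
    if n_photons < 1:
        raise ValueError("n_photons must be >= 1")
    if n_batches < 1 or n_batches > n_photons:
        raise ValueError("n_batches must lie in [1, n_photons]")
    if coupling not in ("matched", "air"):
        raise ValueError("coupling must be 'matched' or 'air'")
    fam, alpha, shape = _phase_params(medium.phase)
    sax_x, sax_z, cos_cone = _source_axis(layout, medium, coupling)
    det_x, det_r, dax_x, dax_z, cos_acc = _detector_arrays(layout, medium, coupling)
    # ring-averaged scoring is an exact expectation identity only when the
    # whole layout is azimuthally symmetric (every fiber untilted)
    symmetric = layout.source.tilt_deg == 0.0 and all(
        f.tilt_deg == 0.0 for _, f in layout.detectors
    )
    rec_cap = max(1024, 2 * n_photons) if record_paths else 1
    out = _transport_kernel(
        np.uint32(seed & 0x7FFFFFFF),
        n_photons,
        n_batches,
        medium.mu_s,
        medium.mu_a,
        medium.n_in / medium.n_out,
        fam,
        alpha,
        shape,
        layout.source.diameter / 2.0,
        sax_x,
        sax_z,
        cos_cone,
        det_x,
        det_r,
        dax_x,
        dax_z,
        cos_acc,
        symmetric,
        coupling == "matched",
        DEPTH_BIN,
        N_DEPTH_BINS,
        N_S_BINS,
        record_paths,
        rec_cap,
    )
    (refl, batch, ps, psc, depth, ndet, cons, rdet, rlen, rw, rs, roverflow) = out
    batch_size = n_photons / n_batches
    batch_means = batch / batch_size
    se = batch_means.std(axis=0, ddof=1) / math.sqrt(n_batches) if n_batches > 1 else np.full(len(det_x), np.nan)
    records = None
    if record_paths:
        records = {
            "det": np.asarray(rdet),
            "path_len": np.asarray(rlen),
            "weight": np.asarray(rw),
            "s": np.asarray(rs),
            "overflow": bool(roverflow),
        }
    return DetectionTally(
        rhos=layout.rhos,
        n_photons=n_photons,
        n_batches=n_batches,
        reflectance=refl / n_photons,
        reflectance_se=se,
        ps=ps,
        ps_counts=psc,
        depth_hist=depth,
        depth_bin=DEPTH_BIN,
        n_detected=ndet,
        conservation={
            "exited": cons[0] / n_photons,
            "absorbed": cons[1] / n_photons,
            "cap_killed": cons[2] / n_photons,
            "roulette_net": cons[3] / n_photons,
        },
        seed=seed,
        records=records,
    )


def launch_photons(
    layout: ProbeLayout,
    medium: Medium,
    n: int,
    rng: np.random.Generator,
    coupling: str = "matched",
):
    """Sample launch positions and in-tissue directions (reference
    implementation of the kernel's launch step, for validation)."""
    src = layout.source
    r = src.diameter / 2.0 * np.sqrt(rng.random(n))
    ang = rng.uniform(0, 2 * np.pi, n)
    pos = np.column_stack([r * np.cos(ang), r * np.sin(ang), np.zeros(n)])
    ax, az, cos_cone = _source_axis(layout, medium, coupling)
    cb = 1.0 - rng.random(n) * (1.0 - cos_cone)
    sb = np.sqrt(1.0 - cb**2)
    ph = rng.uniform(0, 2 * np.pi, n)
    if ax > 1e-12:
        e1 = np.array([0.0, -1.0, 0.0])
        e2 = np.array([az, 0.0, -ax])
    else:
        e1 = np.array([1.0, 0.0, 0.0])
        e2 = np.array([0.0, 1.0, 0.0])
    axis = np.array([ax, 0.0, az])
    dirs = (
        cb[:, None] * axis
        + (sb * np.cos(ph))[:, None] * e1
        + (sb * np.sin(ph))[:, None] * e2
    )
    return pos, dirs


def detect(
    exit_position,
    exit_direction,
    layout: ProbeLayout,
    coupling: str = "matched",
    n_in: float = 1.43,
    n_out: float = 1.0,
):
    """Detector index collecting a photon reaching ``exit_position`` on
    z = 0 with upward-going unit direction ``exit_direction``; None if no
    detector collects it.

    In "matched" coupling the direction is the internal one at the
    footprint and the acceptance half-angle is asin(NA/n_in) about the
    un-refracted tilted axis; in "air" coupling the direction is the
    refracted external one with half-angle asin(NA/n_out).
    """
    x, y, _ = exit_position
    ux, uy, uz = exit_direction
    if uz >= 0:
        raise ValueError("exit direction must point out of the tissue (uz < 0)")
    n_ref = n_in if coupling == "matched" else n_out
    for j, (rho, f) in enumerate(layout.detectors):
        if (x - rho) ** 2 + y**2 <= (f.diameter / 2.0) ** 2:
            tilt = math.radians(f.tilt_deg)
            axis = (math.sin(tilt), 0.0, -math.cos(tilt))
            cos_acc = math.sqrt(1.0 - (f.na / n_ref) ** 2)
            if ux * axis[0] + uy * axis[1] + uz * axis[2] >= cos_acc:
                return j
            return None  # inside a footprint but outside the cone
    return None


def sampling_depth_zv80(
    tally: DetectionTally, det: int, fraction: float = 0.8
) -> float:
    """Depth (mm) above which the given fraction (default 80%) of the
    weighted scattering events of the detector's collected photons occur,
    with linear interpolation inside the containing bin."""
    hist = tally.depth_hist[det]
    total = hist.sum()
    if total <= 0:
        raise ValueError(f"detector {det} has no recorded scattering events")
    target = fraction * total
    cum = np.cumsum(hist)
    idx = int(np.searchsorted(cum, target))
    below = cum[idx - 1] if idx > 0 else 0.0
    frac_in_bin = (target - below) / hist[idx]
    return (idx + frac_in_bin) * tally.depth_bin


def reflectance_uncertainty(tally: DetectionTally) -> np.ndarray:
    """Relative standard error of the reflectance per detector, from batch
    means.  Detectors with no signal are flagged as NaN."""
    if tally.n_batches < 2:
        raise ValueError("uncertainty requires the run partitioned into batches")
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = tally.reflectance_se / tally.reflectance
    rel[tally.reflectance <= 0] = np.nan
    return rel


def reweight_reflectance(tally: DetectionTally, mu_a: float, mu_a_run: float = 0.0):
    """Reflectance at absorption ``mu_a`` from a run performed at
    ``mu_a_run`` (default 0), via Beer–Lambert reweighting of the recorded
    per-photon path lengths.  Returns (reflectance, standard_error)."""
    if tally.records is None:
        raise ValueError("run must be performed with record_paths=True")
    if tally.records["overflow"]:
        raise ValueError("path records overflowed; rerun with fewer photons")
    nd = len(tally.rhos)
    det = tally.records["det"]
    w = tally.records["weight"] * np.exp(
        -(mu_a - mu_a_run) * tally.records["path_len"]
    )
    refl = np.zeros(nd)
    se = np.zeros(nd)
    n = tally.n_photons
    for j in range(nd):
        wj = w[det == j]
        refl[j] = wj.sum() / n
        # photon-level SE of the mean (zero weights for undetected photons)
        se[j] = math.sqrt(max((wj**2).sum() / n - refl[j] ** 2, 0.0) / n)
    return refl, se
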