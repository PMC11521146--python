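"""The scattering-order criterion F and the minimum source–detector
separation.

For each detector, F is the detected-weight distribution of scattering
counts ``p_s`` contracted with the per-order weights ``W_s``:

    F = sum_s p_s W_s.

F estimates the relative contribution of phase-function Legendre moments
above order 2 to the detected reflectance: photons that scattered few
times still carry higher-moment information (large W_s), photons that
scattered many times have an essentially isotropic effective phase
function (W_s ~ 0).  F <= 0.1 marks the separations where the
second-order (mus', gamma) description of the reflectance is valid — the
calibration being that the reflectance error from neglected higher
moments then stays below 10%.  The smallest such separation on the probe
grid is rho_min.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .effective_scattering import WsTable, ws_table
from .phase_functions import MomentSet, analytic_moments
from .transport import DetectionTally, Medium, ProbeLayout, propagate

__all__ = [
    "f_value",
    "f_curve",
    "CriterionCurve",
    "find_rho_min",
    "ws_table_for_medium",
]

DEFAULT_THRESHOLD = 0.1


def ws_table_for_medium(medium: Medium, **kwargs) -> WsTable:
    """Ws table for the (g1, g2) pair of the medium's phase function."""
    g1, g2 = analytic_moments(medium.phase, 2)
    return ws_table(MomentSet(float(g1), float(g2)), **kwargs)


def f_value(
    tally: DetectionTally, ws: WsTable, det: int, weighted: bool = True
) -> float:
    """Criterion F for one detector.

    ``p_s`` is the detected-weight distribution of scattering counts by
    default; ``weighted=False`` switches to raw detection counts (kept for
    sensitivity analysis; the weighted form is what multiplies a weighted
    reflectance estimator consistently).  Orders beyond the Ws table
    contribute zero.
    """
    hist = tally.ps[det] if weighted else tally.ps_counts[det]
    total = hist.sum()
    if total <= 0:
        raise ValueError(f"detector {det} collected no photons")
    ps = hist / total
    s_idx = np.arange(len(ps))
    return float(ps @ ws.value(s_idx))


def f_curve(tally: DetectionTally, ws: WsTable) -> np.ndarray:
    """F for every detector of a run (NaN where nothing was collected)."""
    out = np.full(len(tally.rhos), np.nan)
    for j in range(len(tally.rhos)):
        if tally.ps[j].sum() > 0:
            out[j] = f_value(tally, ws, j)
    return out


@dataclasses.dataclass(frozen=True)
class CriterionCurve:
    """F versus source–detector separation, with the selected rho_min."""

    rhos: np.ndarray
    f: np.ndarray
    threshold: float
    rho_min: Optional[float]  # None when no grid point satisfies F <= threshold

    def passes(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.f <= self.threshold


def find_rho_min(
    medium: Medium,
    rho_grid: Sequence[float],
    tilt_deg: float = 0.0,
    n_photons: int = 10**6,
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
    ws: Optional[WsTable] = None,
    coupling: str = "matched",
    fiber_diameter: float = 0.1,
    fiber_na: float = 0.4,
    tally_out: Optional[list] = None,
) -> CriterionCurve:
    """Smallest separation on ``rho_grid`` whose criterion F falls at or
    below ``threshold``, from a single multi-detector transport run.

    The Ws table defaults to the medium's own phase-function moments.  The
    full F-vs-rho curve is returned alongside rho_min; if ``tally_out`` is
    given the underlying :class:`DetectionTally` is appended to it (the
    same run also provides ps and depth histograms per detector).
    """
    rho_grid = np.asarray(sorted(rho_grid), dtype=float)
    layout = ProbeLayout.linear(
        rho_grid, tilt_deg=tilt_deg, diameter=fiber_diameter, na=fiber_na
    )
    tally = propagate(medium, layout, n_photons, seed, coupling=coupling)
    if tally_out is not None:
        tally_out.append(tally)
    if ws is None:
        ws = ws_table_for_medium(medium)
    f = f_curve(tally, ws)
    ok = np.where(f <= threshold)[0]
    rho_min = float(rho_grid[ok[0]]) if len(ok) else None
    return CriterionCurve(rho_grid, f, threshold, rho_min)
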