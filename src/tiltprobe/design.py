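"""Three-step probe-design workflow.

Given a target medium (worst-case intrinsic optical properties) and a
fiber tilt angle, the workflow

1. finds the minimum source–detector separation rho_min from the
   scattering-order criterion F (F <= 0.1 marks the subdiffusive-validity
   range),
2. finds the maximum separation rho_max from the noise-robustness of the
   LUT inverse solver (detectors every 0.1 mm from rho_min outward; the
   smallest extent whose mean estimation error under 10% measurement
   noise is at most 10%),
3. evaluates the probe's sampling depth zv80 at rho_max — the fiber at
   the largest separation samples deepest and thus defines the probe's
   sampled volume.

The limiting-case design input (case #2: mus' = 1/mm, gamma = 1.9,
mu_a = 0.2/mm) represents realistic tissue properties that demand the
largest rho_min, so a probe designed for it stays subdiffusive-valid for
more benign tissues.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional, Sequence

import numpy as np

from .criterion import CriterionCurve, find_rho_min, ws_table_for_medium
from .inversion import (
    LUT,
    RobustnessResult,
    build_lut,
    robustness_experiment,
)
from .transport import Medium, sampling_depth_zv80

__all__ = [
    "CASE1",
    "CASE2",
    "limiting_case_scenario",
    "DesignReport",
    "run_design",
]

#: IOPs typical of biological tissue in the visible range (mus' 1/mm,
#: gamma, mu_a 1/mm)
CASE1 = {"mus_prime": 2.0, "gamma": 1.5, "mua": 0.2}
#: limiting-case IOPs requiring the largest rho_min
CASE2 = {"mus_prime": 1.0, "gamma": 1.9, "mua": 0.2}


def limiting_case_scenario(
    family: str = "mhg", g1: float = 0.9, n_in: float = 1.43, n_out: float = 1.0
) -> Medium:
    """The case #2 limiting-case medium used as default design input."""
    return Medium.from_reduced(
        CASE2["mus_prime"], CASE2["gamma"], CASE2["mua"], family, g1, n_in, n_out
    )


@dataclasses.dataclass
class DesignReport:
    """Outcome of the three-step design for one tilt angle."""

    mus_prime: float
    gamma: float
    mua: float
    tilt_deg: float
    coupling: str
    rho_min: Optional[float]
    rho_max: Optional[float]
    zv80_at_rho_max: Optional[float]  # mm
    f_curve: CriterionCurve
    robustness: Optional[RobustnessResult]
    seeds: dict
    budgets: dict
    complete: bool

    def to_dict(self) -> dict:
        d = {
            "medium": {
                "mus_prime": self.mus_prime,
                "gamma": self.gamma,
                "mua": self.mua,
            },
            "tilt_deg": self.tilt_deg,
            "coupling": self.coupling,
            "rho_min_mm": self.rho_min,
            "rho_max_mm": self.rho_max,
            "zv80_at_rho_max_mm": self.zv80_at_rho_max,
            "f_curve": {
                "rho_mm": self.f_curve.rhos.tolist(),
                "f": self.f_curve.f.tolist(),
                "threshold": self.f_curve.threshold,
            },
            "seeds": self.seeds,
            "budgets": self.budgets,
            "complete": self.complete,
        }
        if self.robustness is not None:
            d["robustness"] = {
                "rho_max_grid_mm": self.robustness.rho_max_grid.tolist(),
                "mean_error": self.robustness.mean_error.tolist(),
                "se_error": self.robustness.se_error.tolist(),
                "noise_frac": self.robustness.noise_frac,
                "n_reps": self.robustness.n_reps,
                "error_tol": self.robustness.error_tol,
            }
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def run_design(
    medium: Medium,
    tilt_deg: float = 0.0,
    rho_grid: Sequence[float] = None,
    n_photons_criterion: int = 2 * 10**6,
    n_photons_truth: int = 2 * 10**6,
    lut_photons_per_node: int = 10**5,
    lut_grids: Optional[dict] = None,
    seed: int = 0,
    threshold: float = 0.1,
    noise_frac: float = 0.10,
    n_reps: int = 10,
    error_tol: float = 0.10,
    coupling: str = "matched",
    lut: Optional[LUT] = None,
) -> DesignReport:
    """Execute the three-step design procedure for one tilt angle.

    A single multi-detector criterion run yields the F curve, ps and depth
    histograms for every grid separation; the robustness step builds (or
    reuses) a LUT for the same layout and corrupts an independently seeded
    truth reflectance.  Missing results propagate: if no separation
    satisfies the criterion, or no extent meets the error tolerance, the
    report is returned partially filled with ``complete=False``.
    """
    if rho_grid is None:
        rho_grid = np.round(np.arange(0.1, 2.001, 0.1), 10)
    rho_grid = np.asarray(rho_grid, dtype=float)
    ss = np.random.SeedSequence(seed)
    s_crit, s_lut, s_noise = (int(x) for x in ss.generate_state(3) & 0x7FFFFFFF)
    seeds = {"master": seed, "criterion": s_crit, "lut": s_lut, "noise": s_noise}
    budgets = {
        "n_photons_criterion": n_photons_criterion,
        "lut_photons_per_node": lut_photons_per_node,
        "n_reps": n_reps,
    }

    ws = ws_table_for_medium(medium)
    tallies: list = []
    curve = find_rho_min(
        medium,
        rho_grid,
        tilt_deg=tilt_deg,
        n_photons=n_photons_criterion,
        seed=s_crit,
        threshold=threshold,
        ws=ws,
        coupling=coupling,
        tally_out=tallies,
    )
    tally = tallies[0]
    report = DesignReport(
        mus_prime=medium.mus_prime,
        gamma=_gamma_of(medium),
        mua=medium.mu_a,
        tilt_deg=tilt_deg,
        coupling=coupling,
        rho_min=curve.rho_min,
        rho_max=None,
        zv80_at_rho_max=None,
        f_curve=curve,
        robustness=None,
        seeds=seeds,
        budgets=budgets,
        complete=False,
    )
    if curve.rho_min is None:
        return report

    if lut is None:
        from .transport import ProbeLayout

        layout = ProbeLayout.linear(rho_grid, tilt_deg=tilt_deg)
        lut = build_lut(
            layout,
            n_photons=lut_photons_per_node,
            seed=s_lut,
            n_in=medium.n_in,
            n_out=medium.n_out,
            coupling=coupling,
        )
    # independently seeded truth reflectance: the criterion run doubles as
    # the truth run (its seed is independent of the LUT's)
    truth_iops = (medium.mus_prime, _gamma_of(medium), medium.mu_a)
    rob = robustness_experiment(
        lut,
        tally.reflectance,
        truth_iops,
        curve.rho_min,
        noise_frac=noise_frac,
        n_reps=n_reps,
        error_tol=error_tol,
        rng=np.random.default_rng(s_noise),
    )
    report.robustness = rob
    report.rho_max = rob.rho_max
    if rob.rho_max is None:
        return report

    det_at_rho_max = int(np.argmin(np.abs(tally.rhos - rob.rho_max)))
    report.zv80_at_rho_max = float(sampling_depth_zv80(tally, det_at_rho_max))
    report.complete = True
    return report


def _gamma_of(medium: Medium) -> float:
    g1, g2 = medium.phase.moments(2)
    return float((1.0 - g2) / (1.0 - g1))
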