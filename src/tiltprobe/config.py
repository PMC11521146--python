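"""Run configuration: YAML schema, validation, hashing and fixtures.

A run configuration bundles the medium (intrinsic optical properties or
raw coefficients), the probe layout, the photon budgets and the master
seed.  All physical quantities are in mm / 1/mm / degrees.  The config
hash stamps every output for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json

import numpy as np
import yaml

from .transport import Medium, ProbeLayout

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "config_hash",
    "make_fixtures",
    "CASE_PRESETS",
]

CASE_PRESETS = {
    "case1": {"mus_prime": 2.0, "gamma": 1.5, "mua": 0.2},
    "case2": {"mus_prime": 1.0, "gamma": 1.9, "mua": 0.2},
}

_ALLOWED_TOP = {"medium", "layout", "run", "profile"}
_ALLOWED_MEDIUM = {
    "preset",
    "mus_prime",
    "gamma",
    "mua",
    "family",
    "g1",
    "n_in",
    "n_out",
}
_ALLOWED_LAYOUT = {
    "tilt_deg",
    "rhos",
    "rho_start",
    "rho_stop",
    "rho_step",
    "diameter",
    "na",
    "coupling",
}
_ALLOWED_RUN = {"photons", "batches", "seed", "threshold"}


class ConfigError(ValueError):
    """Raised with the full list of schema violations."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated run configuration."""

    mus_prime: float
    gamma: float
    mua: float
    family: str
    g1: float
    n_in: float
    n_out: float
    tilt_deg: float
    rhos: tuple
    diameter: float
    na: float
    coupling: str
    photons: int
    batches: int
    seed: int
    threshold: float
    profile: str

    def medium(self) -> Medium:
        return Medium.from_reduced(
            self.mus_prime,
            self.gamma,
            self.mua,
            self.family,
            self.g1,
            self.n_in,
            self.n_out,
        )

    def layout(self) -> ProbeLayout:
        return ProbeLayout.linear(
            self.rhos, tilt_deg=self.tilt_deg, diameter=self.diameter, na=self.na
        )

    def to_dict(self) -> dict:
        return {
            "medium": {
                "mus_prime": self.mus_prime,
                "gamma": self.gamma,
                "mua": self.mua,
                "family": self.family,
                "g1": self.g1,
                "n_in": self.n_in,
                "n_out": self.n_out,
            },
            "layout": {
                "tilt_deg": self.tilt_deg,
                "rhos": list(self.rhos),
                "diameter": self.diameter,
                "na": self.na,
                "coupling": self.coupling,
            },
            "run": {
                "photons": self.photons,
                "batches": self.batches,
                "seed": self.seed,
                "threshold": self.threshold,
            },
            "profile": self.profile,
        }

    def dump(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


def config_hash(d: dict) -> str:
    """Short reproducible hash of a configuration dictionary."""
    return hashlib.sha256(
        json.dumps(d, sort_keys=True, default=float).encode()
    ).hexdigest()[:12]


def _parse(raw: dict) -> RunConfig:
    errors = []
    if not isinstance(raw, dict):
        raise ConfigError(["config root must be a mapping"])
    for key in raw:
        if key not in _ALLOWED_TOP:
            errors.append(f"unknown top-level key {key!r}")
    med = raw.get("medium", {}) or {}
    lay = raw.get("layout", {}) or {}
    run = raw.get("run", {}) or {}
    for key in med:
        if key not in _ALLOWED_MEDIUM:
            errors.append(f"unknown medium key {key!r}")
    for key in lay:
        if key not in _ALLOWED_LAYOUT:
            errors.append(f"unknown layout key {key!r}")
    for key in run:
        if key not in _ALLOWED_RUN:
            errors.append(f"unknown run key {key!r}")

    preset = med.get("preset")
    base = dict(CASE_PRESETS.get(preset, {})) if preset else {}
    if preset and preset not in CASE_PRESETS:
        errors.append(f"unknown medium preset {preset!r}")
    mus_prime = float(med.get("mus_prime", base.get("mus_prime", 2.0)))
    gamma = float(med.get("gamma", base.get("gamma", 1.5)))
    mua = float(med.get("mua", base.get("mua", 0.2)))
    family = str(med.get("family", "mhg"))
    g1 = float(med.get("g1", 0.9))
    n_in = float(med.get("n_in", 1.43))
    n_out = float(med.get("n_out", 1.0))
    if mus_prime <= 0:
        errors.append(f"medium.mus_prime must be > 0 mm^-1, got {mus_prime}")
    if mua < 0:
        errors.append(f"medium.mua must be >= 0 mm^-1, got {mua}")
    if family not in ("mhg", "mpc", "hg"):
        errors.append(f"medium.family must be hg, mhg or mpc, got {family!r}")
    if not 0.0 < g1 < 1.0:
        errors.append(f"medium.g1 must lie in (0, 1), got {g1}")
    if n_in < 1.0 or n_out < 1.0:
        errors.append("refractive indices must be >= 1")

    tilt_deg = float(lay.get("tilt_deg", 0.0))
    if not 0.0 <= tilt_deg < 90.0:
        errors.append(f"layout.tilt_deg must lie in [0, 90) degrees, got {tilt_deg}")
    if "rhos" in lay:
        rhos = tuple(float(r) for r in lay["rhos"])
    else:
        start = float(lay.get("rho_start", 0.1))
        stop = float(lay.get("rho_stop", 2.0))
        step = float(lay.get("rho_step", 0.1))
        if step <= 0 or stop < start:
            errors.append("layout rho range must have step > 0 and stop >= start")
            rhos = ()
        else:
            rhos = tuple(np.round(np.arange(start, stop + step / 2, step), 10))
    if any(r <= 0 for r in rhos):
        errors.append("layout.rhos must all be > 0 mm")
    diameter = float(lay.get("diameter", 0.1))
    na = float(lay.get("na", 0.4))
    coupling = str(lay.get("coupling", "matched"))
    if diameter <= 0:
        errors.append(f"layout.diameter must be > 0 mm, got {diameter}")
    if na <= 0:
        errors.append(f"layout.na must be > 0, got {na}")
    if coupling not in ("matched", "air"):
        errors.append(f"layout.coupling must be 'matched' or 'air', got {coupling!r}")

    photons = int(run.get("photons", 10**6))
    batches = int(run.get("batches", 10))
    seed = int(run.get("seed", 0))
    threshold = float(run.get("threshold", 0.1))
    if photons < 1:
        errors.append(f"run.photons must be >= 1, got {photons}")
    if batches < 1:
        errors.append(f"run.batches must be >= 1, got {batches}")
    if not 0.0 < threshold <= 1.0:
        errors.append(f"run.threshold must lie in (0, 1], got {threshold}")

    profile = str(raw.get("profile", "desk"))
    if profile not in ("desk", "paper"):
        errors.append(f"profile must be 'desk' or 'paper', got {profile!r}")

    if errors:
        raise ConfigError(errors)
    return RunConfig(
        mus_prime,
        gamma,
        mua,
        family,
        g1,
        n_in,
        n_out,
        tilt_deg,
        rhos,
        diameter,
        na,
        coupling,
        photons,
        batches,
        seed,
        threshold,
        profile,
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; raises
    :class:`ConfigError` carrying every schema violation found."""
    with open(path) as f:
        raw = yaml.safe_load(f)
    return _parse(raw if raw is not None else {})


# ---------------------------------------------------------------------------
# deterministic fixtures for criterion / inversion tests without transport
# ---------------------------------------------------------------------------


def make_fixtures(seed: int = 0) -> dict:
    """Small deterministic synthetic fixtures: a scattering-count
    distribution, a 3-detector reflectance curve, and a 6x6x6 mini-LUT
    built from a smooth closed-form reflectance surrogate (monotone
    decreasing in mu_a, as any physical table must be).

    These are synthetic stand-ins shaped like transport outputs, intended
    for exercising the criterion and inversion plumbing quickly.
    """
    rng = np.random.default_rng(seed)
    s = np.arange(200)
    ps = np.zeros(200)
    ps[1:] = s[1:] ** 2 * np.exp(-s[1:] / 12.0)
    ps /= ps.sum()

    rhos = np.array([0.4, 0.5, 0.6])
    refl = 0.02 * np.exp(-2.2 * rhos) * (1.0 + 0.01 * rng.standard_normal(3))

    mus_grid = np.linspace(0.5, 3.0, 6)
    gamma_grid = np.linspace(1.2, 1.9, 6)
    mua_grid = np.linspace(0.0, 1.0, 6)
    # smooth surrogate: rises with mus', falls exponentially with mua and rho
    m, g, a, r = np.meshgrid(
        mus_grid, gamma_grid, mua_grid, rhos, indexing="ij", sparse=False
    )
    values = 0.01 * m**0.8 * (1.0 + 0.15 * (g - 1.5)) * np.exp(-(2.0 + 2.5 * a) * r)
    from .inversion import LUT

    lut = LUT(
        mus_grid,
        gamma_grid,
        mua_grid,
        rhos,
        values,
        np.zeros_like(values),
        np.ones((6, 6), dtype=bool),
        meta={"synthetic": True, "seed": seed},
    )
    return {"ps": ps, "rhos": rhos, "reflectance": refl, "mini_lut": lut}
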