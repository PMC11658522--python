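"""Monte Carlo estimate of the fiber-collected diffuse reflectance of bone.

The probe geometry is two parallel 400 um-core, NA 0.22 optical fibers
(source and collector) touching the top face of a homogeneous 3 x 3 x 3 mm
tissue volume, their axes 1.3 mm apart.  Photons are launched from the
source core, random-walked through the medium (exponential free paths with
mu_t = mu_a + mu_s, Henyey-Greenstein deflections with anisotropy g,
absorption handled by weight deposition with single-scatter albedo
mu_s / mu_t, Russian roulette below a weight threshold) and every photon
that re-emerges through the top face is tested against the collector's
core disc and acceptance cone.  The collected weight fraction R_tissue is
the quantity the device's photocurrent model consumes; bone values land
around 1e-4, i.e. 0.1-0.15 permille.

Conventions (see docs/methods.md for the reasoning):

* optical properties are given in cm^-1 (tissue-optics convention) and
  converted to mm^-1 internally; geometry is in mm;
* refractive indices are matched across the top face by default (no
  Fresnel reflection, no refraction) with n_tissue = n_external = 1, so the
  fiber launch/acceptance half-angle is asin(NA); this is the convention
  that reproduces the reference permille reflectances (an index-matched
  n = 1.4 cone, asin(NA/1.4), halves the collected solid angle and the
  collected fraction with it — both conventions are available through
  :class:`ProbeGeometry`).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _mc

__all__ = [
    "OpticalProperties",
    "ProbeGeometry",
    "MCConfig",
    "ReflectanceEstimate",
    "sample_hg_cosine",
    "launch_photon",
    "detect_collection",
    "propagate",
    "simulate_reflectance",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption / reduced-scattering / anisotropy triple, in cm^-1.

    ``mu_s_prime`` is the reduced scattering coefficient
    mu_s' = mu_s * (1 - g); the transport kernel uses the unreduced
    ``mu_s = mu_s' / (1 - g)``.
    """

    mu_a: float
    mu_s_prime: float
    g: float

    def __post_init__(self) -> None:
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s_prime < 0:
            raise ValueError(f"mu_s_prime must be >= 0, got {self.mu_s_prime}")
        if not -1 < self.g < 1:
            raise ValueError(f"g must lie in (-1, 1), got {self.g}")

    @property
    def mu_s(self) -> float:
        """Unreduced scattering coefficient mu_s' / (1 - g), cm^-1."""
        return self.mu_s_prime / (1.0 - self.g)


@dataclass(frozen=True)
class ProbeGeometry:
    """Probe and tissue-volume geometry, lengths in mm.

    The tissue occupies ``|x| <= volume[0]/2, |y| <= volume[1]/2,
    0 <= z <= volume[2]`` with the fibers on the z = 0 face: source axis at
    x = -sds/2, collector axis at x = +sds/2.
    """

    core_diameter: float = 0.4
    numerical_aperture: float = 0.22
    sds: float = 1.3
    volume: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_tissue: float = 1.0
    n_external: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.numerical_aperture < 1:
            raise ValueError("numerical_aperture must lie in (0, 1)")
        if min(self.core_diameter, self.sds, *self.volume) <= 0:
            raise ValueError("all lengths must be positive")
        if self.sds <= self.core_diameter:
            raise ValueError("fibers overlap: require sds > core_diameter")
        if self.n_tissue < 1 or self.n_external < 1:
            raise ValueError("refractive indices must be >= 1")

    @property
    def acceptance_cos(self) -> float:
        """Cosine of the in-tissue acceptance half-angle asin(NA/n_tissue)."""
        return math.cos(math.asin(self.numerical_aperture / self.n_tissue))

    @property
    def source_x(self) -> float:
        return -self.sds / 2.0

    @property
    def collector_x(self) -> float:
        return self.sds / 2.0


@dataclass(frozen=True)
class MCConfig:
    """Run-control knobs of the transport estimator (not physics)."""

    n_photons: int = 10_000_000
    rng_seed: int = 1
    roulette_threshold: float = 1e-4
    roulette_survival: float = 10.0
    max_path_steps: int = 1_000_000

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if not 0 < self.roulette_threshold < 1:
            raise ValueError("roulette_threshold must lie in (0, 1)")
        if self.roulette_survival < 2:
            raise ValueError("roulette_survival factor must be >= 2")
        if self.max_path_steps < 1:
            raise ValueError("max_path_steps must be >= 1")


@dataclass(frozen=True)
class ReflectanceEstimate:
    """Collected-fraction estimate with its Monte Carlo weight ledger.

    ``r_tissue`` is the collected weight fraction (dimensionless; multiply
    by 1000 for the permille figure the design tables use).  The ledger
    satisfies r_tissue + weight_absorbed + weight_escaped + residual_weight
    = 1 to within 1e-6 of the launched weight; ``residual_weight`` is the
    net of roulette terminations minus roulette survival bonuses.  A run
    with zero collected photons reports ``std_error = nan`` (unreliable).
    """

    r_tissue: float
    std_error: float
    n_collected: int
    weight_absorbed: float
    weight_escaped: float
    residual_weight: float
    n_photons: int
    rng_seed: int
    n_lost: int = 0

    @property
    def r_permille(self) -> float:
        return 1e3 * self.r_tissue

    @property
    def std_error_permille(self) -> float:
        return 1e3 * self.std_error

    def to_record(self, tissue: str | None = None,
                  wavelength_nm: int | None = None) -> dict:
        """JSON-serializable result record."""
        return {
            "tissue": tissue,
            "wavelength_nm": wavelength_nm,
            "r_tissue_permille": self.r_permille,
            "std_error_permille": self.std_error_permille,
            "n_collected": self.n_collected,
            "n_photons": self.n_photons,
            "seed": self.rng_seed,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_record(**kw))


def sample_hg_cosine(g: float, u: float) -> float:
    """Deflection cosine from the Henyey-Greenstein inverse CDF.

    For g = 0 the distribution is isotropic and the map reduces to
    cos(theta) = 2u - 1; for g != 0 the return is monotone in *u* with
    expectation g over uniform *u*.
    """
    if not -1 < g < 1:
        raise ValueError(f"g must lie in (-1, 1), got {g}")
    if not 0 <= u < 1:
        raise ValueError(f"u must lie in [0, 1), got {u}")
    return _mc.hg_cosine(g, u)


def launch_photon(geom: ProbeGeometry, rng: np.random.Generator):
    """Sample an initial photon state (position, direction, weight).

    Position is uniform over the source-fiber core disc on the top face;
    direction is uniform in solid angle within the acceptance cone of
    half-angle asin(NA / n_tissue) about the inward normal; weight is 1.
    """
    core_r = geom.core_diameter / 2.0
    r = core_r * math.sqrt(rng.random())
    phi = 2.0 * math.pi * rng.random()
    cos_min = geom.acceptance_cos
    cz = cos_min + (1.0 - cos_min) * rng.random()
    sz = math.sqrt(max(0.0, 1.0 - cz * cz))
    psi = 2.0 * math.pi * rng.random()
    pos = np.array([geom.source_x + r * math.cos(phi), r * math.sin(phi), 0.0])
    direction = np.array([sz * math.cos(psi), sz * math.sin(psi), cz])
    return pos, direction, 1.0


def detect_collection(exit_position, exit_direction, geom: ProbeGeometry) -> bool:
    """Collector aperture test for a photon leaving through the top face:
    within the core disc of the collection fiber *and* within its
    acceptance cone about the outward surface normal."""
    x, y, _ = exit_position
    uz = exit_direction[2]
    return bool(_mc.is_collected(float(x), float(y), float(uz),
                                 geom.collector_x, geom.core_diameter / 2.0,
                                 geom.acceptance_cos))


_EVENT_NAMES = {_mc.ABSORBED: "absorbed", _mc.ESCAPED: "escaped",
                _mc.COLLECTED: "collected", _mc.LOST: "lost"}


def propagate(props: OpticalProperties, geom: ProbeGeometry, cfg: MCConfig,
              photon) -> dict:
    """Track a single photon to its terminal event (seeded via *cfg*).

    *photon* is a (position, direction, weight) triple as produced by
    :func:`launch_photon`.  Returns a dict with the terminal ``event``
    ('collected' | 'escaped' | 'absorbed' | 'lost') and the per-bucket
    weights.  Mostly a unit-testing window into the compiled kernel; bulk
    runs go through :func:`simulate_reflectance`.
    """
    pos, direction, weight = photon
    if weight <= 0:
        raise ValueError("photon weight must be positive")
    hx, hy, depth = geom.volume[0] / 2, geom.volume[1] / 2, geom.volume[2]
    if abs(pos[0]) > hx or abs(pos[1]) > hy or not 0 <= pos[2] <= depth:
        raise ValueError("photon starts outside the tissue volume")
    mu_a_mm, mu_s_mm = props.mu_a / 10.0, props.mu_s / 10.0
    if mu_a_mm + mu_s_mm <= 0:
        raise ValueError("mu_a + mu_s must be positive to propagate")
    _mc.seed_kernel_rng(cfg.rng_seed % 2**31)
    ev, wc, wa, we, wt, bonus, n_steps = _mc.propagate_one(
        mu_a_mm, mu_s_mm, props.g, hx, hy, depth,
        geom.collector_x, geom.core_diameter / 2.0, geom.acceptance_cos,
        cfg.roulette_threshold, cfg.roulette_survival, cfg.max_path_steps,
        float(pos[0]), float(pos[1]), float(pos[2]),
        float(direction[0]), float(direction[1]), float(direction[2]),
        float(weight))
    return {"event": _EVENT_NAMES[ev], "collected": wc, "absorbed": wa,
            "escaped": we, "terminated": wt, "roulette_bonus": bonus,
            "n_steps": n_steps}


def simulate_reflectance(props: OpticalProperties,
                         geom: ProbeGeometry = ProbeGeometry(),
                         cfg: MCConfig = MCConfig()) -> ReflectanceEstimate:
    """Estimate the collected fraction R_tissue for one tissue/wavelength.

    Deterministic for a fixed ``cfg.rng_seed``.  The standard error is the
    sample standard deviation of the per-photon collected weight divided by
    sqrt(n_photons).  For the default bone properties R is about 1e-4, so
    at least ~1e6 photons are needed for the rule-of-thumb 100 expected
    collections; a smaller budget triggers a warning, and a run that
    collects nothing returns ``std_error = nan``.
    """
    if props.mu_a + props.mu_s <= 0:
        raise ValueError("mu_a + mu_s must be positive")
    if cfg.n_photons * 1e-4 < 100:
        warnings.warn(
            f"n_photons = {cfg.n_photons:g} expects fewer than 100 collected "
            "photons at bone-like reflectance (~1e-4); the estimate will be "
            "noisy", stacklevel=2)
    hx, hy, depth = geom.volume[0] / 2, geom.volume[1] / 2, geom.volume[2]
    coll_w, coll_w2, abs_w, esc_w, term_w, bonus_w, n_coll, n_lost = (
        _mc.run_ensemble(
            props.mu_a / 10.0, props.mu_s / 10.0, props.g,
            hx, hy, depth, geom.source_x, geom.collector_x,
            geom.core_diameter / 2.0, geom.acceptance_cos,
            cfg.roulette_threshold, cfg.roulette_survival,
            cfg.max_path_steps, cfg.n_photons, cfg.rng_seed % 2**31))
    n = cfg.n_photons
    m1 = coll_w / n
    var = max(0.0, coll_w2 / n - m1 * m1)
    se = math.sqrt(var / n) if n_coll > 0 else float("nan")
    return ReflectanceEstimate(
        r_tissue=m1,
        std_error=se,
        n_collected=n_coll,
        weight_absorbed=abs_w / n,
        weight_escaped=esc_w / n,
        residual_weight=(term_w - bonus_w) / n,
        n_photons=n,
        rng_seed=cfg.rng_seed,
        n_lost=n_lost,
    )
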