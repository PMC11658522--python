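"""Numba kernels for photon transport in a homogeneous turbid slab.

Everything here works in millimetres and mm^-1 and is compiled with numba.
The public, validated API lives in :mod:`osteosense.optics`.

Random numbers come from numba's internal Mersenne Twister; it is seeded
with :func:`seed_kernel_rng` (the seed must be applied *inside* an njit
function to reach numba's RNG state, not numpy's).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# terminal event codes
ABSORBED = 0      # weight fully deposited / killed by roulette
ESCAPED = 1       # left the volume uncollected
COLLECTED = 2     # exited the top face into the collection fiber's aperture
LOST = 3          # exceeded the step budget (counted separately, never silent)

_BIG = 1e30


@njit(cache=True)
def seed_kernel_rng(seed):
    np.random.seed(seed)


@njit(cache=True, fastmath=True)
def hg_cosine(g, u):
    """Inverse-CDF sample of the Henyey-Greenstein deflection cosine."""
    if g == 0.0:
        return 2.0 * u - 1.0
    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - t * t) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True, fastmath=True)
def _spin(ux, uy, uz, cos_t, psi):
    """Rotate a unit direction by deflection cosine cos_t and azimuth psi."""
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cos_p = np.cos(psi)
    sin_p = np.sin(psi)
    if abs(uz) > 0.99999:
        nx = sin_t * cos_p
        ny = sin_t * sin_p
        nz = cos_t * (1.0 if uz >= 0.0 else -1.0)
    else:
        den = np.sqrt(1.0 - uz * uz)
        nx = sin_t * (ux * uz * cos_p - uy * sin_p) / den + ux * cos_t
        ny = sin_t * (uy * uz * cos_p + ux * sin_p) / den + uy * cos_t
        nz = -sin_t * cos_p * den + uz * cos_t
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, fastmath=True)
def launch(src_x, core_r, cos_min):
    """Sample a photon start: uniform over the source-fiber core disc on the
    top face, direction uniform in solid angle within the acceptance cone
    (deflection cosine from the inward normal uniform in [cos_min, 1])."""
    r = core_r * np.sqrt(np.random.random())
    phi = 2.0 * np.pi * np.random.random()
    cz = cos_min + (1.0 - cos_min) * np.random.random()
    sz = np.sqrt(max(0.0, 1.0 - cz * cz))
    psi = 2.0 * np.pi * np.random.random()
    return (src_x + r * np.cos(phi), r * np.sin(phi), 0.0,
            sz * np.cos(psi), sz * np.sin(psi), cz)


@njit(cache=True, fastmath=True)
def is_collected(x, y, uz, det_x, core_r, cos_min):
    """Aperture test for a photon exiting the top face: inside the collector
    core disc and within the acceptance cone about the outward normal."""
    dx = x - det_x
    return (dx * dx + y * y <= core_r * core_r) and (-uz >= cos_min)


@njit(cache=True, fastmath=True)
def propagate_one(mu_a, mu_s, g,
                  half_x, half_y, depth,
                  det_x, core_r, cos_min,
                  w_threshold, m_survival, max_steps,
                  x, y, z, ux, uy, uz, w):
    """Track one photon to its terminal event.

    Returns (event, w_collected, w_absorbed, w_escaped, w_terminated,
    roulette_bonus, n_steps).  w_terminated holds weight destroyed by
    roulette or by the step budget; roulette_bonus holds weight created by
    roulette survival, so per photon

        w_launched + bonus == collected + absorbed + escaped + terminated

    to machine precision.
    """
    mu_t = mu_a + mu_s
    albedo = mu_s / mu_t
    w_abs = 0.0
    bonus = 0.0
    for step in range(max_steps):
        s = -np.log(1.0 - np.random.random()) / mu_t

        # distance to the nearest box face along the current direction
        t_exit = _BIG
        face_top = False
        if ux > 0.0:
            t = (half_x - x) / ux
            if t < t_exit:
                t_exit = t
        elif ux < 0.0:
            t = (-half_x - x) / ux
            if t < t_exit:
                t_exit = t
        if uy > 0.0:
            t = (half_y - y) / uy
            if t < t_exit:
                t_exit = t
        elif uy < 0.0:
            t = (-half_y - y) / uy
            if t < t_exit:
                t_exit = t
        if uz > 0.0:
            t = (depth - z) / uz
            if t < t_exit:
                t_exit = t
        elif uz < 0.0:
            t = (0.0 - z) / uz
            if t <= t_exit:
                t_exit = t
                face_top = True

        if s >= t_exit:
            # matched refractive indices: the photon leaves at the face
            x += ux * t_exit
            y += uy * t_exit
            if face_top and is_collected(x, y, uz, det_x, core_r, cos_min):
                return COLLECTED, w, w_abs, 0.0, 0.0, bonus, step
            return ESCAPED, 0.0, w_abs, w, 0.0, bonus, step

        x += ux * s
        y += uy * s
        z += uz * s

        # deposit the absorbed share, then scatter
        w_abs += w * (1.0 - albedo)
        w *= albedo
        cos_t = hg_cosine(g, np.random.random())
        psi = 2.0 * np.pi * np.random.random()
        ux, uy, uz = _spin(ux, uy, uz, cos_t, psi)

        if w < w_threshold:
            if np.random.random() * m_survival < 1.0:
                bonus += w * (m_survival - 1.0)
                w *= m_survival
            else:
                return ABSORBED, 0.0, w_abs, 0.0, w, bonus, step
    return LOST, 0.0, w_abs, 0.0, w, bonus, max_steps


@njit(cache=True, fastmath=True)
def run_ensemble(mu_a, mu_s, g,
                 half_x, half_y, depth,
                 src_x, det_x, core_r, cos_min,
                 w_threshold, m_survival, max_steps,
                 n_photons, seed):
    """Launch and track *n_photons*; return the weight ledger.

    Returns (coll_w, coll_w2, abs_w, esc_w, term_w, bonus_w, n_collected,
    n_lost) where coll_w2 accumulates squared per-photon collected weight
    for the binomial-style standard error.
    """
    np.random.seed(seed)
    coll_w = 0.0
    coll_w2 = 0.0
    abs_w = 0.0
    esc_w = 0.0
    term_w = 0.0
    bonus_w = 0.0
    n_coll = 0
    n_lost = 0
    for _ in range(n_photons):
        x, y, z, ux, uy, uz = launch(src_x, core_r, cos_min)
        ev, wc, wa, we, wt, bb, _ = propagate_one(
            mu_a, mu_s, g, half_x, half_y, depth,
            det_x, core_r, cos_min,
            w_threshold, m_survival, max_steps,
            x, y, z, ux, uy, uz, 1.0)
        coll_w += wc
        coll_w2 += wc * wc
        abs_w += wa
        esc_w += we
        term_w += wt
        bonus_w += bb
        if ev == COLLECTED:
            n_coll += 1
        elif ev == LOST:
            n_lost += 1
    return coll_w, coll_w2, abs_w, esc_w, term_w, bonus_w, n_coll, n_lost
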