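"""Photon-transport unit and property tests.

The Henyey-Greenstein sampler is checked against a numeric inversion of
the analytic CDF; the transport estimator is checked for weight
conservation, physical limits (no scattering, opaque absorber) and seeded
reproducibility.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.optimize import brentq

from conftest import BONE_CELLS, small_mc
from osteosense import MCConfig, OpticalProperties, ProbeGeometry
from osteosense.optics import (detect_collection, launch_photon, propagate,
                               sample_hg_cosine, simulate_reflectance)


def hg_cdf(c, g):
    """Analytic CDF of the HG deflection cosine, the independent oracle."""
    if g == 0:
        return (c + 1) / 2
    return (1 - g**2) / (2 * g) * (1 / math.sqrt(1 + g**2 - 2 * g * c)
                                   - 1 / (1 + g))


class TestHenyeyGreenstein:
    def test_isotropic_case_is_linear_map(self):
        assert sample_hg_cosine(0.0, 0.5) == pytest.approx(0.0)
        assert sample_hg_cosine(0.0, 0.0) == pytest.approx(-1.0)

    @pytest.mark.parametrize("g", [0.0, 0.5, 0.9])
    def test_sample_mean_equals_anisotropy(self, g, rng):
        n = 10**6
        u = rng.random(n)
        c = np.array([sample_hg_cosine(g, ui) for ui in u])
        se = c.std(ddof=1) / math.sqrt(n)
        assert abs(c.mean() - g) < 4 * se

    @pytest.mark.parametrize("g", [0.3, 0.9, -0.6])
    def test_matches_numeric_cdf_inversion(self, g):
        """Sampled quantiles agree with brentq inversion of the CDF."""
        for u in [1e-6, 0.1, 0.25, 0.5, 0.75, 0.9, 1 - 1e-6]:
            oracle = brentq(lambda c: hg_cdf(c, g) - u, -1, 1, xtol=1e-12)
            assert sample_hg_cosine(g, u) == pytest.approx(oracle, abs=1e-9)

    def test_monotone_in_u_and_bounded(self):
        u = np.linspace(0, 1 - 1e-9, 1001)
        c = np.array([sample_hg_cosine(0.9, ui) for ui in u])
        assert np.all(np.diff(c) >= 0)
        assert c.min() >= -1 and c.max() <= 1

    def test_isotropic_samples_uniform(self, rng):
        c = np.array([sample_hg_cosine(0.0, u) for u in rng.random(20000)])
        assert stats.kstest(c, stats.uniform(-1, 2).cdf).pvalue > 1e-3

    @given(g=st.floats(-0.99, 0.99), u=st.floats(0, 1, exclude_max=True))
    @settings(max_examples=200, deadline=None)
    def test_always_a_valid_cosine(self, g, u):
        assert -1.0 <= sample_hg_cosine(g, u) <= 1.0

    @pytest.mark.parametrize("g,u", [(1.0, 0.5), (-1.0, 0.5), (0.5, 1.0),
                                     (0.5, -0.1)])
    def test_rejects_out_of_range(self, g, u):
        with pytest.raises(ValueError):
            sample_hg_cosine(g, u)


class TestLaunch:
    def test_positions_within_core_and_cone(self, geom, rng):
        cos_min = geom.acceptance_cos
        for _ in range(10_000):
            pos, d, w = launch_photon(geom, rng)
            r = math.hypot(pos[0] - geom.source_x, pos[1])
            assert r <= geom.core_diameter / 2 + 1e-12
            assert pos[2] == 0.0 and w == 1.0
            assert d[2] >= cos_min - 1e-12
            assert np.linalg.norm(d) == pytest.approx(1.0)

    def test_vanishing_na_launches_along_normal(self, rng):
        geom = ProbeGeometry(numerical_aperture=1e-6)
        _, d, _ = launch_photon(geom, rng)
        assert d[2] == pytest.approx(1.0, abs=1e-9)


class TestDetection:
    def test_on_axis_normal_exit_is_collected(self, geom):
        assert detect_collection((geom.collector_x, 0.0, 0.0), (0, 0, -1.0),
                                 geom)

    def test_exit_at_source_fiber_is_not(self, geom):
        assert not detect_collection((geom.source_x, 0.0, 0.0), (0, 0, -1.0),
                                     geom)

    def test_exit_outside_acceptance_cone_is_not(self, geom):
        theta = math.asin(geom.numerical_aperture / geom.n_tissue) + 0.05
        d = (math.sin(theta), 0.0, -math.cos(theta))
        assert not detect_collection((geom.collector_x, 0.0, 0.0), d, geom)


class TestPropagation:
    def test_no_scattering_collects_nothing(self, geom):
        est = simulate_reflectance(OpticalProperties(1.0, 0.0, 0.0), geom,
                                   small_mc(50_000))
        assert est.r_tissue == 0.0
        assert math.isnan(est.std_error)

    def test_opaque_absorber_collects_nothing(self, geom):
        props = OpticalProperties(216.0, 28.6, 0.9)  # 1000x cancellous mu_a
        est = simulate_reflectance(props, geom, small_mc(50_000))
        assert est.r_permille < 1e-3
        assert est.weight_absorbed > 0.99

    @pytest.mark.parametrize("tissue,wl,props,_", BONE_CELLS,
                             ids=lambda v: str(v))
    def test_weight_conservation(self, geom, tissue, wl, props, _):
        est = simulate_reflectance(props, geom, small_mc(100_000))
        total = (est.r_tissue + est.weight_absorbed + est.weight_escaped
                 + est.residual_weight)
        assert abs(total - 1.0) < 1e-6

    def test_reflectance_nonincreasing_in_absorption(self, geom):
        base = BONE_CELLS[0][2]
        r = [simulate_reflectance(
                OpticalProperties(base.mu_a * f, base.mu_s_prime, base.g),
                geom, small_mc(200_000)).r_tissue
             for f in (1.0, 10.0, 100.0)]
        assert r[0] >= r[1] >= r[2]

    def test_seeded_runs_are_bit_identical(self, geom):
        props = BONE_CELLS[2][2]
        a = simulate_reflectance(props, geom, small_mc(50_000, seed=9))
        b = simulate_reflectance(props, geom, small_mc(50_000, seed=9))
        assert a == b

    def test_single_photon_propagate_events(self, geom, rng):
        # bone has near-unit albedo (escape dominates); a strong absorber
        # forces roulette terminations, exercising both event paths
        events = set()
        for props in (BONE_CELLS[0][2], OpticalProperties(50.0, 10.0, 0.5)):
            for seed in range(100):
                photon = launch_photon(geom, rng)
                out = propagate(props, geom,
                                MCConfig(n_photons=1, rng_seed=seed), photon)
                events.add(out["event"])
                ledger = (out["collected"] + out["absorbed"] + out["escaped"]
                          + out["terminated"] - out["roulette_bonus"])
                assert ledger == pytest.approx(1.0, abs=1e-9)
        assert "escaped" in events and "absorbed" in events

    def test_propagate_rejects_outside_start(self, geom):
        props = BONE_CELLS[0][2]
        with pytest.raises(ValueError):
            propagate(props, geom, small_mc(1), ((0, 0, -1.0), (0, 0, 1.0), 1.0))

    def test_low_budget_warns(self, geom):
        with pytest.warns(UserWarning, match="fewer than 100"):
            simulate_reflectance(BONE_CELLS[0][2], geom, small_mc(10_000))


class TestValidation:
    @pytest.mark.parametrize("kw", [dict(mu_a=-1.0, mu_s_prime=1, g=0),
                                    dict(mu_a=1, mu_s_prime=-1, g=0),
                                    dict(mu_a=1, mu_s_prime=1, g=1.0)])
    def test_optical_properties(self, kw):
        with pytest.raises(ValueError):
            OpticalProperties(**kw)

    def test_fibers_must_not_overlap(self):
        with pytest.raises(ValueError):
            ProbeGeometry(sds=0.3)

    def test_mc_config_guards(self):
        with pytest.raises(ValueError):
            MCConfig(n_photons=0)
        with pytest.raises(ValueError):
            MCConfig(roulette_survival=1.5)

    def test_mu_s_derivation(self):
        p = OpticalProperties(0.216, 28.6, 0.9)
        assert p.mu_s == pytest.approx(286.0)
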