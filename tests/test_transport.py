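"""Transport engine: single-step physics and whole-run invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import voxfluor as vf
from voxfluor.transport import (
    PhotonState,
    deposit,
    fresnel,
    roulette,
    sample_hg_cos,
    sample_step,
    spin,
)
from oracles import hg_mean_cos_numeric


def photon(w=1.0, d=(0, 0, 1)):
    return PhotonState(np.zeros(3), np.array(d, dtype=float), weight=w)


class TestSampleStep:
    @pytest.mark.parametrize("xi,mu_t,expect", [(math.exp(-1), 1.0, 1.0),
                                                (math.exp(-2), 4.0, 0.5)])
    def test_closed_form(self, xi, mu_t, expect):
        assert sample_step(xi, mu_t) == pytest.approx(expect)

    def test_mean_free_path(self, rng):
        s = np.array([sample_step(x, 10.0) for x in rng.random(100_000)])
        se = s.std(ddof=1) / math.sqrt(s.size)
        assert abs(s.mean() - 0.1) < 3 * se

    def test_vacuum_rejected(self):
        with pytest.raises(ValueError):
            sample_step(0.5, 0.0)


class TestDeposit:
    def test_arithmetic(self):
        p = photon()
        dw = deposit(p, vf.OpticalProperties(mu_a=1.0, mu_s=3.0, g=0.9, n=1.4))
        assert dw == pytest.approx(0.25)
        assert p.weight == pytest.approx(0.75)

    def test_vis_skin_values(self):
        p = photon(w=0.5)
        dw = deposit(p, vf.get_tissue_optics("skin", "VIS", "excitation"))
        assert dw == pytest.approx(0.5 * 6.0 / 631.0)

    def test_zero_absorption(self):
        p = photon()
        assert deposit(p, vf.OpticalProperties(0.0, 10.0, 0.9, 1.4)) == 0.0
        assert p.weight == 1.0


class TestSpin:
    def test_isotropic_mean_cos_zero(self, rng):
        ct = np.array([sample_hg_cos(0.0, u) for u in rng.random(200_000)])
        se = ct.std(ddof=1) / math.sqrt(ct.size)
        assert abs(ct.mean()) < 3 * se

    def test_hg_mean_cos_equals_g(self, rng):
        g = 0.9
        ct = np.array([sample_hg_cos(g, u) for u in rng.random(500_000)])
        se = ct.std(ddof=1) / math.sqrt(ct.size)
        assert abs(ct.mean() - g) < 3 * se
        # and the target itself agrees with quadrature over the HG density
        assert hg_mean_cos_numeric(g) == pytest.approx(g, abs=1e-6)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.floats(-0.99, 0.99), st.floats(0.001, 0.999), st.floats(0, 1),
           st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1))
    def test_output_always_unit(self, g, x1, x2, dx, dy, dz):
        v = np.array([dx, dy, dz])
        n = np.linalg.norm(v)
        if n < 1e-3:
            v = np.array([0.0, 0.0, 1.0]); n = 1.0
        out = spin(v / n, g, x1, x2)
        assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-9)

    def test_deflection_angle_matches_sampled_cos(self):
        d = np.array([0.0, 0.0, 1.0])
        out = spin(d, 0.9, 0.3, 0.77)
        assert float(out @ d) == pytest.approx(sample_hg_cos(0.9, 0.3), abs=1e-12)


class TestFresnel:
    def test_matched_media(self):
        R, ct = fresnel(1.4, 1.4, 0.6)
        assert R == 0.0 and ct == 0.6

    def test_air_skin_normal_incidence(self):
        R, _ = fresnel(1.0, 1.37, 1.0)
        assert R == pytest.approx((0.37 / 2.37) ** 2, abs=1e-12)

    def test_total_internal_reflection(self):
        crit = math.sqrt(1 - (1.0 / 1.45) ** 2)  # cos of critical angle
        R, _ = fresnel(1.45, 1.0, 0.9 * crit)
        assert R == 1.0

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.floats(1.0, 2.0), st.floats(1.0, 2.0), st.floats(0.01, 1.0))
    def test_reflectance_in_unit_interval_and_snell(self, n1, n2, ci):
        R, ct = fresnel(n1, n2, ci)
        assert 0.0 <= R <= 1.0
        if R < 1.0:
            si = math.sqrt(1 - ci * ci)
            assert n1 * si == pytest.approx(n2 * math.sqrt(1 - ct * ct), abs=1e-9)


class TestRoulette:
    def test_survival_and_death(self):
        p = photon(w=1e-5)
        delta = roulette(p, 10, 0.05)
        assert p.weight == pytest.approx(1e-4) and delta == pytest.approx(9e-5)
        p = photon(w=1e-5)
        delta = roulette(p, 10, 0.5)
        assert not p.alive and delta == pytest.approx(-1e-5)

    def test_unbiased(self, rng):
        w0, m, n = 1e-5, 10, 200_000
        out = np.where(rng.random(n) * m < 1.0, w0 * m, 0.0)
        se = out.std(ddof=1) / math.sqrt(n)
        assert abs(out.mean() - w0) < 3 * se


class TestEngine:
    def test_beer_lambert_pure_absorber(self, uniform_optics_factory):
        """Transmission through a matched-index pure absorber is e^(-mu_a L)."""
        mu_a, L = 1.0, 2.0
        vol = vf.generate_slab_phantom(L, shape=(30, 30, 42), voxel_size=0.05,
                                       air_layers=2)
        tab = uniform_optics_factory(mu_a, 0.0, 0.0, 1.0)
        n = 100_000
        fl = vf.run_excitation(vol, "NIR", vf.SourceConfig(kind="pencil"),
                               vf.SimConfig(n_photons=n, seed=11), optics=tab)
        p = math.exp(-mu_a * L)
        trans = (fl.ledger.escaped - fl.ledger.surface_escaped) / n
        se = math.sqrt(p * (1 - p) / n)
        assert abs(trans - p) < 3 * se

    def test_specular_launch_deduction(self, uniform_optics_factory):
        """With an opaque n=1.37 medium, escaped weight is exactly the
        specular Fresnel fraction, deducted deterministically at launch."""
        vol = vf.generate_slab_phantom(1.9, shape=(20, 20, 40), voxel_size=0.05)
        tab = uniform_optics_factory(1e4, 0.0, 0.0, 1.37)
        n = 2000
        fl = vf.run_excitation(vol, "NIR", vf.SourceConfig(kind="pencil"),
                               vf.SimConfig(n_photons=n, seed=5), optics=tab)
        r_spec = (0.37 / 2.37) ** 2
        assert fl.ledger.escaped / n == pytest.approx(r_spec, rel=1e-12)

    def test_ledger_closure_and_determinism(self, breast_phantom):
        runs = []
        for _ in range(2):
            fl = vf.run_excitation(breast_phantom, "SWIR", vf.SourceConfig(),
                                   vf.SimConfig(n_photons=5000, seed=42))
            assert fl.ledger.closure_residual <= 1e-9
            runs.append(fl)
        np.testing.assert_array_equal(runs[0].absorbed, runs[1].absorbed)
        np.testing.assert_array_equal(runs[0].surface_weight, runs[1].surface_weight)
        assert runs[0].ledger.as_dict() == runs[1].ledger.as_dict()

    def test_grid_refinement_consistency(self, uniform_optics_factory):
        """Halving the voxel size leaves absorbed/escaped fractions
        unchanged within Monte Carlo error."""
        tab = uniform_optics_factory(0.5, 20.0, 0.9, 1.4)
        n = 30_000
        fracs = []
        for h, shape in [(0.1, (40, 40, 42)), (0.05, (80, 80, 84))]:
            vol = vf.generate_slab_phantom(4.0, shape=shape, voxel_size=h,
                                           air_layers=2)
            fl = vf.run_excitation(vol, "NIR", vf.SourceConfig(kind="pencil"),
                                   vf.SimConfig(n_photons=n, seed=9),
                                   optics=tab, n_ambient=1.4)
            fracs.append(fl.ledger.absorbed / n)
        se = math.sqrt(fracs[0] * (1 - fracs[0]) / n)
        assert abs(fracs[0] - fracs[1]) < 3 * math.sqrt(2) * se

    def test_fluence_linearity_in_irradiance(self, breast_phantom):
        kw = dict(sim=vf.SimConfig(n_photons=3000, seed=3))
        a = vf.run_excitation(breast_phantom, "NIR",
                              vf.SourceConfig(irradiance=0.05), **kw)
        b = vf.run_excitation(breast_phantom, "NIR",
                              vf.SourceConfig(irradiance=0.10), **kw)
        np.testing.assert_allclose(b.fluence, 2.0 * a.fluence, rtol=1e-12)

    def test_single_voxel_absorption_sanity(self, uniform_optics_factory):
        """Pencil beam through a one-voxel-thick pure absorber: absorbed
        fraction is 1 - e^(-mu_a h)."""
        h, mu_a = 0.05, 8.0
        vol = vf.generate_slab_phantom(h, shape=(10, 10, 10), voxel_size=h)
        tab = uniform_optics_factory(mu_a, 0.0, 0.0, 1.0)
        n = 100_000
        fl = vf.run_excitation(vol, "NIR", vf.SourceConfig(kind="pencil"),
                               vf.SimConfig(n_photons=n, seed=21), optics=tab)
        p = 1 - math.exp(-mu_a * h)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(fl.ledger.absorbed / n - p) < 3 * se

    def test_zero_mu_a_tissue_rejected(self, uniform_optics_factory):
        vol = vf.generate_slab_phantom(1.0, shape=(10, 10, 24), voxel_size=0.05)
        tab = uniform_optics_factory(0.0, 10.0, 0.9, 1.4)
        with pytest.raises(ValueError, match="mu_a"):
            vf.run_excitation(vol, "NIR", vf.SourceConfig(kind="pencil"),
                              vf.SimConfig(n_photons=100, seed=1), optics=tab)
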