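"""Excitation-emission coupling: weights, launch statistics, full runs."""

import numpy as np
import pytest
from scipy import stats

import voxfluor as vf
from voxfluor import TissueLabel
from voxfluor.fluorescence import EmissionSource, launch_emission, emission_weight
from voxfluor.transport import FluenceVolume, Ledger


def make_excitation(shape=(12, 12, 12), h=0.05, fill=2.0, gradient_axis=None):
    """Hand-built excitation fluence volume for coupling tests."""
    phi = np.full(shape, fill)
    if gradient_axis is not None:
        ramp = np.linspace(2.0, 0.5, shape[gradient_axis])
        phi = phi * ramp.reshape([-1 if a == gradient_axis else 1 for a in range(3)])
    return FluenceVolume(phi, np.zeros(shape), np.zeros(shape[:2]), Ledger(), h)


def cancer_block(shape=(12, 12, 12), lo=4, hi=8):
    idx = np.argwhere(np.ones(shape, dtype=bool))
    keep = ((idx >= lo) & (idx < hi)).all(axis=1)
    return idx[keep]


@pytest.fixture()
def swir_probe():
    return vf.get_fluorophore("SWIR")


class TestEmissionWeights:
    def test_modes_coincide_under_uniform_excitation(self, swir_probe, rng):
        exc = make_excitation()
        vox = cancer_block()
        kw = dict(cancer_voxels=vox, excitation=exc, fluorophore=swir_probe,
                  n_photons=5000)
        wg = launch_emission(EmissionSource(mode="with_gradient", **kw),
                             np.random.default_rng(7))
        wo = launch_emission(EmissionSource(mode="without_gradient", **kw),
                             np.random.default_rng(7))
        np.testing.assert_allclose(wg[3], wo[3], rtol=1e-12)
        np.testing.assert_array_equal(wg[1], wo[1])

    def test_total_power_accounting_identity(self, swir_probe):
        """Sum of launched weights equals QY*epsC*sum(Phi*V) over the cancer
        to 1e-9 relative, in gradient mode."""
        exc = make_excitation(gradient_axis=2)
        vox = cancer_block()
        src = EmissionSource("with_gradient", vox, exc, swir_probe, 20_000)
        _, _, _, w = launch_emission(src, np.random.default_rng(3))
        v_vox = exc.voxel_size**3
        target = (swir_probe.quantum_yield * swir_probe.epsC
                  * exc.fluence[tuple(vox.T)].sum() * v_vox)
        assert abs(w.sum() - target) / target < 1e-9

    def test_zero_quantum_yield_zeroes_everything(self, swir_probe):
        exc = make_excitation()
        probe = vf.FluorophoreSpec("dead", "SWIR", 970, 1100, 1e-300, 1e-6, 0.63)
        src = EmissionSource("with_gradient", cancer_block(), exc, probe, 1000)
        _, _, _, w = launch_emission(src, np.random.default_rng(1))
        assert w.sum() == pytest.approx(0.0, abs=1e-250)

    def test_emission_weight_point_function(self, swir_probe):
        exc = make_excitation(gradient_axis=2)
        vox = cancer_block()
        src = EmissionSource("with_gradient", vox, exc, swir_probe, 1000)
        h = exc.voxel_size
        pos = (vox[0] + 0.5) * h
        w = emission_weight(pos, src)
        expect = (swir_probe.quantum_yield * swir_probe.epsC
                  * exc.fluence[tuple(vox[0])] * src.cancer_volume / 1000)
        assert w == pytest.approx(expect)
        with pytest.raises(ValueError, match="outside the cancer"):
            emission_weight(np.zeros(3) + h / 2, src)

    def test_empty_cancer_rejected(self, swir_probe):
        with pytest.raises(ValueError, match="empty"):
            EmissionSource("with_gradient", np.empty((0, 3)), make_excitation(),
                           swir_probe, 100)
        with pytest.raises(ValueError, match="mode"):
            EmissionSource("sideways", cancer_block(), make_excitation(),
                           swir_probe, 100)


class TestLaunchStatistics:
    def test_isotropic_directions(self, swir_probe):
        src = EmissionSource("without_gradient", cancer_block(), make_excitation(),
                             swir_probe, 100_000)
        _, _, dirs, _ = launch_emission(src, np.random.default_rng(5))
        np.testing.assert_allclose(np.linalg.norm(dirs, axis=1), 1.0, atol=1e-12)
        se = 1.0 / np.sqrt(3 * dirs.shape[0])  # component std of a unit vector
        assert (np.abs(dirs.mean(axis=0)) < 3 * se).all()

    def test_positions_uniform_over_voxels(self, swir_probe):
        """Chi-square goodness of fit against uniform occupancy on a
        10-voxel cancer."""
        vox = np.array([[i, 5, 5] for i in range(10)])
        src = EmissionSource("without_gradient", vox, make_excitation(), swir_probe,
                             50_000)
        out_vox, pos, _, _ = launch_emission(src, np.random.default_rng(11))
        counts = np.bincount(out_vox[:, 0], minlength=10)
        p = stats.chisquare(counts).pvalue
        assert p > 0.01
        # positions fall inside their voxel
        h = 0.05
        np.testing.assert_array_equal(np.floor(pos / h).astype(int), out_vox)


class TestFullRuns:
    def test_vis_deep_cancer_silent(self, breast_phantom):
        """A 1 mm cancer at 3 cm depth yields no VIS fluorescence at all:
        no excitation reaches the probe."""
        res = vf.run_fluorescence(breast_phantom, "VIS", vf.CancerSpec(0.1, 3.0),
                                  sim=vf.SimConfig(n_photons=20_000, seed=2))
        assert res.surface_irradiance.max() == 0.0
        assert res.diagnostics["launched_power_W"] == 0.0

    def test_gradient_centroid_above_center(self, breast_phantom):
        """With top illumination the emission-weighted launch centroid sits
        above the cancer's geometric centre."""
        res = vf.run_fluorescence(breast_phantom, "SWIR", vf.CancerSpec(1.0, 1.0),
                                  sim=vf.SimConfig(n_photons=20_000, seed=2),
                                  mode="with_gradient")
        assert (res.diagnostics["launch_centroid_z_cm"]
                < res.diagnostics["mean_launch_z_cm"])

    def test_without_gradient_weights_equal(self, breast_phantom):
        vol = vf.embed_cancer(breast_phantom, vf.CancerSpec(1.0, 1.0))
        exc = vf.run_excitation(vol, "SWIR", sim=vf.SimConfig(n_photons=10_000, seed=2))
        vox = np.argwhere(vol.labels == int(TissueLabel.CANCER))
        src = EmissionSource("without_gradient", vox, exc,
                             vf.get_fluorophore("SWIR"), 5000)
        _, _, _, w = launch_emission(src, np.random.default_rng(2))
        assert np.ptp(w) == 0.0

    def test_surface_scales_with_excitation(self, breast_phantom):
        """Scaling the excitation fluence by k scales the surface map by k
        (two-stage linearity), exactly on a fixed seed."""
        vol = vf.embed_cancer(breast_phantom, vf.CancerSpec(1.0, 1.0))
        exc = vf.run_excitation(vol, "SWIR", sim=vf.SimConfig(n_photons=10_000, seed=2))
        vox = np.argwhere(vol.labels == int(TissueLabel.CANCER))
        probe = vf.get_fluorophore("SWIR")
        sim = vf.SimConfig(n_photons=5000, seed=6)
        from voxfluor.fluorescence import run_emission

        em1, _ = run_emission(vol, "SWIR",
                              EmissionSource("with_gradient", vox, exc, probe, 5000),
                              sim)
        exc2 = FluenceVolume(exc.fluence * 3.0, exc.absorbed, exc.surface_weight,
                             exc.ledger, exc.voxel_size)
        em2, _ = run_emission(vol, "SWIR",
                              EmissionSource("with_gradient", vox, exc2, probe, 5000),
                              sim)
        np.testing.assert_allclose(em2.surface_weight, 3.0 * em1.surface_weight,
                                   rtol=1e-9)
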