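"""Excitation-to-emission coupling.

The fluorescent probe is assumed uniformly concentrated in the cancer; its
local emission power density is QY x epsC x Phi_ex(r), i.e. proportional
to the excitation fluence that actually reaches each point (the
"excitation gradient").  The simpler legacy mode replaces Phi_ex(r) by its
value at the cancer centre, making the source spatially uniform.  In both
modes the total launched emission power obeys the accounting identity

    P_em = QY * epsC * sum_v Phi_ex[v] * V_voxel      (with gradient)
    P_em = QY * epsC * Phi_ex[centre] * V_cancer      (without gradient)

enforced exactly over the launched ensemble.  Emission photons start at
uniformly random positions inside the cancer with isotropic directions and
are transported at the emission wavelength; a single fluorescence
generation is simulated (emitted light does not re-excite the probe, and
the probe's epsC is not added to the tissue mu_a — coupling is through the
fluence only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from ._kernel import L_ABS, L_ESC, L_KILL, L_GAIN, L_SURF, L_CAP
from .geometry import CancerSpec, LabelVolume, embed_cancer
from .labels import TissueLabel
from .optics import FluorophoreSpec, OpticsTable, default_optics, get_fluorophore
from .transport import (
    FluenceVolume,
    Ledger,
    SimConfig,
    SourceConfig,
    run_excitation,
    score_fluence,
)

__all__ = [
    "EmissionSource",
    "emission_weight",
    "launch_emission",
    "run_emission",
    "run_fluorescence",
    "FluorescenceResult",
]

MODES = ("with_gradient", "without_gradient")


@dataclass
class EmissionSource:
    """Emission launch description: cancer voxels, excitation fluence,
    fluorophore and the gradient mode."""

    mode: str
    cancer_voxels: np.ndarray  # (K, 3) int indices
    excitation: FluenceVolume
    fluorophore: FluorophoreSpec
    n_photons: int

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        self.cancer_voxels = np.asarray(self.cancer_voxels, dtype=np.int64)
        if self.cancer_voxels.size == 0:
            raise ValueError("cancer voxel set is empty")

    @property
    def center_voxel(self) -> tuple[int, int, int]:
        """Voxel nearest the cancer centroid (the 'centre of the cancer')."""
        centroid = self.cancer_voxels.mean(axis=0)
        k = int(np.argmin(((self.cancer_voxels - centroid) ** 2).sum(axis=1)))
        return tuple(self.cancer_voxels[k])

    @property
    def cancer_volume(self) -> float:
        return self.cancer_voxels.shape[0] * self.excitation.voxel_size**3

    def total_power(self) -> float:
        """Analytic launched emission power (W) for this mode."""
        phi = self.excitation.fluence
        f = self.fluorophore
        v_vox = self.excitation.voxel_size**3
        if self.mode == "with_gradient":
            idx = tuple(self.cancer_voxels.T)
            return f.quantum_yield * f.epsC * float(phi[idx].sum()) * v_vox
        cv = self.center_voxel
        return f.quantum_yield * f.epsC * float(phi[cv]) * self.cancer_volume


def emission_weight(position, source: EmissionSource) -> float:
    """Initial emission weight (W) for a photon launched at ``position``.

    With the gradient, weight tracks the local excitation fluence; without
    it, every photon inherits the centre-voxel fluence.  The per-photon
    normalization V_cancer/N makes the ensemble total match
    :meth:`EmissionSource.total_power` in expectation (the launcher then
    rescales the finite ensemble to match it exactly).
    """
    h = source.excitation.voxel_size
    vox = np.floor(np.asarray(position, dtype=float) / h).astype(np.int64)
    if not (source.cancer_voxels == vox).all(axis=1).any():
        raise ValueError(f"position {tuple(position)} is outside the cancer")
    f = source.fluorophore
    phi = source.excitation.fluence
    if source.mode == "with_gradient":
        local = float(phi[tuple(vox)])
    else:
        local = float(phi[source.center_voxel])
    return f.quantum_yield * f.epsC * local * source.cancer_volume / source.n_photons


def launch_emission(source: EmissionSource, rng: np.random.Generator):
    """Sample the emission ensemble: uniform positions over the cancer
    voxel union, isotropic directions, fluence-coupled weights.

    Returns (voxel_idx (N,3), positions (N,3) cm, directions (N,3),
    weights (N,) W).  The weight vector is rescaled so its sum equals the
    mode's analytic total power exactly.
    """
    n = source.n_photons
    h = source.excitation.voxel_size
    k = rng.integers(0, source.cancer_voxels.shape[0], size=n)
    vox = source.cancer_voxels[k]
    pos = (vox + rng.random((n, 3))) * h

    uz = 2.0 * rng.random(n) - 1.0
    phi_az = 2.0 * np.pi * rng.random(n)
    st = np.sqrt(np.maximum(0.0, 1.0 - uz**2))
    dirs = np.column_stack([st * np.cos(phi_az), st * np.sin(phi_az), uz])

    f = source.fluorophore
    phi = source.excitation.fluence
    if source.mode == "with_gradient":
        local = phi[tuple(vox.T)]
    else:
        local = np.full(n, phi[source.center_voxel])
    w = f.quantum_yield * f.epsC * local * source.cancer_volume / n
    total = w.sum()
    target = source.total_power()
    if total > 0:
        w = w * (target / total)
    return vox, pos, dirs, w


def run_emission(
    volume: LabelVolume,
    band: str,
    source: EmissionSource,
    sim: SimConfig,
    optics: OpticsTable | None = None,
    n_ambient: float = 1.0,
) -> tuple[FluenceVolume, dict]:
    """Transport the emission ensemble at the band's emission wavelength.

    Returns the emission fluence volume (weights carried in watts, so the
    surface grid is escaped power per bin) and a dict of launch
    diagnostics (ensemble power, weighted launch centroid).
    """
    optics = optics or default_optics()
    mu_a, mu_s, g_arr, n_arr = optics.property_arrays(band, "emission")
    h = volume.voxel_size
    rng = np.random.default_rng(sim.seed)
    vox, pos, dirs, w = launch_emission(source, rng)

    diagnostics = {
        "launched_power_W": float(w.sum()),
        "analytic_power_W": source.total_power(),
        "launch_centroid_z_cm": (
            float((w * pos[:, 2]).sum() / w.sum()) if w.sum() > 0 else float("nan")
        ),
        "mean_launch_z_cm": float(pos[:, 2].mean()),
    }

    absorbed = np.zeros(volume.shape)
    surf = np.zeros(volume.shape[:2])
    led = np.zeros(8)
    total_w = float(w.sum())
    if total_w > 0:
        # run the kernel on weights normalized to unit mean so the roulette
        # threshold acts relative to a typical photon, then rescale to watts
        scale = total_w / w.size
        kseed = int(rng.integers(0, 2**31 - 1))
        _kernel.propagate(
            volume.labels, mu_a, mu_s, g_arr, n_arr, float(n_ambient),
            np.ascontiguousarray(vox[:, 0]), np.ascontiguousarray(vox[:, 1]),
            np.ascontiguousarray(vox[:, 2]),
            np.ascontiguousarray(pos[:, 0]), np.ascontiguousarray(pos[:, 1]),
            np.ascontiguousarray(pos[:, 2]),
            np.ascontiguousarray(dirs[:, 0]), np.ascontiguousarray(dirs[:, 1]),
            np.ascontiguousarray(dirs[:, 2]),
            w / scale,
            h, sim.weight_threshold, float(sim.roulette_m), sim.max_events, kseed,
            absorbed, surf, led,
        )
        absorbed *= scale
        surf *= scale
        for slot in (L_ABS, L_ESC, L_KILL, L_GAIN, L_SURF):
            led[slot] *= scale

    ledger = Ledger(
        launched=float(w.sum()),
        absorbed=led[L_ABS],
        escaped=led[L_ESC],
        roulette_killed=led[L_KILL],
        roulette_gain=led[L_GAIN],
        surface_escaped=led[L_SURF],
        capped_photons=int(led[L_CAP]),
        n_photons=source.n_photons,
    )
    # weights are watts: fluence = absorbed / (mu_a * V); no N or P factor
    v_vox = h**3
    mu_map = mu_a[volume.labels]
    fl = np.zeros_like(absorbed)
    ok = mu_map > 0
    fl[ok] = absorbed[ok] / (mu_map[ok] * v_vox)
    em = FluenceVolume(
        fl, absorbed, surf, ledger, h,
        meta={"band": band, "role": "emission", "mode": source.mode,
              "seed": sim.seed, "launch": diagnostics,
              "normalization": "weights in W; fluence = absorbed/(mu_a*V_voxel)"},
    )
    return em, diagnostics


@dataclass
class FluorescenceResult:
    """Bundle of one excitation + emission run."""

    excitation: FluenceVolume
    emission: FluenceVolume
    surface_irradiance: np.ndarray  # W/cm^2 per (x, y) bin
    bin_size: float
    diagnostics: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def run_fluorescence(
    volume: LabelVolume,
    band: str,
    cancer: CancerSpec | None = None,
    source: SourceConfig | None = None,
    sim: SimConfig | None = None,
    mode: str = "with_gradient",
    optics: OpticsTable | None = None,
    fluorophore: FluorophoreSpec | None = None,
    n_emission_photons: int | None = None,
    n_ambient: float = 1.0,
) -> FluorescenceResult:
    """Full two-stage simulation: excitation transport at the band's Ex
    wavelength, fluence-coupled emission launch inside the cancer, and
    emission transport at the Em wavelength with surface scoring.

    If ``cancer`` is given it is embedded into a copy of ``volume`` first;
    otherwise the volume must already contain cancer voxels.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    source = source or SourceConfig()
    sim = sim or SimConfig()
    if cancer is not None:
        volume = embed_cancer(volume, cancer)
    cancer_idx = np.argwhere(volume.labels == int(TissueLabel.CANCER))
    if cancer_idx.size == 0:
        raise ValueError("volume contains no cancer voxels")

    exc = run_excitation(volume, band, source, sim, optics=optics, n_ambient=n_ambient)
    fluor = fluorophore or get_fluorophore(band)
    em_source = EmissionSource(
        mode=mode,
        cancer_voxels=cancer_idx,
        excitation=exc,
        fluorophore=fluor,
        n_photons=n_emission_photons or sim.n_photons,
    )
    em_sim = SimConfig(
        n_photons=em_source.n_photons,
        weight_threshold=sim.weight_threshold,
        roulette_m=sim.roulette_m,
        seed=sim.seed + 1,
        max_events=sim.max_events,
    )
    em, diag = run_emission(volume, band, em_source, em_sim, optics=optics, n_ambient=n_ambient)

    h = volume.voxel_size
    surface_irradiance = em.surface_weight / (h * h)
    return FluorescenceResult(
        excitation=exc,
        emission=em,
        surface_irradiance=surface_irradiance,
        bin_size=h,
        diagnostics=diag,
        meta={"band": band, "mode": mode, "seed": sim.seed,
              "cancer_voxels": int(cancer_idx.shape[0])},
    )
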