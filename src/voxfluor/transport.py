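"""Monte Carlo photon transport in voxelized media.

Implements the standard weighted-photon random walk of multi-layer tissue
Monte Carlo, generalized to a voxel grid: dimensionless pathlength
s = -ln(xi) is sampled once per free flight and consumed voxel-by-voxel as
mu_t * distance; at interaction sites a fraction mu_a/mu_t of the weight is
deposited and the direction is re-sampled from the Henyey-Greenstein phase
function; faces where the refractive index changes apply unpolarized
Fresnel reflection / Snell refraction; low-weight photons play Russian
roulette.  Fluence is estimated per voxel as absorbed weight divided by
(mu_a x voxel volume x photon count), scaled to the source power.

The single-step operations (:func:`sample_step`, :func:`deposit`,
:func:`spin`, :func:`fresnel`, :func:`roulette`) are plain-Python mirrors
of the compiled kernel, exposed for testing and interactive use.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _kernel
from ._kernel import L_ABS, L_ESC, L_KILL, L_GAIN, L_SURF, L_CAP
from .geometry import LabelVolume
from .labels import TissueLabel
from .optics import OpticalProperties, OpticsTable, default_optics

__all__ = [
    "PhotonState",
    "SourceConfig",
    "SimConfig",
    "Ledger",
    "FluenceVolume",
    "sample_step",
    "deposit",
    "spin",
    "sample_hg_cos",
    "fresnel",
    "roulette",
    "run_excitation",
    "score_fluence",
    "surface_height_map",
]


@dataclass
class PhotonState:
    """The random walker: position (cm), unit direction, statistical weight."""

    position: np.ndarray
    direction: np.ndarray
    weight: float = 1.0
    alive: bool = True

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(self.direction)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")


@dataclass(frozen=True)
class SourceConfig:
    """Collimated source on the air side, normally incident (+z).

    ``kind='disk'`` is a uniform disk of ``radius`` cm centred over the
    anchor (or ``center`` if given); ``kind='pencil'`` is a zero-width beam
    used for validation.  ``irradiance`` is in W/cm^2 (default 50 mW/cm^2,
    the usual tissue-spectroscopy level).  The beam aperture area used for
    power normalization is pi r^2 for the disk and 1 cm^2 by convention for
    the pencil.
    """

    kind: str = "disk"
    radius: float = 1.0
    irradiance: float = 0.05
    center: tuple[float, float] | None = None

    def __post_init__(self):
        if self.kind not in ("disk", "pencil"):
            raise ValueError("source kind must be 'disk' or 'pencil'")
        if self.irradiance <= 0:
            raise ValueError("irradiance must be positive")
        if self.kind == "disk" and self.radius <= 0:
            raise ValueError("disk radius must be positive")

    @property
    def beam_area(self) -> float:
        return math.pi * self.radius**2 if self.kind == "disk" else 1.0

    @property
    def power(self) -> float:
        """Total source power (W) = irradiance x aperture area."""
        return self.irradiance * self.beam_area


@dataclass(frozen=True)
class SimConfig:
    """Run controls: photon count, roulette parameters, seed, event cap."""

    n_photons: int = 100_000
    weight_threshold: float = 1e-4
    roulette_m: int = 10
    seed: int = 1
    max_events: int = 10_000_000

    def __post_init__(self):
        if not 0 < self.weight_threshold < 1:
            raise ValueError("weight threshold must lie in (0, 1)")
        if self.roulette_m < 2:
            raise ValueError("roulette survival factor m must be >= 2")
        if self.n_photons < 1:
            raise ValueError("need at least one photon")


@dataclass
class Ledger:
    """Per-run weight accounting.

    Russian roulette adds weight (m-1)W to every survivor, so the exact
    per-run identity is

        launched + roulette_gain = absorbed + escaped + roulette_killed

    which reduces to launched = absorbed + escaped + roulette_killed in
    expectation (roulette is unbiased).
    """

    launched: float = 0.0
    absorbed: float = 0.0
    escaped: float = 0.0
    roulette_killed: float = 0.0
    roulette_gain: float = 0.0
    surface_escaped: float = 0.0
    capped_photons: int = 0
    n_photons: int = 0

    @property
    def closure_residual(self) -> float:
        """Relative imbalance of the exact accounting identity."""
        lhs = self.launched + self.roulette_gain
        rhs = self.absorbed + self.escaped + self.roulette_killed
        scale = max(abs(lhs), 1e-300)
        return abs(lhs - rhs) / scale

    def as_dict(self) -> dict:
        return {
            "launched": self.launched,
            "absorbed": self.absorbed,
            "escaped": self.escaped,
            "roulette_killed": self.roulette_killed,
            "roulette_gain": self.roulette_gain,
            "surface_escaped": self.surface_escaped,
            "capped_photons": self.capped_photons,
            "n_photons": self.n_photons,
            "closure_residual": self.closure_residual,
        }


@dataclass
class FluenceVolume:
    """Per-voxel fluence rate (W/cm^2) plus the raw absorbed-weight grid,
    the surface-escape grid (raw weight per bin) and the run ledger."""

    fluence: np.ndarray
    absorbed: np.ndarray
    surface_weight: np.ndarray
    ledger: Ledger
    voxel_size: float
    meta: dict = field(default_factory=dict)

    def save(self, path) -> None:
        import nibabel as nib

        path = Path(path)
        h = self.voxel_size
        img = nib.Nifti1Image(self.fluence.astype(np.float32), np.diag([h, h, h, 1.0]))
        nib.save(img, path)
        sidecar = {"ledger": self.ledger.as_dict(), "meta": self.meta}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


# ---------------------------------------------------------------------------
# single-step operations (plain-Python mirrors of the kernel formulas)


def sample_step(xi: float, mu_t: float) -> float:
    """Free-flight step s = -ln(xi)/mu_t (cm) for xi in (0, 1]."""
    if mu_t <= 0:
        raise ValueError("mu_t must be positive; vacuum is handled by traversal")
    if not 0 < xi <= 1:
        raise ValueError("xi must lie in (0, 1]")
    return -math.log(xi) / mu_t


def deposit(photon: PhotonState, props: OpticalProperties) -> float:
    """Deposit dW = W mu_a/mu_t at an interaction site; returns dW."""
    if not photon.alive:
        raise ValueError("photon is not alive")
    dw = photon.weight * props.mu_a / props.mu_t
    photon.weight -= dw
    return dw


def sample_hg_cos(g: float, xi: float) -> float:
    """Henyey-Greenstein deflection cosine for one uniform draw."""
    return float(_kernel._hg_cos(g, xi))


def spin(direction: np.ndarray, g: float, xi1: float, xi2: float) -> np.ndarray:
    """Rotate a unit direction by a Henyey-Greenstein deflection.

    xi1 draws cos(theta) from the HG density (isotropic for g = 0); xi2
    draws the azimuth.  Uses the standard local-frame update with the
    |uz| ~ 1 special case.
    """
    ux, uy, uz = (float(c) for c in direction)
    ct = sample_hg_cos(g, xi1)
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    phi = 2.0 * math.pi * xi2
    cp, sp = math.cos(phi), math.sin(phi)
    if abs(uz) > 0.99999:
        out = np.array([st * cp, st * sp, ct if uz >= 0 else -ct])
    else:
        den = math.sqrt(1.0 - uz * uz)
        out = np.array(
            [
                st * (ux * uz * cp - uy * sp) / den + ux * ct,
                st * (uy * uz * cp + ux * sp) / den + uy * ct,
                -st * cp * den + uz * ct,
            ]
        )
    return out / np.linalg.norm(out)


def fresnel(n_i: float, n_t: float, cos_theta_i: float) -> tuple[float, float]:
    """Unpolarized Fresnel reflectance and transmitted cosine.

    Returns (R, cos_theta_t); R = 1 and cos_theta_t = 0 under total
    internal reflection.
    """
    if not 0 < cos_theta_i <= 1:
        raise ValueError("cos_theta_i must lie in (0, 1]")
    R, ct = _kernel._fresnel(n_i, n_t, cos_theta_i)
    return float(R), float(ct)


def roulette(photon: PhotonState, m: int, xi: float) -> float:
    """Russian roulette: survive with probability 1/m at m-fold weight.

    Returns the ledger delta: +(m-1)W gain on survival (weight created),
    -W on death (weight killed is the negated return's magnitude... the
    sign convention is: positive = roulette_gain, negative = weight moved
    to roulette_killed).
    """
    w = photon.weight
    if xi * m < 1.0:
        photon.weight = w * m
        return (m - 1.0) * w
    photon.alive = False
    photon.weight = 0.0
    return -w


# ---------------------------------------------------------------------------
# full runs


def surface_height_map(volume: LabelVolume) -> np.ndarray:
    """Per-(x, y) column index of the first tissue voxel along +z, or -1
    where the column holds no tissue."""
    tissue = volume.tissue_mask()
    any_t = tissue.any(axis=2)
    first = np.argmax(tissue, axis=2)
    return np.where(any_t, first, -1).astype(np.int64)


def _sample_source_xy(source: SourceConfig, volume: LabelVolume, n: int, rng):
    if source.center is not None:
        cx, cy = source.center
    else:
        cx, cy = volume.anchor_x_cm, volume.anchor_y_cm
    if source.kind == "pencil":
        return np.full(n, cx), np.full(n, cy)
    r = source.radius * np.sqrt(rng.random(n))
    th = 2.0 * np.pi * rng.random(n)
    return cx + r * np.cos(th), cy + r * np.sin(th)


def run_excitation(
    volume: LabelVolume,
    band: str,
    source: SourceConfig | None = None,
    sim: SimConfig | None = None,
    optics: OpticsTable | None = None,
    n_ambient: float = 1.0,
    role: str = "excitation",
) -> FluenceVolume:
    """Run one transport simulation of the source beam at the band's
    excitation wavelength and score the fluence volume.

    Each photon launches with unit weight; the specular Fresnel reflection
    at the air/tissue entry face is deducted deterministically from the
    initial weight and booked as escaped.  Beam columns that miss the
    tissue escape with their full weight.
    """
    source = source or SourceConfig()
    sim = sim or SimConfig()
    optics = optics or default_optics()
    mu_a, mu_s, g_arr, n_arr = optics.property_arrays(band, role)
    _check_mu_a(mu_a, volume)

    h = volume.voxel_size
    nx, ny, nz = volume.shape
    rng = np.random.default_rng(sim.seed)
    n = sim.n_photons

    xs, ys = _sample_source_xy(source, volume, n, rng)
    in_grid = (xs >= 0) & (xs < nx * h) & (ys >= 0) & (ys < ny * h)
    ixs = np.clip(np.floor(xs / h).astype(np.int64), 0, nx - 1)
    iys = np.clip(np.floor(ys / h).astype(np.int64), 0, ny - 1)
    hmap = surface_height_map(volume)
    iz_entry = np.where(in_grid, hmap[ixs, iys], -1)
    hits = iz_entry >= 0
    n_miss = int(np.count_nonzero(~hits))

    ixs, iys = ixs[hits], iys[hits]
    iz0 = iz_entry[hits]
    x0, y0 = xs[hits], ys[hits]
    z0 = iz0.astype(float) * h

    entry_labels = volume.labels[ixs, iys, iz0]
    n_entry = n_arr[entry_labels]
    r_spec = np.array([fresnel(n_ambient, nv, 1.0)[0] for nv in np.unique(n_entry)])
    spec_lookup = dict(zip(np.unique(n_entry), r_spec))
    rs = np.array([spec_lookup[nv] for nv in n_entry])
    w0 = 1.0 - rs

    absorbed = np.zeros(volume.shape)
    surf = np.zeros((nx, ny))
    led = np.zeros(8)
    kseed = int(rng.integers(0, 2**31 - 1))
    _kernel.propagate(
        volume.labels, mu_a, mu_s, g_arr, n_arr, float(n_ambient),
        ixs, iys, iz0.astype(np.int64),
        x0, y0, z0,
        np.zeros(x0.size), np.zeros(x0.size), np.ones(x0.size),
        w0,
        h, sim.weight_threshold, float(sim.roulette_m), sim.max_events, kseed,
        absorbed, surf, led,
    )

    ledger = Ledger(
        launched=float(n),
        absorbed=led[L_ABS],
        escaped=led[L_ESC] + float(rs.sum()) + float(n_miss),
        roulette_killed=led[L_KILL],
        roulette_gain=led[L_GAIN],
        surface_escaped=led[L_SURF],
        capped_photons=int(led[L_CAP]),
        n_photons=n,
    )
    return score_fluence(
        absorbed, mu_a, volume, n, source,
        ledger=ledger, surface_weight=surf,
        meta={"band": band, "role": role, "seed": sim.seed, "n_ambient": n_ambient,
              "source": {"kind": source.kind, "radius_cm": source.radius,
                         "irradiance_W_cm2": source.irradiance,
                         "beam_area_cm2": source.beam_area}},
    )


def _check_mu_a(mu_a: np.ndarray, volume: LabelVolume) -> None:
    present = np.unique(volume.labels)
    bad = [int(l) for l in present if l > 0 and mu_a[l] == 0.0]
    if bad:
        names = [TissueLabel(b).name.lower() for b in bad]
        raise ValueError(
            "collision fluence estimator undefined for zero-mu_a tissues "
            f"present in the volume: {names}"
        )


def score_fluence(
    absorbed: np.ndarray,
    mu_a_per_label: np.ndarray,
    volume: LabelVolume,
    n_photons: int,
    source: SourceConfig,
    *,
    ledger: Ledger | None = None,
    surface_weight: np.ndarray | None = None,
    meta: dict | None = None,
) -> FluenceVolume:
    """Collision-estimator fluence: Phi[v] = absorbed[v] P / (N mu_a[v] V).

    P = irradiance x beam aperture area is the total source power, so the
    result is the fluence rate (W/cm^2) delivered by the configured source.
    """
    h = volume.voxel_size
    v_vox = h**3
    mu_map = mu_a_per_label[volume.labels]
    power = source.power
    fl = np.zeros_like(absorbed)
    ok = mu_map > 0
    fl[ok] = absorbed[ok] * power / (n_photons * v_vox * mu_map[ok])
    if ledger is None:
        ledger = Ledger(n_photons=n_photons)
    if surface_weight is None:
        surface_weight = np.zeros(volume.shape[:2])
    meta = dict(meta or {})
    meta.setdefault("normalization", "absorbed * P_source / (N * mu_a * V_voxel)")
    return FluenceVolume(fl, absorbed, surface_weight, ledger, h, meta)
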