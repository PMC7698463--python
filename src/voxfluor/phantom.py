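"""Synthetic breast phantoms.

The reference anatomy (cryosection-derived thoracic volume: contoured
breast surface, a 2-voxel skin shell, a branching mammary-duct tree inside
fat) is not redistributable, so this module generates label volumes with
the same *structure*: a semi-ellipsoidal breast cap on an elliptic-cylinder
chest block, skin derived per slice by the same 2-pixel border rule the
segmenter uses, and a random recursive duct tree converging on the nipple
apex.  It is a structural stand-in, not anatomically validated.

Also provides flat slab phantoms (the geometry of simpler layered models)
and a grayscale renderer used to round-trip-test the segmenter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .labels import TissueLabel
from .geometry import LabelVolume, segment_slice, stack_to_volume

__all__ = [
    "PhantomParams",
    "generate_breast_phantom",
    "generate_slab_phantom",
    "render_to_grayscale",
]


@dataclass
class PhantomParams:
    """Geometry and duct-tree controls for the synthetic breast.

    Default grid (140, 80, 112) at 0.033 cm voxels spans 4.6 x 2.6 x 3.7 cm
    — a reduced stand-in for the full (500, 250, 220) anatomical grid,
    deep enough to embed cancers down to 3 cm.  The breast is a
    semi-ellipsoid cap (half-axes ``profile_cm``) whose apex defines the
    (x = 0, z = 0) anchor, continued backwards by an elliptic cylinder to
    the grid bottom (the chest block).
    """

    shape: tuple[int, int, int] = (140, 80, 112)
    voxel_size: float = 0.033
    profile_cm: tuple[float, float, float] = (2.0, 1.2, 1.2)  # a, b, c half-axes
    air_layers: int = 2  # voxels of air above the apex
    n_primary_ducts: int = 8
    branch_depth: int = 3
    branch_length_cm: tuple[float, float] = (0.4, 0.9)
    duct_radius_cm: float = 0.05
    skin_voxels: int = 2
    seed: int = 0


def generate_breast_phantom(params: PhantomParams | None = None) -> LabelVolume:
    """Deterministic (per seed) synthetic breast label volume.

    Contains all four labels: a 2-voxel skin shell around the contour,
    fat bulk, and a branching duct tree that starts just below the nipple
    apex and spreads into the depth of the gland.
    """
    p = params or PhantomParams()
    nx, ny, nz = p.shape
    h = p.voxel_size
    a, b, c = p.profile_cm
    rng = np.random.default_rng(p.seed)

    cx = nx * h / 2.0
    cy = ny * h / 2.0
    z0 = p.air_layers * h  # apex plane

    xs = (np.arange(nx) + 0.5) * h - cx
    ys = (np.arange(ny) + 0.5) * h - cy
    zs = (np.arange(nz) + 0.5) * h - z0
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")

    # semi-ellipsoid cap for 0 <= z < c, elliptic cylinder for z >= c
    cap = (X / a) ** 2 + (Y / b) ** 2 + ((Z - c) / c) ** 2 <= 1.0
    cyl = ((X / a) ** 2 + (Y / b) ** 2 <= 1.0) & (Z >= c)
    tissue = (cap | cyl) & (Z >= 0)
    if not tissue.any():
        raise ValueError("breast profile leaves no tissue inside the grid")

    labels = np.zeros(p.shape, dtype=np.uint8)
    labels[tissue] = int(TissueLabel.FAT)

    # per-slice 2-pixel skin border, same rule the segmenter applies;
    # border_value=1 keeps grid-clipped faces (chest block) skin-free
    for iy in range(ny):
        mask = tissue[:, iy, :]
        if not mask.any():
            continue
        interior = ndimage.binary_erosion(mask, iterations=p.skin_voxels, border_value=1)
        labels[:, iy, :][mask & ~interior] = int(TissueLabel.SKIN)

    interior_fat = labels == int(TissueLabel.FAT)
    if not interior_fat.any():
        raise ValueError("phantom parameters leave no fat interior")

    if p.n_primary_ducts > 0:
        duct_mask = _grow_duct_tree(p, rng, interior_fat, cx, cy, z0)
        labels[duct_mask & interior_fat] = int(TissueLabel.DUCT)

    anchor = _apex_anchor(labels, nx, ny)
    vol = LabelVolume(labels, h, anchor, {"generator": "breast_phantom", "seed": p.seed})
    return vol


def _apex_anchor(labels: np.ndarray, nx: int, ny: int) -> tuple[int, int, int]:
    iy = ny // 2
    sl = labels[:, iy, :] != int(TissueLabel.OUTSIDE)
    zmin = int(np.argmax(sl.any(axis=0)))
    xs = np.flatnonzero(sl[:, zmin])
    ix = int(xs[np.argmin(np.abs(xs - nx // 2))])
    return (ix, iy, zmin)


def _grow_duct_tree(p: PhantomParams, rng, fat_mask, cx, cy, z0):
    """Random recursive branching tree, voxelized by capsule rasterization.

    Primary ducts start in a small disc under the nipple apex and do a
    persistence random walk biased toward +z (depth); each branch may split
    into two children down to ``branch_depth`` levels.
    """
    nx, ny, nz = p.shape
    h = p.voxel_size
    mask = np.zeros(p.shape, dtype=bool)

    segments = []  # (start_point, direction) work queue with remaining depth
    for _ in range(p.n_primary_ducts):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.0, 0.25)
        start = np.array([cx + rad * np.cos(ang), cy + rad * np.sin(ang), z0 + 0.12])
        d = np.array([rng.normal(0, 0.4), rng.normal(0, 0.4), 1.0])
        segments.append((start, d / np.linalg.norm(d), p.branch_depth))

    pts = []
    while segments:
        pos, direction, depth = segments.pop()
        length = rng.uniform(*p.branch_length_cm)
        n_steps = max(int(length / (0.5 * h)), 2)
        step = length / n_steps
        for _ in range(n_steps):
            jitter = rng.normal(0, 0.25, size=3)
            jitter[2] = abs(jitter[2]) * 0.5  # keep heading into depth
            direction = direction + 0.3 * jitter
            direction /= np.linalg.norm(direction)
            if direction[2] < 0.1:  # never run back toward the surface
                direction[2] = 0.1
                direction /= np.linalg.norm(direction)
            pos = pos + direction * step
            pts.append(pos.copy())
        if depth > 0:
            for _ in range(2):
                d = direction + rng.normal(0, 0.5, size=3)
                d /= np.linalg.norm(d)
                segments.append((pos.copy(), d, depth - 1))

    if not pts:
        return mask
    pts = np.array(pts)
    r_vox = p.duct_radius_cm / h
    rr = int(np.ceil(r_vox))
    off = np.arange(-rr, rr + 1)
    OX, OY, OZ = np.meshgrid(off, off, off, indexing="ij")
    ball = OX**2 + OY**2 + OZ**2 <= r_vox**2
    bi, bj, bk = np.nonzero(ball)
    bi, bj, bk = bi - rr, bj - rr, bk - rr

    idx = np.floor(pts / h).astype(np.int64)
    for ci, cj, ck in idx:
        ii = ci + bi
        jj = cj + bj
        kk = ck + bk
        ok = (ii >= 0) & (ii < nx) & (jj >= 0) & (jj < ny) & (kk >= 0) & (kk < nz)
        mask[ii[ok], jj[ok], kk[ok]] = True
    return mask


def generate_slab_phantom(
    thickness: float,
    tissue: TissueLabel = TissueLabel.FAT,
    shape: tuple[int, int, int] = (80, 80, 90),
    voxel_size: float = 0.05,
    skin_cap: bool = False,
    air_layers: int = 2,
) -> LabelVolume:
    """Homogeneous slab with a flat air interface at z = 0.

    The slab spans the full lateral extent from ``air_layers`` voxels of
    ambient down to ``thickness`` cm; with ``skin_cap`` the top 2 voxel
    layers are skin.  This reproduces the flat layered geometry of simpler
    breast models and is the workhorse for physics validation.
    """
    nx, ny, nz = shape
    h = voxel_size
    n_slab = int(round(thickness / h))
    if air_layers + n_slab > nz:
        raise ValueError("slab does not fit the grid depth")
    labels = np.zeros(shape, dtype=np.uint8)
    labels[:, :, air_layers : air_layers + n_slab] = int(tissue)
    if skin_cap and n_slab > 2:
        labels[:, :, air_layers : air_layers + 2] = int(TissueLabel.SKIN)
    anchor = (nx // 2, ny // 2, air_layers)
    return LabelVolume(labels, h, anchor, {"generator": "slab", "thickness_cm": thickness})


_RENDER_VALUES = {
    int(TissueLabel.OUTSIDE): 0,
    int(TissueLabel.SKIN): 200,  # skin is re-derived from the border rule
    int(TissueLabel.FAT): 200,
    int(TissueLabel.DUCT): 100,
    int(TissueLabel.CANCER): 200,  # cancer is not segmentable from grayscale
}


def render_to_grayscale(volume: LabelVolume) -> np.ndarray:
    """Render a label volume to the 8-bit grayscale stack the segmenter
    expects (fat/skin 200, duct 100, outside 0); shape preserved."""
    lut = np.zeros(256, dtype=np.uint8)
    for k, v in _RENDER_VALUES.items():
        lut[k] = v
    return lut[volume.labels]


def resegment(volume: LabelVolume) -> LabelVolume:
    """render -> segment_slice per y-slice -> restack (round-trip check)."""
    gray = render_to_grayscale(volume)
    slices = [segment_slice(gray[:, iy, :]) for iy in range(volume.shape[1])]
    return stack_to_volume(slices, volume.voxel_size, anchor=volume.anchor)
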