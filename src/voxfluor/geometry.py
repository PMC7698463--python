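"""Voxelized medium: label volumes, slice segmentation, cancer embedding.

Axis convention (stored in every volume's metadata):

* axis 0 — ``x``, medio-lateral;
* axis 1 — ``y``, the slice/stacking axis;
* axis 2 — ``z``, depth from the anterior (air-facing) surface.

The coordinate anchor ``(x = 0, z = 0)`` sits at the nipple apex voxel of
the mid slice: ``x = 0`` at that voxel's centre, ``z = 0`` at its top
(anterior) face.  Cancer depth is the distance from the ``z = 0`` plane to
the *upper surface* of the embedded sphere.

Voxels are half-open boxes ``[i*h, (i+1)*h)``; membership tests use the
voxel centre.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .labels import TissueLabel, LABEL_NAMES

__all__ = [
    "LabelVolume",
    "CancerSpec",
    "rgb_to_gray",
    "segment_slice",
    "stack_to_volume",
    "embed_cancer",
    "validate_volume",
    "save_volume",
    "load_volume",
]


@dataclass
class LabelVolume:
    """3-D grid of tissue labels at isotropic voxel size (cm).

    ``anchor`` is the (ix, iy, iz) voxel index of the nipple apex; world
    coordinates place x = 0 at that voxel's centre and z = 0 at its top
    face.
    """

    labels: np.ndarray  # uint8, shape (nx, ny, nz)
    voxel_size: float
    anchor: tuple[int, int, int]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.ascontiguousarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        self.anchor = tuple(int(a) for a in self.anchor)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def anchor_x_cm(self) -> float:
        """World x of the x = 0 plane (apex voxel centre)."""
        return (self.anchor[0] + 0.5) * self.voxel_size

    @property
    def anchor_y_cm(self) -> float:
        return (self.anchor[1] + 0.5) * self.voxel_size

    @property
    def anchor_z_cm(self) -> float:
        """World z of the z = 0 plane (apex voxel top face)."""
        return self.anchor[2] * self.voxel_size

    def tissue_mask(self) -> np.ndarray:
        return self.labels != int(TissueLabel.OUTSIDE)

    def count(self, label: TissueLabel) -> int:
        return int(np.count_nonzero(self.labels == int(label)))

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.labels.copy(), self.voxel_size, self.anchor, dict(self.meta))


@dataclass(frozen=True)
class CancerSpec:
    """Spherical fluorescence-labeled cancer placement.

    ``depth`` is measured from z = 0 to the sphere's upper surface;
    ``x``/``y`` are lateral offsets (cm) from the anchor (the reference
    geometry uses x = 0).
    """

    diameter: float
    depth: float
    x: float = 0.0
    y: float = 0.0

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")


# ---------------------------------------------------------------------------
# slice segmentation

_GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])  # ITU-R 601 luma


def rgb_to_gray(image: np.ndarray) -> np.ndarray:
    """24-bit RGB -> 8-bit grayscale via ITU-R 601 luma, rounded to int."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if arr.dtype != np.uint8:
        raise ValueError("expected 8-bit-per-channel RGB input")
    gray = arr.astype(np.float64) @ _GRAY_WEIGHTS
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def segment_slice(
    image: np.ndarray,
    *,
    fat_min: int = 180,
    duct_range: tuple[int, int] = (80, 120),
    skin_width: int = 2,
    background_max: int = 0,
) -> np.ndarray:
    """Threshold one 8-bit grayscale cross-section into tissue labels.

    Pixels above ``background_max`` form the tissue region; its border of
    ``skin_width`` pixels becomes skin.  Interior pixels > ``fat_min`` are
    fat, pixels inside ``duct_range`` (inclusive) are duct, and every other
    interior pixel falls back to fat — fat is the bulk matrix of the breast
    and only three tissue classes are defined.
    """
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if arr.dtype != np.uint8:
        raise ValueError("expected an 8-bit grayscale image")

    labels = np.zeros(arr.shape, dtype=np.uint8)
    tissue = arr > background_max
    if not tissue.any():
        return labels
    # border_value=1: skin forms against the outside *region*, not the image
    # frame — tissue running off the crop edge stays interior
    interior = ndimage.binary_erosion(tissue, iterations=skin_width, border_value=1)
    skin = tissue & ~interior
    labels[skin] = int(TissueLabel.SKIN)
    labels[interior] = int(TissueLabel.FAT)  # fallback
    lo, hi = duct_range
    labels[interior & (arr >= lo) & (arr <= hi)] = int(TissueLabel.DUCT)
    labels[interior & (arr > fat_min)] = int(TissueLabel.FAT)
    return labels


def stack_to_volume(
    slices,
    voxel_size: float,
    anchor: tuple[int, int, int] | None = None,
) -> LabelVolume:
    """Stack per-slice label images (x, z) along the y axis into a volume.

    250 slices of 500 x 220 labels yield a (500, 250, 220) grid.  When no
    anchor is given, the nipple apex is located automatically as the
    shallowest (minimum-z) tissue voxel of the mid slice.
    """
    slices = list(slices)
    if not slices:
        raise ValueError("empty slice stack")
    arrs = [np.asarray(s) for s in slices]
    shape0 = arrs[0].shape
    if any(a.shape != shape0 for a in arrs):
        raise ValueError("ragged slice stack: all slices must share dimensions")
    labels = np.stack(arrs, axis=1).astype(np.uint8)
    if anchor is None:
        anchor = _find_apex(labels)
    return LabelVolume(labels, voxel_size, anchor)


def _find_apex(labels: np.ndarray) -> tuple[int, int, int]:
    """Nipple apex: the minimum-z tissue voxel of the mid slice (ties broken
    toward the lateral centre)."""
    nx, ny, nz = labels.shape
    iy = ny // 2
    sl = labels[:, iy, :] != int(TissueLabel.OUTSIDE)
    if not sl.any():
        return (nx // 2, iy, 0)
    zmin = int(np.argmax(sl.any(axis=0)))
    xs = np.flatnonzero(sl[:, zmin])
    ix = int(xs[np.argmin(np.abs(xs - nx // 2))])
    return (ix, iy, zmin)


# ---------------------------------------------------------------------------
# cancer embedding


def embed_cancer(volume: LabelVolume, spec: CancerSpec) -> LabelVolume:
    """Return a copy of ``volume`` with a spherical cancer relabeled in.

    The sphere's centre sits at (anchor_x + spec.x, anchor_y + spec.y) and
    its upper surface ``spec.depth`` below the z = 0 plane.  Every voxel
    whose centre lies within the sphere becomes cancer; the input volume is
    untouched.  The relabeled voxel count is stored in
    ``meta['cancer_voxels']``.

    Raises :class:`ValueError` if the sphere protrudes above the surface or
    covers any non-tissue voxel.
    """
    h = volume.voxel_size
    r = spec.diameter / 2.0
    cx = volume.anchor_x_cm + spec.x
    cy = volume.anchor_y_cm + spec.y
    cz = volume.anchor_z_cm + spec.depth + r

    if cz - r < volume.anchor_z_cm - 0.5 * h:
        raise ValueError("cancer sphere extends above the z = 0 surface")

    nx, ny, nz = volume.shape
    # bounding box of candidate voxels
    ilo = max(int(np.floor((cx - r) / h)) - 1, 0)
    ihi = min(int(np.ceil((cx + r) / h)) + 1, nx)
    jlo = max(int(np.floor((cy - r) / h)) - 1, 0)
    jhi = min(int(np.ceil((cy + r) / h)) + 1, ny)
    klo = max(int(np.floor((cz - r) / h)) - 1, 0)
    khi = min(int(np.ceil((cz + r) / h)) + 1, nz)
    if ilo >= ihi or jlo >= jhi or klo >= khi:
        raise ValueError("cancer sphere lies outside the grid")

    ii, jj, kk = np.meshgrid(
        np.arange(ilo, ihi), np.arange(jlo, jhi), np.arange(klo, khi), indexing="ij"
    )
    xc = (ii + 0.5) * h
    yc = (jj + 0.5) * h
    zc = (kk + 0.5) * h
    inside = (xc - cx) ** 2 + (yc - cy) ** 2 + (zc - cz) ** 2 <= r * r
    if not inside.any():
        raise ValueError("cancer sphere covers no voxel centre; diameter too small for grid")

    sub = volume.labels[ilo:ihi, jlo:jhi, klo:khi]
    # sphere must not poke out of the grid
    touches_edge = (
        (cx - r < 0) or (cx + r > nx * h) or (cy - r < 0) or (cy + r > ny * h)
        or (cz + r > nz * h)
    )
    if touches_edge:
        raise ValueError("cancer sphere extends outside the grid")
    if (sub[inside] == int(TissueLabel.OUTSIDE)).any():
        raise ValueError("cancer sphere extends outside the tissue")

    out = volume.copy()
    region = out.labels[ilo:ihi, jlo:jhi, klo:khi]
    region[inside] = int(TissueLabel.CANCER)
    n_voxels = int(np.count_nonzero(inside))
    out.meta["cancer_voxels"] = n_voxels
    out.meta["cancer_spec"] = {
        "diameter_cm": spec.diameter,
        "depth_cm": spec.depth,
        "x_cm": spec.x,
        "y_cm": spec.y,
    }
    return out


def validate_volume(volume: LabelVolume) -> None:
    """Check the structural invariants every label volume must satisfy.

    * labels restricted to the five known codes;
    * voxel size positive (enforced at construction);
    * no cancer voxel face-adjacent to ambient air.
    """
    labs = volume.labels
    if labs.max(initial=0) > int(TissueLabel.CANCER):
        raise ValueError("unknown label codes present")
    cancer = labs == int(TissueLabel.CANCER)
    if cancer.any():
        outside = labs == int(TissueLabel.OUTSIDE)
        # pad so grid-boundary cancer voxels count as touching air
        outside = np.pad(outside, 1, constant_values=True)
        near_air = ndimage.binary_dilation(
            outside, structure=ndimage.generate_binary_structure(3, 1)
        )[1:-1, 1:-1, 1:-1]
        if (cancer & near_air).any():
            raise ValueError("cancer voxels touch the air boundary")


# ---------------------------------------------------------------------------
# volume I/O: NIfTI + JSON sidecar


def save_volume(volume: LabelVolume, path) -> None:
    """Write labels as integer NIfTI plus a ``.json`` sidecar with the label
    map, anchor and axis convention."""
    import nibabel as nib

    path = Path(path)
    h = volume.voxel_size
    img = nib.Nifti1Image(volume.labels.astype(np.uint8), np.diag([h, h, h, 1.0]))
    nib.save(img, path)
    sidecar = {
        "label_map": LABEL_NAMES,
        "voxel_size_cm": h,
        "anchor_voxel": list(volume.anchor),
        "axes": ["x_mediolateral", "y_slice", "z_depth"],
        "meta": _jsonable(volume.meta),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_volume(path) -> LabelVolume:
    import nibabel as nib

    path = Path(path)
    img = nib.load(path)
    labels = np.asarray(img.dataobj).astype(np.uint8)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        sc = json.loads(sidecar_path.read_text())
        voxel_size = float(sc["voxel_size_cm"])
        anchor = tuple(sc["anchor_voxel"])
        meta = sc.get("meta", {})
    else:
        voxel_size = float(img.header.get_zooms()[0])
        anchor = _find_apex(labels)
        meta = {}
    return LabelVolume(labels, voxel_size, anchor, meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
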