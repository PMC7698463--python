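"""Optical-property and fluorophore database.

Per-tissue absorption/scattering coefficients, anisotropy and refractive
index at the six discrete (band, role) wavelengths used by the simulator:

====  ==========  ========
band  excitation  emission
====  ==========  ========
VIS   488 nm      520 nm
NIR   780 nm      820 nm
SWIR  970 nm      1100 nm
====  ==========  ========

Values ship as a TSV data file so users can substitute literature values;
no spectral interpolation is attempted between the six points.  Anisotropy
g is not part of the published tissue table; the shipped file uses the
typical soft-tissue value g = 0.9 for every tissue and wavelength, and any
column of the file may be overridden by loading a custom table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .labels import TissueLabel, INTERIOR_TISSUES

BANDS = ("VIS", "NIR", "SWIR")
ROLES = ("excitation", "emission")

#: (band, role) -> wavelength in nm
WAVELENGTHS_NM = {
    ("VIS", "excitation"): 488,
    ("VIS", "emission"): 520,
    ("NIR", "excitation"): 780,
    ("NIR", "emission"): 820,
    ("SWIR", "excitation"): 970,
    ("SWIR", "emission"): 1100,
}


@dataclass(frozen=True)
class OpticalProperties:
    """Single-tissue optical parameters at one wavelength.

    mu_a, mu_s in cm^-1; g dimensionless in [-1, 1]; n >= 1.
    """

    mu_a: float
    mu_s: float
    g: float
    n: float

    def __post_init__(self):
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("mu_a and mu_s must be non-negative")
        if self.mu_a + self.mu_s <= 0:
            raise ValueError("mu_a + mu_s must be positive for interior tissue")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError("anisotropy g must lie in [-1, 1]")
        if not 1.0 <= self.n <= 2.0:
            raise ValueError("refractive index n must lie in [1, 2]")

    @property
    def mu_t(self) -> float:
        """Total attenuation coefficient mu_a + mu_s (cm^-1)."""
        return self.mu_a + self.mu_s


@dataclass(frozen=True)
class FluorophoreSpec:
    """Fluorescent probe: excitation/emission peaks, quantum yield and
    the probe absorption coefficient epsC = molar absorptivity x
    concentration (cm^-1) at the excitation peak."""

    name: str
    band: str
    lambda_ex: float
    lambda_em: float
    quantum_yield: float
    concentration: float
    epsC: float

    def __post_init__(self):
        if not 0.0 < self.quantum_yield <= 1.0:
            raise ValueError("quantum yield must be in (0, 1]")
        if self.epsC <= 0:
            raise ValueError("epsC must be positive")
        if self.lambda_em <= self.lambda_ex:
            raise ValueError("emission peak must be red of excitation peak")


def _data_path(name: str) -> Path:
    return Path(str(resources.files("voxfluor").joinpath("data", name)))


class OpticsTable:
    """(tissue, band, role) -> OpticalProperties lookup backed by a TSV file."""

    def __init__(self, frame: pd.DataFrame):
        required = {"band", "role", "wavelength_nm", "tissue", "mu_a", "mu_s", "g", "n"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"optical table missing columns: {sorted(missing)}")
        self.frame = frame.reset_index(drop=True)
        self._index: dict[tuple[str, str, str], OpticalProperties] = {}
        for row in self.frame.itertuples(index=False):
            key = (str(row.tissue).lower(), str(row.band).upper(), str(row.role).lower())
            self._index[key] = OpticalProperties(
                mu_a=float(row.mu_a), mu_s=float(row.mu_s), g=float(row.g), n=float(row.n)
            )

    @classmethod
    def default(cls) -> "OpticsTable":
        return cls.from_tsv(_data_path("optical_properties.tsv"))

    @classmethod
    def from_tsv(cls, path) -> "OpticsTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def get(self, tissue, band: str, role: str) -> OpticalProperties:
        """Look up the optical properties of one tissue at one (band, role).

        ``tissue`` may be a :class:`TissueLabel` or its lower-case name.
        Ambient air (``outside``) has no table entry: it is handled by the
        transport engine, not the optics table.
        """
        if isinstance(tissue, TissueLabel):
            if tissue == TissueLabel.OUTSIDE:
                raise KeyError(
                    "tissue 'outside' is the non-scattering ambient and has no "
                    "optical-table entry"
                )
            tname = tissue.name.lower()
        else:
            tname = str(tissue).lower()
            if tname == "outside":
                raise KeyError(
                    "tissue 'outside' is the non-scattering ambient and has no "
                    "optical-table entry"
                )
        key = (tname, str(band).upper(), str(role).lower())
        try:
            return self._index[key]
        except KeyError:
            raise KeyError(
                f"no optical properties for tissue={key[0]!r}, band={key[1]!r}, "
                f"role={key[2]!r}"
            ) from None

    def property_arrays(self, band: str, role: str):
        """Per-label property vectors indexed by TissueLabel code.

        Returns (mu_a, mu_s, g, n) float64 arrays of length 5; index 0
        (outside) is filled with zeros / n = 1 and must never be consulted
        for scattering.  This is the layout the transport kernel consumes.
        """
        mu_a = np.zeros(5)
        mu_s = np.zeros(5)
        g = np.zeros(5)
        n = np.ones(5)
        for t in INTERIOR_TISSUES:
            p = self.get(t, band, role)
            mu_a[int(t)] = p.mu_a
            mu_s[int(t)] = p.mu_s
            g[int(t)] = p.g
            n[int(t)] = p.n
        return mu_a, mu_s, g, n


class FluorophoreTable:
    """Band -> FluorophoreSpec lookup backed by a TSV file."""

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame.reset_index(drop=True)
        self._index: dict[str, FluorophoreSpec] = {}
        for row in self.frame.itertuples(index=False):
            spec = FluorophoreSpec(
                name=str(row.name),
                band=str(row.band).upper(),
                lambda_ex=float(row.ex_nm),
                lambda_em=float(row.em_nm),
                quantum_yield=float(row.qy),
                concentration=float(row.conc_molar),
                epsC=float(row.epsC),
            )
            self._index[spec.band] = spec

    @classmethod
    def default(cls) -> "FluorophoreTable":
        return cls.from_tsv(_data_path("fluorophores.tsv"))

    @classmethod
    def from_tsv(cls, path) -> "FluorophoreTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def get(self, band: str) -> FluorophoreSpec:
        key = str(band).upper()
        try:
            return self._index[key]
        except KeyError:
            raise KeyError(f"no fluorophore registered for band {band!r}") from None


_DEFAULT_OPTICS: OpticsTable | None = None
_DEFAULT_FLUOROPHORES: FluorophoreTable | None = None


def default_optics() -> OpticsTable:
    global _DEFAULT_OPTICS
    if _DEFAULT_OPTICS is None:
        _DEFAULT_OPTICS = OpticsTable.default()
    return _DEFAULT_OPTICS


def get_tissue_optics(tissue, band: str, role: str) -> OpticalProperties:
    """Module-level convenience over the shipped optical table."""
    return default_optics().get(tissue, band, role)


def get_fluorophore(band: str) -> FluorophoreSpec:
    """Fluorophore used in each band: fluorescein (VIS), indocyanine green
    (NIR), PbS quantum dots (SWIR)."""
    global _DEFAULT_FLUOROPHORES
    if _DEFAULT_FLUOROPHORES is None:
        _DEFAULT_FLUOROPHORES = FluorophoreTable.default()
    return _DEFAULT_FLUOROPHORES.get(band)
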