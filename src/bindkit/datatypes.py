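"""Shared domain containers.

Every quantity is stored in SI-consistent internal units: concentrations in
mol/L, temperatures in kelvin, times in seconds.  Microolar and Celsius values
are accepted only at the I/O boundary (:mod:`bindkit.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    DuplicateConcentrationError,
    MissingZeroConcentrationError,
    ValidationError,
)

__all__ = [
    "TitrationSeries",
    "SpectralScan",
    "ViscosityRecord",
    "JobRecord",
    "OrbitalEnergies",
    "MoleculeProperties",
    "SAMPLE_TYPES",
]

SAMPLE_TYPES = ("buffer", "dna_only", "complex")


@dataclass(frozen=True)
class TitrationSeries:
    """One quencher-concentration vs signal curve at fixed temperature.

    The first point must be at exactly zero quencher concentration; its signal
    defines F0, the unquenched reference intensity.  F0 is never estimated by
    extrapolation.

    Parameters
    ----------
    series_id : str
        Label identifying the macromolecule/experiment (e.g. ``"BSA"``).
    temperature : float
        Temperature in kelvin.
    quencher_conc : array-like of float
        Quencher (ligand) concentrations in mol/L, strictly increasing,
        starting at exactly 0.
    signal : array-like of float
        Fluorescence (or absorbance) intensities, arbitrary units, all > 0.
    macromolecule_conc : float, optional
        Fixed macromolecule concentration in mol/L.
    excitation_nm, emission_nm : float, optional
        Instrument wavelengths, for bookkeeping only.
    """

    series_id: str
    temperature: float
    quencher_conc: np.ndarray
    signal: np.ndarray
    macromolecule_conc: float | None = None
    excitation_nm: float | None = None
    emission_nm: float | None = None

    def __post_init__(self) -> None:
        q = np.asarray(self.quencher_conc, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "quencher_conc", q)
        object.__setattr__(self, "signal", s)
        if q.ndim != 1 or s.ndim != 1 or q.size != s.size:
            raise ValidationError(
                f"series {self.series_id!r}: concentration and signal must be "
                f"1-D and equal length (got {q.size} and {s.size})"
            )
        if q.size < 4:
            raise ValidationError(
                f"series {self.series_id!r}: at least 4 points required, got {q.size}"
            )
        if np.unique(q).size != q.size:
            raise DuplicateConcentrationError(
                f"series {self.series_id!r}: duplicate quencher concentrations; "
                "replicates belong in separate series"
            )
        if np.any(np.diff(q) <= 0):
            raise ValidationError(
                f"series {self.series_id!r}: concentrations must be strictly increasing"
            )
        if q[0] != 0.0:
            raise MissingZeroConcentrationError(
                f"series {self.series_id!r}: first concentration must be exactly 0 "
                "(defines F0)"
            )
        if np.any(s <= 0) or not np.all(np.isfinite(s)):
            raise ValidationError(
                f"series {self.series_id!r}: all signals must be finite and > 0"
            )
        if self.temperature <= 0:
            raise ValidationError(
                f"series {self.series_id!r}: temperature must be positive kelvin"
            )

    @property
    def f0(self) -> float:
        """Unquenched reference intensity (signal at zero concentration)."""
        return float(self.signal[0])

    def __len__(self) -> int:
        return int(self.quencher_conc.size)


@dataclass(frozen=True)
class SpectralScan:
    """A wavelength scan of absorbance or emission intensity."""

    wavelength_nm: np.ndarray
    values: np.ndarray
    condition_label: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelength_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelength_nm", w)
        object.__setattr__(self, "values", v)
        if w.ndim != 1 or v.ndim != 1 or w.size != v.size:
            raise ValidationError("scan: wavelength and value arrays must match")
        if np.any(np.diff(w) <= 0):
            raise ValidationError("scan: wavelengths must be strictly increasing")

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.values))


@dataclass(frozen=True)
class ViscosityRecord:
    """One stopwatch flow-time measurement from an Ubbelohde viscometer."""

    sample_type: str
    ligand_to_dna_ratio: float
    flow_time_s: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValidationError(
                f"sample_type must be one of {SAMPLE_TYPES}, got {self.sample_type!r}"
            )
        if self.sample_type != "complex" and self.ligand_to_dna_ratio != 0:
            raise ValidationError(
                f"{self.sample_type} rows must have ligand_to_dna_ratio = 0"
            )
        if self.flow_time_s <= 0:
            raise ValidationError("flow_time_s must be > 0")
        if self.replicate < 1:
            raise ValidationError("replicate must be >= 1")


@dataclass(frozen=True)
class JobRecord:
    """One continuous-variation mixture at fixed total concentration."""

    mole_fraction_ligand: float
    absorbance_mix: float
    total_conc: float
    absorbance_ligand_only: float | None = None
    absorbance_macro_only: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.mole_fraction_ligand <= 1.0:
            raise ValidationError("mole_fraction_ligand must lie in [0, 1]")
        if self.total_conc <= 0:
            raise ValidationError("total_conc must be > 0")


@dataclass(frozen=True)
class OrbitalEnergies:
    """Frontier molecular-orbital energies of one compound, in eV."""

    compound_id: str
    e_homo: float
    e_lumo: float

    def __post_init__(self) -> None:
        if self.e_lumo < self.e_homo:
            raise ValidationError(
                f"{self.compound_id}: E_LUMO must not lie below E_HOMO"
            )


@dataclass(frozen=True)
class MoleculeProperties:
    """Physicochemical descriptors consumed by the rule-of-five evaluator.

    All values (MW, cLogP, TPSA, H-bond counts, rotatable bonds) are supplied
    inputs computed upstream; this package never computes them.
    """

    compound_id: str
    mw: float
    clogp: float
    tpsa: float
    n_hba: int
    n_hbd: int
    rotatable_bonds: int = 0

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValidationError(f"{self.compound_id}: mw must be > 0")
        if min(self.n_hba, self.n_hbd, self.rotatable_bonds) < 0:
            raise ValidationError(f"{self.compound_id}: counts must be >= 0")
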