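"""Delimited-text readers and writers.

All tables are comma- or tab-separated with a header row; the delimiter is
auto-detected.  Concentrations may be given in µM (``conc_uM``) or mol/L
(``conc_M``) and are converted to mol/L on read.  Temperatures are given in
°C and converted to kelvin.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    JobRecord,
    MoleculeProperties,
    OrbitalEnergies,
    TitrationSeries,
    ViscosityRecord,
)
from .exceptions import (
    MissingColumnError,
    NonNumericCellError,
    ValidationError,
)

__all__ = [
    "read_titration_table",
    "write_titration_table",
    "read_job_table",
    "read_viscosity_table",
    "read_orbital_table",
    "read_property_table",
    "celsius_to_kelvin",
]

log = logging.getLogger("bindkit")

CELSIUS_OFFSET = 273.15


def celsius_to_kelvin(t_c: float) -> float:
    return float(t_c) + CELSIUS_OFFSET


def _read_delimited(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", skipinitialspace=True)


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing column(s) {missing}")


def _numeric(df: pd.DataFrame, columns: list[str], path) -> pd.DataFrame:
    df = df.copy()
    for col in columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise NonNumericCellError(
                f"{path}: non-numeric value {df[col][row]!r} in column {col!r}, row {row}"
            )
        if converted.isna().any():
            raise NonNumericCellError(f"{path}: empty cell in column {col!r}")
        df[col] = converted
    return df


def read_titration_table(path: str | Path, unit_hint: str | None = None) -> list[TitrationSeries]:
    """Read one or more titration series from a delimited file.

    Expected columns: ``series_id, temperature_C, conc_uM, signal`` (a
    ``conc_M`` column is accepted in place of ``conc_uM``).  Rows are grouped
    by ``(series_id, temperature_C)``, sorted by concentration and validated
    against the :class:`~bindkit.datatypes.TitrationSeries` invariants.

    Parameters
    ----------
    unit_hint : {"uM", "M", None}
        Force interpretation of a bare ``conc`` column; ignored when a
        unit-suffixed column is present.
    """
    df = _read_delimited(path)
    _require_columns(df, ["series_id", "temperature_C", "signal"], path)

    if "conc_uM" in df.columns:
        conc_col, scale = "conc_uM", 1e-6
    elif "conc_M" in df.columns:
        conc_col, scale = "conc_M", 1.0
    elif "conc" in df.columns and unit_hint in ("uM", "M"):
        conc_col, scale = "conc", (1e-6 if unit_hint == "uM" else 1.0)
    else:
        raise MissingColumnError(
            f"{path}: need a conc_uM or conc_M column (or conc with unit_hint)"
        )

    df = _numeric(df, ["temperature_C", conc_col, "signal"], path)

    out: list[TitrationSeries] = []
    for (sid, t_c), grp in df.groupby(["series_id", "temperature_C"], sort=True):
        grp = grp.sort_values(conc_col)
        out.append(
            TitrationSeries(
                series_id=str(sid),
                temperature=celsius_to_kelvin(t_c),
                quencher_conc=grp[conc_col].to_numpy() * scale,
                signal=grp["signal"].to_numpy(),
            )
        )
    log.debug("read %d titration series from %s", len(out), path)
    return out


def write_titration_table(series: list[TitrationSeries], path: str | Path) -> None:
    """Write titration series back to CSV at full double precision (conc in µM)."""
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "series_id": s.series_id,
                    "temperature_C": s.temperature - CELSIUS_OFFSET,
                    "conc_uM": s.quencher_conc * 1e6,
                    "signal": s.signal,
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False, float_format="%.17g")


def read_job_table(path: str | Path) -> list[JobRecord]:
    """Read continuous-variation records.

    Columns: ``mole_fraction_ligand, absorbance_mix, total_conc_uM`` with
    optional ``absorbance_ligand_only`` and ``absorbance_macro_only`` blanks.
    """
    df = _read_delimited(path)
    _require_columns(df, ["mole_fraction_ligand", "absorbance_mix", "total_conc_uM"], path)
    numeric = ["mole_fraction_ligand", "absorbance_mix", "total_conc_uM"]
    optional = [c for c in ("absorbance_ligand_only", "absorbance_macro_only") if c in df.columns]
    df = _numeric(df, numeric + optional, path)
    records = []
    for _, row in df.iterrows():
        records.append(
            JobRecord(
                mole_fraction_ligand=row["mole_fraction_ligand"],
                absorbance_mix=row["absorbance_mix"],
                total_conc=row["total_conc_uM"] * 1e-6,
                absorbance_ligand_only=row.get("absorbance_ligand_only"),
                absorbance_macro_only=row.get("absorbance_macro_only"),
            )
        )
    return records


def read_viscosity_table(path: str | Path) -> list[ViscosityRecord]:
    """Read viscometer flow times.

    Columns: ``sample_type, ligand_to_dna_ratio, flow_time_s, replicate``.
    """
    df = _read_delimited(path)
    _require_columns(df, ["sample_type", "ligand_to_dna_ratio", "flow_time_s", "replicate"], path)
    df = _numeric(df, ["ligand_to_dna_ratio", "flow_time_s", "replicate"], path)
    return [
        ViscosityRecord(
            sample_type=str(row["sample_type"]),
            ligand_to_dna_ratio=float(row["ligand_to_dna_ratio"]),
            flow_time_s=float(row["flow_time_s"]),
            replicate=int(row["replicate"]),
        )
        for _, row in df.iterrows()
    ]


def read_orbital_table(path: str | Path) -> list[OrbitalEnergies]:
    """Read frontier-orbital energies: columns ``compound, e_homo_ev, e_lumo_ev``."""
    df = _read_delimited(path)
    _require_columns(df, ["compound", "e_homo_ev", "e_lumo_ev"], path)
    df = _numeric(df, ["e_homo_ev", "e_lumo_ev"], path)
    return [
        OrbitalEnergies(str(r["compound"]), float(r["e_homo_ev"]), float(r["e_lumo_ev"]))
        for _, r in df.iterrows()
    ]


def read_property_table(path: str | Path) -> list[MoleculeProperties]:
    """Read molecular properties: columns ``compound, mw, clogp, tpsa, hba, hbd, rb``."""
    df = _read_delimited(path)
    _require_columns(df, ["compound", "mw", "clogp", "tpsa", "hba", "hbd"], path)
    numeric = ["mw", "clogp", "tpsa", "hba", "hbd"] + (["rb"] if "rb" in df.columns else [])
    df = _numeric(df, numeric, path)
    return [
        MoleculeProperties(
            compound_id=str(r["compound"]),
            mw=float(r["mw"]),
            clogp=float(r["clogp"]),
            tpsa=float(r["tpsa"]),
            n_hba=int(r["hba"]),
            n_hbd=int(r["hbd"]),
            rotatable_bonds=int(r["rb"]) if "rb" in df.columns else 0,
        )
        for _, r in df.iterrows()
    ]
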