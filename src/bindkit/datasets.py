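"""Bundled reference tables for the 2-aroyl-3-methylthiazolo[3,2-a]pyrimidine
series (compounds 4a-4h) characterized against ct-DNA and BSA.

These are published experimental/computed values consumed as inputs:
mm+ force-field frontier-orbital energies (4a-4g), Osiris-computed molecular
properties (4a-4h), and the fluorescence-derived binding constants of the
2,4-dichlorophenyl derivative 4g with BSA (25/30/35 °C) and ct-DNA (25 °C).
This package never computes orbital energies or cLogP/TPSA itself.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .datatypes import MoleculeProperties, OrbitalEnergies

__all__ = [
    "load_orbital_energies",
    "load_molecule_properties",
    "load_binding_constants",
]


def _data_path(name: str):
    return resources.files("bindkit.data").joinpath(name)


def load_orbital_energies() -> list[OrbitalEnergies]:
    """Frontier-orbital energies (eV) of compounds 4a-4g."""
    with resources.as_file(_data_path("orbital_energies.csv")) as p:
        df = pd.read_csv(p)
    return [
        OrbitalEnergies(str(r.compound), float(r.e_homo_ev), float(r.e_lumo_ev))
        for r in df.itertuples()
    ]


def load_molecule_properties() -> list[MoleculeProperties]:
    """Molecular weight, cLogP, TPSA and H-bond/rotor counts of 4a-4h."""
    with resources.as_file(_data_path("molecule_properties.csv")) as p:
        df = pd.read_csv(p)
    return [
        MoleculeProperties(
            compound_id=str(r.compound),
            mw=float(r.mw),
            clogp=float(r.clogp),
            tpsa=float(r.tpsa),
            n_hba=int(r.hba),
            n_hbd=int(r.hbd),
            rotatable_bonds=int(r.rb),
        )
        for r in df.itertuples()
    ]


def load_binding_constants() -> pd.DataFrame:
    """Reported Ksv, log Kb, Kb, n and ΔG° for 4g with BSA and ct-DNA.

    Columns: ``target, temperature_C, ksv, log_kb, kb, n, delta_g_kcal``.
    Note the printed log Kb / Kb / ΔG triplets are mutually inconsistent at
    the level of ~0.2 kcal/mol (rounding in the source data); comparisons
    against recomputed thermodynamics should use loose tolerances.
    """
    with resources.as_file(_data_path("binding_constants.csv")) as p:
        return pd.read_csv(p)
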