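"""Frontier-orbital reactivity descriptors and drug-likeness evaluation.

Within Koopmans' approximation the ionization potential and electron
affinity are IP = −E_HOMO and EA = −E_LUMO.  The conceptual-DFT global
reactivity descriptors follow:

* energy gap          ΔE = E_LUMO − E_HOMO = IP − EA
* chemical hardness   η = (IP − EA) / 2
* chemical softness   S = 1 / (2η)
* electronegativity   χ = (IP + EA) / 2
* chemical potential  µ = −(IP + EA) / 2
* electrophilicity    ω = µ² / (2η)

A smaller HOMO–LUMO gap means a more reactive (softer) molecule.

The rule-of-five evaluator counts violations of MW <= 500, cLogP <= 5,
H-bond acceptors <= 10, H-bond donors <= 5 (boundaries inclusive) and flags
TPSA > 140 Å² as predictive of poor passive absorption; all property values
are consumed as supplied inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datatypes import MoleculeProperties, OrbitalEnergies
from .exceptions import InsufficientDataError, ZeroHardnessError

__all__ = [
    "ReactivityDescriptors",
    "LipinskiReport",
    "descriptors_from_orbitals",
    "rank_reactivity",
    "lipinski_evaluate",
]

TPSA_LIMIT = 140.0
CLOGP_LIMIT = 5.0
MW_LIMIT = 500.0
HBA_LIMIT = 10
HBD_LIMIT = 5


@dataclass(frozen=True)
class ReactivityDescriptors:
    """Global reactivity descriptors of one compound (all energies in eV)."""

    compound_id: str
    delta_e: float
    ip: float
    ea: float
    hardness_eta: float
    softness_s: float
    electronegativity_chi: float
    chemical_potential_mu: float
    electrophilicity_omega: float

    def as_dict(self) -> dict:
        return {
            "compound": self.compound_id,
            "delta_e": self.delta_e,
            "ip": self.ip,
            "ea": self.ea,
            "hardness_eta": self.hardness_eta,
            "softness_s": self.softness_s,
            "electronegativity_chi": self.electronegativity_chi,
            "chemical_potential_mu": self.chemical_potential_mu,
            "electrophilicity_omega": self.electrophilicity_omega,
        }


@dataclass(frozen=True)
class LipinskiReport:
    """Rule-of-five evaluation of one compound."""

    compound_id: str
    violations: int
    violated_rules: tuple[str, ...]
    tpsa_flag: bool
    clogp_flag: bool
    orally_bioavailable_prediction: bool


def descriptors_from_orbitals(orbitals: OrbitalEnergies) -> ReactivityDescriptors:
    """Compute all eight global reactivity descriptors from E_HOMO/E_LUMO.

    Raises :class:`ZeroHardnessError` on a degenerate gap (E_HOMO = E_LUMO),
    where softness and electrophilicity are undefined.
    """
    ip = -orbitals.e_homo
    ea = -orbitals.e_lumo
    delta_e = ip - ea  # == e_lumo - e_homo
    if delta_e == 0:
        raise ZeroHardnessError(
            f"{orbitals.compound_id}: degenerate HOMO/LUMO gap; "
            "softness and electrophilicity undefined"
        )
    eta = delta_e / 2.0
    mu = -(ip + ea) / 2.0
    return ReactivityDescriptors(
        compound_id=orbitals.compound_id,
        delta_e=delta_e,
        ip=ip,
        ea=ea,
        hardness_eta=eta,
        softness_s=1.0 / (2.0 * eta),
        electronegativity_chi=(ip + ea) / 2.0,
        chemical_potential_mu=mu,
        electrophilicity_omega=mu**2 / (2.0 * eta),
    )


def rank_reactivity(descriptors: list[ReactivityDescriptors]) -> pd.DataFrame:
    """Rank compounds by HOMO–LUMO gap, smallest gap = most reactive.

    Returns a DataFrame sorted by ascending ΔE with a competition ``rank``
    column (ties share a rank) and ``most_reactive``/``least_reactive``
    boolean flags.  Input order does not affect the ranking.
    """
    if len(descriptors) < 2:
        raise InsufficientDataError("ranking needs at least 2 compounds")
    df = pd.DataFrame(
        {"compound": [d.compound_id for d in descriptors],
         "delta_e": [d.delta_e for d in descriptors]}
    ).sort_values(["delta_e", "compound"], kind="stable").reset_index(drop=True)
    df["rank"] = df["delta_e"].rank(method="min").astype(int)
    df["most_reactive"] = df["rank"] == df["rank"].min()
    df["least_reactive"] = df["rank"] == df["rank"].max()
    return df


def lipinski_evaluate(props: MoleculeProperties) -> LipinskiReport:
    """Evaluate the rule of five (plus the TPSA absorption flag).

    A compound is predicted orally bioavailable when it has at most one
    rule-of-five violation and TPSA <= 140 Å².
    """
    violated = []
    if props.mw > MW_LIMIT:
        violated.append(f"MW {props.mw:g} > {MW_LIMIT:g}")
    if props.clogp > CLOGP_LIMIT:
        violated.append(f"cLogP {props.clogp:g} > {CLOGP_LIMIT:g}")
    if props.n_hba > HBA_LIMIT:
        violated.append(f"HBA {props.n_hba} > {HBA_LIMIT}")
    if props.n_hbd > HBD_LIMIT:
        violated.append(f"HBD {props.n_hbd} > {HBD_LIMIT}")
    tpsa_flag = props.tpsa > TPSA_LIMIT
    return LipinskiReport(
        compound_id=props.compound_id,
        violations=len(violated),
        violated_rules=tuple(violated),
        tpsa_flag=tpsa_flag,
        clogp_flag=props.clogp > CLOGP_LIMIT,
        orally_bioavailable_prediction=len(violated) <= 1 and not tpsa_flag,
    )
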