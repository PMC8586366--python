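"""Sample-preparation arithmetic: Beer–Lambert concentration and purity ratio."""

from __future__ import annotations

from typing import NamedTuple

from .exceptions import ParameterError

__all__ = ["concentration_from_absorbance", "purity_ratio", "PurityCheck"]


def concentration_from_absorbance(
    absorbance: float, epsilon: float = 6600.0, path_cm: float = 1.0
) -> float:
    """Concentration in mol/L from Beer–Lambert's law, c = A / (ε l).

    Parameters
    ----------
    absorbance : float
        Measured absorbance (dimensionless), >= 0.
    epsilon : float
        Molar extinction coefficient in L mol^-1 cm^-1.  The default is the
        260 nm coefficient of an isolated ct-DNA strand.
    path_cm : float
        Optical path length in cm.
    """
    if absorbance < 0:
        raise ParameterError("absorbance must be >= 0")
    if epsilon <= 0 or path_cm <= 0:
        raise ParameterError("epsilon and path length must be > 0")
    return absorbance / (epsilon * path_cm)


class PurityCheck(NamedTuple):
    ratio: float
    passed: bool


def purity_ratio(
    a260: float, a280: float, window: tuple[float, float] = (1.8, 1.9)
) -> PurityCheck:
    """A260/A280 attenuance ratio and whether it falls in the protein-free window.

    Nucleic acid free of protein contamination shows a ratio in roughly
    1.8–1.9; a lower ratio indicates aromatic amino-acid absorbance at 280 nm.
    """
    if a280 <= 0:
        raise ZeroDivisionError("a280 must be > 0 to form the ratio")
    ratio = a260 / a280
    lo, hi = window
    return PurityCheck(ratio=ratio, passed=bool(lo <= ratio <= hi))
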