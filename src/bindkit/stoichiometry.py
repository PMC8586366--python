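"""Job's method of continuous variation.

Mixtures of ligand and macromolecule are prepared at a fixed total
concentration while the ligand mole fraction x sweeps (0, 1).  The corrected
absorbance — the measured mixture absorbance minus the mole-fraction-weighted
free-component absorbances — is proportional to the complex concentration and
peaks at x = m/(m+n) for an m:n (ligand:macromolecule) complex; a maximum at
0.5 therefore indicates 1:1 binding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import JobRecord
from .exceptions import InsufficientDataError, ParameterError, ValidationError

__all__ = [
    "JobCurve",
    "JobMaximum",
    "StoichiometryResult",
    "JobAnalysis",
    "build_job_curve",
    "job_maximum",
    "stoichiometry_from_xmax",
]

MAX_RATIO = 3  # continuous variation cannot resolve ratios above ~3 on coarse grids


@dataclass(frozen=True)
class JobCurve:
    """Corrected absorbance vs ligand mole fraction, sorted by mole fraction."""

    mole_fractions: np.ndarray
    corrected_absorbance: np.ndarray
    blank_corrected: bool = False

    def __post_init__(self) -> None:
        x = np.asarray(self.mole_fractions, dtype=float)
        y = np.asarray(self.corrected_absorbance, dtype=float)
        object.__setattr__(self, "mole_fractions", x)
        object.__setattr__(self, "corrected_absorbance", y)
        if x.size != y.size:
            raise ValidationError("curve arrays must have equal length")
        if np.any(np.diff(x) <= 0):
            raise ValidationError("mole fractions must be strictly increasing")

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.mole_fractions, self.corrected_absorbance, "o-")
        ax.set_xlabel("mole fraction of ligand")
        ax.set_ylabel("corrected absorbance")
        return ax


@dataclass(frozen=True)
class JobMaximum:
    """Location of the Job-curve maximum."""

    x_max: float
    method: str  # "argmax" or "quadratic"
    boundary: bool = False
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class StoichiometryResult:
    """Small-integer ligand:macromolecule ratio snapped from x_max."""

    x_max: float
    x_max_method: str
    ratio_ligand: int | None
    ratio_macromolecule: int | None
    residual: float
    determinate: bool

    def __str__(self) -> str:
        if not self.determinate:
            return f"x_max = {self.x_max:.3f}: indeterminate stoichiometry"
        return (
            f"x_max = {self.x_max:.3f}: {self.ratio_ligand}:{self.ratio_macromolecule} "
            f"(residual {self.residual:.3f})"
        )


def build_job_curve(records: list[JobRecord]) -> JobCurve:
    """Assemble a corrected-absorbance curve from continuous-variation records.

    When both component blanks are supplied, corrected absorbance is
    ``A_mix − (1−x)·A_macro_only − x·A_ligand_only``; otherwise the mixture
    absorbances are taken as already corrected.
    """
    if len(records) < 5:
        raise InsufficientDataError("at least 5 continuous-variation records required")
    totals = np.array([r.total_conc for r in records])
    ref = totals[0]
    if np.any(np.abs(totals - ref) > 1e-9 * abs(ref)):
        raise ValidationError(
            "total concentration must be constant across a continuous-variation set"
        )
    has_blanks = all(
        r.absorbance_ligand_only is not None
        and r.absorbance_macro_only is not None
        and np.isfinite([r.absorbance_ligand_only, r.absorbance_macro_only]).all()
        for r in records
    )
    recs = sorted(records, key=lambda r: r.mole_fraction_ligand)
    x = np.array([r.mole_fraction_ligand for r in recs])
    if has_blanks:
        y = np.array(
            [
                r.absorbance_mix
                - (1 - r.mole_fraction_ligand) * r.absorbance_macro_only
                - r.mole_fraction_ligand * r.absorbance_ligand_only
                for r in recs
            ]
        )
    else:
        y = np.array([r.absorbance_mix for r in recs])
    return JobCurve(x, y, blank_corrected=has_blanks)


def job_maximum(curve: JobCurve, method: str = "quadratic") -> JobMaximum:
    """Locate the maximum of a Job curve.

    ``argmax`` returns the grid maximizer.  ``quadratic`` (default) fits a
    parabola through the maximizer and its two neighbours and returns the
    vertex clipped to the neighbour interval — reading the maximum off a
    smooth curve rather than quantising it to the measurement grid.  A maximum on the grid
    boundary skips refinement and attaches a warning.
    """
    if method not in ("argmax", "quadratic"):
        raise ParameterError(f"unknown method {method!r}")
    x = curve.mole_fractions
    y = curve.corrected_absorbance
    if x.size < 5:
        raise InsufficientDataError("at least 5 points required to locate the maximum")
    i = int(np.argmax(y))
    if i in (0, x.size - 1):
        return JobMaximum(
            x_max=float(x[i]), method="argmax", boundary=True,
            warnings=("maximum on grid boundary; vertex refinement skipped",),
        )
    if method == "argmax":
        return JobMaximum(x_max=float(x[i]), method="argmax")
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a >= 0:
        # flat or locally convex triple: vertex undefined, keep the grid point
        return JobMaximum(
            x_max=float(x1), method="argmax",
            warnings=("no local curvature at maximizer; vertex refinement skipped",),
        )
    vertex = float(np.clip(-b / (2 * a), x0, x2))
    return JobMaximum(x_max=vertex, method="quadratic")


def stoichiometry_from_xmax(x_max: float, tolerance: float = 0.08) -> StoichiometryResult:
    """Snap a Job-curve maximum to a small-integer m:n ligand:macromolecule ratio.

    Searches all integer pairs 1 <= m, n <= 3 minimizing |x_max − m/(m+n)|;
    ties break toward the smallest m+n, then the smallest m.  The ratio is
    reported only if the residual is within ``tolerance``; otherwise the
    result is flagged indeterminate.
    """
    if not 0.0 < x_max < 1.0:
        raise ParameterError("x_max must lie strictly inside (0, 1)")
    best = None
    for m in range(1, MAX_RATIO + 1):
        for n in range(1, MAX_RATIO + 1):
            resid = abs(x_max - m / (m + n))
            key = (resid, m + n, m)
            if best is None or key < best[0]:
                best = (key, m, n)
    (resid, _, _), m, n = best
    if resid > tolerance:
        return StoichiometryResult(
            x_max=x_max, x_max_method="", ratio_ligand=None,
            ratio_macromolecule=None, residual=resid, determinate=False,
        )
    return StoichiometryResult(
        x_max=x_max, x_max_method="", ratio_ligand=m,
        ratio_macromolecule=n, residual=resid, determinate=True,
    )


class JobAnalysis:
    """End-to-end continuous-variation analysis of a record set.

    ``fit()`` builds the corrected curve, locates its maximum and snaps the
    stoichiometry; the returned :class:`StoichiometryResult` carries the
    locator method actually used.
    """

    def __init__(self, records: list[JobRecord], method: str = "quadratic",
                 tolerance: float = 0.08):
        self.records = records
        self.method = method
        self.tolerance = tolerance
        self.curve = build_job_curve(records)

    def fit(self) -> StoichiometryResult:
        peak = job_maximum(self.curve, method=self.method)
        result = stoichiometry_from_xmax(peak.x_max, tolerance=self.tolerance)
        return StoichiometryResult(
            x_max=result.x_max,
            x_max_method=peak.method,
            ratio_ligand=result.ratio_ligand,
            ratio_macromolecule=result.ratio_macromolecule,
            residual=result.residual,
            determinate=result.determinate,
        )
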