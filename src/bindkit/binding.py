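"""Binding-constant and thermodynamic analysis via the double-log plot.

For static quenching by complex formation, log10((F0−F)/F) = n log10[Q] +
log10 Kb: the slope of the double-log plot is the apparent number of binding
sites n and the intercept the base-10 log of the association constant Kb.
The standard Gibbs free energy of binding follows as ΔG° = −RT ln Kb.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log

import numpy as np
from scipy import stats

from .datatypes import TitrationSeries
from .exceptions import InsufficientDataError, ParameterError, ValidationError

__all__ = [
    "BindingSiteModel",
    "BindingSiteResults",
    "ThermodynamicSummary",
    "modified_stern_volmer_fit",
    "gibbs_free_energy",
    "affinity_trend",
    "thermodynamic_summary",
]


@dataclass(frozen=True)
class BindingSiteResults:
    """Double-log binding fit: log10 Kb, Kb and site number n with SEs.

    ``excluded_points`` lists (index, reason) for every titration point that
    could not enter the log-log regression: the zero-concentration reference
    and any non-quenched point with F >= F0.
    """

    log10_kb: float
    log10_kb_se: float
    kb: float
    n_sites: float
    n_sites_se: float
    r_squared: float
    temperature: float
    n_points_used: int
    excluded_points: tuple[tuple[int, str], ...] = ()

    def summary(self) -> str:
        lines = [
            "Double-log (modified Stern-Volmer) binding fit",
            "-" * 46,
            f"T (K)            {self.temperature:12.2f}",
            f"points used      {self.n_points_used:12d}",
            f"log10 Kb         {self.log10_kb:12.4f} +/- {self.log10_kb_se:.2g}",
            f"Kb (L/mol)       {self.kb:12.4g}",
            f"n sites          {self.n_sites:12.4f} +/- {self.n_sites_se:.2g}",
            f"R^2              {self.r_squared:12.6f}",
        ]
        for idx, reason in self.excluded_points:
            lines.append(f"excluded point {idx}: {reason}")
        return "\n".join(lines)


class BindingSiteModel:
    """OLS of log10((F0−F)/F) on log10[Q] for one titration series."""

    def __init__(self, series: TitrationSeries):
        self.series = series

    def _eligible(self):
        q = self.series.quencher_conc
        f = self.series.signal
        f0 = self.series.f0
        excluded: list[tuple[int, str]] = []
        keep = []
        for i in range(len(q)):
            if q[i] <= 0:
                excluded.append((i, "zero-concentration reference point"))
            elif f[i] >= f0:
                excluded.append((i, "non-quenched point (F >= F0)"))
            else:
                keep.append(i)
        return np.asarray(keep, dtype=int), tuple(excluded)

    def fit(self) -> BindingSiteResults:
        keep, excluded = self._eligible()
        if keep.size < 3:
            raise InsufficientDataError(
                f"series {self.series.series_id!r}: only {keep.size} eligible "
                "points for the double-log fit (need >= 3)"
            )
        q = self.series.quencher_conc[keep]
        f = self.series.signal[keep]
        f0 = self.series.f0
        x = np.log10(q)
        y = np.log10((f0 - f) / f)
        res = stats.linregress(x, y)
        log10_kb = float(res.intercept)
        return BindingSiteResults(
            log10_kb=log10_kb,
            log10_kb_se=float(res.intercept_stderr),
            kb=10.0 ** log10_kb,
            n_sites=float(res.slope),
            n_sites_se=float(res.stderr),
            r_squared=float(res.rvalue) ** 2,
            temperature=self.series.temperature,
            n_points_used=int(keep.size),
            excluded_points=excluded,
        )

    def plot(self, results: BindingSiteResults | None = None, ax=None):
        """Double-log scatter with the fitted line."""
        import matplotlib.pyplot as plt

        if results is None:
            results = self.fit()
        keep, _ = self._eligible()
        q = self.series.quencher_conc[keep]
        f = self.series.signal[keep]
        x = np.log10(q)
        y = np.log10((self.series.f0 - f) / f)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(x, y, "o", label="data")
        xf = np.linspace(x.min(), x.max(), 50)
        ax.plot(xf, results.log10_kb + results.n_sites * xf, "-",
                label=f"n = {results.n_sites:.2f}, log Kb = {results.log10_kb:.2f}")
        ax.set_xlabel("log10 [Q]")
        ax.set_ylabel("log10 (F0 - F)/F")
        ax.legend()
        return ax


def modified_stern_volmer_fit(series: TitrationSeries) -> BindingSiteResults:
    """Functional wrapper: ``BindingSiteModel(series).fit()``."""
    return BindingSiteModel(series).fit()


def gibbs_free_energy(
    kb: float, temperature: float, gas_constant_kcal: float = 1.9872e-3
) -> float:
    """Standard Gibbs free energy of binding, ΔG° = −RT ln Kb, in kcal/mol.

    Negative ΔG° (any Kb > 1 L/mol) means spontaneous binding.
    """
    if kb <= 0:
        raise ParameterError("kb must be > 0")
    if temperature <= 0:
        raise ParameterError("temperature must be positive kelvin")
    if gas_constant_kcal <= 0:
        raise ParameterError("gas constant must be > 0")
    return -gas_constant_kcal * temperature * log(kb)


def affinity_trend(results: list[BindingSiteResults]) -> str:
    """Direction of the binding affinity across temperature.

    Returns ``"decreasing"`` iff Kb strictly decreases with temperature,
    ``"increasing"`` iff it strictly increases, else ``"flat"``.
    """
    if len(results) < 2:
        raise InsufficientDataError("affinity trend needs results at >= 2 temperatures")
    temps = [r.temperature for r in results]
    if any(b <= a for a, b in zip(temps, temps[1:])):
        raise ValidationError("results must be ordered by strictly increasing temperature")
    kb = [r.kb for r in results]
    if all(b < a for a, b in zip(kb, kb[1:])):
        return "decreasing"
    if all(b > a for a, b in zip(kb, kb[1:])):
        return "increasing"
    return "flat"


@dataclass(frozen=True)
class ThermodynamicSummary:
    """Per-temperature ΔG° with spontaneity flags and the affinity trend."""

    temperatures: tuple[float, ...]
    delta_g_kcal: tuple[float, ...]
    spontaneous: tuple[bool, ...]
    affinity_trend: str
    gas_constant_kcal: float

    def summary(self) -> str:
        lines = ["Binding thermodynamics", "-" * 40,
                 f"{'T (K)':>10} {'dG (kcal/mol)':>15} {'spontaneous':>12}"]
        for t, g, s in zip(self.temperatures, self.delta_g_kcal, self.spontaneous):
            lines.append(f"{t:10.2f} {g:15.3f} {str(s):>12}")
        lines.append(f"affinity trend with temperature: {self.affinity_trend}")
        return "\n".join(lines)


def thermodynamic_summary(
    results: list[BindingSiteResults], gas_constant_kcal: float = 1.9872e-3
) -> ThermodynamicSummary:
    """Assemble ΔG°, spontaneity and trend from binding fits at several temperatures."""
    dg = tuple(
        gibbs_free_energy(r.kb, r.temperature, gas_constant_kcal) for r in results
    )
    trend = affinity_trend(results) if len(results) >= 2 else "flat"
    return ThermodynamicSummary(
        temperatures=tuple(r.temperature for r in results),
        delta_g_kcal=dg,
        spontaneous=tuple(g < 0 for g in dg),
        affinity_trend=trend,
        gas_constant_kcal=gas_constant_kcal,
    )
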