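"""Stern–Volmer analysis of fluorescence quenching titrations.

The Stern–Volmer relation, F0/F = 1 + Ksv[Q] = 1 + Kq τ0 [Q], links the
ratio of unquenched to quenched fluorescence to quencher concentration.
The slope Ksv (L mol^-1) measures quenching efficiency; dividing by the
unquenched lifetime τ0 gives the bimolecular quenching constant Kq
(L mol^-1 s^-1).  Kq far above the diffusion-controlled limit
(~1e10 L mol^-1 s^-1) implies ground-state complex formation (static
quenching); Ksv rising with temperature implies collisional (dynamic)
quenching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datatypes import TitrationSeries
from .exceptions import ParameterError, ValidationError

__all__ = [
    "SternVolmerModel",
    "SternVolmerResults",
    "QuenchingClassification",
    "stern_volmer_fit",
    "quenching_constant",
    "classify_quenching",
]


@dataclass(frozen=True)
class SternVolmerResults:
    """Fitted Stern–Volmer parameters for one titration series.

    ``kq = ksv / tau0`` holds exactly by construction.  ``r_squared`` is NaN
    and ``degenerate`` True when the series shows no quenching at all.
    """

    ksv: float
    ksv_se: float
    intercept: float
    intercept_se: float
    kq: float
    r_squared: float
    temperature: float
    n_points: int
    tau0_s: float
    warnings: tuple[str, ...] = ()
    degenerate: bool = False

    def summary(self) -> str:
        lines = [
            "Stern-Volmer quenching fit",
            "-" * 42,
            f"T (K)            {self.temperature:12.2f}",
            f"n points         {self.n_points:12d}",
            f"Ksv (L/mol)      {self.ksv:12.4g} +/- {self.ksv_se:.2g}",
            f"intercept        {self.intercept:12.4f} +/- {self.intercept_se:.2g}",
            f"Kq (L/mol/s)     {self.kq:12.4g}",
            f"tau0 (s)         {self.tau0_s:12.3g}",
            f"R^2              {self.r_squared:12.6f}",
        ]
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the fitted F0/F vs [Q] line (requires the model's data)."""
        raise NotImplementedError(
            "plot lives on SternVolmerModel, which holds the data; "
            "use SternVolmerModel.plot(results)"
        )


class SternVolmerModel:
    """Ordinary least squares of F0/F against [Q] for one titration series.

    Parameters
    ----------
    series : TitrationSeries
        Validated titration; the zero-concentration point (y = 1 by
        construction) is a measured datum and is included in the regression.
    tau0_s : float
        Assumed unquenched fluorophore lifetime in seconds.
    """

    def __init__(self, series: TitrationSeries, tau0_s: float = 1e-8):
        if tau0_s <= 0:
            raise ParameterError("tau0_s must be > 0")
        self.series = series
        self.tau0_s = float(tau0_s)
        self.x = series.quencher_conc
        self.y = series.f0 / series.signal

    def fit(self) -> SternVolmerResults:
        x, y = self.x, self.y
        warnings: list[str] = []

        if np.allclose(self.series.signal, self.series.f0, rtol=0, atol=0):
            # No quenching anywhere: slope 0, r^2 undefined.
            return SternVolmerResults(
                ksv=0.0, ksv_se=0.0, intercept=1.0, intercept_se=0.0,
                kq=0.0, r_squared=float("nan"),
                temperature=self.series.temperature, n_points=len(x),
                tau0_s=self.tau0_s, warnings=("degenerate: constant signal",),
                degenerate=True,
            )

        res = stats.linregress(x, y)
        ksv = float(res.slope)
        intercept = float(res.intercept)
        if abs(intercept - 1.0) > 0.05:
            warnings.append(
                f"intercept {intercept:.4f} deviates from 1 by more than 0.05 "
                "(possible inner-filter artifact)"
            )
        self._curvature_check(x, y, warnings)
        return SternVolmerResults(
            ksv=ksv,
            ksv_se=float(res.stderr),
            intercept=intercept,
            intercept_se=float(res.intercept_stderr),
            kq=ksv / self.tau0_s,
            r_squared=float(res.rvalue) ** 2,
            temperature=self.series.temperature,
            n_points=len(x),
            tau0_s=self.tau0_s,
            warnings=tuple(warnings),
        )

    @staticmethod
    def _curvature_check(x, y, warnings: list[str]) -> None:
        """Diagnostic quadratic refit: upward curvature hints mixed quenching."""
        if len(x) < 4:
            return
        try:
            coefs, cov = np.polyfit(x, y, 2, cov=True)
        except (np.linalg.LinAlgError, ValueError):
            return
        a, a_var = coefs[0], cov[0, 0]
        if a_var > 0 and a > 0 and a / np.sqrt(a_var) > 2.0:
            warnings.append(
                "significant upward curvature in F0/F vs [Q] "
                "(possible mixed quenching)"
            )

    def plot(self, results: SternVolmerResults | None = None, ax=None):
        """Scatter F0/F vs [Q] with the fitted line overlaid."""
        import matplotlib.pyplot as plt

        if results is None:
            results = self.fit()
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.x * 1e6, self.y, "o", label="data")
        xf = np.linspace(self.x.min(), self.x.max(), 100)
        ax.plot(xf * 1e6, results.intercept + results.ksv * xf, "-",
                label=f"Ksv = {results.ksv:.3g} L/mol")
        ax.set_xlabel("[Q] (µM)")
        ax.set_ylabel("F0/F")
        ax.legend()
        return ax


def stern_volmer_fit(series: TitrationSeries, tau0: float = 1e-8) -> SternVolmerResults:
    """Functional wrapper: ``SternVolmerModel(series, tau0).fit()``."""
    return SternVolmerModel(series, tau0).fit()


def quenching_constant(ksv: float, tau0: float) -> float:
    """Bimolecular quenching constant Kq = Ksv / τ0 (L mol^-1 s^-1)."""
    if tau0 <= 0:
        raise ParameterError("tau0 must be > 0")
    return ksv / tau0


@dataclass(frozen=True)
class QuenchingClassification:
    """Rule-based quenching-mechanism verdict with evidence trail."""

    mechanism: str  # static | dynamic | mixed | indeterminate
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mechanism not in ("static", "dynamic", "mixed", "indeterminate"):
            raise ValidationError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism != "indeterminate" and not self.reasons:
            raise ValidationError("reasons required for a definite mechanism")


def classify_quenching(
    results: list[SternVolmerResults], diffusion_limit: float = 1e10
) -> QuenchingClassification:
    """Classify the quenching mechanism from fits at one or more temperatures.

    Rules (evaluated in order):

    * **static** — every Kq exceeds the diffusion limit, and Ksv is
      non-increasing with temperature (a single temperature suffices);
      ground-state complexation is slower at higher T.
    * **dynamic** — Ksv strictly increases with temperature and every Kq is
      within 2x the diffusion limit; collisions intensify with T.
    * **mixed** — Kq above the limit yet Ksv rising.
    * **indeterminate** — anything else (including a single sub-limit Kq,
      which is necessary but not sufficient evidence for dynamic quenching).

    Ties or plateaus in the temperature trend count as non-increasing, so
    measurement noise does not flip a static call.
    """
    if not results:
        raise ValidationError("at least one Stern-Volmer result required")
    temps = [r.temperature for r in results]
    if len(temps) > 1 and any(b <= a for a, b in zip(temps, temps[1:])):
        raise ValidationError("results must be ordered by strictly increasing temperature")

    ksv = [r.ksv for r in results]
    kq = [r.kq for r in results]
    all_above = all(k > diffusion_limit for k in kq)
    all_within_2x = all(k <= 2 * diffusion_limit for k in kq)
    non_increasing = all(b <= a for a, b in zip(ksv, ksv[1:]))
    strictly_increasing = len(ksv) > 1 and all(b > a for a, b in zip(ksv, ksv[1:]))

    reasons: list[str] = []
    if all_above:
        reasons.append(
            f"every Kq exceeds the diffusion limit {diffusion_limit:.2g} L/mol/s"
        )
        if non_increasing:
            if len(ksv) > 1:
                reasons.append("Ksv is non-increasing with temperature")
            return QuenchingClassification("static", tuple(reasons))
        if strictly_increasing:
            reasons.append("but Ksv increases with temperature")
            return QuenchingClassification("mixed", tuple(reasons))
        reasons.append("temperature trend of Ksv is neither monotone direction")
        return QuenchingClassification("indeterminate", tuple(reasons))
    if strictly_increasing and all_within_2x:
        reasons.append("Ksv strictly increases with temperature")
        reasons.append("every Kq is within 2x the diffusion limit")
        return QuenchingClassification("dynamic", tuple(reasons))
    reasons.append(
        "at least one Kq is at or below the diffusion limit; "
        "insufficient evidence for a static mechanism"
    )
    return QuenchingClassification("indeterminate", tuple(reasons))
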