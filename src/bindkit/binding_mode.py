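"""Binding-mode evidence analysis: groove binding vs intercalation.

Four independent lines of evidence are quantified and then combined by a
conservative voting rule:

* **UV–visible shift** — hyperchromism or a red shift of the macromolecule
  band on ligand addition points to groove binding; hypochromism or a blue
  shift points to intercalation.
* **Competitive dye displacement** — displacement of Hoechst 33258 (a minor
  groove binder) implies the ligand competes for the groove; displacement of
  ethidium bromide (an intercalator) implies intercalation.
* **Relative viscosity** — intercalation lengthens the DNA helix and raises
  (η/η0)^(1/3) with the mixing ratio; groove binders leave it flat.
* **Circular dichroism** (optional boolean) — unperturbed base-stacking and
  helicity bands are consistent with groove binding.

A verdict of groove (or intercalative) requires at least two concordant
votes and no dissenting vote.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import SpectralScan, TitrationSeries, ViscosityRecord
from .exceptions import (
    BoundaryPeakError,
    DegenerateSolventError,
    InsufficientEvidenceError,
    ParameterError,
    ValidationError,
)

__all__ = [
    "ShiftAssessment",
    "DisplacementResult",
    "ViscosityProfile",
    "ViscosityAssay",
    "BindingModeVerdict",
    "assess_absorbance_shift",
    "displacement_analysis",
    "relative_viscosity",
    "viscosity_profile",
    "combine_evidence",
    "DYE_MODES",
]

DYE_MODES = {"ethidium_bromide": "intercalator", "hoechst_33258": "groove_binder"}


@dataclass(frozen=True)
class ShiftAssessment:
    """Peak intensity/position change of a macromolecule band on ligand binding."""

    intensity_change: str  # hyperchromic | hypochromic | none
    wavelength_shift: str  # red | blue | none
    delta_intensity_fraction: float
    delta_lambda_nm: float
    mode_hint: str  # groove | intercalative | none


@dataclass(frozen=True)
class DisplacementResult:
    """Outcome of a competitive dye-displacement titration."""

    dye: str
    max_fractional_decrease: float
    displaced: bool
    dye_mode: str

    def __post_init__(self) -> None:
        if self.dye not in DYE_MODES:
            raise ValidationError(f"unknown dye {self.dye!r}")
        if self.dye_mode != DYE_MODES[self.dye]:
            raise ValidationError(
                f"dye_mode for {self.dye} must be {DYE_MODES[self.dye]!r}"
            )


@dataclass(frozen=True)
class ViscosityProfile:
    """Cube-root relative viscosity vs mixing ratio with its fitted slope."""

    ratios: np.ndarray
    relative_viscosity: np.ndarray
    cube_roots: np.ndarray
    slope: float
    slope_se: float
    classification: str  # groove_consistent | intercalative | indeterminate

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.ratios, self.cube_roots, "o-")
        ax.set_xlabel("[ligand]/[DNA]")
        ax.set_ylabel(r"$(\eta/\eta_0)^{1/3}$")
        ax.set_title(self.classification)
        return ax


@dataclass(frozen=True)
class BindingModeVerdict:
    """Combined groove/intercalative verdict with the per-source vote map."""

    verdict: str  # groove | intercalative | indeterminate
    votes: dict
    rationale: tuple[str, ...]


def assess_absorbance_shift(
    free: SpectralScan,
    bound: SpectralScan,
    intensity_threshold: float = 0.02,
    shift_threshold_nm: float = 1.0,
) -> ShiftAssessment:
    """Compare the absorption peak of the ligand-bound vs free macromolecule.

    Changes smaller than the thresholds (default 2% intensity, 1 nm) are
    classified as none.  Conflicting signals (e.g. hyperchromic with a blue
    shift) yield ``mode_hint = "none"``.
    """
    for scan, name in ((free, "free"), (bound, "bound")):
        i = scan.peak_index
        if i in (0, len(scan.wavelength_nm) - 1):
            raise BoundaryPeakError(
                f"{name} scan: absorption maximum on the range boundary"
            )
    pf = free.values[free.peak_index]
    pb = bound.values[bound.peak_index]
    d_int = (pb - pf) / pf
    d_lam = float(bound.wavelength_nm[bound.peak_index] - free.wavelength_nm[free.peak_index])

    if d_int > intensity_threshold:
        intensity = "hyperchromic"
    elif d_int < -intensity_threshold:
        intensity = "hypochromic"
    else:
        intensity = "none"
    if d_lam > shift_threshold_nm:
        shift = "red"
    elif d_lam < -shift_threshold_nm:
        shift = "blue"
    else:
        shift = "none"

    groove = intensity == "hyperchromic" or shift == "red"
    intercalative = intensity == "hypochromic" or shift == "blue"
    if groove and not intercalative:
        hint = "groove"
    elif intercalative and not groove:
        hint = "intercalative"
    else:
        hint = "none"
    return ShiftAssessment(
        intensity_change=intensity,
        wavelength_shift=shift,
        delta_intensity_fraction=float(d_int),
        delta_lambda_nm=d_lam,
        mode_hint=hint,
    )


def displacement_analysis(
    series: TitrationSeries, dye: str, threshold: float = 0.05
) -> DisplacementResult:
    """Judge whether a ligand displaces a DNA-bound reporter dye.

    The signal at zero ligand is the dye–DNA complex intensity.  Displacement
    requires both a maximum fractional intensity decrease of at least
    ``threshold`` and a monotone-decreasing trend (negative Spearman rank
    correlation of signal with concentration) — a single-point dip does not
    count.
    """
    if dye not in DYE_MODES:
        raise ValidationError(f"unknown dye {dye!r}; choose from {sorted(DYE_MODES)}")
    f0 = series.f0
    decrease = float((f0 - series.signal.min()) / f0)
    monotone = False
    if np.unique(series.signal).size > 1:
        rho = stats.spearmanr(series.quencher_conc, series.signal).statistic
        monotone = bool(np.isfinite(rho) and rho < 0)
    return DisplacementResult(
        dye=dye,
        max_fractional_decrease=decrease,
        displaced=bool(decrease >= threshold and monotone),
        dye_mode=DYE_MODES[dye],
    )


def relative_viscosity(t_complex: float, t_dna: float, t_buffer: float) -> float:
    """Relative viscosity η/η0 from viscometer flow times.

    η/η0 = ((t_complex − t0)/t0) / ((t_DNA − t0)/t0), which reduces to
    (t_complex − t_buffer)/(t_DNA − t_buffer).
    """
    if t_buffer <= 0:
        raise ParameterError("buffer flow time must be > 0")
    if t_dna <= t_buffer:
        raise DegenerateSolventError(
            "DNA flow time must exceed the buffer flow time"
        )
    if t_complex <= t_buffer:
        raise ParameterError("complex flow time must exceed the buffer flow time")
    return (t_complex - t_buffer) / (t_dna - t_buffer)


class ViscosityAssay:
    """Viscometric binding-mode assay over a ligand/DNA ratio series.

    Replicate flow times are averaged per sample; the slope of
    (η/η0)^(1/3) against mixing ratio is fitted by least squares.  When
    replicate scatter is available its standard deviation is propagated to
    the cube-root points by the delta method and used as weights.
    """

    def __init__(self, records: list[ViscosityRecord], slope_threshold: float = 0.05):
        self.records = records
        self.slope_threshold = float(slope_threshold)

    @staticmethod
    def _collect(records, sample_type, ratio=None):
        times = [
            r.flow_time_s
            for r in records
            if r.sample_type == sample_type
            and (ratio is None or r.ligand_to_dna_ratio == ratio)
        ]
        return np.asarray(times)

    def fit(self) -> ViscosityProfile:
        t_buf = self._collect(self.records, "buffer")
        t_dna = self._collect(self.records, "dna_only")
        if t_buf.size == 0 or t_dna.size == 0:
            raise ValidationError("buffer and dna_only rows are both required")
        ratios = sorted({r.ligand_to_dna_ratio for r in self.records if r.sample_type == "complex"})
        if len(ratios) < 3:
            raise ValidationError("at least 3 distinct ligand/DNA ratios required")

        tb, td = t_buf.mean(), t_dna.mean()
        rel, cube, cube_var = [], [], []
        denom = td - tb
        if denom <= 0:
            raise DegenerateSolventError("DNA flow time must exceed buffer flow time")
        for ratio in ratios:
            tc = self._collect(self.records, "complex", ratio)
            eta = relative_viscosity(tc.mean(), td, tb)
            rel.append(eta)
            root = eta ** (1.0 / 3.0)
            cube.append(root)
            # delta method: var((eta)^(1/3)) ≈ (root/(3 eta))^2 * var(eta)
            var_tc = tc.var(ddof=1) / tc.size if tc.size > 1 else 0.0
            var_eta = var_tc / denom**2
            cube_var.append((root / (3.0 * eta)) ** 2 * var_eta)

        ratios = np.asarray(ratios, dtype=float)
        cube = np.asarray(cube)
        cube_var = np.asarray(cube_var)

        if np.all(cube_var > 0):
            w = 1.0 / cube_var
            X = np.column_stack([np.ones_like(ratios), ratios])
            WX = X * w[:, None]
            beta, cov = _wls(X, WX, cube, w)
            slope, slope_se = float(beta[1]), float(np.sqrt(cov[1, 1]))
        else:
            res = stats.linregress(ratios, cube)
            slope, slope_se = float(res.slope), float(res.stderr)
            if not np.isfinite(slope_se):
                slope_se = 0.0

        if abs(slope) <= self.slope_threshold:
            label = "groove_consistent"
        elif slope > self.slope_threshold:
            label = "intercalative"
        else:
            label = "indeterminate"  # significantly negative slope is nonphysical
        return ViscosityProfile(
            ratios=ratios,
            relative_viscosity=np.asarray(rel),
            cube_roots=cube,
            slope=slope,
            slope_se=slope_se,
            classification=label,
        )


def _wls(X, WX, y, w):
    xtwx = X.T @ WX
    beta = np.linalg.solve(xtwx, WX.T @ y)
    cov = np.linalg.inv(xtwx)
    return beta, cov


def viscosity_profile(
    records: list[ViscosityRecord], slope_threshold: float = 0.05
) -> ViscosityProfile:
    """Functional wrapper: ``ViscosityAssay(records, slope_threshold).fit()``."""
    return ViscosityAssay(records, slope_threshold).fit()


def combine_evidence(
    shift: ShiftAssessment | None = None,
    displacements: list[DisplacementResult] = (),
    viscosity: ViscosityProfile | None = None,
    cd_bands_perturbed: bool | None = None,
) -> BindingModeVerdict:
    """Combine independent evidence into a groove/intercalation verdict.

    Each present source casts one vote (groove, intercalative, or none);
    the verdict is groove iff at least two groove votes and no intercalative
    vote were cast, symmetric for intercalative, else indeterminate.
    """
    votes: dict[str, str] = {}
    if shift is not None:
        votes["uv_shift"] = shift.mode_hint
    for d in displacements:
        if d.displaced:
            votes[d.dye] = "groove" if d.dye_mode == "groove_binder" else "intercalative"
        else:
            votes[d.dye] = "none"
    if viscosity is not None:
        votes["viscosity"] = {
            "groove_consistent": "groove",
            "intercalative": "intercalative",
            "indeterminate": "none",
        }[viscosity.classification]
    if cd_bands_perturbed is not None:
        votes["cd"] = "intercalative" if cd_bands_perturbed else "groove"

    if len(votes) < 2:
        raise InsufficientEvidenceError(
            "at least two evidence sources required for a verdict"
        )
    groove = sum(v == "groove" for v in votes.values())
    inter = sum(v == "intercalative" for v in votes.values())
    if groove >= 2 and inter == 0:
        verdict = "groove"
    elif inter >= 2 and groove == 0:
        verdict = "intercalative"
    else:
        verdict = "indeterminate"
    rationale = tuple(f"{src}: voted {v}" for src, v in votes.items())
    return BindingModeVerdict(verdict=verdict, votes=votes, rationale=rationale)
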