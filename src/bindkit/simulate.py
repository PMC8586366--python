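"""Seeded generators for every experimental input the pipeline consumes.

Each generator inverts the model its downstream analysis fits, so ground
truth is known exactly and noiseless generation followed by fitting is an
identity round trip.  Noise is multiplicative Gaussian, parameterized by a
coefficient of variation and truncated at ±4σ so signals stay positive; the
zero-concentration reference point is never noised, mirroring its role as
the exact F0 reference.  Every generator is a deterministic function of its
parameters including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import JobRecord, SpectralScan, TitrationSeries, ViscosityRecord
from .exceptions import ParameterError, ValidationError

__all__ = [
    "QuenchSimParams",
    "JobSimParams",
    "ViscSimParams",
    "simulate_static_quenching",
    "simulate_binding_site",
    "simulate_job",
    "simulate_viscosity",
    "simulate_displacement",
    "simulate_uv_titration",
    "complex_concentration_1to1",
]

# default concentration grid: 0-48 µM in 8 µM steps, the usual titration span
DEFAULT_GRID = tuple(np.arange(0.0, 48.1e-6, 8e-6))


def _truncated_noise(rng: np.random.Generator, n: int, max_sigma: float = 4.0) -> np.ndarray:
    """Standard normal draws redrawn until within ±max_sigma."""
    z = rng.standard_normal(n)
    bad = np.abs(z) > max_sigma
    while bad.any():
        z[bad] = rng.standard_normal(int(bad.sum()))
        bad = np.abs(z) > max_sigma
    return z


@dataclass(frozen=True)
class QuenchSimParams:
    """Parameters for a simulated quenching titration.

    Supply ``ksv_true`` for the linear static-quenching model, or
    ``kb_true``/``n_true`` for the multi-site binding model.
    """

    f0: float = 1000.0
    conc_grid: tuple = DEFAULT_GRID
    noise_cv: float = 0.02
    temperature: float = 298.15
    seed: int = 0
    ksv_true: float | None = None
    kb_true: float | None = None
    n_true: float | None = None
    series_id: str = "sim"

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ParameterError("f0 must be > 0")
        if self.noise_cv < 0:
            raise ParameterError("noise_cv must be >= 0")
        grid = tuple(float(c) for c in self.conc_grid)
        object.__setattr__(self, "conc_grid", grid)
        if not grid or grid[0] != 0.0:
            raise ParameterError("conc_grid must start at exactly 0")


@dataclass(frozen=True)
class JobSimParams:
    """Parameters for a simulated continuous-variation experiment."""

    k_assoc: float = 1e6
    total_conc: float = 20e-6
    stoichiometry: tuple[int, int] = (1, 1)  # (ligand m, macromolecule n)
    mole_fraction_grid: tuple = tuple(np.round(np.arange(0.1, 0.91, 0.1), 10))
    response_coefficient: float = 5e4  # absorbance per mol/L of complex
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_conc <= 0:
            raise ParameterError("total_conc must be > 0")
        if self.k_assoc < 0:
            raise ParameterError("k_assoc must be >= 0")
        if any(not 0.0 < x < 1.0 for x in self.mole_fraction_grid):
            raise ParameterError("mole fractions must lie strictly inside (0, 1)")
        m, n = self.stoichiometry
        if min(m, n) < 1:
            raise ParameterError("stoichiometry coefficients must be >= 1")


@dataclass(frozen=True)
class ViscSimParams:
    """Parameters for a simulated viscometric flow-time experiment."""

    mode: str = "groove"  # groove | intercalator
    cube_root_slope: float = 0.0
    ratio_grid: tuple = (0.2, 0.4, 0.6, 0.8, 1.0)
    t_buffer: float = 100.0
    t_dna: float = 150.0
    noise_cv: float = 0.0
    seed: int = 0
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.mode not in ("groove", "intercalator"):
            raise ParameterError("mode must be 'groove' or 'intercalator'")
        if self.t_dna <= self.t_buffer:
            raise ParameterError("t_dna must exceed t_buffer")
        if self.mode == "groove" and self.cube_root_slope != 0.0:
            raise ParameterError("groove mode implies cube_root_slope = 0")


def _apply_noise(signal: np.ndarray, cv: float, rng: np.random.Generator,
                 protect_first: bool = True) -> np.ndarray:
    if cv == 0:
        return signal.copy()
    out = signal * (1.0 + cv * _truncated_noise(rng, signal.size))
    if protect_first:
        out[0] = signal[0]
    return out


def simulate_static_quenching(params: QuenchSimParams) -> TitrationSeries:
    """Titration following F([Q]) = F0 / (1 + Ksv[Q]), the 1:1 static model."""
    if params.ksv_true is None:
        raise ParameterError("ksv_true required for static-quenching simulation")
    rng = np.random.default_rng(params.seed)
    q = np.asarray(params.conc_grid)
    f = params.f0 / (1.0 + params.ksv_true * q)
    return TitrationSeries(
        series_id=params.series_id,
        temperature=params.temperature,
        quencher_conc=q,
        signal=_apply_noise(f, params.noise_cv, rng),
    )


def simulate_binding_site(params: QuenchSimParams) -> TitrationSeries:
    """Titration following (F0−F)/F = Kb [Q]^n, i.e. F = F0/(1 + Kb [Q]^n).

    With n = 1 this reduces exactly to the static-quenching model with
    Ksv = Kb.
    """
    if params.kb_true is None or params.n_true is None:
        raise ParameterError("kb_true and n_true required for binding-site simulation")
    if params.kb_true <= 0 or params.n_true <= 0:
        raise ParameterError("kb_true and n_true must be > 0")
    rng = np.random.default_rng(params.seed)
    q = np.asarray(params.conc_grid)
    with np.errstate(divide="ignore"):
        f = params.f0 / (1.0 + params.kb_true * np.power(q, params.n_true))
    f[q == 0] = params.f0
    return TitrationSeries(
        series_id=params.series_id,
        temperature=params.temperature,
        quencher_conc=q,
        signal=_apply_noise(f, params.noise_cv, rng),
    )


def complex_concentration_1to1(ligand_total: float, macro_total: float,
                               k_assoc: float) -> float:
    """Equilibrium 1:1 complex concentration by mass action.

    Solves C² − (L + P + 1/K)·C + L·P = 0 for the physical (smaller) root.
    """
    if k_assoc <= 0:
        return 0.0
    b = ligand_total + macro_total + 1.0 / k_assoc
    disc = b * b - 4.0 * ligand_total * macro_total
    c = (b - np.sqrt(disc)) / 2.0
    upper = min(ligand_total, macro_total)
    if not -1e-15 <= c <= upper * (1 + 1e-9) + 1e-30:
        raise AssertionError("nonphysical equilibrium root")
    return float(min(max(c, 0.0), upper))


def simulate_job(params: JobSimParams) -> list[JobRecord]:
    """Continuous-variation records at fixed total concentration.

    For 1:1 stoichiometry the complex concentration solves the mass-action
    quadratic exactly; for general m:n the strong-binding limiting-reagent
    approximation min(L/m, P/n) is used (a documented limitation).  Corrected
    absorbance is ``response_coefficient × [complex]`` plus multiplicative
    noise; the blank-subtraction path is bypassed (records carry no blanks).
    """
    rng = np.random.default_rng(params.seed)
    m, n = params.stoichiometry
    xs = np.asarray(params.mole_fraction_grid)
    complexes = np.empty_like(xs)
    for i, x in enumerate(xs):
        lig = x * params.total_conc
        mac = (1.0 - x) * params.total_conc
        if (m, n) == (1, 1):
            complexes[i] = complex_concentration_1to1(lig, mac, params.k_assoc)
        else:
            complexes[i] = 0.0 if params.k_assoc == 0 else min(lig / m, mac / n)
    absorbance = params.response_coefficient * complexes
    absorbance = _apply_noise(absorbance, params.noise_cv, rng, protect_first=False)
    return [
        JobRecord(
            mole_fraction_ligand=float(x),
            absorbance_mix=float(a),
            total_conc=params.total_conc,
        )
        for x, a in zip(xs, absorbance)
    ]


def simulate_viscosity(params: ViscSimParams) -> list[ViscosityRecord]:
    """Flow-time records inverting the relative-viscosity relation.

    The target profile is (η/η0)^(1/3) = 1 + slope·ratio; complex flow times
    are back-computed as t = t_buffer + (η/η0)·(t_DNA − t_buffer).  Three
    replicates per sample, with multiplicative noise on each flow time.
    """
    rng = np.random.default_rng(params.seed)
    records: list[ViscosityRecord] = []

    def emit(sample_type: str, ratio: float, t_ideal: float) -> None:
        for rep in range(1, params.n_replicates + 1):
            t = t_ideal
            if params.noise_cv > 0:
                t = t_ideal * (1.0 + params.noise_cv * _truncated_noise(rng, 1)[0])
            records.append(
                ViscosityRecord(
                    sample_type=sample_type,
                    ligand_to_dna_ratio=ratio,
                    flow_time_s=float(t),
                    replicate=rep,
                )
            )

    emit("buffer", 0.0, params.t_buffer)
    emit("dna_only", 0.0, params.t_dna)
    slope = params.cube_root_slope if params.mode == "intercalator" else 0.0
    for ratio in params.ratio_grid:
        eta = (1.0 + slope * ratio) ** 3
        emit("complex", float(ratio),
             params.t_buffer + eta * (params.t_dna - params.t_buffer))
    return records


def simulate_displacement(dye: str, mode: str, params: QuenchSimParams) -> TitrationSeries:
    """Dye-displacement titration.

    A ligand displaces the dye whose binding mode it shares: a groove binder
    quenches the DNA-Hoechst complex but leaves DNA-EtBr untouched, and vice
    versa for an intercalator.  Matched dye/mode pairs therefore produce a
    static-quenching-shaped decay; mismatched pairs a flat series at F0
    (plus noise).
    """
    if dye not in ("hoechst_33258", "ethidium_bromide"):
        raise ValidationError(f"unknown dye {dye!r}")
    if mode not in ("groove", "intercalative"):
        raise ValidationError(f"unknown mode {mode!r}")
    matched = (dye == "hoechst_33258") == (mode == "groove")
    if matched:
        if params.ksv_true is None:
            raise ParameterError("ksv_true required for a matched displacement series")
        series = simulate_static_quenching(params)
        return TitrationSeries(
            series_id=f"{dye}",
            temperature=params.temperature,
            quencher_conc=series.quencher_conc,
            signal=series.signal,
        )
    rng = np.random.default_rng(params.seed)
    q = np.asarray(params.conc_grid)
    f = np.full_like(q, params.f0)
    return TitrationSeries(
        series_id=f"{dye}",
        temperature=params.temperature,
        quencher_conc=q,
        signal=_apply_noise(f, params.noise_cv, rng),
    )


def simulate_uv_titration(
    mode: str,
    peak_nm: float = 260.0,
    n_steps: int = 5,
    seed: int = 0,
    growth_per_step: float = 0.02,
    shift_per_step_nm: float = -0.5,
    band_sigma_nm: float = 20.0,
    noise_cv: float = 0.0,
) -> list[SpectralScan]:
    """Gaussian-band absorption spectra over a ligand titration.

    Groove-binding behaviour grows the band height by ``growth_per_step``
    (default +2%) per addition with no shift; intercalative behaviour shrinks
    it by the same fraction while shifting the band ``shift_per_step_nm``
    (default −0.5 nm) per addition.  The first scan is the free macromolecule.
    """
    if n_steps < 2:
        raise ParameterError("n_steps must be >= 2")
    if mode not in ("groove", "intercalative"):
        raise ValidationError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    wl = np.arange(peak_nm - 60.0, peak_nm + 60.0 + 0.5, 1.0)
    scans = []
    for step in range(n_steps):
        if mode == "groove":
            height = 1.0 + growth_per_step * step
            center = peak_nm
        else:
            height = 1.0 - growth_per_step * step
            center = peak_nm + shift_per_step_nm * step
        values = height * np.exp(-((wl - center) ** 2) / (2.0 * band_sigma_nm**2))
        if noise_cv > 0:
            values = values * (1.0 + noise_cv * _truncated_noise(rng, values.size))
        scans.append(SpectralScan(wl, values, condition_label=f"step {step}"))
    return scans
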