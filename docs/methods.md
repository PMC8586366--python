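# Methods

## Scope and data model

The package analyses the standard biophysical characterisation of a
small-molecule ligand binding DNA or serum albumin. All quantities are held
in SI-consistent internal units — mol/L, kelvin, seconds — with µM and °C
accepted only at the I/O boundary, because the quenching and thermodynamic
relations mix L mol⁻¹ constants with molar concentrations and kcal/mol
energies. Every titration series must begin with a measured
zero-concentration point; its signal defines F₀ and is never estimated by
extrapolation. Duplicate concentrations within a series are rejected rather
than averaged so that every fit is unambiguous; replicates belong in
separate series.

## Quenching analysis

F₀/F is regressed on [Q] by ordinary least squares **including** the
zero-concentration point (it is a measured datum, with y = 1 by
construction) and with a **free intercept**. A fitted intercept more than
0.05 from 1 attaches a warning — deviations typically signal inner-filter
artifacts or a non-1:1 binding isotherm — but never alters the slope. A
diagnostic quadratic refit attaches a "possible mixed quenching" warning
when the quadratic coefficient is positive with |t| > 2; again the linear
K_SV is reported unchanged. A series with exactly constant signal returns
K_SV = 0 with R² undefined and a degenerate flag rather than an error.

K_q = K_SV/τ₀ is an exact identity of the result object, with
τ₀ = 10⁻⁸ s by default (the customary mean unquenched lifetime assumed for
biomacromolecules). The mechanism classifier uses two pieces of evidence:
the magnitude of K_q relative to the diffusion-controlled limit (default
10¹⁰ L mol⁻¹ s⁻¹, configurable — 2×10¹⁰ is also a defensible choice, and
the dynamic rule already tolerates K_q up to 2× the limit)
and the temperature trend of K_SV. Static requires every K_q above the
limit and K_SV non-increasing; *ties and plateaus count as non-increasing*
so measurement noise cannot flip a static call. Dynamic requires K_SV
strictly rising with every K_q within 2× the limit. K_q above the limit
with rising K_SV is reported as mixed; everything else — including a single
sub-limit K_q, which is necessary but not sufficient evidence of collisional
quenching — is indeterminate. Every fired rule is recorded as a reason
string.

## Binding constants and thermodynamics

The double-log fit regresses log₁₀((F₀−F)/F) on log₁₀[Q]. Base-10
logarithms are used throughout (matching the log K_b ≈ 5 vs K_b ≈ 10⁵
scaling of reported constants); the natural log appears only inside
ΔG° = −RT ln K_b. Points with [Q] = 0 or F ≥ F₀ are excluded — the log is
undefined there — and every exclusion is listed with its reason rather than
silently clipped. R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹ keeps ΔG° in kcal/mol;
Celsius temperatures convert as T + 273.15.

Reference binding constants bundled with the package (BSA at 25/30/35 °C,
DNA at 25 °C) are **mutually inconsistent as printed**: log K_b = 5.2
implies K_b ≈ 1.6×10⁵ yet 1.8×10⁵ is tabulated, and −RT ln(tabulated K_b)
differs from the tabulated ΔG° by up to ~0.2 kcal/mol. The package computes
at full precision and does not reconcile the triplets; comparisons against
those reference values use a loose ±0.25 kcal/mol tolerance, and tests
document this rather than hide it.

No van't Hoff ΔH/ΔS decomposition is attempted: with K_b at only three
temperatures the ΔG° trend (binding affinity decreasing as temperature
rises) is the supportable conclusion.

## Job's method

"Corrected absorbance" is computed as A_mix − (1−x)·A_macro − x·A_ligand
when component blanks are supplied — the standard continuous-variation
correction, under which a non-interacting mixture corrects to exactly zero —
with a bypass for pre-corrected inputs; the result records which path was
used. The maximum is located by default with quadratic vertex refinement
through the grid maximizer and its neighbours (clipped to the neighbour
interval), since a grid argmax alone quantises x_max to the measurement
grid; a maximum on the grid boundary skips refinement and warns. The
mole-fraction maximum is snapped to integer ratios m:n with 1 ≤ m, n ≤ 3
(coarser grids cannot resolve higher ratios) by minimising |x_max −
m/(m+n)|, accepting only residuals within 0.08; ties — e.g. x_max = 0.5
matching 1:1, 2:2 and 3:3 exactly — break toward the smallest m+n, then the
smallest m, so ratios are always reported in lowest terms.

## Binding-mode evidence

UV assessment compares peak height and position of the bound vs free scans
with 2% intensity and 1 nm shift thresholds; smaller changes classify as
"none", and conflicting indications (e.g. hyperchromic with a blue shift)
yield no hint rather than a forced call. Displacement requires both a ≥ 5%
maximum fractional intensity decrease **and** a monotone-decreasing trend
(negative Spearman rank correlation), guarding against single-point dips; no
numeric "no change" threshold exists in the source protocol, so 5% is a
declared default. Relative viscosity reduces to
(t_complex − t_buffer)/(t_DNA − t_buffer); replicate flow times are averaged
arithmetically, and when replicate scatter is nonzero its standard deviation
is propagated to the cube-root points by the delta method and used as
weights in the slope fit (plain OLS otherwise). |slope| ≤ 0.05 per unit
ratio reads as groove-consistent, a larger positive slope as intercalative,
and a significantly negative slope — nonphysical for either mode — as
indeterminate.

The combiner demands at least two evidence sources and two concordant votes
with zero dissent for a groove (or intercalative) verdict, mirroring how
such studies triangulate UV, displacement, CD and viscosity before
concluding; CD enters only as a supplied bands-perturbed boolean,
quantitative CD modelling being out of scope.

## Reactivity and drug-likeness

Descriptors follow Koopmans' theorem (IP = −E_HOMO, EA = −E_LUMO) and the
Pearson–Parr definitions: η = (IP−EA)/2, S = 1/2η, χ = (IP+EA)/2,
µ = −χ, ω = µ²/2η. Outputs carry full precision; the bundled reference
table rounds intermediates before deriving ω, so agreement with it is
checked at |Δ| ≤ 0.005 eV. A degenerate HOMO/LUMO gap raises a
zero-hardness error instead of returning infinities. Ranking is by
ascending gap with competition ranks for ties. Rule-of-five boundaries are
inclusive (MW ≤ 500, cLogP ≤ 5, HBA ≤ 10, HBD ≤ 5) with TPSA > 140 Å²
flagged separately; oral bioavailability is predicted at ≤ 1 violation with
no TPSA flag. The hardness field is named `hardness_eta` to avoid collision
with viscosity's η.

## Synthetic data

Each generator inverts the model its downstream analysis fits, so noiseless
generation followed by fitting is an identity round trip and noisy recovery
can be benchmarked against known truth. Defaults mirror the study
conditions: F₀-normalised titrations over 0–48 µM quencher, Job mixtures at
20 µM total concentration on a 9-point 0.1–0.9 mole-fraction grid,
three stopwatch replicates per viscometer sample, and a 2% coefficient of
variation as the default noise level in tests (no noise magnitudes are
reported for the original measurements; 2% is a declared assumption
typical of steady-state fluorimetry). Noise is multiplicative Gaussian,
truncated at ±4σ to keep signals positive — fluorescence error scales with
intensity — and the zero-concentration point is never noised, mirroring its
role as the exact F₀ reference.

The 1:1 Job equilibrium is solved exactly via the smaller root of
C² − (L+P+1/K)C + LP = 0, which satisfies mass balance to machine
precision; general m:n mixtures use the strong-binding limiting-reagent
approximation min(L/m, P/n), a documented limitation adequate for locating
the curve maximum but not for estimating K. Viscometer flow times are
back-computed from a target cube-root slope, and dye-displacement series
quench only when the ligand's mode matches the dye's binding site.

For noisy benchmarks of the double-log fit, the quencher decade is placed
around 1/K_b so K_b[Q] spans roughly 2–18 — the informative window for an
association constant, and the window a practitioner would design a
titration into. With the 2% noise default, 500 replicates give median
|n̂ − n| well under 0.05 and median log₁₀K_b error under 0.1 there; weakly
quenched windows (K_b[Q] ≪ 1) inflate the intercept error because the
double-log intercept is an extrapolation to log₁₀[Q] = 0.

What the generators do **not** emulate: inner-filter attenuation,
photobleaching, instrument drift, scattering baselines and correlated
wavelength noise. Passing round-trip tests therefore demonstrates
correctness of the estimators under the stated noise model, not robustness
to every artifact of real instrument exports (raw exports are expected to
be baseline-handled upstream; the readers deliberately perform no
smoothing or inner-filter correction).

## Numerical choices and degenerate inputs

Straight-line fits use `scipy.stats.linregress`; its standard errors are
the reported uncertainties. Constant-signal titrations return a degenerate
zero-slope result rather than raising. Equilibrium roots are validated
against mass balance and an assertion fires on a nonphysical root. All
randomness flows from a single seed (per generator params, or
`AnalysisConfig.random_seed`), making every simulated dataset byte-stable.

## Known limitations

- τ₀ is always a supplied constant; no time-resolved lifetime fitting.
- The double-log model assumes static 1:1-like complexation; for strongly
  cooperative systems n is an apparent, not mechanistic, site count.
- Stoichiometry snapping cannot distinguish ratios beyond 3:3.
- The binding-mode verdict is rule-based, not probabilistic; it reports
  indeterminate whenever evidence genuinely conflicts.
- Association constants cannot be validated against the original instrument
  data, which are unpublished; they are validated by simulation round trips.
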