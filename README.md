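# bindkit

Analysis toolkit for small-molecule binding studies with DNA and serum
albumin — the standard biophysical workup used to characterise a candidate
ligand (here, 2-aroyl-3-methyl-6,7-dihydro-5H-thiazolo[3,2-a]pyrimidines
binding ct-DNA and BSA): fluorescence-quenching binding constants,
binding thermodynamics, Job's-plot stoichiometry, binding-mode evidence
(groove binding vs intercalation), frontier-orbital reactivity descriptors
and rule-of-five drug-likeness. A seeded synthetic-data module generates
every experimental input with known ground truth, so the whole pipeline is
testable without instrument exports.

## Who it is for

Bench scientists and computational chemists running ligand–biomolecule
titrations who want the standard fits and classifications done reproducibly
from plain delimited text, with uncertainties, diagnostics and an explicit
evidence trail instead of spreadsheet arithmetic.

## The models

**Stern–Volmer quenching.** For a fluorophore (DNA or BSA) titrated with
quencher Q,

&nbsp;&nbsp;&nbsp;&nbsp;F₀/F = 1 + K_SV[Q] = 1 + K_q τ₀ [Q]

is fitted by OLS (intercept left free as a diagnostic). K_q = K_SV/τ₀ with
τ₀ = 10⁻⁸ s; K_q far above the diffusion limit (~10¹⁰ L mol⁻¹ s⁻¹) together
with K_SV non-increasing in temperature indicates static (ground-state
complex) quenching.

**Double-log binding fit.** log₁₀((F₀−F)/F) = n·log₁₀[Q] + log₁₀K_b gives
the association constant K_b and apparent site number n, and
ΔG° = −RT ln K_b (R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹) the spontaneity.

**Job's method.** Mixtures at fixed total concentration; the corrected
absorbance peaks at mole fraction m/(m+n) for an m:n complex, located by
quadratic vertex refinement and snapped to small integers.

**Binding mode.** Hyperchromism/red shift, Hoechst 33258 vs ethidium
bromide displacement, the slope of (η/η₀)^{1/3} vs [ligand]/[DNA] and an
optional CD flag each cast a groove/intercalative vote; a verdict needs two
concordant votes and no dissent.

**Reactivity & drug-likeness.** Koopmans' IP = −E_HOMO, EA = −E_LUMO and
the conceptual-DFT descriptors η, S, χ, µ, ω; rule-of-five violation
counting with the TPSA ≤ 140 Å² absorption flag (orbital energies and
molecular properties are consumed as inputs, never computed here).

## Worked example

```python
import bindkit
from bindkit.simulate import QuenchSimParams, simulate_binding_site

series = simulate_binding_site(QuenchSimParams(
    kb_true=1.8e5, n_true=1.1, noise_cv=0.02, seed=42, temperature=298.15))

print(bindkit.stern_volmer_fit(series, tau0=1e-8).summary())
bs = bindkit.modified_stern_volmer_fit(series)
print(bs.summary())
print(f"dG = {bindkit.gibbs_free_energy(bs.kb, series.temperature):.2f} kcal/mol")
```

prints

```
Stern-Volmer quenching fit
------------------------------------------
T (K)                  298.15
n points                    7
Ksv (L/mol)         6.818e+04 +/- 2e+03
intercept              0.9228 +/- 0.057
Kq (L/mol/s)        6.818e+12
tau0 (s)                1e-08
R^2                  0.995818
warning: intercept 0.9228 deviates from 1 by more than 0.05 (possible inner-filter artifact)

Double-log (modified Stern-Volmer) binding fit
----------------------------------------------
T (K)                  298.15
points used                 6
log10 Kb               5.2044 +/- 0.15
Kb (L/mol)          1.601e+05
n sites                1.0875 +/- 0.032
R^2                  0.996447
excluded point 0: zero-concentration reference point

dG = -7.10 kcal/mol
```

The double-log fit recovers the generating K_b = 1.8×10⁵ L/mol and n = 1.1
within its quoted uncertainties; K_q ≈ 6.8×10¹² L mol⁻¹ s⁻¹ lies far above
the 10¹⁰ diffusion limit (static quenching), and ΔG° < 0 marks the binding
spontaneous. Note the linear Stern–Volmer slope differs from K_b here
because the data were generated with n ≠ 1 — exactly the situation the
free-intercept warning is designed to surface.

A command-line interface mirrors the library:

```sh
bindkit simulate quench --seed 1 --out quench.csv
bindkit fit-sv --input quench.csv --out sv.json
bindkit job --input job.csv --out job.json
bindkit viscosity --input visc.csv
bindkit descriptors --input orbitals.csv
```

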