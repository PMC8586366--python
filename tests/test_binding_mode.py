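"""UV shift, dye displacement, viscometry and the binding-mode combiner."""

import itertools

import numpy as np
import pytest

import bindkit
from bindkit.binding_mode import (
    DYE_MODES,
    DisplacementResult,
    ShiftAssessment,
    ViscosityProfile,
)
from bindkit.datatypes import TitrationSeries, ViscosityRecord
from bindkit.exceptions import (
    BoundaryPeakError,
    DegenerateSolventError,
    InsufficientEvidenceError,
    ParameterError,
    ValidationError,
)
from bindkit.simulate import (
    QuenchSimParams,
    ViscSimParams,
    simulate_displacement,
    simulate_uv_titration,
    simulate_viscosity,
)

UM = 1e-6


def _gaussian_scan(height=1.0, center=260.0, label=""):
    wl = np.arange(200.0, 321.0, 1.0)
    return bindkit.SpectralScan(wl, height * np.exp(-((wl - center) ** 2) / 800.0), label)


class TestAssessAbsorbanceShift:
    def test_identical_scans_are_unchanged(self):
        a = _gaussian_scan()
        res = bindkit.assess_absorbance_shift(a, _gaussian_scan())
        assert (res.intensity_change, res.wavelength_shift, res.mode_hint) == (
            "none", "none", "none",
        )

    def test_hyperchromic_without_shift_hints_groove(self):
        res = bindkit.assess_absorbance_shift(
            _gaussian_scan(1.0), _gaussian_scan(1.08, 260.5)
        )
        assert res.intensity_change == "hyperchromic"
        assert res.wavelength_shift == "none"
        assert res.mode_hint == "groove"

    def test_hypochromic_blue_shift_hints_intercalative(self):
        res = bindkit.assess_absorbance_shift(
            _gaussian_scan(1.0, 260.0), _gaussian_scan(0.9, 257.0)
        )
        assert res.intensity_change == "hypochromic"
        assert res.wavelength_shift == "blue"
        assert res.mode_hint == "intercalative"

    def test_conflicting_signals_give_no_hint(self):
        # intensity says groove, shift says intercalation
        res = bindkit.assess_absorbance_shift(
            _gaussian_scan(1.0, 260.0), _gaussian_scan(1.10, 256.0)
        )
        assert res.mode_hint == "none"

    def test_boundary_peak_rejected(self):
        wl = np.arange(200.0, 260.0, 1.0)
        rising = bindkit.SpectralScan(wl, np.linspace(0.1, 1.0, wl.size))
        with pytest.raises(BoundaryPeakError):
            bindkit.assess_absorbance_shift(rising, rising)


class TestDisplacementAnalysis:
    def test_monotone_forty_percent_drop_displaces_hoechst(self):
        q = np.arange(0, 49, 8) * UM
        f = np.linspace(1000.0, 600.0, q.size)
        series = TitrationSeries("h", 298.15, q, f)
        res = bindkit.displacement_analysis(series, "hoechst_33258")
        assert res.displaced
        assert res.max_fractional_decrease == pytest.approx(0.4)
        assert res.dye_mode == "groove_binder"

    def test_constant_etbr_series_not_displaced(self):
        q = np.arange(0, 49, 8) * UM
        series = TitrationSeries("e", 298.15, q, np.full(q.size, 1000.0))
        res = bindkit.displacement_analysis(series, "ethidium_bromide")
        assert not res.displaced
        assert res.dye_mode == "intercalator"

    def test_small_drop_below_threshold_not_displaced(self):
        q = np.arange(0, 49, 8) * UM
        f = np.linspace(1000.0, 970.0, q.size)  # 3% monotone decrease
        series = TitrationSeries("h", 298.15, q, f)
        assert not bindkit.displacement_analysis(series, "hoechst_33258", 0.05).displaced

    def test_single_dip_without_trend_not_displaced(self):
        q = np.arange(0, 49, 8) * UM
        f = np.array([1000.0, 1010.0, 1005.0, 600.0, 1008.0, 1002.0, 1006.0])
        series = TitrationSeries("h", 298.15, q, f)
        assert not bindkit.displacement_analysis(series, "hoechst_33258").displaced

    def test_unknown_dye_rejected(self):
        q = np.arange(0, 49, 8) * UM
        series = TitrationSeries("x", 298.15, q, np.full(q.size, 1.0))
        with pytest.raises(ValidationError):
            bindkit.displacement_analysis(series, "acridine_orange")


class TestRelativeViscosity:
    def test_unchanged_flow_time_gives_unity(self):
        assert bindkit.relative_viscosity(150.0, 150.0, 100.0) == pytest.approx(1.0)

    def test_hand_evaluated_ratio(self):
        assert bindkit.relative_viscosity(160.0, 150.0, 100.0) == pytest.approx(1.2)

    def test_homogeneous_of_degree_zero_in_excess_times(self):
        base = bindkit.relative_viscosity(160.0, 150.0, 100.0)
        # scale both excess flow times (t - t_buffer) by a common factor
        for k in (0.5, 3.0):
            assert bindkit.relative_viscosity(
                100.0 + k * 60.0, 100.0 + k * 50.0, 100.0
            ) == pytest.approx(base, rel=1e-12)

    def test_degenerate_solvent_rejected(self):
        with pytest.raises(DegenerateSolventError):
            bindkit.relative_viscosity(160.0, 100.0, 100.0)
        with pytest.raises(ParameterError):
            bindkit.relative_viscosity(90.0, 150.0, 100.0)


class TestViscosityProfile:
    def test_flat_profile_is_groove_consistent(self):
        records = simulate_viscosity(ViscSimParams(mode="groove"))
        profile = bindkit.viscosity_profile(records)
        assert profile.slope == pytest.approx(0.0, abs=1e-12)
        assert profile.classification == "groove_consistent"
        np.testing.assert_allclose(profile.cube_roots**3, profile.relative_viscosity)

    def test_noiseless_intercalator_slope_recovered_exactly(self):
        records = simulate_viscosity(
            ViscSimParams(mode="intercalator", cube_root_slope=0.1)
        )
        profile = bindkit.viscosity_profile(records)
        assert profile.slope == pytest.approx(0.1, rel=1e-9)
        assert profile.classification == "intercalative"

    def test_noisy_groove_profiles_classified_correctly(self):
        hits = 0
        for seed in range(100):
            records = simulate_viscosity(
                ViscSimParams(mode="groove", noise_cv=0.01, seed=seed)
            )
            if bindkit.viscosity_profile(records).classification == "groove_consistent":
                hits += 1
        assert hits >= 99

    def test_missing_buffer_rows_rejected(self):
        records = [
            r for r in simulate_viscosity(ViscSimParams()) if r.sample_type != "buffer"
        ]
        with pytest.raises(ValidationError):
            bindkit.viscosity_profile(records)

    def test_too_few_ratios_rejected(self):
        records = simulate_viscosity(ViscSimParams(ratio_grid=(0.5, 1.0)))
        with pytest.raises(ValidationError):
            bindkit.viscosity_profile(records)


def _shift(hint):
    return ShiftAssessment(
        intensity_change="hyperchromic" if hint == "groove" else "hypochromic",
        wavelength_shift="none",
        delta_intensity_fraction=0.08 if hint == "groove" else -0.08,
        delta_lambda_nm=0.0,
        mode_hint=hint,
    )


def _displacement(dye, displaced):
    return DisplacementResult(
        dye=dye, max_fractional_decrease=0.4 if displaced else 0.0,
        displaced=displaced, dye_mode=DYE_MODES[dye],
    )


def _visc(classification):
    slope = {"groove_consistent": 0.0, "intercalative": 0.5, "indeterminate": -0.5}
    r = np.array([0.2, 0.4, 0.6])
    return ViscosityProfile(
        ratios=r, relative_viscosity=np.ones(3), cube_roots=np.ones(3),
        slope=slope[classification], slope_se=0.0, classification=classification,
    )


class TestCombineEvidence:
    def test_full_concordant_pattern_is_groove(self):
        verdict = bindkit.combine_evidence(
            shift=_shift("groove"),
            displacements=[
                _displacement("hoechst_33258", True),
                _displacement("ethidium_bromide", False),
            ],
            viscosity=_visc("groove_consistent"),
            cd_bands_perturbed=False,
        )
        assert verdict.verdict == "groove"
        assert verdict.votes["hoechst_33258"] == "groove"
        assert verdict.votes["ethidium_bromide"] == "none"
        assert len(verdict.rationale) == 5

    def test_mirrored_pattern_is_intercalative(self):
        verdict = bindkit.combine_evidence(
            shift=_shift("intercalative"),
            displacements=[_displacement("ethidium_bromide", True)],
            viscosity=_visc("intercalative"),
        )
        assert verdict.verdict == "intercalative"

    def test_split_vote_is_indeterminate(self):
        verdict = bindkit.combine_evidence(
            shift=_shift("groove"),
            displacements=[_displacement("ethidium_bromide", True)],
        )
        assert verdict.verdict == "indeterminate"

    def test_fewer_than_two_sources_rejected(self):
        with pytest.raises(InsufficientEvidenceError):
            bindkit.combine_evidence(shift=_shift("groove"))

    def test_never_groove_with_any_intercalative_vote(self):
        """Exhaustive enumeration of every achievable vote pattern."""
        shift_opts = [None, _shift("groove"), _shift("intercalative")]
        hoechst_opts = [None, True, False]
        etbr_opts = [None, True, False]
        visc_opts = [None, "groove_consistent", "intercalative", "indeterminate"]
        cd_opts = [None, True, False]
        for sh, ho, et, vi, cd in itertools.product(
            shift_opts, hoechst_opts, etbr_opts, visc_opts, cd_opts
        ):
            displacements = []
            if ho is not None:
                displacements.append(_displacement("hoechst_33258", ho))
            if et is not None:
                displacements.append(_displacement("ethidium_bromide", et))
            kwargs = dict(
                shift=sh, displacements=displacements,
                viscosity=_visc(vi) if vi else None, cd_bands_perturbed=cd,
            )
            if (sh is not None) + len(displacements) + (vi is not None) + (cd is not None) < 2:
                continue
            verdict = bindkit.combine_evidence(**kwargs)
            votes = list(verdict.votes.values())
            if "intercalative" in votes:
                assert verdict.verdict != "groove"
            if "groove" in votes:
                assert verdict.verdict != "intercalative"


class TestSimulatedEvidenceEndToEnd:
    def test_groove_uv_simulation_hints_groove(self):
        scans = simulate_uv_titration("groove", n_steps=5)
        res = bindkit.assess_absorbance_shift(scans[0], scans[-1])
        assert res.mode_hint == "groove"

    def test_intercalative_uv_simulation_hints_intercalative(self):
        scans = simulate_uv_titration("intercalative", n_steps=5)
        res = bindkit.assess_absorbance_shift(scans[0], scans[-1])
        assert res.mode_hint == "intercalative"

    def test_matched_and_mismatched_displacement(self):
        params = QuenchSimParams(ksv_true=4.2e4, noise_cv=0.0)
        matched = simulate_displacement("hoechst_33258", "groove", params)
        mismatched = simulate_displacement("ethidium_bromide", "groove", params)
        assert bindkit.displacement_analysis(matched, "hoechst_33258").displaced
        assert not bindkit.displacement_analysis(mismatched, "ethidium_bromide").displaced
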