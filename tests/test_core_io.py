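"""Readers, writers, unit handling and sample-preparation arithmetic."""

import numpy as np
import pytest

import bindkit
from bindkit import io
from bindkit.exceptions import (
    DuplicateConcentrationError,
    MissingColumnError,
    MissingZeroConcentrationError,
    NonNumericCellError,
    ParameterError,
    ValidationError,
)


def _write(tmp_path, text, name="t.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadTitrationTable:
    def test_micromolar_units_convert_to_molar(self, tmp_path):
        p = _write(
            tmp_path,
            "series_id,temperature_C,conc_uM,signal\n"
            "BSA,25,0,1000\nBSA,25,8,900\nBSA,25,16,820\nBSA,25,24,760\n",
        )
        (series,) = io.read_titration_table(p)
        np.testing.assert_allclose(series.quencher_conc, [0, 8e-6, 1.6e-5, 2.4e-5])
        assert series.temperature == pytest.approx(298.15)
        assert series.f0 == 1000

    def test_molar_column_equivalent_to_micromolar(self, tmp_path):
        rows = [(0, 1000), (8, 900), (16, 820), (24, 760)]
        p_um = _write(
            tmp_path,
            "series_id,temperature_C,conc_uM,signal\n"
            + "".join(f"s,25,{c},{f}\n" for c, f in rows),
            "um.csv",
        )
        p_m = _write(
            tmp_path,
            "series_id,temperature_C,conc_M,signal\n"
            + "".join(f"s,25,{c * 1e-6!r},{f}\n" for c, f in rows),
            "m.csv",
        )
        (a,) = io.read_titration_table(p_um)
        (b,) = io.read_titration_table(p_m)
        np.testing.assert_allclose(a.quencher_conc, b.quencher_conc)

    def test_interleaved_series_are_grouped_and_sorted(self, tmp_path):
        # rows deliberately shuffled across two series; hand-grouped oracle below
        p = _write(
            tmp_path,
            "series_id,temperature_C,conc_uM,signal\n"
            "B,25,8,90\nA,25,0,100\nB,25,0,95\nA,25,16,70\n"
            "B,25,16,80\nA,25,8,85\nB,25,24,72\nA,25,24,60\n",
        )
        series = {s.series_id: s for s in io.read_titration_table(p)}
        assert set(series) == {"A", "B"}
        np.testing.assert_allclose(series["A"].signal, [100, 85, 70, 60])
        np.testing.assert_allclose(series["B"].signal, [95, 90, 80, 72])

    def test_missing_zero_row_names_series(self, tmp_path):
        p = _write(
            tmp_path,
            "series_id,temperature_C,conc_uM,signal\n"
            "BSA,25,8,900\nBSA,25,16,820\nBSA,25,24,760\nBSA,25,32,700\n",
        )
        with pytest.raises(MissingZeroConcentrationError, match="BSA"):
            io.read_titration_table(p)

    def test_duplicate_concentration_rejected(self, tmp_path):
        p = _write(
            tmp_path,
            "series_id,temperature_C,conc_uM,signal\n"
            "s,25,0,1000\ns,25,8,900\ns,25,8,910\ns,25,16,820\n",
        )
        with pytest.raises(DuplicateConcentrationError):
            io.read_titration_table(p)

    def test_missing_column_and_non_numeric_cell(self, tmp_path):
        p = _write(tmp_path, "series_id,conc_uM,signal\ns,0,1\n", "bad1.csv")
        with pytest.raises(MissingColumnError):
            io.read_titration_table(p)
        p2 = _write(
            tmp_path,
            "series_id,temperature_C,conc_uM,signal\n"
            "s,25,0,1000\ns,25,8,oops\ns,25,16,820\ns,25,24,760\n",
            "bad2.csv",
        )
        with pytest.raises(NonNumericCellError, match="oops"):
            io.read_titration_table(p2)

    def test_tab_delimiter_autodetected(self, tmp_path):
        p = _write(
            tmp_path,
            "series_id\ttemperature_C\tconc_uM\tsignal\n"
            "s\t25\t0\t1000\ns\t25\t8\t900\ns\t25\t16\t820\ns\t25\t24\t760\n",
        )
        (series,) = io.read_titration_table(p)
        assert len(series) == 4

    def test_roundtrip_preserves_full_precision(self, tmp_path, linear_quench_series):
        out = tmp_path / "rt.csv"
        io.write_titration_table([linear_quench_series], out)
        (back,) = io.read_titration_table(out)
        np.testing.assert_allclose(
            back.quencher_conc, linear_quench_series.quencher_conc, rtol=1e-15
        )
        np.testing.assert_allclose(back.signal, linear_quench_series.signal, rtol=1e-15)
        assert back.temperature == pytest.approx(linear_quench_series.temperature)


class TestSeriesInvariants:
    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            bindkit.TitrationSeries("s", 298.15, [0, 1e-6, 2e-6], [3, 2, 1])

    def test_nonpositive_signal_rejected(self):
        with pytest.raises(ValidationError):
            bindkit.TitrationSeries(
                "s", 298.15, [0, 1e-6, 2e-6, 3e-6], [3, 2, 0, 1]
            )


class TestBeerLambert:
    @pytest.mark.parametrize(
        "absorbance,expected",
        [(0.0, 0.0), (0.4752, 7.2e-5), (0.66, 1.0e-4)],
    )
    def test_hand_evaluated_concentrations(self, absorbance, expected):
        c = bindkit.concentration_from_absorbance(absorbance, 6600.0, 1.0)
        assert c == pytest.approx(expected, rel=1e-12)

    def test_homogeneous_of_degree_one_in_absorbance(self):
        base = bindkit.concentration_from_absorbance(0.3, 6600.0, 1.0)
        for k in (0.5, 2.0, 7.0):
            assert bindkit.concentration_from_absorbance(
                0.3 * k, 6600.0, 1.0
            ) == pytest.approx(k * base, rel=1e-12)

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            bindkit.concentration_from_absorbance(0.5, -1.0, 1.0)
        with pytest.raises(ParameterError):
            bindkit.concentration_from_absorbance(0.5, 6600.0, 0.0)
        with pytest.raises(ParameterError):
            bindkit.concentration_from_absorbance(-0.1, 6600.0, 1.0)


class TestPurityRatio:
    @pytest.mark.parametrize(
        "a260,a280,ratio,passed",
        [(1.85, 1.0, 1.85, True), (1.0, 1.0, 1.0, False), (1.95, 1.0, 1.95, False)],
    )
    def test_window(self, a260, a280, ratio, passed):
        result = bindkit.purity_ratio(a260, a280)
        assert result.ratio == pytest.approx(ratio)
        assert result.passed is passed

    def test_zero_a280_raises(self):
        with pytest.raises(ZeroDivisionError):
            bindkit.purity_ratio(1.8, 0.0)


class TestConfig:
    def test_yaml_roundtrip_and_overrides(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("tau0_s: 2.0e-8\nrandom_seed: 7\n")
        cfg = bindkit.load_config(p, diffusion_limit=2e10)
        assert cfg.tau0_s == pytest.approx(2e-8)
        assert cfg.random_seed == 7
        assert cfg.diffusion_limit == pytest.approx(2e10)

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("not_a_field: 1\n")
        with pytest.raises(ParameterError):
            bindkit.load_config(p)

    def test_seeded_rng_is_reproducible(self):
        cfg = bindkit.AnalysisConfig(random_seed=123)
        assert cfg.rng().integers(1 << 30) == cfg.rng().integers(1 << 30)
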