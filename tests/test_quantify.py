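"""Channel summation, isotopic corrections, single-point quantification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avlipidome.containers import IstdSpec, PeakTable
from avlipidome.errors import (
    DegenerateDesign,
    MissingIstd,
    ZeroDenominator,
    ZeroIstdArea,
)
from avlipidome.isotopes import m2_ratio, monoisotopic_fraction
from avlipidome.nomenclature import elemental_formula, parse_shorthand
from avlipidome.quantify import (
    fit_calibration,
    linearity_screen,
    quantify_single_point,
    recovery_rate,
    sum_channels,
    type2_correct,
)


def peaks_from_rows(*rows) -> PeakTable:
    return PeakTable(
        pd.DataFrame(rows, columns=["sample_id", "analyte", "channel", "area"])
    )


def meta(sample_ids, mass=20.0) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient": [f"P{i}" for i in range(len(sample_ids))],
            "sex": "M",
            "morphology": "TAV",
            "stage": "mildly_diseased",
            "tissue_mass_mg": mass,
        },
        index=list(sample_ids),
    )


class TestSumChannels:
    def test_adduct_and_fragment_areas_add(self):
        p = peaks_from_rows(
            ("S1", "PC 34:1", "[M+H]+", 100.0),
            ("S1", "PC 34:1", "[M+H-H2O]+", 20.0),
        )
        summed, flagged = sum_channels(p)
        assert summed.data["area"].tolist() == [120.0]
        assert flagged == []

    def test_single_channel_unchanged(self):
        p = peaks_from_rows(("S1", "CE 18:2", "[M+NH4]+", 55.0))
        summed, _ = sum_channels(p)
        assert summed.data["area"].tolist() == [55.0]

    def test_empty_channel_list_flags_analyte(self):
        p = peaks_from_rows(("S1", "PC 34:1", "[M+H]+", 100.0))
        summed, flagged = sum_channels(p, channel_map={"PC": []})
        assert flagged == ["PC 34:1"]
        assert len(summed.data) == 0

    def test_unmapped_channel_ignored(self):
        p = peaks_from_rows(
            ("S1", "PC 34:1", "[M+H]+", 100.0),
            ("S1", "PC 34:1", "weird", 999.0),
        )
        summed, _ = sum_channels(p, channel_map={"PC": ["[M+H]+"]})
        assert summed.data["area"].tolist() == [100.0]


class TestType2Correction:
    def test_single_species_is_idempotent(self):
        p = peaks_from_rows(("S1", "PC 34:1", "sum", 500.0))
        out = type2_correct(p)
        assert out.data["area"].tolist() == [500.0]

    def test_two_species_toy_matches_oracle_r2(self):
        """A(d) loses exactly A(d+1) x (M+2/M0 of the d+1 species)."""
        r2 = m2_ratio(elemental_formula(parse_shorthand("PC 34:2")))
        p = peaks_from_rows(
            ("S1", "PC 34:2", "sum", 1000.0),
            ("S1", "PC 34:1", "sum", 1000.0),
        )
        out = type2_correct(p).data.set_index("analyte")["area"]
        assert out["PC 34:2"] == 1000.0
        assert out["PC 34:1"] == pytest.approx(1000.0 - 1000.0 * r2)

    def test_cascade_uses_corrected_upstream_area(self):
        r2_2 = m2_ratio(elemental_formula(parse_shorthand("PC 34:2")))
        r2_1 = m2_ratio(elemental_formula(parse_shorthand("PC 34:1")))
        p = peaks_from_rows(
            ("S1", "PC 34:2", "sum", 1000.0),
            ("S1", "PC 34:1", "sum", 500.0),
            ("S1", "PC 34:0", "sum", 100.0),
        )
        out = type2_correct(p).data.set_index("analyte")["area"]
        corr1 = 500.0 - 1000.0 * r2_2
        assert out["PC 34:1"] == pytest.approx(corr1)
        assert out["PC 34:0"] == pytest.approx(100.0 - corr1 * r2_1)

    def test_never_negative(self):
        p = peaks_from_rows(
            ("S1", "PC 34:2", "sum", 1e9),
            ("S1", "PC 34:1", "sum", 1.0),
        )
        out = type2_correct(p).data
        assert (out["area"] >= 0).all()

    def test_different_carbon_counts_untouched(self):
        p = peaks_from_rows(
            ("S1", "PC 36:2", "sum", 1000.0),
            ("S1", "PC 34:1", "sum", 1000.0),
        )
        out = type2_correct(p).data.set_index("analyte")["area"]
        assert out["PC 34:1"] == 1000.0


def pc_istd(spike=100.0) -> dict[str, IstdSpec]:
    parsed = parse_shorthand("PC 33:1(d7)")
    return {
        "PC": IstdSpec(
            standard_name="PC 33:1(d7)",
            serves_subclass="PC",
            spiked_amount_pmol=spike,
            deuterium_count=7,
            isotopic_purity=0.98,
            formula=elemental_formula(parsed),
        )
    }


class TestSinglePoint:
    def test_equal_area_same_formula_gives_spike_over_mass(self):
        """Analyte area == ISTD area with matched formulas: 100 pmol / 20 mg."""
        parsed = parse_shorthand("PC 34:1")
        istds = {
            "PC": IstdSpec(
                standard_name="PC-STD",
                serves_subclass="PC",
                spiked_amount_pmol=100.0,
                deuterium_count=0,
                isotopic_purity=1.0,
                formula=elemental_formula(parsed),
            )
        }
        p = peaks_from_rows(
            ("S1", "PC 34:1", "sum", 777.0), ("S1", "PC-STD", "sum", 777.0)
        )
        m = quantify_single_point(p, istds, meta(["S1"], mass=20.0))
        assert m.values.loc["PC 34:1", "S1"] == pytest.approx(5.0)

    def test_doubling_mass_halves_concentration(self):
        p = peaks_from_rows(
            ("S1", "PC 34:1", "sum", 300.0), ("S1", "PC 33:1(d7)", "sum", 100.0)
        )
        c20 = quantify_single_point(p, pc_istd(), meta(["S1"], 20.0))
        c40 = quantify_single_point(p, pc_istd(), meta(["S1"], 40.0))
        assert c40.values.iloc[0, 0] == pytest.approx(c20.values.iloc[0, 0] / 2)

    @given(area=st.floats(1.0, 1e6), scale=st.floats(0.5, 4.0))
    @settings(max_examples=25, deadline=None)
    def test_linear_in_analyte_area(self, area, scale):
        def conc(a):
            p = peaks_from_rows(
                ("S1", "PC 34:1", "sum", a), ("S1", "PC 33:1(d7)", "sum", 500.0)
            )
            return quantify_single_point(
                p, pc_istd(), meta(["S1"])
            ).values.iloc[0, 0]

        assert conc(area * scale) == pytest.approx(conc(area) * scale, rel=1e-9)

    def test_missing_istd_raises(self):
        p = peaks_from_rows(("S1", "CE 18:2", "sum", 10.0))
        with pytest.raises(MissingIstd):
            quantify_single_point(p, pc_istd(), meta(["S1"]))

    def test_zero_istd_area_raises(self):
        p = peaks_from_rows(
            ("S1", "PC 34:1", "sum", 10.0), ("S1", "PC 33:1(d7)", "sum", 0.0)
        )
        with pytest.raises(ZeroIstdArea):
            quantify_single_point(p, pc_istd(), meta(["S1"]))

    def test_type1_factor_applied(self):
        """Labeled standard and analyte differ in M0 share; the ratio
        must be rescaled by M0(istd)/M0(analyte)."""
        p = peaks_from_rows(
            ("S1", "PC 34:1", "sum", 100.0), ("S1", "PC 33:1(d7)", "sum", 100.0)
        )
        m = quantify_single_point(p, pc_istd(spike=100.0), meta(["S1"], 20.0))
        istd = pc_istd()["PC"]
        f_istd = monoisotopic_fraction(istd.formula, label_purity=0.98)
        f_analyte = monoisotopic_fraction(
            elemental_formula(parse_shorthand("PC 34:1"))
        )
        assert m.values.iloc[0, 0] == pytest.approx(
            (f_istd / f_analyte) * 100.0 / 20.0
        )


class TestCalibration:
    def test_perfect_line_full_range(self):
        pts = pd.DataFrame({"amount": [1, 2, 5, 10, 20, 50, 100],
                            "area": [10, 20, 50, 100, 200, 500, 1000]})
        cc = fit_calibration(pts)
        assert cc.r_squared == pytest.approx(1.0)
        assert cc.linear_range == (1.0, 100.0)
        assert cc.slope == pytest.approx(10.0)

    def test_saturating_top_point_excluded(self):
        amounts = [1, 2, 5, 10, 20, 50, 100]
        areas = [10.0 * a for a in amounts]
        areas[-1] *= 0.90  # top point 10% under the line
        cc = fit_calibration(
            pd.DataFrame({"amount": amounts, "area": areas}),
            rel_residual_threshold=0.05,
        )
        assert cc.linear_range == (1.0, 50.0)

    def test_constant_amounts_degenerate(self):
        with pytest.raises(DegenerateDesign):
            fit_calibration(pd.DataFrame({"amount": [5, 5, 5],
                                          "area": [1, 2, 3]}))


class TestLinearityScreen:
    def _setup(self, inflate=None):
        sids = [f"S{i}" for i in range(1, 8)]
        conc = np.array([1.0, 2, 3, 4, 5, 6, 7])
        area = conc * 50.0
        if inflate is not None:
            area = area.copy()
            area[inflate] *= 10
        peaks = PeakTable(pd.DataFrame({
            "sample_id": sids, "analyte": "PC 34:1", "channel": "sum",
            "area": area,
        }))
        from avlipidome.containers import ConcentrationMatrix
        values = pd.DataFrame([conc], index=["PC 34:1"], columns=sids)
        return ConcentrationMatrix(values, meta(sids)), peaks

    def test_proportional_data_unflagged(self):
        matrix, peaks = self._setup()
        flags = linearity_screen(matrix, peaks)
        assert flags.nonlinear_lipids == []
        assert len(flags.outlier_samples) == 0

    def test_inflated_sample_flagged_as_outlier(self):
        matrix, peaks = self._setup(inflate=3)
        flags = linearity_screen(matrix, peaks)
        flagged = set(flags.outlier_samples["sample_id"])
        assert "S4" in flagged

    def test_too_few_samples_skipped(self):
        matrix, peaks = self._setup()
        small = matrix.subset_samples(["S1", "S2", "S3"])
        flags = linearity_screen(small, peaks)
        assert flags.skipped_lipids == ["PC 34:1"]


class TestRecovery:
    def test_identity(self):
        assert recovery_rate([10, 20], [10, 20]) == pytest.approx(100.0)

    def test_half(self):
        assert recovery_rate([50, 60, 70], [100, 120, 140]) == pytest.approx(50.0)

    def test_empty_group_raises(self):
        with pytest.raises(ZeroDenominator):
            recovery_rate([], [1, 2])
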