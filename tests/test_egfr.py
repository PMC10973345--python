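"""Hyperfiltration quantities, the gestational eGFR formula and the RI table."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gestri import (
    CohortConfig,
    DegreeSearchConfig,
    EgfrParameters,
    NonPhysiologicWarning,
    PolynomialCurve,
    PreImplantationError,
    ResampleConfig,
    analytic_median_table,
    build_egfr_ri,
    derive_normal_gfr,
    generate_cohort,
    gestational_egfr,
    hyperfiltration_gap,
    k_gw,
    load_canonical_parameters,
    load_canonical_ri_table,
    make_ri_table,
    mg_dl_to_umol_l,
    overall_hyperfiltration_ratio,
    ri_table_to_frame,
    simple_hyperfiltration_gap_ratio,
    umol_l_to_mg_dl,
)

positive_scr = st.floats(min_value=1.0, max_value=110.0)
valid_gw = st.integers(min_value=4, max_value=41)


class TestHyperfiltrationQuantities:
    def test_gap_examples(self):
        assert hyperfiltration_gap(55.25, 55.25) == 0.0
        assert hyperfiltration_gap(55.25, 40.0) == pytest.approx(15.25)

    def test_overall_ratio_examples(self):
        assert overall_hyperfiltration_ratio(55.25, 55.25) == pytest.approx(1.0)
        assert overall_hyperfiltration_ratio(55.25, 2 * 55.25) == pytest.approx(0.0)
        assert overall_hyperfiltration_ratio(55.25, 40.0) == pytest.approx(1.27602, abs=1e-5)

    @settings(max_examples=200, derandomize=True)
    @given(bsc=st.floats(10.0, 200.0), scr=st.floats(1.0, 300.0))
    def test_ratio_identity_and_gap_conservation(self, bsc, scr):
        # overall ratio - 1 == simple gap ratio; gap + scr == bsc
        assert overall_hyperfiltration_ratio(bsc, scr) - 1 == pytest.approx(
            simple_hyperfiltration_gap_ratio(bsc, scr), abs=1e-12)
        assert hyperfiltration_gap(bsc, scr) + scr == pytest.approx(bsc, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            hyperfiltration_gap(0.0, 40.0)
        with pytest.raises(ValueError):
            overall_hyperfiltration_ratio(55.25, -1.0)


class TestKgw:
    def test_value_at_nadir_week(self, params):
        assert k_gw(22, params) == pytest.approx(55.25 / 39.8367, abs=1e-4)

    def test_unity_when_median_equals_baseline(self):
        flat = EgfrParameters(50.0, 100.0, PolynomialCurve((50.0,), domain=(4, 41)))
        assert k_gw(30, flat) == pytest.approx(1.0)

    def test_maximal_at_mid_pregnancy(self, params):
        gws = np.arange(4, 42)
        ks = np.array([k_gw(g, params) for g in gws])
        assert gws[np.argmax(ks)] in (22, 23)

    @pytest.mark.parametrize("gw", [0, 1, 3])
    def test_preimplantation_rejected(self, gw):
        with pytest.raises(PreImplantationError):
            k_gw(gw)

    def test_outside_domain_rejected(self, params):
        with pytest.raises(ValueError):
            k_gw(45, params)


class TestGestationalEgfr:
    def test_baseline_scr_gives_normal_gfr_times_k(self, params):
        assert gestational_egfr(55.25, 22, params) == pytest.approx(142.99, abs=0.01)

    def test_full_formula_hand_value(self, params):
        assert gestational_egfr(40.0, 20, params) == pytest.approx(180.85, abs=0.05)

    @settings(max_examples=150, derandomize=True)
    @given(scr=positive_scr, gw=valid_gw)
    def test_equals_ratio_times_gfr_times_k(self, params, scr, gw):
        expected = overall_hyperfiltration_ratio(55.25, scr) * 103.1 * k_gw(gw, params)
        assert gestational_egfr(scr, gw, params) == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(scr=st.floats(1.0, 100.0), delta=st.floats(0.5, 10.0), gw=valid_gw)
    def test_strictly_decreasing_in_scr(self, params, scr, delta, gw):
        assert gestational_egfr(scr + delta, gw, params) < gestational_egfr(scr, gw, params)

    def test_zero_at_twice_baseline(self, params):
        with pytest.warns(NonPhysiologicWarning):
            value = gestational_egfr(2 * 55.25, 22, params)
        assert value == pytest.approx(0.0, abs=1e-9)

    def test_preimplantation_week_rejected(self, params):
        with pytest.raises(PreImplantationError):
            gestational_egfr(50.0, 2, params)


class TestUnits:
    def test_normal_gfr_derivation(self):
        assert round(derive_normal_gfr(110.1, 1.62, 1.73), 1) == 103.1
        assert derive_normal_gfr(100.0, 1.73, 1.73) == pytest.approx(100.0)
        assert derive_normal_gfr(100.0, 0.865, 1.73) == pytest.approx(50.0)

    def test_creatinine_conversion(self):
        assert mg_dl_to_umol_l(0.0) == 0.0
        assert mg_dl_to_umol_l(1.0) == pytest.approx(88.42)
        assert umol_l_to_mg_dl(mg_dl_to_umol_l(0.73)) == pytest.approx(0.73, rel=1e-12)
        with pytest.raises(ValueError):
            mg_dl_to_umol_l(-0.1)


class TestCanonicalTableConsistency:
    def test_median_column_reproduced_for_all_weeks(self, params):
        table = load_canonical_ri_table()
        med = np.round(params.median_curve(table["gw"].to_numpy(float)), 1)
        np.testing.assert_array_equal(med, table["scr_median"].to_numpy())

    def test_increment_column_from_rounded_medians(self, params):
        table = load_canonical_ri_table()
        inc = np.round(100 * (table["scr_median"] / params.bsc - 1), 1)
        np.testing.assert_array_equal(inc.to_numpy(), table["scr_increment_pct"].to_numpy())

    def test_analytic_median_table(self, params):
        table = analytic_median_table(params)
        assert list(table["gw"]) == list(range(4, 42))
        row4 = table[table.gw == 4].iloc[0]
        assert (row4.scr_median, row4.scr_increment_pct) == (54.3, -1.7)
        row41 = table[table.gw == 41].iloc[0]
        assert (row41.scr_median, row41.scr_increment_pct) == (48.7, -11.9)


@pytest.fixture(scope="module")
def curves(params):
    md = params.median_curve
    scr = {2.5: PolynomialCurve(tuple(0.6 * c for c in md.coefficients)),
           50.0: md,
           97.5: PolynomialCurve(tuple(1.5 * c for c in md.coefficients))}
    egfr = {p: PolynomialCurve((100.0 + p, 0.5)) for p in (2.5, 50.0, 97.5)}
    return scr, egfr


class TestRiTable:
    def test_row_count_and_examples(self, curves, params):
        rows = make_ri_table(*curves, params)
        assert len(rows) == 38
        assert rows[0].gw == 4 and rows[-1].gw == 41
        assert rows[0].scr_median == 54.3 and rows[0].scr_increment_pct == -1.7
        assert rows[-1].scr_median == 48.7 and rows[-1].scr_increment_pct == -11.9

    def test_ordering_within_each_analyte(self, curves, params):
        frame = ri_table_to_frame(make_ri_table(*curves, params))
        assert (frame.scr_lower < frame.scr_median).all()
        assert (frame.scr_median < frame.scr_upper).all()
        assert (frame.egfr_lower < frame.egfr_median).all()
        assert (frame.egfr_median < frame.egfr_upper).all()

    def test_configurable_egfr_baseline(self, curves, params):
        rows_a = make_ri_table(*curves, params, egfr_baseline=100.0)
        rows_b = make_ri_table(*curves, params, egfr_baseline=150.0)
        assert rows_a[0].egfr_increment_pct > rows_b[0].egfr_increment_pct


@pytest.fixture(scope="module")
def result(params):
    cohort = generate_cohort(CohortConfig(seed=31))
    return build_egfr_ri(cohort, params,
                         resample=ResampleConfig(max_attempts=30, seed=9),
                         search=DegreeSearchConfig(repeats=100, seed=9))


class TestEgfrPipeline:
    def test_limits_ordered(self, result):
        gws = np.arange(4, 42)
        assert np.all(result.curves[2.5](gws) < result.curves[50.0](gws))
        assert np.all(result.curves[50.0](gws) < result.curves[97.5](gws))

    def test_median_egfr_peaks_mid_pregnancy(self, result):
        gws = np.arange(4, 42)
        med = result.curves[50.0](gws)
        assert 20 <= gws[np.argmax(med)] <= 26
        assert med[np.argmax(med)] > med[0] and med[np.argmax(med)] > med[-1]

    def test_baseline_close_to_normal_gfr(self, result, params):
        # pre-implantation SCr sits near BSC, so the eGFR baseline sits near normal GFR
        assert result.baseline == pytest.approx(params.normal_gfr, rel=0.10)

    def test_degenerate_noise_collapses_interval(self, params):
        cohort = generate_cohort(CohortConfig(dispersion=0.0, seed=4))
        res = build_egfr_ri(cohort, params,
                            resample=ResampleConfig(max_attempts=3, seed=2),
                            search=DegreeSearchConfig(repeats=50, seed=2))
        # limits collapse onto the transformed truth curve up to the width of a
        # gestational period (the only remaining spread is across weeks in a bin)
        for gw in (22, 30, 36):
            truth = gestational_egfr(float(params.median_curve(gw)), gw, params)
            assert res.curves[2.5](gw) == pytest.approx(truth, rel=0.10)
            assert res.curves[97.5](gw) == pytest.approx(truth, rel=0.10)
            gap = res.curves[97.5](gw) - res.curves[2.5](gw)
            assert gap < 0.15 * truth
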