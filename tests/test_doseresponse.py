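"""Viability normalization, dose ladders, and median-effect fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from comboscreen import (
    ConcentrationResponse,
    DoseLadder,
    FitError,
    MedianEffectFit,
    NormalizationError,
    ParameterError,
    PlateRecord,
    fit_median_effect,
    make_ladder,
    normalize_viability,
    predict_fa,
)


def make_records(model="M1", treatment="drugA", doses=(1.0, 2.0), absorbances=None,
                 control_abs=(0.5, 0.5)):
    records = [
        PlateRecord(model, "control", 0.0, i + 1, a, True)
        for i, a in enumerate(control_abs)
    ]
    absorbances = absorbances or {d: [0.25] for d in doses}
    for d in doses:
        for i, a in enumerate(absorbances[d]):
            records.append(PlateRecord(model, treatment, d, i + 1, a))
    return records


class TestNormalizeViability:
    @pytest.mark.parametrize(
        "treated,expected",
        [(0.50, 100.0), (0.25, 50.0), (0.60, 120.0)],
    )
    def test_percent_of_control_mean(self, treated, expected):
        records = make_records(absorbances={1.0: [treated], 2.0: [treated]})
        (curve,) = normalize_viability(records)
        assert curve.viability[0][0] == pytest.approx(expected)

    def test_over_control_wells_are_retained_and_flagged(self):
        records = make_records(absorbances={1.0: [0.6], 2.0: [0.2]})
        (curve,) = normalize_viability(records)
        assert curve.viability[0][0] == pytest.approx(120.0)
        assert curve.over_control[0][0] and not curve.over_control[1][0]

    def test_control_wells_average_to_exactly_100(self):
        records = make_records(control_abs=(0.4, 0.5, 0.6))
        mean = np.mean([r.absorbance for r in records if r.is_control])
        viabs = [r.absorbance / mean * 100 for r in records if r.is_control]
        assert np.mean(viabs) == pytest.approx(100.0, abs=1e-12)

    def test_replicates_grouped_per_dose_in_increasing_order(self):
        records = make_records(doses=(2.0, 1.0),
                               absorbances={2.0: [0.1, 0.2], 1.0: [0.3]})
        (curve,) = normalize_viability(records)
        assert list(curve.doses) == [1.0, 2.0]
        assert curve.viability[1].size == 2

    def test_missing_controls_error_names_the_model(self):
        records = [PlateRecord("M7", "drugA", 1.0, 1, 0.2)]
        with pytest.raises(NormalizationError, match="M7"):
            normalize_viability(records)

    def test_zero_control_mean_is_rejected(self):
        records = make_records(control_abs=(0.0, 0.0))
        with pytest.raises(NormalizationError, match="nonpositive control mean"):
            normalize_viability(records)

    def test_negative_absorbance_rejected_at_record_level(self):
        with pytest.raises(ParameterError, match="negative absorbance"):
            PlateRecord("M1", "drugA", 1.0, 1, -0.1)

    def test_treated_well_at_zero_concentration_is_rejected(self):
        records = make_records() + [PlateRecord("M1", "drugA", 0.0, 9, 0.3)]
        with pytest.raises(NormalizationError, match="zero concentration"):
            normalize_viability(records)


class TestMakeLadder:
    @pytest.mark.parametrize(
        "ladder,expected",
        [
            (DoseLadder(10, 6, 10), [10, 1, 0.1, 0.01, 0.001, 0.0001]),
            (DoseLadder(1, 2, 2), [1, 0.5]),
        ],
    )
    def test_serial_dilution_from_top(self, ladder, expected):
        assert make_ladder(ladder) == pytest.approx(expected, rel=1e-12)

    @given(top=st.floats(0.01, 100.0), n=st.integers(2, 10))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_tenfold_ladders_contain_top_and_ten_percent_top(self, top, n):
        doses = make_ladder(DoseLadder(top, n, 10.0))
        assert doses[0] == top
        if n >= 2:
            assert np.any(np.isclose(doses, 0.1 * top, rtol=1e-9))

    def test_half_log_six_point_ladder_contains_ten_percent_top(self):
        doses = make_ladder(DoseLadder(5.0))
        assert np.any(np.isclose(doses, 0.5, rtol=1e-12))

    @pytest.mark.parametrize("kwargs", [dict(top=0), dict(top=-1),
                                        dict(top=1, dilution_factor=1.0),
                                        dict(top=1, n_points=1)])
    def test_invalid_ladder_parameters(self, kwargs):
        with pytest.raises(ParameterError):
            DoseLadder(**kwargs)


def median_effect_curve(dm, m, doses, model="M1", treatment="drugA"):
    doses = np.asarray(doses, dtype=float)
    fa = 1.0 / (1.0 + (dm / doses) ** m)
    return ConcentrationResponse(model, treatment, doses,
                                 [np.array([100.0 * (1 - f)]) for f in fa])


def grid_search_fit(curve, m_grid, dm_grid, clip_eps=0.005):
    """Independent brute-force least-squares oracle on the log-log plot."""
    fa = curve.mean_fa
    keep = (fa > clip_eps) & (fa < 1 - clip_eps)
    fa = fa[keep]
    x, y = np.log10(curve.doses[keep]), np.log10(fa / (1 - fa))
    best = (np.inf, None, None)
    for m in m_grid:
        for dm in dm_grid:
            sse = np.sum((y - m * (x - np.log10(dm))) ** 2)
            if sse < best[0]:
                best = (sse, dm, m)
    return best


class TestFitMedianEffect:
    def test_noiseless_data_recovers_parameters_exactly(self):
        doses = make_ladder(DoseLadder(10.0))
        curve = median_effect_curve(1.0, 2.0, sorted(doses))
        fit = fit_median_effect(curve)
        assert fit.dm == pytest.approx(1.0, abs=1e-9)
        assert fit.m == pytest.approx(2.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0)

    def test_two_point_fit_passes_through_median_effect_dose(self):
        # fa = 0.5 observed exactly at D = 1 pins Dm at 1 for any slope
        fa_low = 1.0 / (1.0 + (1.0 / 0.25) ** 1.3)
        curve = ConcentrationResponse(
            "M1", "drugA", [0.25, 1.0],
            [np.array([100 * (1 - fa_low)]), np.array([50.0])],
        )
        fit = fit_median_effect(curve)
        assert fit.dm == pytest.approx(1.0, rel=1e-9)
        assert fit.n_points_used == 2

    def test_noisy_fit_matches_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        doses = np.sort(make_ladder(DoseLadder(10.0)))
        fa_true = 1.0 / (1.0 + (1.0 / doses) ** 1.5)
        viab = 100.0 * (1 - fa_true) * (1 + rng.normal(0, 0.02, doses.size))
        curve = ConcentrationResponse("M1", "drugA", doses,
                                      [np.array([v]) for v in viab])
        fit = fit_median_effect(curve)
        sse_grid, dm_grid, m_grid = grid_search_fit(
            curve, np.linspace(0.5, 3.0, 501), np.logspace(-1, 1, 801)
        )
        assert fit.m == pytest.approx(m_grid, abs=0.01)
        assert fit.dm == pytest.approx(dm_grid, rel=0.01)
        # OLS must be at least as good as the best grid point
        fa_m = curve.mean_fa
        keep = (fa_m > 0.005) & (fa_m < 0.995)
        x = np.log10(doses[keep])
        y = np.log10(fa_m[keep] / (1 - fa_m[keep]))
        sse_fit = np.sum((y - fit.m * (x - np.log10(fit.dm))) ** 2)
        assert sse_fit <= sse_grid + 1e-12

    def test_clipped_points_excluded_by_default_but_countable(self):
        doses = np.array([0.001, 0.01, 0.5, 1.0, 2.0, 5.0])
        curve = median_effect_curve(1.0, 2.0, doses)
        fit = fit_median_effect(curve, clip_eps=0.005)
        assert fit.n_clipped == 2  # fa ~ 1e-6 and 1e-4 at the two lowest doses
        assert fit.n_points_used == 4
        fit_all = fit_median_effect(curve, clip_eps=0.005, include_clipped=True)
        assert fit_all.n_points_used == 6

    def test_too_few_interior_points_is_a_fit_error(self):
        curve = ConcentrationResponse(
            "M1", "drugA", [1.0, 2.0], [np.array([100.0]), np.array([99.9])]
        )
        with pytest.raises(FitError, match="usable points"):
            fit_median_effect(curve)

    def test_flat_response_gives_nonpositive_slope_error(self):
        curve = ConcentrationResponse(
            "M1", "drugA", [1.0, 2.0, 4.0],
            [np.array([40.0]), np.array([50.0]), np.array([60.0])],
        )
        with pytest.raises(FitError, match="nonpositive"):
            fit_median_effect(curve)


class TestPredictFa:
    def test_definitional_points(self, noiseless_fit):
        assert predict_fa(noiseless_fit, noiseless_fit.dm) == pytest.approx(0.5)
        assert predict_fa(noiseless_fit, 0.0) == 0.0

    def test_hyperbolic_case(self):
        fit = MedianEffectFit("M1", "d", dm=1.0, m=1.0, r2=1.0, n_points_used=6)
        assert predict_fa(fit, 3.0) == pytest.approx(0.75)

    @given(st.data())
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_monotone_nondecreasing_in_dose(self, data):
        dm = data.draw(st.floats(0.01, 100.0))
        m = data.draw(st.floats(0.2, 5.0))
        fit = MedianEffectFit("M1", "d", dm=dm, m=m, r2=1.0, n_points_used=6)
        doses = np.sort(
            np.array(data.draw(st.lists(st.floats(0.0, 1e4), min_size=2, max_size=10)))
        )
        fa = predict_fa(fit, doses)
        assert np.all(np.diff(fa) >= -1e-15)
        assert np.all((fa >= 0) & (fa <= 1))

    @given(dm=st.floats(0.05, 20.0), m=st.floats(0.5, 4.0))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_roundtrip_fit_recovers_parameters(self, dm, m):
        """Forward-simulated ladders refit to the same (Dm, m) near machine precision."""
        doses = np.sort(make_ladder(DoseLadder(top=dm * 10.0)))
        curve = median_effect_curve(dm, m, doses)
        interior = (curve.mean_fa > 0.005) & (curve.mean_fa < 0.995)
        if interior.sum() < 2:
            return
        fit = fit_median_effect(curve)
        assert fit.dm == pytest.approx(dm, rel=1e-8)
        assert fit.m == pytest.approx(m, rel=1e-8)
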