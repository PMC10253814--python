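"""Boltzmann-sigmoid model, fitting, and cross-condition comparisons."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fibrilkit import datasets
from fibrilkit.errors import (
    AlignmentError,
    DegenerateParameterError,
    GroupingError,
    NoTransitionError,
    OrderingError,
    ValidationError,
    ZeroRangeError,
)
from fibrilkit.kinetics import (
    KineticTrace,
    aggregate_replicates,
    aggregation_rate,
    boltzmann_model,
    fit_sigmoid,
    normalize_trace,
    parse_condition,
    rank_conditions,
    reduction_percent,
)
from fibrilkit.synthetic import KineticsSpec, make_kinetics


class TestBoltzmannModel:
    def test_midpoint_value(self):
        assert boltzmann_model(79.0, 2.0, 10.0, 67.0, 79.0) == pytest.approx(6.0)

    def test_asymptotes(self):
        assert boltzmann_model(1e6, 0.0, 1.0, 67.0, 79.0) == pytest.approx(1.0)
        assert boltzmann_model(-1e6, 0.0, 1.0, 67.0, 79.0) == pytest.approx(0.0)

    def test_value_at_lag_time(self):
        # closed form: y1 + (y2-y1)/(1+e^2)
        expected = 3.0 + (11.0 - 3.0) / (1.0 + np.e**2)
        assert boltzmann_model(50.0, 3.0, 11.0, 50.0, 60.0) == pytest.approx(expected)
        assert expected == pytest.approx(3.0 + 0.11920292 * 8.0, abs=1e-6)

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(DegenerateParameterError):
            boltzmann_model(10.0, 0.0, 1.0, 50.0, 50.0)

    @given(
        t1=st.floats(-50, 250),
        t2=st.floats(-50, 250),
        y2=st.floats(0.5, 100.0),
    )
    def test_strictly_increasing_for_growth(self, t1, t2, y2):
        v1 = boltzmann_model(t1, 0.0, y2, 30.0, 40.0)
        v2 = boltzmann_model(t2, 0.0, y2, 30.0, 40.0)
        if t1 + 1e-6 < t2:  # resolvable separation in float64
            assert v1 < v2

    @given(dt=st.floats(0.0, 100.0))
    def test_point_symmetry_about_half_time(self, dt):
        y1, y2, t_lag, t_half = 1.0, 5.0, 30.0, 45.0
        above = boltzmann_model(t_half + dt, y1, y2, t_lag, t_half)
        below = boltzmann_model(t_half - dt, y1, y2, t_lag, t_half)
        assert above + below == pytest.approx(y1 + y2, rel=1e-12)


class TestAggregationRate:
    @pytest.mark.parametrize(
        "t_lag,t_half,expected",
        [
            (66.93, 79.42, 0.160),  # IL-free control
            (33.61, 35.71, 0.952),  # EMIM HSO4 10 mM
            (10.0, 12.0, 1.0),  # 2-minute gap
        ],
    )
    def test_worked_examples(self, t_lag, t_half, expected):
        assert round(aggregation_rate(t_lag, t_half), 3) == pytest.approx(expected)

    def test_ordering_enforced(self):
        with pytest.raises(OrderingError):
            aggregation_rate(50.0, 50.0)
        with pytest.raises(OrderingError):
            aggregation_rate(50.0, 40.0)

    def test_reference_table_consistency(self):
        """2/(t_half - t_lag) reproduces every tabulated k_agg within the
        rounding window implied by two-decimal inputs."""
        ref = datasets.load_kinetics_reference()
        for _, row in ref.iterrows():
            lo = 2.0 / (row.t_half_min - row.t_lag_min + 0.01)
            hi = 2.0 / (row.t_half_min - row.t_lag_min - 0.01)
            assert lo - 5e-4 <= row.k_agg_min_inv <= hi + 5e-4, row.condition


class TestFitSigmoid:
    def test_exact_recovery_noise_free(self):
        spec = KineticsSpec(y1=0.0, y2=1.0, t_lag=67.0, t_half=79.0, noise_sd=0.0,
                            n_replicates=1)
        fit = fit_sigmoid(make_kinetics(spec)[0])
        assert fit.converged
        assert fit.t_lag == pytest.approx(67.0, rel=1e-4)
        assert fit.t_half == pytest.approx(79.0, rel=1e-4)
        assert fit.y1 == pytest.approx(0.0, abs=1e-6)
        assert fit.y2 == pytest.approx(1.0, rel=1e-4)
        assert fit.k_agg == pytest.approx(2.0 / 12.0, rel=1e-3)

    def test_constant_trace_raises(self):
        t = np.arange(5, dtype=float)
        with pytest.raises(NoTransitionError):
            fit_sigmoid(KineticTrace(times=t, intensities=np.ones(5)))

    def test_k_agg_consistent_with_parameters(self):
        spec = KineticsSpec(t_lag=30.0, t_half=40.0, noise_sd=0.02, seed=3,
                            n_replicates=1)
        fit = fit_sigmoid(make_kinetics(spec)[0])
        assert fit.k_agg == pytest.approx(2.0 / (fit.t_half - fit.t_lag), rel=1e-12)

    def test_noisy_recovery_within_5_percent(self):
        spec = KineticsSpec(t_lag=67.0, t_half=79.0, noise_sd=0.02, seed=42,
                            n_replicates=1)
        fit = fit_sigmoid(make_kinetics(spec)[0])
        assert abs(fit.t_lag - 67.0) / 67.0 < 0.05
        assert abs(fit.t_half - 79.0) / 79.0 < 0.05

    def test_monte_carlo_median_recovery(self):
        """Median relative error over noisy traces: t_half < 2%, t_lag < 5%."""
        errs_lag, errs_half = [], []
        for seed in range(100):
            spec = KineticsSpec(t_lag=40.0, t_half=50.0, noise_sd=0.02, seed=seed,
                                n_replicates=1)
            fit = fit_sigmoid(make_kinetics(spec)[0])
            errs_lag.append(abs(fit.t_lag - 40.0) / 40.0)
            errs_half.append(abs(fit.t_half - 50.0) / 50.0)
        assert np.median(errs_half) < 0.02
        assert np.median(errs_lag) < 0.05

    def test_tangent_at_half_time_intercepts_baseline_at_lag_time(self):
        """The tangent construction that defines t_lag holds on a fitted curve."""
        spec = KineticsSpec(t_lag=30.0, t_half=42.0, noise_sd=0.01, seed=7,
                            n_replicates=1)
        fit = fit_sigmoid(make_kinetics(spec)[0])
        h = 1e-4 * (fit.t_half - fit.t_lag)
        args = (fit.y1, fit.y2, fit.t_lag, fit.t_half)
        slope = (
            boltzmann_model(fit.t_half + h, *args)
            - boltzmann_model(fit.t_half - h, *args)
        ) / (2 * h)
        assert slope == pytest.approx((fit.y2 - fit.y1) * fit.k_agg / 4.0, rel=1e-6)
        midpoint = boltzmann_model(fit.t_half, *args)
        intercept = fit.t_half - (midpoint - fit.y1) / slope
        assert intercept == pytest.approx(fit.t_lag, rel=1e-6)

    def test_steep_underdetermined_fit_is_flagged(self):
        # two-point rise: lag and half-time nearly coincide, errors blow up
        t = np.arange(0.0, 101.0, 10.0)
        spec = KineticsSpec(t_lag=48.0, t_half=50.0, noise_sd=0.08, seed=2,
                            n_replicates=1, time_grid=t)
        fit = fit_sigmoid(make_kinetics(spec)[0])
        assert fit.flagged


class TestNormalizeTrace:
    def test_plateau_and_midpoint_mapping(self, clean_trace):
        fit = fit_sigmoid(clean_trace)
        norm = normalize_trace(clean_trace, fit)
        # fitted plateaus map to 0/1; midpoint maps to 0.5
        assert norm.intensities[0] == pytest.approx(0.0, abs=1e-3)
        assert norm.intensities[-1] == pytest.approx(1.0, abs=1e-3)
        mid = np.interp(fit.t_half, norm.times, norm.intensities)
        assert mid == pytest.approx(0.5, abs=1e-3)

    def test_matches_unit_sigmoid_for_clean_trace(self, clean_trace):
        fit = fit_sigmoid(clean_trace)
        norm = normalize_trace(clean_trace, fit)
        expected = boltzmann_model(norm.times, 0.0, 1.0, fit.t_lag, fit.t_half)
        np.testing.assert_allclose(norm.intensities, expected, atol=1e-6)

    def test_refit_of_normalized_trace_has_unit_plateaus(self, clean_trace):
        fit = fit_sigmoid(clean_trace)
        refit = fit_sigmoid(normalize_trace(clean_trace, fit))
        assert refit.y1 == pytest.approx(0.0, abs=1e-3)
        assert refit.y2 == pytest.approx(1.0, abs=1e-3)

    def test_zero_range_rejected(self, clean_trace):
        from fibrilkit.kinetics import SigmoidFit

        bad = SigmoidFit(y1=1.0, y2=1.0, t_lag=10.0, t_half=20.0, k_agg=0.2)
        with pytest.raises(ZeroRangeError):
            normalize_trace(clean_trace, bad)


class TestAggregateReplicates:
    def test_mean_and_average_deviation(self):
        t = np.arange(5, dtype=float)
        traces = [
            KineticTrace(times=t, intensities=np.full(5, v), replicate=i)
            for i, v in enumerate((1.0, 2.0, 3.0))
        ]
        rset = aggregate_replicates(traces)
        np.testing.assert_allclose(rset.mean_trace.intensities, 2.0)
        np.testing.assert_allclose(rset.avg_dev_trace, 2.0 / 3.0)

    def test_identical_traces_zero_deviation(self, clean_trace):
        rset = aggregate_replicates([clean_trace] * 3)
        np.testing.assert_allclose(rset.avg_dev_trace, 0.0, atol=1e-12)

    def test_single_trace_degenerate(self, clean_trace):
        rset = aggregate_replicates([clean_trace])
        np.testing.assert_allclose(
            rset.mean_trace.intensities, clean_trace.intensities
        )
        np.testing.assert_allclose(rset.avg_dev_trace, 0.0)

    def test_mismatched_grids_rejected(self, clean_trace):
        other = KineticTrace(
            times=clean_trace.times + 1.0,
            intensities=clean_trace.intensities,
        )
        with pytest.raises(AlignmentError):
            aggregate_replicates([clean_trace, other])


def _fits_from_reference(concentration=None):
    from fibrilkit.kinetics import SigmoidFit

    ref = datasets.load_kinetics_reference()
    fits = {}
    for _, row in ref.iterrows():
        anion, conc = parse_condition(row.condition)
        if concentration is not None and anion is not None and conc != concentration:
            continue
        if concentration is not None and anion is None:
            continue
        fits[row.condition] = SigmoidFit(
            y1=0.0,
            y2=1.0,
            t_lag=row.t_lag_min,
            t_half=row.t_half_min,
            k_agg=row.k_agg_min_inv,
            condition=row.condition,
        )
    return fits


class TestReductionPercent:
    def test_tabulated_reductions(self):
        fits = _fits_from_reference()
        control = fits["control"]
        r = reduction_percent(fits["EMIM BF4 [10 mM]"], control, "t_lag")
        assert r == pytest.approx(53.67, abs=0.01)
        assert 30.0 <= r <= 55.0
        r = reduction_percent(fits["EMIM NO3 [100 mM]"], control, "t_half")
        assert r == pytest.approx(74.62, abs=0.01)
        assert 55.0 <= r <= 75.0

    def test_identity_is_zero(self):
        fits = _fits_from_reference()
        assert reduction_percent(fits["control"], fits["control"], "t_lag") == 0.0

    def test_nonpositive_control_rejected(self):
        from fibrilkit.kinetics import SigmoidFit

        bad = SigmoidFit(y1=0, y2=1, t_lag=0.0, t_half=10.0, k_agg=0.2)
        good = SigmoidFit(y1=0, y2=1, t_lag=5.0, t_half=10.0, k_agg=0.4)
        with pytest.raises(ValidationError):
            reduction_percent(good, bad, "t_lag")


class TestRankConditions:
    def test_100mM_reverse_electroselectivity_match(self):
        fits = _fits_from_reference(concentration=100.0)
        ordered, match = rank_conditions(fits, "t_half")
        anions = [parse_condition(lbl)[0] for lbl in ordered]
        assert anions == ["BF4", "NO3", "Cl", "AC", "HSO4"]
        assert match == "reverse"

    def test_25mM_no_match(self):
        fits = _fits_from_reference(concentration=25.0)
        ordered, match = rank_conditions(fits, "t_half")
        anions = [parse_condition(lbl)[0] for lbl in ordered]
        assert anions == ["NO3", "BF4", "HSO4", "AC", "Cl"]
        assert match == "none"

    def test_single_condition_has_no_verdict(self):
        fits = _fits_from_reference(concentration=100.0)
        (label, fit), = [list(fits.items())[0]]
        ordered, match = rank_conditions({label: fit}, "t_half")
        assert ordered == [label]
        assert match is None

    def test_mixed_concentrations_rejected(self):
        fits = _fits_from_reference()
        subset = {
            "EMIM Cl [10 mM]": fits["EMIM Cl [10 mM]"],
            "EMIM Cl [100 mM]": fits["EMIM Cl [100 mM]"],
        }
        with pytest.raises(GroupingError):
            rank_conditions(subset, "t_half")


class TestTraceValidation:
    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            KineticTrace(times=[0, 1, 2], intensities=[0, 1, 2])

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValidationError):
            KineticTrace(times=[0, 1, 1, 2, 3], intensities=np.zeros(5))

    def test_condition_label_parsing(self):
        assert parse_condition("control") == (None, 0.0)
        assert parse_condition("EMIM HSO4 [100 mM]") == ("HSO4", 100.0)
        assert parse_condition("NO3 [25 mM]") == ("NO3", 25.0)
        with pytest.raises(ValidationError):
            parse_condition("EMIM SCN [10 mM]")
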