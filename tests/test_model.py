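"""Forward-model layer: time transform, Hill laws, RTF evaluation,
fold-changes and parameter accounting."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtfit import (
    DoseParams,
    FoldChangeSet,
    HillTriplet,
    ModelSpec,
    SingleDoseParams,
    SpecError,
    apply_fold_changes,
    count_free_parameters,
    dose_params_at,
    eval_dose_rtf,
    eval_hill,
    eval_rtf,
    free_parameter_names,
    transform_time,
)


def make_dose_params(**overrides):
    base = dict(
        A=HillTriplet(M=2.0, K=1.5, h=2.0),
        B=HillTriplet(M=1.0, K=2.0, h=3.0),
        alpha=HillTriplet(M=0.8, K=1.0, h=1.5),
        beta=HillTriplet(M=1.2, K=1.5, h=2.0),
        gamma=HillTriplet(M=0.5, K=2.5, h=1.0),
        tau=HillTriplet(M=1.0, K=1.8, h=2.0, direction="decreasing"),
        b=0.3,
        sigma=0.1,
    )
    base.update(overrides)
    return DoseParams(**base)


class TestTransformTime:
    @pytest.mark.parametrize("tau,T", [(0.3, 5.0), (-2.0, 1.0), (5.0, 100.0)])
    def test_zero_at_origin(self, tau, T):
        assert transform_time(0.0, tau, T) == 0.0

    def test_negligible_shift_recovers_rescaled_time(self):
        # with 10^tau -> 0 both logs reduce to 10*t_real/T
        assert transform_time(7.0, -12.0, 7.0) == pytest.approx(10.0, abs=1e-8)

    def test_hand_computed_value(self):
        # exponent 10*1/10 = 1: log10((10 + 1)/2) = log10(5.5)
        assert transform_time(1.0, 0.0, 10.0) == pytest.approx(np.log10(5.5), abs=1e-12)

    def test_overflow_guarded(self):
        out = transform_time(400.0, 500.0, 1.0)
        assert np.isfinite(out) and out >= 0.0

    @given(t=st.floats(0.0, 50.0), tau=st.floats(-20.0, 20.0),
           T=st.floats(0.1, 100.0))
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_monotonicity(self, t, tau, T):
        val = transform_time(t, tau, T)
        assert -1e-9 <= val <= 10.0 * t / T + 1e-9
        assert transform_time(t + 0.5, tau, T) >= val          # increasing in t
        assert transform_time(t, tau + 0.5, T) <= val + 1e-12  # non-increasing in tau

    @pytest.mark.parametrize("bad", [np.nan, np.inf])
    def test_non_finite_rejected(self, bad):
        with pytest.raises(ValueError):
            transform_time(bad, 0.0, 1.0)
        with pytest.raises(ValueError):
            transform_time(1.0, bad, 1.0)

    def test_nonpositive_range_rejected(self):
        with pytest.raises(ValueError):
            transform_time(1.0, 0.0, 0.0)


class TestHill:
    def test_half_maximal_point(self):
        assert eval_hill(HillTriplet(M=2.0, K=3.0, h=5.0), 3.0) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # 3 * 3^4 / (2^4 + 3^4) = 243/97
        got = eval_hill(HillTriplet(M=3.0, K=2.0, h=4.0), 3.0)
        assert got == pytest.approx(243.0 / 97.0, rel=1e-12)

    def test_decreasing_at_zero_dose(self):
        trip = HillTriplet(M=1.0, K=1.0, h=2.0, direction="decreasing")
        assert eval_hill(trip, 0.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("direction", ["increasing", "decreasing"])
    def test_k_zero_is_constant(self, direction):
        trip = HillTriplet(M=1.7, K=0.0, h=3.0, direction=direction)
        for d in (0.0, 0.5, 10.0, 1e6):
            assert eval_hill(trip, d) == 1.7

    def test_range_and_monotonicity(self):
        doses = np.linspace(0.0, 50.0, 200)
        inc = eval_hill(HillTriplet(M=2.0, K=5.0, h=2.0), doses)
        assert np.all(np.diff(inc) > 0)
        assert inc[0] == 0.0 and inc[-1] < 2.0
        dec = eval_hill(HillTriplet(M=2.0, K=5.0, h=2.0, direction="decreasing"), doses)
        assert np.all(np.diff(dec) < 0)
        assert dec[0] == 2.0

    def test_negative_amplitude_range(self):
        vals = eval_hill(HillTriplet(M=-1.5, K=2.0, h=1.0), np.linspace(0, 100, 50))
        assert np.all(vals <= 0.0) and vals.min() > -1.5

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            eval_hill(HillTriplet(M=1.0, K=1.0, h=1.0), -0.1)

    def test_invalid_triplet_rejected(self):
        with pytest.raises(ValueError):
            HillTriplet(M=1.0, K=-1.0, h=1.0)
        with pytest.raises(ValueError):
            HillTriplet(M=1.0, K=1.0, h=0.0)


class TestEvalRtf:
    @given(A=st.floats(-2, 3), B=st.floats(-2, 3), alpha=st.floats(0.01, 5),
           beta=st.floats(0.01, 5), gamma=st.floats(0.01, 5),
           tau=st.floats(-3, 3), b=st.floats(-2, 2))
    @settings(max_examples=100, deadline=None)
    def test_offset_at_time_zero(self, A, B, alpha, beta, gamma, tau, b):
        p = SingleDoseParams(A, B, alpha, beta, gamma, tau, b)
        assert eval_rtf(0.0, p, 5.0) == pytest.approx(b, abs=1e-12)

    def test_sustained_only_value(self):
        # tau = -12 makes transformed time = 10*t_real/T; pick t' = 2
        p = SingleDoseParams(A=2.0, B=0.0, alpha=0.5, beta=1.0, gamma=1.0,
                             tau=-12.0, b=1.0)
        expect = 2.0 * (1.0 - np.exp(-1.0)) + 1.0
        assert eval_rtf(2.0, p, 10.0) == pytest.approx(expect, abs=1e-6)

    def test_full_value_at_unit_transformed_time(self):
        p = SingleDoseParams(A=1.0, B=2.0, alpha=1.0, beta=2.0, gamma=0.5,
                             tau=-12.0, b=0.0)
        expect = (1.0 - np.exp(-1.0)) + 2.0 * (1.0 - np.exp(-2.0)) * np.exp(-0.5)
        assert eval_rtf(1.0, p, 10.0) == pytest.approx(expect, abs=1e-6)

    def test_long_time_limit_is_sustained_plateau(self):
        p = SingleDoseParams(A=1.4, B=2.0, alpha=0.7, beta=2.0, gamma=0.5,
                             tau=0.4, b=-0.2)
        T = 5.0
        val = eval_rtf(1e6 * T, p, T)
        assert val == pytest.approx(p.A + p.b, abs=1e-6 * abs(p.A))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SingleDoseParams(A=1, B=0, alpha=-0.1, beta=1, gamma=1, tau=0, b=0)
        with pytest.raises(ValueError):
            SingleDoseParams(A=1, B=0, alpha=1, beta=1, gamma=1, tau=0, b=0, sigma=0)


class TestDoseParamsAt:
    def test_all_k_zero_returns_maxima(self):
        dp = make_dose_params(
            A=HillTriplet.constant(2.0), B=HillTriplet.constant(1.0),
            alpha=HillTriplet.constant(0.8), beta=HillTriplet.constant(1.2),
            gamma=HillTriplet.constant(0.5),
            tau=HillTriplet.constant(1.0, "decreasing"))
        p = dose_params_at(dp, 2.0)
        assert (p.A, p.B, p.alpha, p.beta, p.gamma, p.tau) == (2.0, 1.0, 0.8, 1.2, 0.5, 1.0)
        assert (p.b, p.sigma) == (dp.b, dp.sigma)

    def test_half_maximal_dose_halves_everything(self):
        K, h = 2.0, 3.0
        dp = make_dose_params(
            A=HillTriplet(2.0, K, h), B=HillTriplet(1.0, K, h),
            alpha=HillTriplet(0.8, K, h), beta=HillTriplet(1.2, K, h),
            gamma=HillTriplet(0.5, K, h),
            tau=HillTriplet(1.0, K, h, "decreasing"))
        p = dose_params_at(dp, K)
        for name, M in [("A", 2.0), ("B", 1.0), ("alpha", 0.8),
                        ("beta", 1.2), ("gamma", 0.5), ("tau", 1.0)]:
            assert getattr(p, name) == pytest.approx(M / 2.0)

    def test_hand_computed_amplitude(self):
        dp = make_dose_params(A=HillTriplet(M=4.0, K=1.0, h=1.0))
        assert dose_params_at(dp, 3.0).A == pytest.approx(3.0)

    def test_tie_applied_after_hill_evaluation(self):
        dp = make_dose_params()
        p = dose_params_at(dp, 1.3, ties={"gamma": "alpha"})
        assert p.gamma == p.alpha
        assert p.alpha == eval_hill(dp.alpha, 1.3)


class TestEvalDoseRtf:
    def test_k_zero_degeneracy(self):
        vals = dict(A=2.0, B=1.0, alpha=0.8, beta=1.2, gamma=0.5, tau=1.0)
        dp = make_dose_params(
            A=HillTriplet.constant(vals["A"]), B=HillTriplet.constant(vals["B"]),
            alpha=HillTriplet.constant(vals["alpha"]),
            beta=HillTriplet.constant(vals["beta"]),
            gamma=HillTriplet.constant(vals["gamma"]),
            tau=HillTriplet.constant(vals["tau"], "decreasing"))
        p = SingleDoseParams(b=dp.b, sigma=dp.sigma, **vals)
        T = 8.0
        for t in np.linspace(0.0, T, 9):
            ref = eval_rtf(t, p, T)
            for d in (0.01, 1.0, 5.0, 1e3):
                got = eval_dose_rtf(t, d, dp, T)
                assert got == pytest.approx(ref, rel=1e-12, abs=1e-12)

    def test_offset_at_time_zero_any_dose(self):
        dp = make_dose_params()
        for d in (0.0, 0.7, 3.0, 100.0):
            assert eval_dose_rtf(0.0, d, dp, 5.0) == pytest.approx(dp.b, abs=1e-12)

    def test_matches_composition_of_primitives(self):
        # independent recomposition from eval_hill + transform_time + Eq. of R
        dp = make_dose_params()
        T = 6.0
        for t in np.linspace(0.0, T, 5):
            for d in (0.5, 1.8, 4.0):
                A = eval_hill(dp.A, d)
                B = eval_hill(dp.B, d)
                alpha = eval_hill(dp.alpha, d)
                beta = eval_hill(dp.beta, d)
                gamma = eval_hill(dp.gamma, d)
                tau = eval_hill(dp.tau, d)
                tt = transform_time(t, tau, T)
                expect = (A * (1 - np.exp(-alpha * tt))
                          + B * (1 - np.exp(-beta * tt)) * np.exp(-gamma * tt)
                          + dp.b)
                assert eval_dose_rtf(t, d, dp, T) == pytest.approx(expect, rel=1e-12)

    def test_monotone_in_dose_for_activating_surface(self):
        dp = make_dose_params()
        T = 6.0
        doses = np.linspace(0.0, 10.0, 30)
        for t in (0.5, 1.0, 3.0, 6.0):
            vals = [eval_dose_rtf(t, d, dp, T) for d in doses]
            assert np.all(np.diff(vals) >= -1e-12)


class TestFoldChanges:
    def test_identity_at_unit_deltas(self):
        dp = make_dose_params()
        out = apply_fold_changes(dp, FoldChangeSet({"A_M": 1.0, "tau_K": 1.0}))
        assert out == dp

    def test_scaling(self):
        dp = make_dose_params(A=HillTriplet(M=1.5, K=2.0, h=1.0))
        out = apply_fold_changes(dp, FoldChangeSet({"A_M": 2.0}))
        assert out.A.M == pytest.approx(3.0)

    def test_untouched_fields_shared(self):
        dp = make_dose_params()
        out = apply_fold_changes(dp, FoldChangeSet({"A_M": 2.0, "A_K": 0.5}))
        for name in ("B", "alpha", "beta", "gamma", "tau"):
            assert getattr(out, name) == getattr(dp, name)
        assert out.A.h == dp.A.h and out.b == dp.b and out.sigma == dp.sigma

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ValueError):
            FoldChangeSet({"A_M": 0.0})
        with pytest.raises(ValueError):
            FoldChangeSet({"A_M": -2.0})

    def test_unknown_target_rejected(self):
        with pytest.raises(SpecError):
            apply_fold_changes(make_dose_params(), FoldChangeSet({"zeta_M": 2.0}))


class TestModelSpecAccounting:
    @pytest.mark.parametrize("spec,expected", [
        (ModelSpec(dose_dependent=("A", "B", "alpha", "beta", "gamma", "tau")), 20),
        (ModelSpec.dose_response(), 11),
        (ModelSpec.single_dose(), 8),
        (ModelSpec.single_dose(transient=False), 5),
        (ModelSpec.single_dose(tie_rates=True), 7),
    ])
    def test_counts(self, spec, expected):
        assert count_free_parameters(spec) == expected
        assert len(free_parameter_names(spec)) == expected

    def test_individual_dose_counting(self):
        spec = ModelSpec.single_dose(transient=False)
        assert count_free_parameters(spec, n_doses_fitted_individually=7) == 35

    def test_individual_counting_requires_dose_independent_spec(self):
        with pytest.raises(SpecError):
            count_free_parameters(ModelSpec.dose_response(),
                                  n_doses_fitted_individually=7)

    def test_condition_deltas_counted(self):
        spec = ModelSpec.dose_response(
            conditions=("wt", "ko"), condition_dependent=("A_M", "alpha_K", "b"))
        assert count_free_parameters(spec) == 11 + 3
        names = free_parameter_names(spec)
        assert "delta_A_M_ko" in names and "delta_b_ko" in names

    def test_b_zero_removes_transient_rates(self):
        names = free_parameter_names(ModelSpec.single_dose(transient=False))
        assert names == ["A", "alpha", "tau", "b", "sigma"]

    def test_tie_to_dose_dependent_parameter_rejected(self):
        with pytest.raises(SpecError):
            ModelSpec(dose_dependent=("gamma",), ties={"gamma": "alpha"})

    def test_tie_to_absent_source_rejected(self):
        with pytest.raises(SpecError):
            ModelSpec(fixed_to_zero=("B",), ties={"alpha": "beta"})

    def test_sigma_cannot_be_condition_dependent(self):
        with pytest.raises(SpecError):
            ModelSpec(conditions=("a", "b"), condition_dependent=("sigma",))

    def test_spec_is_immutable(self):
        spec = ModelSpec.dose_response()
        with pytest.raises(dataclasses.FrozenInstanceError):
            spec.conditions = ("x",)
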