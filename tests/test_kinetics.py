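import numpy as np
import pytest

from myoflow import (
    InputFunctionModel,
    OneTissueParams,
    default_frame_schedule,
    fit_1tcm,
    forward_tac,
    simulate_input_function,
)
from myoflow.frames import SampledCurve
from myoflow.synthesis import add_frame_noise


class TestInputFunction:
    def test_zero_amplitude_gives_zero_curve(self, schedule):
        model = InputFunctionModel(amplitude=0.0)
        curve = simulate_input_function(model, schedule)
        assert np.all(curve.values == 0)

    def test_late_bolus_gives_zero_curve(self, schedule):
        model = InputFunctionModel(bolus_arrival_s=1000.0)
        curve = simulate_input_function(model, schedule)
        assert np.max(np.abs(curve.values)) < 1e-9

    def test_frame_averages_match_bruteforce_quadrature(self, input_model, schedule):
        """Analytic frame averages vs 10 000-point trapezoid per frame."""
        curve = simulate_input_function(input_model, schedule)
        for i, (start, dur) in enumerate(schedule.frames):
            t = np.linspace(start, start + dur, 10_000)
            ca = input_model.evaluate(t - schedule.pre_injection_offset_s)
            brute = np.trapezoid(ca, t) / dur
            assert abs(curve.values[i] - brute) < 1e-6 * input_model.amplitude

    @pytest.mark.parametrize(
        "kwargs",
        [{"shape_alpha": 0.0}, {"shape_beta": -1.0}, {"tail_rate": 0.0},
         {"recirculation_fraction": 1.0}, {"amplitude": -5.0}],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            InputFunctionModel(**kwargs)


class TestForwardModel:
    def test_no_uptake_gives_zero_tissue(self, input_curve, schedule):
        tac = forward_tac(input_curve, OneTissueParams(0.0, 0.3, 0.0), schedule)
        assert np.all(tac.values == 0)

    def test_irreversible_trapping_is_monotone(self, input_curve, schedule):
        tac = forward_tac(input_curve, OneTissueParams(1.0, 0.0, 0.0), schedule)
        assert np.all(np.diff(tac.values) >= 0)

    def test_linearity_in_k1_without_spillover(self, input_curve, schedule):
        base = forward_tac(input_curve, OneTissueParams(0.8, 0.25, 0.0), schedule)
        doubled = forward_tac(input_curve, OneTissueParams(1.6, 0.25, 0.0), schedule)
        nz = base.values > 0
        assert np.max(np.abs(doubled.values[nz] / base.values[nz] - 2.0)) < 1e-10

    def test_continuous_input_matches_fine_ode_solver(self, input_model, schedule):
        """Frame averages vs an RK4 discretization at 0.01 s steps."""
        params = OneTissueParams(K1=1.0, k2=0.2, fv=0.1)
        tac = forward_tac(input_model, params, schedule)

        dt = 0.01
        t = np.arange(0.0, schedule.total_time_s + dt / 2, dt)
        ca = input_model.evaluate(t - schedule.pre_injection_offset_s)
        k1c, k2c = params.K1 / 60.0, params.k2 / 60.0
        ct = np.zeros_like(t)
        for n in range(len(t) - 1):  # RK4 with linear interp of Ca
            ca_mid = 0.5 * (ca[n] + ca[n + 1])
            f = lambda c, a: k1c * a - k2c * c
            y = ct[n]
            s1 = f(y, ca[n])
            s2 = f(y + 0.5 * dt * s1, ca_mid)
            s3 = f(y + 0.5 * dt * s2, ca_mid)
            s4 = f(y + dt * s3, ca[n + 1])
            ct[n + 1] = y + dt / 6.0 * (s1 + 2 * s2 + 2 * s3 + s4)
        cmeas = (1 - params.fv) * ct + params.fv * ca
        oracle = np.array(
            [
                np.trapezoid(
                    cmeas[int(round(s / dt)) : int(round((s + d) / dt)) + 1], dx=dt
                )
                / d
                for s, d in schedule.frames
            ]
        )
        rel = np.abs(tac.values - oracle) / np.max(oracle)
        assert np.max(rel) < 1e-4

    def test_schedule_mismatch_raises(self, input_curve):
        other = default_frame_schedule(n_long=10)
        with pytest.raises(ValueError, match="schedule"):
            forward_tac(input_curve, OneTissueParams(1.0, 0.2, 0.0), other)


class TestFit:
    @pytest.mark.parametrize(
        "true",
        [
            OneTissueParams(1.2, 0.3, 0.15),
            OneTissueParams(0.4, 0.1, 0.05),
            OneTissueParams(2.5, 0.8, 0.30),
        ],
    )
    def test_noiseless_self_consistency(self, input_curve, schedule, true):
        """Exact-model identifiability: all parameters back within 1%."""
        tac = forward_tac(input_curve, true, schedule)
        res = fit_1tcm(tac, input_curve)
        assert res.converged
        assert abs(res.params.K1 - true.K1) / true.K1 < 0.01
        assert abs(res.params.k2 - true.k2) / true.k2 < 0.01
        assert abs(res.params.fv - true.fv) / true.fv < 0.01

    def test_all_zero_tac_returns_zero_k1_with_flag(self, input_curve, schedule):
        tac = SampledCurve(schedule, np.zeros(20))
        res = fit_1tcm(tac, input_curve)
        assert res.params.K1 == 0.0
        assert not res.converged

    def test_determinism(self, input_curve, schedule):
        true = OneTissueParams(1.1, 0.25, 0.1)
        rng = np.random.default_rng(7)
        tac = forward_tac(input_curve, true, schedule)
        noisy = add_frame_noise(tac, 5e4, rng)
        r1 = fit_1tcm(noisy, input_curve)
        r2 = fit_1tcm(noisy, input_curve)
        assert r1 == r2

    def test_too_few_frames_rejected(self):
        sched = default_frame_schedule(n_short=3, n_long=2)
        model = InputFunctionModel()
        inp = simulate_input_function(model, sched)
        tac = forward_tac(inp, OneTissueParams(1.0, 0.2, 0.1), sched)
        with pytest.raises(ValueError, match="6 frames"):
            fit_1tcm(tac, inp)

    def test_monte_carlo_recovery_at_clinical_count_level(self, input_curve, schedule):
        """Median |K1 error| < 10% over 200 seeded noisy replicates."""
        true = OneTissueParams(1.0, 0.3, 0.1)
        tac = forward_tac(input_curve, true, schedule)
        rng = np.random.default_rng(42)
        errors = []
        for _ in range(200):
            noisy = add_frame_noise(tac, 5e4, rng)
            res = fit_1tcm(noisy, input_curve)
            errors.append(abs(res.params.K1 - true.K1) / true.K1)
        assert np.median(errors) < 0.10

    def test_recovery_degrades_monotonically_with_noise(self, input_curve, schedule):
        """Median |K1 error| non-decreasing across 3 increasing noise levels."""
        true = OneTissueParams(1.0, 0.3, 0.1)
        tac = forward_tac(input_curve, true, schedule)
        medians = []
        for count_scale in (5e5, 5e4, 5e3):  # decreasing counts = more noise
            rng = np.random.default_rng(11)
            errs = [
                abs(fit_1tcm(add_frame_noise(tac, count_scale, rng), input_curve).params.K1 - true.K1)
                for _ in range(200)
            ]
            medians.append(np.median(errs))
        assert medians[0] <= medians[1] <= medians[2]
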