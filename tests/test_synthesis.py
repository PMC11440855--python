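import dataclasses
import math

import numpy as np
import pytest
from scipy import stats as sps

from myoflow import (
    NAC,
    CohortConfig,
    OneTissueParams,
    fit_1tcm,
    flow_from_k1,
    forward_tac,
    generate_cohort,
    generate_dynamic_study,
)
from myoflow.kinetics import InputFunctionModel, simulate_input_function
from myoflow.synthesis import (
    FLOW_CALIBRATION,
    add_frame_noise,
    lognormal_from_quartiles,
    spearman_to_gaussian,
)


class TestLognormalCalibration:
    @pytest.mark.parametrize("target", [(2.02, 1.71, 2.37), (0.86, 0.72, 1.02)])
    def test_median_and_iqr_width_match(self, target):
        med, q25, q75 = target
        mu, sigma = lognormal_from_quartiles(med, q25, q75)
        dist_med = math.exp(mu)
        dist_q25 = math.exp(mu + sigma * sps.norm.ppf(0.25))
        dist_q75 = math.exp(mu + sigma * sps.norm.ppf(0.75))
        assert dist_med == pytest.approx(med, rel=1e-12)
        assert dist_q75 - dist_q25 == pytest.approx(q75 - q25, rel=1e-9)

    def test_degenerate_zero_marginal(self):
        assert lognormal_from_quartiles(0.0, 0.0, 0.0) is None

    def test_zero_lower_quartile_fallback(self):
        mu, sigma = lognormal_from_quartiles(1.8, 0.0, 6.9)
        assert math.exp(mu + sigma * sps.norm.ppf(0.75)) == pytest.approx(6.9, rel=1e-9)

    def test_invalid_quartiles_rejected(self):
        with pytest.raises(ValueError):
            lognormal_from_quartiles(1.0, 2.0, 1.0)


class TestGenerateCohort:
    def test_determinism_same_seed(self):
        p1, t1 = generate_cohort(seed=123)
        p2, t2 = generate_cohort(seed=123)
        assert [dataclasses.asdict(a) for a in p1] == [dataclasses.asdict(b) for b in p2]
        assert [dataclasses.asdict(a) for a in t1] == [dataclasses.asdict(b) for b in t2]

    def test_different_seeds_differ(self):
        p1, _ = generate_cohort(seed=1)
        p2, _ = generate_cohort(seed=2)
        assert p1[0].flow["NAC"]["global"].stress_mbf != p2[0].flow["NAC"]["global"].stress_mbf

    def test_group_sizes(self):
        patients, truths = generate_cohort(CohortConfig(n_minoca=4, n_micad=7), seed=0)
        assert sum(p.group == "MINOCA" for p in patients) == 4
        assert sum(p.group == "MICAD" for p in patients) == 7
        assert all(p.group == t.group for p, t in zip(patients, truths))

    def test_calibration_recovery_large_n(self):
        """Generated medians converge to the configured Table medians (n=1000)."""
        cfg = CohortConfig(n_minoca=1000, n_micad=1000)
        patients, _ = generate_cohort(cfg, seed=9)
        for group, state, target in [
            ("MINOCA", "stress", FLOW_CALIBRATION[("NAC", "MINOCA", "stress")][0]),
            ("MICAD", "stress", FLOW_CALIBRATION[("NAC", "MICAD", "stress")][0]),
            ("MINOCA", "rest", FLOW_CALIBRATION[("NAC", "MINOCA", "rest")][0]),
        ]:
            vals = [
                getattr(p.flow["NAC"]["global"], f"{state}_mbf")
                for p in patients
                if p.group == group
            ]
            assert np.median(vals) == pytest.approx(target, rel=0.03)

    def test_copula_rank_correlation_recovery(self):
        """Troponin vs stress MBF Spearman within +-0.1 of the -0.4 target."""
        cfg = CohortConfig(n_minoca=1000, n_micad=1)
        patients, _ = generate_cohort(cfg, seed=17)
        minoca = [p for p in patients if p.group == "MINOCA"]
        flow = [p.flow["NAC"]["global"].stress_mbf for p in minoca]
        tn = [p.troponin_ng_ml[0] for p in minoca]
        rho = sps.spearmanr(flow, tn).statistic
        assert rho == pytest.approx(-0.4, abs=0.1)

    def test_zero_correlation_gives_independence(self):
        cfg = CohortConfig(n_minoca=1000, n_micad=1, troponin_spearman=0.0)
        patients, _ = generate_cohort(cfg, seed=5)
        minoca = [p for p in patients if p.group == "MINOCA"]
        flow = [p.flow["NAC"]["global"].stress_mbf for p in minoca]
        tn = [p.troponin_ng_ml[0] for p in minoca]
        assert abs(sps.spearmanr(flow, tn).statistic) < 0.1

    def test_injury_more_frequent_in_micad(self):
        cfg = CohortConfig(n_minoca=200, n_micad=200)
        _, truths = generate_cohort(cfg, seed=3)
        rates = {"MINOCA": [], "MICAD": []}
        for t in truths:
            rates[t.group].extend(t.injury.values())
        assert np.mean(rates["MICAD"]) > np.mean(rates["MINOCA"])
        assert np.mean(rates["MINOCA"]) == pytest.approx(5 / 30, abs=0.06)
        assert np.mean(rates["MICAD"]) == pytest.approx(34 / 63, abs=0.06)

    def test_injured_territory_flow_reduced(self):
        cfg = CohortConfig(n_minoca=1, n_micad=500)
        patients, truths = generate_cohort(cfg, seed=4)
        injured, healthy = [], []
        for p, t in zip(patients, truths):
            for terr in ("LAD", "LCx", "RCA"):
                (injured if t.injury[terr] else healthy).append(
                    p.flow["NAC"][terr].stress_mbf
                )
        assert np.median(injured) < np.median(healthy)

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(troponin_spearman=-1.0)
        with pytest.raises(ValueError):
            spearman_to_gaussian(1.5)


@pytest.fixture(scope="module")
def truth():
    _, truths = generate_cohort(CohortConfig(n_minoca=1, n_micad=1), seed=6)
    return truths[0]


class TestDynamicStudy:

    def test_infinite_counts_reproduce_noiseless_forward(self, truth):
        study = generate_dynamic_study(truth, count_scale=np.inf, seed=0)
        inp = study.curves[("stress", "input")]
        params = study.true_params[("stress", "global")]
        clean = forward_tac(inp, params, study.schedule)
        assert np.allclose(study.curves[("stress", "global")].values, clean.values)

    def test_high_count_limit_converges(self, truth):
        """At 1e7 peak-frame counts the noisy curve deviates < 0.5%."""
        clean = generate_dynamic_study(truth, count_scale=np.inf, seed=1)
        noisy = generate_dynamic_study(truth, count_scale=1e7, seed=1)
        ref = clean.curves[("stress", "global")].values
        dev = np.abs(noisy.curves[("stress", "global")].values - ref) / ref.max()
        assert dev.max() < 0.005

    def test_stress_rest_dose_ratio(self, truth):
        """Noiseless input amplitudes scale 3x with the injected dose."""
        study = generate_dynamic_study(truth, count_scale=np.inf, seed=0)
        ratio = (
            study.curves[("stress", "input")].values.max()
            / study.curves[("rest", "input")].values.max()
        )
        assert ratio == pytest.approx(3.0, rel=1e-9)

    def test_determinism(self, truth):
        s1 = generate_dynamic_study(truth, seed=11)
        s2 = generate_dynamic_study(truth, seed=11)
        for key in s1.curves:
            assert np.array_equal(s1.curves[key].values, s2.curves[key].values)

    def test_end_to_end_recovery(self, truth):
        """simulate -> fit -> invert recovers true stress MBF within 10% (median)."""
        errors = []
        for seed in range(100):
            study = generate_dynamic_study(truth, seed=seed, regions=("global",))
            res = fit_1tcm(
                study.curves[("stress", "global")], study.curves[("stress", "input")]
            )
            mbf_hat = flow_from_k1(res.params.K1, NAC)
            true_mbf = truth.flows["NAC"]["global"]["stress"]
            errors.append(abs(mbf_hat - true_mbf) / true_mbf)
        assert np.median(errors) < 0.10


class TestFrameNoise:
    def test_zero_peak_passthrough(self, schedule):
        from myoflow.frames import SampledCurve

        curve = SampledCurve(schedule, np.zeros(20))
        rng = np.random.default_rng(0)
        out = add_frame_noise(curve, 5e4, rng)
        assert np.all(out.values == 0)

    def test_nonpositive_scale_rejected(self, input_curve):
        with pytest.raises(ValueError):
            add_frame_noise(input_curve, 0.0, np.random.default_rng(0))
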