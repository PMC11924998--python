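"""Stay regression, RT contrast, group tests, and covariate adjustments."""

import numpy as np
import pandas as pd
import pytest

from fourstep.behav_stats import (
    CovariateRecord,
    build_stay_design,
    covariates_to_frame,
    group_tests,
    lesion_volume_regression,
    pooled_stay_design,
    residualize,
    rt_contrast,
    stay_regression,
)
from fourstep.cohort import CohortSpec, make_covariates
from fourstep.twostep_model import TwoStepParams, simulate_agent
from fourstep.twostep_task import TaskConfig, generate_schedule, trials_to_frame


def _sim_frame(params, rng, subject="s0"):
    sch = generate_schedule(TaskConfig(), rng)
    return trials_to_frame(simulate_agent(params, sch, rng), subject)


class TestStayDesign:
    def test_design_has_n_minus_1_rows(self, rng):
        df = _sim_frame(TwoStepParams(), rng)
        d = build_stay_design(df)
        assert len(d.stay) == len(df) - 1

    def test_always_repeat_agent_stays_everywhere(self, rng):
        df = _sim_frame(TwoStepParams(p=60.0, beta_mf=0.001, beta_mb=0.001),
                        rng)
        d = build_stay_design(df)
        assert d.stay.min() == 1.0
        with pytest.raises(ValueError):
            stay_regression(d)

    def test_correct_indicator_on_worked_example(self):
        # hand-built 5-trial table: high shape 0 lives in state A (=1);
        # choice1=0 commonly leads to state A, so correct=1 iff the
        # previous choice1 was 0 while shape 0 (or 1) was high
        df = pd.DataFrame({
            "subject_id": "s",
            "trial": range(5),
            "choice1": [0, 1, 0, 1, 0],
            "transition": ["common"] * 5,
            "state2": [1, 2, 1, 2, 1],
            "choice2": [0, 0, 0, 0, 0],
            "reward": [1, 0, 1, 0, 0],
            "rt2_ms": [500.0] * 5,
            "high_shape": [0, 0, 0, 3, 3],
        })
        d = build_stay_design(df)
        # previous trials 0..3: choice1 = 0,1,0,1; high state = A,A,A,B
        assert list(d.correct) == [1.0, 0.0, 1.0, 1.0]
        assert list(d.stay) == [0.0, 0.0, 0.0, 0.0]

    def test_too_few_trials_rejected(self):
        df = pd.DataFrame({"choice1": [0], "transition": ["common"],
                           "reward": [1], "high_shape": [0]})
        with pytest.raises(ValueError):
            build_stay_design(df)


class TestStaySignatures:
    # the cohort signature is evaluated on the pooled design: these
    # extreme agents put per-subject logistic fits near separation,
    # where the MLE is biased away from zero

    def test_model_free_cohort_shows_outcome_main_effect(self, rng):
        params = TwoStepParams(beta_mf=5.0, beta_mb=0.001, lam=0.5,
                               beta_step2=3.0, p=0.0)
        frames = [_sim_frame(params, rng) for _ in range(40)]
        co = stay_regression(pooled_stay_design(frames))
        assert co.outcome > 0.3
        assert abs(co.interaction) < 0.35

    def test_model_based_cohort_shows_interaction(self, rng):
        params = TwoStepParams(beta_mf=0.001, beta_mb=5.0, alpha=0.6,
                               beta_step2=3.0, p=0.0)
        frames = [_sim_frame(params, rng) for _ in range(40)]
        co = stay_regression(pooled_stay_design(frames))
        assert co.interaction > 0.3


class TestRTContrast:
    def test_planted_slowing_recovered(self, rng):
        df = _sim_frame(TwoStepParams(), rng)
        rare = df["transition"] == "rare"
        base = rng.lognormal(np.log(700), 0.25, len(df))
        df["rt2_ms"] = base + 150.0 * rare
        c = rt_contrast(df)
        assert 100 < c < 200

    def test_null_contrast_near_zero(self, rng):
        df = _sim_frame(TwoStepParams(), rng)
        df["rt2_ms"] = rng.lognormal(np.log(700), 0.25, len(df))
        assert abs(rt_contrast(df)) < 60

    def test_missing_rts_rejected(self, rng):
        df = _sim_frame(TwoStepParams(), rng)
        df["rt2_ms"] = np.nan
        with pytest.raises(ValueError):
            rt_contrast(df)


class TestGroupTests:
    def test_rank_tests_invariant_to_monotone_transform(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.8, 1, 12)
        vals = np.concatenate([a, b])
        labels = ["a"] * 12 + ["b"] * 12
        r1 = group_tests(vals, labels, test="mannwhitney")
        r2 = group_tests(np.exp(vals), labels, test="mannwhitney")
        assert r1.p_value == pytest.approx(r2.p_value)
        k1 = group_tests(vals, labels, test="kruskal")
        k2 = group_tests(vals ** 3, labels, test="kruskal")
        assert k1.p_value == pytest.approx(k2.p_value)

    def test_type_one_error_calibrated(self, rng):
        # identical distributions: rejection rate at alpha=.05 must sit
        # in [0.03, 0.07] over 2000 simulated datasets
        n_sim = 2000
        rejections = 0
        for _ in range(n_sim):
            vals = rng.normal(0, 1, 16)
            labels = ["a"] * 8 + ["b"] * 8
            res = group_tests(vals, labels, test="mannwhitney")
            rejections += res.p_value < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_power_against_one_sd_shift(self, rng):
        n_sim = 600
        hits = 0
        for _ in range(n_sim):
            vals = np.concatenate([rng.normal(0, 1, 15),
                                   rng.normal(1.0, 1, 15)])
            labels = ["a"] * 15 + ["b"] * 15
            hits += group_tests(vals, labels,
                                test="mannwhitney").p_value < 0.05
        assert hits / n_sim > 0.5

    def test_one_sample_tests_and_fisher(self, rng):
        v = rng.normal(0.5, 1, 25)
        w = group_tests(v, test="wilcoxon", alternative="greater")
        t = group_tests(v, test="ttest_1samp", alternative="greater")
        assert 0 <= w.p_value <= 1 and 0 <= t.p_value <= 1
        f = group_tests([[8, 2], [3, 7]], test="fisher")
        assert f.test == "fisher"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_tests([1.0, 2.0], ["a", "a"], test="mannwhitney")


class TestVolumeRegression:
    def _covariates(self, rng, n=24):
        spec = CohortSpec(group_sizes={"vmPFC": n // 2, "LC": n // 2, "HC": 0})
        return covariates_to_frame(make_covariates(spec, rng))

    def test_recovers_planted_slope(self, rng):
        cov = self._covariates(rng)
        slopes = []
        for _ in range(30):
            metric = -0.1 * cov["v_vmpfc"].to_numpy() + \
                rng.normal(0, 50, len(cov))
            res = lesion_volume_regression(cov, metric)
            slopes.append(res.beta_vmpfc)
        assert abs(np.mean(slopes) - (-0.1)) < 0.02

    def test_null_slope_covered(self, rng):
        cov = self._covariates(rng)
        cover = 0
        n_sim = 200
        for _ in range(n_sim):
            metric = rng.normal(0, 1, len(cov))
            res = lesion_volume_regression(cov, metric)
            cover += res.p_vmpfc > 0.05
        assert cover / n_sim > 0.85

    def test_constant_vmpfc_volume_rejected(self, rng):
        spec = CohortSpec(group_sizes={"vmPFC": 0, "LC": 10, "HC": 0})
        cov = covariates_to_frame(make_covariates(spec, rng))
        with pytest.raises(ValueError, match="rank"):
            lesion_volume_regression(cov, rng.normal(0, 1, len(cov)))


class TestResidualize:
    def _cov_frame(self, rng, n_hc=20, n_other=10):
        spec = CohortSpec(group_sizes={"vmPFC": n_other, "LC": 0,
                                       "HC": n_hc})
        return covariates_to_frame(make_covariates(spec, rng))

    def test_exact_age_dependence_zeroed_within_reference(self, rng):
        cov = self._cov_frame(rng)
        metric = 2.0 * cov["age"].to_numpy()
        res = residualize(metric, cov, reference_group="HC")
        hc = (cov["group"] == "HC").to_numpy()
        assert np.allclose(res[hc], 0.0, atol=1e-8)

    def test_idempotent(self, rng):
        cov = self._cov_frame(rng)
        metric = rng.normal(0, 1, len(cov)) + 0.05 * cov["age"].to_numpy()
        once = residualize(metric, cov)
        twice = residualize(once, cov)
        assert np.allclose(once, twice, atol=1e-8)

    def test_missing_covariate_rejected(self, rng):
        cov = self._cov_frame(rng)
        cov.loc[0, "education"] = np.nan
        with pytest.raises(ValueError):
            residualize(np.zeros(len(cov)), cov)


class TestCovariateRecord:
    def test_volume_ordering_enforced(self):
        with pytest.raises(ValueError):
            CovariateRecord("s", "vmPFC", 60, 3, v_vmpfc=10, v_total=5)
        with pytest.raises(ValueError):
            CovariateRecord("s", "LC", 60, 3, v_vmpfc=2, v_total=5)
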