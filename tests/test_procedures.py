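"""Threshold procedures: ZEST, 4-2 staircase, Full Threshold, MOCS."""

import numpy as np
import pytest

import perimetry as pm
from perimetry.machine import prob_seen
from perimetry.procedures import (
    FosFitError,
    ProcedureConfigError,
    ProcedureStateError,
)

DOMAIN = np.arange(0.0, 41.0)


class TestZestPrior:
    def test_abnormal_peak_at_zero(self):
        p = pm.make_zest_prior(DOMAIN, peak_normal=30.0, w_abn=1.0)
        assert p.mode() == 0.0

    def test_bimodal_with_default_weights(self):
        p = pm.make_zest_prior(DOMAIN, peak_normal=30.0)
        m = p.masses
        interior = np.flatnonzero(
            (m[1:-1] > m[:-2]) & (m[1:-1] >= m[2:])) + 1
        maxima = set(DOMAIN[interior])
        if m[0] > m[1]:
            maxima.add(DOMAIN[0])
        assert 30.0 in maxima
        assert m[0] > m[5]  # rises toward the 0-dB damage peak

    def test_unimodal_when_w_abn_zero(self):
        p = pm.make_zest_prior(DOMAIN, peak_normal=30.0, w_abn=0.0)
        assert p.mode() == 30.0
        assert np.all(np.diff(p.masses[:31]) >= -1e-15)

    @pytest.mark.parametrize("w", [-0.1, 1.1])
    def test_weight_bounds(self, w):
        with pytest.raises(ProcedureConfigError):
            pm.make_zest_prior(DOMAIN, 30.0, w_abn=w)

    def test_masses_normalized(self):
        for w in (0.0, 0.3, 0.7, 1.0):
            p = pm.make_zest_prior(DOMAIN, 25.0, w_abn=w)
            assert p.masses.sum() == pytest.approx(1.0, abs=1e-12)

    def test_peak_outside_domain(self):
        with pytest.raises(ProcedureConfigError):
            pm.make_zest_prior(DOMAIN, peak_normal=50.0)


class TestZest:
    def test_uniform_prior_starts_at_mean(self):
        prior = pm.PMF.from_weights(DOMAIN, np.ones_like(DOMAIN))
        st = pm.zest_create(prior)
        assert pm.zest_next_level(st) == 20.0

    def test_posterior_matches_product_oracle(self, rng):
        """Sequential Bayesian updates equal the one-shot normalized
        product of prior and all trial likelihoods."""
        prior = pm.make_zest_prior(DOMAIN, 28.0)
        for _ in range(20):
            st = pm.zest_create(prior, max_presentations=50, stop_sd=0.0)
            w = prior.masses.copy()
            for _k in range(6):
                level = float(rng.choice(DOMAIN))
                seen = bool(rng.random() < 0.5)
                pm.zest_update(st, level, seen)
                like = prob_seen(level, DOMAIN, st.likelihood_sd,
                                 st.fp_l, st.fn_l)
                w = w * (like if seen else 1.0 - like)
            np.testing.assert_allclose(st.pmf.masses, w / w.sum(),
                                       atol=1e-12)

    def test_deterministic_observer_converges(self):
        st = pm.zest_create(pm.make_zest_prior(DOMAIN, 30.0))
        while not st.finished:
            lv = pm.zest_next_level(st)
            pm.zest_update(st, lv, lv < 25.0)
        assert pm.zest_estimate(st) == pytest.approx(25.0, abs=1.5)

    def test_history_bounds_and_finish(self):
        st = pm.zest_create(pm.make_zest_prior(DOMAIN, 30.0),
                            min_presentations=4, max_presentations=6,
                            stop_sd=0.0)  # sd rule can never fire
        for _ in range(6):
            pm.zest_update(st, pm.zest_next_level(st), True)
        assert st.finished and len(st.history) == 6
        with pytest.raises(ProcedureStateError):
            pm.zest_update(st, 20.0, True)

    def test_sd_shrinks_with_consistent_responses(self):
        st = pm.zest_create(pm.make_zest_prior(DOMAIN, 30.0),
                            stop_sd=0.0, max_presentations=10)
        sds = [st.pmf.sd()]
        for _ in range(10):
            lv = pm.zest_next_level(st)
            pm.zest_update(st, lv, lv < 22.0)
            sds.append(st.pmf.sd())
        assert sds[-1] < sds[0] / 2

    def test_quest_mode_uses_pmf_mode(self):
        prior = pm.make_zest_prior(DOMAIN, 30.0, w_abn=0.0)
        st = pm.zest_create(prior, use_mode=True)
        assert pm.zest_next_level(st) == prior.mode()


class TestStaircase:
    def test_spec_trace(self):
        """Start 25, responses S S N N S -> levels 25,29,33,29,27 and
        estimate (27 + 29) / 2 = 28."""
        st = pm.staircase_create(25.0)
        presented = []
        for seen in (True, True, False, False, True):
            presented.append(st.current_level)
            pm.staircase_update(st, seen)
        assert presented == [25.0, 29.0, 33.0, 29.0, 27.0]
        assert st.finished and pm.staircase_estimate(st) == 28.0
        assert st.reversals == 2 and not st.pinned

    def test_pinned_at_floor(self):
        st = pm.staircase_create(25.0)
        while not st.finished:
            pm.staircase_update(st, False)
        assert st.pinned and st.estimate == 0.0
        assert [lv for lv, _ in st.history] == \
            [25.0, 21.0, 17.0, 13.0, 9.0, 5.0, 1.0, 0.0]

    def test_pinned_at_ceiling(self):
        st = pm.staircase_create(25.0)
        while not st.finished:
            pm.staircase_update(st, True)
        assert st.pinned and st.estimate == 40.0

    def test_update_after_finish_errors(self):
        st = pm.staircase_create(25.0)
        for seen in (True, False, True):
            pm.staircase_update(st, seen)
        assert st.finished
        with pytest.raises(ProcedureStateError):
            pm.staircase_update(st, True)

    def test_estimate_before_finish_errors(self):
        st = pm.staircase_create(25.0)
        with pytest.raises(ProcedureStateError):
            pm.staircase_estimate(st)

    def test_start_outside_range(self):
        with pytest.raises(ProcedureConfigError):
            pm.staircase_create(45.0)


class TestFullThreshold:
    def test_no_retest_near_start(self):
        res = pm.full_threshold_run(25.0, lambda lv: lv < 25.0)
        assert not res.retested
        assert abs(res.estimate - 25.0) < 4.0
        assert res.trials == res.trials  # log present
        assert len(res.trials) >= 3

    def test_retest_far_from_start(self):
        res = pm.full_threshold_run(30.0, lambda lv: lv < 12.0)
        assert res.retested
        assert res.second_estimate == res.estimate
        assert abs(res.first_estimate - 30.0) >= 4.0
        assert res.estimate == pytest.approx(12.0, abs=2.0)

    def test_trial_log_is_sum_of_staircases(self):
        calls = []

        def responder(lv):
            calls.append(lv)
            return lv < 12.0

        res = pm.full_threshold_run(30.0, responder)
        assert len(res.trials) == len(calls)
        assert [lv for lv, _ in res.trials] == calls


class TestMocs:
    def test_presentation_order_is_permutation(self, rng):
        levels = [20.0, 22.0, 24.0]
        rec = pm.mocs_run(levels, reps=5, responder=lambda lv: True,
                          rng=rng)
        presented = sorted(lv for lv, _ in rec.trials)
        assert presented == sorted(levels * 5)
        assert np.all(rec.n_presented == 5)

    def test_perfect_separation_midpoint(self, rng):
        rec = pm.FosRecord(levels=[20.0, 30.0], n_presented=[10, 10],
                           n_seen=[10, 0])
        fit = pm.fit_fos(rec)
        assert fit.fallback
        assert fit.threshold == pytest.approx(25.0)

    def test_parameter_recovery(self, rng):
        truth_t, truth_sd = 25.0, 2.0
        levels = np.arange(19.0, 32.0, 2.0)  # 7 levels

        def responder(lv):
            return rng.random() < prob_seen(lv, truth_t, truth_sd,
                                            0.03, 0.03)

        rec = pm.mocs_run(levels, reps=50, responder=responder, rng=rng)
        fit = pm.fit_fos(rec, fp=0.03, fn=0.03)
        assert fit.converged
        assert fit.threshold == pytest.approx(truth_t, abs=1.0)
        assert 0.5 < fit.fos_sd < 5.0

    def test_degenerate_records_rejected(self):
        rec = pm.FosRecord(levels=[20.0, 30.0], n_presented=[5, 5],
                           n_seen=[5, 5])
        with pytest.raises(FosFitError, match="widen"):
            pm.fit_fos(rec)

    def test_config_errors(self, rng):
        with pytest.raises(ProcedureConfigError):
            pm.mocs_run([20.0], reps=5, responder=lambda lv: True, rng=rng)
        with pytest.raises(ProcedureConfigError):
            pm.mocs_run([20.0, 25.0], reps=0, responder=lambda lv: True,
                        rng=rng)
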