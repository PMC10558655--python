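"""Rescorla-Wagner / Pearce-Hall trajectories, likelihood, and fitting."""

import numpy as np
import pytest
from scipy import stats

from dyadcoupling import rlmodel, synth


def make_two_trial_schedule():
    t0 = synth.Trial(onset_s=10.0, cs_type="CS+", us=True, us_onset_s=15.5)
    t1 = synth.Trial(onset_s=30.0, cs_type="CS+", us=False, us_onset_s=None)
    return synth.TrialSchedule(trials=[t0, t1])


class TestTrajectories:
    def test_one_step_hand_value(self):
        sched = make_two_trial_schedule()
        traj = rlmodel.rw_trajectory(sched, V0=0.5, alpha=0.5)
        # after a reinforced trial: 0.5 + 0.5*(1 - 0.5) = 0.75
        assert traj.V[1] == pytest.approx(0.75)
        assert traj.delta[0] == pytest.approx(0.5)

    def test_alpha_zero_freezes_values(self, short_schedule):
        traj = rlmodel.rw_trajectory(short_schedule, V0=0.3, alpha=0.0)
        assert np.allclose(traj.V, 0.3)

    def test_alpha_one_tracks_last_outcome(self, short_schedule):
        traj = rlmodel.rw_trajectory(short_schedule, V0=0.5, alpha=1.0)
        # each CS stream: V equals the previous U of that CS
        streams = {}
        for cs, u, v in zip(traj.cs_types, traj.us, traj.V):
            if cs in streams:
                assert v == pytest.approx(streams[cs])
            streams[cs] = u

    def test_delta_identity_and_bounds(self, short_schedule):
        traj = rlmodel.rw_trajectory(short_schedule, V0=0.5, alpha=0.37)
        assert np.allclose(traj.delta + traj.V, traj.us)
        assert np.all((traj.V >= 0.0) & (traj.V <= 1.0))

    def test_per_cs_streams_are_independent(self, short_schedule):
        traj = rlmodel.rw_trajectory(short_schedule, V0=0.5, alpha=0.8)
        # a CS- stream never sees a US, so its values only decay toward 0
        vminus = traj.streams["CS-"]
        assert np.all(np.diff(vminus) <= 1e-12)

    def test_ph_eta_zero_reduces_to_rw(self, short_schedule):
        rw = rlmodel.rw_trajectory(short_schedule, V0=0.5, alpha=0.4)
        ph = rlmodel.ph_trajectory(short_schedule, V0=0.5, alpha0=0.4, eta=0.0)
        assert np.allclose(rw.V, ph.V)

    def test_ph_hand_unrolled_three_trials(self):
        trials = [synth.Trial(onset_s=10.0 * (i + 1), cs_type="CS+",
                              us=u, us_onset_s=10.0 * (i + 1) + 5.5 if u
                              else None)
                  for i, u in enumerate([True, False, True])]
        sched = synth.TrialSchedule(trials=trials)
        a0, eta, v0 = 0.3, 0.6, 0.2
        traj = rlmodel.ph_trajectory(sched, V0=v0, alpha0=a0, eta=eta)
        # hand recursion
        v, a = v0, a0
        expect = []
        for u in (1.0, 0.0, 1.0):
            expect.append(v)
            d = u - v
            v = v + a * d
            a = eta * abs(d) + (1 - eta) * a
        assert np.allclose(traj.V, expect)

    def test_ph_full_eta_after_predicted_trial_freezes(self):
        # delta = 0 on trial 1 (V0=1, US) -> with eta=1 associability drops to 0
        trials = [synth.Trial(onset_s=10.0, cs_type="CS+", us=True,
                              us_onset_s=15.5),
                  synth.Trial(onset_s=30.0, cs_type="CS+", us=False,
                              us_onset_s=None),
                  synth.Trial(onset_s=50.0, cs_type="CS+", us=False,
                              us_onset_s=None)]
        sched = synth.TrialSchedule(trials=trials)
        traj = rlmodel.ph_trajectory(sched, V0=1.0, alpha0=0.5, eta=1.0)
        assert traj.V[1] == pytest.approx(1.0)  # frozen after delta = 0


class TestLoglik:
    def test_single_trial_at_mean(self, short_schedule):
        traj = rlmodel.rw_trajectory(short_schedule, V0=0.5, alpha=0.3)
        one = rlmodel.ValueTrajectory(V=traj.V[:1], delta=traj.delta[:1],
                                      cs_types=traj.cs_types[:1],
                                      us=traj.us[:1])
        scr = np.array([0.2 + 1.0 * one.V[0]])
        ll = rlmodel.scr_loglik(scr, one, beta0=0.2, beta1=1.0, sigma=1.0)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)
        ll2 = rlmodel.scr_loglik(scr, one, beta0=0.2, beta1=1.0, sigma=2.0)
        assert ll - ll2 == pytest.approx(np.log(2.0), abs=1e-12)

    def test_matches_independent_density_sum(self, short_schedule, rng):
        traj = rlmodel.rw_trajectory(short_schedule, V0=0.5, alpha=0.3)
        scr = rng.standard_normal(len(traj))
        b0, b1, s = 0.1, 0.8, 0.4
        oracle = stats.norm.logpdf(scr, loc=b0 + b1 * traj.V, scale=s).sum()
        assert rlmodel.scr_loglik(scr, traj, b0, b1, s) == pytest.approx(
            oracle, abs=1e-10)

    def test_guards(self, short_schedule):
        traj = rlmodel.rw_trajectory(short_schedule, V0=0.5, alpha=0.3)
        with pytest.raises(ValueError):
            rlmodel.scr_loglik(np.zeros(len(traj)), traj, 0, 1, sigma=0.0)
        with pytest.raises(ValueError):
            rlmodel.scr_loglik(np.zeros(3), traj, 0, 1, sigma=1.0)


class TestFit:
    def test_near_noiseless_recovery(self, short_schedule):
        p = rlmodel.RWParams(V0=0.5, alpha=0.35, beta0=0.0, beta1=1.0,
                             sigma=1e-4)
        scr = synth.simulate_scr(short_schedule, p, seed=0)
        fit = rlmodel.fit_rw(scr, short_schedule, model_id="RW-fixedV0",
                             n_starts=10, seed=0)
        assert fit.params.alpha == pytest.approx(0.35, abs=0.02)

    def test_fit_beats_truth_likelihood(self, short_schedule):
        p = rlmodel.RWParams(V0=0.5, alpha=0.6, beta0=0.2, beta1=1.5,
                             sigma=0.3)
        scr = synth.simulate_scr(short_schedule, p, seed=3)
        fit = rlmodel.fit_rw(scr, short_schedule, model_id="RW-fixedV0",
                             n_starts=10, seed=0)
        traj = rlmodel.rw_trajectory(short_schedule, 0.5, p.alpha)
        ll_truth = rlmodel.scr_loglik(scr, traj, p.beta0, p.beta1, p.sigma)
        assert fit.loglik >= ll_truth - 1e-6

    def test_constant_scr_flags_degenerate(self, short_schedule):
        with pytest.warns(UserWarning, match="flat likelihood"):
            fit = rlmodel.fit_rw(np.full(short_schedule.n_trials, 0.7),
                                 short_schedule, model_id="RW-fixedV0",
                                 n_starts=4, seed=0)
        assert fit.degenerate
        assert abs(fit.params.beta1 * np.std(
            rlmodel.rw_trajectory(short_schedule, 0.5,
                                  fit.params.alpha).V)) < 1e-5

    def test_guards(self, short_schedule):
        with pytest.raises(ValueError):
            rlmodel.fit_rw(np.zeros(4), short_schedule, model_id="RW-fixedV0")
        with pytest.raises(ValueError):
            rlmodel.fit_rw(np.zeros(short_schedule.n_trials), short_schedule,
                           model_id="nonsense")


class TestCompare:
    def _fits(self, short_schedule, seed=0):
        p = rlmodel.RWParams(V0=0.5, alpha=0.4, beta0=0.0, beta1=1.2,
                             sigma=0.3)
        scr = synth.simulate_scr(short_schedule, p, seed=seed)
        return [rlmodel.fit_rw(scr, short_schedule, model_id=m, n_starts=6,
                               seed=seed)
                for m in ("RW-fixedV0", "PH-fixedV0")]

    def test_single_model(self, short_schedule):
        fits = self._fits(short_schedule)
        table = rlmodel.compare_models(fits[:1])
        assert len(table) == 1 and table["delta"].iloc[0] == 0.0

    def test_rw_data_prefers_rw(self, short_schedule):
        # group-level AIC over a batch of simulated subjects
        wins = 0
        for batch in range(3):
            aic = {"RW-fixedV0": 0.0, "PH-fixedV0": 0.0}
            for subj in range(15):
                fits = self._fits(short_schedule, seed=100 * batch + subj)
                for f in fits:
                    aic[f.model_id] += f.aic
            wins += aic["RW-fixedV0"] < aic["PH-fixedV0"]
        assert wins >= 2

    def test_tie_reported(self, short_schedule):
        fits = self._fits(short_schedule)
        twin = rlmodel.RWFitResult(params=fits[0].params,
                                   loglik=fits[0].loglik,
                                   n_trials=fits[0].n_trials,
                                   model_id="RW-freeV0",
                                   n_params=fits[0].n_params,
                                   ic_scores=dict(fits[0].ic_scores))
        table = rlmodel.compare_models([fits[0], twin])
        assert table["tied"].all()

    def test_mixed_lengths_raise(self, short_schedule):
        fits = self._fits(short_schedule)
        other = rlmodel.RWFitResult(params=fits[0].params, loglik=-1.0,
                                    n_trials=99, model_id="RW-freeV0",
                                    n_params=4,
                                    ic_scores={"aic": 1.0, "bic": 1.0})
        with pytest.raises(ValueError):
            rlmodel.compare_models([fits[0], other])


class TestShrinkage:
    def test_shrinks_toward_group_mean(self, short_schedule):
        fits = []
        for seed, a in enumerate((0.2, 0.5, 0.8)):
            p = rlmodel.RWParams(V0=0.5, alpha=a, beta0=0.0, beta1=1.0,
                                 sigma=0.3)
            scr = synth.simulate_scr(short_schedule, p, seed=seed)
            fits.append(rlmodel.fit_rw(scr, short_schedule,
                                       model_id="RW-fixedV0", n_starts=6,
                                       seed=seed))
        raw = np.array([f.params.alpha for f in fits])
        shrunk = rlmodel.shrink_alphas(fits)
        group = raw.mean()
        assert np.all(np.abs(shrunk - group) <= np.abs(raw - group) + 1e-12)
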