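"""Synthetic dyad generator: schedules, planted coupling, SCR, pupil, fixations."""

import numpy as np
import pytest

from dyadcoupling import btbc, ocular, rlmodel, spectral, synth


class TestSchedule:
    def test_reinforcement_counts(self):
        s = synth.make_schedule(16, 16, 0.625, seed=0)
        us = [t for t in s.trials if t.us]
        assert len(us) == 10
        assert all(t.cs_type == "CS+" for t in us)
        assert all(t.us_onset_s - t.onset_s == pytest.approx(5.5)
                   for t in us)

    @pytest.mark.parametrize("rate, expected", [(0.0, 0), (1.0, 16)])
    def test_rate_extremes(self, rate, expected):
        s = synth.make_schedule(16, 16, rate, seed=3)
        assert sum(t.us for t in s.trials) == expected
        assert not any(t.us for t in s.trials if t.cs_type == "CS-")

    def test_us_count_constant_across_seeds(self):
        counts = {sum(t.us for t in
                      synth.make_schedule(16, 16, 0.625, seed=s).trials)
                  for s in range(100)}
        assert counts == {10}

    def test_seed_determinism(self):
        a = synth.make_schedule(8, 8, 0.625, seed=42)
        b = synth.make_schedule(8, 8, 0.625, seed=42)
        assert a.to_frame().equals(b.to_frame())

    def test_onsets_strictly_increasing_with_min_gap(self):
        s = synth.make_schedule(12, 12, 0.5, seed=7)
        gaps = np.diff(s.onsets)
        assert np.all(gaps >= s.cs_duration_s + s.iti_range_s[0] - 1e-9)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            synth.make_schedule(-1, 4, 0.5)
        with pytest.raises(ValueError):
            synth.make_schedule(4, 4, 1.5)

    def test_tsv_round_trip(self, tmp_path):
        s = synth.make_schedule(6, 6, 0.5, seed=1)
        path = tmp_path / "sched.tsv"
        s.to_tsv(path)
        back = synth.TrialSchedule.from_tsv(path)
        assert back.to_frame().equals(s.to_frame())

    def test_cs_minus_us_rejected(self):
        with pytest.raises(ValueError):
            synth.TrialSchedule(trials=[synth.Trial(10.0, "CS-", True, 15.5)])


class TestDyadSignals:
    def test_contracts(self, planted_dyad):
        rec = planted_dyad
        assert rec.demonstrator_signals.shape == rec.observer_signals.shape
        assert np.all(np.isfinite(rec.observer_signals))
        assert all(len(v) >= 1 for v in rec.neighbor_graph.values())

    def test_full_coupling_pair_is_near_perfect(self, short_schedule, delta):
        pl = [synth.PlantedCoupling("D00", "O00", kappa=1.0)]
        rec = synth.simulate_dyad_signals(short_schedule, pl, band=delta,
                                          fs=250.0, n_channels=2, seed=5)
        tab = btbc.epoch_coupling(rec, delta, include_baseline=False)
        planted = tab[tab["pair"] == "D00_O00"]
        assert planted["ccorr_raw"].mean() >= 0.9

    def test_null_pair_is_null(self, short_schedule, delta):
        rec = synth.simulate_dyad_signals(short_schedule, [], band=delta,
                                          fs=250.0, n_channels=2, seed=6)
        tab = btbc.epoch_coupling(rec, delta, include_baseline=False)
        assert abs(tab["ccorr_raw"].mean()) < 0.1

    def test_condition_specific_planting(self, short_schedule, delta):
        pl = [synth.PlantedCoupling("D00", "O00", kappa=0.9, condition="CS+")]
        diffs = []
        for seed in range(6):
            rec = synth.simulate_dyad_signals(short_schedule, pl, band=delta,
                                              fs=250.0, n_channels=2,
                                              seed=seed)
            tab = btbc.epoch_coupling(rec, delta, include_baseline=False)
            planted = tab[tab["pair"] == "D00_O00"]
            by_cs = planted.groupby("cs_type")["z_abs"].mean()
            diffs.append(by_cs["CS+"] - by_cs["CS-"])
        assert np.mean(diffs) > 0.3
        assert np.all(np.array(diffs) > 0)

    def test_baseline_segment_uncoupled(self, planted_dyad, delta):
        tab = btbc.epoch_coupling(planted_dyad, delta, include_baseline=True)
        planted = tab[tab["pair"] == "D00_O00"]
        base = planted[planted["epoch"] == "baseline"]["z_abs"].mean()
        task = planted[planted["epoch"] == "task"]["z_abs"].mean()
        assert task > base + 0.5

    def test_coupling_monotone_in_kappa(self, short_schedule, delta):
        means = []
        for kappa in (0.0, 0.3, 0.6, 0.9):
            vals = []
            for seed in range(6):
                pl = [synth.PlantedCoupling("D00", "O00", kappa=kappa)]
                rec = synth.simulate_dyad_signals(
                    short_schedule, pl, band=delta, fs=250.0, n_channels=2,
                    seed=seed)
                tab = btbc.epoch_coupling(rec, delta, include_baseline=False)
                vals.append(tab[tab["pair"] == "D00_O00"]["ccorr_raw"].mean())
            means.append(np.mean(vals))
        assert np.all(np.diff(means) > 0)

    def test_guards(self, short_schedule, delta):
        with pytest.raises(ValueError):
            synth.simulate_dyad_signals(short_schedule, [], band=delta,
                                        fs=10.0)
        with pytest.raises(ValueError):
            synth.PlantedCoupling("D00", "O00", kappa=1.2)


class TestPseudoDemonstrator:
    def test_identical_sources_reproduce(self, rng):
        src = rng.standard_normal((3, 500))
        out = synth.make_pseudo_demonstrator([src, src.copy()], seed=0)
        assert np.array_equal(out, src)

    def test_membership_at_every_index(self, rng):
        sources = [rng.standard_normal((2, 300)) for _ in range(3)]
        out = synth.make_pseudo_demonstrator(sources, seed=1)
        stack = np.stack(sources)
        for t in range(300):
            assert any(np.array_equal(out[:, t], stack[k, :, t])
                       for k in range(3))

    def test_variance_preserved(self, rng):
        sources = [rng.standard_normal((4, 5000)) * (1 + 0.1 * k)
                   for k in range(3)]
        out = synth.make_pseudo_demonstrator(sources, seed=2)
        src_var = np.mean([s.var(axis=-1) for s in sources], axis=0)
        assert np.all(np.abs(out.var(axis=-1) / src_var - 1.0) < 0.1)

    def test_guards(self, rng):
        a = rng.standard_normal((2, 100))
        with pytest.raises(ValueError):
            synth.make_pseudo_demonstrator([a])
        with pytest.raises(ValueError):
            synth.make_pseudo_demonstrator([a, rng.standard_normal((2, 99))])

    def test_attenuates_planted_coupling(self, short_schedule, delta):
        recs = [synth.simulate_dyad_signals(
            short_schedule, [synth.PlantedCoupling("D00", "O00", kappa=0.8)],
            band=delta, fs=125.0, n_channels=2, seed=seed)
            for seed in range(4)]
        dems = [r.demonstrator_signals for r in recs]
        g, p = [], []
        for i, rec in enumerate(recs):
            gt = btbc.epoch_coupling(rec, delta, include_baseline=False)
            surrogate = synth.make_pseudo_demonstrator(dems, seed=i)
            pt = btbc.epoch_coupling(rec, delta, include_baseline=False,
                                     dem_override=surrogate)
            g.append(gt["z_abs"].mean())
            p.append(pt["z_abs"].mean())
        assert np.mean(g) > np.mean(p)


class TestSCRGenerator:
    def test_noiseless_limit_equals_values(self, short_schedule):
        p = rlmodel.RWParams(V0=0.5, alpha=0.4, beta0=0.0, beta1=1.0,
                             sigma=1e-12)
        scr = synth.simulate_scr(short_schedule, p, seed=0)
        traj = rlmodel.rw_trajectory(short_schedule, 0.5, 0.4)
        assert np.allclose(scr, traj.V, atol=1e-9)

    def test_alpha_zero_constant(self, short_schedule):
        p = rlmodel.RWParams(V0=0.5, alpha=1e-9, beta0=0.0, beta1=2.0,
                             sigma=1e-12)
        # alpha ~ 0: values stay at V0 -> scr = 2 * 0.5 = 1
        scr = synth.simulate_scr(short_schedule, p, seed=0)
        assert np.allclose(scr, 1.0, atol=1e-6)

    def test_monte_carlo_mean(self, short_schedule):
        p = rlmodel.RWParams(V0=0.5, alpha=0.3, beta0=0.2, beta1=1.5,
                             sigma=0.5)
        traj = rlmodel.rw_trajectory(short_schedule, 0.5, 0.3)
        draws = np.stack([synth.simulate_scr(short_schedule, p, seed=s)
                          for s in range(2000)])
        target = p.beta0 + p.beta1 * traj.V[0]
        se = p.sigma / np.sqrt(len(draws))
        assert abs(draws[:, 0].mean() - target) < 3 * se

    def test_sigma_guard(self, short_schedule):
        with pytest.raises(ValueError):
            synth.simulate_scr(short_schedule,
                               rlmodel.RWParams(sigma=0.3, alpha=1.5), seed=0)


class TestPupilAndFixations:
    def test_forced_hand_allocation(self, short_schedule):
        _, _, stream = synth.simulate_pupil_and_fixations(
            short_schedule, shared_gain=0.5, seed=0, hand_bias=1.0)
        prop = ocular.fixation_proportion(stream, short_schedule,
                                          window=(4.7, 5.5))
        plus = prop[(prop["cs_type"] == "CS+") & prop["valid"]]
        assert np.allclose(plus["hand"], 1.0)

    def test_proportions_sum_to_one(self, short_schedule):
        _, _, stream = synth.simulate_pupil_and_fixations(
            short_schedule, shared_gain=0.5, seed=1, hand_bias=0.3)
        prop = ocular.fixation_proportion(stream, short_schedule)
        valid = prop[prop["valid"]]
        sums = valid[["hand", "face", "stimulus", "elsewhere"]].sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_blinks_inserted_and_removed(self, short_schedule):
        dem, _, _ = synth.simulate_pupil_and_fixations(
            short_schedule, shared_gain=0.5, seed=2)
        assert np.isnan(dem.data).any()
        clean = ocular.preprocess_pupil(dem)
        assert not np.isnan(clean.data).any()
        assert clean.fs == 100.0

    def test_negative_gain_rejected(self, short_schedule):
        with pytest.raises(ValueError):
            synth.simulate_pupil_and_fixations(short_schedule, -0.1, seed=0)

    def test_shared_gain_drives_eye_coupling(self, short_schedule):
        high, low = [], []
        for seed in range(3):
            for gain, sink in ((3.0, high), (0.0, low)):
                d, o, _ = synth.simulate_pupil_and_fixations(
                    short_schedule, gain, seed=seed)
                dp = ocular.preprocess_pupil(d)
                op = ocular.preprocess_pupil(o)
                tab = ocular.eye_coupling(dp, op, short_schedule)
                sink.append(tab["z_abs"].mean())
        assert np.mean(high) > np.mean(low)
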