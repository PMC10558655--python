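"""Circular-correlation coupling core: statistic, normalization, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dyadcoupling import btbc


def ccorr_reference(x, y):
    """Independent one-line evaluation of the circular correlation formula."""
    xb = np.angle(np.mean(np.exp(1j * np.asarray(x))))
    yb = np.angle(np.mean(np.exp(1j * np.asarray(y))))
    sx, sy = np.sin(x - xb), np.sin(y - yb)
    return np.sum(sx * sy) / np.sqrt(np.sum(sx**2) * np.sum(sy**2))


class TestCCorr:
    def test_identity_is_one(self, rng):
        x = rng.uniform(-np.pi, np.pi, 500)
        assert btbc.ccorr(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_constant_offset_invariance(self, rng):
        x = rng.uniform(-np.pi, np.pi, 500)
        assert btbc.ccorr(x, x + np.pi / 3) == pytest.approx(1.0, abs=1e-9)

    def test_matches_formula_on_spec_arrays(self):
        x = np.array([0.1, 0.5, 1.0, 1.4])
        y = np.array([0.2, 0.6, 0.9, 1.5])
        assert btbc.ccorr(x, y) == pytest.approx(ccorr_reference(x, y),
                                                 abs=1e-12)

    def test_matches_circstat_port(self, rng):
        pingouin = pytest.importorskip("pingouin")
        for _ in range(20):
            x = rng.uniform(-np.pi, np.pi, 100)
            y = rng.uniform(-np.pi, np.pi, 100)
            assert btbc.ccorr(x, y) == pytest.approx(
                pingouin.circ_corrcc(x, y)[0], abs=1e-10)

    def test_symmetry_and_bounds(self, rng):
        for _ in range(50):
            x = rng.uniform(-np.pi, np.pi, 64)
            y = rng.uniform(-np.pi, np.pi, 64)
            r = btbc.ccorr(x, y)
            assert r == pytest.approx(btbc.ccorr(y, x), abs=1e-12)
            assert -1.0 - 1e-12 <= r <= 1.0 + 1e-12

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000), shift=st.floats(-10, 10))
    def test_offset_invariance_property(self, seed, shift):
        x = np.random.default_rng(seed).uniform(-np.pi, np.pi, 80)
        y = np.random.default_rng(seed + 1).uniform(-np.pi, np.pi, 80)
        assert btbc.ccorr(x + shift, y) == pytest.approx(btbc.ccorr(x, y),
                                                         abs=1e-9)

    def test_degenerate_and_mismatch_errors(self):
        x = np.full(64, 0.3)
        with pytest.raises(btbc.DegenerateInputError):
            btbc.ccorr(x, x)
        with pytest.raises(ValueError):
            btbc.ccorr(np.zeros(10), np.zeros(11))

    def test_null_distribution_is_tight(self, rng):
        # independent uniform phases, 5500 samples: |r| < 0.1 in >= 99% of draws
        n_draws = 1000
        count = 0
        for _ in range(n_draws):
            x = rng.uniform(-np.pi, np.pi, 5500)
            y = rng.uniform(-np.pi, np.pi, 5500)
            count += abs(btbc.ccorr(x, y)) < 0.1
        assert count / n_draws >= 0.99

    def test_matrix_agrees_with_scalar(self, rng):
        a = rng.uniform(-np.pi, np.pi, (3, 200))
        b = rng.uniform(-np.pi, np.pi, (2, 200))
        m = btbc.ccorr_matrix(a, b)
        for i in range(3):
            for j in range(2):
                assert m[i, j] == pytest.approx(btbc.ccorr(a[i], b[j]),
                                                abs=1e-12)


class TestNormalize:
    @pytest.mark.parametrize("r, expected", [
        (0.0, 0.0),
        (0.5, 0.5493061443),
        (-0.5, 0.5493061443),
    ])
    def test_closed_form(self, r, expected):
        assert btbc.normalize(r) == pytest.approx(expected, abs=1e-9)

    def test_even_and_finite_at_one(self):
        assert btbc.normalize(1.0) == btbc.normalize(-1.0)
        assert np.isfinite(btbc.normalize(1.0))
        with pytest.raises(ValueError):
            btbc.normalize(1.5)


class TestBHFDR:
    def test_step_up_hand_example(self):
        # hand application of the step-up rule
        p = [0.01, 0.02, 0.03, 0.04, 0.2]
        reject, q = btbc.bh_fdr(p, q=0.05)
        assert list(reject) == [True, True, True, True, False]

    @pytest.mark.parametrize("p, expected", [
        ([0.001] * 10, [True] * 10),
        ([0.9], [False]),
    ])
    def test_edge_cases(self, p, expected):
        reject, _ = btbc.bh_fdr(p, q=0.05)
        assert list(reject) == expected

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            btbc.bh_fdr([0.5, 1.2])


def _toy_table(rng, n_dyads=8, n_pairs=4, planted=("P0",), effect=0.5,
               n_trials=6):
    rows = []
    for d in range(n_dyads):
        for j in range(n_pairs):
            pair = f"P{j}"
            for epoch, n in (("task", n_trials), ("baseline", n_trials)):
                for t in range(n):
                    mu = 0.3
                    if epoch == "task" and pair in planted:
                        mu += effect
                    rows.append({
                        "dyad_id": d, "pair": pair, "epoch": epoch,
                        "trial": t, "cs_type": "CS+" if epoch == "task"
                        else "baseline",
                        "z_abs": mu + 0.1 * rng.standard_normal()})
    return pd.DataFrame(rows)


class TestSelection:
    def test_baseline_filter_retains_planted_only(self, rng):
        tab = _toy_table(rng, planted=("P0",), effect=0.6)
        sel = btbc.baseline_filter(tab)
        assert sel.retained == ["P0"]

    def test_task_equal_baseline_retains_nothing(self):
        rng = np.random.default_rng(0)
        tab = _toy_table(rng, planted=(), effect=0.0)
        task = tab[tab["epoch"] == "task"].copy()
        base = task.copy()
        base["epoch"] = "baseline"
        sel = btbc.baseline_filter(pd.concat([task, base], ignore_index=True))
        assert sel.retained == []

    def test_selection_idempotent(self, rng):
        tab = _toy_table(rng, planted=("P0", "P2"), effect=0.6)
        sel1 = btbc.baseline_filter(tab)
        sub = tab[tab["pair"].isin(sel1.retained)]
        sel2 = btbc.baseline_filter(sub)
        assert set(sel2.retained) == set(sel1.retained)

    def test_missing_baseline_raises(self, rng):
        tab = _toy_table(rng)
        with pytest.raises(ValueError):
            btbc.baseline_filter(tab[tab["epoch"] == "task"])


class TestConditionContrast:
    def test_detects_planted_interaction(self, rng):
        rows = []
        for dem in range(3):
            for o in range(6):
                dyad = f"d{dem}o{o}"
                status = "LS" if o % 2 == 0 else "HS"
                for pair in ("P1", "P2"):
                    for t in range(12):
                        cs = "CS+" if t % 2 == 0 else "CS-"
                        mu = 0.3
                        if pair == "P1" and status == "LS" and cs == "CS+":
                            mu = 0.9
                        rows.append({"dyad_id": dyad, "pair": pair,
                                     "epoch": "task", "cs_type": cs,
                                     "z_abs": mu + 0.15 * rng.standard_normal()})
        tab = pd.DataFrame(rows)
        status = {f"d{d}o{o}": ("LS" if o % 2 == 0 else "HS")
                  for d in range(3) for o in range(6)}
        dem = {f"d{d}o{o}": f"dem{d}" for d in range(3) for o in range(6)}
        res = btbc.condition_contrast(tab, status, dem)
        inter = res[res["effect"] == "interaction"].set_index("pair")
        assert inter.loc["P1", "significant"]
        assert not inter.loc["P2", "significant"]
        assert (res["q"] >= res["p"] - 1e-12).all()

    def test_single_dyad_errors(self):
        tab = pd.DataFrame({"dyad_id": ["d0"] * 8, "pair": ["P"] * 8,
                            "epoch": ["task"] * 8,
                            "cs_type": ["CS+", "CS-"] * 4,
                            "z_abs": np.arange(8.0)})
        with pytest.raises(ValueError):
            btbc.condition_contrast(tab, {"d0": "LS"}, {"d0": "dem0"})


class TestPseudoComparison:
    def test_identical_tables_give_null(self, rng):
        tab = _toy_table(rng)
        res = btbc.pseudo_comparison(tab, tab.copy())
        assert res.t == 0.0 and res.p == 1.0

    def test_mismatched_dyads_raise(self, rng):
        tab = _toy_table(rng)
        other = tab[tab["dyad_id"] != 0]
        with pytest.raises(ValueError):
            btbc.pseudo_comparison(tab, other)


class TestSelectionPermutationVariant:
    def test_permutation_agrees_with_ttest_on_planted(self):
        rng = np.random.default_rng(4)
        tab = _toy_table(rng, planted=("P1",), effect=0.6)
        t_sel = btbc.baseline_filter(tab, method="ttest")
        p_sel = btbc.baseline_filter(tab, method="permutation", n_perm=500,
                                     seed=1)
        assert t_sel.retained == p_sel.retained == ["P1"]

    def test_unknown_method_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            btbc.baseline_filter(_toy_table(rng), method="bogus")
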