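import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from gazecone import (CohortSpec, FitConfig, FitFailure, JointFitParams,
                      ObserverParams, aggregate_counts, cone_width_pipeline,
                      find_crossings, fit_joint, fit_many, predict_proportions,
                      simulate_cohort)
from gazecone.io import DESIGN_AZIMUTHS
from gazecone.psychometric import nelder_mead_batch

from conftest import counts_from_params, make_count_table


params_strategy = st.tuples(
    st.floats(-35, -1), st.floats(0.05, 2.0),
    st.floats(1, 35), st.floats(0.05, 2.0))


class TestPredictProportions:
    @given(params_strategy, st.floats(-90, 90))
    @settings(max_examples=200, deadline=None)
    def test_sum_to_one_identity(self, params, x):
        pL, pM, pR = predict_proportions(params, x)
        assert pL + pM + pR == pytest.approx(1.0, abs=1e-12)

    def test_logistic_midpoint(self):
        p = JointFitParams(-15, 0.3, 15, 0.3)
        pL, _, pR = predict_proportions(p, -15.0)
        assert pL == pytest.approx(0.5)
        _, _, pR = predict_proportions(p, 15.0)
        assert pR == pytest.approx(0.5)

    def test_mirror_symmetry(self):
        p = JointFitParams(-12, 0.4, 12, 0.4)
        for x in (0.0, 7.0, 33.0):
            a = predict_proportions(p, x)
            b = predict_proportions(p, -x)
            assert a[0] == pytest.approx(b[2])
            assert a[1] == pytest.approx(b[1])

    def test_against_hand_evaluation(self):
        # independent evaluation of the stated logistic forms
        import math
        pL, pM, pR = predict_proportions(JointFitParams(-15, 0.3, 15, 0.3), 0.0)
        eL = 1 / (1 + math.exp(0.3 * (0 - (-15))))
        eR = 1 / (1 + math.exp(-0.3 * (0 - 15)))
        assert pL == pytest.approx(eL, abs=1e-12)
        assert pR == pytest.approx(eR, abs=1e-12)
        assert pM == pytest.approx(1 - eL - eR, abs=1e-12)


class TestNelderMead:
    def test_matches_scipy_on_fit_objective(self):
        # same algorithm as scipy's simplex: identical optima on real data
        rng = np.random.default_rng(0)
        true = (-12.0, 0.25, 12.0, 0.25)
        pL, pM, pR = predict_proportions(true, DESIGN_AZIMUTHS)
        P = np.stack([pL, pM, pR], 1)
        obs = np.array([rng.multinomial(10, p) for p in P]) / 10.0

        def sse(th):
            l, m, r = predict_proportions(th, DESIGN_AZIMUTHS)
            return float(((np.stack([l, m, r], 1) - obs) ** 2).sum())

        starts = np.array([[-12, 0.2, 12, 0.2], [-8, 0.3, 15, 0.15],
                           [-20, 0.1, 5, 0.4]])
        ours, fours, _, _ = nelder_mead_batch(
            lambda t, i: np.array([sse(r) for r in np.atleast_2d(t)]),
            starts, xatol=1e-6, fatol=1e-10, maxiter=2000)
        for x0, xb, fb in zip(starts, ours, fours):
            ref = minimize(sse, x0, method="Nelder-Mead",
                           options=dict(xatol=1e-6, fatol=1e-10, maxiter=2000))
            assert fb == pytest.approx(ref.fun, abs=1e-9)
            assert np.allclose(xb, ref.x, atol=1e-3)

    def test_quadratic_bowl(self):
        target = np.array([[1.0, -2.0, 3.0, 0.5], [0.0, 0.0, 0.0, 0.0]])

        def f(t, i):
            return ((np.atleast_2d(t) - target[i]) ** 2).sum(axis=1)

        x, fx, conv, _ = nelder_mead_batch(f, np.ones((2, 4)) * 0.3)
        assert conv.all()
        assert np.allclose(x, target, atol=1e-4)


class TestFitJoint:
    def test_recovery_from_exact_proportions(self):
        true = JointFitParams(-14.0, 0.22, 11.0, 0.3)
        counts = counts_from_params(true, n_total=1000)
        res = fit_joint(counts, FitConfig(seed=1))
        assert res.converged
        assert res.params.mu_left == pytest.approx(true.mu_left, abs=0.1)
        assert res.params.mu_right == pytest.approx(true.mu_right, abs=0.1)
        assert res.params.beta_left == pytest.approx(true.beta_left, abs=0.02)
        assert res.params.beta_right == pytest.approx(true.beta_right, abs=0.02)

    def test_sse_not_above_coarse_grid(self):
        # oracle bound: returned optimum beats every point of a parameter grid
        true = JointFitParams(-12.0, 0.25, 12.0, 0.25)
        counts = counts_from_params(true, n_total=50)
        res = fit_joint(counts, FitConfig(seed=0))
        obs = counts[["n_left", "n_middle", "n_right"]].to_numpy() / 50.0

        best = np.inf
        for ml in np.linspace(-30, -2, 15):
            for mr in np.linspace(2, 30, 15):
                for b in np.linspace(0.05, 0.6, 8):
                    l, m, r = predict_proportions((ml, b, mr, b), DESIGN_AZIMUTHS)
                    sse = ((np.stack([l, m, r], 1) - obs) ** 2).sum()
                    best = min(best, sse)
        assert res.loss <= best + 1e-12

    def test_all_middle_is_unfittable(self):
        counts = make_count_table(fills={az: (0, 10, 0) for az in DESIGN_AZIMUTHS})
        with pytest.raises(FitFailure):
            fit_joint(counts, FitConfig(seed=0))

    def test_mirror_dataset_mirrors_params(self):
        rng = np.random.default_rng(4)
        true = (-9.0, 0.3, 16.0, 0.2)
        pL, pM, pR = predict_proportions(true, DESIGN_AZIMUTHS)
        counts = np.array([rng.multinomial(200, p) for p in
                           np.stack([pL, pM, pR], 1)])
        fwd = pd.DataFrame({"azimuth_deg": DESIGN_AZIMUTHS,
                            "n_left": counts[:, 0], "n_middle": counts[:, 1],
                            "n_right": counts[:, 2], "n_total": 200})
        mir = pd.DataFrame({"azimuth_deg": DESIGN_AZIMUTHS,
                            "n_left": counts[::-1, 2], "n_middle": counts[::-1, 1],
                            "n_right": counts[::-1, 0], "n_total": 200})
        a = fit_joint(fwd, FitConfig(seed=2)).params
        b = fit_joint(mir, FitConfig(seed=2)).params
        assert b.mu_right == pytest.approx(-a.mu_left, abs=0.05)
        assert b.mu_left == pytest.approx(-a.mu_right, abs=0.05)
        assert b.beta_right == pytest.approx(a.beta_left, abs=0.01)
        assert b.beta_left == pytest.approx(a.beta_right, abs=0.01)

    def test_width_invariant_to_count_scaling(self):
        true = JointFitParams(-13.0, 0.28, 13.0, 0.28)
        c1 = counts_from_params(true, n_total=10)
        c10 = c1.copy()
        for col in ("n_left", "n_middle", "n_right", "n_total"):
            c10[col] *= 10
        w1 = find_crossings(fit_joint(c1, FitConfig(seed=0)).params).width
        w10 = find_crossings(fit_joint(c10, FitConfig(seed=0)).params).width
        assert w1 == pytest.approx(w10, abs=1e-3)

    def test_too_few_azimuths(self):
        counts = make_count_table().iloc[:3]
        with pytest.raises(FitFailure):
            fit_joint(counts, FitConfig(seed=0))


class TestFindCrossings:
    @staticmethod
    def brute_force(params, lo=-90, hi=90, step=1e-3):
        grid = np.arange(lo, hi, step)
        pL, pM, pR = predict_proportions(params, grid)

        def nearest_root(diff):
            s = np.sign(diff)
            idx = np.flatnonzero(s[:-1] * s[1:] <= 0)
            if len(idx) == 0:
                return None
            mids = grid[idx] + step / 2
            return float(mids[np.argmin(np.abs(mids))])

        return nearest_root(pL - pM), nearest_root(pR - pM)

    def test_against_bruteforce_scan(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            p = (rng.uniform(-30, -5), rng.uniform(0.1, 1.0),
                 rng.uniform(5, 30), rng.uniform(0.1, 1.0))
            cone = find_crossings(p)
            xl, xr = self.brute_force(p)
            assert cone.status == "ok"
            assert cone.x_left_cross == pytest.approx(xl, abs=0.01)
            assert cone.x_right_cross == pytest.approx(xr, abs=0.01)

    def test_step_function_limit(self):
        cone = find_crossings((-20.0, 50.0, 20.0, 50.0))
        assert cone.width == pytest.approx(40.0, abs=0.01)

    def test_mirror_symmetry(self):
        cone = find_crossings((-17.0, 0.33, 17.0, 0.33))
        assert cone.x_left_cross == pytest.approx(-cone.x_right_cross, abs=1e-3)

    def test_no_crossing_status(self):
        # left curve never reaches the middle curve within range
        cone = find_crossings((-200.0, 0.5, 20.0, 0.5), search_range=(-90, 90))
        assert cone.status == "no_left_cross"
        assert np.isnan(cone.width)


class TestConeWidthPipeline:
    def test_empty_input(self):
        out = cone_width_pipeline(pd.DataFrame(
            columns=["participant_id", "condition", "azimuth_deg",
                     "n_left", "n_middle", "n_right", "n_total"]))
        assert out.empty

    def test_fit_failure_flags_whole_participant(self):
        good = make_count_table("p1", "direct_gaze")
        bad = make_count_table("p1", "eyes_closed",
                               fills={az: (0, 10, 0) for az in DESIGN_AZIMUTHS})
        other = make_count_table("p2", "direct_gaze")
        other2 = make_count_table("p2", "eyes_closed")
        counts = pd.concat([good, bad, other, other2], ignore_index=True)
        out = cone_width_pipeline(counts, FitConfig(seed=0))
        p1 = out[out["participant_id"] == "p1"]
        p2 = out[out["participant_id"] == "p2"]
        assert not p1["participant_fit_ok"].any()
        assert p2["participant_fit_ok"].all()

    def test_recovery_against_ground_truth(self):
        # dense data: recovered widths land within a degree of the oracle truth
        spec = CohortSpec(n_participants={"white": 6}, design="exp1",
                          trials_per_cell=500, between_participant_sd=2.0, seed=6)
        trials, truth = simulate_cohort(spec)
        out = cone_width_pipeline(aggregate_counts(trials), FitConfig(seed=0))
        merged = out.merge(truth, on=["participant_id", "condition"])
        assert merged["fit_ok"].all()
        err = (merged["width"] - merged["true_width"]).abs()
        assert err.mean() < 1.0

    def test_recovery_at_study_scale(self):
        # 10 trials/cell, many participants: small mean signed error and a
        # strong truth correlation
        spec = CohortSpec(n_participants={"white": 50, "east_asian": 50},
                          design="exp1", seed=13)
        trials, truth = simulate_cohort(spec)
        out = cone_width_pipeline(aggregate_counts(trials), FitConfig(seed=0))
        merged = out[out["fit_ok"]].merge(truth, on=["participant_id", "condition"])
        signed = (merged["width"] - merged["true_width"]).mean()
        assert abs(signed) < 1.5
        assert np.corrcoef(merged["width"], merged["true_width"])[0, 1] > 0.7
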