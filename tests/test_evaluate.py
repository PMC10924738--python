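import numpy as np
import pandas as pd
import pytest

from growthnorm.evaluate import (
    compare_models,
    make_cv_plan,
    rf_trajectory,
    score,
    sp_trajectory,
)


class TestCVPlans:
    def test_cvg_folds_partition_genotypes(self):
        genos = [f"g{i}" for i in range(10)]
        plan = make_cv_plan(genos, ["E1"], "CV-G", k_folds=5, repeats=1, seed=0)
        folds = [set(fold) for _, fold, _ in plan.cells]
        assert all(len(f) == 2 for f in folds)
        assert set().union(*folds) == set(genos)
        assert sum(len(f) for f in folds) == 10  # disjoint

    def test_cvge_grid_is_folds_times_environments(self):
        genos = [f"g{i}" for i in range(10)]
        envs = [f"E{j}" for j in range(8)]
        plan = make_cv_plan(genos, envs, "CV-GE", k_folds=5, repeats=1, seed=0)
        assert len(plan.cells) == 40
        design = pd.DataFrame(
            [
                {"plot_id": f"{e}-{g}", "genotype": g, "environment": e}
                for g in genos
                for e in envs
            ]
        )
        for cell in plan.cells:
            tr = design[plan.training_mask(design, cell)]
            te = design[plan.test_mask(design, cell)]
            # training = 4 folds x 7 environments
            assert tr["genotype"].nunique() == 8
            assert tr["environment"].nunique() == 7
            assert not set(te["genotype"]) & set(tr["genotype"])
            assert not set(te["environment"]) & set(tr["environment"])

    def test_cv_integrity_over_random_plans(self):
        """No CV-GE training record shares genotype or environment with its
        test cell, across 10 random plans."""
        genos = [f"g{i}" for i in range(17)]
        envs = [f"E{j}" for j in range(5)]
        design = pd.DataFrame(
            [
                {"plot_id": f"{e}-{g}", "genotype": g, "environment": e}
                for g in genos
                for e in envs
            ]
        )
        for seed in range(10):
            plan = make_cv_plan(genos, envs, "CV-GE", k_folds=5, repeats=1, seed=seed)
            for cell in plan.cells:
                tr = design[plan.training_mask(design, cell)]
                te = design[plan.test_mask(design, cell)]
                assert not set(tr["plot_id"]) & set(te["plot_id"])
                assert not set(tr["genotype"]) & set(te["genotype"])
                assert not set(tr["environment"]) & set(te["environment"])

    def test_cv_e_is_leave_one_environment_out(self):
        plan = make_cv_plan(["g1", "g2"], ["E1", "E2", "E3"], "CV-E")
        assert len(plan.cells) == 3
        assert {env for _, _, env in plan.cells} == {"E1", "E2", "E3"}

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValueError):
            make_cv_plan(["g1", "g2"], ["E1"], "CV-X")


class TestTrajectories:
    def test_zero_coefficients_give_flat_trajectory(self, rng):
        from growthnorm.spline_rn import SplineReactionNorm, build_basis

        fit = SplineReactionNorm(Q=3)
        fit.basis_ = build_basis(rng.uniform(2, 8, 50), 3)
        days = np.arange(1.0, 6.0)
        fit.coefs_ = {("g", float(d)): np.zeros(3) for d in days}
        traj = sp_trajectory(fit, "g", days, np.full(5, 5.0), y0=7.0)
        np.testing.assert_array_equal(traj, 7.0)

    def test_true_coefficients_reproduce_noise_free_trajectory(self, noise_free_trial):
        """Exact recursion: feeding planted coefficients and the true initial
        value reproduces the generative trajectory to machine precision."""
        from growthnorm.spline_rn import SplineReactionNorm

        design = noise_free_trial["design"]
        truth = noise_free_trial["truth"]
        days = truth.days.astype(float)
        gl = {g: i for i, g in enumerate(truth.extras["genotypes"].genotype_ids)}
        fit = SplineReactionNorm(Q=truth.true_coefs.shape[0])
        fit.basis_ = truth.basis
        moist = truth.extras["moisture_dense"]
        for pi in (0, 7, 19):
            g = design["genotype"].iloc[pi]
            fit.coefs_ = {
                (g, float(d)): truth.true_coefs[:, gl[g], k]
                for k, d in enumerate(days)
            }
            ref = truth.extras["trajectory_unclipped"]
            traj = sp_trajectory(fit, g, days, moist[pi], y0=ref[pi, 0])
            np.testing.assert_allclose(traj, ref[pi], atol=1e-9)

    def test_injected_error_propagates_undiminished(self, noise_free_trial):
        """A first-day perturbation shifts the whole SP trajectory additively:
        absolute error never decreases along the horizon."""
        from growthnorm.spline_rn import SplineReactionNorm

        design = noise_free_trial["design"]
        truth = noise_free_trial["truth"]
        days = truth.days.astype(float)
        gl = {g: i for i, g in enumerate(truth.extras["genotypes"].genotype_ids)}
        g = design["genotype"].iloc[3]
        fit = SplineReactionNorm(Q=truth.true_coefs.shape[0])
        fit.basis_ = truth.basis
        fit.coefs_ = {
            (g, float(d)): truth.true_coefs[:, gl[g], k] for k, d in enumerate(days)
        }
        moist = truth.extras["moisture_dense"]
        ref = truth.extras["trajectory_unclipped"]
        traj = sp_trajectory(fit, g, days, moist[3], y0=ref[3, 0] + 0.5)
        err = np.abs(traj - ref[3])
        assert np.all(np.diff(err) >= -1e-12)

    def test_missing_moisture_reported_with_days(self, rng):
        from growthnorm.spline_rn import SplineReactionNorm, build_basis

        fit = SplineReactionNorm(Q=3)
        fit.basis_ = build_basis(rng.uniform(2, 8, 50), 3)
        days = np.arange(1.0, 4.0)
        fit.coefs_ = {("g", float(d)): np.zeros(3) for d in days}
        s = np.array([5.0, np.nan, 5.0])
        with pytest.raises(ValueError, match="2.0"):
            sp_trajectory(fit, "g", days, s, y0=1.0)


class TestRunSchemeCVE:
    def test_leave_one_environment_out_covers_every_environment(self, small_trial):
        from growthnorm.evaluate import run_scheme
        from growthnorm.preprocess import smooth_all_plots

        design = small_trial["design"]
        truth = small_trial["truth"]
        smoothed = smooth_all_plots(small_trial["phenotypes"])
        moisture = pd.DataFrame(
            {
                "plot_id": np.repeat(design["plot_id"].to_numpy(), len(truth.days)),
                "day": np.tile(truth.days.astype(float), len(design)),
                "moisture": truth.extras["moisture_dense"].ravel(),
            }
        )
        preds = run_scheme(
            design, smoothed, moisture, truth.extras["kernel"], "CV-E",
            models=("SP",), seed=0,
        )
        # every environment appears as a test cell exactly once, all plots
        per_env = preds.groupby("environment")["plot_id"].nunique()
        counts = design.groupby("environment")["plot_id"].nunique()
        pd.testing.assert_series_equal(per_env, counts, check_names=False)
        assert np.isfinite(preds["predicted"]).all()


class TestScore:
    def _preds(self, values):
        rows = []
        for k, v in enumerate(values):
            rows.append(
                {"model": "M", "scheme": "CV-G", "repeat": 0, "environment": "E",
                 "day": 1.0, "plot_id": f"p{k}", "predicted": v}
            )
        return pd.DataFrame(rows)

    def test_perfect_and_inverted_predictions(self, rng):
        truth_vals = rng.uniform(0, 10, 6)
        truth = pd.DataFrame(
            {"plot_id": [f"p{k}" for k in range(6)], "day": 1.0, "smoothed": truth_vals}
        )
        rep = score(self._preds(truth_vals), truth)
        assert rep["r"].iloc[0] == pytest.approx(1.0)
        rep = score(self._preds(-truth_vals), truth)
        assert rep["r"].iloc[0] == pytest.approx(-1.0)

    def test_hand_built_cell_matches_direct_formula(self):
        pred_vals = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        true_vals = np.array([2.0, 2.5, 1.0, 4.0, 6.0])
        truth = pd.DataFrame(
            {"plot_id": [f"p{k}" for k in range(5)], "day": 1.0, "smoothed": true_vals}
        )
        rep = score(self._preds(pred_vals), truth)
        assert rep["r"].iloc[0] == pytest.approx(np.corrcoef(pred_vals, true_vals)[0, 1])

    def test_zero_variance_cells_excluded(self):
        truth = pd.DataFrame(
            {"plot_id": [f"p{k}" for k in range(4)], "day": 1.0, "smoothed": 3.0}
        )
        with pytest.raises(ValueError):
            score(self._preds([1.0, 2.0, 3.0, 4.0]), truth)

    def test_repeat_averaging_before_reporting(self, rng):
        rows = []
        truth_vals = rng.uniform(0, 10, 4)
        for rep_id in (0, 1):
            for k in range(4):
                rows.append(
                    {"model": "M", "scheme": "CV-G", "repeat": rep_id,
                     "environment": "E", "day": 1.0, "plot_id": f"p{k}",
                     "predicted": truth_vals[k] if rep_id == 0 else -truth_vals[k]}
                )
        truth = pd.DataFrame(
            {"plot_id": [f"p{k}" for k in range(4)], "day": 1.0, "smoothed": truth_vals}
        )
        rep = score(pd.DataFrame(rows), truth)
        assert rep["r"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert rep["repeats"].iloc[0] == 2


class TestCompareModels:
    def _report(self, rs):
        return pd.DataFrame(
            [
                {"model": "A", "scheme": "CV-G", "environment": "E", "day": float(d), "r": r}
                for d, r in enumerate(rs)
            ]
        )

    def test_identical_reports_zero_wins(self):
        a = self._report([0.1, 0.2, 0.3])
        out = compare_models(a, a.copy())
        assert out["wins"] == 0 and out["ties"] == 3

    def test_uniform_epsilon_wins_everywhere(self):
        a = self._report([0.1, 0.2, 0.3])
        b = a.copy()
        a["r"] += 1e-6
        out = compare_models(a, b)
        assert out["wins"] == out["total"] == 3

    def test_wins_losses_ties_partition_total(self, rng):
        a = self._report(rng.uniform(-1, 1, 20))
        b = self._report(rng.uniform(-1, 1, 20))
        out = compare_models(a, b)
        assert out["wins"] + out["losses"] + out["ties"] == out["total"] == 20

    def test_mismatched_grids_rejected(self):
        a = self._report([0.1, 0.2])
        b = self._report([0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            compare_models(a, b)
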