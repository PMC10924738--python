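import numpy as np
import pandas as pd
import pytest

from growthnorm.spline_rn import (
    BSplineBasis,
    SplineReactionNorm,
    build_basis,
    extract_rn_curves,
    fit_target,
)


@pytest.fixture()
def moisture_sample(rng):
    return rng.uniform(2.0, 8.0, 200)


class TestBasis:
    @pytest.mark.parametrize("Q", [3, 4, 5])
    def test_partition_of_unity_on_interior_grid(self, moisture_sample, Q):
        basis = build_basis(moisture_sample, Q)
        s = np.linspace(basis.lo, basis.hi, 100)
        np.testing.assert_allclose(basis.design(s).sum(axis=1), 1.0, atol=1e-10)

    def test_q4_cubic_has_no_interior_knots(self, moisture_sample):
        basis = build_basis(moisture_sample, 4)
        assert basis.degree == 3
        assert basis.Q == 4
        assert len(basis.knots) == 8  # 2 x (degree+1), nothing interior

    def test_q3_degree_reduced(self, moisture_sample):
        basis = build_basis(moisture_sample, 3)
        assert basis.degree == 2
        assert basis.Q == 3

    def test_evaluation_outside_support_clamped(self, moisture_sample):
        basis = build_basis(moisture_sample, 4)
        lo_val = basis.design(np.array([basis.lo]))
        below = basis.design(np.array([basis.lo - 5.0]))
        np.testing.assert_allclose(below, lo_val)

    def test_basis_functions_non_negative(self, moisture_sample):
        basis = build_basis(moisture_sample, 5)
        s = np.linspace(basis.lo, basis.hi, 200)
        assert np.all(basis.design(s) >= -1e-12)

    def test_degenerate_support_rejected(self):
        with pytest.raises(ValueError):
            build_basis(np.full(10, 3.3), 3)


class TestFitTarget:
    def test_uniform_weights_ols_on_linear_data(self, rng):
        """Q=2 linear basis, exact linear data: recovers the line."""
        s = rng.uniform(0, 1, 30)
        basis = build_basis(s, 2)  # degree 1, two hat functions
        phi = basis.design(s)
        dy = 1.5 + 2.0 * s
        c = fit_target(phi, dy, np.ones(30), ridge=0.0)
        np.testing.assert_allclose(phi @ c, dy, atol=1e-9)

    def test_single_record_constant_basis(self):
        phi = np.ones((1, 1))
        c = fit_target(phi, np.array([3.7]), np.array([1.0]))
        assert c[0] == pytest.approx(3.7)

    def test_matches_brute_force_weighted_normal_equations(self, rng):
        """Random fixtures: closed-form solve equals explicit (Φ'WΦ)⁻¹Φ'Wy."""
        for Q in (3, 4, 5):
            for _ in range(10):
                n = 30
                s = rng.uniform(1, 9, n)
                basis = build_basis(s, Q)
                phi = basis.design(s)
                dy = rng.normal(0, 1, n)
                w = rng.uniform(0.1, 2.0, n)
                got = fit_target(phi, dy, w)
                W = np.diag(w)
                expect = np.linalg.solve(phi.T @ W @ phi, phi.T @ W @ dy)
                np.testing.assert_allclose(got, expect, atol=1e-8)

    def test_zero_weights_raise_with_effective_n(self):
        phi = np.ones((5, 2))
        phi[:, 1] = np.arange(5)
        with pytest.raises(np.linalg.LinAlgError, match="effective sample size"):
            fit_target(phi, np.zeros(5), np.zeros(5))


def _fit_frame(rng, n_geno=4, n_days=6, seed_kernel=True):
    genos = [f"g{i}" for i in range(n_geno)]
    days = np.arange(1.0, n_days + 1)
    rows = []
    for g in genos:
        for d in days[1:]:
            rows.append(
                {
                    "genotype": g,
                    "day": d,
                    "s_prev": rng.uniform(2, 8),
                    "dy": rng.normal(1, 0.3),
                }
            )
    kern = np.eye(n_geno) * 0.5 + 0.5
    kw = pd.DataFrame(kern, index=genos, columns=genos)
    return pd.DataFrame(rows), kw, genos, days


class TestSplineReactionNormEstimator:
    def test_targets_with_identical_weight_profile_share_coefficients(self, rng):
        table, kw, genos, days = _fit_frame(rng)
        kw.loc["g1"] = kw.loc["g0"].to_numpy()  # same kernel row
        fit = SplineReactionNorm(Q=3, ridge=0.0).fit(table, kw, target_days=days)
        for d in days:
            np.testing.assert_allclose(
                fit.coefs_[("g0", d)], fit.coefs_[("g1", d)], atol=1e-10
            )

    def test_infinite_bandwidth_all_ones_kernel_pools_to_single_ols(self, rng):
        table, kw, genos, days = _fit_frame(rng)
        kw[:] = 1.0
        fit = SplineReactionNorm(Q=3, lambda0=1e12, ridge=0.0).fit(
            table, kw, target_days=days
        )
        phi = fit.basis_.design(table["s_prev"].to_numpy())
        pooled = np.linalg.lstsq(phi, table["dy"].to_numpy(), rcond=None)[0]
        for key, c in fit.coefs_.items():
            np.testing.assert_allclose(c, pooled, atol=1e-6)

    def test_estimator_matches_per_target_brute_force(self, rng):
        """Vectorised fit equals a per-target explicit WLS solve."""
        table, kw, genos, days = _fit_frame(rng, n_geno=5, n_days=5)
        lam0 = 30.0
        fit = SplineReactionNorm(Q=3, lambda0=lam0, ridge=0.0).fit(
            table, kw, target_days=days
        )
        phi = fit.basis_.design(table["s_prev"].to_numpy())
        for g in genos:
            for d in days:
                w = (
                    kw.loc[g, table["genotype"]].to_numpy(float)
                    * np.exp(-((d - table["day"].to_numpy(float)) ** 2) / lam0)
                )
                expect = np.linalg.solve(
                    phi.T @ (phi * w[:, None]), phi.T @ (w * table["dy"].to_numpy())
                )
                np.testing.assert_allclose(fit.coefs_[(g, d)], expect, atol=1e-8)

    def test_weight_locality_lambda0(self, rng):
        """Larger lambda0 never decreases any day weight."""
        d = np.abs(rng.uniform(0, 20, 50))
        w10 = np.exp(-(d**2) / 10.0)
        w70 = np.exp(-(d**2) / 70.0)
        assert np.all(w70 >= w10)

    def test_scaling_of_response_scales_coefficients(self, rng):
        table, kw, genos, days = _fit_frame(rng)
        fit1 = SplineReactionNorm(Q=3, ridge=0.0).fit(table, kw, target_days=days)
        table2 = table.assign(dy=table["dy"] * 4.0)
        fit2 = SplineReactionNorm(Q=3, ridge=0.0).fit(table2, kw, target_days=days)
        for key in fit1.coefs_:
            np.testing.assert_allclose(fit2.coefs_[key], 4.0 * fit1.coefs_[key], atol=1e-8)

    def test_evaluate_is_sum_of_basis_coefficients(self, rng):
        table, kw, genos, days = _fit_frame(rng)
        fit = SplineReactionNorm(Q=3).fit(table, kw, target_days=days)
        g, d = genos[0], days[2]
        s = 5.0
        expect = float((fit.basis_.design(np.array([s])) @ fit.coefs_[(g, d)])[0])
        assert fit.evaluate(g, d, s) == pytest.approx(expect, abs=1e-12)
        # unit coefficient vector returns the basis function itself
        fit.coefs_[(g, d)] = np.array([0.0, 1.0, 0.0])
        phi = fit.basis_.design(np.array([s]))[0]
        assert fit.evaluate(g, d, s) == pytest.approx(phi[1])
        fit.coefs_[(g, d)] = np.zeros(3)
        assert fit.evaluate(g, d, s) == 0.0

    def test_missing_target_raises(self, rng):
        table, kw, genos, days = _fit_frame(rng)
        fit = SplineReactionNorm(Q=3).fit(table, kw, target_days=days)
        with pytest.raises(KeyError):
            fit.evaluate("nope", days[0], 5.0)

    def test_recovery_degrades_monotonically_with_noise(self):
        """Median curve correlation with truth decreases as growth noise grows."""
        from growthnorm.synthetic import SimConfig, simulate_trial
        from growthnorm.genomics import clip_negative
        from tests.conftest import sp_training_table

        meds = []
        for noise in (0.0, 0.4, 1.2):
            cfg = SimConfig(
                n_genotypes=10, n_markers=100, day_start=15, day_end=40,
                noise_sd_growth=noise, noise_sd_obs=0.0, bias_range=(1.0, 1.0),
                seed=31,
            )
            design, _, _, _, truth = simulate_trial(cfg)
            table = sp_training_table(design, truth, realized=True)
            kern = clip_negative(truth.extras["kernel"])
            genos = sorted(design["genotype"].unique())
            kw = pd.DataFrame(
                kern.submatrix(genos, genos), index=genos, columns=genos
            )
            days = truth.days.astype(float)
            fit = SplineReactionNorm(Q=3, lambda0=10).fit(
                table, kw, target_genotypes=genos, target_days=days
            )
            gl = {g: i for i, g in enumerate(truth.extras["genotypes"].genotype_ids)}
            sgrid = np.linspace(truth.basis.lo + 0.3, truth.basis.hi - 0.3, 20)
            phi = truth.basis.design(sgrid)
            cors = []
            for (g, d), c in fit.coefs_.items():
                k = int(d - days[0])
                tc = phi @ truth.true_coefs[:, gl[g], k]
                est = fit.curve(g, d, sgrid)
                if tc.std() > 1e-9 and est.std() > 1e-9:
                    cors.append(np.corrcoef(tc, est)[0, 1])
            meds.append(np.median(cors))
        assert meds[0] > meds[1] > meds[2]


class TestExtractCurves:
    def test_support_mask_reflects_nearby_moisture_window(self, rng):
        table, kw, genos, days = _fit_frame(rng)
        fit = SplineReactionNorm(Q=3).fit(table, kw, target_days=days)
        moisture = pd.DataFrame({"day": [2.0, 3.0], "value": [4.0, 5.0]})
        sgrid = np.linspace(fit.basis_.lo, fit.basis_.hi, 11)
        curves, _ = extract_rn_curves(fit, [3.0], sgrid, moisture=moisture)
        m = curves.groupby("s")["in_support"].first()
        for s, flag in m.items():
            assert flag == (4.0 <= s <= 5.0)

    def test_identical_genotypes_get_stable_tiebreak_groups(self, rng):
        table, kw, genos, days = _fit_frame(rng)
        kw[:] = 1.0  # all genotypes identical weight profile -> identical curves
        fit = SplineReactionNorm(Q=3, lambda0=1e9).fit(table, kw, target_days=days)
        sgrid = np.linspace(fit.basis_.lo, fit.basis_.hi, 5)
        _, groups = extract_rn_curves(
            fit, [days[1]], sgrid, probe=(days[1], float(sgrid[2]))
        )
        # deterministic tie-break: rerun gives identical assignment
        _, groups2 = extract_rn_curves(
            fit, [days[1]], sgrid, probe=(days[1], float(sgrid[2]))
        )
        pd.testing.assert_frame_equal(groups, groups2)
        assert set(groups["group"]) <= {"low", "middle", "high"}

    def test_probe_outside_support_flagged(self, rng):
        table, kw, genos, days = _fit_frame(rng)
        fit = SplineReactionNorm(Q=3).fit(table, kw, target_days=days)
        with pytest.raises(ValueError, match="extrapolation"):
            extract_rn_curves(
                fit, [days[1]], np.array([5.0]), probe=(days[1], fit.basis_.hi + 10)
            )
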