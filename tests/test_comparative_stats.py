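import numpy as np
import pandas as pd
import pytest

from glottolearn import comparative_stats as cs


class TestEnumeration:
    def test_study1_counts(self):
        pairs = cs.enumerate_model_subsets(1)
        assert len(pairs) == 2430  # 4860 fits counting both members

    def test_study2_counts(self):
        pairs = cs.enumerate_model_subsets(2)
        assert len(pairs) == 728  # 1456 fits counting both members

    def test_reduced_specs_drop_population_and_slopes(self):
        for study in (1, 2):
            for full, red in cs.enumerate_model_subsets(study):
                assert full.include_population and not red.include_population
                assert red.slopes == ()
                assert red.intercepts == full.intercepts
                assert red.fixed == full.fixed

    def test_interaction_only_with_main_effects(self):
        for full, _ in cs.enumerate_model_subsets(1):
            if "h:L" in full.fixed:
                assert "h" in full.fixed and "L" in full.fixed

    def test_slopes_are_subset_of_intercepts(self):
        for full, _ in cs.enumerate_model_subsets(2):
            assert set(full.slopes) <= set(full.intercepts)
            assert "language" not in full.slopes


class TestDeltaAIC:
    def _fit(self, aic, converged=True):
        return cs.AssocFit(spec=cs.ModelSpec(2), beta=0.0, se=1.0, aic=aic, converged=converged)

    def test_lower_full_aic_wins(self):
        out = cs.delta_aic_compare(self._fit(100), self._fit(110))
        assert out.delta == pytest.approx(10) and out.full_apt

    def test_reduced_failure_makes_full_apt(self):
        out = cs.delta_aic_compare(self._fit(100), self._fit(np.nan, converged=False))
        assert out.full_apt

    def test_tie_favors_reduced(self):
        assert not cs.delta_aic_compare(self._fit(100), self._fit(100)).full_apt

    def test_double_failure_is_undefined(self):
        out = cs.delta_aic_compare(
            self._fit(np.nan, False), self._fit(np.nan, False)
        )
        assert out.full_apt is None


class TestFMA:
    def _fit(self, beta, aic, converged=True):
        return cs.AssocFit(spec=cs.ModelSpec(2), beta=beta, se=1.0, aic=aic, converged=converged)

    def test_single_model_passthrough(self):
        res = cs.fma_estimate([self._fit(-0.05, 120.0)])
        assert res.beta_fma == pytest.approx(-0.05)
        np.testing.assert_allclose(res.weights, [1.0])

    def test_equal_aic_symmetry(self):
        res = cs.fma_estimate([self._fit(0.0, 50.0), self._fit(1.0, 50.0)])
        assert res.beta_fma == pytest.approx(0.5)

    def test_hand_evaluated_weights(self):
        res = cs.fma_estimate(
            [self._fit(1.0, 10.0), self._fit(2.0, 12.0), self._fit(3.0, 14.0)]
        )
        w = np.exp([-0.0, -1.0, -2.0])
        w = w / w.sum()
        assert res.beta_fma == pytest.approx(w @ [1.0, 2.0, 3.0])
        assert res.weights.sum() == pytest.approx(1.0)

    def test_shift_invariance_and_failed_fits_excluded(self):
        a = cs.fma_estimate([self._fit(1.0, 10.0), self._fit(2.0, 11.0)])
        b = cs.fma_estimate([self._fit(1.0, 1010.0), self._fit(2.0, 1011.0)])
        assert a.beta_fma == pytest.approx(b.beta_fma)
        c = cs.fma_estimate(
            [self._fit(1.0, 10.0), self._fit(99.0, 5.0, converged=False)]
        )
        assert c.beta_fma == pytest.approx(1.0)
        assert c.weights[1] == 0.0

    def test_no_converged_fit_raises(self):
        with pytest.raises(ValueError):
            cs.fma_estimate([self._fit(1.0, 10.0, converged=False)])


@pytest.fixture()
def meta_frame():
    rng = np.random.default_rng(0)
    n = 80
    return pd.DataFrame(
        {
            "family": rng.choice(["F1", "F2", "F3"], n),
            "script": rng.choice(["S1", "S2"], n),
            "macro_area": rng.choice(["A1", "A2", "A3", "A4"], n),
            "egids": rng.integers(0, 10, n),
            "latitude": rng.uniform(-60, 60, n),
            "longitude": rng.uniform(-170, 170, n),
            "range_size": np.exp(rng.normal(5, 1, n)),
            "distance_to_water": np.exp(rng.normal(3, 1, n)),
            "altitude": np.exp(rng.normal(5, 1, n)),
            "n_countries": rng.integers(1, 8, n),
            "climate_pc1": rng.standard_normal(n),
            "climate_pc2": rng.standard_normal(n),
        }
    )


class TestCandidateSet:
    def test_spline_dimension_arithmetic(self, meta_frame):
        small = cs.build_candidate_set(meta_frame, "small")
        lat_cols = [c for c in small.columns if c.startswith("lat_bs")]
        lon_cols = [c for c in small.columns if c.startswith("lon_bs")]
        # (3 interior knots) + (degree 3) + 1 = 7 basis columns per axis
        assert len(lat_cols) == 7 and len(lon_cols) == 7
        medium = cs.build_candidate_set(meta_frame, "medium")
        assert len([c for c in medium.columns if "_x_" in c]) == 49

    def test_tiers_are_nested(self, meta_frame):
        small = set(cs.build_candidate_set(meta_frame, "small").columns)
        medium = set(cs.build_candidate_set(meta_frame, "medium").columns)
        big = set(cs.build_candidate_set(meta_frame, "big").columns)
        assert small < medium < big

    def test_degenerate_coordinates_dropped(self, meta_frame):
        flat = meta_frame.copy()
        flat["latitude"] = 12.0
        out = cs.build_candidate_set(flat, "small")
        assert not any(c.startswith("lat_bs") for c in out.columns)


class TestDoubleSelection:
    def test_zero_candidates_equals_simple_regression(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(100)
        y = 2.0 - 0.4 * x + 0.1 * rng.standard_normal(100)
        fit = cs.double_selection(y, x, pd.DataFrame(index=range(100)))
        slope = np.polyfit(x, y, 1)[0]
        assert fit.beta_ds == pytest.approx(slope, abs=1e-10)

    def test_confounder_recovery(self):
        betas = []
        for rep in range(10):
            rng = np.random.default_rng(500 + rep)
            n = 150
            c = rng.standard_normal(n)
            x = 0.6 * c + 0.8 * rng.standard_normal(n)
            y = -0.3 * x + 1.0 * c + 0.5 * rng.standard_normal(n)
            cand = pd.DataFrame(
                {"c": c, **{f"noise{j}": rng.standard_normal(n) for j in range(10)}}
            )
            betas.append(cs.double_selection(y, x, cand, seed=rep).beta_ds)
        naive = np.polyfit(x, y, 1)[0]
        assert abs(np.mean(betas) + 0.3) < 0.05
        assert abs(naive + 0.3) > 0.1  # the unadjusted slope is biased

    def test_pure_noise_candidates_leave_slope_alone(self):
        rng = np.random.default_rng(9)
        n = 200
        x = rng.standard_normal(n)
        y = -0.3 * x + 0.3 * rng.standard_normal(n)
        cand = pd.DataFrame({f"n{j}": rng.standard_normal(n) for j in range(15)})
        fit = cs.double_selection(y, x, cand, seed=0)
        assert len(fit.selected) <= 5
        assert fit.beta_ds == pytest.approx(np.polyfit(x, y, 1)[0], abs=0.02)


class TestFreedmanLane:
    def test_default_permutation_count(self):
        import inspect

        assert inspect.signature(cs.freedman_lane_test).parameters["n_perm"].default == 10000

    def test_perfect_effect_gives_smallest_p(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(40)
        res = cs.freedman_lane_test(y, y, None, n_perm=200, seed=1)
        assert res.p == pytest.approx(1 / 200)

    def test_null_rejection_rate_is_calibrated(self):
        rng = np.random.default_rng(42)
        rej = 0
        n_data = 100
        for _ in range(n_data):
            C = rng.standard_normal((60, 2))
            x = C @ np.array([0.5, -0.3]) + rng.standard_normal(60)
            y = C @ np.array([1.0, 0.7]) + rng.standard_normal(60)
            res = cs.freedman_lane_test(y, x, C, n_perm=300, seed=int(rng.integers(2**31)))
            rej += res.p <= 0.05
        assert 0.01 <= rej / n_data <= 0.10


class TestPGLS:
    def test_star_tree_equals_ols(self):
        import dendropy

        n = 20
        newick = "(" + ",".join(f"T{i}:1.0" for i in range(n)) + ");"
        tree = dendropy.Tree.get(data=newick, schema="newick")
        rng = np.random.default_rng(0)
        x = pd.Series(rng.standard_normal(n), index=[f"T{i}" for i in range(n)])
        y = -0.3 * x + 0.2 * rng.standard_normal(n)
        fit = cs.fit_pgls(y, x, tree)
        slope = np.polyfit(x.to_numpy(), y.to_numpy(), 1)[0]
        assert fit.beta_pgls == pytest.approx(slope, abs=1e-8)

    def test_perfect_linear_relation_has_unit_r2(self):
        import dendropy

        n = 10
        tree = dendropy.Tree.get(
            data="(" + ",".join(f"T{i}:1.0" for i in range(n)) + ");", schema="newick"
        )
        x = pd.Series(np.arange(n, dtype=float), index=[f"T{i}" for i in range(n)])
        fit = cs.fit_pgls(2.0 * x + 1.0, x, tree)
        assert fit.r2 == pytest.approx(1.0)

    def test_missing_language_is_reported(self):
        import dendropy

        tree = dendropy.Tree.get(data="(A:1,B:1);", schema="newick")
        y = pd.Series([0.0, 1.0, 2.0], index=["A", "B", "Z"])
        with pytest.raises(ValueError, match="Z"):
            cs.fit_pgls(y, y, tree)


class TestHaversine:
    def test_identical_points_zero(self):
        d = cs.haversine_matrix(np.array([10.0, 10.0]), np.array([20.0, 20.0]))
        assert d.iloc[0, 1] == pytest.approx(0.0)

    def test_antipodal_points_half_circumference(self):
        d = cs.haversine_matrix(np.array([0.0, 0.0]), np.array([0.0, 180.0]))
        assert d.iloc[0, 1] == pytest.approx(np.pi * cs.EARTH_RADIUS_KM, rel=1e-9)

    def test_symmetry_and_range_check(self):
        rng = np.random.default_rng(0)
        lat, lon = rng.uniform(-90, 90, 10), rng.uniform(-180, 180, 10)
        d = cs.haversine_matrix(lat, lon).to_numpy()
        np.testing.assert_array_equal(d, d.T)
        with pytest.raises(ValueError):
            cs.haversine_matrix(np.array([100.0]), np.array([0.0]))


def _random_weights(n, rng):
    lat, lon = rng.uniform(-60, 60, n), rng.uniform(-180, 180, n)
    return cs.inverse_distance_weights(cs.haversine_matrix(lat, lon).to_numpy())


class TestSAR:
    def test_weights_row_standardized_and_zero_capped(self):
        d = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 2.0], [0.0, 2.0, 0.0]])
        W = cs.inverse_distance_weights(d)
        np.testing.assert_allclose(W.sum(axis=1), 1.0)
        assert np.all(np.diag(W) == 0)
        assert np.isfinite(W).all()  # the zero off-diagonal was capped

    def test_independent_errors_match_ols(self):
        rng = np.random.default_rng(0)
        n = 120
        W1, W2 = _random_weights(n, rng), _random_weights(n, rng)
        x = rng.standard_normal(n)
        y = 1.0 - 0.3 * x + 0.5 * rng.standard_normal(n)
        fit = cs.fit_sar(y, x, W1, W2)
        slope = np.polyfit(x, y, 1)[0]
        assert abs(fit.beta_sar - slope) < 2 * fit.se

    def test_label_order_invariance(self):
        rng = np.random.default_rng(1)
        n = 60
        W1, W2 = _random_weights(n, rng), _random_weights(n, rng)
        x = rng.standard_normal(n)
        u = np.linalg.solve(np.eye(n) - 0.4 * W1, rng.standard_normal(n))
        y = -0.3 * x + u
        fit = cs.fit_sar(y, x, W1, W2)
        perm = rng.permutation(n)
        fit_p = cs.fit_sar(y[perm], x[perm], W1[np.ix_(perm, perm)], W2[np.ix_(perm, perm)])
        assert fit_p.beta_sar == pytest.approx(fit.beta_sar, abs=1e-8)

    def test_dependence_recovery(self):
        rng = np.random.default_rng(21)
        betas, lams = [], []
        for _ in range(10):
            n = 150
            W1, W2 = _random_weights(n, rng), _random_weights(n, rng)
            x = rng.standard_normal(n)
            u = np.linalg.solve(np.eye(n) - 0.5 * W1, rng.standard_normal(n))
            fit = cs.fit_sar(0.5 - 0.3 * x + u, x, W1, W2)
            betas.append(fit.beta_sar)
            lams.append(fit.lambda1)
        assert abs(np.mean(betas) + 0.3) < 0.05
        assert np.mean(lams) > 0.2

    def test_permutation_test_detects_duplicated_outcome(self):
        rng = np.random.default_rng(3)
        n = 50
        W1, W2 = _random_weights(n, rng), _random_weights(n, rng)
        y = rng.standard_normal(n)
        res = cs.sar_permutation_test(y, y, W1, W2, n_perm=200, seed=0)
        assert res.p == pytest.approx(1 / 200)
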