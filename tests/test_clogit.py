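import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from nhbd_lab import clogit


def direct_loglik(beta, X, y, groups):
    """Literal evaluation of log prod_s exp(x_case.b) / sum_j exp(x_j.b)."""
    ll = 0.0
    for g in np.unique(groups):
        sel = groups == g
        eta = X[sel] @ beta
        ll += eta[y[sel] == 1][0] - logsumexp(eta)
    return ll


def random_toy_strata(rng, n_strata=20, max_records=4, n_cov=2):
    X, y, groups = [], [], []
    for s in range(n_strata):
        m = rng.integers(2, max_records + 1)
        Xs = rng.normal(size=(m, n_cov))
        case = rng.integers(0, m)
        X.append(Xs)
        y.extend(int(i == case) for i in range(m))
        groups.extend([s] * m)
    return np.vstack(X), np.asarray(y), np.asarray(groups)


class TestLikelihood:
    def test_matches_direct_formula(self, rng):
        X, y, groups = random_toy_strata(rng, n_strata=60)
        for _ in range(10):
            beta = rng.normal(0, 2, X.shape[1])
            ours = clogit.conditional_loglik(beta, X, y, groups)
            assert ours == pytest.approx(direct_loglik(beta, X, y, groups), abs=1e-12)

    def test_null_likelihood_is_log_one_twelfth(self, rng):
        df = clogit.simulate_strata(30, {"nhbd": 0.7}, rng)
        X = df[["nhbd"]].to_numpy()
        ll0 = clogit.conditional_loglik(
            np.zeros(1), X, df["outcome"].to_numpy(), df["stratum"].to_numpy()
        )
        assert ll0 == pytest.approx(30 * np.log(1 / 12), abs=1e-10)

    def test_invariant_to_stratum_constant_shift(self, rng):
        X, y, groups = random_toy_strata(rng)
        beta = rng.normal(size=X.shape[1])
        base = clogit.conditional_loglik(beta, X, y, groups)
        shifts = rng.normal(0, 5, groups.max() + 1)
        X2 = X + shifts[groups][:, None]  # same shift within each stratum
        assert clogit.conditional_loglik(beta, X2, y, groups) == pytest.approx(
            base, abs=1e-9
        )


class TestNewtonFit:
    def grid_mle(self, X, y, groups):
        """Vectorized grid maximization of the written likelihood (1 cov)."""

        def ll_on(grid):
            out = np.zeros(len(grid))
            for g in np.unique(groups):
                sel = groups == g
                eta = np.outer(grid, X[sel, 0])  # (n_grid, m)
                out += eta[:, y[sel] == 1][:, 0] - logsumexp(eta, axis=1)
            return out

        coarse = np.linspace(-10, 10, 2001)
        b0 = coarse[ll_on(coarse).argmax()]
        fine = np.linspace(b0 - 0.02, b0 + 0.02, 4001)
        return fine[ll_on(fine).argmax()]

    def test_matches_grid_search(self, rng):
        for _ in range(3):
            X, y, groups = random_toy_strata(rng, n_strata=25, n_cov=1)
            est = clogit.ConditionalLogisticRegression().fit(X, y, groups)
            if not est.converged_:
                continue
            assert abs(est.coef_[0] - self.grid_mle(X, y, groups)) < 1e-3

    def test_cross_check_against_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.discrete.conditional_models import ConditionalLogit

        df = clogit.simulate_strata(80, {"nhbd": 0.8, "z": -0.4}, rng)
        X = df[["nhbd", "z"]]
        est = clogit.ConditionalLogisticRegression().fit(
            X, df["outcome"].to_numpy(), df["stratum"].to_numpy()
        )
        ref = ConditionalLogit(
            df["outcome"], X.to_numpy(), groups=df["stratum"]
        ).fit(disp=False)
        np.testing.assert_allclose(est.coef_, ref.params, atol=1e-4)
        np.testing.assert_allclose(est.se_, ref.bse, atol=1e-4)

    def test_monotone_likelihood_and_convergence(self, rng):
        df = clogit.simulate_strata(50, {"nhbd": 1.0}, rng)
        est = clogit.ConditionalLogisticRegression().fit(
            df[["nhbd"]], df["outcome"].to_numpy(), df["stratum"].to_numpy()
        )
        assert est.converged_
        assert est.llf_ >= est.llnull_

    def test_stratum_constant_covariate_rejected_by_name(self, rng):
        df = clogit.simulate_strata(10, {"nhbd": 0.5}, rng)
        df["sexcode"] = df["stratum"] % 2  # constant within every stratum
        with pytest.raises(ValueError, match="sexcode"):
            clogit.ConditionalLogisticRegression().fit(
                df[["nhbd", "sexcode"]],
                df["outcome"].to_numpy(),
                df["stratum"].to_numpy(),
            )

    def test_separation_flagged_without_intervals(self):
        # the covariate identifies the case perfectly: beta diverges
        rows = []
        for s in range(15):
            for i in range(4):
                rows.append({"stratum": s, "outcome": int(i == 0), "x": float(i == 0)})
        df = pd.DataFrame(rows)
        est = clogit.ConditionalLogisticRegression().fit(
            df[["x"]], df["outcome"].to_numpy(), df["stratum"].to_numpy()
        )
        assert est.separation_ and not est.converged_
        assert est.conf_int_ is None

    def test_multiple_cases_per_stratum_rejected(self):
        df = pd.DataFrame(
            {"stratum": [0, 0, 0], "outcome": [1, 1, 0], "x": [0.1, 0.2, 0.3]}
        )
        with pytest.raises(ValueError, match="exactly one case"):
            clogit.ConditionalLogisticRegression().fit(
                df[["x"]], df["outcome"].to_numpy(), df["stratum"].to_numpy()
            )

    def test_sklearn_param_interface(self):
        est = clogit.ConditionalLogisticRegression(tol=1e-6)
        assert est.get_params()["tol"] == 1e-6
        est.set_params(max_iter=50)
        assert est.max_iter == 50

    def test_predict_proba_sums_to_one_per_stratum(self, rng):
        df = clogit.simulate_strata(20, {"nhbd": 1.0}, rng)
        est = clogit.ConditionalLogisticRegression().fit(
            df[["nhbd"]], df["outcome"].to_numpy(), df["stratum"].to_numpy()
        )
        p = est.predict_proba(df[["nhbd"]].to_numpy(), df["stratum"].to_numpy())
        sums = pd.Series(p).groupby(df["stratum"]).sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)


def exact_corr_columns(rng, r, n=400):
    """Two standardized columns with empirical Pearson correlation exactly r."""
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    x = (x - x.mean()) / x.std()
    z = z - z.mean()
    z -= x * (x @ z) / (x @ x)  # orthogonalize
    z /= z.std()
    y = r * x + np.sqrt(1 - r**2) * z
    return x, y


class TestCorrelationScreen:
    def test_duplicate_column_dropped(self, rng):
        x = rng.normal(size=100)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=100)})
        kept = clogit.correlation_screen(df, priority=["a", "b", "c"])
        assert kept == ["a", "c"]

    def test_threshold_is_sharp(self, rng):
        x, y = exact_corr_columns(rng, 0.61)
        assert len(clogit.correlation_screen(pd.DataFrame({"a": x, "b": y}))) == 1
        x, y = exact_corr_columns(rng, 0.59)
        assert len(clogit.correlation_screen(pd.DataFrame({"a": x, "b": y}))) == 2

    def test_retains_the_reference_model_set(self, rng):
        # construct each screened-out variable as highly correlated with a
        # retained partner; weakly correlated elsewhere
        n = 500
        partners = {
            "pct_human_dominated": "human_density",
            "pct_agricultural": "human_density",
            "altitude": "pct_mountain",
            "roughness": "slope",
            "pct_mire": "pct_forest",
            "secondary_road_density": "main_road_density",
        }
        retained = [
            "pct_forest", "pct_water", "pct_mountain", "main_road_density",
            "bear_index", "slope", "human_accessibility",
            "moose_harvest_density", "human_density", "wolf_pair_density",
        ]
        df = pd.DataFrame({c: rng.normal(size=n) for c in retained})
        for victim, partner in partners.items():
            noise = rng.normal(size=n)
            df[victim] = 0.9 * (df[partner] - df[partner].mean()) / df[partner].std() + 0.3 * noise
        kept = clogit.correlation_screen(df)
        assert sorted(kept) == sorted(retained)

    def test_bad_threshold_rejected(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=10)})
        with pytest.raises(ValueError):
            clogit.correlation_screen(df, threshold=1.5)


class TestModelSuite:
    def suite_data(self, rng, n=40):
        df = clogit.simulate_strata(n, {"nhbd": 1.0, "wolf_pair_density": 0.3}, rng)
        meta = pd.DataFrame(
            {
                "stratum": np.arange(n),
                "sex": rng.choice(["F", "M"], n),
                "distance_category": rng.choice(["short", "medium"], n),
            }
        )
        return df.merge(meta, on="stratum")

    def test_pooled_fit_contains_interactions(self, rng):
        out = clogit.fit_model_suite(
            self.suite_data(rng), ["nhbd", "wolf_pair_density"]
        )
        pooled = out[out["group"] == "pooled"]
        assert {"nhbd_x_wolf_pair_density", "nhbd_x_sex"} <= set(pooled["variable"])

    def test_groups_and_combined_cells_present(self, rng):
        out = clogit.fit_model_suite(
            self.suite_data(rng), ["nhbd", "wolf_pair_density"]
        )
        assert {"all/short", "all/medium", "pooled"} <= set(out["group"])

    def test_empty_cell_skipped_others_fitted(self, rng):
        data = self.suite_data(rng)
        data.loc[
            (data["sex"] == "F") & (data["distance_category"] == "medium"),
            "distance_category",
        ] = "short"
        single = data[data["stratum"] == 0].copy()
        single["sex"], single["distance_category"] = "F", "medium"
        single["stratum"] = 999
        out = clogit.fit_model_suite(
            pd.concat([data, single]), ["nhbd", "wolf_pair_density"]
        )
        skipped = out[(out["group"] == "F/medium")]
        assert (skipped["note"] == "too few strata").all()
        assert (out[out["group"] == "pooled"]["converged"]).all()

    def test_deterministic(self, rng):
        data = self.suite_data(rng)
        a = clogit.fit_model_suite(data, ["nhbd", "wolf_pair_density"])
        b = clogit.fit_model_suite(data, ["nhbd", "wolf_pair_density"])
        pd.testing.assert_frame_equal(a, b)
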