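"""Statistical chain: standardization, residualization, OLS reporting,
BH-FDR, permutation testing, mediation, and BIC subset search."""

import numpy as np
import pandas as pd
import pytest

import topoconn as tc
from topoconn.errors import (
    CollinearityError,
    DegenerateMediatorError,
    DegenerateScaleError,
    InsufficientDataError,
    InvalidParameterError,
)


class TestStandardizeBehavior:
    def test_self_standardization(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(10, 3, 50)
        z = tc.standardize_behavior(scores, scores.mean(), scores.std())
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std() == pytest.approx(1, abs=1e-12)

    def test_speed_sign_inversion(self):
        # faster-than-baseline reaction time -> positive z
        z = tc.standardize_behavior([400.0], 500.0, 50.0, is_speed=True)
        assert z[0] == pytest.approx(2.0)

    def test_follow_up_uses_baseline_norms(self):
        rng = np.random.default_rng(1)
        bl = rng.normal(10, 2, 80)
        fu = bl + 1.5  # uniform improvement
        z_fu = tc.standardize_behavior(fu, bl.mean(), bl.std())
        assert z_fu.mean() == pytest.approx(1.5 / bl.std(), abs=1e-10)
        assert z_fu.mean() != pytest.approx(0, abs=0.1)

    def test_zero_sd(self):
        with pytest.raises(DegenerateScaleError):
            tc.standardize_behavior([1.0], 0.0, 0.0)


class TestResidualization:
    def test_hand_ols_fixture(self):
        res = tc.residualize_on_baseline([2, 2, 5], [1, 2, 3])
        np.testing.assert_allclose(res, [0.5, -1.0, 0.5], atol=1e-12)

    def test_orthogonal_change_is_centered(self):
        baseline = np.array([-1.0, 0.0, 1.0])
        change = np.array([2.0, 5.0, 2.0])  # orthogonal to baseline
        np.testing.assert_allclose(
            tc.residualize_on_baseline(change, baseline), change - 3.0, atol=1e-12
        )

    def test_perfect_fit_gives_zero(self):
        baseline = np.array([1.0, 2.0, 3.0, 4.0])
        np.testing.assert_allclose(
            tc.residualize_on_baseline(2 * baseline, baseline), 0.0, atol=1e-12
        )

    def test_constant_baseline_warns_and_centers(self):
        change = np.array([1.0, 2.0, 6.0])
        with pytest.warns(UserWarning, match="constant"):
            out = tc.residualize_on_baseline(change, np.full(3, 7.0))
        np.testing.assert_allclose(out, change - 3.0)

    def test_scrubbing_contamination_fully_removed(self):
        rng = np.random.default_rng(2)
        scrub = rng.normal(0.4, 0.1, 200)
        measure = 3.0 + 2.5 * scrub + rng.normal(0, 0.2, 200)
        adj = tc.remove_scrubbing(measure, scrub)
        assert abs(np.corrcoef(adj, scrub)[0, 1]) < 1e-10


class TestFitModel:
    def test_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(10, 3)), columns=["a", "b", "c"])
        y = rng.normal(size=10)
        res = tc.fit_model(y, X)
        design = np.column_stack([np.ones(10), X.to_numpy()])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        np.testing.assert_allclose(res.params["coef"].to_numpy(), beta[1:], atol=1e-10)

    def test_perfect_fit_limit(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=100)
        y = 2.0 * x + rng.normal(0, 1e-6, 100)
        res = tc.fit_model(y, pd.DataFrame({"x": x}))
        assert res.params.loc["x", "beta_std"] == pytest.approx(1.0, abs=1e-6)
        assert res.params.loc["x", "eta_p2"] == pytest.approx(1.0, abs=1e-6)

    def test_null_standardized_betas_small(self):
        hits = 0
        for s in range(60):
            rng = np.random.default_rng(500 + s)
            X = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
            res = tc.fit_model(rng.normal(size=200), X)
            hits += np.all(np.abs(res.params["beta_std"]) < 0.2)
        assert hits >= 57  # >= 95% of seeds

    def test_ci_brackets_coef_and_eta_in_range(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        res = tc.fit_model(rng.normal(size=50) + X["a"], X)
        for _, row in res.params.iterrows():
            assert row["ci_low"] <= row["coef"] <= row["ci_high"]
            assert 0.0 <= row["eta_p2"] <= 1.0

    def test_collinearity_names_columns(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=30)
        X = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.normal(size=30)})
        with pytest.raises(CollinearityError) as err:
            tc.fit_model(rng.normal(size=30), X)
        assert set(err.value.columns) & {"a", "b"}

    def test_insufficient_data(self):
        X = pd.DataFrame(np.eye(3), columns=list("abc"))
        with pytest.raises(InsufficientDataError):
            tc.fit_model([1.0, 2.0, 3.0], X)


class TestFdrFamily:
    def test_single_p_unchanged(self):
        adj, rej = tc.fdr_family([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_step_up_by_hand(self):
        adj, _ = tc.fdr_family([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, 0.04)

    def test_invalid_p(self):
        with pytest.raises(InvalidParameterError):
            tc.fdr_family([0.5, 1.2])

    def test_adjusted_never_below_raw_and_rank_monotone(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=40)
        adj, rej = tc.fdr_family(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        assert rej.sum() <= np.sum(p < 0.05)


class TestPermutationTest:
    def _planted(self, seed=8):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(150, 4)), columns=["t", "u", "v", "w"])
        y = 0.8 * X["t"] + 0.6 * rng.normal(size=150)
        return y, X

    def test_planted_effect_min_p(self):
        y, X = self._planted()
        assert tc.permutation_test(y, X, "t", n_perm=1000, seed=1) == 0.0

    def test_add_one_convention(self):
        y, X = self._planted()
        p = tc.permutation_test(y, X, "t", n_perm=1000, seed=1, add_one=True)
        assert p == pytest.approx(1 / 1001)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=["t", "u", "v"])
        y = rng.normal(size=60)
        p1 = tc.permutation_test(y, X, "t", n_perm=300, seed=5)
        p2 = tc.permutation_test(y, X, "t", n_perm=300, seed=5)
        assert p1 == p2

    def test_matches_literal_row_shuffle(self):
        """The fast inverse-permutation path equals literally refitting on
        shuffled predictor rows."""
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=["t", "u", "v"])
        y = rng.normal(size=40)
        observed = tc.fit_model(y, X).params.loc["t", "beta_std"]
        n_perm, seed = 200, 3
        p_fast = tc.permutation_test(y, X, "t", n_perm=n_perm, seed=seed)
        rng2 = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng2.permutation(40)
            shuffled = X.iloc[perm].reset_index(drop=True)
            stat = abs(tc.fit_model(y, shuffled).params.loc["t", "beta_std"])
            count += stat >= abs(observed)
        assert p_fast == pytest.approx(count / n_perm)

    def test_invalid_n_perm(self):
        y, X = self._planted()
        with pytest.raises(InvalidParameterError):
            tc.permutation_test(y, X, "t", n_perm=0)


class TestMediation:
    def _chain(self, n, a=-0.5, b=0.4, c=-0.1, seed=11):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        m = a * x + rng.normal(size=n)
        y = c * x + b * m + rng.normal(size=n)
        return x, m, y

    def test_product_of_coefficients_truth(self):
        x, m, y = self._chain(2000)
        res = tc.mediation_bootstrap(x, m, y, n_boot=500, seed=2)
        assert res.acme == pytest.approx(-0.20, abs=0.03)
        assert res.acme_ci[0] < res.acme < res.acme_ci[1]

    def test_exact_total_decomposition(self):
        x, m, y = self._chain(300, seed=12)
        res = tc.mediation_bootstrap(x, m, y, n_boot=50, seed=0)
        assert res.direct + res.acme == pytest.approx(res.total, abs=1e-10)

    def test_full_mediation_proportion(self):
        # c' = 0 by construction; outcome noise kept small so the ratio
        # estimator's sampling error is well inside the tolerance
        rng = np.random.default_rng(13)
        n = 2000
        x = rng.normal(size=n)
        m = -0.5 * x + rng.normal(size=n)
        y = 0.4 * m + 0.3 * rng.normal(size=n)
        res = tc.mediation_bootstrap(x, m, y, n_boot=500, seed=4)
        assert res.proportion == pytest.approx(1.0, abs=0.1)

    def test_covariates_accepted_and_deterministic(self):
        x, m, y = self._chain(200, seed=14)
        cov = pd.DataFrame({"c1": np.random.default_rng(15).normal(size=200)})
        r1 = tc.mediation_bootstrap(x, m, y, covariates=cov, n_boot=100, seed=9)
        r2 = tc.mediation_bootstrap(x, m, y, covariates=cov, n_boot=100, seed=9)
        assert r1.acme == r2.acme and r1.acme_ci == r2.acme_ci

    def test_degenerate_mediator(self):
        x, _, y = self._chain(100)
        with pytest.raises(DegenerateMediatorError):
            tc.mediation_bootstrap(x, np.zeros(100), y, n_boot=10)

    def test_too_few_cases(self):
        x, m, y = self._chain(20)
        with pytest.raises(InsufficientDataError):
            tc.mediation_bootstrap(x, m, y, n_boot=10)


class TestBicSearch:
    def test_seven_candidates_127_models(self):
        rng = np.random.default_rng(16)
        cands = pd.DataFrame(rng.normal(size=(60, 7)), columns=list("abcdefg"))
        table, _ = tc.bic_search(rng.normal(size=60), cands)
        assert len(table) == 127

    def test_single_candidate_single_model(self):
        rng = np.random.default_rng(17)
        table, _ = tc.bic_search(
            rng.normal(size=30), pd.DataFrame({"a": rng.normal(size=30)})
        )
        assert len(table) == 1

    def test_recovers_planted_subset(self):
        hits = 0
        for s in range(30):
            rng = np.random.default_rng(700 + s)
            cands = pd.DataFrame(
                rng.normal(size=(500, 7)),
                columns=["age", "nart", "edu", "sex", "ct", "wmh", "dauc"],
            )
            y = 0.6 * cands["age"] + 0.6 * cands["dauc"] + rng.normal(size=500)
            table, _ = tc.bic_search(y, cands)
            winner = set(table.loc[0, "predictors"].split("+"))
            hits += {"age", "dauc"} <= winner
        assert hits >= 27  # >= 90% of seeds

    def test_insufficient_data(self):
        rng = np.random.default_rng(18)
        cands = pd.DataFrame(rng.normal(size=(6, 7)), columns=list("abcdefg"))
        with pytest.raises(InsufficientDataError):
            tc.bic_search(rng.normal(size=6), cands)
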