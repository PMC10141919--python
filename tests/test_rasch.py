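"""Rating Scale Model estimation, fit diagnostics and the flow label."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from flowsense import rasch
from flowsense import synthetic as syn


def independent_rsm_loglik(x, beta, delta, tau):
    """Joint RSM log-likelihood written from the category definition,
    independent of the package's probability code."""
    n_persons, n_items = x.shape
    m = len(tau)
    total = 0.0
    for p in range(n_persons):
        for i in range(n_items):
            etas = []
            for k in range(m + 1):
                etas.append(k * (beta[p] - delta[i]) - sum(tau[:k]))
            denom = np.log(np.sum(np.exp(etas)))
            total += etas[x[p, i]] - denom
    return total


def independent_mle(x, m):
    """Maximize the joint likelihood with scipy under the same constraints
    (mean delta = 0, sum tau = 0), as an oracle for the JMLE path."""
    n_persons, n_items = x.shape

    def unpack(theta):
        beta = theta[:n_persons]
        d_free = theta[n_persons:n_persons + n_items - 1]
        delta = np.append(d_free, -d_free.sum())
        t_free = theta[n_persons + n_items - 1:]
        tau = np.append(t_free, -t_free.sum())
        return beta, delta, tau

    def nll(theta):
        return -independent_rsm_loglik(x, *unpack(theta))

    theta0 = np.zeros(n_persons + n_items - 1 + m - 1)
    res = minimize(nll, theta0, method="BFGS",
                   options={"maxiter": 2000, "gtol": 1e-9})
    return unpack(res.x), -res.fun


class TestFit:
    def test_matches_independent_likelihood_maximizer(self):
        # 5 persons x 3 items x 3 categories, no extreme rows/columns
        x = np.array([
            [0, 1, 0],
            [1, 2, 0],
            [2, 1, 1],
            [1, 2, 2],
            [2, 2, 1],
        ])
        fit = rasch.RatingScaleModel(x).fit(tol=1e-8, max_iter=2000)
        (beta_o, delta_o, tau_o), ll_o = independent_mle(x, m=2)
        np.testing.assert_allclose(fit.person_measures.to_numpy(), beta_o, atol=1e-2)
        np.testing.assert_allclose(fit.item_difficulties.to_numpy(), delta_o, atol=1e-2)
        np.testing.assert_allclose(fit.thresholds, tau_o, atol=1e-2)
        assert fit.loglik == pytest.approx(ll_o, abs=1e-3)

    def test_identical_rows_get_identical_measures(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 5, size=(10, 9))
        x[3] = x[7]
        x[0] = np.array([0, 1, 0, 2, 4, 1, 2, 0, 1])  # keep rows non-extreme
        fit = rasch.RatingScaleModel(x).fit()
        b = fit.person_measures.to_numpy()
        assert b[3] == pytest.approx(b[7], abs=1e-4)

    def test_constraints_hold(self, rsm_simulated):
        responses, *_ = rsm_simulated
        fit = rasch.RatingScaleModel(responses).fit()
        keep = ~fit.extreme_items.to_numpy()
        assert fit.item_difficulties.to_numpy()[keep].mean() == pytest.approx(0, abs=1e-6)
        assert fit.thresholds.sum() == pytest.approx(0, abs=1e-6)

    def test_extreme_person_flagged_and_placed_on_top(self):
        rng = np.random.default_rng(1)
        x = rng.integers(1, 4, size=(12, 9))
        x[0] = [0, 1, 2, 3, 4, 1, 2, 3, 1]  # anchor all five categories
        x[5] = 4  # all strongly-agree
        fit = rasch.RatingScaleModel(x).fit()
        assert fit.extreme_persons.iloc[5]
        measures = fit.person_measures
        assert np.isfinite(measures.iloc[5])
        assert measures.iloc[5] > measures.drop(measures.index[5]).max()

    def test_parameter_recovery_simulated(self, rsm_simulated):
        responses, beta_true, delta_true, _ = rsm_simulated
        fit = rasch.RatingScaleModel(responses).fit()
        keep = ~fit.extreme_persons.to_numpy()
        r_beta = np.corrcoef(fit.person_measures.to_numpy()[keep], beta_true[keep])[0, 1]
        r_delta = np.corrcoef(fit.item_difficulties.to_numpy(), delta_true)[0, 1]
        assert r_delta >= 0.9
        assert r_beta >= 0.85

    def test_unobserved_category_collapsed_with_warning(self):
        x = np.array([[0, 1], [1, 0], [4, 1], [1, 4], [0, 4]])  # 2,3 unseen
        with pytest.warns(UserWarning, match="collaps"):
            model = rasch.RatingScaleModel(x)
        assert model.max_score == 2

    def test_all_rows_extreme_unidentifiable(self):
        x = np.array([[0, 0, 0], [4, 4, 4], [0, 0, 0]])
        with pytest.raises(rasch.RaschError, match="unidentifiable|non-extreme"):
            rasch.RatingScaleModel(x).fit()

    def test_expected_score_monotone_in_beta(self):
        delta = np.array([-0.5, 0.0, 0.7])
        tau = np.array([-1.0, 0.0, 1.0])
        betas = np.linspace(-4, 4, 81)
        scores = rasch.rsm_expected_score(betas, delta, tau).sum(axis=1)
        assert np.all(np.diff(scores) > 0)

    def test_extremes_equally_likely_at_item_difficulty(self):
        # with sum(tau) = 0, P(X=0) = P(X=M) exactly when beta = delta_i
        tau = np.array([-1.2, -0.3, 0.3, 1.2])
        p = rasch.rsm_category_probs(np.array([0.7]), np.array([0.7]), tau)[0, 0]
        assert p[0] == pytest.approx(p[-1])


class TestFitStatistics:
    def test_infit_outfit_near_one_under_the_model(self):
        rng = np.random.default_rng(7)
        delta = np.linspace(-1.2, 1.2, 9)
        tau = np.array([-1.5, -0.5, 0.5, 1.5])
        rows = [syn.generate_fss_responses(b, delta, tau, rng)
                for b in rng.normal(0, 1.5, size=500)]
        fit = rasch.RatingScaleModel(pd.DataFrame(rows)).fit()
        fs = fit.fit_statistics()
        assert ((fs.item_infit >= 0.8) & (fs.item_infit <= 1.2)).all()
        assert ((fs.item_outfit >= 0.8) & (fs.item_outfit <= 1.2)).all()

    def test_deterministic_guttman_item_overfits(self):
        rng = np.random.default_rng(8)
        delta = np.zeros(9)
        tau = np.array([-1.5, -0.5, 0.5, 1.5])
        betas = rng.normal(0, 1.5, size=300)
        rows = np.array([syn.generate_fss_responses(b, delta, tau, rng)
                         for b in betas])
        # replace one item by a deterministic graded (Guttman-like) function
        # of beta: perfectly ordered responses overfit the stochastic model
        q = np.quantile(betas, [0.2, 0.4, 0.6, 0.8])
        rows[:, 4] = np.searchsorted(q, betas)
        fit = rasch.RatingScaleModel(pd.DataFrame(rows)).fit()
        fs = fit.fit_statistics()
        assert fs.item_outfit.iloc[4] < 1.0
        assert fs.item_infit.iloc[4] < 1.0

    def test_misfit_flagging_rule(self):
        fs = rasch.FitStats(
            expected=pd.DataFrame(), variance=pd.DataFrame(), z=pd.DataFrame(),
            item_infit=pd.Series({"a": 1.0, "b": 1.6, "c": 0.9}),
            item_outfit=pd.Series({"a": 1.0, "b": 1.1, "c": 1.51}),
            person_infit=pd.Series(dtype=float),
            person_outfit=pd.Series(dtype=float),
        )
        assert fs.misfitting_items == ["b", "c"]


class TestResidualPCA:
    def test_model_generated_data_looks_unidimensional(self):
        # under the fitted model, the first residual eigenvalue should fall
        # below 2 in nearly every replicate
        rng = np.random.default_rng(9)
        delta = np.linspace(-1.3, 1.3, 9)
        tau = np.array([-1.5, -0.5, 0.5, 1.5])
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            rows = [syn.generate_fss_responses(b, delta, tau, rng)
                    for b in rng.normal(0, 1.5, size=500)]
            fit = rasch.RatingScaleModel(pd.DataFrame(rows)).fit()
            hits += fit.residual_pca().unidimensional
        assert hits >= 0.95 * n_rep

    def test_planted_second_dimension_is_detected(self):
        rng = np.random.default_rng(10)
        delta = np.zeros(9)
        tau = np.array([-1.5, -0.5, 0.5, 1.5])
        betas = rng.normal(0, 1.2, size=400)
        nuisance = rng.normal(0, 1.2, size=400)
        rows = []
        for b, u in zip(betas, nuisance):
            r = syn.generate_fss_responses(b, delta, tau, rng)
            # items 0-2 also respond to an independent second trait
            r2 = syn.generate_fss_responses(b + 1.5 * u, delta, tau, rng)
            r[:3] = r2[:3]
            rows.append(r)
        fit = rasch.RatingScaleModel(pd.DataFrame(rows)).fit()
        pca = fit.residual_pca()
        assert not pca.unidimensional
        top3 = pca.loadings.abs().sort_values(ascending=False).index[:3]
        assert set(top3) == {0, 1, 2}
        planted = pca.loadings.iloc[[0, 1, 2]]
        assert (np.sign(planted) == np.sign(planted.iloc[0])).all()

    def test_eigenvalues_sum_to_item_count(self, rsm_simulated):
        responses, *_ = rsm_simulated
        pca = rasch.RatingScaleModel(responses).fit().residual_pca()
        assert pca.eigenvalues.sum() == pytest.approx(len(pca.retained_items))
        assert np.all(np.diff(pca.eigenvalues) <= 1e-9)


class TestReliability:
    def test_limits(self):
        base = rasch.RatingScaleModel(
            np.array([[0, 1, 2], [1, 2, 0], [2, 0, 1], [2, 2, 1]])).fit()
        spread = pd.Series([-2.0, -1.0, 1.0, 2.0], index=base.person_measures.index)
        base.person_measures = spread
        base.person_se = pd.Series(0.0, index=spread.index)
        person, _ = base.separation_reliability()
        assert person == pytest.approx(1.0)
        base.person_se = pd.Series(np.sqrt(spread.var(ddof=1)), index=spread.index)
        person, _ = base.separation_reliability()
        assert person == pytest.approx(0.0, abs=1e-9)

    def test_simulation_stability(self):
        rng = np.random.default_rng(11)
        delta = np.linspace(-1.3, 1.3, 9)
        tau = np.array([-1.5, -0.5, 0.5, 1.5])
        rels = []
        for _ in range(2):
            rows = [syn.generate_fss_responses(b, delta, tau, rng)
                    for b in rng.normal(0, 1.5, size=500)]
            fit = rasch.RatingScaleModel(pd.DataFrame(rows)).fit()
            rels.append(fit.separation_reliability()[0])
        assert abs(rels[0] - rels[1]) < 0.1


class TestWrightMap:
    def test_items_sorted_ascending(self, rsm_simulated):
        responses, *_ = rsm_simulated
        table = rasch.RatingScaleModel(responses).fit().wright_map()
        items = table[table["kind"] == "item"]["measure"].to_numpy()
        assert np.all(np.diff(items) >= 0)

    def test_hardest_generated_item_estimated_hardest(self, study1_bundle):
        fit = rasch.RatingScaleModel(study1_bundle.fss_matrix()).fit()
        assert fit.item_difficulties.idxmax() == "transformation_of_time"

    def test_summary_renders(self, rsm_simulated):
        responses, *_ = rsm_simulated
        text = rasch.RatingScaleModel(responses).fit().summary()
        assert "transformation_of_time" in text and "reliability" in text


class TestLabelFlow:
    @pytest.mark.parametrize("rating, label", [(0, 0), (2, 0), (3, 1), (4, 1)])
    def test_agree_threshold(self, rating, label):
        row = {name: 2 for name in rasch.ITEM_NAMES}
        row["transformation_of_time"] = rating
        out = rasch.label_flow(pd.DataFrame([row]))
        assert out.iloc[0] == label

    def test_all_zero_row_is_no_flow(self):
        out = rasch.label_flow(pd.DataFrame([{n: 0 for n in rasch.ITEM_NAMES}]))
        assert out.iloc[0] == 0

    def test_missing_item_column_errors(self):
        frame = pd.DataFrame([{n: 1 for n in rasch.ITEM_NAMES[:5]}])
        with pytest.raises(rasch.RaschError, match="transformation_of_time"):
            rasch.label_flow(frame)

    def test_missing_rating_errors(self):
        row = {n: 1.0 for n in rasch.ITEM_NAMES}
        row["transformation_of_time"] = np.nan
        with pytest.raises(rasch.RaschError, match="missing"):
            rasch.label_flow(pd.DataFrame([row]))
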