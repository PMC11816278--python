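import contextlib
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

import nfpmarkov as nm
from nfpmarkov.errors import SeparationWarning
from nfpmarkov.estimators import MCMCTransitionEstimator, MLTransitionEstimator
from nfpmarkov.panel import transition_pairs
from nfpmarkov.simulate import recovery_config


def test_intercept_only_mle_equals_empirical_matrix(cohort_20k):
    small = nm.generate_population(nm.default_config(n_participants=3000, seed=31))
    for data in (cohort_20k, small):
        for behavior in ("smoking", "betel"):
            emp = nm.empirical_transition_probs(data, behavior)
            fit = nm.fit_ml(data, behavior, None)
            fitted = fit.model_hat.transition_matrix().p
            np.testing.assert_allclose(fitted, emp.p, atol=1e-8)


def test_ml_agrees_with_statsmodels_mnlogit(cohort_20k):
    """Independent oracle: each origin row is a conditional multinomial
    logit with 'stay' as the reference category."""
    import statsmodels.api as sm

    fit = nm.fit_ml(cohort_20k, "smoking", ["male"])
    pairs = transition_pairs(cohort_20k, "smoking")
    row = 1  # origin: low dose
    sub = pairs[pairs["from_state"] == row]
    # relabel so the stay outcome is category 0 (MNLogit's reference)
    relabel = {1: 0, 0: 1, 2: 2}
    endog = sub["to_state"].map(relabel).to_numpy()
    exog = np.column_stack(
        [np.ones(len(sub)), (sub["sex"] == "male").astype(float)]
    )
    res = sm.MNLogit(endog, exog).fit(method="newton", disp=False, tol=1e-12)
    params = np.asarray(res.params)  # (k_exog, J-1)
    # category 1 = low->none, category 2 = low->high
    ours = fit.ci["estimate"]
    np.testing.assert_allclose(
        params[:, 0],
        [ours["low->none:intercept"], ours["low->none:male"]],
        atol=1e-6,
    )
    np.testing.assert_allclose(
        params[:, 1],
        [ours["low->high:intercept"], ours["low->high:male"]],
        atol=1e-6,
    )


def test_recovers_generating_coefficient():
    truth = 0.86
    cfg = recovery_config(
        "smoking", "none", seed=3, n_participants=200_000,
        contrast="opmd_positive", prevalence=0.075,
        transition="none->low", effect=truth,
    )
    data = nm.generate_population(cfg)
    with pytest.warns(SeparationWarning):  # only the none row is populated
        fit = nm.fit_ml(data, "smoking", ["opmd_positive"])
    row = fit.ci.loc["none->low:opmd_positive"]
    assert abs(row["estimate"] - np.log(truth)) < 3 * row["se"]


def test_duplication_halves_variance(cohort_20k):
    sub = nm.PanelDataset(
        cohort_20k.frame[
            cohort_20k.frame["id"].isin(cohort_20k.frame["id"].unique()[:8000])
        ]
    )
    doubled_frame = pd.concat(
        [sub.frame, sub.frame.assign(id="dup_" + sub.frame["id"])],
        ignore_index=True,
    )
    doubled = nm.PanelDataset(doubled_frame)
    f1 = nm.fit_ml(sub, "smoking", ["male"])
    f2 = nm.fit_ml(doubled, "smoking", ["male"])
    np.testing.assert_allclose(
        f2.model_hat.to_flat(), f1.model_hat.to_flat(), atol=1e-7
    )
    np.testing.assert_allclose(f2.se, f1.se / np.sqrt(2), rtol=1e-5)


def test_wald_interval_brackets_estimate(cohort_20k):
    fit = nm.fit_ml(cohort_20k, "betel", ["male", "urban"])
    assert (fit.ci["ci_low"] <= fit.ci["estimate"]).all()
    assert (fit.ci["estimate"] <= fit.ci["ci_high"]).all()


def test_rank_deficient_design_is_rejected(cohort_20k):
    pairs = transition_pairs(cohort_20k, "smoking")
    pairs["living_area"] = "urban"  # constant column -> no contrast variation
    est = MLTransitionEstimator(contrasts=["urban"])
    with pytest.raises(ValueError, match="rank-deficient"):
        est.fit(pairs, pairs["to_state"])


def test_estimators_support_sklearn_protocol(cohort_20k):
    est = MLTransitionEstimator(contrasts=["male"], behavior="betel")
    assert clone(est).get_params()["behavior"] == "betel"
    pairs = transition_pairs(cohort_20k, "betel").head(2000)
    est.fit(pairs, pairs["to_state"])
    proba = est.predict_proba(pairs.head(5))
    assert proba.shape == (5, 3)
    np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
    assert set(est.predict(pairs.head(5))) <= {"none", "low", "high"}


def test_recovery_coverage_over_replicates():
    """Across 20 replicate cohorts (n=100,000) the ML and MCMC estimates
    land within 3 reported SEs / posterior SDs of the generating
    coefficient in at least 19 cases each."""
    truth = math.log(2.0)
    ml_hits = mcmc_hits = 0
    for rep in range(20):
        cfg = recovery_config(
            "smoking", "low", seed=1000 + rep, n_participants=100_000,
            contrast="urban", prevalence=0.5,
            transition="low->high", effect=2.0,
        )
        data = nm.generate_population(cfg)
        with np.errstate(all="ignore"), _suppress_separation():
            fit = nm.fit_ml(data, "smoking", ["urban"])
            post = nm.fit_mcmc(
                data, "smoking", ["urban"], chains=2,
                iterations=1500, burn_in=500, seed=2000 + rep,
            )
        row = fit.ci.loc["low->high:urban"]
        ml_hits += abs(row["estimate"] - truth) < 3 * row["se"]
        prow = post.summary.loc["low->high:urban"]
        mcmc_hits += abs(prow["mean"] - truth) < 3 * prow["sd"]
    assert ml_hits >= 19
    assert mcmc_hits >= 19


@contextlib.contextmanager
def _suppress_separation():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SeparationWarning)
        yield


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------


def test_mcmc_requires_seed(cohort_20k):
    pairs = transition_pairs(cohort_20k, "smoking").head(100)
    with pytest.raises(ValueError, match="seed"):
        MCMCTransitionEstimator().fit(pairs, pairs["to_state"])


def test_mcmc_identical_seeds_identical_draws():
    data = nm.generate_population(nm.default_config(n_participants=2000, seed=6))
    kwargs = dict(chains=2, iterations=400, burn_in=200, seed=123)
    a = nm.fit_mcmc(data, "smoking", ["male"], **kwargs)
    b = nm.fit_mcmc(data, "smoking", ["male"], **kwargs)
    np.testing.assert_array_equal(a.draws, b.draws)
    c = nm.fit_mcmc(data, "smoking", ["male"], chains=2, iterations=400,
                    burn_in=200, seed=124)
    assert not np.array_equal(a.draws, c.draws)


def test_posterior_matches_ml_at_large_n(mcmc_50k, ml_50k):
    """Bernstein–von Mises: posterior means within 3 posterior SDs of the
    ML point estimates on the standard fixture."""
    z = (
        mcmc_50k.summary["mean"].to_numpy() - ml_50k.model_hat.to_flat()
    ) / mcmc_50k.summary["sd"].to_numpy()
    assert np.max(np.abs(z)) < 3


def test_mcmc_chains_mix(mcmc_50k):
    assert float(np.max(mcmc_50k.diagnostics["rhat"])) <= 1.05
    acc = np.asarray(mcmc_50k.diagnostics["acceptance"])
    assert (acc > 0.1).all() and (acc < 0.7).all()


def test_prior_only_run_recovers_prior():
    empty = pd.DataFrame(
        {"from_state": pd.Series([], dtype=int), "to_state": pd.Series([], dtype=int)}
    )
    est = MCMCTransitionEstimator(seed=3, chains=4, iterations=3000, burn_in=1000)
    est.fit(empty, empty["to_state"])
    assert np.max(np.abs(est.summary_["mean"])) < 2.5
    assert est.summary_["sd"].between(8, 12).all()


def test_posterior_round_trip(tmp_path):
    data = nm.generate_population(nm.default_config(n_participants=1000, seed=4))
    post = nm.fit_mcmc(data, "betel", ["male"], chains=2, iterations=300,
                       burn_in=100, seed=9)
    path = tmp_path / "fit.json"
    post.save(path)
    back = nm.load_fit(path)
    assert isinstance(back, nm.PosteriorResult)
    np.testing.assert_allclose(back.flat_draws, post.flat_draws)
    np.testing.assert_allclose(
        back.model_hat.to_flat(), post.model_hat.to_flat()
    )


def test_ml_fit_round_trip(tmp_path, cohort_20k):
    fit = nm.fit_ml(cohort_20k, "smoking", ["male"])
    path = tmp_path / "fit.json"
    fit.save(path)
    back = nm.load_fit(path)
    assert isinstance(back, nm.FitResult)
    np.testing.assert_allclose(back.model_hat.to_flat(), fit.model_hat.to_flat())
    np.testing.assert_allclose(back.se, fit.se)
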