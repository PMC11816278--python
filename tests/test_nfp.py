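import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import nfpmarkov as nm
from nfpmarkov.covariates import CovariateSpec
from nfpmarkov.errors import UndefinedRatioError
from nfpmarkov.inference import FitResult, PosteriorResult, _param_table_ml
from nfpmarkov.model import alphas_from_matrix
from nfpmarkov.nfp import PATTERNS


def _fit_from_model(model, sd=0.0):
    """Wrap a known model as an ML fit with isotropic parameter noise."""
    width = 2 * (1 + len(model.spec))
    se = np.full(model.n_params, sd)
    return FitResult(
        model_hat=model,
        se=se,
        ci=_param_table_ml(model, se),
        loglik_at_max=0.0,
        convergence={"converged": True},
        cov_rows=[sd**2 * np.eye(width) for _ in range(3)],
    )


def _progressive_model(names=("urban",), beta=None, behavior="smoking"):
    """A model whose net forces are positive at every binary profile."""
    matrix = np.array([
        [0.70, 0.20, 0.10],
        [0.05, 0.75, 0.20],
        [0.05, 0.10, 0.85],
    ])
    spec = CovariateSpec.from_names(names)
    b = np.zeros((6, len(spec))) if beta is None else beta
    return nm.TransitionModel(
        behavior=behavior, spec=spec, alpha=alphas_from_matrix(matrix), beta=b
    )


def test_nfp_zero_on_identity_and_uniform():
    for m in (np.eye(3), np.full((3, 3), 1 / 3)):
        assert nm.nfp_from_none(m) == 0.0
        assert nm.nfp_low_high(m) == 0.0


def test_nfp_direct_arithmetic():
    p = np.array([
        [0.7, 0.2, 0.1],
        [0.05, 0.90, 0.05],
        [0.05, 0.05, 0.90],
    ])
    assert nm.nfp_from_none(p) == pytest.approx(0.2)
    p2 = np.array([
        [0.9, 0.05, 0.05],
        [0.0, 0.858, 0.142],
        [0.0, 0.142, 0.858],
    ])
    assert nm.nfp_low_high(p2) == pytest.approx(0.0)


@given(st.integers(0, 2**31 - 1))
def test_nfp_antisymmetric_under_progression_regression_swap(seed):
    rng = np.random.default_rng(seed)
    p = rng.dirichlet(np.ones(3), size=3)
    swapped = p.copy()
    swapped[0, 1], swapped[1, 0] = p[1, 0], p[0, 1]
    swapped[0, 2], swapped[2, 0] = p[2, 0], p[0, 2]
    swapped[1, 2], swapped[2, 1] = p[2, 1], p[1, 2]
    assert nm.nfp_from_none(swapped) == pytest.approx(-nm.nfp_from_none(p))
    assert nm.nfp_low_high(swapped) == pytest.approx(-nm.nfp_low_high(p))


def test_null_covariates_give_unit_rr():
    fit = _fit_from_model(_progressive_model(), sd=0.0)
    for pattern in PATTERNS:
        est = nm.rr_nfp(fit, "urban", pattern, n_draws=50)
        assert est.rr == pytest.approx(1.0, abs=1e-12)


def test_rr_matches_plugin_arithmetic():
    beta = np.zeros((6, 1))
    beta[0, 0] = math.log(1.5)   # none->low
    beta[3, 0] = math.log(0.7)   # low->high
    model = _progressive_model(beta=beta)
    fit = _fit_from_model(model, sd=0.0)
    for pattern, func in (("from_none", nm.nfp_from_none),
                          ("low_high", nm.nfp_low_high)):
        expected = func(model.transition_matrix({"living_area": "urban"}).p) / func(
            model.transition_matrix(None).p
        )
        est = nm.rr_nfp(fit, "urban", pattern, n_draws=50)
        assert est.rr == pytest.approx(expected, abs=1e-12)


def test_rr_interval_contains_point_estimate():
    beta = np.zeros((6, 1))
    beta[1, 0] = math.log(1.3)
    fit = _fit_from_model(_progressive_model(beta=beta), sd=0.05)
    est = nm.rr_nfp(fit, "urban", "from_none", n_draws=500, seed=1)
    assert est.lo <= est.rr <= est.hi


def test_rr_undefined_when_net_force_negative():
    model = _progressive_model()
    matrix = np.array([
        [0.90, 0.07, 0.03],
        [0.40, 0.55, 0.05],
        [0.40, 0.30, 0.30],
    ])
    regressive = nm.TransitionModel(
        behavior="smoking", spec=model.spec,
        alpha=alphas_from_matrix(matrix), beta=np.zeros((6, 1)),
    )
    fit = _fit_from_model(regressive, sd=0.0)
    with pytest.raises(UndefinedRatioError, match="reference"):
        nm.rr_nfp(fit, "urban", "from_none", n_draws=10)


def test_rr_equivariant_under_reference_relabel():
    """Swapping the covariate's reference level inverts the RR and swaps the
    interval endpoints."""
    beta = np.zeros((6, 1))
    beta[3, 0] = math.log(1.4)
    model = _progressive_model(beta=beta)
    nparam = model.n_params
    rng = np.random.default_rng(2)
    draws = model.to_flat() + 0.03 * rng.standard_normal((2, 400, nparam))
    # relabelled parameterization: alpha' = alpha + beta, beta' = -beta
    width = 1 + len(model.spec)
    relab = draws.copy()
    relab[..., ::width] = draws[..., ::width] + draws[..., 1::width]
    relab[..., 1::width] = -draws[..., 1::width]

    def posterior(d, m):
        flat = d.reshape(-1, nparam)
        return PosteriorResult(
            model_hat=nm.TransitionModel.from_flat(
                flat.mean(axis=0), m.behavior, m.spec
            ),
            draws=d, chains=2, burn_in=0, seed=0,
            summary=pd.DataFrame({"mean": flat.mean(axis=0)}),
        )

    a = nm.rr_nfp(posterior(draws, model), "urban", "low_high")
    b = nm.rr_nfp(posterior(relab, model), "urban", "low_high")
    assert b.rr == pytest.approx(1 / a.rr, rel=1e-9)
    assert b.lo == pytest.approx(1 / a.hi, rel=0.02)
    assert b.hi == pytest.approx(1 / a.lo, rel=0.02)


def test_stage_arr_identities():
    fit = _fit_from_model(_progressive_model(), sd=0.0)
    est = nm.stage_specific_arr(fit, "low->high", "urban")
    assert est.rr == pytest.approx(1.0)
    assert est.lo == pytest.approx(1.0) and est.hi == pytest.approx(1.0)

    beta = np.zeros((6, 1))
    beta[3, 0] = math.log(2)
    fit2 = _fit_from_model(_progressive_model(beta=beta), sd=0.0)
    est2 = nm.stage_specific_arr(fit2, "low->high", "urban")
    assert est2.rr == pytest.approx(2.0)
    assert (est2.lo, est2.hi) == (pytest.approx(2.0), pytest.approx(2.0))


def test_stage_arr_rejects_unknown_parameter():
    fit = _fit_from_model(_progressive_model(), sd=0.0)
    with pytest.raises(KeyError):
        nm.stage_specific_arr(fit, "low->high", "male")
    with pytest.raises(KeyError):
        nm.stage_specific_arr(fit, "low->low", "urban")


def test_rr_reduces_to_stage_arr_in_degenerate_pattern():
    """With zero regression force, the covariate acting only on the single
    progression transition, and that transition rare (so the row
    normalization is essentially unchanged), the NFP ratio equals
    exp(beta)."""
    eps, q = 1e-9, 2e-4
    matrix = np.array([
        [1 - q - eps, q, eps],
        [eps, 1 - q - eps, q],
        [eps, eps, 1 - 2 * eps],
    ])
    beta = np.zeros((6, 1))
    beta[3, 0] = math.log(1.3)  # low->high only
    spec = CovariateSpec.from_names(["urban"])
    model = nm.TransitionModel(
        behavior="smoking", spec=spec,
        alpha=alphas_from_matrix(matrix), beta=beta,
    )
    fit = _fit_from_model(model, sd=0.0)
    rr = nm.rr_nfp(fit, "urban", "low_high", n_draws=10)
    arr = nm.stage_specific_arr(fit, "low->high", "urban")
    assert rr.rr == pytest.approx(arr.rr, rel=1e-3)


def test_report_bundle_structure_and_determinism(tmp_path, cohort_20k):
    fits = {
        b: nm.fit_ml(cohort_20k, b, ["male", "opmd_positive"])
        for b in ("smoking", "betel")
    }
    w1 = nm.make_report(fits, cohort_20k, tmp_path / "r1", n_draws=100, seed=0)
    w2 = nm.make_report(fits, cohort_20k, tmp_path / "r2", n_draws=100, seed=0)
    assert {f"transitions_{b}" for b in ("smoking", "betel")} <= set(w1)
    for b in ("smoking", "betel"):
        mat = pd.read_csv(w1[f"transitions_{b}"], sep="\t", index_col=0)
        assert ((mat.to_numpy() >= 0) & (mat.to_numpy() <= 100)).all()
        np.testing.assert_allclose(mat.sum(axis=1), 100.0, atol=0.001)
        rr = pd.read_csv(w1[f"nfp_rr_{b}"], sep="\t")
        assert set(rr["pattern"]) == set(PATTERNS)
        assert len(rr) == 2 * 2  # two contrasts x two patterns
    for key, path in w1.items():
        assert path.read_bytes() == w2[key].read_bytes()
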