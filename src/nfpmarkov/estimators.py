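"""Scikit-learn-style estimators for the transition model.

Both estimators consume one observation per consecutive screen pair:
``X`` is a DataFrame carrying a ``from_state`` column (state labels or
integer codes) plus the covariate columns the contrasts refer to, and ``y``
is the destination state. ``predict_proba`` returns the one-step
distribution over destination states, so the fitted object composes with
scikit-learn tooling; ``transition_matrix`` evaluates the full 3×3 matrix
at a covariate profile.

The likelihood factorizes over origin rows, each row being an independent
conditional multinomial logit with "stay" as the reference category, so
fitting proceeds row by row on aggregated sufficient statistics.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .covariates import Contrast, CovariateSpec
from .errors import SamplerError, SchemaError, SeparationWarning
from .model import (
    TransitionModel,
    aggregate_pairs,
    row_hessian,
    row_loglik,
    row_loglik_grad,
)
from .states import STATE_INDEX, STATES

def _row_slices(p: int):
    """Flat-vector slices of the three per-origin-row parameter blocks."""
    width = 2 * (1 + p)
    return [slice(r * width, (r + 1) * width) for r in range(3)]


def _resolve_spec(contrasts) -> CovariateSpec:
    if contrasts is None:
        return CovariateSpec(())
    if isinstance(contrasts, CovariateSpec):
        return contrasts
    if all(isinstance(c, Contrast) for c in contrasts):
        return CovariateSpec(tuple(contrasts))
    return CovariateSpec.from_names(contrasts)


def _state_codes(values) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype.kind in "iu":
        codes = arr.astype(np.int64)
        if ((codes < 0) | (codes > 2)).any():
            raise ValueError("state codes must be in {0, 1, 2}")
        return codes
    try:
        return np.array([STATE_INDEX[v] for v in arr], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"unknown state label {exc.args[0]!r}") from None


class _BaseTransitionEstimator(BaseEstimator):
    """Shared input handling for the ML and MCMC transition estimators."""

    def __init__(self, contrasts=None, behavior: str = "smoking"):
        self.contrasts = contrasts
        self.behavior = behavior

    def _extract(self, X: pd.DataFrame, y):
        spec = _resolve_spec(self.contrasts)
        if not isinstance(X, pd.DataFrame):
            raise SchemaError("X must be a DataFrame with a 'from_state' column")
        if "from_state" not in X.columns:
            raise SchemaError("X must contain a 'from_state' column")
        frm = _state_codes(X["from_state"])
        to = _state_codes(y)
        if len(frm) != len(to):
            raise ValueError("X and y have different lengths")
        design = spec.design_matrix(X)
        if len(design) and len(spec):
            aug = np.hstack([np.ones((len(design), 1)), design])
            rank = np.linalg.matrix_rank(aug)
            if rank < 1 + len(spec):
                raise ValueError(
                    "design matrix is rank-deficient for contrasts "
                    f"{spec.names}"
                )
        return spec, design, frm, to

    # -- prediction interface -------------------------------------------------

    @property
    def classes_(self):
        return np.array(STATES)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Per-pair next-state distribution (n, 3) given ``from_state`` and
        covariates."""
        model: TransitionModel = self.model_
        frm = _state_codes(X["from_state"])
        design = model.spec.design_matrix(X)
        mats = model.matrix_from_design(design.astype(float))
        return mats[np.arange(len(frm)), frm, :]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def transition_matrix(self, profile: Mapping[str, str] | None = None):
        return self.model_.transition_matrix(profile)


class MLTransitionEstimator(_BaseTransitionEstimator):
    """Maximum-likelihood fit of the exponential-regression transition model.

    Each origin row is maximized by L-BFGS-B (analytic gradient, parameters
    box-bounded at ±``bound`` to keep separation finite) followed by Newton
    polishing with the analytic Hessian when the optimum is interior.
    Standard errors come from the observed-information inverse; 95% Wald
    intervals are formed on the log-weight scale.

    Fitted attributes: ``model_`` (:class:`TransitionModel`), ``alpha_``,
    ``beta_``, ``se_alpha_``, ``se_beta_``, ``cov_rows_`` (per-row
    covariance blocks), ``loglik_``, ``converged_``, ``n_pairs_``.
    """

    def __init__(self, contrasts=None, behavior: str = "smoking",
                 bound: float = 15.0):
        super().__init__(contrasts=contrasts, behavior=behavior)
        self.bound = bound

    def fit(self, X: pd.DataFrame, y=None):
        if y is None:
            y = X["to_state"]
        spec, design, frm, to = self._extract(X, y)
        patterns, counts = aggregate_pairs(design, frm, to)
        p = len(spec)
        width = 1 + p
        theta = np.zeros(6 * width)
        cov_rows, converged = [], []
        separated = []
        for row, sl in enumerate(_row_slices(p)):
            counts_row = counts[:, row, :]
            theta_r, cov_r, ok, sep = self._fit_row(patterns, counts_row, row, p)
            theta[sl] = theta_r
            cov_rows.append(cov_r)
            converged.append(ok)
            separated.extend(sep)
        if separated:
            warnings.warn(
                "possible separation (estimate at bound) for parameter(s): "
                f"{separated}; estimates are bounded at ±{self.bound}",
                SeparationWarning,
                stacklevel=2,
            )
        self.model_ = TransitionModel.from_flat(theta, self.behavior, spec)
        self.theta_ = theta
        self.alpha_ = self.model_.alpha
        self.beta_ = self.model_.beta
        self.cov_rows_ = cov_rows
        se = np.concatenate([np.sqrt(np.maximum(np.diag(c), 0.0)) for c in cov_rows])
        self.se_ = se
        self.se_alpha_ = se[::width].copy()
        self.se_beta_ = np.stack(
            [se[t * width + 1:(t + 1) * width] for t in range(6)]
        ).reshape(6, p)
        from .model import loglik_from_stats

        self.loglik_ = loglik_from_stats(theta, patterns, counts)
        self.converged_ = all(converged)
        self.convergence_ = {
            "per_row": converged,
            "separated_params": separated,
        }
        self.n_pairs_ = int(counts.sum())
        self._patterns_, self._counts_ = patterns, counts
        return self

    def _fit_row(self, patterns, counts_row, row, p):
        width = 1 + p
        dim = 2 * width
        ntot = counts_row.sum()
        if ntot == 0:
            warnings.warn(
                f"origin state {STATES[row]!r} never observed; its "
                "parameters stay at 0 with undefined standard errors",
                SeparationWarning,
                stacklevel=3,
            )
            return np.zeros(dim), np.full((dim, dim), np.nan), True, []
        # init at the smoothed intercept-only estimate
        dests = [s for s in range(3) if s != row]
        tot = counts_row.sum(axis=0)
        theta0 = np.zeros(dim)
        for j, s in enumerate(dests):
            theta0[j * width] = np.log((tot[s] + 0.5) / (tot[row] + 0.5))

        def negll(th):
            ll, g = row_loglik_grad(th, patterns, counts_row, row)
            return -ll, -g

        res = minimize(
            negll, theta0, jac=True, method="L-BFGS-B",
            bounds=[(-self.bound, self.bound)] * dim,
            options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
        )
        theta_r = res.x
        at_bound = np.abs(np.abs(theta_r) - self.bound) < 1e-6
        ok = bool(res.success)
        # Newton polish for tight agreement with the saturated MLE
        if not at_bound.any():
            for _ in range(50):
                ll, g = row_loglik_grad(theta_r, patterns, counts_row, row)
                if np.max(np.abs(g)) < 1e-10:
                    break
                H = row_hessian(theta_r, patterns, counts_row, row)
                try:
                    step = np.linalg.solve(H, g)
                except np.linalg.LinAlgError:
                    break
                cand = theta_r - step
                scale = 1.0
                while (
                    row_loglik(cand, patterns, counts_row, row) < ll
                    and scale > 1e-8
                ):
                    scale /= 2
                    cand = theta_r - scale * step
                theta_r = cand
            ok = True
        H = row_hessian(theta_r, patterns, counts_row, row)
        try:
            cov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(-H)
        names = []
        if at_bound.any():
            pnames = self._row_param_names(row, p)
            names = [pnames[i] for i in np.flatnonzero(at_bound)]
        return theta_r, cov, ok, names

    @staticmethod
    def _row_param_names(row, p):
        spec_names = [f"x{k}" for k in range(p)]
        names = []
        for s in (s for s in range(3) if s != row):
            base = f"{STATES[row]}->{STATES[s]}"
            names.append(f"{base}:intercept")
            names.extend(f"{base}:{n}" for n in spec_names)
        return names


class MCMCTransitionEstimator(_BaseTransitionEstimator):
    """Bayesian fit by adaptive random-walk Metropolis.

    Independent normal(0, ``prior_sd``²) priors on every log-weight
    parameter. Proposals update one origin-row block at a time with a
    Gaussian step preconditioned by the per-parameter curvature scales of
    the observed information at the initial estimates (prior scale where
    the data carry no curvature); a global per-block step factor adapts
    toward a 0.30–0.40 acceptance rate during burn-in only, so the kept
    draws target the exact posterior. Chains initialize at the smoothed
    empirical intercept-only estimates plus seeded overdispersion jitter.

    Fitted attributes: ``draws_`` (chains, kept, n_params), ``summary_``
    (posterior mean/sd/2.5/50/97.5% per parameter), ``rhat_``,
    ``acceptance_`` (per chain × row block), ``model_`` (posterior means),
    ``step_trace_``.
    """

    def __init__(self, contrasts=None, behavior: str = "smoking",
                 chains: int = 4, iterations: int = 5000, burn_in: int = 2000,
                 seed: int | None = None, prior_sd: float = 10.0,
                 init_jitter: float = 0.1):
        super().__init__(contrasts=contrasts, behavior=behavior)
        self.chains = chains
        self.iterations = iterations
        self.burn_in = burn_in
        self.seed = seed
        self.prior_sd = prior_sd
        self.init_jitter = init_jitter

    def fit(self, X: pd.DataFrame, y=None):
        if self.seed is None:
            raise ValueError("seed is mandatory for MCMC fits")
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for diagnostics")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("need 0 <= burn_in < iterations")
        if y is None:
            y = X["to_state"]
        spec, design, frm, to = self._extract(X, y)
        patterns, counts = aggregate_pairs(design, frm, to)
        p = len(spec)
        width = 1 + p
        nparam = 6 * width
        slices = _row_slices(p)
        kept = self.iterations - self.burn_in

        theta_init = np.zeros(nparam)
        for row, sl in enumerate(slices):
            tot = counts[:, row, :].sum(axis=0)
            dests = [s for s in range(3) if s != row]
            for j, s in enumerate(dests):
                theta_init[sl][j * width] = np.log(
                    (tot[s] + 0.5) / (tot[row] + 0.5)
                )

        scales = self._proposal_scales(theta_init, patterns, counts, slices)

        seeds = np.random.SeedSequence(self.seed).spawn(self.chains)
        draws = np.empty((self.chains, kept, nparam))
        acceptance = np.zeros((self.chains, 3))
        step_trace = []
        for c in range(self.chains):
            rng = np.random.default_rng(seeds[c])
            d, acc, steps = self._run_chain(
                rng, theta_init, patterns, counts, slices, kept, scales
            )
            draws[c] = d
            acceptance[c] = acc
            step_trace.append(steps)
        if (acceptance == 0).any():
            raise SamplerError(
                "a chain rejected every post-burn-in proposal in at least "
                f"one block; step-size trace: {step_trace}"
            )

        self.draws_ = draws
        self.acceptance_ = acceptance
        self.step_trace_ = step_trace
        flat = draws.reshape(-1, nparam)
        mean = flat.mean(axis=0)
        self.model_ = TransitionModel.from_flat(mean, self.behavior, spec)
        names = self.model_.param_names()
        self.summary_ = pd.DataFrame(
            {
                "mean": mean,
                "sd": flat.std(axis=0, ddof=1),
                "q2.5": np.quantile(flat, 0.025, axis=0),
                "median": np.quantile(flat, 0.5, axis=0),
                "q97.5": np.quantile(flat, 0.975, axis=0),
            },
            index=names,
        )
        self.rhat_ = pd.Series(_split_rhat(draws), index=names)
        self.n_pairs_ = int(counts.sum())
        return self

    def _proposal_scales(self, theta_init, patterns, counts, slices):
        """Per-block Cholesky factors of the curvature-based proposal
        covariance: inverse observed information (plus prior curvature) at
        the initial estimates, falling back to the prior scale where the
        data are flat."""
        factors = []
        for r, sl in enumerate(slices):
            dim = sl.stop - sl.start
            H = row_hessian(theta_init[sl], patterns, counts[:, r, :], r)
            # posterior curvature includes the prior
            H = H - np.eye(dim) / self.prior_sd ** 2
            try:
                cov = np.linalg.inv(-H)
                L = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                L = self.prior_sd * np.eye(dim)
            factors.append(L)
        return factors

    def _run_chain(self, rng, theta_init, patterns, counts, slices, kept, scales):
        nparam = len(theta_init)
        theta = theta_init.copy()
        for sl, L in zip(slices, scales):
            theta[sl] += self.init_jitter * (
                L @ rng.standard_normal(sl.stop - sl.start)
            )
        row_ll = [
            row_loglik(theta[sl], patterns, counts[:, r, :], r)
            for r, sl in enumerate(slices)
        ]
        var = self.prior_sd ** 2
        row_lp = [float(-0.5 * np.sum(theta[sl] ** 2) / var)
                  for sl in slices]
        dims = [sl.stop - sl.start for sl in slices]
        steps = [2.38 / np.sqrt(d) for d in dims]
        window_acc = np.zeros(3)
        post_acc = np.zeros(3)
        out = np.empty((kept, nparam))
        for it in range(self.iterations):
            for r, sl in enumerate(slices):
                prop = theta[sl] + steps[r] * (
                    scales[r] @ rng.standard_normal(dims[r])
                )
                ll = row_loglik(prop, patterns, counts[:, r, :], r)
                lp = float(-0.5 * np.sum(prop ** 2) / var)
                log_ratio = (ll + lp) - (row_ll[r] + row_lp[r])
                if np.log(rng.random()) < log_ratio:
                    theta = theta.copy()
                    theta[sl] = prop
                    row_ll[r], row_lp[r] = ll, lp
                    window_acc[r] += 1
                    if it >= self.burn_in:
                        post_acc[r] += 1
            if it < self.burn_in and (it + 1) % 50 == 0:
                for r in range(3):
                    rate = window_acc[r] / 50.0
                    if rate < 0.25:
                        steps[r] *= 0.7
                    elif rate > 0.45:
                        steps[r] *= 1.4
                window_acc[:] = 0.0
            if it >= self.burn_in:
                out[it - self.burn_in] = theta
        return out, post_acc / kept, steps


def _split_rhat(draws: np.ndarray) -> np.ndarray:
    """Split-R̂ per parameter via arviz (rank-normalized split-R̂)."""
    import arviz as az

    half = draws.shape[1] // 2
    split = np.concatenate([draws[:, :half, :], draws[:, half: 2 * half, :]], axis=0)
    ds = az.convert_to_dataset({"theta": split})
    return np.asarray(az.rhat(ds)["theta"].values, dtype=float)
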