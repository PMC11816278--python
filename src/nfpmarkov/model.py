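"""Three-state transition model with exponential-regression behavior weights.

For origin state r, the weight of staying put is fixed at 1 and the weight
of moving to s ≠ r is

    w_rs(x) = exp(alpha_rs + sum_k beta_rs,k x_k),

so the one-step probabilities are the row-normalized weights — a
multinomial logit per origin row with the diagonal ("no change") as the
reference category. exp(beta_rs,k) is then the relative weight ratio of the
r→s transition between covariate strata, which is how per-transition
adjusted relative risks are reported.

The likelihood of a screening panel conditions on each participant's
first-screen state and multiplies the one-step probabilities of all
consecutive screen pairs (time-homogeneous, round-indexed chain).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.special import logsumexp

from .covariates import CovariateSpec
from .states import BEHAVIORS, STATES, TRANSITIONS

__all__ = [
    "TransitionModel",
    "StochasticMatrix",
    "transition_matrix",
    "log_likelihood",
    "empirical_transition_probs",
    "alphas_from_matrix",
]

_ROW_DESTS = {r: tuple(s for s in range(3) if s != r) for r in range(3)}


@dataclass(frozen=True)
class StochasticMatrix:
    """A 3×3 row-stochastic one-step transition matrix.

    Rows whose origin state was never observed may be all-NaN ("undefined");
    every defined row must lie in [0, 1] and sum to 1 within 1e-12.
    """

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (3, 3):
            raise ValueError(f"expected a 3x3 matrix, got shape {p.shape}")
        defined = ~np.isnan(p).any(axis=1)
        if ((p[defined] < -1e-12) | (p[defined] > 1 + 1e-12)).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        sums = p[defined].sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"rows must sum to 1, got {sums}")
        object.__setattr__(self, "p", p)

    @property
    def undefined_rows(self) -> list[str]:
        return [STATES[r] for r in range(3) if np.isnan(self.p[r]).any()]

    def __getitem__(self, key) -> float:
        r, s = key
        if isinstance(r, str):
            r = STATES.index(r)
        if isinstance(s, str):
            s = STATES.index(s)
        return float(self.p[r, s])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.p, index=list(STATES), columns=list(STATES))


def alphas_from_matrix(p: np.ndarray | StochasticMatrix) -> np.ndarray:
    """Baseline log-weights reproducing a strictly positive matrix exactly:
    alpha_rs = ln(P(r→s) / P(r→r))."""
    if isinstance(p, StochasticMatrix):
        p = p.p
    p = np.asarray(p, dtype=float)
    if (p <= 0).any():
        raise ValueError("all entries must be positive to invert to log-weights")
    return np.array([np.log(p[r, s] / p[r, r]) for r, s in TRANSITIONS])


@dataclass
class TransitionModel:
    """Parameters of the exponential-regression transition model.

    ``alpha`` holds the six baseline log-weights in the canonical transition
    order (N→L, N→H, L→N, L→H, H→N, H→L); ``beta`` is (6, p) with one column
    per contrast of ``spec``.
    """

    behavior: str
    spec: CovariateSpec
    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        if self.behavior not in BEHAVIORS:
            raise ValueError(f"behavior must be one of {BEHAVIORS}")
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float).reshape(6, len(self.spec))
        if self.alpha.shape != (6,):
            raise ValueError("alpha must have exactly 6 entries")
        if not (np.isfinite(self.alpha).all() and np.isfinite(self.beta).all()):
            raise ValueError("parameters must be finite")

    # -- flat parameter vector ------------------------------------------------
    # Layout: transitions in canonical order; per transition the intercept
    # followed by the p contrast coefficients. Transitions sharing an origin
    # row are adjacent, so per-row parameter blocks are contiguous slices.

    @property
    def n_params(self) -> int:
        return 6 * (1 + len(self.spec))

    def to_flat(self) -> np.ndarray:
        width = 1 + len(self.spec)
        theta = np.empty(self.n_params)
        for t in range(6):
            theta[t * width] = self.alpha[t]
            theta[t * width + 1 : (t + 1) * width] = self.beta[t]
        return theta

    @classmethod
    def from_flat(
        cls, theta: np.ndarray, behavior: str, spec: CovariateSpec
    ) -> "TransitionModel":
        width = 1 + len(spec)
        theta = np.asarray(theta, dtype=float).reshape(6 * width)
        alpha = theta[::width].copy()
        beta = np.stack(
            [theta[t * width + 1 : (t + 1) * width] for t in range(6)]
        ).reshape(6, len(spec))
        return cls(behavior=behavior, spec=spec, alpha=alpha, beta=beta)

    def param_names(self) -> list[str]:
        names = []
        for (r, s) in TRANSITIONS:
            label = f"{STATES[r]}->{STATES[s]}"
            names.append(f"{label}:intercept")
            names.extend(f"{label}:{c}" for c in self.spec.names)
        return names

    # -- evaluation -----------------------------------------------------------

    def matrix_from_design(self, x: np.ndarray) -> np.ndarray:
        """Transition matrices (..., 3, 3) for design rows x of shape (..., p)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        eta = np.zeros(x.shape[:-1] + (3, 3))
        for t, (r, s) in enumerate(TRANSITIONS):
            eta[..., r, s] = self.alpha[t] + x @ self.beta[t]
        w = np.exp(eta - logsumexp(eta, axis=-1, keepdims=True))
        return w

    def transition_matrix(
        self, profile: Mapping[str, str] | None = None
    ) -> StochasticMatrix:
        """One-step matrix at a covariate profile (reference by default)."""
        x = self.spec.profile_vector(profile)
        return StochasticMatrix(self.matrix_from_design(x)[0])

    # -- serialization --------------------------------------------------------

    def to_json(self) -> dict:
        return {
            "behavior": self.behavior,
            "covariate_spec": self.spec.to_json(),
            "alpha": {f"{STATES[r]}->{STATES[s]}": self.alpha[t]
                      for t, (r, s) in enumerate(TRANSITIONS)},
            "beta": {
                f"{STATES[r]}->{STATES[s]}": dict(zip(self.spec.names, self.beta[t]))
                for t, (r, s) in enumerate(TRANSITIONS)
            },
        }

    @classmethod
    def from_json(cls, doc: Mapping) -> "TransitionModel":
        spec = CovariateSpec.from_json(doc["covariate_spec"])
        alpha = np.zeros(6)
        beta = np.zeros((6, len(spec)))
        for t, (r, s) in enumerate(TRANSITIONS):
            key = f"{STATES[r]}->{STATES[s]}"
            alpha[t] = doc["alpha"][key]
            for k, name in enumerate(spec.names):
                beta[t, k] = doc["beta"][key][name]
        return cls(behavior=doc["behavior"], spec=spec, alpha=alpha, beta=beta)

    def dumps(self) -> str:
        return json.dumps(self.to_json(), indent=1, sort_keys=True)

    @classmethod
    def loads(cls, s: str) -> "TransitionModel":
        return cls.from_json(json.loads(s))


def transition_matrix(
    model: TransitionModel, profile: Mapping[str, str] | None = None
) -> StochasticMatrix:
    """Module-level convenience: ``model.transition_matrix(profile)``."""
    return model.transition_matrix(profile)


# -- sufficient statistics and likelihood -------------------------------------


def aggregate_pairs(X: np.ndarray, frm: np.ndarray, to: np.ndarray):
    """Collapse transition pairs to sufficient statistics.

    Returns ``(patterns, counts)`` where ``patterns`` is the (m, p) array of
    unique design rows and ``counts[u, r, s]`` the number of r→s pairs with
    pattern u. The likelihood depends on the data only through these.
    """
    X = np.asarray(X)
    if X.shape[1] == 0:
        patterns = np.zeros((1, 0))
        idx = np.zeros(len(frm), dtype=np.int64)
    else:
        patterns, idx = np.unique(X, axis=0, return_inverse=True)
        idx = idx.reshape(-1)
    counts = np.zeros((len(patterns), 3, 3))
    np.add.at(counts, (idx, np.asarray(frm), np.asarray(to)), 1.0)
    return patterns.astype(float), counts


def _row_eta(theta_r: np.ndarray, patterns: np.ndarray, row: int) -> np.ndarray:
    """Linear predictors (m, 3) for origin ``row``; the stay column is 0."""
    p = patterns.shape[1]
    width = 1 + p
    eta = np.zeros((len(patterns), 3))
    for j, s in enumerate(_ROW_DESTS[row]):
        block = theta_r[j * width : (j + 1) * width]
        eta[:, s] = block[0] + patterns @ block[1:]
    return eta


def row_loglik(theta_r, patterns, counts_row, row) -> float:
    """Multinomial log-likelihood contribution of one origin row."""
    eta = _row_eta(theta_r, patterns, row)
    logp = eta - logsumexp(eta, axis=1, keepdims=True)
    return float(np.sum(counts_row * logp))


def row_loglik_grad(theta_r, patterns, counts_row, row):
    """Log-likelihood and analytic gradient for one origin row."""
    p = patterns.shape[1]
    eta = _row_eta(theta_r, patterns, row)
    logp = eta - logsumexp(eta, axis=1, keepdims=True)
    ll = float(np.sum(counts_row * logp))
    prob = np.exp(logp)
    ntot = counts_row.sum(axis=1)
    grad = np.empty_like(theta_r)
    width = 1 + p
    for j, s in enumerate(_ROW_DESTS[row]):
        resid = counts_row[:, s] - ntot * prob[:, s]
        grad[j * width] = resid.sum()
        grad[j * width + 1 : (j + 1) * width] = patterns.T @ resid
    return ll, grad


def row_hessian(theta_r, patterns, counts_row, row) -> np.ndarray:
    """Analytic Hessian of the row log-likelihood (negative definite)."""
    p = patterns.shape[1]
    width = 1 + p
    eta = _row_eta(theta_r, patterns, row)
    prob = np.exp(eta - logsumexp(eta, axis=1, keepdims=True))
    ntot = counts_row.sum(axis=1)
    xt = np.hstack([np.ones((len(patterns), 1)), patterns])
    dests = _ROW_DESTS[row]
    H = np.zeros((2 * width, 2 * width))
    for j, s in enumerate(dests):
        for jp, sp in enumerate(dests):
            w = ntot * (prob[:, s] * (1.0 if s == sp else 0.0) - prob[:, s] * prob[:, sp])
            block = -(xt * w[:, None]).T @ xt
            H[j * width : (j + 1) * width, jp * width : (jp + 1) * width] = block
    return H


def loglik_from_stats(theta, patterns, counts) -> float:
    """Full log-likelihood at a flat parameter vector from sufficient stats."""
    width = 1 + patterns.shape[1]
    total = 0.0
    for row in range(3):
        theta_r = theta[2 * row * width : 2 * (row + 1) * width]
        total += row_loglik(theta_r, patterns, counts[:, row, :], row)
    return total


def log_likelihood(model: TransitionModel, data) -> float:
    """Panel log-likelihood of a fitted or hypothesized model.

    Sums ``ln P(state_{t+1} | state_t, x)`` over all consecutive screen
    pairs of every participant, skipping pairs with a missing endpoint.
    First-screen states are conditioned on, not modelled. Empty data gives
    0 by the empty-sum convention.
    """
    from .panel import transition_pairs

    pairs = transition_pairs(data, model.behavior)
    if len(pairs) == 0:
        return 0.0
    X = model.spec.design_matrix(pairs)
    patterns, counts = aggregate_pairs(
        X, pairs["from_state"].to_numpy(), pairs["to_state"].to_numpy()
    )
    return loglik_from_stats(model.to_flat(), patterns, counts)


def empirical_transition_probs(data, behavior: str) -> StochasticMatrix:
    """Saturated intercept-only MLE: row-normalized transition counts.

    Origin states never observed yield an all-NaN row, reported via
    :attr:`StochasticMatrix.undefined_rows` and a warning.
    """
    from .panel import transition_pairs

    pairs = transition_pairs(data, behavior)
    counts = np.zeros((3, 3))
    np.add.at(
        counts,
        (pairs["from_state"].to_numpy(), pairs["to_state"].to_numpy()),
        1.0,
    )
    totals = counts.sum(axis=1)
    p = np.full((3, 3), np.nan)
    for r in range(3):
        if totals[r] > 0:
            p[r] = counts[r] / totals[r]
    missing = [STATES[r] for r in range(3) if totals[r] == 0]
    if missing:
        warnings.warn(
            f"origin state(s) never observed for {behavior}: {missing}; "
            "corresponding rows are undefined",
            stacklevel=2,
        )
    return StochasticMatrix(p)
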