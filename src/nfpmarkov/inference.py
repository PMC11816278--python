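"""Panel-level fitting interface: maximum likelihood and MCMC.

Thin wrappers that extract transition pairs from a :class:`PanelDataset`
and delegate to the scikit-learn-style estimators in
:mod:`nfpmarkov.estimators`, packaging the results with parameter tables
and serialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .covariates import CovariateSpec
from .estimators import MCMCTransitionEstimator, MLTransitionEstimator
from .model import TransitionModel
from .panel import PanelDataset, transition_pairs

_Z95 = float(norm.ppf(0.975))


def _param_table_ml(model: TransitionModel, se: np.ndarray) -> pd.DataFrame:
    est = model.to_flat()
    lo = est - _Z95 * se
    hi = est + _Z95 * se
    return pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "ci_low": lo,
            "ci_high": hi,
            "rr": np.exp(est),
            "rr_low": np.exp(lo),
            "rr_high": np.exp(hi),
        },
        index=model.param_names(),
    )


@dataclass
class FitResult:
    """Maximum-likelihood fit: point estimates, observed-information SEs and
    95% Wald intervals (log scale; exponentiated columns give the
    relative-weight / RR scale)."""

    model_hat: TransitionModel
    se: np.ndarray
    ci: pd.DataFrame
    loglik_at_max: float
    convergence: dict
    cov_rows: list

    @property
    def spec(self) -> CovariateSpec:
        return self.model_hat.spec

    def to_json(self) -> dict:
        return {
            "kind": "ml",
            "model": self.model_hat.to_json(),
            "se": list(map(float, self.se)),
            "loglik_at_max": float(self.loglik_at_max),
            "convergence": self.convergence,
            "cov_rows": [np.asarray(c).tolist() for c in self.cov_rows],
            "params": json.loads(self.ci.to_json(orient="index")),
        }

    @classmethod
    def from_json(cls, doc: Mapping) -> "FitResult":
        model = TransitionModel.from_json(doc["model"])
        se = np.asarray(doc["se"], dtype=float)
        return cls(
            model_hat=model,
            se=se,
            ci=_param_table_ml(model, se),
            loglik_at_max=doc["loglik_at_max"],
            convergence=dict(doc["convergence"]),
            cov_rows=[np.asarray(c, dtype=float) for c in doc["cov_rows"]],
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "FitResult":
        return cls.from_json(json.loads(Path(path).read_text()))


@dataclass
class PosteriorResult:
    """MCMC fit: posterior draws, summaries and sampler diagnostics."""

    model_hat: TransitionModel          # posterior means
    draws: np.ndarray                   # (chains, kept, n_params)
    chains: int
    burn_in: int
    seed: int
    summary: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)

    @property
    def spec(self) -> CovariateSpec:
        return self.model_hat.spec

    @property
    def flat_draws(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def to_json(self) -> dict:
        return {
            "kind": "mcmc",
            "model": self.model_hat.to_json(),
            "chains": self.chains,
            "burn_in": self.burn_in,
            "seed": self.seed,
            "summary": json.loads(self.summary.to_json(orient="index")),
            "diagnostics": {
                k: (np.asarray(v).tolist() if isinstance(v, (np.ndarray, pd.Series)) else v)
                for k, v in self.diagnostics.items()
            },
            "draws_shape": list(self.draws.shape),
        }

    def save(self, path) -> None:
        """Write the summary JSON plus a ``*_draws.csv`` sidecar holding the
        flattened draws (text; needed to rebuild interval estimates)."""
        path = Path(path)
        path.write_text(json.dumps(self.to_json(), indent=1, sort_keys=True))
        draws_path = path.with_name(path.stem + "_draws.csv")
        pd.DataFrame(
            self.flat_draws, columns=self.model_hat.param_names()
        ).to_csv(draws_path, index=False)

    @classmethod
    def load(cls, path) -> "PosteriorResult":
        path = Path(path)
        doc = json.loads(path.read_text())
        draws_path = path.with_name(path.stem + "_draws.csv")
        flat = pd.read_csv(draws_path).to_numpy()
        shape = tuple(doc["draws_shape"])
        model = TransitionModel.from_json(doc["model"])
        summary = pd.DataFrame.from_dict(doc["summary"], orient="index")
        return cls(
            model_hat=model,
            draws=flat.reshape(shape),
            chains=doc["chains"],
            burn_in=doc["burn_in"],
            seed=doc["seed"],
            summary=summary,
            diagnostics=doc.get("diagnostics", {}),
        )


def fit_ml(
    data: PanelDataset,
    behavior: str,
    covariate_spec: CovariateSpec | list | None = None,
) -> FitResult:
    """Fit the transition model for one behavior by maximum likelihood."""
    pairs = transition_pairs(data, behavior)
    est = MLTransitionEstimator(contrasts=covariate_spec, behavior=behavior)
    est.fit(pairs, pairs["to_state"])
    return FitResult(
        model_hat=est.model_,
        se=est.se_,
        ci=_param_table_ml(est.model_, est.se_),
        loglik_at_max=est.loglik_,
        convergence={"converged": est.converged_, **est.convergence_},
        cov_rows=est.cov_rows_,
    )


def fit_mcmc(
    data: PanelDataset,
    behavior: str,
    covariate_spec: CovariateSpec | list | None = None,
    chains: int = 4,
    iterations: int = 5000,
    burn_in: int = 2000,
    seed: int | None = None,
) -> PosteriorResult:
    """Fit the transition model for one behavior by adaptive random-walk
    Metropolis MCMC (normal(0, 10²) priors). ``seed`` is mandatory."""
    pairs = transition_pairs(data, behavior)
    est = MCMCTransitionEstimator(
        contrasts=covariate_spec, behavior=behavior, chains=chains,
        iterations=iterations, burn_in=burn_in, seed=seed,
    )
    est.fit(pairs, pairs["to_state"])
    return PosteriorResult(
        model_hat=est.model_,
        draws=est.draws_,
        chains=chains,
        burn_in=burn_in,
        seed=seed,
        summary=est.summary_,
        diagnostics={
            "acceptance": est.acceptance_,
            "rhat": est.rhat_,
            "step_trace": est.step_trace_,
        },
    )


def load_fit(path) -> FitResult | PosteriorResult:
    """Load a fit saved by :meth:`FitResult.save` or
    :meth:`PosteriorResult.save`, dispatching on its ``kind`` field."""
    doc = json.loads(Path(path).read_text())
    if doc.get("kind") == "mcmc":
        return PosteriorResult.load(path)
    return FitResult.load(path)
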