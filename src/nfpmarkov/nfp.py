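"""Net Force Progression statistics and covariate relative risks.

The net force of progression summarizes a one-step transition matrix in two
patterns:

* **from none** — total force of starting the behavior minus total force of
  returning to none: ``[P(N→L) + P(N→H)] − [P(L→N) + P(H→N)]``;
* **between low and high** — force of dose escalation minus force of dose
  reduction: ``P(L→H) − P(H→L)``.

A covariate's relative risk on an NFP pattern is the ratio of the pattern's
value at the contrasted covariate profile to its value at the reference
profile (all other covariates at reference); it is defined only where both
net forces are positive. A covariate's *stage-specific* adjusted relative
risk on a single directed transition is ``exp(beta)`` for that transition —
the relative weight ratio of the exponential-regression parameterization.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .covariates import STANDARD_CONTRASTS, Contrast
from .errors import UndefinedRatioError
from .inference import FitResult, PosteriorResult, fit_ml
from .model import StochasticMatrix, TransitionModel, empirical_transition_probs
from .panel import PanelDataset, summarize_baseline
from .states import BEHAVIORS, STATES, TRANSITION_INDEX

PATTERNS = ("from_none", "low_high")


def nfp_from_none(p: StochasticMatrix | np.ndarray) -> float:
    """Net force of progression from the none stage."""
    m = p.p if isinstance(p, StochasticMatrix) else np.asarray(p, dtype=float)
    return float((m[0, 1] + m[0, 2]) - (m[1, 0] + m[2, 0]))


def nfp_low_high(p: StochasticMatrix | np.ndarray) -> float:
    """Net force of progression between the low and high doses."""
    m = p.p if isinstance(p, StochasticMatrix) else np.asarray(p, dtype=float)
    return float(m[1, 2] - m[2, 1])


_NFP_FUNCS = {"from_none": nfp_from_none, "low_high": nfp_low_high}


def _resolve_contrast(contrast) -> Contrast:
    if isinstance(contrast, Contrast):
        return contrast
    try:
        return STANDARD_CONTRASTS[contrast]
    except KeyError:
        raise KeyError(f"unknown covariate contrast {contrast!r}") from None


def _nfp_ratio(model: TransitionModel, contrast: Contrast, pattern: str) -> float:
    func = _NFP_FUNCS[pattern]
    ref = func(model.transition_matrix(None).p)
    alt_profile = {contrast.column: contrast.level}
    alt = func(model.transition_matrix(alt_profile).p)
    for name, value, profile in (
        ("reference", ref, "reference"),
        (contrast.name, alt, alt_profile),
    ):
        if not value > 0:
            raise UndefinedRatioError(
                f"NFP ({pattern}) is {value:.4g} <= 0 at the {name} profile "
                f"({profile}); a ratio of signed net forces is not a "
                "relative risk"
            )
    return alt / ref


def _draw_models(fit: FitResult | PosteriorResult, n_draws: int, seed: int):
    """Parameter draws for interval construction: posterior draws for MCMC,
    multivariate-normal parametric bootstrap for ML."""
    spec = fit.spec
    behavior = fit.model_hat.behavior
    if isinstance(fit, PosteriorResult):
        flat = fit.flat_draws
    else:
        rng = np.random.default_rng(seed)
        blocks = []
        theta = fit.model_hat.to_flat()
        width = 2 * (1 + len(spec))
        for r, cov in enumerate(fit.cov_rows):
            mean = theta[r * width:(r + 1) * width]
            cov = np.asarray(cov, dtype=float)
            blocks.append(rng.multivariate_normal(mean, cov, size=n_draws,
                                                  method="svd"))
        flat = np.hstack(blocks)
    for row in flat:
        yield TransitionModel.from_flat(row, behavior, spec)


@dataclass(frozen=True)
class RREstimate:
    """A relative risk with its 95% interval."""

    rr: float
    lo: float
    hi: float
    kind: str  # "adjusted" or "crude"

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.rr, self.lo, self.hi)


def rr_nfp(
    fit: FitResult | PosteriorResult,
    contrast,
    pattern: str,
    n_draws: int = 2000,
    seed: int = 0,
) -> RREstimate:
    """Relative risk of a covariate contrast on one NFP pattern.

    The point estimate is the plug-in ratio of net forces at the contrasted
    vs reference profile. Intervals are percentile intervals over posterior
    draws (MCMC fit) or over ``n_draws`` parametric-bootstrap parameter
    draws (ML fit, fixed ``seed``). Raises :class:`UndefinedRatioError`
    when either net force is not positive.
    """
    if pattern not in PATTERNS:
        raise ValueError(f"pattern must be one of {PATTERNS}, got {pattern!r}")
    contrast = _resolve_contrast(contrast)
    if contrast.name not in fit.spec.names:
        raise KeyError(
            f"contrast {contrast.name!r} not in the fitted design {fit.spec.names}"
        )
    point = _nfp_ratio(fit.model_hat, contrast, pattern)
    ratios = []
    n_invalid = 0
    for model in _draw_models(fit, n_draws, seed):
        try:
            ratios.append(_nfp_ratio(model, contrast, pattern))
        except UndefinedRatioError:
            n_invalid += 1
    if not ratios or n_invalid > len(ratios):
        raise UndefinedRatioError(
            f"NFP ({pattern}) not positive in {n_invalid} of "
            f"{n_invalid + len(ratios)} parameter draws; interval undefined"
        )
    lo, hi = np.quantile(ratios, [0.025, 0.975])
    kind = "adjusted" if len(fit.spec) > 1 else "crude"
    return RREstimate(rr=point, lo=float(lo), hi=float(hi), kind=kind)


def stage_specific_arr(
    fit: FitResult | PosteriorResult, transition, contrast
) -> RREstimate:
    """Per-transition adjusted relative risk ``exp(beta)`` with 95% interval.

    ``transition`` is a label like ``"low->high"`` or a state-index pair.
    ML fits use exponentiated Wald limits; MCMC fits use posterior
    quantiles of ``exp(beta)``.
    """
    if isinstance(transition, str):
        label = transition
        r, s = [STATES.index(x) for x in transition.split("->")]
    else:
        r, s = transition
        label = f"{STATES[r]}->{STATES[s]}"
    if (r, s) not in TRANSITION_INDEX:
        raise KeyError(f"{label!r} is not a directed off-diagonal transition")
    contrast = _resolve_contrast(contrast)
    if contrast.name not in fit.spec.names:
        raise KeyError(
            f"contrast {contrast.name!r} not in the fitted design {fit.spec.names}"
        )
    t = TRANSITION_INDEX[(r, s)]
    k = fit.spec.names.index(contrast.name)
    width = 1 + len(fit.spec)
    flat_idx = t * width + 1 + k
    kind = "adjusted" if len(fit.spec) > 1 else "crude"
    if isinstance(fit, PosteriorResult):
        draws = fit.flat_draws[:, flat_idx]
        rr = float(np.exp(draws.mean()))
        lo, hi = np.exp(np.quantile(draws, [0.025, 0.975]))
        return RREstimate(rr=rr, lo=float(lo), hi=float(hi), kind=kind)
    row = fit.ci.iloc[flat_idx]
    return RREstimate(
        rr=float(row["rr"]), lo=float(row["rr_low"]), hi=float(row["rr_high"]),
        kind=kind,
    )


# ---------------------------------------------------------------------------
# report bundle
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    return "NA" if not np.isfinite(x) else format(x, ".4f")


def _rr_cell(func, *args, **kwargs) -> str:
    try:
        est = func(*args, **kwargs)
    except UndefinedRatioError:
        return "NA\tNA\tNA"
    return f"{_fmt(est.rr)}\t{_fmt(est.lo)}\t{_fmt(est.hi)}"


def make_report(
    fits: Mapping[str, FitResult | PosteriorResult],
    data: PanelDataset,
    out_dir,
    crude: bool = True,
    n_draws: int = 2000,
    seed: int = 0,
) -> dict[str, Path]:
    """Emit the full results bundle as TSV + plain text.

    Per behavior: the baseline state-distribution table, the empirical 3×3
    transition matrix (percent), the NFP relative-risk table for both
    patterns (crude RR from single-contrast refits when ``crude``; adjusted
    from the supplied fit) and the stage-specific aRR table. Undefined NFP
    ratios print as NA. Deterministic formatting: identical inputs produce
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    summary_lines = []
    for behavior in BEHAVIORS:
        if behavior not in fits:
            continue
        fit = fits[behavior]
        base = summarize_baseline(data, behavior)
        path = out_dir / f"baseline_{behavior}.tsv"
        base.round(4).to_csv(path, sep="\t")
        written[f"baseline_{behavior}"] = path

        emp = empirical_transition_probs(data, behavior)
        mat = pd.DataFrame(
            100.0 * emp.p, index=list(STATES), columns=list(STATES)
        ).round(4)
        path = out_dir / f"transitions_{behavior}.tsv"
        mat.to_csv(path, sep="\t")
        written[f"transitions_{behavior}"] = path

        ref_mat = fit.model_hat.transition_matrix(None)
        nfp_vals = {p: _NFP_FUNCS[p](ref_mat.p) for p in PATTERNS}
        summary_lines.append(
            f"{behavior}: NFP(from none) = {nfp_vals['from_none']:+.4f}, "
            f"NFP(low-high) = {nfp_vals['low_high']:+.4f} at reference profile"
        )

        lines = ["contrast\tpattern\tRR\tRR_lo\tRR_hi\taRR\taRR_lo\taRR_hi"]
        for name in fit.spec.names:
            for pattern in PATTERNS:
                adj = _rr_cell(rr_nfp, fit, name, pattern,
                               n_draws=n_draws, seed=seed)
                if crude and len(fit.spec) > 1:
                    crude_fit = fit_ml(data, behavior, [name])
                    cr = _rr_cell(rr_nfp, crude_fit, name, pattern,
                                  n_draws=n_draws, seed=seed)
                else:
                    cr = adj
                lines.append(f"{name}\t{pattern}\t{cr}\t{adj}")
        path = out_dir / f"nfp_rr_{behavior}.tsv"
        path.write_text("\n".join(lines) + "\n")
        written[f"nfp_rr_{behavior}"] = path

        lines = ["transition\tcontrast\taRR\taRR_lo\taRR_hi"]
        for (r, s), _t in TRANSITION_INDEX.items():
            label = f"{STATES[r]}->{STATES[s]}"
            for name in fit.spec.names:
                est = stage_specific_arr(fit, label, name)
                lines.append(
                    f"{label}\t{name}\t{_fmt(est.rr)}\t{_fmt(est.lo)}\t{_fmt(est.hi)}"
                )
        path = out_dir / f"stage_arr_{behavior}.tsv"
        path.write_text("\n".join(lines) + "\n")
        written[f"stage_arr_{behavior}"] = path

    summary = out_dir / "summary.txt"
    body = (
        f"participants: {data.n_participants}\n"
        f"rows: {data.n_rows}\n"
        f"provenance: {data.provenance}\n" + "\n".join(summary_lines) + "\n"
    )
    summary.write_text(body)
    written["summary"] = summary
    return written


def bundle_hash(paths: Mapping[str, Path]) -> str:
    """SHA-256 over the concatenated bundle contents (order-stable)."""
    h = hashlib.sha256()
    for key in sorted(paths):
        h.update(key.encode())
        h.update(Path(paths[key]).read_bytes())
    return h.hexdigest()
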