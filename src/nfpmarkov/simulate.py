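"""Synthetic screening-cohort generator.

Emulates the structure of an organized oral-mucosal screening panel: fixed
baseline covariates drawn independently at their cohort prevalences, a
first-screen behavior state drawn from the baseline distribution, and
subsequent screens evolved by one step of the covariate-specific transition
matrix per round. Smoking and betel chewing evolve independently given the
covariates; screen counts are independent of states (no informative
dropout); ages are drawn at 30+ so generated cohorts pass the eligibility
filter unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .covariates import COVARIATE_LEVELS, CovariateSpec, default_covariate_spec
from .errors import ConfigError
from .model import TransitionModel, alphas_from_matrix
from .panel import PanelDataset
from .states import BEHAVIORS, STATES, TRANSITION_INDEX

# ---------------------------------------------------------------------------
# Cohort-level defaults. Baseline state distributions and covariate
# prevalences follow the first-screen composition of the 2.57 M-participant
# Taiwanese screening cohort (2010–2021); probability vectors are
# normalized count ratios. Only the low-dose rows of the one-step matrices
# are published; the none- and high-dose rows below are package defaults
# consistent with the cohort's qualitative behavior (most participants
# unchanged, smoking cessation below 10%, >20% dose reduction in high-dose
# groups, high-dose betel quitting roughly four times likelier than
# high-dose smoking quitting). See docs/methods.md.
# ---------------------------------------------------------------------------

_N_COHORT = 2_578_245

DEFAULT_COVARIATE_PREVALENCES: dict[str, dict[str, float]] = {
    "sex": {"female": 387_296 / _N_COHORT, "male": 2_190_949 / _N_COHORT},
    "age_group": {"elder": 700_655 / _N_COHORT, "younger": 1_877_590 / _N_COHORT},
    "education": {
        "low": 515_778 / _N_COHORT,
        "high": 860_054 / _N_COHORT,
        "unknown": 1_202_413 / _N_COHORT,
    },
    "living_area": {
        "rural": 968_718 / (968_718 + 1_609_524),
        "urban": 1_609_524 / (968_718 + 1_609_524),
    },
    "screening_place": {
        "small": 1_851_831 / _N_COHORT,
        "large": 726_200 / _N_COHORT,
        "unknown": 214 / _N_COHORT,
    },
    "opmd": {"negative": 2_384_989 / _N_COHORT, "positive": 193_256 / _N_COHORT},
}

_BETEL_BASELINE_RAW = np.array([0.767, 0.167, 0.067])  # printed row sums to 1.001

DEFAULT_BASELINE_STATE_PROBS: dict[str, tuple[float, float, float]] = {
    "smoking": (0.224, 0.484, 0.292),
    "betel": tuple(_BETEL_BASELINE_RAW / _BETEL_BASELINE_RAW.sum()),
}

#: Default one-step matrices at the reference covariate profile
#: (rows: none, low, high). Low-dose rows are the published values.
DEFAULT_TRUE_MATRICES: dict[str, np.ndarray] = {
    "smoking": np.array([
        [0.870, 0.100, 0.030],
        [0.069, 0.789, 0.142],
        [0.070, 0.220, 0.710],
    ]),
    "betel": np.array([
        [0.940, 0.050, 0.010],
        [0.285, 0.619, 0.096],
        [0.260, 0.220, 0.520],
    ]),
}

#: Default nonzero covariate effects on single transitions
#: (behavior → {(transition label, contrast name): relative weight ratio}).
#: These are the published stage-specific adjusted relative risks.
DEFAULT_STAGE_EFFECTS: dict[str, dict[tuple[str, str], float]] = {
    "smoking": {
        ("none->low", "opmd_positive"): 0.86,
        ("none->high", "edu_high"): 0.82,
        ("low->high", "place_large"): 0.86,
        ("high->low", "place_large"): 1.19,
    },
    "betel": {
        ("high->low", "edu_high"): 1.07,
    },
}

_TRANSITION_LABELS = {
    f"{STATES[r]}->{STATES[s]}": t for (r, s), t in TRANSITION_INDEX.items()
}


def make_true_model(
    behavior: str,
    matrix: np.ndarray | None = None,
    effects: Mapping[tuple[str, str], float] | None = None,
    spec: CovariateSpec | None = None,
) -> TransitionModel:
    """Build a generating :class:`TransitionModel` from a reference-profile
    matrix plus per-transition relative weight ratios.

    ``effects`` maps ``(transition label, contrast name)`` — e.g.
    ``("low->high", "place_large")`` — to the multiplicative effect on that
    transition's weight (``beta = ln(effect)``).
    """
    if matrix is None:
        matrix = DEFAULT_TRUE_MATRICES[behavior]
    if effects is None:
        effects = DEFAULT_STAGE_EFFECTS.get(behavior, {})
    if spec is None:
        spec = default_covariate_spec()
    alpha = alphas_from_matrix(np.asarray(matrix, dtype=float))
    beta = np.zeros((6, len(spec)))
    for (label, contrast), ratio in effects.items():
        if label not in _TRANSITION_LABELS:
            raise ConfigError(f"unknown transition label {label!r}")
        if contrast not in spec.names:
            raise ConfigError(f"contrast {contrast!r} not in spec {spec.names}")
        if not ratio > 0:
            raise ConfigError(f"effect for {(label, contrast)} must be > 0")
        beta[_TRANSITION_LABELS[label], spec.names.index(contrast)] = np.log(ratio)
    return TransitionModel(behavior=behavior, spec=spec, alpha=alpha, beta=beta)


@dataclass
class GeneratorConfig:
    """Full specification of one synthetic cohort. ``seed`` is mandatory."""

    seed: int
    n_participants: int = 10_000
    screens_per_participant: dict[int, float] = field(
        default_factory=lambda: {2: 0.5, 3: 0.5}
    )
    covariate_prevalences: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_COVARIATE_PREVALENCES.items()
        }
    )
    baseline_state_probs: dict[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_STATE_PROBS)
    )
    true_model: dict[str, TransitionModel] = field(default_factory=dict)
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        for b in BEHAVIORS:
            self.true_model.setdefault(b, make_true_model(b))
        self.validate()

    def validate(self) -> None:
        def _check(probs, what):
            probs = np.asarray(list(probs), dtype=float)
            if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-12:
                raise ConfigError(
                    f"{what} must be a probability vector summing to 1, "
                    f"got {probs.tolist()}"
                )

        _check(self.screens_per_participant.values(), "screens_per_participant")
        if min(self.screens_per_participant) < 2:
            raise ConfigError("every participant needs at least 2 screens")
        for cov, levels in self.covariate_prevalences.items():
            if cov not in COVARIATE_LEVELS:
                raise ConfigError(f"unknown covariate {cov!r}")
            if set(levels) - set(COVARIATE_LEVELS[cov]):
                raise ConfigError(
                    f"invalid level(s) for {cov!r}: {sorted(levels)}"
                )
            _check(levels.values(), f"prevalences of {cov!r}")
        for b, probs in self.baseline_state_probs.items():
            _check(probs, f"baseline state probabilities of {b!r}")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigError("missing_rate must lie in [0, 1]")


def default_config(n_participants: int = 10_000, seed: int = 0) -> GeneratorConfig:
    """The study-condition defaults (cohort composition, published low-dose
    transition rows, published stage-specific covariate effects)."""
    return GeneratorConfig(seed=seed, n_participants=n_participants)


def recovery_config(
    behavior: str,
    start_state: str,
    seed: int,
    n_participants: int = 200_000,
    contrast: str | None = None,
    prevalence: float | None = None,
    transition: str | None = None,
    effect: float | None = None,
) -> GeneratorConfig:
    """Config for a parameter-recovery experiment.

    Every participant attends exactly two screens and starts ``behavior``
    in ``start_state``; covariates sit at their reference levels except an
    optional single binary ``contrast`` drawn with the given ``prevalence``
    and multiplying one ``transition``'s weight by ``effect``. The
    reference-profile dynamics are the default true matrices.
    """
    from .covariates import STANDARD_CONTRASTS

    prevalences = {
        col: {levels[0]: 1.0} for col, levels in COVARIATE_LEVELS.items()
    }
    if contrast is not None:
        c = STANDARD_CONTRASTS[contrast]
        if not 0.0 < prevalence < 1.0:
            raise ConfigError("prevalence must lie strictly in (0, 1)")
        prevalences[c.column] = {c.reference: 1.0 - prevalence, c.level: prevalence}
        spec = CovariateSpec([c])
        effects = {(transition, contrast): effect}
    else:
        spec = CovariateSpec(())
        effects = {}
    start = np.zeros(3)
    start[STATES.index(start_state)] = 1.0
    true_model = {
        b: make_true_model(b, effects=effects if b == behavior else {}, spec=spec)
        for b in BEHAVIORS
    }
    return GeneratorConfig(
        seed=seed,
        n_participants=n_participants,
        screens_per_participant={2: 1.0},
        covariate_prevalences=prevalences,
        baseline_state_probs={b: tuple(start) for b in BEHAVIORS},
        true_model=true_model,
    )


def _sample_levels(rng, levels_probs: dict[str, float], order, n) -> np.ndarray:
    levels = [lv for lv in order if lv in levels_probs]
    probs = np.array([levels_probs[lv] for lv in levels], dtype=float)
    idx = rng.choice(len(levels), size=n, p=probs)
    return np.asarray(levels, dtype=object)[idx]


def generate_population(config: GeneratorConfig) -> PanelDataset:
    """Draw one synthetic screening panel. Same config (incl. seed) →
    identical dataset."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    cov = {}
    for col, order in COVARIATE_LEVELS.items():
        cov[col] = _sample_levels(rng, config.covariate_prevalences[col], order, n)
    younger = cov["age_group"] == "younger"
    age = np.where(
        younger,
        rng.integers(30, 61, size=n),
        rng.integers(61, 86, size=n),
    )

    screen_levels = sorted(config.screens_per_participant)
    screen_probs = np.array(
        [config.screens_per_participant[k] for k in screen_levels], dtype=float
    )
    n_screens = np.asarray(screen_levels)[
        rng.choice(len(screen_levels), size=n, p=screen_probs)
    ]
    k_max = int(n_screens.max())

    cov_frame = pd.DataFrame(cov)
    states: dict[str, np.ndarray] = {}
    for b in BEHAVIORS:
        model = config.true_model[b]
        X = model.spec.design_matrix(cov_frame).astype(float)
        if len(model.spec):
            patterns, idx = np.unique(X, axis=0, return_inverse=True)
            idx = idx.reshape(-1)
        else:
            patterns, idx = np.zeros((1, 0)), np.zeros(n, dtype=np.int64)
        mats = model.matrix_from_design(patterns)  # (m, 3, 3)
        cums = np.cumsum(mats, axis=2)
        traj = np.empty((n, k_max), dtype=np.int64)
        base = np.asarray(config.baseline_state_probs[b], dtype=float)
        u0 = rng.random(n)
        traj[:, 0] = (u0[:, None] >= np.cumsum(base)[:2][None, :]).sum(axis=1)
        for t in range(1, k_max):
            c = cums[idx, traj[:, t - 1], :]  # (n, 3) cumulative rows
            u = rng.random(n)
            traj[:, t] = (u[:, None] >= c[:, :2]).sum(axis=1)
        states[b] = traj

    ids = np.array([f"P{i + 1:07d}" for i in range(n)], dtype=object)
    keep = np.repeat(np.arange(n), n_screens)
    rounds = np.concatenate([np.arange(1, k + 1) for k in n_screens])
    frame = pd.DataFrame(
        {
            "id": ids[keep],
            "round": rounds,
            "age": age[keep],
            **{col: cov[col][keep] for col in COVARIATE_LEVELS},
            "smoking_state": np.asarray(STATES, dtype=object)[
                states["smoking"][keep, rounds - 1]
            ],
            "betel_state": np.asarray(STATES, dtype=object)[
                states["betel"][keep, rounds - 1]
            ],
        }
    )
    frame = frame.drop(columns=["age_group"])
    data = PanelDataset(frame, provenance=f"synthetic(seed={config.seed})")
    if config.missing_rate > 0:
        data = inject_missing(data, config.missing_rate, seed=int(rng.integers(2**31)))
    return data


def inject_missing(data: PanelDataset, rate: float, seed: int) -> PanelDataset:
    """Independently flip each participant's education and screening place to
    "unknown" with probability ``rate`` (all of their rows; covariates are
    baseline-fixed). Other fields are untouched."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must lie in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    df = data.frame.copy()
    ids = df["id"].unique()
    for col in ("education", "screening_place"):
        flip = ids[rng.random(len(ids)) < rate]
        df.loc[df["id"].isin(flip), col] = "unknown"
    return PanelDataset(df, provenance=data.provenance)
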