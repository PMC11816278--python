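"""Screening-panel I/O, validation, exclusion filtering and baseline summary.

The on-disk format is a long, comma-delimited table with one row per
participant-screen::

    id, round, age, sex, education, living_area, screening_place, opmd,
    smoking_state, betel_state

Behavior states are spelled ``none|low|high`` (empty = missing at that
screen); covariates take the enumerated levels of
:data:`nfpmarkov.covariates.COVARIATE_LEVELS`. Covariates are treated as
baseline-fixed: downstream modelling reads them from the first screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .covariates import COVARIATE_LEVELS
from .errors import IntegrityError, PanelValidationError, SchemaError
from .states import BEHAVIORS, STATE_INDEX, STATES

logger = logging.getLogger(__name__)

PANEL_COLUMNS = (
    "id", "round", "age", "sex", "education", "living_area",
    "screening_place", "opmd", "smoking_state", "betel_state",
)

_STATE_COLUMNS = {"smoking": "smoking_state", "betel": "betel_state"}

#: First-screen age at or below this is "younger"; above is "elder".
YOUNGER_AGE_MAX = 60


@dataclass(frozen=True)
class ScreenObservation:
    round_index: int
    smoking: str | None
    betel: str | None


@dataclass(frozen=True)
class ParticipantRecord:
    id: str
    age_at_first_screen: float
    covariates: Mapping[str, str]
    screens: tuple[ScreenObservation, ...]


@dataclass
class PanelDataset:
    """A validated long-format screening panel.

    ``frame`` holds one row per participant-screen, sorted by
    ``(id, round)``; ``provenance`` is a free-text source tag.
    """

    frame: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        self.frame = _validate_frame(self.frame)

    @property
    def n_participants(self) -> int:
        return self.frame["id"].nunique()

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def first_screens(self) -> pd.DataFrame:
        """One row per participant: the earliest screening round."""
        return self.frame.drop_duplicates("id", keep="first")

    def records(self) -> Iterator[ParticipantRecord]:
        """Iterate participants as structured records (small data only)."""
        for pid, grp in self.frame.groupby("id", sort=False):
            first = grp.iloc[0]
            covs = {c: first[c] for c in COVARIATE_LEVELS if c in grp.columns}
            covs["age_group"] = (
                "younger" if float(first["age"]) <= YOUNGER_AGE_MAX else "elder"
            )
            yield ParticipantRecord(
                id=str(pid),
                age_at_first_screen=float(first["age"]),
                covariates=covs,
                screens=tuple(
                    ScreenObservation(
                        round_index=int(r["round"]),
                        smoking=None if pd.isna(r["smoking_state"]) else r["smoking_state"],
                        betel=None if pd.isna(r["betel_state"]) else r["betel_state"],
                    )
                    for _, r in grp.iterrows()
                ),
            )


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"panel is missing mandatory column(s): {missing}")
    df = df.loc[:, list(PANEL_COLUMNS)].copy()
    df["round"] = pd.to_numeric(df["round"], errors="raise").astype(int)
    df["age"] = pd.to_numeric(df["age"], errors="raise")
    if (df["round"] < 1).any():
        bad = df.index[df["round"] < 1].tolist()[:5]
        raise PanelValidationError(f"round must be >= 1; bad rows: {bad}")

    problems: list[str] = []
    for col, levels in COVARIATE_LEVELS.items():
        if col not in df.columns:  # age_group is derived from age
            continue
        bad = ~df[col].isin(levels)
        if bad.any():
            rows = df.index[bad].tolist()[:5]
            vals = sorted(df.loc[bad, col].astype(str).unique())[:5]
            problems.append(
                f"column {col!r}: invalid value(s) {vals} at row(s) {rows} "
                f"(levels: {list(levels)})"
            )
    for col in ("smoking_state", "betel_state"):
        ok = df[col].isin(STATES) | df[col].isna()
        if not ok.all():
            rows = df.index[~ok].tolist()[:5]
            vals = sorted(df.loc[~ok, col].astype(str).unique())[:5]
            problems.append(
                f"column {col!r}: invalid state(s) {vals} at row(s) {rows} "
                f"(states: {list(STATES)})"
            )
    if problems:
        raise PanelValidationError("; ".join(problems))

    dup = df.duplicated(subset=["id", "round"])
    if dup.any():
        pairs = df.loc[dup, ["id", "round"]].head().to_records(index=False).tolist()
        raise IntegrityError(f"duplicate (id, round) pairs, e.g. {pairs}")

    return df.sort_values(["id", "round"], kind="stable").reset_index(drop=True)


def read_panel(path, provenance: str | None = None) -> PanelDataset:
    """Read and validate a panel CSV.

    Raises :class:`SchemaError` for missing columns,
    :class:`IntegrityError` for duplicate (id, round) pairs and
    :class:`PanelValidationError` (naming offending rows) for values outside
    the enumerated levels.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("smoking_state", "betel_state"):
        if col in df.columns:
            df[col] = df[col].replace("", np.nan)
    return PanelDataset(df, provenance=provenance or str(path))


def write_panel(data: PanelDataset, path) -> None:
    """Write a panel CSV; ``read_panel(write_panel(...))`` round-trips."""
    out = data.frame.copy()
    out["age"] = out["age"].map(lambda a: format(float(a), "g"))
    out.to_csv(path, index=False, na_rep="")


def apply_exclusions(
    data: PanelDataset, min_age: float = 30, min_screens: int = 2
) -> PanelDataset:
    """Apply the cohort eligibility rules.

    Retains participants whose age at the first screen is at least
    ``min_age`` years (default 30; age exactly 30 is kept) and who attended
    at least ``min_screens`` screening rounds (default 2). Counts removed
    per rule are logged. Idempotent.
    """
    df = data.frame
    first = df.drop_duplicates("id", keep="first").set_index("id")
    n_screens = df.groupby("id", sort=False).size()
    young = set(first.index[first["age"] < min_age])
    few = set(n_screens.index[n_screens < min_screens])
    logger.info(
        "exclusions: %d participant(s) below age %s, %d with fewer than %d screens",
        len(young), min_age, len(few), min_screens,
    )
    keep = ~df["id"].isin(young | few)
    out = PanelDataset(df.loc[keep].reset_index(drop=True), provenance=data.provenance)
    return out


def _age_group(age: pd.Series) -> pd.Series:
    return pd.Series(
        np.where(age <= YOUNGER_AGE_MAX, "younger", "elder"), index=age.index
    )


#: Demographic rows of the baseline summary, in display order.
_BASELINE_GROUPS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("sex", ("male", "female")),
    ("age_group", ("younger", "elder")),
    ("education", ("low", "high", "unknown")),
    ("living_area", ("urban", "rural")),
    ("screening_place", ("large", "small", "unknown")),
    ("opmd", ("positive", "negative")),
)


def summarize_baseline(data: PanelDataset, behavior: str) -> pd.DataFrame:
    """Percent distribution of first-screen behavior states per demographic.

    Returns a DataFrame indexed by ``(covariate, level)`` — plus an
    ``(overall, all)`` row — with columns ``none``, ``low``, ``high``
    (percentages over the participants whose state is observed) and ``n``
    (participants in the row). Rows sum to 100 within rounding.
    """
    if behavior not in BEHAVIORS:
        raise ValueError(f"behavior must be one of {BEHAVIORS}, got {behavior!r}")
    if data.n_rows == 0:
        raise ValueError("cannot summarize an empty panel")
    first = data.first_screens().copy()
    first["age_group"] = _age_group(first["age"])
    state_col = _STATE_COLUMNS[behavior]

    def _row(sub: pd.DataFrame) -> list[float]:
        states = sub[state_col].dropna()
        n = len(states)
        if n == 0:
            return [float("nan")] * 3 + [0]
        pct = [100.0 * (states == s).sum() / n for s in STATES]
        return pct + [len(sub)]

    rows, index = [], []
    for col, levels in _BASELINE_GROUPS:
        for level in levels:
            rows.append(_row(first[first[col] == level]))
            index.append((col, level))
    rows.append(_row(first))
    index.append(("overall", "all"))
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["covariate", "level"]),
        columns=[*STATES, "n"],
    )


def transition_pairs(data: PanelDataset, behavior: str) -> pd.DataFrame:
    """Consecutive-screen transition pairs for one behavior.

    Returns one row per consecutive screen pair per participant with the
    baseline (first-screen) covariates, integer ``from_state`` and
    ``to_state`` codes, and ``age_group`` derived from first-screen age.
    Pairs with a missing endpoint are dropped (count logged); the first
    screen's state is the conditioning origin of the first pair.
    """
    if behavior not in BEHAVIORS:
        raise ValueError(f"behavior must be one of {BEHAVIORS}, got {behavior!r}")
    df = data.frame
    state_col = _STATE_COLUMNS[behavior]
    same = df["id"].to_numpy()[:-1] == df["id"].to_numpy()[1:]
    frm = df[state_col].to_numpy()[:-1][same]
    to = df[state_col].to_numpy()[1:][same]
    origin_pos = np.flatnonzero(np.concatenate([same, [False]]))

    first = df.drop_duplicates("id", keep="first").copy()
    first["age_group"] = _age_group(first["age"])
    cov = first.set_index("id")[list(COVARIATE_LEVELS)]
    ids = df["id"].to_numpy()[origin_pos]

    pairs = cov.loc[ids].reset_index()
    pairs["from_state"] = frm
    pairs["to_state"] = to
    observed = pairs["from_state"].notna() & pairs["to_state"].notna()
    n_dropped = int((~observed).sum())
    if n_dropped:
        logger.info(
            "dropped %d transition pair(s) with a missing %s endpoint",
            n_dropped, behavior,
        )
    pairs = pairs.loc[observed].reset_index(drop=True)
    pairs["from_state"] = pairs["from_state"].map(STATE_INDEX).astype(np.int64)
    pairs["to_state"] = pairs["to_state"].map(STATE_INDEX).astype(np.int64)
    return pairs
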