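"""Covariate contrasts and design-matrix construction.

All covariates in the screening panel are categorical with a declared
reference level; each non-reference level of interest enters the model as a
0/1 contrast. A :class:`CovariateSpec` is an ordered list of contrasts and
maps a panel DataFrame (or a single covariate profile) to a design matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError

#: Enumerated levels of every panel covariate; first listed level is the
#: modelling reference.
COVARIATE_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("female", "male"),
    "age_group": ("elder", "younger"),
    "education": ("low", "high", "unknown"),
    "living_area": ("rural", "urban"),
    "screening_place": ("small", "large", "unknown"),
    "opmd": ("negative", "positive"),
}


@dataclass(frozen=True)
class Contrast:
    """One 0/1 covariate contrast: indicator of `column == level`."""

    name: str
    column: str
    level: str

    @property
    def reference(self) -> str:
        return COVARIATE_LEVELS[self.column][0]

    def to_dict(self) -> dict:
        return {"name": self.name, "column": self.column, "level": self.level}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Contrast":
        return cls(name=d["name"], column=d["column"], level=d["level"])


#: Named contrasts available out of the box.
STANDARD_CONTRASTS: dict[str, Contrast] = {
    c.name: c
    for c in (
        Contrast("male", "sex", "male"),
        Contrast("younger", "age_group", "younger"),
        Contrast("edu_high", "education", "high"),
        Contrast("edu_unknown", "education", "unknown"),
        Contrast("urban", "living_area", "urban"),
        Contrast("place_large", "screening_place", "large"),
        Contrast("place_unknown", "screening_place", "unknown"),
        Contrast("opmd_positive", "opmd", "positive"),
    )
}


class CovariateSpec:
    """Ordered list of contrasts defining the regression design.

    An empty spec is the intercept-only design.
    """

    def __init__(self, contrasts: Sequence[Contrast] = ()):  # noqa: D401
        contrasts = tuple(contrasts)
        names = [c.name for c in contrasts]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate contrast names: {names}")
        self.contrasts = contrasts

    @classmethod
    def from_names(cls, names: Iterable[str]) -> "CovariateSpec":
        """Build a spec from :data:`STANDARD_CONTRASTS` names."""
        contrasts = []
        for name in names:
            try:
                contrasts.append(STANDARD_CONTRASTS[name])
            except KeyError:
                raise SchemaError(
                    f"unknown covariate contrast {name!r}; available: "
                    f"{sorted(STANDARD_CONTRASTS)}"
                ) from None
        return cls(contrasts)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.contrasts]

    def __len__(self) -> int:
        return len(self.contrasts)

    def __eq__(self, other) -> bool:
        return isinstance(other, CovariateSpec) and self.contrasts == other.contrasts

    def __repr__(self) -> str:
        return f"CovariateSpec({self.names})"

    def design_matrix(self, df: pd.DataFrame) -> np.ndarray:
        """0/1 design matrix (n, p) for the contrasts, given panel columns."""
        n = len(df)
        X = np.zeros((n, len(self.contrasts)), dtype=np.int8)
        for k, c in enumerate(self.contrasts):
            if c.column not in df.columns:
                raise SchemaError(f"covariate column {c.column!r} missing")
            X[:, k] = (df[c.column].to_numpy() == c.level).astype(np.int8)
        return X

    def profile_vector(self, profile: Mapping[str, str] | None) -> np.ndarray:
        """Design row for one covariate profile (dict column → level).

        Columns omitted from ``profile`` sit at their reference level.
        """
        profile = dict(profile or {})
        for col, level in profile.items():
            if col not in COVARIATE_LEVELS:
                raise SchemaError(f"unknown covariate {col!r}")
            if level not in COVARIATE_LEVELS[col]:
                raise SchemaError(
                    f"level {level!r} not valid for covariate {col!r} "
                    f"(levels: {COVARIATE_LEVELS[col]})"
                )
        x = np.zeros(len(self.contrasts))
        for k, c in enumerate(self.contrasts):
            x[k] = 1.0 if profile.get(c.column, c.reference) == c.level else 0.0
        return x

    def reference_profile(self) -> dict[str, str]:
        """Every covariate at its reference level."""
        return {col: levels[0] for col, levels in COVARIATE_LEVELS.items()}

    def to_json(self) -> list[dict]:
        return [c.to_dict() for c in self.contrasts]

    @classmethod
    def from_json(cls, items: Sequence[Mapping]) -> "CovariateSpec":
        return cls([Contrast.from_dict(d) for d in items])


def default_covariate_spec() -> CovariateSpec:
    """All standard contrasts — the fully adjusted design."""
    return CovariateSpec(tuple(STANDARD_CONTRASTS.values()))
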