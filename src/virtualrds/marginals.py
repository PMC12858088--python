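"""Categorical population marginals used as calibration targets.

A :class:`PopulationMarginals` object holds, for each demographic variable,
its ordered category labels and the target population proportions.  These
are the post-stratification targets (census-style marginal distributions)
that the weighting stage calibrates a respondent sample to, and also the
sampling distribution that the synthetic-population generator draws from.

The default category system mirrors a national household-survey setting:
sex, race/skin colour, a four-level education variable, a five-category
fine age variable (from which both the three analysis age groups and the
four invitation age groups derive), 27 federative units grouped into five
macro-regions, and capital-city residence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "MarginalVariable",
    "PopulationMarginals",
    "default_population_marginals",
    "rake_targets",
    "add_derived_columns",
    "DERIVED_MAPS",
]


class ConfigurationError(ValueError):
    """Raised when a configuration object violates its invariants."""


@dataclass(frozen=True)
class MarginalVariable:
    """One categorical variable: ordered labels and target proportions."""

    name: str
    categories: tuple[str, ...]
    proportions: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.categories) < 2:
            raise ConfigurationError(
                f"variable {self.name!r} needs at least 2 categories"
            )
        if len(set(self.categories)) != len(self.categories):
            raise ConfigurationError(
                f"variable {self.name!r} has duplicate category labels"
            )
        if len(self.proportions) != len(self.categories):
            raise ConfigurationError(
                f"variable {self.name!r}: {len(self.categories)} categories but "
                f"{len(self.proportions)} proportions"
            )
        p = np.asarray(self.proportions, dtype=float)
        if (p < 0).any() or (p > 1).any():
            raise ConfigurationError(
                f"variable {self.name!r}: proportions must lie in [0, 1]"
            )
        if abs(p.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"variable {self.name!r}: proportions sum to {p.sum():.12f}, not 1"
            )

    def as_series(self) -> pd.Series:
        return pd.Series(self.proportions, index=list(self.categories), name=self.name)


@dataclass(frozen=True)
class PopulationMarginals:
    """Ordered collection of :class:`MarginalVariable` targets."""

    variables: tuple[MarginalVariable, ...]

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate variable names in marginals")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.variables)

    def variable(self, name: str) -> MarginalVariable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def __iter__(self):
        return iter(self.variables)

    @classmethod
    def from_dict(cls, spec: Mapping[str, Mapping[str, float]] | Iterable) -> "PopulationMarginals":
        """Build from ``{variable: {category: proportion}}`` (e.g. parsed YAML)."""
        variables = []
        for name, cats in dict(spec).items():
            variables.append(
                MarginalVariable(
                    name=name,
                    categories=tuple(cats.keys()),
                    proportions=tuple(float(x) for x in cats.values()),
                )
            )
        return cls(tuple(variables))

    def to_dict(self) -> dict[str, dict[str, float]]:
        return {
            v.name: dict(zip(v.categories, v.proportions)) for v in self.variables
        }


# ---------------------------------------------------------------------------
# Default category system and census-style targets
# ---------------------------------------------------------------------------

SEX = ("men", "women")
RACE = ("white", "nonwhite")

# Fine education: lowest two levels merge into the analysis category
# "some high school or lower"; top two merge into the invitation category
# "high school or more".
EDUCATION4 = ("some_elementary", "elementary_some_hs", "hs_some_college", "college_plus")
EDUCATION3 = ("some_hs_or_less", "hs_some_college", "college_plus")
EDUCATION_INVITE = ("some_elementary", "elementary_some_hs", "hs_or_more")

# Fine age categories refine both groupings: analysis groups 18-39/40-59/60+
# and invitation groups 18-29/30-44/45-59/60+ share no common boundary at
# 39/40 vs 44/45, so a five-way partition carries both.
AGE5 = ("18-29", "30-39", "40-44", "45-59", "60+")
AGE_GROUP = ("18-39", "40-59", "60+")
AGE_INVITE = ("18-29", "30-44", "45-59", "60+")

REGIONS = ("north", "northeast", "southeast", "south", "midwest")
# 27 federative units in five macro-regions (7/9/4/3/4).
_REGION_FU_COUNTS = {"north": 7, "northeast": 9, "southeast": 4, "south": 3, "midwest": 4}
FUS = tuple(f"FU{i:02d}" for i in range(1, 28))
FU_TO_REGION: dict[str, str] = {}
_i = 0
for _region, _count in _REGION_FU_COUNTS.items():
    for _ in range(_count):
        FU_TO_REGION[FUS[_i]] = _region
        _i += 1

CAPITAL = ("capital", "noncapital")

EDUCATION4_TO_3 = {
    "some_elementary": "some_hs_or_less",
    "elementary_some_hs": "some_hs_or_less",
    "hs_some_college": "hs_some_college",
    "college_plus": "college_plus",
}
EDUCATION4_TO_INVITE = {
    "some_elementary": "some_elementary",
    "elementary_some_hs": "elementary_some_hs",
    "hs_some_college": "hs_or_more",
    "college_plus": "hs_or_more",
}
AGE5_TO_GROUP = {
    "18-29": "18-39",
    "30-39": "18-39",
    "40-44": "40-59",
    "45-59": "40-59",
    "60+": "60+",
}
AGE5_TO_INVITE = {
    "18-29": "18-29",
    "30-39": "30-44",
    "40-44": "30-44",
    "45-59": "45-59",
    "60+": "60+",
}

DERIVED_MAPS: dict[str, tuple[str, Mapping[str, str]]] = {
    "education3": ("education4", EDUCATION4_TO_3),
    "education_invite": ("education4", EDUCATION4_TO_INVITE),
    "age_group": ("age5", AGE5_TO_GROUP),
    "age_invite": ("age5", AGE5_TO_INVITE),
    "region": ("fu", FU_TO_REGION),
}


def default_population_marginals() -> PopulationMarginals:
    """Census-style (PNADC-2022) marginal targets for population generation.

    The fine education and age shares are chosen so that the merged analysis
    categories reproduce the printed census marginals exactly:
    education 44.5/38.2/17.3 and age 45.9/34.0/20.1.
    """
    return PopulationMarginals(
        (
            MarginalVariable("sex", SEX, (0.481, 0.519)),
            MarginalVariable("race", RACE, (0.434, 0.566)),
            MarginalVariable("education4", EDUCATION4, (0.305, 0.140, 0.382, 0.173)),
            MarginalVariable("age5", AGE5, (0.250, 0.209, 0.095, 0.245, 0.201)),
            MarginalVariable(
                "fu",
                FUS,
                tuple(
                    # region share split evenly across the region's FUs
                    _fu_share(fu) for fu in FUS
                ),
            ),
            MarginalVariable("capital", CAPITAL, (0.248, 0.752)),
        )
    )


_REGION_SHARES = {
    "north": 0.081,
    "northeast": 0.263,
    "southeast": 0.433,
    "south": 0.146,
    "midwest": 0.077,
}


def _fu_share(fu: str) -> float:
    region = FU_TO_REGION[fu]
    return _REGION_SHARES[region] / _REGION_FU_COUNTS[region]


def rake_targets() -> PopulationMarginals:
    """The four census marginals used for post-stratification raking:
    sex, analysis age group, three-level education, race."""
    return PopulationMarginals(
        (
            MarginalVariable("sex", SEX, (0.481, 0.519)),
            MarginalVariable("age_group", AGE_GROUP, (0.459, 0.340, 0.201)),
            MarginalVariable("education3", EDUCATION3, (0.445, 0.382, 0.173)),
            MarginalVariable("race", RACE, (0.434, 0.566)),
        )
    )


def add_derived_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Append the grouped/derived categorical columns (analysis and
    invitation groupings, macro-region) wherever their source column exists."""
    out = df.copy()
    for derived, (source, mapping) in DERIVED_MAPS.items():
        if source in out.columns:
            out[derived] = out[source].map(mapping)
            if out[derived].isna().any():
                bad = sorted(out.loc[out[derived].isna(), source].unique())
                raise ConfigurationError(
                    f"unknown {source} categories {bad} while deriving {derived}"
                )
    return out
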