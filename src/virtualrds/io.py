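"""Readers/writers for respondent and edge tables, plus config loading.

CSV dialect: comma-separated, UTF-8, header mandatory, "." decimal.
Respondent tables are validated on read and write: required columns,
integer waves >= 0, degrees >= 1, recruiter ids resolving to respondents
with wave exactly one less, optional category vocabulary checks, and the
one-respondent-per-household rule.  Errors name the offending rows.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .marginals import PopulationMarginals

__all__ = [
    "ValidationError",
    "REQUIRED_RESPONDENT_COLUMNS",
    "validate_respondents",
    "read_respondents",
    "write_respondents",
    "read_edges",
    "write_edges",
    "load_config",
]


class ValidationError(ValueError):
    pass


REQUIRED_RESPONDENT_COLUMNS = (
    "person_id",
    "wave",
    "recruiter_id",
    "household_id",
    "degree",
)


def validate_respondents(
    df: pd.DataFrame,
    *,
    vocabularies: PopulationMarginals | Mapping[str, tuple[str, ...]] | None = None,
    one_per_household: bool = True,
) -> None:
    missing = [c for c in REQUIRED_RESPONDENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    if df["person_id"].duplicated().any():
        rows = df.index[df["person_id"].duplicated()].tolist()
        raise ValidationError(f"duplicate person_id at rows {rows}")
    wave = df["wave"]
    bad = df.index[(wave < 0) | (wave != wave.astype(np.int64))].tolist()
    if bad:
        raise ValidationError(f"waves must be integers >= 0; bad rows {bad}")
    bad = df.index[df["degree"] < 1].tolist()
    if bad:
        raise ValidationError(f"degree must be >= 1; bad rows {bad}")

    rec = df["recruiter_id"]
    is_seed = rec.isna()
    bad = df.index[is_seed & (df["wave"] != 0)].tolist()
    if bad:
        raise ValidationError(f"respondents without recruiter must be wave 0; rows {bad}")
    bad = df.index[~is_seed & (df["wave"] == 0)].tolist()
    if bad:
        raise ValidationError(f"wave-0 respondents cannot have a recruiter; rows {bad}")
    known = df.set_index("person_id")["wave"]
    nonseed = df[~is_seed]
    orphan = nonseed.index[~nonseed["recruiter_id"].astype("Int64").isin(known.index)].tolist()
    if orphan:
        raise ValidationError(f"recruiter_id not among respondents; rows {orphan}")
    rw = known.reindex(nonseed["recruiter_id"].astype(np.int64)).to_numpy()
    bad = nonseed.index[nonseed["wave"].to_numpy() != rw + 1].tolist()
    if bad:
        raise ValidationError(
            f"recruitee wave must equal recruiter wave + 1; rows {bad}"
        )
    if one_per_household and df["household_id"].duplicated().any():
        rows = df.index[df["household_id"].duplicated()].tolist()
        raise ValidationError(f"households with more than one respondent; rows {rows}")

    if vocabularies is not None:
        if isinstance(vocabularies, PopulationMarginals):
            vocab = {v.name: v.categories for v in vocabularies.variables}
        else:
            vocab = dict(vocabularies)
        for var, cats in vocab.items():
            if var not in df.columns:
                continue
            ok = df[var].astype(str).isin([str(c) for c in cats])
            bad = df.index[~ok].tolist()
            if bad:
                raise ValidationError(
                    f"unknown {var!r} categories at rows {bad[:10]}"
                )


def read_respondents(
    path: str | Path,
    *,
    vocabularies: PopulationMarginals | Mapping[str, tuple[str, ...]] | None = None,
    one_per_household: bool = True,
) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    if "recruiter_id" in df.columns:
        df["recruiter_id"] = df["recruiter_id"].astype("Int64")
    validate_respondents(
        df, vocabularies=vocabularies, one_per_household=one_per_household
    )
    return df


def write_respondents(df: pd.DataFrame, path: str | Path) -> Path:
    validate_respondents(df, one_per_household=False)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
    return path


def read_edges(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    required = {"recruiter_id", "recruitee_id", "recruiter_wave", "recruitee_wave"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"edge table lacks columns {sorted(missing)}")
    bad = df.index[df["recruitee_wave"] != df["recruiter_wave"] + 1].tolist()
    if bad:
        raise ValidationError(f"edge wave arithmetic violated at rows {bad}")
    if df["recruitee_id"].duplicated().any():
        rows = df.index[df["recruitee_id"].duplicated()].tolist()
        raise ValidationError(f"recruitee with multiple recruiters at rows {rows}")
    return df


def write_edges(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
    return path


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
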