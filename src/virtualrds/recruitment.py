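"""Chain-referral (respondent-driven sampling) recruitment simulation.

Recruitment proceeds wave by wave over a fixed contact network.  Seeds
(wave 0) are chosen per federative unit by a diversity-maximising directed
choice.  In quota mode each seed sends one invitation into every stratum of
the sex x invitation-age x invitation-education cross product found among
its contacts; later-wave participants invite a uniform number of contacts
in a configured range.  Invitees answer with their individual response
propensity, at most once, and at most one respondent per household when the
household rule is active.  The recruiter of every respondent is recorded,
so the recruitment records form a forest rooted at the seeds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .marginals import AGE_INVITE, EDUCATION_INVITE, SEX, ConfigurationError

__all__ = [
    "RecruitmentConfig",
    "RecruitmentResult",
    "build_invitation_strata",
    "select_seeds",
    "run_recruitment",
]

STRATA_VARIABLES = ("sex", "age_invite", "education_invite")


@dataclass(frozen=True)
class RecruitmentConfig:
    """Field-procedure parameters.

    Defaults mirror a national online chain-referral survey: one seed per
    federative unit, 24 seed invitations (one per sex(2) x age(4) x
    education(3) stratum), three to five invitations per later participant,
    one respondent per household, recruitment stopped at the target size.
    """

    seeds_per_fu: int = 1
    total_seeds: int | None = None
    invitation_sex: tuple[str, ...] = SEX
    invitation_age: tuple[str, ...] = AGE_INVITE
    invitation_education: tuple[str, ...] = EDUCATION_INVITE
    seed_invitation_mode: Literal["strata"] | int = "strata"
    invites_min: int = 3
    invites_max: int = 5
    one_per_household: bool = True
    target_sample_size: int = 3805
    max_waves: int | None = None

    def __post_init__(self) -> None:
        for name, cats in (
            ("invitation_sex", self.invitation_sex),
            ("invitation_age", self.invitation_age),
            ("invitation_education", self.invitation_education),
        ):
            if len(cats) == 0:
                raise ConfigurationError(f"{name} category list is empty")
        if self.invites_min < 1:
            raise ConfigurationError("invites_min must be >= 1")
        if self.invites_max < self.invites_min:
            raise ConfigurationError("invites_max must be >= invites_min")
        if self.target_sample_size < 1:
            raise ConfigurationError("target sample size must be >= 1")

    @property
    def n_strata(self) -> int:
        return (
            len(self.invitation_sex)
            * len(self.invitation_age)
            * len(self.invitation_education)
        )


@dataclass
class RecruitmentResult:
    """Respondent and recruitment-edge tables plus run status."""

    respondents: pd.DataFrame
    edges: pd.DataFrame
    status: Literal["complete", "extinct", "max_waves"]
    warnings: list[str] = field(default_factory=list)


def build_invitation_strata(config: RecruitmentConfig) -> list[tuple[str, str, str]]:
    """Full invitation-stratum cross product, sex-major then age then
    education (deterministic order)."""
    return list(
        itertools.product(
            config.invitation_sex, config.invitation_age, config.invitation_education
        )
    )


def _diversity_order(
    candidates: pd.DataFrame, count: int, rng: np.random.Generator
) -> list[int]:
    """Greedy round-robin over demographic cells: no cell is used twice
    before every represented cell has been used once."""
    cells = candidates.groupby(
        list(STRATA_VARIABLES), observed=True, sort=True
    ).groups
    pools = {}
    for cell, idx in cells.items():
        arr = np.asarray(list(idx))
        rng.shuffle(arr)
        pools[cell] = list(arr)
    chosen: list[int] = []
    cell_order = sorted(pools)
    while len(chosen) < count and any(pools.values()):
        for cell in cell_order:
            if pools[cell]:
                chosen.append(int(pools[cell].pop()))
                if len(chosen) == count:
                    break
    return chosen


def select_seeds(
    population: pd.DataFrame,
    config: RecruitmentConfig,
    *,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Directed choice of seeds maximizing sociodemographic diversity.

    With ``total_seeds`` unset, picks ``seeds_per_fu`` in every federative
    unit (error naming any FU without eligible people); with ``total_seeds``
    set, picks that many population-wide by the same round-robin rule.
    Returns person ids, deterministic under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    missing = [v for v in STRATA_VARIABLES if v not in population.columns]
    if missing:
        raise ConfigurationError(f"population lacks stratum columns {missing}")
    if config.total_seeds is not None:
        rows = _diversity_order(population, config.total_seeds, rng)
        return population.loc[rows, "person_id"].to_numpy()
    if "fu" not in population.columns:
        raise ConfigurationError("population lacks an 'fu' column")
    fu_col = population["fu"]
    if isinstance(fu_col.dtype, pd.CategoricalDtype):
        fu_levels = list(fu_col.cat.categories)
    else:
        fu_levels = sorted(fu_col.unique())
    chosen: list[int] = []
    for fu in fu_levels:
        group = population[fu_col == fu]
        if len(group) == 0:
            raise ConfigurationError(f"federative unit {fu!r} has no eligible person")
        rows = _diversity_order(group, config.seeds_per_fu, rng)
        if len(rows) < config.seeds_per_fu:
            raise ConfigurationError(
                f"federative unit {fu!r} has only {len(rows)} eligible people, "
                f"{config.seeds_per_fu} seeds requested"
            )
        chosen.extend(rows)
    return population.loc[chosen, "person_id"].to_numpy()


def _adjacency(edges: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """CSR-style neighbour arrays from an undirected edge list."""
    if len(edges) == 0:
        return np.zeros(n + 1, dtype=np.int64), np.empty(0, dtype=np.int64)
    both = np.concatenate([edges, edges[:, ::-1]])
    order = np.lexsort((both[:, 1], both[:, 0]))
    both = both[order]
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(indptr, both[:, 0] + 1, 1)
    indptr = np.cumsum(indptr)
    return indptr, both[:, 1].copy()


def run_recruitment(
    population: pd.DataFrame,
    network_edges: np.ndarray,
    config: RecruitmentConfig,
    *,
    seed: int | np.random.Generator = 0,
    seeds: np.ndarray | None = None,
) -> RecruitmentResult:
    """Simulate the wave-by-wave recruitment process.

    Waves are processed breadth-first; within a wave recruiters act in
    person-id order (reproducibility).  A person may be invited repeatedly
    but responds at most once; the first successful invitation fixes the
    recruiter.  Recruitment stops at the target sample size, at ``max_waves``,
    or when a wave produces no respondent (partial sample, flagged, never an
    exception).
    """
    rng = np.random.default_rng(seed)
    pop = population.reset_index(drop=True)
    if not (pop["person_id"].to_numpy() == np.arange(len(pop))).all():
        pop = pop.set_index("person_id", drop=False).sort_index().reset_index(drop=True)
    n = len(pop)
    if "propensity" not in pop.columns:
        pop = pop.copy()
        pop["propensity"] = 1.0
    if "degree" not in pop.columns:
        raise ConfigurationError("population lacks realized degrees; build the network first")

    indptr, neigh = _adjacency(np.asarray(network_edges, dtype=np.int64), n)
    if seeds is None:
        seeds = select_seeds(pop, config, seed=rng)
    seeds = np.asarray(seeds, dtype=np.int64)

    propensity = pop["propensity"].to_numpy(float)
    household = pop["household_id"].to_numpy()
    stratum_of = np.array(
        ["|".join(t) for t in zip(*(pop[v].astype(str) for v in STRATA_VARIABLES))],
        dtype=object,
    )

    responded = np.zeros(n, dtype=bool)
    wave_of = np.full(n, -1, dtype=np.int64)
    recruiter_of = np.full(n, -1, dtype=np.int64)
    stratum_label = np.full(n, "", dtype=object)
    used_households: set = set()

    warnings: list[str] = []
    target = config.target_sample_size

    current: list[int] = []
    for s in seeds:
        if responded[s]:
            continue
        if config.one_per_household and household[s] in used_households:
            warnings.append(f"seed {s} skipped: household already represented")
            continue
        responded[s] = True
        wave_of[s] = 0
        used_households.add(household[s])
        current.append(int(s))
        if responded.sum() >= target:
            break

    strata = build_invitation_strata(config)
    status = "complete" if responded.sum() >= target else None
    wave = 0
    while status is None:
        nxt: list[int] = []
        for rec in sorted(current):
            if status is not None:
                break
            contacts = neigh[indptr[rec]: indptr[rec + 1]]
            if len(contacts) == 0:
                continue
            if wave == 0 and config.seed_invitation_mode == "strata":
                invitees = []
                contact_strata = stratum_of[contacts]
                for st in strata:
                    label = "|".join(st)
                    pool = contacts[contact_strata == label]
                    if len(pool) == 0:
                        continue  # no contact in this stratum: slot skipped
                    invitees.append((int(rng.choice(pool)), label))
            else:
                if wave == 0 and isinstance(config.seed_invitation_mode, int):
                    k = config.seed_invitation_mode
                else:
                    k = int(rng.integers(config.invites_min, config.invites_max + 1))
                k = min(k, len(contacts))
                picks = rng.choice(contacts, size=k, replace=False)
                invitees = [(int(p), "") for p in picks]
            for person, st_label in invitees:
                if responded[person]:
                    continue
                if config.one_per_household and household[person] in used_households:
                    continue
                if rng.random() >= propensity[person]:
                    continue
                responded[person] = True
                wave_of[person] = wave + 1
                recruiter_of[person] = rec
                if wave == 0:
                    stratum_label[person] = st_label
                used_households.add(household[person])
                nxt.append(person)
                if responded.sum() >= target:
                    status = "complete"
                    break
        wave += 1
        if status is None and not nxt:
            status = "extinct"
            warnings.append(
                f"recruitment died out at wave {wave} with "
                f"{int(responded.sum())} of {target} respondents"
            )
        if status is None and config.max_waves is not None and wave >= config.max_waves:
            status = "max_waves"
        current = nxt

    resp_idx = np.flatnonzero(responded)
    resp = pop.iloc[resp_idx].copy()
    resp["wave"] = wave_of[resp_idx]
    rid = recruiter_of[resp_idx]
    resp["recruiter_id"] = pd.array(
        [r if r >= 0 else None for r in rid], dtype="Int64"
    )
    resp["invitation_stratum"] = stratum_label[resp_idx]
    resp = resp.sort_values(["wave", "person_id"]).reset_index(drop=True)

    nonseed = resp[resp["recruiter_id"].notna()]
    edges = pd.DataFrame(
        {
            "recruiter_id": nonseed["recruiter_id"].astype(np.int64).to_numpy(),
            "recruitee_id": nonseed["person_id"].to_numpy(),
            "recruitee_wave": nonseed["wave"].to_numpy(),
        }
    )
    edges["recruiter_wave"] = edges["recruitee_wave"] - 1
    edges = edges[["recruiter_id", "recruitee_id", "recruiter_wave", "recruitee_wave"]]
    edges = edges.sort_values(["recruitee_wave", "recruitee_id"]).reset_index(drop=True)
    return RecruitmentResult(resp, edges, status, warnings)
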