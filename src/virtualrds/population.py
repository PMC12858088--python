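"""Synthetic finite populations, outcomes, and homophilous contact networks.

The generator produces a population table whose categorical marginals match
configured targets, attaches binary health outcomes whose prevalence varies
by demographic cell through a logistic model, assigns household identifiers
and response propensities, and builds an undirected social contact network
with tunable per-trait homophily.

Joint dependence model
----------------------
Only marginal distributions are configured (as in published census tables);
the joint distribution is a log-linear model: a base affinity tensor
(all-ones under independence, or exp of user-supplied two-way log-affinities)
is scaled by iterative proportional fitting until every axis matches its
marginal targets.  Cell probabilities therefore reproduce the marginals
exactly in expectation regardless of the association structure.

Homophily model
---------------
Each person emits "stubs" (half-edges).  For a trait with homophily strength
``h in (0, 1]``, each stub independently constrains its partner to share the
person's category with probability ``h``; otherwise the partner is drawn
degree-proportionally from the whole population (proportionate mixing).
For ``h < 0`` the constraint is to *differ* with probability ``|h|``.  Under
this construction the probability that a contact of a category-``a`` person
is also category ``a`` is ``h + (1-h) * s_a`` (``s_a`` = degree-weighted
population share), so the Heckathorn-style homophily index of the contact
process equals ``h`` by design.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .marginals import (
    ConfigurationError,
    MarginalVariable,
    PopulationMarginals,
    add_derived_columns,
)

__all__ = [
    "OutcomeSpec",
    "NetworkSpec",
    "generate_population",
    "attach_outcomes",
    "assign_response_propensity",
    "build_social_network",
]


@dataclass(frozen=True)
class OutcomeSpec:
    """A binary outcome with cell-dependent prevalence.

    ``baseline`` is the prevalence at the reference cell (all offsets zero)
    on the probability scale; ``offsets`` maps variable name -> category ->
    additive log-odds shift.
    """

    name: str
    baseline: float
    offsets: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline <= 1.0:
            raise ConfigurationError(
                f"outcome {self.name!r}: baseline {self.baseline} outside [0, 1]"
            )


@dataclass(frozen=True)
class NetworkSpec:
    """Contact-network configuration.

    mean_degree
        Expected number of contacts per person.
    dispersion
        Negative-binomial shape k; variance of target degree is
        ``m + m^2 / k`` (smaller k = heavier tail).
    homophily
        Per-trait assortative mixing weight in [-1, 1]; 0 means
        proportionate (random) mixing on that trait.
    """

    mean_degree: float = 12.0
    dispersion: float = 5.0
    homophily: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mean_degree < 1:
            raise ConfigurationError("mean degree must be >= 1")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        for trait, h in self.homophily.items():
            if not -1.0 <= h <= 1.0:
                raise ConfigurationError(
                    f"homophily for {trait!r} must lie in [-1, 1], got {h}"
                )


def _ipf_tensor(base: np.ndarray, targets: Sequence[np.ndarray],
                max_iter: int = 500, tol: float = 1e-12) -> np.ndarray:
    """Scale ``base`` (nonnegative tensor) so every axis marginal matches
    ``targets``; classical iterative proportional fitting on arrays."""
    p = base / base.sum()
    axes = list(range(p.ndim))
    for _ in range(max_iter):
        max_dev = 0.0
        for ax, t in zip(axes, targets):
            other = tuple(a for a in axes if a != ax)
            cur = p.sum(axis=other)
            max_dev = max(max_dev, float(np.abs(cur - t).max()))
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(cur > 0, t / np.where(cur > 0, cur, 1.0), 0.0)
            shape = [1] * p.ndim
            shape[ax] = -1
            p = p * ratio.reshape(shape)
        if max_dev < tol:
            break
    return p / p.sum()


def generate_population(
    marginals: PopulationMarginals,
    n_pop: int,
    *,
    seed: int | np.random.Generator = 0,
    association: Mapping[tuple[str, str], np.ndarray] | None = None,
    household_mean: float = 3.0,
    household_max: int = 10,
    household_by: str | None = "fu",
) -> pd.DataFrame:
    """Sample ``n_pop`` individuals whose categorical marginals match targets.

    Parameters
    ----------
    association
        Optional ``{(var_a, var_b): log-affinity matrix}`` inducing two-way
        dependence between variables; independence when omitted.  Marginals
        remain exact in expectation (IPF re-calibrates the joint).
    household_mean, household_max
        Household sizes are truncated-geometric with this mean, capped at
        ``household_max``; one household never spans two ``household_by``
        groups (households are geographically coherent by default).

    Returns a DataFrame with one row per person: ``person_id``, one column
    per marginal variable, derived grouping columns, and ``household_id``.
    """
    if n_pop < 1:
        raise ConfigurationError("n_pop must be >= 1")
    rng = np.random.default_rng(seed)
    variables = list(marginals.variables)
    names = [v.name for v in variables]
    shape = [len(v.categories) for v in variables]

    base = np.ones(shape, dtype=float)
    if association:
        for (va, vb), logaff in association.items():
            ia, ib = names.index(va), names.index(vb)
            logaff = np.asarray(logaff, dtype=float)
            expected = (shape[ia], shape[ib])
            if logaff.shape != expected:
                raise ConfigurationError(
                    f"association for ({va}, {vb}) must have shape {expected}"
                )
            bshape = [1] * len(shape)
            bshape[ia], bshape[ib] = shape[ia], shape[ib]
            axes_order = [ia, ib]
            mat = np.exp(logaff)
            # broadcast the 2-way affinity into the full tensor
            expanded = np.ones(shape)
            mov = np.moveaxis(expanded, axes_order, [0, 1])
            mov *= mat.reshape(mat.shape + (1,) * (len(shape) - 2))
            base = base * expanded

    targets = [np.asarray(v.proportions, dtype=float) for v in variables]
    joint = _ipf_tensor(base, targets)

    counts = rng.multinomial(n_pop, joint.ravel())
    cell_index = np.repeat(np.arange(joint.size), counts)
    codes = np.unravel_index(cell_index, joint.shape)

    data = {}
    for v, code in zip(variables, codes):
        data[v.name] = pd.Categorical.from_codes(code, categories=list(v.categories))
    df = pd.DataFrame(data)
    df = add_derived_columns(df)

    # households: geographically coherent, truncated-geometric sizes;
    # shuffle within each geographic group so households mix demographics
    shuffle_key = rng.random(n_pop)
    if household_by is not None and household_by in df.columns:
        order = np.lexsort((shuffle_key, df[household_by].astype(str).to_numpy()))
    else:
        order = np.argsort(shuffle_key)
    df = df.iloc[order].reset_index(drop=True)
    df.insert(0, "person_id", np.arange(n_pop))
    df["household_id"] = _household_ids(n_pop, household_mean, household_max, rng)
    if household_by is not None and household_by in df.columns:
        # never let a household straddle two geographic groups
        grp = df[household_by].astype(str).to_numpy()
        boundary = np.r_[False, grp[1:] != grp[:-1]]
        bump = np.cumsum(boundary)
        df["household_id"] = pd.factorize(df["household_id"].to_numpy() * (bump.max() + 1) + bump)[0]
    return df


def _household_ids(n: int, mean: float, cap: int, rng: np.random.Generator) -> np.ndarray:
    if mean < 1:
        raise ConfigurationError("household mean size must be >= 1")
    p = 1.0 / mean
    sizes = []
    total = 0
    while total < n:
        s = int(min(rng.geometric(p), cap))
        sizes.append(s)
        total += s
    ids = np.repeat(np.arange(len(sizes)), sizes)[:n]
    return ids


def attach_outcomes(
    population: pd.DataFrame,
    specs: Sequence[OutcomeSpec],
    *,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw binary outcome columns from a per-cell logistic prevalence model.

    Each person's probability is ``expit(logit(baseline) + sum of offsets)``
    over that person's categories; the overall prevalence is therefore the
    cell-share-weighted mixture of cell prevalences.
    """
    rng = np.random.default_rng(seed)
    out = population.copy()
    for spec in specs:
        if spec.baseline == 0.0 and not spec.offsets:
            out[spec.name] = np.zeros(len(out), dtype=bool)
            continue
        if spec.baseline == 1.0 and not spec.offsets:
            out[spec.name] = np.ones(len(out), dtype=bool)
            continue
        eta = np.full(len(out), logit(spec.baseline))
        for var, cat_offsets in spec.offsets.items():
            if var not in out.columns:
                raise ConfigurationError(
                    f"outcome {spec.name!r}: unknown variable {var!r}"
                )
            col = out[var].astype(str)
            known = set(col.unique())
            unknown = set(cat_offsets) - known
            if unknown:
                raise ConfigurationError(
                    f"outcome {spec.name!r}: categories {sorted(unknown)} not "
                    f"present in variable {var!r}"
                )
            eta = eta + col.map(lambda c: cat_offsets.get(c, 0.0)).to_numpy(float)
        out[spec.name] = rng.random(len(out)) < expit(eta)
    return out


def assign_response_propensity(
    population: pd.DataFrame,
    *,
    by: str | None = "education4",
    intercept: float = -0.6,
    slope: float = 0.35,
    constant: float | None = None,
) -> pd.DataFrame:
    """Attach the probability that an invited person answers.

    Default is logistic in the ordered education level (lowest level
    under-responds), emulating the differential web-survey response that
    under-represents low-education groups.  ``constant`` overrides with a
    single value for every person.
    """
    out = population.copy()
    if constant is not None:
        if not 0.0 <= constant <= 1.0:
            raise ConfigurationError("constant propensity must be in [0, 1]")
        out["propensity"] = float(constant)
        return out
    if by is None or by not in out.columns:
        raise ConfigurationError(f"propensity variable {by!r} not in population")
    level = out[by].cat.codes.to_numpy() if isinstance(out[by].dtype, pd.CategoricalDtype) \
        else pd.factorize(out[by], sort=True)[0]
    out["propensity"] = expit(intercept + slope * level)
    return out


# ---------------------------------------------------------------------------
# Contact network
# ---------------------------------------------------------------------------

def build_social_network(
    population: pd.DataFrame,
    spec: NetworkSpec,
    *,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Build an undirected simple contact network with per-trait homophily.

    Returns ``(edges, population)`` where ``edges`` is an ``(m, 2)`` integer
    array of person-id pairs (each undirected edge once, no self-loops) and
    the returned population carries the realized ``degree`` column (floored
    at 1, since a chain-referral respondent always reports at least one
    contact).
    """
    if len(population) == 0:
        raise ConfigurationError("population is empty")
    rng = np.random.default_rng(seed)
    n = len(population)

    m = spec.mean_degree
    k = spec.dispersion
    target = rng.negative_binomial(k, k / (k + m), size=n)
    target = np.maximum(target, 1)
    # each node emits ~half its target degree as stubs; the other half
    # arrives as partner choices, keeping E[degree] = mean_degree
    stubs = rng.binomial(target, 0.5)

    traits = [(t, h) for t, h in spec.homophily.items() if h != 0.0]
    for t, _ in traits:
        if t not in population.columns:
            raise ConfigurationError(f"homophily trait {t!r} not in population")
    codes = {}
    ncat = {}
    for t, _ in traits:
        c, cats = pd.factorize(population[t], sort=True)
        codes[t] = c.astype(np.int64)
        ncat[t] = len(cats)

    total = int(stubs.sum())
    src = np.repeat(np.arange(n), stubs)

    # per-stub constraints: same-category (h>0) or different-category (h<0)
    same_req = {}
    diff_req = {}
    for t, h in traits:
        u = rng.random(total)
        if h > 0:
            same_req[t] = u < h
        else:
            diff_req[t] = u < -h

    # group stubs by their same-category constraint signature and sample
    # partners degree-proportionally within each pool
    weights = target.astype(float)
    partner = np.empty(total, dtype=np.int64)

    same_traits = list(same_req)
    if same_traits:
        sig = np.zeros(total, dtype=np.int64)
        mult = 1
        for t in same_traits:
            # signature digit: category+1 when constrained, 0 when free
            digit = np.where(same_req[t], codes[t][src] + 1, 0)
            sig = sig + digit * mult
            mult *= ncat[t] + 1
    else:
        sig = np.zeros(total, dtype=np.int64)

    cum_all = np.cumsum(weights)
    pool_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for s in np.unique(sig):
        idx = np.flatnonzero(sig == s)
        if s == 0:
            pool, cw = np.arange(n), cum_all
        else:
            key = s
            if key not in pool_cache:
                mask = np.ones(n, dtype=bool)
                rem = s
                for t in same_traits:
                    base = ncat[t] + 1
                    digit = rem % base
                    rem //= base
                    if digit > 0:
                        mask &= codes[t] == (digit - 1)
                pool = np.flatnonzero(mask)
                cw = np.cumsum(weights[pool])
                pool_cache[key] = (pool, cw)
            pool, cw = pool_cache[key]
        if len(pool) == 0:
            partner[idx] = rng.integers(0, n, size=len(idx))
            continue
        u = rng.random(len(idx)) * cw[-1]
        partner[idx] = pool[np.searchsorted(cw, u)]

    # different-category constraints and self-loops: rejection resampling
    # from the stub's own pool (bounded retries)
    for _ in range(50):
        bad = partner == src
        for t, req in diff_req.items():
            bad |= req & (codes[t][partner] == codes[t][src])
        if not bad.any():
            break
        idx = np.flatnonzero(bad)
        u = rng.random(len(idx)) * cum_all[-1]
        partner[idx] = np.searchsorted(cum_all, u)
    keep = partner != src
    a = np.minimum(src[keep], partner[keep])
    b = np.maximum(src[keep], partner[keep])
    edges = np.unique(np.stack([a, b], axis=1), axis=0)

    deg = np.bincount(edges.ravel(), minlength=n)
    pop = population.copy()
    pop["degree"] = np.maximum(deg, 1)
    return edges, pop
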