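"""Weighted prevalence estimation with chain-bootstrap confidence intervals.

The chain (Salganik-style) bootstrap regrows recruitment chains: a replicate
of size n is built by drawing a seed with replacement from the observed
seeds and repeatedly extending with a respondent drawn, with replacement,
from the pool of observed recruitees whose recruiter shared the current
member's category; a fresh resampled seed starts whenever the drawn seed's
observed chain length is exhausted.  This mimics the Markov process that
generated the sample, so replicate variability reflects the clustered,
unequal-probability design.  Percentile intervals are taken from the
replicate estimates.

A degree-weighted (Volz–Heckathorn style, inverse personal network size)
estimator is included as a standard chain-referral cross-check, and the
classical prevalence sample-size formula (optionally inflated by a design
effect) covers survey planning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EstimationError",
    "WeightedEstimate",
    "SampleSizeResult",
    "weighted_prevalence",
    "chain_bootstrap",
    "percentile_ci",
    "bootstrap_prevalence",
    "degree_weighted_estimate",
    "srs_sample_size",
]


class EstimationError(ValueError):
    pass


@dataclass
class WeightedEstimate:
    """A weighted proportion with its chain-bootstrap percentile CI."""

    outcome: str
    estimate: float
    ci_lower: float
    ci_upper: float
    level: float
    replicates: np.ndarray
    n_replicates: int
    seed: int | None
    design_effect: float | None = None

    def as_percent(self, digits: int = 1) -> tuple[float, float, float]:
        """Point and interval on the percentage scale, survey-table style."""
        r = lambda x: round(100.0 * x, digits)
        return r(self.estimate), r(self.ci_lower), r(self.ci_upper)


def weighted_prevalence(y: np.ndarray, weights: np.ndarray) -> float:
    """Hajek-style weighted proportion ``sum(w y) / sum(w)``."""
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if len(y) == 0:
        raise EstimationError("empty sample")
    if len(y) != len(w):
        raise EstimationError("outcome and weight vectors differ in length")
    if (w <= 0).any():
        raise EstimationError("weights must be positive")
    return float(np.sum(w * y) / np.sum(w))


def degree_weighted_estimate(y: np.ndarray, degrees: np.ndarray) -> float:
    """Inverse-degree weighted proportion ``sum(y/d) / sum(1/d)``: the
    standard correction for degree-proportional inclusion in chain referral."""
    y = np.asarray(y, dtype=float)
    d = np.asarray(degrees, dtype=float)
    if len(y) == 0:
        raise EstimationError("empty sample")
    if (d < 1).any():
        raise EstimationError("degrees must be >= 1")
    return float(np.sum(y / d) / np.sum(1.0 / d))


def percentile_ci(replicates: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed percentile interval (linear-interpolation quantiles)."""
    reps = np.asarray(replicates, dtype=float)
    if len(reps) < 2:
        raise EstimationError("need at least 2 bootstrap replicates")
    if not 0.0 < level < 1.0:
        raise EstimationError("level must lie in (0, 1)")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def _chain_roots(respondents: pd.DataFrame) -> np.ndarray:
    """Positional index of the seed at the root of each respondent's chain."""
    pos = {pid: i for i, pid in enumerate(respondents["person_id"].to_numpy())}
    rec = respondents["recruiter_id"].to_numpy()
    wave = respondents["wave"].to_numpy()
    n = len(respondents)
    root = np.arange(n)
    for i in np.argsort(wave, kind="stable"):
        r = rec[i]
        if r is not None and not pd.isna(r):
            root[i] = root[pos[int(r)]]
    return root


def chain_bootstrap(
    respondents: pd.DataFrame,
    edges: pd.DataFrame,
    trait: str,
    B: int = 1000,
    *,
    seed: int | np.random.Generator = 0,
    size: int | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Draw ``B`` chain-bootstrap replicates.

    Returns ``(indices, warnings)`` where ``indices`` is a ``(B, size)``
    array of positional indices into ``respondents``.  Pools are the
    observed recruitees grouped by their recruiter's category; a category
    with no recruitee pool falls back to the unconditional respondent pool
    with a logged warning.
    """
    rng = np.random.default_rng(seed)
    n = len(respondents)
    size = n if size is None else size
    if n == 0 or B < 1:
        raise EstimationError("empty sample or B < 1")
    if trait not in respondents.columns:
        raise EstimationError(f"trait {trait!r} not in respondent table")
    warnings: list[str] = []

    cats, cat_codes = np.unique(respondents[trait].astype(str).to_numpy(), return_inverse=True)
    k = len(cats)
    pos = {pid: i for i, pid in enumerate(respondents["person_id"].to_numpy())}

    pools: list[np.ndarray] = []
    if len(edges):
        rec_pos = np.array([pos[int(r)] for r in edges["recruiter_id"]])
        ree_pos = np.array([pos[int(r)] for r in edges["recruitee_id"]])
        rec_cat = cat_codes[rec_pos]
        for c in range(k):
            pools.append(ree_pos[rec_cat == c])
    else:
        pools = [np.empty(0, dtype=int)] * k
    everyone = np.arange(n)
    for c in range(k):
        if len(pools[c]) == 0:
            warnings.append(
                f"no recruitees observed under recruiter category {cats[c]!r}; "
                "falling back to the unconditional pool"
            )
            pools[c] = everyone

    seeds_mask = respondents["recruiter_id"].isna().to_numpy()
    seed_pos = np.flatnonzero(seeds_mask)
    if len(seed_pos) == 0:
        raise EstimationError("no seeds (wave-0 respondents) in the sample")
    roots = _chain_roots(respondents)
    chain_sizes = np.bincount(roots, minlength=n)[seed_pos]

    out = np.empty((B, size), dtype=np.int64)
    cur_cat = np.zeros(B, dtype=np.int64)
    remaining = np.zeros(B, dtype=np.int64)
    for j in range(size):
        need = remaining <= 0
        if need.any():
            pick = rng.integers(0, len(seed_pos), int(need.sum()))
            sel = seed_pos[pick]
            out[need, j] = sel
            remaining[need] = chain_sizes[pick]
            cur_cat[need] = cat_codes[sel]
        cont = ~need
        if cont.any():
            prev_cat = cur_cat.copy()  # freeze the state for this slot
            for c in range(k):
                m = cont & (prev_cat == c)
                nm = int(m.sum())
                if nm == 0:
                    continue
                idx = pools[c][rng.integers(0, len(pools[c]), nm)]
                out[m, j] = idx
                cur_cat[m] = cat_codes[idx]
        remaining -= 1
    return out, warnings


def _replicate_rake(
    idx: np.ndarray,
    y: np.ndarray,
    respondents: pd.DataFrame,
    margins,  # PopulationMarginals
    max_iter: int = 100,
    tol: float = 1e-10,
) -> np.ndarray:
    """Re-rake every bootstrap replicate and return its calibrated estimate.

    Raked weights are constant within a joint margin cell, so calibration
    reduces to iterative proportional fitting on the replicates' cell-count
    matrix — vectorised across all B replicates at once.  Respondents with a
    category outside a margin's target list occupy cells that margin never
    rescales.
    """
    B, size = idx.shape
    n_resp = len(respondents)
    level_maps = []  # (codes per respondent, targets incl. unlisted slot)
    n_cells = 1
    for var in margins.variables:
        col = respondents[var.name].astype(str).to_numpy()
        cats = list(var.categories)
        codes = np.full(n_resp, len(cats), dtype=np.int64)  # unlisted slot
        for j, c in enumerate(cats):
            codes[col == c] = j
        k = len(cats) + 1
        level_maps.append((codes, np.asarray(var.proportions, float), k))
        n_cells *= k
    cell = np.zeros(n_resp, dtype=np.int64)
    mult = 1
    cell_levels = []
    for codes, targets, k in level_maps:
        cell = cell + codes * mult
        cell_levels.append((mult, k, targets))
        mult *= k

    draw_cells = cell[idx]
    rows = np.repeat(np.arange(B), size)
    counts = np.zeros((B, n_cells))
    ysums = np.zeros((B, n_cells))
    np.add.at(counts, (rows, draw_cells.ravel()), 1.0)
    np.add.at(ysums, (rows, draw_cells.ravel()), y[idx].ravel())

    # level index of each cell on each margin axis
    cell_ids = np.arange(n_cells)
    axis_levels = []
    for mult_, k, targets in cell_levels:
        axis_levels.append(((cell_ids // mult_) % k, k, targets))

    w = np.ones((B, n_cells))
    for _ in range(max_iter):
        max_dev = 0.0
        for lev, k, targets in axis_levels:
            mass = np.zeros((B, k))
            cw = counts * w
            for level in range(k - 1):  # last slot = unlisted, untouched
                mass[:, level] = cw[:, lev == level].sum(axis=1)
            listed = mass[:, : k - 1].sum(axis=1)
            total = cw.sum(axis=1)
            t = targets / targets.sum()
            desired = listed[:, None] * t[None, :]
            with np.errstate(divide="ignore", invalid="ignore"):
                factor = np.where(mass[:, : k - 1] > 0, desired / np.where(
                    mass[:, : k - 1] > 0, mass[:, : k - 1], 1.0), 1.0)
            dev = np.abs(
                np.where(mass[:, : k - 1] > 0,
                         mass[:, : k - 1] / total[:, None] -
                         desired / total[:, None], 0.0)
            ).max()
            max_dev = max(max_dev, float(dev))
            full = np.concatenate([factor, np.ones((B, 1))], axis=1)
            w *= full[:, lev]
        if max_dev < tol:
            break
    cw = counts * w
    with np.errstate(invalid="ignore"):
        reps = (ysums * w).sum(axis=1) / cw.sum(axis=1)
    return reps


def bootstrap_prevalence(
    respondents: pd.DataFrame,
    edges: pd.DataFrame,
    outcome: str,
    *,
    weights: np.ndarray | None = None,
    trait: str = "race",
    B: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
    include_seeds: bool = True,
    calibrate_margins=None,  # PopulationMarginals | None
) -> WeightedEstimate:
    """Weighted prevalence with a chain-bootstrap percentile CI and the
    implied design effect.

    With ``calibrate_margins`` given, every replicate is re-raked to those
    marginal targets before its estimate is taken — the full estimation
    procedure (calibration included) is repeated inside the bootstrap, as a
    survey bootstrap should.  Otherwise the supplied weights travel with
    the resampled individuals.  ``include_seeds`` False drops wave-0
    respondents from the point estimate but the bootstrap still restarts
    chains from the observed seeds.
    """
    y = respondents[outcome].to_numpy(dtype=float)
    w = np.ones(len(respondents)) if weights is None else np.asarray(weights, float)
    est_mask = np.ones(len(respondents), dtype=bool)
    if not include_seeds:
        est_mask = ~respondents["recruiter_id"].isna().to_numpy()
    point = weighted_prevalence(y[est_mask], w[est_mask])

    seed_int = seed if isinstance(seed, (int, np.integer)) else None
    idx, _ = chain_bootstrap(respondents, edges, trait, B, seed=seed)
    if calibrate_margins is not None:
        reps = _replicate_rake(idx, y, respondents, calibrate_margins)
    else:
        wy = w[idx] * y[idx]
        reps = wy.sum(axis=1) / w[idx].sum(axis=1)
    lo, hi = percentile_ci(reps, level)

    deff = None
    if 0.0 < point < 1.0:
        deff = float(np.var(reps, ddof=1) / (point * (1 - point) / len(respondents)))
    return WeightedEstimate(
        outcome=outcome,
        estimate=point,
        ci_lower=float(np.clip(lo, 0, 1)),
        ci_upper=float(np.clip(hi, 0, 1)),
        level=level,
        replicates=reps,
        n_replicates=B,
        seed=seed_int,
        design_effect=deff,
    )


@dataclass(frozen=True)
class SampleSizeResult:
    """Prevalence sample size: exact ceiling, conventional rounding to the
    nearest hundred, and the design-effect-inflated size."""

    raw: int
    rounded_hundred: int
    design_effect: float
    with_design_effect: int


def srs_sample_size(
    p: float, error: float, level: float = 0.95, *, design_effect: float = 1.0
) -> SampleSizeResult:
    """Minimum n to estimate a prevalence ``p`` within ``+/- error`` at the
    given two-sided confidence level: ``n0 = z^2 p (1-p) / error^2``.

    The design-effect-inflated size multiplies the rounded n0, the
    convention used when planning peer-recruitment samples.
    """
    if not 0.0 < p < 1.0:
        raise EstimationError("p must lie strictly in (0, 1)")
    if error <= 0:
        raise EstimationError("error must be positive")
    if not 0.0 < level < 1.0:
        raise EstimationError("level must lie in (0, 1)")
    if design_effect <= 0:
        raise EstimationError("design effect must be positive")
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    n0 = z * z * p * (1.0 - p) / (error * error)
    raw = int(math.ceil(n0))
    rounded = int(round(raw / 100.0)) * 100
    return SampleSizeResult(
        raw=raw,
        rounded_hundred=rounded,
        design_effect=float(design_effect),
        with_design_effect=int(round(rounded * design_effect)),
    )
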