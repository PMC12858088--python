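"""Markov-chain diagnostics for chain-referral recruitment.

Chain-referral recruitment is modelled as a Markov process on a categorical
trait: the category of a recruitee depends only on the category of its
recruiter.  These diagnostics estimate the recruiter-to-recruitee transition
matrix, its stationary (equilibrium) distribution, the wave at which the
sample composition stops depending on the seeds, per-category homophily
indices, and the design effect of the resulting complex sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import linalg

__all__ = [
    "TransitionMatrix",
    "EquilibriumReport",
    "ConvergenceReport",
    "DiagnosticsError",
    "transition_matrix",
    "equilibrium_distribution",
    "convergence_wave",
    "homophily_index",
    "design_effect",
    "cluster_robust_variance",
    "PLANNING_DESIGN_EFFECT",
]

#: Conventional planning value for the design effect of peer recruitment,
#: used when sizing a chain-referral sample before any data exist.
PLANNING_DESIGN_EFFECT = 2.0


class DiagnosticsError(ValueError):
    """Raised when a diagnostic is undefined for the given input."""


@dataclass
class TransitionMatrix:
    """Row-stochastic recruiter-category -> recruitee-category matrix."""

    trait: str
    categories: tuple[str, ...]
    matrix: np.ndarray          # rows with no pairs are NaN, flagged below
    counts: np.ndarray          # pair counts per (recruiter, recruitee) cell
    undefined_rows: tuple[str, ...] = ()

    @property
    def k(self) -> int:
        return len(self.categories)


@dataclass
class EquilibriumReport:
    distribution: np.ndarray
    categories: tuple[str, ...]


@dataclass
class ConvergenceReport:
    """Empirical and theoretical wave of convergence to equilibrium."""

    empirical_wave: int | None
    theoretical_wave: int | None
    tolerance: float
    wave_distances: dict[int, float]    # TV distance of each wave to pi*
    last_distance: float


def transition_matrix(
    respondents: pd.DataFrame, edges: pd.DataFrame, trait: str
) -> TransitionMatrix:
    """Maximum-likelihood (row-normalised pair count) transition estimate.

    Rows whose recruiter category produced no pairs are reported as
    undefined (NaN), never fabricated.
    """
    if len(edges) == 0:
        raise DiagnosticsError("no recruiter-recruitee pairs: transition matrix undefined")
    if trait not in respondents.columns:
        raise DiagnosticsError(f"trait {trait!r} not in respondent table")
    cat_of = respondents.set_index("person_id")[trait].astype(str)
    categories = tuple(sorted(cat_of.unique()))
    index = {c: i for i, c in enumerate(categories)}
    rec = cat_of.loc[edges["recruiter_id"].to_numpy()].map(index).to_numpy()
    ree = cat_of.loc[edges["recruitee_id"].to_numpy()].map(index).to_numpy()
    k = len(categories)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (rec, ree), 1)
    rowsum = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        matrix = counts / rowsum[:, None]
    undefined = tuple(categories[i] for i in np.flatnonzero(rowsum == 0))
    matrix[rowsum == 0] = np.nan
    return TransitionMatrix(trait, categories, matrix, counts, undefined)


def _check_ergodic(T: np.ndarray, categories: Sequence[str]) -> None:
    g = nx.DiGraph()
    g.add_nodes_from(range(len(categories)))
    for i, j in zip(*np.nonzero(T > 0)):
        g.add_edge(int(i), int(j))
    if not nx.is_strongly_connected(g):
        comps = [
            sorted(categories[i] for i in c)
            for c in nx.strongly_connected_components(g)
        ]
        raise DiagnosticsError(
            f"transition matrix is reducible; communicating classes: {comps}"
        )
    if not nx.is_aperiodic(g):
        raise DiagnosticsError("transition matrix is periodic; no unique equilibrium")


def equilibrium_distribution(T: TransitionMatrix | np.ndarray) -> np.ndarray:
    """Unique stationary distribution pi* with pi* T = pi*.

    The left Perron eigenvector, after checking irreducibility and
    aperiodicity (an absorbing or periodic chain has no unique equilibrium
    and raises with the violating structure named).
    """
    if isinstance(T, TransitionMatrix):
        if T.undefined_rows:
            raise DiagnosticsError(
                f"rows with no observed pairs: {list(T.undefined_rows)}"
            )
        mat, cats = T.matrix, T.categories
    else:
        mat = np.asarray(T, dtype=float)
        cats = tuple(str(i) for i in range(mat.shape[0]))
    if np.isnan(mat).any():
        raise DiagnosticsError("transition matrix contains undefined rows")
    if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
        raise DiagnosticsError("matrix rows do not sum to 1")
    _check_ergodic(mat, cats)
    w, vl = linalg.eig(mat, left=True, right=False)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(vl[:, i])
    pi = pi / pi.sum()
    if (pi < -1e-10).any():
        raise DiagnosticsError("no nonnegative stationary vector found")
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    if np.abs(pi @ mat - pi).max() > 1e-8:
        raise DiagnosticsError("stationary fixed point not attained to 1e-8")
    return pi


def _tv(p: np.ndarray, q: np.ndarray) -> float:
    return 0.5 * float(np.abs(p - q).sum())


def convergence_wave(
    respondents: pd.DataFrame,
    T: TransitionMatrix,
    tolerance: float = 0.02,
    max_theoretical_waves: int = 1000,
) -> ConvergenceReport:
    """First wave whose composition is within ``tolerance`` total-variation
    distance of equilibrium.

    ``empirical_wave`` scans the observed per-wave compositions;
    ``theoretical_wave`` propagates the observed seed composition through
    powers of the transition matrix (the memoryless-chain bound).  A sentinel
    ``None`` with the last distance is returned when never reached.
    """
    pi = equilibrium_distribution(T)
    cats = list(T.categories)
    comp = (
        respondents.assign(_c=respondents[T.trait].astype(str))
        .groupby(["wave", "_c"], observed=True)
        .size()
        .unstack("_c", fill_value=0)
        .reindex(columns=cats, fill_value=0)
    )
    shares = comp.div(comp.sum(axis=1), axis=0)
    wave_distances = {int(w): _tv(shares.loc[w].to_numpy(), pi) for w in shares.index}
    empirical = next(
        (w for w in sorted(wave_distances) if wave_distances[w] <= tolerance), None
    )
    x = shares.loc[0].to_numpy() if 0 in shares.index else pi.copy()
    theoretical = None
    d = _tv(x, pi)
    for w in range(max_theoretical_waves + 1):
        d = _tv(x, pi)
        if d <= tolerance:
            theoretical = w
            break
        x = x @ T.matrix
    last = wave_distances[max(wave_distances)] if wave_distances else d
    return ConvergenceReport(empirical, theoretical, tolerance, wave_distances, last)


def homophily_index(
    T: TransitionMatrix, population_shares: Mapping[str, float] | np.ndarray
) -> dict[str, float]:
    """Per-category homophily in [-1, 1].

    For category ``a`` with in-group recruitment probability ``T[a,a]`` and
    population share ``pi_a``::

        H_a = (T[a,a] - pi_a) / (1 - pi_a)   if T[a,a] >= pi_a
        H_a = (T[a,a] - pi_a) / pi_a         otherwise

    0 means proportionate recruitment, 1 exclusive in-group recruitment,
    -1 exclusive out-group recruitment.
    """
    if isinstance(population_shares, Mapping):
        shares = np.array([population_shares[c] for c in T.categories], dtype=float)
    else:
        shares = np.asarray(population_shares, dtype=float)
    out: dict[str, float] = {}
    for i, c in enumerate(T.categories):
        pa = shares[i]
        if pa <= 0.0 or pa >= 1.0:
            raise DiagnosticsError(
                f"homophily undefined for category {c!r} with share {pa}"
            )
        taa = T.matrix[i, i]
        if np.isnan(taa):
            out[c] = float("nan")
        elif taa >= pa:
            out[c] = float((taa - pa) / (1.0 - pa))
        else:
            out[c] = float((taa - pa) / pa)
    return out


def cluster_robust_variance(
    y: np.ndarray, weights: np.ndarray, clusters: np.ndarray
) -> float:
    """Taylor-linearised variance of the weighted proportion with clustering
    (clusters = people recruited through the same seed or recruiter)."""
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    p = float(np.sum(w * y) / np.sum(w))
    z = w * (y - p) / np.sum(w)
    df_ = pd.DataFrame({"z": z, "c": np.asarray(clusters)})
    totals = df_.groupby("c")["z"].sum().to_numpy()
    m = len(totals)
    if m < 2:
        raise DiagnosticsError("need at least 2 clusters for a robust variance")
    return float(m / (m - 1) * np.sum(totals**2))


def design_effect(
    y: np.ndarray,
    weights: np.ndarray,
    *,
    variance: float | None = None,
    clusters: np.ndarray | None = None,
) -> float:
    """Design effect: achieved variance over the simple-random-sampling
    binomial variance ``p(1-p)/n`` at the same n and weighted p.

    ``variance`` is typically a bootstrap variance of the estimate; when
    omitted, a cluster-robust variance is computed from ``clusters``.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if (w <= 0).any():
        raise DiagnosticsError("weights must be positive")
    n = len(y)
    p = float(np.sum(w * y) / np.sum(w))
    if p <= 0.0 or p >= 1.0:
        raise DiagnosticsError(f"degenerate prevalence p={p}: SRS variance is zero")
    if variance is None:
        if clusters is None:
            raise DiagnosticsError("provide either a variance or cluster ids")
        variance = cluster_robust_variance(y, w, clusters)
    return float(variance / (p * (1.0 - p) / n))
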