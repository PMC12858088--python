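"""Post-stratification and raking weights.

Calibrates a respondent sample to known population targets: either exact
joint-cell post-stratification (``poststratify_cells``) or iterative
proportional fitting to several marginal distributions (``rake_weights``),
which is the procedure that forces weighted sample margins to equal the
census margins.  Weights are normalised to sum to the sample size.

Categories present in the sample but absent from a margin's target list
(e.g. a sex category the census does not tabulate) are left untouched during
that margin's update; the listed categories are scaled to the remaining
weight mass.  Sparse joint cells can be merged along a declared collapse
order before joint-cell post-stratification (``collapse_cells``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .marginals import ConfigurationError, MarginalVariable, PopulationMarginals

__all__ = [
    "WeightingError",
    "RakeResult",
    "poststratify_cells",
    "rake_weights",
    "collapse_cells",
]


class WeightingError(ValueError):
    """Raised when calibration is impossible or fails to converge."""


@dataclass
class RakeResult:
    """Raking output: weights (sum to n) and an audit trail."""

    weights: np.ndarray
    iterations: int
    max_margin_deviation: float
    margin_deviations: dict[str, float]
    converged: bool = True


def _weighted_shares(col: pd.Series, w: np.ndarray) -> pd.Series:
    return pd.Series(w).groupby(col.astype(str).to_numpy()).sum() / w.sum()


def poststratify_cells(
    respondents: pd.DataFrame,
    variables: Sequence[str],
    cell_targets: Mapping[tuple, float],
    *,
    initial_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Exact joint-cell post-stratification.

    ``w_i = (target share of i's cell) / (sample share of i's cell)``,
    normalised to sum to n.  Every cell with a nonzero target must contain
    at least one respondent (collapse first if not).
    """
    n = len(respondents)
    if n == 0:
        raise WeightingError("empty respondent table")
    w0 = np.ones(n) if initial_weights is None else np.asarray(initial_weights, float)
    keys = list(zip(*(respondents[v].astype(str) for v in variables)))
    sample_mass = pd.Series(w0).groupby(pd.Series(keys, dtype=object).to_numpy()).sum()
    total_target = float(sum(cell_targets.values()))
    empty = [
        c for c, t in cell_targets.items() if t > 0 and tuple(map(str, c)) not in sample_mass.index
    ]
    if empty:
        raise WeightingError(f"nonzero-target cells with no respondents: {empty}")
    factor = {}
    for cell, t in cell_targets.items():
        key = tuple(map(str, cell))
        if key in sample_mass.index:
            factor[key] = (t / total_target) / (sample_mass[key] / w0.sum())
    w = np.array([w0[i] * factor.get(tuple(map(str, k)), 1.0) for i, k in enumerate(keys)])
    return w * n / w.sum()


def rake_weights(
    respondents: pd.DataFrame,
    marginals: PopulationMarginals,
    *,
    max_iterations: int = 200,
    tolerance: float = 1e-8,
    initial_weights: np.ndarray | None = None,
) -> RakeResult:
    """Iterative proportional fitting to several marginal targets.

    Margins are updated in the declared variable order each iteration until
    every weighted constrained margin is within ``tolerance`` of its target.
    Raises with the last achieved distances on non-convergence.
    """
    n = len(respondents)
    if n == 0:
        raise WeightingError("empty respondent table")
    w = np.ones(n) if initial_weights is None else np.asarray(initial_weights, float).copy()
    if (w <= 0).any():
        raise WeightingError("initial weights must be positive")

    cols: dict[str, np.ndarray] = {}
    targets: dict[str, dict[str, float]] = {}
    for var in marginals.variables:
        if var.name not in respondents.columns:
            raise WeightingError(f"margin variable {var.name!r} not in respondents")
        col = respondents[var.name].astype(str).to_numpy()
        present = set(np.unique(col))
        missing = [
            c for c, t in zip(var.categories, var.proportions) if t > 0 and c not in present
        ]
        if missing:
            raise WeightingError(
                f"margin {var.name!r}: nonzero-target categories with no "
                f"respondents: {missing}"
            )
        cols[var.name] = col
        targets[var.name] = dict(zip(var.categories, var.proportions))

    devs: dict[str, float] = {}
    for iterations in range(1, max_iterations + 1):
        for var in marginals.variables:
            col = cols[var.name]
            t = targets[var.name]
            t_sum = sum(t.values())
            listed = np.isin(col, list(var.categories))
            listed_mass = w[listed].sum()
            for c, tc in t.items():
                mask = col == c
                cur = w[mask].sum()
                if cur == 0.0:
                    continue  # zero-target empty category
                desired = (tc / t_sum) * listed_mass
                w[mask] *= desired / cur
        # convergence: every margin simultaneously, on the total-share scale
        # with listed targets rescaled to the constrained weight mass
        max_dev = 0.0
        for var in marginals.variables:
            col = cols[var.name]
            t = targets[var.name]
            listed = np.isin(col, list(var.categories))
            scale = w[listed].sum() / w.sum() / sum(t.values())
            d = max(
                abs(w[col == c].sum() / w.sum() - tc * scale) for c, tc in t.items()
            )
            devs[var.name] = d
            max_dev = max(max_dev, d)
        if max_dev <= tolerance:
            w *= n / w.sum()
            return RakeResult(w, iterations, max_dev, devs, True)
    raise WeightingError(
        f"raking did not converge in {max_iterations} iterations; "
        f"last margin deviations: { {k: float(v) for k, v in devs.items()} }"
    )


def collapse_cells(
    respondents: pd.DataFrame,
    variables: Sequence[MarginalVariable],
    cell_targets: Mapping[tuple, float],
    min_count: int,
    *,
    collapse_order: Sequence[str] = ("education3", "age_group"),
) -> tuple[dict[tuple, float], dict[tuple, tuple]]:
    """Merge sparse joint cells with a neighbour along a declared order.

    Cells with fewer than ``min_count`` respondents are merged with the cell
    that differs only in the adjacent category of the first collapse variable
    (education first, then age); targets are summed and an audit mapping from
    original to merged cell labels is returned.  Total target mass is
    conserved.
    """
    var_names = [v.name for v in variables]
    var_cats = {v.name: list(v.categories) for v in variables}
    collapse_order = [cv for cv in collapse_order if cv in var_names]
    if not collapse_order:
        raise WeightingError("no collapse variable among the cell variables")

    keys = list(zip(*(respondents[v].astype(str) for v in var_names)))
    counts = pd.Series(keys, dtype=object).value_counts().to_dict()

    # mapping from every original cell to its current merged representative
    mapping: dict[tuple, tuple] = {tuple(map(str, c)): tuple(map(str, c)) for c in cell_targets}
    targets = {tuple(map(str, c)): float(t) for c, t in cell_targets.items()}

    def cell_count(cell: tuple) -> int:
        members = [orig for orig, rep in mapping.items() if rep == cell]
        return sum(counts.get(m, 0) for m in members)

    def merge(a: tuple, b: tuple, merged_label: tuple) -> None:
        for orig, rep in list(mapping.items()):
            if rep in (a, b):
                mapping[orig] = merged_label
        targets[merged_label] = targets.pop(a) + targets.pop(b)

    changed = True
    while changed:
        changed = False
        deficient = sorted(
            c for c, t in targets.items() if t > 0 and cell_count(c) < min_count
        )
        if not deficient:
            break
        cell = deficient[0]
        merged = False
        for cv in collapse_order:
            axis = var_names.index(cv)
            cats = var_cats[cv]
            # the representative label on this axis may already be a merge
            label = cell[axis]
            members = label.split("+")
            positions = sorted(cats.index(mb) for mb in members if mb in cats)
            if not positions:
                continue
            for neighbor_pos in (positions[-1] + 1, positions[0] - 1):
                if not 0 <= neighbor_pos < len(cats):
                    continue
                # find an existing cell identical except on this axis and
                # containing the neighbour category
                for other in list(targets):
                    if other == cell:
                        continue
                    if any(other[i] != cell[i] for i in range(len(var_names)) if i != axis):
                        continue
                    if cats[neighbor_pos] in other[axis].split("+"):
                        new_members = sorted(
                            set(members) | set(other[axis].split("+")),
                            key=cats.index,
                        )
                        new_cell = tuple(
                            "+".join(new_members) if i == axis else cell[i]
                            for i in range(len(var_names))
                        )
                        merge(cell, other, new_cell)
                        merged = True
                        break
                if merged:
                    break
            if merged:
                break
        if not merged:
            raise WeightingError(
                f"cannot collapse cell {cell} to reach minimum count {min_count}"
            )
        changed = True

    still = [c for c, t in targets.items() if t > 0 and cell_count(c) < min_count]
    if still:
        raise WeightingError(
            f"cells below minimum even after full collapse: {still}"
        )
    return targets, mapping
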