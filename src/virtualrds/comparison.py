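"""Survey-to-survey comparison arithmetic and deterministic reports.

Places estimated percentages side by side with a reference survey's printed
values: ratios in both directions (rounded to one decimal, the convention
of prose statements such as "1.7 times greater"), absolute differences, and
a confidence-interval overlap flag.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ComparisonError", "compare", "render_report"]


class ComparisonError(ValueError):
    pass


def compare(estimates: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Join estimate and reference tables on ``indicator`` and compute the
    comparison columns.

    Both inputs need columns ``indicator``, ``pct`` and optionally
    ``ci_low``/``ci_high`` (percent scale).  Output columns: the two
    percentages, ``ratio`` (estimate over reference, one decimal),
    ``ratio_reverse`` (reference over estimate), ``abs_diff``, and
    ``ci_overlap`` (True iff the intervals intersect; NA without intervals).
    A zero reference leaves the ratio undefined (NaN) and flags it.
    """
    for df, label in ((estimates, "estimates"), (reference, "reference")):
        missing = {"indicator", "pct"} - set(df.columns)
        if missing:
            raise ComparisonError(f"{label} table lacks columns {sorted(missing)}")
    merged = estimates.merge(
        reference, on="indicator", suffixes=("_est", "_ref"), how="inner"
    )
    if len(merged) == 0:
        raise ComparisonError("no indicators in common between the two tables")
    est = merged["pct_est"].to_numpy(float)
    ref = merged["pct_ref"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ref != 0, est / ref, np.nan)
        ratio_rev = np.where(est != 0, ref / est, np.nan)
    out = pd.DataFrame(
        {
            "indicator": merged["indicator"],
            "estimate_pct": est,
            "reference_pct": ref,
            "ratio": np.round(ratio, 1),
            "ratio_reverse": np.round(ratio_rev, 1),
            "abs_diff": np.round(np.abs(est - ref), 1),
            "ratio_undefined": ref == 0,
        }
    )
    have_ci = all(
        c in merged.columns
        for c in ("ci_low_est", "ci_high_est", "ci_low_ref", "ci_high_ref")
    )
    if have_ci:
        out["ci_overlap"] = (
            (merged["ci_low_est"] <= merged["ci_high_ref"])
            & (merged["ci_low_ref"] <= merged["ci_high_est"])
        ).to_numpy()
    else:
        out["ci_overlap"] = pd.NA
    return out


def render_report(comparisons: pd.DataFrame, out_prefix: str | Path) -> dict[str, Path]:
    """Write the comparison table as CSV and JSON; byte-deterministic for
    identical inputs.  Returns the written paths."""
    if len(comparisons) == 0:
        raise ComparisonError("nothing to report: comparison table is empty")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    csv_path = out_prefix.with_suffix(".csv")
    json_path = out_prefix.with_suffix(".json")
    comparisons.to_csv(csv_path, index=False, float_format="%.6g", lineterminator="\n")
    records = json.loads(comparisons.to_json(orient="records"))
    json_path.write_text(
        json.dumps(records, indent=2, sort_keys=True, allow_nan=True) + "\n",
        encoding="utf-8",
    )
    return {"csv": csv_path, "json": json_path}
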