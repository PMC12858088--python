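"""End-to-end pipeline: generate -> recruit -> diagnose -> weight ->
estimate -> compare, with seeded reproducibility and stamped artifacts.

Every stage draws from a child random stream derived deterministically from
the single top-level seed, so one integer reproduces the whole run
byte for byte.  Each artifact directory carries a ``manifest.json`` with
the seed, a hash of the configuration, and stage timings/warnings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import references
from .comparison import compare, render_report
from .diagnostics import (
    convergence_wave,
    equilibrium_distribution,
    homophily_index,
    transition_matrix,
)
from .estimation import bootstrap_prevalence
from .io import write_edges, write_respondents
from .marginals import (
    ConfigurationError,
    PopulationMarginals,
    default_population_marginals,
    rake_targets,
)
from .population import (
    NetworkSpec,
    OutcomeSpec,
    assign_response_propensity,
    attach_outcomes,
    build_social_network,
    generate_population,
)
from .recruitment import RecruitmentConfig, run_recruitment
from .weighting import rake_weights

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "default_outcomes"]


def default_outcomes() -> list[OutcomeSpec]:
    """Default binary health outcomes with realistic demographic gradients:
    hypertension (strongly age-graded), depression, and an any-chronic-
    disease indicator, at roughly national adult prevalences."""
    return [
        OutcomeSpec(
            "hypertension",
            baseline=0.12,
            offsets={"age_group": {"40-59": 0.9, "60+": 1.8}},
        ),
        OutcomeSpec(
            "depression",
            baseline=0.15,
            offsets={"sex": {"women": 0.35}},
        ),
        OutcomeSpec(
            "any_ncd",
            baseline=0.40,
            offsets={"age_group": {"40-59": 0.8, "60+": 1.5}},
        ),
    ]


@dataclass
class RunConfig:
    """Top-level pipeline configuration (all stages by reference)."""

    seed: int = 0
    outdir: str | Path = "virtualrds-run"
    n_pop: int = 30_000
    marginals: PopulationMarginals = field(default_factory=default_population_marginals)
    targets: PopulationMarginals = field(default_factory=rake_targets)
    outcomes: list[OutcomeSpec] = field(default_factory=default_outcomes)
    network: NetworkSpec = field(
        default_factory=lambda: NetworkSpec(mean_degree=25.0, dispersion=4.0,
                                           homophily={"race": 0.3})
    )
    recruitment: RecruitmentConfig = field(default_factory=RecruitmentConfig)
    propensity_constant: float | None = None
    bootstrap_B: int = 1000
    bootstrap_trait: str = "race"
    ci_level: float = 0.95
    stages: tuple[str, ...] = (
        "generate",
        "recruit",
        "diagnose",
        "weight",
        "estimate",
        "compare",
    )


@dataclass
class PipelineResult:
    outdir: Path
    artifacts: dict[str, Path]
    manifest: dict


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (Path, np.integer, np.floating)):
            return str(o)
        return repr(o)

    blob = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the enabled stages in order, writing stamped artifacts.

    A disabled upstream stage makes any dependent stage raise a clear
    dependency error.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_children = np.random.SeedSequence(config.seed).spawn(8)
    artifacts: dict[str, Path] = {}
    manifest: dict = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "stages": {},
        "warnings": [],
    }
    stages = set(config.stages)

    def require(stage: str, needs: str, obj) -> None:
        if obj is None:
            raise ConfigurationError(
                f"stage {stage!r} needs the output of disabled stage {needs!r}"
            )

    population = edges = None
    result = None
    weights = None
    estimates_df = None

    if "generate" in stages:
        t0 = time.perf_counter()
        population = generate_population(
            config.marginals, config.n_pop,
            seed=np.random.default_rng(rng_children[0]),
        )
        population = attach_outcomes(
            population, config.outcomes, seed=np.random.default_rng(rng_children[1])
        )
        if config.propensity_constant is not None:
            population = assign_response_propensity(
                population, constant=config.propensity_constant
            )
        else:
            population = assign_response_propensity(population)
        edges, population = build_social_network(
            population, config.network, seed=np.random.default_rng(rng_children[2])
        )
        pop_path = outdir / "population.csv"
        population.to_csv(pop_path, index=False, lineterminator="\n")
        net_path = outdir / "network_edges.csv"
        pd.DataFrame(edges, columns=["person_a", "person_b"]).to_csv(
            net_path, index=False, lineterminator="\n"
        )
        artifacts["population"] = pop_path
        artifacts["network_edges"] = net_path
        manifest["stages"]["generate"] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "n_pop": len(population),
            "n_network_edges": int(len(edges)),
        }

    if "recruit" in stages:
        require("recruit", "generate", population)
        t0 = time.perf_counter()
        result = run_recruitment(
            population, edges, config.recruitment,
            seed=np.random.default_rng(rng_children[3]),
        )
        manifest["warnings"].extend(result.warnings)
        artifacts["respondents"] = write_respondents(
            result.respondents, outdir / "respondents.csv"
        )
        artifacts["recruitment_edges"] = write_edges(
            result.edges, outdir / "recruitment_edges.csv"
        )
        manifest["stages"]["recruit"] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "n_respondents": len(result.respondents),
            "n_waves": int(result.respondents["wave"].max()) if len(result.respondents) else 0,
            "status": result.status,
        }

    if "diagnose" in stages:
        require("diagnose", "recruit", result)
        t0 = time.perf_counter()
        report: dict = {"seed": config.seed, "traits": {}}
        for trait in ("race", "sex"):
            try:
                T = transition_matrix(result.respondents, result.edges, trait)
                pi = equilibrium_distribution(T)
                conv = convergence_wave(result.respondents, T)
                shares = {
                    c: float((population[trait].astype(str) == c).mean())
                    for c in T.categories
                }
                report["traits"][trait] = {
                    "categories": list(T.categories),
                    "transition_matrix": np.nan_to_num(T.matrix).tolist(),
                    "equilibrium": pi.tolist(),
                    "empirical_convergence_wave": conv.empirical_wave,
                    "theoretical_convergence_wave": conv.theoretical_wave,
                    "homophily_index": homophily_index(T, shares),
                }
            except Exception as exc:  # degenerate chains reported, not fatal
                report["traits"][trait] = {"error": str(exc)}
        diag_path = outdir / "diagnostics.json"
        diag_path.write_text(json.dumps(report, indent=2) + "\n", encoding="utf-8")
        artifacts["diagnostics"] = diag_path
        manifest["stages"]["diagnose"] = {"seconds": round(time.perf_counter() - t0, 3)}

    if "weight" in stages:
        require("weight", "recruit", result)
        t0 = time.perf_counter()
        rake = rake_weights(result.respondents, config.targets)
        weights = rake.weights
        weighted = result.respondents.copy()
        weighted["weight"] = weights
        artifacts["respondents_weighted"] = write_respondents(
            weighted, outdir / "respondents_weighted.csv"
        )
        audit = {
            "seed": config.seed,
            "iterations": rake.iterations,
            "max_margin_deviation": rake.max_margin_deviation,
            "margin_deviations": rake.margin_deviations,
        }
        audit_path = outdir / "weighting_audit.json"
        audit_path.write_text(json.dumps(audit, indent=2) + "\n", encoding="utf-8")
        artifacts["weighting_audit"] = audit_path
        manifest["stages"]["weight"] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "iterations": rake.iterations,
        }

    if "estimate" in stages:
        require("estimate", "recruit", result)
        require("estimate", "weight", weights)
        t0 = time.perf_counter()
        boot_seed = int(rng_children[4].generate_state(1)[0] % (2**31))
        rows = []
        for spec in config.outcomes:
            est = bootstrap_prevalence(
                result.respondents,
                result.edges,
                spec.name,
                weights=weights,
                trait=config.bootstrap_trait,
                B=config.bootstrap_B,
                level=config.ci_level,
                seed=boot_seed,
            )
            pct, lo, hi = est.as_percent()
            rows.append(
                {
                    "indicator": spec.name,
                    "pct": pct,
                    "ci_low": lo,
                    "ci_high": hi,
                    "B": est.n_replicates,
                    "seed": boot_seed,
                    "deff": round(est.design_effect, 3) if est.design_effect else None,
                }
            )
        estimates_df = pd.DataFrame(rows)
        est_path = outdir / "estimates.csv"
        estimates_df.to_csv(est_path, index=False, lineterminator="\n")
        artifacts["estimates"] = est_path
        manifest["stages"]["estimate"] = {"seconds": round(time.perf_counter() - t0, 3)}

    if "compare" in stages:
        require("compare", "estimate", estimates_df)
        t0 = time.perf_counter()
        ref = references.pns_2019_health()
        merged = compare(estimates_df, ref)
        paths = render_report(merged, outdir / "comparison")
        artifacts["comparison_csv"] = paths["csv"]
        artifacts["comparison_json"] = paths["json"]
        manifest["stages"]["compare"] = {"seconds": round(time.perf_counter() - t0, 3)}

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    artifacts["manifest"] = manifest_path
    return PipelineResult(outdir, artifacts, manifest)
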