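"""Monte-Carlo validation studies for the chain-referral machinery.

Self-contained simulation studies that exercise the whole stack on known
ground truth: empirical coverage of chain-bootstrap confidence intervals
under a null design, and recovery of a population prevalence by raked
weighting under education-biased response.  Used by the test suite and by
reproduction scripts; every study takes a single integer seed and is fully
deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimation import bootstrap_prevalence, weighted_prevalence
from .marginals import default_population_marginals, rake_targets
from .population import (
    NetworkSpec,
    OutcomeSpec,
    assign_response_propensity,
    attach_outcomes,
    build_social_network,
    generate_population,
)
from .recruitment import RecruitmentConfig, run_recruitment, select_seeds
from .weighting import rake_weights

__all__ = [
    "CoverageStudyResult",
    "RecoveryStudyResult",
    "bootstrap_coverage_study",
    "parameter_recovery_study",
]


@dataclass
class CoverageStudyResult:
    coverage_pct: float
    n_replications: int
    n_covered: int
    mean_ci_width: float
    mean_estimate: float


def bootstrap_coverage_study(
    *,
    n_replications: int = 500,
    sample_size: int = 400,
    n_seeds: int = 10,
    invites: int = 3,
    prevalence: float = 0.20,
    B: int = 500,
    level: float = 0.95,
    n_pop: int = 5000,
    mean_degree: float = 8.0,
    response_propensity: float = 0.65,
    seed: int = 0,
) -> CoverageStudyResult:
    """Empirical coverage of percentile chain-bootstrap CIs under a null.

    One synthetic population and zero-homophily contact network are built;
    each replication re-draws the outcome (true prevalence exactly
    ``prevalence``), recruits a fresh chain-referral sample of
    ``sample_size`` from ``n_seeds`` seeds with a fixed number of
    invitations, rakes it to the census margins, and computes a nominal
    ``level`` percentile CI for the weighted prevalence.  Returns the
    percentage of intervals covering the true value.
    """
    ss = np.random.SeedSequence(seed)
    base, reps = ss.spawn(2)
    base_children = base.spawn(2)
    marginals = default_population_marginals()
    pop = generate_population(
        marginals, n_pop, seed=np.random.default_rng(base_children[0])
    )
    pop = assign_response_propensity(pop, constant=response_propensity)
    net = NetworkSpec(mean_degree=mean_degree, dispersion=4.0, homophily={})
    edges, pop = build_social_network(
        pop, net, seed=np.random.default_rng(base_children[1])
    )
    targets = rake_targets()
    config = RecruitmentConfig(
        total_seeds=n_seeds,
        seed_invitation_mode=invites,
        invites_min=invites,
        invites_max=invites,
        target_sample_size=sample_size,
    )

    covered = 0
    widths = np.empty(n_replications)
    points = np.empty(n_replications)
    for i, child in enumerate(reps.spawn(n_replications)):
        c_outcome, c_recruit, c_boot = child.spawn(3)
        pop_i = attach_outcomes(
            pop, [OutcomeSpec("y", prevalence)], seed=np.random.default_rng(c_outcome)
        )
        rng = np.random.default_rng(c_recruit)
        seeds = select_seeds(pop_i, config, seed=rng)
        res = run_recruitment(pop_i, edges, config, seed=rng, seeds=seeds)
        rake = rake_weights(res.respondents, targets)
        est = bootstrap_prevalence(
            res.respondents,
            res.edges,
            "y",
            weights=rake.weights,
            trait="race",
            B=B,
            level=level,
            seed=np.random.default_rng(c_boot),
            calibrate_margins=targets,
        )
        covered += int(est.ci_lower <= prevalence <= est.ci_upper)
        widths[i] = est.ci_upper - est.ci_lower
        points[i] = est.estimate
    return CoverageStudyResult(
        coverage_pct=100.0 * covered / n_replications,
        n_replications=n_replications,
        n_covered=covered,
        mean_ci_width=float(widths.mean()),
        mean_estimate=float(points.mean()),
    )


@dataclass
class RecoveryStudyResult:
    true_prevalence: float
    mean_raked: float
    mean_unweighted: float
    mc_se: float
    n_replications: int


def parameter_recovery_study(
    *,
    n_replications: int = 25,
    sample_size: int = 600,
    n_pop: int = 10_000,
    seed: int = 0,
) -> RecoveryStudyResult:
    """Raked weighting recovers the population prevalence under biased response.

    The outcome depends only on education (strong negative gradient), the
    contact network has zero homophily, and response propensity rises with
    education — so low-education, high-prevalence people under-respond.
    The unweighted sample mean is then biased downwards while raking to the
    education margin removes the bias.  Returns the truth, the two Monte-
    Carlo means, and the Monte-Carlo standard error of the raked mean.
    """
    ss = np.random.SeedSequence(seed)
    base, reps = ss.spawn(2)
    b0, b1, b2 = base.spawn(3)
    marginals = default_population_marginals()
    pop = generate_population(marginals, n_pop, seed=np.random.default_rng(b0))
    outcome = OutcomeSpec(
        "y",
        baseline=0.10,
        offsets={
            "education4": {
                "some_elementary": 1.90,
                "elementary_some_hs": 1.45,
                "hs_some_college": 0.87,
            }
        },
    )
    pop = attach_outcomes(pop, [outcome], seed=np.random.default_rng(b1))
    pop = assign_response_propensity(pop)  # logistic in education level
    edges, pop = build_social_network(
        pop, NetworkSpec(mean_degree=12.0, dispersion=4.0, homophily={}),
        seed=np.random.default_rng(b2),
    )
    truth = float(pop["y"].mean())
    targets = rake_targets()
    config = RecruitmentConfig(
        total_seeds=20,
        seed_invitation_mode=5,
        target_sample_size=sample_size,
    )
    raked = np.empty(n_replications)
    unweighted = np.empty(n_replications)
    for i, child in enumerate(reps.spawn(n_replications)):
        rng = np.random.default_rng(child)
        res = run_recruitment(pop, edges, config, seed=rng)
        r = res.respondents
        rake = rake_weights(r, targets)
        raked[i] = weighted_prevalence(r["y"].to_numpy(), rake.weights)
        unweighted[i] = float(r["y"].mean())
    return RecoveryStudyResult(
        true_prevalence=truth,
        mean_raked=float(raked.mean()),
        mean_unweighted=float(unweighted.mean()),
        mc_se=float(raked.std(ddof=1) / np.sqrt(n_replications)),
        n_replications=n_replications,
    )
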