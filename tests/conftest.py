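import numpy as np
import pytest

import virtualrds as v


@pytest.fixture(scope="session")
def homophilous_sim():
    """A medium chain-referral simulation with race homophily 0.4,
    education-biased response, and the default field procedure."""
    marginals = v.default_population_marginals()
    pop = v.generate_population(marginals, 8000, seed=11)
    pop = v.attach_outcomes(pop, v.default_outcomes(), seed=12)
    pop = v.assign_response_propensity(pop)
    edges, pop = v.build_social_network(
        pop, v.NetworkSpec(mean_degree=14, dispersion=4, homophily={"race": 0.4}),
        seed=13,
    )
    config = v.RecruitmentConfig(target_sample_size=800)
    result = v.run_recruitment(pop, edges, config, seed=14)
    return {"pop": pop, "net_edges": edges, "config": config, "result": result}


@pytest.fixture(scope="session")
def null_sim():
    """Zero-homophily simulation with constant response propensity: the
    closest thing to simple random chain referral."""
    marginals = v.default_population_marginals()
    pop = v.generate_population(marginals, 6000, seed=21)
    pop = v.attach_outcomes(pop, [v.OutcomeSpec("y", 0.3)], seed=22)
    pop = v.assign_response_propensity(pop, constant=0.8)
    edges, pop = v.build_social_network(
        pop, v.NetworkSpec(mean_degree=10, dispersion=4, homophily={}), seed=23
    )
    config = v.RecruitmentConfig(
        total_seeds=12,
        seed_invitation_mode=4,
        invites_min=3,
        invites_max=5,
        target_sample_size=900,
    )
    result = v.run_recruitment(pop, edges, config, seed=24)
    return {"pop": pop, "net_edges": edges, "config": config, "result": result}
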