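"""Synthetic population, outcomes, and contact-network generator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import virtualrds as v
from virtualrds.marginals import ConfigurationError, MarginalVariable, PopulationMarginals
from virtualrds.population import build_social_network


def two_var_marginals(p_a=0.6, p_x=0.5):
    return PopulationMarginals(
        (
            MarginalVariable("g", ("a", "b"), (p_a, 1 - p_a)),
            MarginalVariable("h", ("x", "y"), (p_x, 1 - p_x)),
        )
    )


CENSUS = PopulationMarginals(
    (
        MarginalVariable("sex", ("men", "women"), (0.481, 0.519)),
        MarginalVariable("race", ("white", "nonwhite"), (0.434, 0.566)),
        MarginalVariable(
            "education3",
            ("some_hs_or_less", "hs_some_college", "college_plus"),
            (0.445, 0.382, 0.173),
        ),
        MarginalVariable("age_group", ("18-39", "40-59", "60+"), (0.459, 0.340, 0.201)),
    )
)


class TestMarginalsValidation:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ConfigurationError, match="sum"):
            MarginalVariable("g", ("a", "b"), (0.6, 0.5))

    def test_at_least_two_categories(self):
        with pytest.raises(ConfigurationError):
            MarginalVariable("g", ("a",), (1.0,))

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ConfigurationError):
            MarginalVariable("g", ("a", "a"), (0.5, 0.5))

    def test_round_trips_through_dict(self):
        m = two_var_marginals()
        assert PopulationMarginals.from_dict(m.to_dict()) == m


class TestGeneratePopulation:
    def test_independence_joint_factorises(self):
        """Under independence, joint cell frequencies approach the product
        of the marginal targets."""
        m = two_var_marginals(0.6, 0.3)
        pop = v.generate_population(m, 100_000, seed=1, household_by=None)
        joint = (
            pop.groupby(["g", "h"], observed=True).size().unstack() / len(pop)
        )
        expected = np.outer([0.6, 0.4], [0.3, 0.7])
        assert np.abs(joint.to_numpy() - expected).max() < 0.01

    def test_census_marginals_recovered(self):
        """Empirical marginals at n=1e5 fall within 0.01 of the census
        targets for every post-stratification variable."""
        pop = v.generate_population(CENSUS, 100_000, seed=2, household_by=None)
        for var in CENSUS:
            emp = pop[var.name].value_counts(normalize=True)
            for cat, target in zip(var.categories, var.proportions):
                assert abs(emp[cat] - target) < 0.01

    def test_chi_square_distance_within_multinomial_band(self):
        """The chi-square statistic of each sampled marginal against its
        target sits below the 99th percentile of its multinomial sampling
        distribution (chi-square with k-1 degrees of freedom)."""
        n = 100_000
        pop = v.generate_population(CENSUS, n, seed=3, household_by=None)
        for var in CENSUS:
            counts = pop[var.name].value_counts()
            expected = np.array(var.proportions) * n
            observed = np.array([counts[c] for c in var.categories])
            stat = float(((observed - expected) ** 2 / expected).sum())
            assert stat < stats.chi2.ppf(0.99, df=len(var.categories) - 1)

    def test_association_preserves_marginals(self):
        """Two-way log-linear association changes the joint but the
        calibrated marginals stay on target."""
        m = two_var_marginals(0.6, 0.3)
        assoc = {("g", "h"): np.array([[0.8, 0.0], [0.0, 0.8]])}
        pop = v.generate_population(
            m, 50_000, seed=4, association=assoc, household_by=None
        )
        assert abs((pop["g"] == "a").mean() - 0.6) < 0.01
        assert abs((pop["h"] == "x").mean() - 0.3) < 0.01
        # positive association: P(x | a) > P(x | b)
        p_x_a = (pop.loc[pop["g"] == "a", "h"] == "x").mean()
        p_x_b = (pop.loc[pop["g"] == "b", "h"] == "x").mean()
        assert p_x_a > p_x_b + 0.05

    def test_households_respect_geography_and_size_cap(self):
        pop = v.generate_population(
            v.default_population_marginals(), 20_000, seed=5, household_max=6
        )
        by_household = pop.groupby("household_id")
        assert by_household["fu"].nunique().max() == 1
        assert by_household.size().max() <= 6
        assert by_household.size().mean() == pytest.approx(3.0, abs=0.5)

    def test_invalid_proportions_raise(self):
        with pytest.raises(ConfigurationError):
            v.generate_population(
                PopulationMarginals(
                    (MarginalVariable("g", ("a", "b"), (0.7, 0.2)),)
                ),
                100,
            )


class TestAttachOutcomes:
    def test_zero_baseline_all_false(self):
        pop = v.generate_population(two_var_marginals(), 500, seed=6, household_by=None)
        pop = v.attach_outcomes(pop, [v.OutcomeSpec("o", 0.0)], seed=6)
        assert not pop["o"].any()

    def test_uniform_prevalence_recovered(self):
        """Cell-independent prevalence 0.22 is recovered within 0.005 at 1e5."""
        pop = v.generate_population(two_var_marginals(), 100_000, seed=7, household_by=None)
        pop = v.attach_outcomes(pop, [v.OutcomeSpec("o", 0.22)], seed=7)
        assert pop["o"].mean() == pytest.approx(0.22, abs=0.005)

    def test_mixture_identity(self):
        """Overall prevalence equals the cell-share-weighted cell prevalences:
        two equal cells at 0.1 and 0.3 mix to 0.2."""
        m = PopulationMarginals((MarginalVariable("g", ("a", "b"), (0.5, 0.5)),))
        pop = v.generate_population(m, 100_000, seed=8, household_by=None)
        # offsets chosen so P(o|a)=0.1, P(o|b)=0.3 via logit arithmetic
        from scipy.special import logit

        spec = v.OutcomeSpec(
            "o", baseline=0.1, offsets={"g": {"b": float(logit(0.3) - logit(0.1))}}
        )
        pop = v.attach_outcomes(pop, [spec], seed=8)
        p_a = pop.loc[pop["g"] == "a", "o"].mean()
        p_b = pop.loc[pop["g"] == "b", "o"].mean()
        mc_se = 3 * np.sqrt(0.2 * 0.8 / len(pop))
        assert p_a == pytest.approx(0.1, abs=0.01)
        assert p_b == pytest.approx(0.3, abs=0.01)
        assert pop["o"].mean() == pytest.approx(0.2, abs=mc_se + 0.01)

    def test_unknown_offset_category_raises(self):
        pop = v.generate_population(two_var_marginals(), 100, seed=9, household_by=None)
        with pytest.raises(ConfigurationError, match="categories"):
            v.attach_outcomes(
                pop, [v.OutcomeSpec("o", 0.2, offsets={"g": {"zz": 1.0}})], seed=9
            )


class TestSocialNetwork:
    @staticmethod
    def _population(n=4000, seed=30):
        pop = v.generate_population(two_var_marginals(0.45, 0.5), n, seed=seed,
                                    household_by=None)
        return pop

    def test_handshake_identity(self):
        """n=1000 at mean degree 10 yields about 5000 undirected edges."""
        pop = self._population(1000)
        edges, pop = build_social_network(pop, v.NetworkSpec(10, 4, {}), seed=31)
        assert len(edges) == pytest.approx(5000, rel=0.08)
        assert pop["degree"].mean() == pytest.approx(10, rel=0.08)

    def test_edges_simple_and_undirected(self):
        pop = self._population(800)
        edges, _ = build_social_network(pop, v.NetworkSpec(8, 4, {}), seed=32)
        assert (edges[:, 0] < edges[:, 1]).all()
        assert len(np.unique(edges, axis=0)) == len(edges)

    def test_zero_homophily_mixing_proportionate(self):
        """Without homophily, the category mix among a group's contacts
        equals the degree-weighted population shares."""
        pop = self._population(6000)
        edges, pop = build_social_network(pop, v.NetworkSpec(12, 4, {}), seed=33)
        g = pop["g"].astype(str).to_numpy()
        ends = np.concatenate([edges, edges[:, ::-1]])
        share_pop = (pop["degree"] * (g == "a")).sum() / pop["degree"].sum()
        for cat in ("a", "b"):
            contacts = ends[g[ends[:, 0]] == cat, 1]
            share = (g[contacts] == "a").mean()
            assert share == pytest.approx(share_pop, abs=0.02)

    def test_assortativity_monotone_in_homophily(self):
        """Newman attribute assortativity increases with the homophily
        strength under the same seed protocol."""
        import networkx as nx

        pop = self._population(3000)
        coeffs = []
        for h in (0.0, 0.4, 0.8):
            edges, pop_h = build_social_network(
                pop, v.NetworkSpec(10, 4, {"g": h}), seed=34
            )
            graph = nx.Graph(list(map(tuple, edges)))
            nx.set_node_attributes(
                graph, pop_h.set_index("person_id")["g"].astype(str).to_dict(), "g"
            )
            coeffs.append(nx.attribute_assortativity_coefficient(graph, "g"))
        assert coeffs[0] < coeffs[1] < coeffs[2]
        assert coeffs[0] == pytest.approx(0.0, abs=0.05)
        assert coeffs[2] == pytest.approx(0.8, abs=0.07)

    def test_mean_degree_below_one_rejected(self):
        with pytest.raises(ConfigurationError):
            v.NetworkSpec(mean_degree=0.5)

    def test_homophily_outside_band_rejected(self):
        with pytest.raises(ConfigurationError):
            v.NetworkSpec(homophily={"g": 1.5})


class TestResponsePropensity:
    def test_constant_override(self):
        pop = v.generate_population(v.default_population_marginals(), 200, seed=40)
        pop = v.assign_response_propensity(pop, constant=0.5)
        assert (pop["propensity"] == 0.5).all()

    def test_education_gradient(self):
        """Default propensity rises with education level, so the lowest
        level under-responds."""
        pop = v.generate_population(v.default_population_marginals(), 5000, seed=41)
        pop = v.assign_response_propensity(pop)
        means = pop.groupby("education4", observed=True)["propensity"].mean()
        assert (
            means["some_elementary"]
            < means["elementary_some_hs"]
            < means["hs_some_college"]
            < means["college_plus"]
        )
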