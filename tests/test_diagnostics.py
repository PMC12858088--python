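"""Markov recruitment diagnostics: transitions, equilibrium, homophily, deff."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import virtualrds as v
from virtualrds.diagnostics import (
    DiagnosticsError,
    TransitionMatrix,
    cluster_robust_variance,
    convergence_wave,
    design_effect,
    equilibrium_distribution,
    homophily_index,
    transition_matrix,
)


def _tiny_sample(pairs):
    """Respondent/edge tables from a list of (recruiter_cat, recruitee_cat)."""
    rows = []
    edges = []
    rows.append({"person_id": 0, "wave": 0, "t": pairs[0][0]})
    next_id = 1
    cat_holder = {pairs[0][0]: 0}
    for rec_cat, ree_cat in pairs:
        if rec_cat not in cat_holder:
            rows.append({"person_id": next_id, "wave": 0, "t": rec_cat})
            cat_holder[rec_cat] = next_id
            next_id += 1
        rows.append({"person_id": next_id, "wave": 1, "t": ree_cat})
        edges.append(
            {
                "recruiter_id": cat_holder[rec_cat],
                "recruitee_id": next_id,
                "recruiter_wave": 0,
                "recruitee_wave": 1,
            }
        )
        next_id += 1
    return pd.DataFrame(rows), pd.DataFrame(edges)


class TestTransitionMatrix:
    def test_hand_counted_rows(self):
        """Pairs {A->A x3, A->B x1, B->B x2, B->A x2} give rows
        (0.75, 0.25) and (0.5, 0.5)."""
        pairs = [("A", "A")] * 3 + [("A", "B")] + [("B", "B")] * 2 + [("B", "A")] * 2
        resp, edges = _tiny_sample(pairs)
        T = transition_matrix(resp, edges, "t")
        assert T.categories == ("A", "B")
        np.testing.assert_allclose(T.matrix, [[0.75, 0.25], [0.5, 0.5]])

    def test_perfect_homophily_is_identity(self):
        pairs = [("A", "A")] * 4 + [("B", "B")] * 4
        resp, edges = _tiny_sample(pairs)
        T = transition_matrix(resp, edges, "t")
        np.testing.assert_allclose(T.matrix, np.eye(2))

    def test_zero_pair_rows_flagged_not_fabricated(self):
        pairs = [("A", "A"), ("A", "B")]
        resp, edges = _tiny_sample(pairs)
        T = transition_matrix(resp, edges, "t")
        assert T.undefined_rows == ("B",)
        assert np.isnan(T.matrix[1]).all()

    def test_no_edges_raises(self):
        resp, edges = _tiny_sample([("A", "B")])
        with pytest.raises(DiagnosticsError):
            transition_matrix(resp, edges.iloc[0:0], "t")

    def test_rows_stochastic_under_edge_permutation(self, homophilous_sim):
        res = homophilous_sim["result"]
        T1 = transition_matrix(res.respondents, res.edges, "race")
        shuffled = res.edges.sample(frac=1.0, random_state=0)
        T2 = transition_matrix(res.respondents, shuffled, "race")
        np.testing.assert_allclose(T1.matrix, T2.matrix)
        np.testing.assert_allclose(np.nansum(T1.matrix, axis=1), 1.0, atol=1e-9)

    def test_zero_homophily_rows_match_population_shares(self, null_sim):
        """Under proportionate mixing each transition row approximates the
        (degree-weighted) population shares, within 3 binomial SEs."""
        res = null_sim["result"]
        pop = null_sim["pop"]
        T = transition_matrix(res.respondents, res.edges, "race")
        share_white = (pop["degree"] * (pop["race"] == "white")).sum() / pop["degree"].sum()
        for i in range(2):
            n_row = T.counts[i].sum()
            se = np.sqrt(share_white * (1 - share_white) / n_row)
            white_col = T.categories.index("white")
            assert abs(T.matrix[i, white_col] - share_white) < 3 * se + 1e-9


class TestEquilibrium:
    def test_two_state_hand_solution(self):
        """pi T = pi for T=[[.75,.25],[.5,.5]] solves to (2/3, 1/3)."""
        pi = equilibrium_distribution(np.array([[0.75, 0.25], [0.5, 0.5]]))
        np.testing.assert_allclose(pi, [2 / 3, 1 / 3], atol=1e-10)

    def test_identity_chain_is_reducible(self):
        with pytest.raises(DiagnosticsError, match="reducible"):
            equilibrium_distribution(np.eye(2))

    def test_periodic_chain_rejected(self):
        with pytest.raises(DiagnosticsError, match="periodic"):
            equilibrium_distribution(np.array([[0.0, 1.0], [1.0, 0.0]]))

    def test_doubly_stochastic_gives_uniform(self):
        T = np.array([[0.2, 0.5, 0.3], [0.5, 0.3, 0.2], [0.3, 0.2, 0.5]])
        np.testing.assert_allclose(equilibrium_distribution(T), np.ones(3) / 3, atol=1e-10)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(2, 5), st.integers(0, 10_000))
    def test_matches_power_iteration_oracle(self, k, seed):
        """Eigen-solution equals brute-force power iteration (200 steps)
        within 1e-8 on random small ergodic chains."""
        rng = np.random.default_rng(seed)
        T = rng.random((k, k)) + 0.05  # strictly positive => ergodic
        T /= T.sum(axis=1, keepdims=True)
        pi = equilibrium_distribution(T)
        brute = np.full(k, 1.0 / k)
        for _ in range(200):
            brute = brute @ T
        assert np.abs(pi - brute).max() < 1e-8


class TestConvergenceWave:
    @staticmethod
    def _tm(matrix, cats=("A", "B")):
        return TransitionMatrix("t", cats, np.asarray(matrix, float),
                                np.ones((len(cats), len(cats)), int))

    def test_rank_one_chain_converges_at_wave_one(self):
        """When all rows are equal the chain forgets the seeds after a
        single wave, whatever the seed composition."""
        T = self._tm([[0.6, 0.4], [0.6, 0.4]])
        resp = pd.DataFrame({"person_id": [0], "wave": [0], "t": ["A"]})
        rep = convergence_wave(resp, T, tolerance=0.01)
        assert rep.theoretical_wave == 1

    def test_power_iteration_wave_from_all_A_seeds(self):
        """Seeds all A under T=[[.75,.25],[.5,.5]]: TV distances to (2/3,1/3)
        are 1/3, 1/12, 1/48, ... (second eigenvalue 0.25); the first wave
        within 0.01 is wave 3 by direct powering."""
        T = self._tm([[0.75, 0.25], [0.5, 0.5]])
        resp = pd.DataFrame({"person_id": [0], "wave": [0], "t": ["A"]})
        rep = convergence_wave(resp, T, tolerance=0.01)
        x = np.array([1.0, 0.0])
        pi = np.array([2 / 3, 1 / 3])
        w = 0
        while 0.5 * np.abs(x - pi).sum() > 0.01:
            x = x @ T.matrix
            w += 1
        assert rep.theoretical_wave == w == 3

    def test_vacuous_tolerance_is_wave_zero(self):
        T = self._tm([[0.75, 0.25], [0.5, 0.5]])
        resp = pd.DataFrame({"person_id": [0], "wave": [0], "t": ["A"]})
        rep = convergence_wave(resp, T, tolerance=1.0)
        assert rep.theoretical_wave == 0
        assert rep.empirical_wave == 0

    def test_empirical_convergence_on_null_simulation(self, null_sim):
        res = null_sim["result"]
        T = transition_matrix(res.respondents, res.edges, "race")
        rep = convergence_wave(res.respondents, T, tolerance=0.05)
        assert rep.empirical_wave is not None
        assert rep.empirical_wave <= 3


class TestHomophilyIndex:
    @staticmethod
    def _tm(diag, cats=("A", "B")):
        M = np.array([[diag[0], 1 - diag[0]], [1 - diag[1], diag[1]]])
        return TransitionMatrix("t", cats, M, np.ones((2, 2), int))

    def test_proportionate_recruitment_is_zero(self):
        T = self._tm([0.434, 0.566])
        h = homophily_index(T, {"A": 0.434, "B": 0.566})
        assert h["A"] == pytest.approx(0.0, abs=1e-12)
        assert h["B"] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_in_group_is_one(self):
        T = self._tm([1.0, 1.0])
        h = homophily_index(T, {"A": 0.3, "B": 0.7})
        assert h["A"] == 1.0 and h["B"] == 1.0

    def test_plug_in_arithmetic(self):
        """T[a,a]=0.75 against share 0.434: (0.75-0.434)/0.566 = 0.558."""
        T = self._tm([0.75, 0.5])
        h = homophily_index(T, {"A": 0.434, "B": 0.566})
        assert h["A"] == pytest.approx((0.75 - 0.434) / 0.566, abs=1e-12)
        assert h["A"] == pytest.approx(0.558, abs=0.001)

    def test_avoidance_is_negative_and_bounded(self):
        T = self._tm([0.0, 0.0])
        h = homophily_index(T, {"A": 0.3, "B": 0.7})
        assert h["A"] == -1.0 and h["B"] == -1.0

    def test_degenerate_share_rejected(self):
        T = self._tm([0.5, 0.5])
        with pytest.raises(DiagnosticsError):
            homophily_index(T, {"A": 0.0, "B": 1.0})

    def test_recovers_network_homophily_strength(self, homophilous_sim):
        """The estimated diagonal inflation of the recruitment transition
        matrix tracks the generating network homophily (0.4 on race)."""
        res = homophilous_sim["result"]
        pop = homophilous_sim["pop"]
        T = transition_matrix(res.respondents, res.edges, "race")
        shares = {c: float((pop["race"] == c).mean()) for c in T.categories}
        h = homophily_index(T, shares)
        for c in T.categories:
            assert 0.25 < h[c] < 0.55


class TestDesignEffect:
    def test_independent_equal_weight_draws_near_one(self):
        rng = np.random.default_rng(1)
        n = 4000
        y = rng.random(n) < 0.3
        w = np.ones(n)
        clusters = rng.integers(0, 400, n)  # arbitrary grouping of iid draws
        deff = design_effect(y, w, clusters=clusters)
        assert deff == pytest.approx(1.0, abs=0.2)

    def test_clustered_outcome_inflates_deff(self, homophilous_sim):
        """Recruitment chains plus a homophilous trait-linked outcome push
        the design effect above 1."""
        res = homophilous_sim["result"]
        r = res.respondents
        # cluster = recruitment chain root; outcome strongly linked to race
        from virtualrds.estimation import _chain_roots

        roots = _chain_roots(r)
        y = (r["race"].astype(str) == "white").to_numpy()
        deff = design_effect(y, np.ones(len(r)), clusters=roots)
        assert deff > 1.3

    def test_degenerate_prevalence_rejected(self):
        with pytest.raises(DiagnosticsError):
            design_effect(np.ones(10), np.ones(10), variance=0.01)

    def test_planning_constant_is_two(self):
        assert v.PLANNING_DESIGN_EFFECT == 2.0
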