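import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fluxgraphs as fg
from fluxgraphs.flux_balance import FluxSolution, SteadyStateError

from conftest import small_random_models


def nfg_triple_loop(model):
    """Independent edge-by-edge evaluation of the flow-probability weights."""
    sys = fg.unfold(model)
    n = model.n
    m2 = 2 * model.m
    D = np.zeros((m2, m2))
    for k in range(n):
        wp = sys.Splus[k].sum()
        wm = sys.Sminus[k].sum()
        if wp == 0 or wm == 0:
            continue
        for i in range(m2):
            for j in range(m2):
                D[i, j] += (sys.Splus[k, i] / wp) * (sys.Sminus[k, j] / wm)
    D /= n
    idx = np.flatnonzero(sys.active)
    return D[np.ix_(idx, idx)]


def mfg_triple_loop(model, v2m):
    """Independent proportional-allocation evaluation of the mass flows."""
    sys = fg.unfold(model)
    m2 = 2 * model.m
    M = np.zeros((m2, m2))
    for k in range(model.n):
        total = sum(sys.Sminus[k, h] * v2m[h] for h in range(m2))
        if total == 0:
            continue
        for i in range(m2):
            for j in range(m2):
                M[i, j] += (sys.Splus[k, i] * v2m[i]) * \
                           (sys.Sminus[k, j] * v2m[j]) / total
    return M


def balanced_solution(model, v):
    v2m, j = fg.unfold_fluxes(v, model, atol=1e-8)
    return FluxSolution(status="optimal", objective_value=float(model.c @ v),
                        v=v, v2m=v2m, j=j)


class TestUnfold:
    def test_reversible_column_sign_flip(self):
        model = fg.MetabolicModel(
            ["X1", "X2"], ["R"], S=np.array([[-1.0], [2.0]]),
            r=np.array([1]), lb=np.array([-10.0]), ub=np.array([10.0]),
            c=np.zeros(1))
        sys = fg.unfold(model)
        # forward: consumes 1 X1, produces 2 X2
        np.testing.assert_array_equal(sys.Sminus[:, 0], [1.0, 0.0])
        np.testing.assert_array_equal(sys.Splus[:, 0], [0.0, 2.0])
        # reverse: produces 1 X1, consumes 2 X2
        np.testing.assert_array_equal(sys.Splus[:, 1], [1.0, 0.0])
        np.testing.assert_array_equal(sys.Sminus[:, 1], [0.0, 2.0])

    def test_splits_are_complementary(self):
        for model in small_random_models(n_models=4):
            sys = fg.unfold(model)
            np.testing.assert_array_equal(sys.Splus - sys.Sminus, sys.S2m)
            assert np.all(sys.Splus * sys.Sminus == 0)
            np.testing.assert_array_equal(sys.wplus, sys.Splus.sum(axis=1))

    def test_irreversible_reverse_columns_are_zero_and_inactive(self, chain):
        sys = fg.unfold(chain)
        assert np.all(sys.S2m[:, 2:] == 0)
        assert sys.active.tolist() == [True, True, False, False]

    def test_ecoli_active_direction_count(self, ecoli):
        sys = fg.unfold(ecoli)
        assert int(sys.active.sum()) == 154


class TestRag:
    def test_diagonal_counts_metabolites_per_reaction(self, toy):
        rag = fg.build_rag(toy)
        j = toy.reaction_index("R8")  # biomass touches X3, X4, X5
        assert rag.W[j, j] == 3

    def test_shared_metabolite_count(self):
        # R1 and R2 share X1 and X2
        model = fg.MetabolicModel(
            ["X1", "X2", "X3"], ["R1", "R2"],
            S=np.array([[1.0, -1.0], [1.0, -1.0], [0.0, 1.0]]),
            r=np.zeros(2, int), lb=np.zeros(2), ub=np.full(2, 10.0),
            c=np.zeros(2))
        rag = fg.build_rag(model)
        assert rag.W[0, 1] == 2

    def test_symmetric_integer_weights(self):
        for model in small_random_models(n_models=4):
            rag = fg.build_rag(model)
            np.testing.assert_array_equal(rag.W, rag.W.T)
            assert np.all(rag.W == np.round(rag.W))
            assert not rag.directed


class TestNfg:
    def test_chain_single_edge_probability_one(self, chain):
        nfg = fg.build_nfg(chain)
        assert nfg.n_nodes == 2
        i, j = nfg.node_index("R1"), nfg.node_index("R2")
        assert nfg.W[i, j] == pytest.approx(1.0, abs=1e-15)
        assert nfg.total_weight() == pytest.approx(1.0, abs=1e-15)

    @pytest.mark.parametrize("seed", range(6))
    def test_weights_sum_to_coverage_fraction(self, seed):
        """Sum of weights = (#metabolites both produced and consumed) / n."""
        model = fg.random_model(
            fg.FixtureSpec(seed=seed), ensure_mass_flow=False)
        sys = fg.unfold(model)
        covered = int(np.sum((sys.wplus > 0) & (sys.wminus > 0)))
        nfg = fg.build_nfg(model, edge_threshold=0.0)
        assert nfg.total_weight() == pytest.approx(covered / model.n, abs=1e-12)

    def test_matrix_form_matches_triple_loop(self):
        for model in small_random_models(n_models=6):
            nfg = fg.build_nfg(model, edge_threshold=0.0)
            np.testing.assert_allclose(nfg.W, nfg_triple_loop(model), atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**20))
    def test_mass_flow_coverage_implies_unit_probability_mass(self, seed):
        rng = np.random.default_rng(seed)
        model = fg.random_model(fg.FixtureSpec(
            n_metabolites=int(rng.integers(3, 12)),
            n_reactions=int(rng.integers(4, 16)),
            fraction_reversible=float(rng.uniform(0, 0.9)),
            density=float(rng.uniform(0.1, 0.6)),
            seed=seed,
        ))
        nfg = fg.build_nfg(model, edge_threshold=0.0)
        assert abs(nfg.total_weight() - 1.0) <= 1e-12


class TestPairwiseFlow:
    def test_worked_allocation_example(self):
        """Producer at 1.5, consumer at 3.0 of a metabolite with total flux 10
        exchange 0.45 mmol/gDW/h."""
        # X1 produced by P1 (1.5) and P2 (8.5); consumed by C1 (3.0), C2 (7.0)
        model = fg.MetabolicModel(
            ["X1"], ["P1", "P2", "C1", "C2"],
            S=np.array([[1.0, 1.0, -1.0, -1.0]]),
            r=np.zeros(4, int), lb=np.zeros(4), ub=np.full(4, 100.0),
            c=np.zeros(4))
        v = np.array([1.5, 8.5, 3.0, 7.0])
        sol = balanced_solution(model, v)
        sys = fg.unfold(model)
        flow = fg.pairwise_flow(0, 0, 2, sys, sol)
        assert flow == pytest.approx(0.45, abs=1e-15)

    def test_sole_producer_and_consumer_pass_full_flux(self, chain):
        sol = balanced_solution(chain, np.array([4.0, 4.0]))
        sys = fg.unfold(chain)
        assert fg.pairwise_flow(0, 0, 1, sys, sol) == pytest.approx(4.0)

    def test_zero_flux_consumer_receives_nothing(self):
        model = fg.MetabolicModel(
            ["X1"], ["P", "C1", "C2"],
            S=np.array([[1.0, -1.0, -1.0]]),
            r=np.zeros(3, int), lb=np.zeros(3), ub=np.full(3, 100.0),
            c=np.zeros(3))
        sol = balanced_solution(model, np.array([5.0, 5.0, 0.0]))
        sys = fg.unfold(model)
        assert fg.pairwise_flow(0, 0, 2, sys, sol) == 0.0


class TestMfg:
    def test_chain_edge_carries_the_flux(self, chain):
        sol = balanced_solution(chain, np.array([2.0, 2.0]))
        mfg = fg.build_mfg(chain, sol)
        assert mfg.n_nodes == 2
        i, j = mfg.node_index("R1"), mfg.node_index("R2")
        assert mfg.W[i, j] == pytest.approx(2.0, abs=1e-12)
        assert mfg.weight_semantics == "flux_mmol_gDW_h"

    def test_matrix_form_matches_triple_loop(self):
        checked = 0
        for model in small_random_models(n_models=6):
            try:
                v = fg.random_balanced_flux(model, seed=11)
            except ValueError:
                continue
            sol = balanced_solution(model, v)
            mfg = fg.build_mfg(model, sol, flux_prune_rel=0.0,
                               edge_threshold=0.0)
            oracle = mfg_triple_loop(model, sol.v2m)
            sys = fg.unfold(model)
            idx = [k for k, nid in enumerate(sys.node_ids)
                   if sys.active[k] and nid in mfg.node_ids]
            sub = oracle[np.ix_(idx, idx)]
            np.testing.assert_allclose(mfg.W, sub, atol=1e-12)
            checked += 1
        assert checked >= 3

    def test_total_edge_mass_equals_total_consumed_metabolite_flux(self, ecoli):
        scen = fg.builtin_scenarios(ecoli)[0]
        sol = fg.solve_fba(ecoli, scen)
        mfg = fg.build_mfg(ecoli, sol)
        sys = fg.unfold(ecoli)
        consumption = sys.Sminus @ sol.v2m
        production = sys.Splus @ sol.v2m
        consumed = (consumption > 1e-9) & (production > 1e-9)
        assert mfg.total_weight() == pytest.approx(
            float(production[consumed].sum()), rel=1e-9)

    def test_row_sums_equal_node_production_when_all_consumed(self, chain):
        sol = balanced_solution(chain, np.array([3.0, 3.0]))
        mfg = fg.build_mfg(chain, sol)
        i = mfg.node_index("R1")
        assert mfg.W[i].sum() == pytest.approx(3.0)

    def test_zero_flux_reactions_are_pruned(self, toy):
        sol = fg.solve_fba(toy)
        assert sol.status == "optimal"
        mfg = fg.build_mfg(toy, sol)
        kept = {rid for rid, _ in mfg.node_ids}
        zero = {rid for rid, flux in zip(toy.reaction_ids, sol.v)
                if abs(flux) < 1e-9}
        assert kept.isdisjoint(zero)

    def test_unbalanced_solution_rejected_naming_worst_metabolite(self, chain):
        sol = FluxSolution(status="optimal", objective_value=0.0,
                           v=np.array([5.0, 1.0]),
                           v2m=np.array([5.0, 1.0, 0.0, 0.0]),
                           j=np.array([5.0]))
        with pytest.raises(SteadyStateError, match="X1"):
            fg.build_mfg(chain, sol)


class TestCompetitionSynergy:
    def test_two_rivals_for_one_molecule(self):
        # both reactions consume the single X1 molecule once: w- = 2
        model = fg.MetabolicModel(
            ["X1"], ["P", "C1", "C2"],
            S=np.array([[2.0, -1.0, -1.0]]),
            r=np.zeros(3, int), lb=np.zeros(3), ub=np.full(3, 10.0),
            c=np.zeros(3))
        comp = fg.build_competition_graph(model)
        i, j = comp.node_index("C1"), comp.node_index("C2")
        assert comp.W[i, j] == pytest.approx((1 / model.n) * (1 / 4), abs=1e-15)

    def test_symmetry_and_nonnegativity(self):
        for model in small_random_models(n_models=4):
            for graph in (fg.build_competition_graph(model),
                          fg.build_synergy_graph(model)):
                np.testing.assert_array_equal(graph.W, graph.W.T)
                assert np.all(graph.W >= 0)

    def test_no_shared_substrates_no_competition_edges(self, chain):
        comp = fg.build_competition_graph(chain)
        offdiag = comp.W - np.diag(np.diag(comp.W))
        assert np.all(offdiag == 0)

    def test_full_coverage_normalisation(self, seed=3):
        """When every metabolite is consumed, competition weights sum to 1."""
        model = fg.random_model(fg.FixtureSpec(seed=seed))
        comp = fg.build_competition_graph(model, edge_threshold=0.0)
        assert comp.total_weight() == pytest.approx(1.0, abs=1e-12)


class TestAverageGraphs:
    def test_average_of_identical_graphs_is_identity(self, chain):
        nfg = fg.build_nfg(chain)
        avg = fg.average_graphs([nfg, nfg, nfg])
        assert avg.node_ids == nfg.node_ids
        np.testing.assert_allclose(avg.W, nfg.W)

    def test_missing_edges_average_as_zero(self, chain):
        g1 = fg.build_nfg(chain)
        g2 = fg.ReactionGraph(node_ids=[("R1", "fwd")], W=np.zeros((1, 1)),
                              directed=True, weight_semantics="probability")
        avg = fg.average_graphs([g1, g2])
        i, j = avg.node_ids.index(("R1", "fwd")), avg.node_ids.index(("R2", "fwd"))
        assert avg.W[i, j] == pytest.approx(g1.W[0, 1] / 2)

    def test_mixed_semantics_rejected(self, chain):
        with pytest.raises(ValueError, match="semantics"):
            fg.average_graphs([fg.build_nfg(chain), fg.build_rag(chain)])


class TestWriters:
    def test_graphml_round_trip(self, tmp_path, toy):
        nfg = fg.build_nfg(toy)
        path = tmp_path / "nfg.graphml"
        fg.write_graphml(nfg, path, subsystem=toy.subsystem)
        back = fg.read_graphml(path)
        assert set(back.node_ids) == set(nfg.node_ids)
        perm = [back.node_ids.index(nid) for nid in nfg.node_ids]
        np.testing.assert_allclose(back.W[np.ix_(perm, perm)], nfg.W)

    def test_edgelist_weights_full_precision(self, tmp_path, chain):
        nfg = fg.build_nfg(chain)
        path = tmp_path / "edges.tsv"
        fg.write_edgelist(nfg, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "source\ttarget\tweight"
        src, tgt, w = lines[1].split("\t")
        assert (src, tgt) == ("R1[fwd]", "R2[fwd]")
        assert float(w) == nfg.W[0, 1]
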