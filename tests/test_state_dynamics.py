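import pytest

from brnkit import (attractors, build_state_graph, stable_states, successors)
from brnkit.logical_model import Entity, Interaction, LogicalNetwork, \
    Parameterization, ParameterSpec
from brnkit.state_dynamics import export_state_graph, state_graph_summary
from brnkit.synthetic import random_brn, toy_circuits

from conftest import MTOR_CYCLE_STATES, MTOR_STABLE_STATE
from oracles import naive_state_graph


class TestSuccessors:
    def test_deadlock_state_has_none(self, mtor):
        net, K = mtor
        assert successors(net, K, MTOR_STABLE_STATE) == set()

    def test_pten_rescue_transition(self, mtor):
        # with PTEN present, overactive PI3K is pushed back down
        net, K = mtor
        assert (0, 1, 1, 1, 1, 0) in successors(net, K, (1, 1, 1, 1, 1, 0))

    def test_all_zero_state_calls(self, mtor):
        # every entity whose empty-resource parameter is nonzero steps up;
        # inhibitor-absence counts as a resource for PI3K/PTEN/mTORC2/
        # mTORC1/FOXO but Akt needs both its activators
        net, K = mtor
        succ = successors(net, K, (0, 0, 0, 0, 0, 0))
        assert len(succ) == 5
        changed = {net.entity_order[i]
                   for s in succ for i in range(6) if s[i] != 0}
        assert changed == {"PI3K", "PTEN", "mTORC2", "mTORC1", "FOXO"}


class TestBuildStateGraph:
    def test_mtor_counts(self, mtor_graph):
        assert mtor_graph.n_states == 64
        assert mtor_graph.n_edges == 192

    def test_single_decaying_entity(self):
        net = LogicalNetwork([Entity("x")], [],
                             [ParameterSpec("x", frozenset(), (0,))])
        K = Parameterization({("x", frozenset()): 0})
        sg = build_state_graph(net, K)
        assert sg.n_states == 2 and sg.n_edges == 1
        assert list(sg.graph.edges) == [((1,), (0,))]

    def test_unit_step_edges(self, mtor_graph):
        for u, v in mtor_graph.graph.edges:
            diffs = [abs(a - b) for a, b in zip(u, v)]
            assert sum(diffs) == 1 and max(diffs) == 1

    def test_state_cap(self, mtor):
        net, K = mtor
        with pytest.raises(ValueError):
            build_state_graph(net, K, cap=10)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_naive_builder_on_random_networks(self, seed):
        net, K = random_brn(4, density=0.5, max_level=2, seed=seed)
        sg = build_state_graph(net, K)
        nodes, edges = naive_state_graph(net, K)
        assert set(sg.graph.nodes) == nodes
        assert set(sg.graph.edges) == edges


class TestStableStatesAndAttractors:
    def test_mtor_unique_stable_state(self, mtor_graph):
        assert stable_states(mtor_graph) == [MTOR_STABLE_STATE]
        rep = attractors(mtor_graph)
        assert rep.n_attractors == 1
        assert rep.kinds == ["stable"]
        assert rep.attractors[0] == frozenset({MTOR_STABLE_STATE})

    def test_stable_iff_no_successor(self, mtor):
        net, K = mtor
        sg = build_state_graph(net, K)
        for s in sg.graph.nodes:
            assert (sg.graph.out_degree(s) == 0) == \
                (successors(net, K, s) == set())

    def test_mutual_activation_bistable(self):
        net, K = toy_circuits()["mutual_activation"]
        sg = build_state_graph(net, K)
        assert sorted(stable_states(sg)) == [(0, 0), (1, 1)]

    def test_negative_loop_oscillates(self):
        net, K = toy_circuits()["negative_loop"]
        sg = build_state_graph(net, K)
        assert stable_states(sg) == []
        rep = attractors(sg)
        assert rep.n_attractors == 1
        assert rep.kinds == ["cyclic"]
        assert rep.attractors[0] == frozenset({(0, 0), (1, 0), (1, 1), (0, 1)})

    def test_edgeless_graph_all_stable(self):
        # a self-sustaining entity: both levels are fixed points
        net = LogicalNetwork(
            [Entity("x")], [Interaction("x", "x", "+")],
            [ParameterSpec("x", frozenset(), (0,)),
             ParameterSpec("x", frozenset({"x"}), (1,))])
        K = Parameterization({("x", frozenset()): 0,
                              ("x", frozenset({"x"})): 1})
        sg = build_state_graph(net, K)
        assert sg.n_edges == 0
        rep = attractors(sg)
        assert rep.n_attractors == 2
        assert rep.kinds == ["stable", "stable"]


class TestCycleEmbedding:
    def test_printed_cycle_transitions_are_edges(self, mtor_graph):
        states = MTOR_CYCLE_STATES
        for a, b in zip(states, states[1:] + states[:1]):
            assert mtor_graph.graph.has_edge(a, b)

    def test_stable_state_degrees(self, mtor_graph):
        assert mtor_graph.graph.out_degree(MTOR_STABLE_STATE) == 0
        assert mtor_graph.graph.in_degree(MTOR_STABLE_STATE) > 0


class TestExport:
    def test_graphml_and_summary(self, mtor_graph, tmp_path):
        import networkx as nx
        p = tmp_path / "g.graphml"
        export_state_graph(mtor_graph, "graphml", p)
        g = nx.read_graphml(p)
        assert g.number_of_nodes() == 64
        assert g.number_of_edges() == 192
        assert g.nodes["101110"]["stable"] is True
        summary = state_graph_summary(mtor_graph)
        assert summary == {"n_states": 64, "n_edges": 192,
                           "stable_states": ["101110"], "n_attractors": 1}

    def test_dot_output(self, mtor_graph, tmp_path):
        p = tmp_path / "g.dot"
        export_state_graph(mtor_graph, "dot", p)
        text = p.read_text()
        assert text.count("->") == 192
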