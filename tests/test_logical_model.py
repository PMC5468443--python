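import random

import pytest

from brnkit import logical_model as lm
from brnkit.logical_model import (Entity, Interaction, LogicalNetwork,
                                  Parameterization, focal, read_model,
                                  regulators, resources, snoussi_holds,
                                  write_model)

from conftest import MTOR_STABLE_STATE


class TestRegulators:
    @pytest.mark.parametrize("target, expected", [
        ("Akt", ["PI3K", "mTORC2"]),
        ("PTEN", ["PI3K"]),
        ("PI3K", ["PTEN", "mTORC1"]),
        ("mTORC2", ["FOXO", "PI3K", "mTORC1"]),
        ("FOXO", ["Akt", "mTORC1"]),
    ])
    def test_mtor_regulators(self, mtor, target, expected):
        net, _ = mtor
        assert regulators(net, target) == sorted(expected)

    def test_isolated_node(self):
        net = LogicalNetwork([Entity("a"), Entity("b")],
                             [Interaction("a", "b", "+")])
        assert regulators(net, "a") == []

    def test_unknown_target(self, mtor):
        net, _ = mtor
        with pytest.raises(lm.ModelError):
            regulators(net, "nope")


class TestResources:
    def test_stable_state_resource_sets(self, mtor):
        # hand evaluation of the resource rule at the deadlock state
        net, _ = mtor
        s = MTOR_STABLE_STATE
        assert resources(net, s, "PI3K") == {"PTEN"}
        assert resources(net, s, "Akt") == {"mTORC2", "PI3K"}
        assert resources(net, s, "PTEN") == set()
        assert resources(net, s, "mTORC1") == {"Akt", "FOXO"}

    def test_all_zero_state(self, mtor):
        net, _ = mtor
        assert resources(net, (0,) * 6, "Akt") == set()
        # inhibitors absent count as resources
        assert resources(net, (0,) * 6, "FOXO") == {"Akt", "mTORC1"}

    def test_resources_subset_of_regulators_randomized(self, mtor):
        net, _ = mtor
        rng = random.Random(7)
        for _ in range(50):
            s = tuple(rng.randint(0, 1) for _ in range(6))
            for t in net.entity_order:
                assert resources(net, s, t) <= set(regulators(net, t))

    def test_malformed_state(self, mtor):
        net, _ = mtor
        with pytest.raises(lm.ModelError):
            resources(net, (0, 0, 0), "Akt")
        with pytest.raises(lm.ModelError):
            resources(net, (2, 0, 0, 0, 0, 0), "Akt")


class TestFocal:
    def test_retained_parameter_values(self, mtor):
        net, K = mtor
        assert focal(net, K, (0,) * 6, "FOXO") == 1   # both inhibitors absent
        assert focal(net, K, MTOR_STABLE_STATE, "PTEN") == 0
        # PTEN and mTORC1 both present: no resources for PI3K
        assert focal(net, K, (1, 1, 0, 0, 1, 0), "PI3K") == 0

    def test_stable_state_is_focal_everywhere(self, mtor):
        net, K = mtor
        for t in net.entity_order:
            i = net.index(t)
            assert focal(net, K, MTOR_STABLE_STATE, t) == MTOR_STABLE_STATE[i]

    def test_missing_parameter(self, mtor):
        net, K = mtor
        K2 = Parameterization(K)
        del K2[("Akt", frozenset())]
        with pytest.raises(lm.ModelError):
            focal(net, K2, (0,) * 6, "Akt")


class TestSnoussi:
    def test_retained_parameterization_is_monotone(self, mtor):
        net, K = mtor
        assert snoussi_holds(net, K)

    def test_inclusion_violation_detected(self, mtor):
        net, K = mtor
        K2 = Parameterization(K)
        K2[("PI3K", frozenset({"PTEN"}))] = 1
        K2[("PI3K", frozenset({"mTORC1", "PTEN"}))] = 0
        assert not snoussi_holds(net, K2)

    def test_no_regulators_trivially_monotone(self):
        net = LogicalNetwork([Entity("a")], [])
        assert snoussi_holds(net, Parameterization({("a", frozenset()): 0}))

    def test_invariant_under_entity_relabeling(self, mtor):
        net, K = mtor
        mapping = {n: f"n{i}" for i, n in enumerate(net.entity_order)}
        ents = [Entity(mapping[e.name], e.max_level) for e in net.entities]
        ias = [lm.Interaction(mapping[i.source], mapping[i.target], i.sign,
                              i.threshold) for i in net.interactions]
        specs = [lm.ParameterSpec(mapping[s.target],
                                  frozenset(mapping[r] for r in s.resources),
                                  s.range) for s in net.parameter_specs]
        net2 = LogicalNetwork(ents, ias, specs)
        K2 = Parameterization({(mapping[t], frozenset(mapping[r] for r in res)): v
                               for (t, res), v in K.items()})
        assert snoussi_holds(net2, K2) == snoussi_holds(net, K)


class TestSchema:
    def test_parameter_completeness_count(self, mtor):
        # sum over targets of 2^(number of regulators): 4+2+8+4+4+4 = 26
        net, K = mtor
        assert len(net.parameter_specs) == 26
        assert len(K) == 26
        net.complete_specs()

    def test_round_trip(self, mtor, tmp_path):
        net, _ = mtor
        p = tmp_path / "m.yaml"
        write_model(net, p)
        net2 = read_model(p)
        assert net2.entity_order == net.entity_order
        assert set(net2.interactions) == set(net.interactions)
        assert set(net2.parameter_specs) == set(net.parameter_specs)
        assert net2.selected == net.selected

    def test_selected_outside_range_rejected(self, mtor, tmp_path):
        import yaml
        net, _ = mtor
        doc = lm.network_to_dict(net)
        doc["selected"][0]["value"] = 1  # K_PI3K({}) has range [0]
        p = tmp_path / "bad.yaml"
        p.write_text(yaml.safe_dump(doc))
        with pytest.raises(lm.ModelError):
            read_model(p)

    def test_duplicate_interaction_rejected(self):
        with pytest.raises(lm.ModelError):
            LogicalNetwork([Entity("a"), Entity("b")],
                           [Interaction("a", "b", "+"),
                            Interaction("a", "b", "-")])

    def test_dot_export_mentions_all_edges(self, mtor):
        net, _ = mtor
        dot = lm.network_to_dot(net)
        assert dot.count("->") == len(net.interactions)
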