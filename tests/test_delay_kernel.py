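import random
from fractions import Fraction

import pytest

from brnkit import delay_kernel as dk
from brnkit.polyhedra import EQ, LT, LinearConstraint
from brnkit.state_graph_analysis import QualitativeCycle
from brnkit.synthetic import random_cycle_instance

from conftest import MTOR_CYCLE_STATES


@pytest.fixture(scope="module")
def mtor_system(mtor):
    net, _ = mtor
    cycle = QualitativeCycle.from_states(MTOR_CYCLE_STATES)
    events, constants = dk.cycle_events(cycle, net.entity_order)
    return dk.build_timing_system(events, len(cycle), constants)


@pytest.fixture(scope="module")
def mtor_kernel(mtor_system):
    return dk.project_delay_constraints(mtor_system)


def toggle_system():
    cycle = QualitativeCycle.from_states([(0,), (1,)])
    events, constants = dk.cycle_events(cycle, ("x",))
    return dk.build_timing_system(events, 2, constants)


class TestCycleEvents:
    def test_mtor_event_sequence(self, mtor):
        net, _ = mtor
        # use the printed rotation so positions match the published listing
        cycle = QualitativeCycle(tuple(MTOR_CYCLE_STATES))
        events, constants = dk.cycle_events(cycle, net.entity_order)
        assert [(e.entity, e.direction) for e in events] == [
            ("Akt", 1), ("FOXO", -1), ("mTORC1", 1), ("PI3K", -1),
            ("Akt", -1), ("mTORC2", -1), ("FOXO", 1), ("mTORC1", -1),
            ("mTORC2", 1), ("PI3K", 1)]
        assert [e.position for e in events] == list(range(1, 11))
        assert constants == {"PTEN": 1}

    def test_toggle_events(self):
        cycle = QualitativeCycle.from_states([(0,), (1,)])
        events, constants = dk.cycle_events(cycle, ("x",))
        assert [(e.entity, e.direction) for e in events] == \
            [("x", 1), ("x", -1)]
        assert constants == {}


class TestTimingSystem:
    def test_mtor_shape(self, mtor):
        net, _ = mtor
        cycle = QualitativeCycle(tuple(MTOR_CYCLE_STATES))
        events, constants = dk.cycle_events(cycle, net.entity_order)
        system = dk.build_timing_system(events, 10, constants)
        assert len(system.equations) == 10
        assert len(system.delay_symbols) == 10

        # the Akt degradation window spans locations 2..5 (rise leaving 1,
        # fall leaving 5); the mTORC2 one wraps 10,1..6 and contains it
        def window(sym):
            for eq in system.equations:
                if eq.coeff(sym) == -1:
                    return {v for v, _ in eq.terms if v.startswith("d_")}
            raise KeyError(sym)

        akt_fall = window("dAkt-")
        mtorc2_fall = window("dmTORC2-")
        assert akt_fall == {"d_2", "d_3", "d_4", "d_5"}
        assert mtorc2_fall == {"d_10", "d_1", "d_2", "d_3", "d_4", "d_5", "d_6"}
        assert akt_fall < mtorc2_fall

    def test_toggle_windows(self):
        system = toggle_system()
        assert len(system.equations) == 2
        assert {str(eq) for eq in system.equations} == \
            {"d_1 - dx+ = 0", "d_2 - dx- = 0"}

    def test_single_event_entity_rejected(self):
        ev = [dk.CycleEvent("x", 1, 1), dk.CycleEvent("y", -1, 2)]
        with pytest.raises(ValueError):
            dk.build_timing_system(ev, 2)


class TestProjection:
    def test_toggle_projects_to_positivity_only(self):
        kernel = dk.project_delay_constraints(toggle_system())
        assert kernel.constraints == []   # any positive delays admit a toggle
        assert {s.name for s in kernel.symbols} == {"dx+", "dx-"}

    def test_no_duration_variables_survive(self, mtor_kernel):
        names = {s.name for s in mtor_kernel.symbols}
        for c in mtor_kernel:
            assert c.variables() <= names

    def test_equal_periods(self, mtor_kernel):
        for x in ("PI3K", "Akt", "mTORC1", "FOXO"):
            assert mtor_kernel.entails(
                dk.parse_constraint(f"pi({x}) = pi(mTORC2)"))

    def test_akt_mtorc2_degradation_order(self, mtor_kernel):
        assert mtor_kernel.entails(dk.parse_constraint("dAkt- <= dmTORC2-"))

    def test_strict_order_witness_and_reverse_infeasibility(self, mtor_kernel):
        strictly_less = LinearConstraint.make(
            {"dAkt-": 1, "dmTORC2-": -1}, 0, LT)
        ok, w = dk.feasible(mtor_kernel.with_positivity(), [strictly_less])
        assert ok and w["dAkt-"] < w["dmTORC2-"]
        reverse = LinearConstraint.make({"dmTORC2-": 1, "dAkt-": -1}, 0, LT)
        assert dk.feasible(mtor_kernel.with_positivity(), [reverse])[0] is False

    def test_canonicalization_idempotent(self, mtor_kernel, mtor_system):
        again = dk.project_delay_constraints(mtor_system)
        assert again.constraints == mtor_kernel.constraints


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(4))
    def test_membership_iff_schedulable_mtor(self, mtor_system, mtor_kernel,
                                             seed):
        rng = random.Random(seed)
        for _ in range(25):
            point = {s.name: Fraction(rng.randint(1, 12))
                     for s in mtor_system.delay_symbols}
            ok, schedule = dk.simulate_cycle(point, mtor_system)
            assert ok == mtor_kernel.contains(point)
            if ok:
                assert all(v >= 0 for v in schedule.values())
                for eq in mtor_system.equations:
                    assert eq.evaluate({**schedule, **point})

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_membership_iff_schedulable_random_cycles(self, n):
        _, _, _, system = random_cycle_instance(n, seed=n)
        kernel = dk.project_delay_constraints(system)
        rng = random.Random(n)
        for _ in range(25):
            point = {s.name: Fraction(rng.randint(1, 8), rng.randint(1, 3))
                     for s in system.delay_symbols}
            ok, _ = dk.simulate_cycle(point, system)
            assert ok == kernel.contains(point)

    def test_random_cycles_have_equal_periods(self):
        for seed in range(5):
            _, _, _, system = random_cycle_instance(3, seed=seed)
            kernel = dk.project_delay_constraints(system)
            names = sorted({s.entity for s in system.delay_symbols})
            for a, b in zip(names, names[1:]):
                assert kernel.entails(dk.parse_constraint(f"pi({a}) = pi({b})"))


class TestRelationMatrix:
    def test_forced_equality(self):
        syms = [dk.DelaySymbol("a", "+"), dk.DelaySymbol("b", "+")]
        cons = [LinearConstraint.make({"da+": 1, "db+": -1}, 0, EQ)]
        m = dk.relation_matrix(cons, syms)
        assert m.relation("da+", "db+") == dk.FORCED_EQ

    def test_mtor_headline_pair_forced(self, mtor_kernel):
        m = dk.relation_matrix(mtor_kernel)
        assert m.relation("dAkt-", "dmTORC2-") == dk.FORCED_LE
        assert m.relation("dmTORC2-", "dAkt-") == dk.FORCED_GE

    def test_mtor_free_pair(self, mtor_kernel):
        m = dk.relation_matrix(mtor_kernel)
        assert m.relation("dFOXO+", "dPI3K+") == dk.FREE

    def test_dataframe_rendering(self, mtor_kernel):
        m = dk.relation_matrix(mtor_kernel)
        df = m.to_dataframe()
        assert df.loc["dAkt-", "dmTORC2-"] == "<=" \
            or df.loc["dmTORC2-", "dAkt-"] == ">="


class TestConstraintFormat:
    @pytest.mark.parametrize("text", [
        "dFOXO+ <= dmTORC1- + dAkt-",
        "pi(FOXO) + dPI3K- <= pi(Akt) + pi(mTORC1)",
        "2*dA+ - 1/2 dB- >= 0",
        "pi(X) = pi(Y)",
    ])
    def test_parse_round_trip(self, text):
        c = dk.parse_constraint(text)
        assert dk.parse_constraint(str(c)) == c

    def test_pi_expansion(self):
        c = dk.parse_constraint("pi(A) <= dB+")
        assert c.variables() == {"dA+", "dA-", "dB+"}

    def test_packaged_constraint_file_loads(self):
        from importlib import resources
        path = resources.files("brnkit") / "data" / "mtor_delay_constraints.txt"
        cons = dk.read_constraints(str(path))
        assert len(cons) == 9

    def test_write_read_round_trip(self, mtor_kernel, tmp_path):
        p = tmp_path / "kernel.txt"
        dk.write_constraints(mtor_kernel.constraints, p)
        again = dk.read_constraints(p)
        assert again == [c.canonical() for c in mtor_kernel.constraints]
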