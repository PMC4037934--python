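"""The repair algorithm: projection, sensitivity, templates, failure cases,
application, verification and attractor elimination."""

import itertools

import pytest

from boolrepair import (
    Attractor,
    ContractionError,
    Damage,
    NetworkState,
    RuleModification,
    apply_modifications,
    attractors_and_basins,
    eliminate_attractor,
    enumerate_modifications,
    find_synchronous_attractor,
    ga_transition_matrix,
    identify_sensitive_nodes,
    parse_rules,
    project_attractor,
    repair,
    superset_state,
    synchronous_step,
    verify_repair,
)
from boolrepair.fixtures import ABA_CYCLE, APOPTOSIS_STATE, TLGL_STATE
from boolrepair.network import evaluate_expr
from boolrepair.repair import _ORIG_REQUIRED, compose_expression


def att_from_strings(strings, kind="limit_cycle"):
    return Attractor(kind, tuple(NetworkState.from_string(s) for s in strings))


def dummy_net(n):
    """n-node identity network, used only for name/index resolution."""
    names = [chr(ord("A") + i) for i in range(n)]
    return parse_rules("\n".join(f"{x} = {x}" for x in names))


class TestProjection:
    def test_two_states_merge_into_one(self):
        net = dummy_net(3)
        att = att_from_strings(["101", "001"])
        t = project_attractor(net, att, Damage("A", 1))
        assert [str(s) for s in t.states] == ["101"]
        assert t.mode == "steady_state"

    def test_six_cycle_contracts_to_five(self):
        # knocking out the third node maps the sixth state onto the first:
        # the repairable cycle has five states, not six
        net = dummy_net(5)
        att = att_from_strings(
            ["11001", "01011", "10111", "10101", "01101", "11101"]
        )
        t = project_attractor(net, att, Damage("C", 0))
        assert len(t.states) == 5
        assert {str(s) for s in t.states} == \
            {"11001", "01011", "10011", "10001", "01001"}
        # single cycle: desired_next is a 5-cycle permutation
        cur = t.states[0]
        seen = []
        for _ in range(5):
            seen.append(cur)
            cur = t.desired_next[cur]
        assert cur == t.states[0] and len(set(seen)) == 5

    def test_aba_caim_projection_stays_five_distinct(self, aba):
        t = project_attractor(aba.network, aba.attractors[0], Damage("CaIM", 0))
        assert len(t.states) == 5
        i = aba.network.index["CaIM"]
        assert all(s.bits[i] == 0 for s in t.states)

    def test_steady_state_projects_to_fixed_target(self, tlgl):
        att = att_from_strings([APOPTOSIS_STATE], kind="steady_state")
        t = project_attractor(tlgl.network, att, Damage("FAS", 1))
        s = t.states[0]
        assert str(s) == "001001"
        assert t.desired_next[s] == s

    def test_inconsistent_collision_raises_unless_largest(self):
        net = dummy_net(3)
        att = att_from_strings(["000", "001", "100", "011"])
        with pytest.raises(ContractionError):
            project_attractor(net, att, Damage("A", 0))
        t = project_attractor(net, att, Damage("A", 0),
                              on_collision="largest")
        assert len(t.states) == 2  # largest formable simple cycle


class TestSuperset:
    def test_figure_style_five_state_superset(self):
        net = dummy_net(5)
        att = att_from_strings(
            ["11001", "01011", "10011", "10001", "01001"]
        )
        assert str(superset_state(net, att, Damage("C", 0))) == "11011"

    def test_superset_of_steady_state_is_itself(self, tlgl):
        att = att_from_strings([TLGL_STATE], kind="steady_state")
        assert str(superset_state(tlgl.network, att)) == TLGL_STATE

    def test_aba_cycle_superset_all_ones(self, aba):
        assert str(superset_state(aba.network, aba.attractors[0])) == "1" * 7

    def test_threshold_variant(self):
        net = dummy_net(2)
        att = att_from_strings(["10", "10", "01"])
        assert str(superset_state(net, att, on_fraction=0.5)) == "10"


class TestSensitivity:
    def test_aba_caim_damage_only_calcium_sensitive(self, aba):
        d = Damage("CaIM", 0)
        t = project_attractor(aba.network, aba.attractors[0], d)
        recs = identify_sensitive_nodes(aba.network, d, t)
        assert [r.node for r in recs] == ["Ca2+c"]
        assert len(recs[0].mismatches) == 2  # 2 of the 5 transitions

    def test_tlgl_apoptosis_knockout_sensitive_trio(self, tlgl):
        d = Damage("Apoptosis", 0)
        att = att_from_strings([APOPTOSIS_STATE], kind="steady_state")
        t = project_attractor(tlgl.network, att, d)
        recs = identify_sensitive_nodes(tlgl.network, d, t)
        assert sorted(r.node for r in recs) == ["FAS", "FLIP", "S1P"]

    def test_non_downstream_nodes_robust(self, aba):
        # Closure regulates nothing, so damaging it deregulates no one
        d = Damage("Closure", 0)
        t = project_attractor(aba.network, aba.attractors[0], d)
        assert identify_sensitive_nodes(aba.network, d, t) == []


def oracle_enumerate(net, node, state, desired, pool):
    """Independent brute force: compose each template as an expression tree,
    evaluate it, and apply the paired-regulator occupancy rule."""
    f = net.functions[node]
    found = set()
    for family in ("and", "or"):
        for new in pool:
            combos = [(1, None), (2, None)] + [
                (row, orig) for row, orig in
                itertools.product((3, 4, 5, 6), f.regulators)
            ]
            for row, orig in combos:
                mod = RuleModification(node, family, row, new, orig)
                if orig is not None:
                    req = _ORIG_REQUIRED[(family, row)]
                    if state.bits[net.index[orig]] != req:
                        continue
                composed = mod.compose(f.expression)
                if evaluate_expr(composed, net.env(state)) == desired:
                    found.add((family, row, new, orig))
    return found


class TestEnumerateModifications:
    def test_three_node_example_against_brute_force(self):
        net = parse_rules("A = B\nB = B\nC = C")
        state = NetworkState.from_string("110")
        pool = ["A", "C"]  # non-regulators of A (A does not self-regulate)
        mods = enumerate_modifications(net, "A", state, 0, pool)
        got = {(m.family, m.row, m.new_regulator, m.orig_regulator)
               for m in mods}
        assert got == oracle_enumerate(net, "A", state, 0, pool)
        # forcing OFF at a state where C is OFF: "... and C" qualifies
        assert ("and", 1, "C", None) in got
        # paired form "... and (not A or not B)" with A new, B orig
        assert ("and", 5, "A", "B") in got

    def test_aba_off_to_on_includes_not_kout(self, aba):
        state = aba.network.state_from_string("0000000")
        pool = [n for n in aba.network.node_names
                if n not in aba.network.functions["Ca2+c"].regulators]
        mods = enumerate_modifications(aba.network, "Ca2+c", state, 1, pool)
        assert any(m.family == "or" and m.row == 2 and
                   m.new_regulator == "KOUT" for m in mods)

    def test_brute_force_on_random_states(self, random_net):
        import numpy as np

        net = random_net(n=6, k=2, seed=11)
        rng = np.random.default_rng(4)
        for _ in range(10):
            state = NetworkState(tuple(rng.integers(0, 2, 6).tolist()))
            node = net.node_names[int(rng.integers(6))]
            desired = int(rng.integers(2))
            pool = [n for n in net.node_names
                    if n not in net.functions[node].regulators]
            mods = enumerate_modifications(net, node, state, desired, pool)
            got = {(m.family, m.row, m.new_regulator, m.orig_regulator)
                   for m in mods}
            assert got == oracle_enumerate(net, node, state, desired, pool)

    def test_pool_with_current_regulator_rejected(self, aba):
        with pytest.raises(Exception):
            enumerate_modifications(
                aba.network, "Ca2+c",
                aba.network.state_from_string("0000000"), 1, ["CaIM"],
            )


class TestRepairTaxonomy:
    @pytest.mark.parametrize("node,expected", [
        ("CIS", "already_stable"),
        ("Closure", "already_stable"),
        ("Ca2+ATPase", "repaired"),
        ("CaIM", "repaired"),
        ("Depolar", "failure_case_2"),
        ("KOUT", "failure_case_3"),
        ("Ca2+c", "failure_case_3"),
    ])
    def test_aba_knockout_classification(self, aba, node, expected):
        r = repair(aba.network, aba.attractors[0], Damage(node, 0),
                   "limit_cycle")
        assert r.status == expected

    def test_caim_repair_contains_or_not_kout(self, aba):
        d = Damage("CaIM", 0)
        r = repair(aba.network, aba.attractors[0], d, "limit_cycle")
        mods = r.viable["Ca2+c"]
        kout = [m for m in mods if m.family == "or" and m.row == 2
                and m.new_regulator == "KOUT"]
        assert kout, "expected the 'or not KOUT' modification"
        repaired = apply_modifications(aba.network, [kout[0]])
        ok, report = verify_repair(repaired, d, r.target)
        assert ok
        # no alternative attractors anywhere in the 128-state space
        assert report["new_attractors"] == []

    def test_failure_diagnostics_name_offenders(self, aba):
        r = repair(aba.network, aba.attractors[0], Damage("Depolar", 0))
        assert r.status == "failure_case_2"
        assert r.diagnostics["node"]

    def test_superset_mode_always_repairs_aba(self, aba):
        for node in aba.network.node_names:
            r = repair(aba.network, aba.attractors[0], Damage(node, 0),
                       "superset")
            assert r.status in ("already_stable", "repaired")
            if r.status == "repaired":
                repaired = apply_modifications(
                    aba.network, [mods[0] for mods in r.viable.values()]
                )
                ok, _ = verify_repair(repaired, Damage(node, 0), r.target)
                assert ok

    def test_every_viable_modification_works_alone(self, aba):
        # each viable choice, combined with any choice for other nodes,
        # reproduces every desired transition (exhaustive check)
        d = Damage("Ca2+ATPase", 0)
        r = repair(aba.network, aba.attractors[0], d)
        assert r.status == "repaired"
        for node, mods in r.viable.items():
            for m in mods:
                repaired = apply_modifications(aba.network, [m])
                ok, _ = verify_repair(repaired, d, r.target)
                assert ok


class TestApplyModifications:
    def test_tlgl_disc_rewrite_matches_published_rule(self, tlgl):
        mod = RuleModification("DISC", "or", 1, "S1P",
                               context="not Apoptosis")
        net2 = apply_modifications(tlgl.network, [mod])
        assert net2.functions["DISC"].text() == \
            "(Ceramide or FAS and not FLIP or S1P) and not Apoptosis"
        # logically identical to the printed
        # "((Ceramide or (FAS and not FLIP)) or S1P) and not Apoptosis"
        ref = parse_rules(
            "S1P = S1P\nFLIP = FLIP\nFAS = FAS\nCeramide = Ceramide\n"
            "DISC = ((Ceramide or (FAS and not FLIP)) or S1P) and not Apoptosis\n"
            "Apoptosis = Apoptosis"
        )
        assert net2.functions["DISC"].truth_table() == \
            ref.functions["DISC"].truth_table()

    def test_empty_modification_list_is_identity(self, aba):
        net2 = apply_modifications(aba.network, [])
        for n in aba.network.node_names:
            assert net2.functions[n].truth_table() == \
                aba.network.functions[n].truth_table()

    def test_two_modifications_on_one_node_rejected(self, aba):
        m1 = RuleModification("Ca2+c", "or", 2, "KOUT")
        m2 = RuleModification("Ca2+c", "or", 1, "Depolar")
        with pytest.raises(Exception):
            apply_modifications(aba.network, [m1, m2])

    def test_existing_regulator_as_new_rejected(self, aba):
        bad = RuleModification("Ca2+c", "or", 1, "CaIM")
        with pytest.raises(Exception):
            compose_expression(aba.network, bad)

    def test_applied_repair_adds_exactly_one_regulator(self, aba):
        mod = RuleModification("Ca2+c", "or", 2, "KOUT")
        net2 = apply_modifications(aba.network, [mod])
        before = set(aba.network.functions["Ca2+c"].regulators)
        after = set(net2.functions["Ca2+c"].regulators)
        assert after == before | {"KOUT"}


class TestVerifyRepair:
    def test_unrepaired_damaged_network_fails(self, aba):
        d = Damage("CaIM", 0)
        t = project_attractor(aba.network, aba.attractors[0], d)
        ok, _ = verify_repair(aba.network, d, t)
        assert not ok


class TestEliminateAttractor:
    def test_tlgl_elimination_includes_s1p(self, tlgl):
        net = tlgl.network
        mods = eliminate_attractor(net, net.state_from_string(TLGL_STATE),
                                   "DISC", context="not Apoptosis")
        s1p = [m for m in mods if m.row == 1 and m.new_regulator == "S1P"]
        assert s1p, "expected the 'or S1P' modification"

    def test_every_returned_modification_breaks_fixed_point(self, tlgl):
        net = tlgl.network
        bad = net.state_from_string(TLGL_STATE)
        mods = eliminate_attractor(net, bad, "DISC", context="not Apoptosis")
        assert mods
        for m in mods:
            net2 = apply_modifications(net, [m])
            assert synchronous_step(net2, bad) != bad

    def test_modified_network_single_attractor_full_basin(self, tlgl):
        net = tlgl.network
        mods = eliminate_attractor(net, net.state_from_string(TLGL_STATE),
                                   "DISC", context="not Apoptosis")
        s1p = [m for m in mods if m.row == 1 and m.new_regulator == "S1P"][0]
        net2 = apply_modifications(net, [s1p])
        an = attractors_and_basins(ga_transition_matrix(net2))
        assert len(an.attractors) == 1
        assert an.attractors[0].state_strings == (APOPTOSIS_STATE,)
        assert all(v == frozenset({0}) for v in an.basins.values())

    def test_non_fixed_point_rejected(self, tlgl):
        with pytest.raises(Exception):
            eliminate_attractor(
                tlgl.network, tlgl.network.state_from_string("111111"), "DISC"
            )


class TestPoolExhaustion:
    def test_fully_regulated_node_raises_named_error(self):
        from boolrepair import PoolExhaustedError

        net = parse_rules("A = A and B and C\nB = B\nC = C")
        att = att_from_strings(["111"], kind="steady_state")
        with pytest.raises(PoolExhaustedError, match="A"):
            repair(net, att, Damage("B", 0), "steady_state")
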