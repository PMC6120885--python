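import itertools

import numpy as np
import pandas as pd
import pytest

import craft
from craft import causal
from craft.causal import (
    DirectedTargetSets,
    EffectTest,
    Regulome,
    SubModule,
    compose_signs,
    receptor_target_sets,
    therapeutic_direction,
)
from craft.coexpression import ModulePartition
from craft.core_io import DETable, FormatError


def regulome_of(rt, tt) -> Regulome:
    return Regulome(frozenset(rt), frozenset(tt))


def random_regulome(rng, n_receptors=5, n_tfs=8, n_genes=30, n_edges=60) -> Regulome:
    receptors = [f"R{i}" for i in range(n_receptors)]
    tfs = [f"T{i}" for i in range(n_tfs)]
    genes = [f"g{i}" for i in range(n_genes)]
    rt = {(rng.choice(receptors), rng.choice(tfs), rng.choice(causal.SIGNS))
          for _ in range(n_edges // 3)}
    tt = {(rng.choice(tfs), rng.choice(genes), rng.choice(causal.SIGNS))
          for _ in range(n_edges)}
    return regulome_of(rt, tt)


def brute_force_target_sets(reg: Regulome, receptor: str, mode: str):
    """Independent two-hop path enumeration oracle."""
    act, inh, unk = set(), set(), set()
    for r, tf, s1 in reg.receptor_tf_edges:
        if r != receptor:
            continue
        for t, g, s2 in reg.tf_target_edges:
            if t != tf:
                continue
            if s1 == "unk" or s2 == "unk":
                unk.add(g)
            elif mode == "multiplicative":
                sign = "act" if s1 == s2 else "inh"
                (act if sign == "act" else inh).add(g)
            else:  # as_printed: only act->inh composes to inhibited
                (inh if (s1, s2) == ("act", "inh") else act).add(g)
    return act, inh, unk - act - inh


class TestRegulomeIO:
    def test_round_trip_and_dedup(self, tmp_path):
        path = tmp_path / "reg.tsv"
        path.write_text(
            "source\ttarget\tlayer\tsign\n"
            "R1\tT1\treceptor_tf\tact\n"
            "R1\tT1\treceptor_tf\tact\n"  # duplicate collapses
            "T1\tG1\ttf_target\tact\n")
        reg = causal.read_regulome(path)
        assert len(reg.receptor_tf_edges) == 1
        assert reg.receptors == {"R1"} and reg.targets == {"G1"}
        out = tmp_path / "back.tsv"
        causal.write_regulome(reg, out)
        again = causal.read_regulome(out)
        assert again == reg

    def test_conflicting_signs_both_kept(self, tmp_path):
        path = tmp_path / "reg.tsv"
        path.write_text(
            "source\ttarget\tlayer\tsign\n"
            "T1\tG1\ttf_target\tact\n"
            "T1\tG1\ttf_target\tinh\n")
        reg = causal.read_regulome(path)
        assert len(reg.tf_target_edges) == 2

    def test_bad_sign_token_lists_allowed(self, tmp_path):
        path = tmp_path / "reg.tsv"
        path.write_text("source\ttarget\tlayer\tsign\nR1\tT1\treceptor_tf\tactivates\n")
        with pytest.raises(FormatError, match="act"):
            causal.read_regulome(path)

    def test_filter_to_expressed(self):
        reg = regulome_of(
            [("R1", "T1", "act"), ("R2", "T1", "act")],
            [("T1", "g1", "act"), ("T1", "g2", "inh")])
        out = causal.filter_to_expressed(reg, {"R1", "T1", "g1"})
        assert out.receptors == {"R1"}
        assert out.targets == {"g1"}
        identity = causal.filter_to_expressed(reg, {"R1", "R2", "T1", "g1", "g2"})
        assert identity == reg

    def test_empty_expressed_warns(self):
        reg = regulome_of([("R1", "T1", "act")], [("T1", "g1", "act")])
        with pytest.warns(UserWarning, match="empty"):
            out = causal.filter_to_expressed(reg, set())
        assert causal.regulome_counts(out)["receptors"] == 0


class TestSignAlgebra:
    @pytest.mark.parametrize("s1,s2,expected", [
        ("act", "act", "act"),
        ("act", "inh", "inh"),
        ("inh", "inh", "act"),
    ])
    def test_uncontested_rows_in_both_modes(self, s1, s2, expected):
        assert compose_signs(s1, s2, "multiplicative") == expected
        assert compose_signs(s1, s2, "as_printed") == expected

    def test_contested_row_differs_by_mode(self):
        assert compose_signs("inh", "act", "multiplicative") == "inh"
        assert compose_signs("inh", "act", "as_printed") == "act"

    def test_unknown_absorbs(self):
        for s in causal.SIGNS:
            assert compose_signs("unk", s) == "unk"
            assert compose_signs(s, "unk") == "unk"

    def test_multiplicative_is_sign_group_with_absorbing_unk(self):
        # associativity over all 27 triples; act is the identity
        for a, b, c in itertools.product(causal.SIGNS, repeat=3):
            left = compose_signs(compose_signs(a, b), c)
            right = compose_signs(a, compose_signs(b, c))
            assert left == right
        for s in causal.SIGNS:
            assert compose_signs("act", s) == s
            assert compose_signs(s, "act") == s

    def test_invalid_token_rejected(self):
        with pytest.raises(ValueError):
            compose_signs("act", "up")


class TestTargetSets:
    def test_single_path_each(self):
        reg = regulome_of([("R", "T", "act")],
                          [("T", "g1", "act"), ("T", "g2", "inh")])
        ts = receptor_target_sets(reg, "R")
        assert ts.activated == {"g1"} and ts.inhibited == {"g2"}

    def test_two_path_conflict_lands_in_both(self):
        reg = regulome_of(
            [("R", "T1", "act"), ("R", "T2", "inh")],
            [("T1", "g", "act"), ("T2", "g", "act")])
        ts = receptor_target_sets(reg, "R")
        assert "g" in ts.activated and "g" in ts.inhibited

    def test_unknown_only_when_no_signed_path(self):
        reg = regulome_of(
            [("R", "T1", "unk"), ("R", "T2", "act")],
            [("T1", "g1", "act"), ("T1", "g2", "act"), ("T2", "g2", "act")])
        ts = receptor_target_sets(reg, "R")
        assert ts.unknown == {"g1"} and ts.activated == {"g2"}

    def test_absent_receptor_rejected(self):
        reg = regulome_of([("R", "T", "act")], [("T", "g", "act")])
        with pytest.raises(KeyError):
            receptor_target_sets(reg, "Rx")

    @pytest.mark.parametrize("mode", ["multiplicative", "as_printed"])
    def test_matches_brute_force_oracle_on_random_regulomes(self, mode):
        rng = np.random.default_rng(77)
        for _ in range(100):
            reg = random_regulome(rng)
            for receptor in reg.receptors:
                ts = receptor_target_sets(reg, receptor, mode=mode)
                act, inh, unk = brute_force_target_sets(reg, receptor, mode)
                assert ts.activated == act
                assert ts.inhibited == inh
                assert ts.unknown == unk


class TestSubModules:
    @staticmethod
    def de_of(over=(), under=(), rest=()):
        rows = [{"gene_id": g, "direction": "over", "q": 0.01} for g in over]
        rows += [{"gene_id": g, "direction": "under", "q": 0.01} for g in under]
        rows += [{"gene_id": g, "direction": "none", "q": 1.0} for g in rest]
        return DETable(pd.DataFrame(rows))

    def test_partition_by_de_label(self):
        genes = [f"g{i}" for i in range(10)]
        part = ModulePartition({g: "M1" for g in genes}, K=1)
        de = self.de_of(over=genes[:4], under=genes[4:7], rest=genes[7:])
        subs = causal.build_submodules(part, de)
        sizes = {(s.direction): len(s.genes) for s in subs}
        assert sizes == {"o": 4, "u": 3}

    def test_module_without_de_genes_dropped_with_note(self):
        part = ModulePartition({"g1": "M1", "g2": "M1"}, K=1)
        de = self.de_of(rest=["g1", "g2"])
        with pytest.warns(UserWarning, match="no DE genes"):
            assert causal.build_submodules(part, de) == []

    def test_conflicting_de_rows_rejected_at_load(self):
        with pytest.raises(FormatError, match="more than once"):
            self.de_of(over=["g1"], under=["g1"])


class TestEffectTests:
    def test_disjoint_activated_set_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        ts = DirectedTargetSets("R", frozenset({"g0", "g1"}), frozenset(), frozenset())
        sub = SubModule("M1", "o", frozenset({"g10", "g11", "g12"}))
        pos, neg = causal.effect_enrichment(ts, sub, universe)
        assert pos.p == pytest.approx(1.0)
        assert neg is None  # empty inhibited set is untested, not p = 1

    def test_closed_form_full_overlap(self):
        universe = {f"g{i}" for i in range(20)}
        five = frozenset({f"g{i}" for i in range(5)})
        ts = DirectedTargetSets("R", five, frozenset(), frozenset())
        sub = SubModule("M1", "o", five)
        pos, _ = causal.effect_enrichment(ts, sub, universe)
        assert pos.p == pytest.approx(1.0 / 15504, rel=1e-12)  # 1/C(20,5)

    def test_family_bh_and_classification(self):
        rng = np.random.default_rng(3)
        cfg = craft.SimulationConfig(
            n_genes=600, n_case=4, n_control=4,
            module_specs=[craft.ModuleSpec(size=67, loading_case=0.5,
                                           loading_control=0.0,
                                           de_fraction=0.6, de_direction="over")],
            regulome_spec=craft.RegulomeSpec(n_targets=500, driver_coverage=0.8,
                                             n_decoys=6),
            seed=9)
        _, _, _, truth = craft.simulate_expression(cfg)
        reg, truth = craft.simulate_regulome(cfg, truth)
        part = ModulePartition(
            {g: "SM1" for g in truth.module_members["SM1"]}, K=1)
        subs = causal.build_submodules(part, truth.de_table())
        tests = causal.run_effect_tests(reg, subs, reg.targets, kind="receptor")
        assert all(np.isfinite(t.q) for t in tests)
        calls = causal.make_calls(tests)
        driver = next(c for c in calls if c.regulator == "R_driver")
        assert driver.clazz == "act"
        assert driver.activity == pytest.approx(
            next(t.k / t.n for t in tests
                 if t.regulator == "R_driver" and t.effect_sign == "positive"))


class TestClassification:
    @staticmethod
    def t(q, sign="positive"):
        return EffectTest("R", "M.o", sign, 5, 10, 8, 100, q / 2, q)

    def test_act_rule(self):
        assert causal.classify_regulator(self.t(0.01), self.t(0.50, "negative")) == "act"

    def test_uns_rule(self):
        assert causal.classify_regulator(self.t(0.01), self.t(0.01, "negative")) == "uns"

    def test_ns_rule(self):
        assert causal.classify_regulator(self.t(0.20), self.t(0.20, "negative")) == "ns"

    def test_inh_with_untested_positive(self):
        assert causal.classify_regulator(None, self.t(0.01, "negative")) == "inh"


class TestRanking:
    @staticmethod
    def call(reg, clazz, activity, weight, q=0.01):
        return causal.RegulatorCall(reg, "M.o", clazz, activity, weight, q)

    def test_defined_direction_outranks_unspecified(self):
        a = self.call("A", "act", 0.5, 0.4)
        b = self.call("B", "uns", 0.9, 0.8)
        ranked = causal.absolute_ranking([a, b])
        assert [c.regulator for c in ranked] == ["A", "B"]
        assert ranked[0].absolute_rank == 1

    def test_ranksum_tie_broken_by_q_then_id(self):
        a = self.call("A", "act", 0.6, 0.2, q=0.02)
        b = self.call("B", "act", 0.3, 0.5, q=0.01)
        ranked = causal.absolute_ranking([a, b])
        assert [c.regulator for c in ranked] == ["B", "A"]
        c = self.call("C", "act", 0.6, 0.2, q=0.02)
        ranked2 = causal.absolute_ranking([a, c])
        assert [x.regulator for x in ranked2] == ["A", "C"]

    def test_single_regulator_rank_one(self):
        ranked = causal.absolute_ranking([self.call("A", "inh", 0.2, 0.2)])
        assert ranked[0].absolute_rank == 1

    def test_ns_excluded(self):
        ranked = causal.absolute_ranking([
            self.call("A", "act", 0.5, 0.5), self.call("B", "ns", 0.9, 0.9)])
        assert [c.regulator for c in ranked] == ["A"]

    def test_deterministic(self):
        calls = [self.call(f"R{i}", "act", 0.5, 0.5, q=0.01) for i in range(5)]
        r1 = causal.absolute_ranking(calls)
        r2 = causal.absolute_ranking(list(reversed(calls)))
        assert [c.regulator for c in r1] == [c.regulator for c in r2]


class TestRelativeRanking:
    @staticmethod
    def setup_pair():
        sub = SubModule("M", "o", frozenset(f"g{i}" for i in range(1, 11)))
        ts = {
            "A": DirectedTargetSets("A", frozenset(f"g{i}" for i in range(1, 7)),
                                    frozenset(), frozenset()),
            "B": DirectedTargetSets("B", frozenset(f"g{i}" for i in range(5, 11)),
                                    frozenset(), frozenset()),
        }
        calls = [
            causal.RegulatorCall("A", "M.o", "act", 0.9, 0.6, 0.001),
            causal.RegulatorCall("B", "M.o", "act", 0.8, 0.6, 0.002),
        ]
        return sub, ts, calls

    def test_greedy_coverage_trace(self):
        sub, ts, calls = self.setup_pair()
        entries = causal.relative_ranking(calls, ts, sub)
        assert [e.call.regulator for e in entries] == ["A", "B"]
        assert [e.cumulative_coverage for e in entries] == [6, 10]
        assert entries[1].new_genes == 4  # g5, g6 already covered by A

    def test_identical_target_sets_second_listed_last_with_zero(self):
        sub, ts, calls = self.setup_pair()
        ts["B"] = ts["A"]
        entries = causal.relative_ranking(calls, ts, sub)
        assert entries[1].new_genes == 0
        assert entries[1].cumulative_coverage == entries[0].cumulative_coverage

    def test_complementary_pair_beats_redundant_decoy(self):
        sub = SubModule("M", "o", frozenset(f"g{i}" for i in range(10)))
        ts = {
            "A": DirectedTargetSets("A", frozenset(f"g{i}" for i in range(6)),
                                    frozenset(), frozenset()),
            "B": DirectedTargetSets("B", frozenset(f"g{i}" for i in range(6, 10)),
                                    frozenset(), frozenset()),
            # decoy overlaps A almost entirely and ranks between them
            "D": DirectedTargetSets("D", frozenset(f"g{i}" for i in range(5)),
                                    frozenset(), frozenset()),
        }
        calls = [
            causal.RegulatorCall("A", "M.o", "act", 1.0, 0.6, 0.001),
            causal.RegulatorCall("D", "M.o", "act", 1.0, 0.5, 0.002),
            causal.RegulatorCall("B", "M.o", "act", 1.0, 0.4, 0.003),
        ]
        entries = causal.relative_ranking(calls, ts, sub)
        assert [e.call.regulator for e in entries][:2] == ["A", "B"]


class TestTherapeuticDirection:
    @pytest.mark.parametrize("clazz,direction,expected", [
        ("act", "o", "blockade"),
        ("inh", "o", "activation"),
        ("act", "u", "activation"),
        ("inh", "u", "blockade"),
    ])
    def test_signature_reversion_logic(self, clazz, direction, expected):
        assert therapeutic_direction(clazz, direction) == expected

    def test_undetermined_for_uns_and_ns(self):
        assert therapeutic_direction("uns", "o") == "undetermined"
        assert therapeutic_direction("ns", "u") == "undetermined"

    def test_bad_direction_rejected(self):
        with pytest.raises(ValueError):
            therapeutic_direction("act", "x")
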