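"""Association-rule confidence: exact arithmetic and report rounding."""

from fractions import Fraction

import numpy as np
import pytest

from snpfim import confidence, display_confidence, eclat, generate_rules, rule_chain, rules_table
from snpfim.transactions import TransactionDB

from conftest import make_random_db


class TestConfidence:
    def test_exact_ratio(self):
        assert confidence(0.74, 0.82) == pytest.approx(0.74 / 0.82, abs=1e-15)

    def test_self_rule_is_certain(self):
        for x in (0.2, 0.5, 1.0):
            assert confidence(x, x) == 1.0

    def test_zero_antecedent_rejected(self):
        with pytest.raises(ValueError, match="Support\\(A\\)"):
            confidence(0.1, 0.0)

    def test_inconsistent_supports_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            confidence(0.9, 0.5)

    def test_display_rounds_half_up(self):
        assert display_confidence(0.985) == "0.99"
        assert display_confidence(0.845) == "0.85"  # half-up, not banker's
        assert display_confidence(0.9024) == "0.90"
        assert display_confidence(1.0) == "1.00"


def _db_with_counts():
    """50 transactions: a in 40, b in 45, both in 36 -> conf(a->b) = 0.90,
    conf(b->a) = 0.80."""
    transactions = (
        [{"a", "b"}] * 36 + [{"a"}] * 4 + [{"b"}] * 9 + [set()] * 1
    )
    return TransactionDB(
        voxel_ids=[f"t{k}" for k in range(50)],
        transactions=transactions,
        alpha=0.05,
    )


class TestGenerateRules:
    def test_pair_rules_both_directions(self):
        td = _db_with_counts()
        result = eclat(td, 0.5)
        rules = generate_rules(result, td, min_confidence=0.8)
        by_dir = {(r.antecedent, r.consequent): r for r in rules}
        assert by_dir[(("a",), ("b",))].confidence == pytest.approx(0.90)
        assert by_dir[(("b",), ("a",))].confidence == pytest.approx(0.80)

    def test_universal_consequent_confidence_one(self):
        td = TransactionDB(
            voxel_ids=["1", "2", "3", "4"],
            transactions=[{"a", "b"}, {"b"}, {"a", "b"}, {"b"}],
            alpha=0.05,
        )
        rules = generate_rules(eclat(td, 0.5), td)
        rule = next(r for r in rules if r.antecedent == ("a",))
        assert rule.confidence == 1.0

    def test_low_confidence_flagged_not_dropped(self):
        td = _db_with_counts()
        rules = generate_rules(eclat(td, 0.5), td, min_confidence=0.85)
        flags = {(r.antecedent, r.consequent): r.meets_min_confidence for r in rules}
        assert flags[(("a",), ("b",))] is True
        assert flags[(("b",), ("a",))] is False
        table = rules_table(rules)
        low = table[~table["meets_min_confidence"]]
        assert (low["display"] == "--").all()

    def test_foreign_mining_result_rejected(self):
        td = _db_with_counts()
        other = TransactionDB(
            voxel_ids=["x"], transactions=[{"a", "b"}], alpha=0.05
        )
        result = eclat(other, 1.0)
        with pytest.raises(ValueError, match="wrong TD"):
            generate_rules(result, td)

    def test_powerset_policy_enumerates_all_splits(self):
        td = TransactionDB(
            voxel_ids=list("123"),
            transactions=[{"a", "b", "c"}] * 3,
            alpha=0.05,
        )
        result = eclat(td, 1.0)
        rules = generate_rules(result, td, antecedent_policy="powerset")
        triple_rules = [r for r in rules
                        if len(r.antecedent) + len(r.consequent) == 3]
        assert len(triple_rules) == 6  # 2^3 - 2 splits of {a,b,c}

    def test_min_confidence_range_checked(self):
        td = _db_with_counts()
        with pytest.raises(ValueError):
            generate_rules(eclat(td, 0.5), td, min_confidence=1.5)


class TestRuleChain:
    def test_planted_chain_high_until_final_step(self):
        # a nested structure where the last extension is rare: the
        # (k-1)->1 chain stays above 0.9 until the final step drops below 0.7
        transactions = (
            [{"a", "b", "c", "d", "e"}] * 30
            + [{"a", "b", "c", "d"}] * 45
            + [{"a", "b", "c"}] * 5
            + [{"a", "b"}] * 5
            + [{"a"}] * 5
            + [set()] * 10
        )
        td = TransactionDB(
            voxel_ids=[f"t{k}" for k in range(100)],
            transactions=transactions,
            alpha=0.05,
        )
        chain = rule_chain(("a", "b", "c", "d", "e"), td, min_confidence=0.7)
        confs = [r.confidence for r in chain]
        assert all(c > 0.9 for c in confs[:-1])
        assert confs[-1] == pytest.approx(30 / 75)
        assert [r.meets_min_confidence for r in chain] == [True, True, True, False]


class TestInvariants:
    def test_confidence_times_support_identity(self):
        for seed in range(15):
            rng = np.random.default_rng(seed)
            td = make_random_db(rng, max_items=8, max_transactions=30)
            result = eclat(td, 0.2)
            for r in generate_rules(result, td, min_confidence=0.0):
                ca = td.support(r.antecedent)
                cab = td.support(tuple(r.antecedent) + tuple(r.consequent))
                assert Fraction(cab, ca) == Fraction(r.confidence).limit_denominator(
                    10 * td.td_num
                )
                assert r.confidence >= r.support_ab
                assert r.confidence <= 1.0

    def test_bidirectional_ratio(self):
        td = _db_with_counts()
        rules = generate_rules(eclat(td, 0.5), td, min_confidence=0.0)
        ab = next(r for r in rules if r.antecedent == ("a",))
        ba = next(r for r in rules if r.antecedent == ("b",))
        # conf(a->b)/conf(b->a) = support(b)/support(a)
        assert ab.confidence / ba.confidence == pytest.approx(
            td.support(["b"]) / td.support(["a"])
        )
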