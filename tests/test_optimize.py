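"""Exact selection: scoring decomposition, ILP vs brute force, preprocessing."""

import numpy as np
import pytest

from domctx.context import ContextNetwork
from domctx.core import NestingRules, validate_selection
from domctx.optimize import (
    SelectionProblem,
    brute_force_oracle,
    eliminate_candidates,
    selection_score,
    solve_exact,
    solve_proteins,
    total_score,
)
from domctx.baselines import standard_filter

from conftest import make_hit, random_problem


def problem_of(candidates, thresholds, rules, network, mode="edge-once"):
    return SelectionProblem("p", candidates, thresholds, rules, network, mode)


class TestSelectionScore:
    def test_lone_domain_reduces_to_normalized_score(
        self, thresholds, rules, network
    ):
        h = make_hit(score=25.0)
        assert selection_score(h, [h], thresholds, rules, network) == 5.0

    def test_context_partner_adds_pair_score(self, thresholds, rules, network):
        a = make_hit(family="A", start=1, end=30, score=19.0)  # H-T = -1
        b = make_hit(family="B", start=50, end=80, score=25.0)
        assert selection_score(a, [a, b], thresholds, rules, network) == 2.0

    def test_overlapping_partner_contributes_nothing(
        self, thresholds, network
    ):
        rules = NestingRules.from_pairs([("A", "B")])
        a = make_hit(family="A", start=1, end=100, score=25.0)
        b = make_hit(family="B", start=20, end=40, score=25.0)  # nested in a
        assert selection_score(a, [a, b], thresholds, rules, network) == 5.0

    def test_repeat_hits_use_self_pair_score(self, thresholds, rules, network):
        a1 = make_hit(family="A", start=1, end=30, score=25.0, hit_id="a1")
        a2 = make_hit(family="A", start=50, end=80, score=25.0, hit_id="a2")
        s = selection_score(a1, [a1, a2], thresholds, rules, network)
        assert s == 5.0 + 1.5  # normalized + C_AA


class TestTotalScore:
    def test_empty_set_scores_zero(self, thresholds, rules, network):
        assert total_score([], problem_of([], thresholds, rules, network)) == 0.0

    def test_edge_counted_once_by_default(self, thresholds, rules, network):
        a = make_hit(family="A", start=1, end=30, score=19.0)
        b = make_hit(family="B", start=50, end=80, score=19.0)
        prob = problem_of([a, b], thresholds, rules, network)
        assert total_score([a, b], prob) == pytest.approx(1.0)  # -1 -1 +3

    def test_edge_twice_mode_doubles_pair_term(self, thresholds, rules, network):
        a = make_hit(family="A", start=1, end=30, score=19.0)
        b = make_hit(family="B", start=50, end=80, score=19.0)
        prob = problem_of([a, b], thresholds, rules, network, mode="edge-twice")
        assert total_score([a, b], prob) == pytest.approx(4.0)


class TestSolveExact:
    def test_weak_pair_boosted_over_thresholds(self, thresholds, rules, network):
        a = make_hit(family="A", start=1, end=30, score=19.0, hit_id="a")
        b = make_hit(family="B", start=50, end=80, score=19.0, hit_id="b")
        sel = solve_exact(problem_of([a, b], thresholds, rules, network))
        assert sel.hit_ids() == ("a", "b")
        assert sel.total == pytest.approx(1.0)
        assert all(s >= 0 for s in sel.per_domain_scores.values())

    def test_negative_context_excludes_weaker_hit(self, thresholds, rules):
        net = ContextNetwork(scores={}, unobserved_penalty=-4.0, n=6, c=15.0)
        a = make_hit(family="A", start=1, end=30, score=22.0, hit_id="a")
        b = make_hit(family="B", start=50, end=80, score=25.0, hit_id="b")
        sel = solve_exact(problem_of([a, b], thresholds, rules, net))
        assert sel.hit_ids() == ("b",)
        assert sel.total == pytest.approx(5.0)

    def test_zero_network_reduces_to_standard_filter(self, thresholds, rules):
        cands = [
            make_hit(family="A", start=1, end=30, score=25.0, hit_id="a"),
            make_hit(family="B", start=50, end=80, score=19.0, hit_id="b"),
            make_hit(family="C", start=100, end=130, score=21.0, hit_id="c"),
        ]
        sel = solve_exact(
            problem_of(cands, thresholds, rules, ContextNetwork.zero())
        )
        expected = standard_filter(cands, thresholds, rules)
        assert set(sel.chosen) == expected

    def test_empty_pool_gives_empty_selection(self, thresholds, rules, network):
        sel = solve_exact(problem_of([], thresholds, rules, network))
        assert sel.chosen == [] and sel.total == 0.0

    def test_disallowed_overlap_never_selected(self, thresholds, network):
        a = make_hit(family="A", start=1, end=60, score=30.0, hit_id="a")
        b = make_hit(family="B", start=40, end=90, score=29.0, hit_id="b")
        sel = solve_exact(problem_of([a, b], thresholds, NestingRules(), network))
        assert sel.hit_ids() == ("a",)

    def test_output_always_validates(self, thresholds, rules, network):
        rng = np.random.default_rng(5)
        for _ in range(20):
            prob = random_problem(rng, int(rng.integers(0, 10)))
            sel = solve_exact(prob)
            assert (
                validate_selection(
                    sel.chosen, prob.thresholds, prob.rules, prob.network
                )
                == []
            )

    @pytest.mark.parametrize("mode", ["edge-once", "edge-twice"])
    def test_matches_oracle_on_random_instances(self, mode):
        rng = np.random.default_rng(42)
        for _ in range(60):
            prob = random_problem(rng, int(rng.integers(2, 11)))
            prob.objective_mode = mode
            assert solve_exact(prob).total == pytest.approx(
                brute_force_oracle(prob).total, abs=1e-6
            )

    def test_raising_an_edge_never_lowers_the_optimum(
        self, thresholds, rules, network
    ):
        rng = np.random.default_rng(9)
        for _ in range(10):
            prob = random_problem(rng, 6)
            base = solve_exact(prob).total
            pair = ("A", "B")
            boosted = dict(prob.network.scores)
            boosted[pair] = boosted.get(pair, 0.0) + 2.0
            prob.network = ContextNetwork(
                boosted,
                prob.network.unobserved_penalty,
                prob.network.n,
                prob.network.c,
            )
            assert solve_exact(prob).total >= base - 1e-9

    def test_deterministic(self):
        rng1 = np.random.default_rng(3)
        rng2 = np.random.default_rng(3)
        p1 = random_problem(rng1, 8)
        p2 = random_problem(rng2, 8)
        assert solve_exact(p1).hit_ids() == solve_exact(p2).hit_ids()


class TestBruteForceOracle:
    def test_no_candidates(self, thresholds, rules, network):
        sel = brute_force_oracle(problem_of([], thresholds, rules, network))
        assert sel.chosen == [] and sel.total == 0.0

    def test_single_passing_candidate_selected(self, thresholds, rules, network):
        h = make_hit(score=20.0)  # H - T = 0 exactly: boundary pass
        sel = brute_force_oracle(problem_of([h], thresholds, rules, network))
        assert len(sel.chosen) == 1

    def test_size_limit_enforced(self, thresholds, rules, network):
        cands = [
            make_hit(start=1 + 100 * k, end=50 + 100 * k, hit_id=f"h{k}")
            for k in range(26)
        ]
        with pytest.raises(ValueError):
            brute_force_oracle(problem_of(cands, thresholds, rules, network))


class TestEliminateCandidates:
    def test_hopeless_candidate_removed(self, thresholds, rules, network):
        doomed = make_hit(family="A", start=1, end=30, score=10.0, hit_id="x")
        partner = make_hit(family="B", start=50, end=80, score=25.0, hit_id="y")
        # best case for x: -10 + 3 < 0
        out = eliminate_candidates(
            problem_of([doomed, partner], thresholds, rules, network)
        )
        assert [h.hit_id for h in out.candidates] == ["y"]

    def test_passing_candidate_never_removed(self, thresholds, rules, network):
        h = make_hit(score=21.0)
        out = eliminate_candidates(problem_of([h], thresholds, rules, network))
        assert out.candidates == [h]

    def test_optimum_unchanged_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            prob = random_problem(rng, int(rng.integers(2, 11)))
            full = brute_force_oracle(prob).total
            pruned = brute_force_oracle(eliminate_candidates(prob)).total
            assert pruned == pytest.approx(full, abs=1e-9)


class TestSolveProteins:
    def test_pool_respects_evalue_cutoff(self, thresholds, rules, network):
        inside = make_hit(evalue=0.5, hit_id="in")
        outside = make_hit(
            family="B", start=100, end=130, evalue=5.0, hit_id="out"
        )
        sels = solve_proteins([inside, outside], thresholds, rules, network)
        assert sels["p"].hit_ids() == ("in",)

    def test_proteins_solved_independently(self, thresholds, rules, network):
        a = make_hit(protein="p1", hit_id="a")
        b = make_hit(protein="p2", hit_id="b")
        sels = solve_proteins([a, b], thresholds, rules, network)
        assert set(sels) == {"p1", "p2"}
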