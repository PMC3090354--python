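"""Shuffled-sequence FDR estimation and ortholog coherence scoring."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from domctx.benchmarks import (
    ProteinRecord,
    RatePredictor,
    UndefinedFdrError,
    attribute_hit,
    concatenate_and_split,
    domain_coherence,
    estimate_fdr,
    map_to_alignment,
    method_coherence,
    new_domain_fdr,
    run_fdr_experiment,
    shuffle_sequence,
)

from conftest import make_hit


class TestShuffleSequence:
    def test_monorepeat_fixed_point(self):
        assert shuffle_sequence("AAAA", 0) == "AAAA"

    @given(seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_composition_preserved(self, seq):
        assert sorted(shuffle_sequence(seq, 1)) == sorted(seq)

    def test_deterministic_per_seed(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        assert shuffle_sequence(seq, 5) == shuffle_sequence(seq, 5)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            shuffle_sequence("", 0)


class TestConcatenateAndAttribute:
    def test_boundary_is_real_length(self):
        concat, boundary = concatenate_and_split("MKTA", "ATKM")
        assert concat == "MKTAATKM" and boundary == 4

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            concatenate_and_split("MKTA", "AT")

    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (1, 90, "real"),  # entirely within real portion
            (110, 190, "shuffled"),  # entirely past boundary
            (81, 130, "shuffled"),  # 60% past boundary: majority rule
            (71, 120, "real"),  # 40% past boundary
            (91, 110, "real"),  # exact tie goes to real
        ],
    )
    def test_majority_attribution(self, start, end, expected):
        assert attribute_hit(start, end, boundary=100) == expected

    def test_strict_attribution_requires_containment(self):
        assert attribute_hit(81, 130, 100, mode="strict") == "real"
        assert attribute_hit(101, 130, 100, mode="strict") == "shuffled"


class TestEstimateFdr:
    def test_worked_example_three_over_twenty(self):
        """2 real predictions, 3 shuffled-portion hits over 20 replicates
        give (3/20)/2 = 0.075."""
        rec = ProteinRecord("p", real_count=2.0, shuffled_mean=3 / 20)
        assert estimate_fdr([rec]) == pytest.approx(0.075)

    def test_zero_shuffled_hits_zero_fdr(self):
        assert estimate_fdr([ProteinRecord("p", 2.0, 0.0)]) == 0.0

    def test_pure_noise_predictor_fdr_one(self):
        recs = [ProteinRecord(f"p{i}", 3.0, 3.0) for i in range(5)]
        assert estimate_fdr(recs) == pytest.approx(1.0)

    def test_no_real_predictions_undefined(self):
        with pytest.raises(UndefinedFdrError):
            estimate_fdr([ProteinRecord("p", 0.0, 1.0)])

    def test_means_taken_across_proteins(self):
        recs = [ProteinRecord("a", 4.0, 0.0), ProteinRecord("b", 0.0, 1.0)]
        assert estimate_fdr(recs) == pytest.approx(0.5 / 2.0)


class TestNewDomainFdr:
    def test_no_new_shuffled_hits(self):
        assert new_domain_fdr(0.05, 2.0, 0.05, 1.5) == 0.0

    def test_difference_ratio(self):
        assert new_domain_fdr(0.20, 2.0, 0.05, 1.5) == pytest.approx(0.30)

    def test_degenerate_counts_raise(self):
        with pytest.raises(UndefinedFdrError):
            new_domain_fdr(0.2, 1.5, 0.1, 1.5)


class TestRunFdrExperiment:
    def test_pure_noise_rate_predictor_near_one(self):
        from domctx.simulate import simulate_proteome

        proteome = simulate_proteome(150, seed=21)
        predictor = RatePredictor(rate_per_residue=0.01, seed=22)
        records = run_fdr_experiment(proteome, predictor, n_shuffles=20, seed=23)
        assert estimate_fdr(records) == pytest.approx(1.0, abs=0.1)

    def test_deterministic_per_seed(self):
        proteome = {"p": "MKTAYIAKQRQISFVKSHFSRQ" * 10}
        rec1 = run_fdr_experiment(
            proteome, RatePredictor(0.01, seed=5), n_shuffles=5, seed=9
        )
        rec2 = run_fdr_experiment(
            proteome, RatePredictor(0.01, seed=5), n_shuffles=5, seed=9
        )
        assert [(r.real_count, r.shuffled_mean) for r in rec1] == [
            (r.real_count, r.shuffled_mean) for r in rec2
        ]


class TestMapToAlignment:
    def test_gapless_row_is_identity(self):
        assert map_to_alignment(2, 3, "ABCD") == (2, 3)

    def test_gap_skipping(self):
        assert map_to_alignment(2, 3, "A-BC") == (3, 4)

    def test_leading_gap(self):
        assert map_to_alignment(1, 1, "-A") == (2, 2)

    def test_hit_past_row_rejected(self):
        with pytest.raises(ValueError):
            map_to_alignment(1, 5, "AB--")


def figure_like_group():
    """Four aligned proteins reproducing the coherence worked example:
    one family shared by two members only (score 1/3 each), one family
    in all four (scores 1), and two non-matching domains (scores 0)."""
    group = ["Pf1", "Pf2", "Pv1", "Pc1"]
    aln = {p: "X" * 400 for p in group}
    hits = {
        "Pf1": [
            make_hit("Pf1", "famA", 1, 50, hit_id="S"),
            make_hit("Pf1", "famU", 100, 150, hit_id="U1"),
        ],
        "Pf2": [
            make_hit("Pf2", "famA", 10, 60, hit_id="T"),
            make_hit("Pf2", "famU", 100, 150, hit_id="U2"),
        ],
        "Pv1": [
            make_hit("Pv1", "famU", 110, 160, hit_id="U3"),
            make_hit("Pv1", "famV", 300, 350, hit_id="V"),
        ],
        "Pc1": [
            make_hit("Pc1", "famU", 100, 150, hit_id="U4"),
            make_hit("Pc1", "famY", 300, 350, hit_id="Y"),
        ],
    }
    return group, aln, hits


def make_hit_on(protein, family, start, end, hit_id):
    return make_hit(protein, family, start, end, hit_id=hit_id)


class TestDomainCoherence:
    def test_family_in_two_of_four_members_scores_one_third(self):
        group, aln, hits = figure_like_group()
        s = hits["Pf1"][0]
        assert domain_coherence(s, hits, aln, group) == pytest.approx(1 / 3)

    def test_family_conserved_everywhere_scores_one(self):
        group, aln, hits = figure_like_group()
        u1 = hits["Pf1"][1]
        assert domain_coherence(u1, hits, aln, group) == pytest.approx(1.0)

    def test_overlap_of_different_family_scores_zero(self):
        group, aln, hits = figure_like_group()
        y = hits["Pc1"][1]
        assert domain_coherence(y, hits, aln, group) == 0.0

    def test_denominator_is_group_size_minus_one(self):
        group = ["a", "b", "c"]
        aln = {p: "X" * 100 for p in group}
        hits = {
            "a": [make_hit("a", "fam", 1, 50, hit_id="ha")],
            "b": [make_hit("b", "fam", 10, 60, hit_id="hb")],
            "c": [],
        }
        assert domain_coherence(hits["a"][0], hits, aln, group) == pytest.approx(
            1 / 2
        )

    def test_singleton_group_rejected(self):
        h = make_hit("a", "fam", 1, 50)
        with pytest.raises(ValueError):
            domain_coherence(h, {"a": [h]}, {"a": "X" * 60}, ["a"])


class TestMethodCoherence:
    def test_worked_example_mean_and_density(self):
        """Coherence multiset {1/3, 1/3, 1, 1, 1, 1, 0, 0} over 4 proteins:
        mean ~0.583, 2 domains per protein."""
        group, aln, hits = figure_like_group()
        mean, per_protein = method_coherence(
            hits, {"g": group}, {"g": aln}
        )
        assert mean == pytest.approx((2 / 3 + 4) / 8)
        assert per_protein == pytest.approx(2.0)

    def test_oversized_groups_excluded(self):
        group, aln, hits = figure_like_group()
        with pytest.raises(UndefinedFdrError):
            method_coherence(hits, {"g": group}, {"g": aln}, max_group_size=3)

    def test_identical_synthetic_groups_score_one(self):
        from domctx.simulate import SimSpec, simulate_ortholog_groups

        spec = SimSpec(n_groups=4, group_size=4, domain_dropout=0.0, seed=31)
        groups, alignments, predictions = simulate_ortholog_groups(spec)
        mean, _ = method_coherence(predictions, groups, alignments)
        assert mean == pytest.approx(1.0)

    def test_dropping_one_member_domain_gives_two_thirds(self):
        group = ["a", "b", "c", "d"]
        aln = {p: "X" * 100 for p in group}
        hits = {
            p: [make_hit(p, "fam", 1, 50, hit_id=f"h{p}")]
            for p in ["a", "b", "c"]
        }
        hits["d"] = []
        for p in ["a", "b", "c"]:
            assert domain_coherence(
                hits[p][0], hits, aln, group
            ) == pytest.approx(2 / 3)
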