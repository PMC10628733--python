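import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stoichdir import (NetworkValidationError, RunConfig, StoichiometryMatrix,
                       annotate_network, annotations_to_dataframe, bin_terms,
                       complete_reverse_annotations, compute_null_space,
                       is_unambiguous, map_sums, p1_norm, sequence_vector)
from stoichdir.outcomes import ReactionAnnotation
from stoichdir.subspace import SubspaceState


def _state(pool):
    return SubspaceState(iteration=3, pool=tuple(pool), H_size=0,
                         dup_group_count=0, dup_member_count=0, L_count=0,
                         tau=0, tau_bar=0, w=0, cardinality=len(pool))


def _seq(terms, config=RunConfig()):
    pool = [tuple([t]) for t in terms]
    return sequence_vector(_state(pool), 0, config)


class TestSequenceVector:
    def test_row_extraction_and_descriptors(self):
        seq = sequence_vector(_state([(1, 2), (3, 4)]), 0)
        assert seq.terms == (1, 3)
        assert seq.mean == 2 and seq.min == 1 and seq.max == 3
        assert seq.n_terms == 2

    def test_constant_row_has_zero_sd(self):
        assert _seq([5, 5, 5]).sd == 0.0

    def test_descriptors_match_independent_recomputation(self):
        terms = [3, -1, 4, 1, -5, 9, 2, -6]
        seq = _seq(terms)
        assert seq.sum == sum(terms)
        assert seq.mean == pytest.approx(statistics.fmean(terms))
        assert seq.sd == pytest.approx(statistics.stdev(terms))
        assert seq.n_positive + seq.n_negative + seq.n_near_zero == seq.n_terms

    def test_out_of_range_index_is_an_error(self):
        with pytest.raises(IndexError):
            sequence_vector(_state([(1, 2)]), 5)


class TestBinTerms:
    def test_no_divergence_leaves_all_subsets_empty(self):
        F, B, E = bin_terms(_seq([1, 2, 3, 4]))
        assert F == B == E == ()

    def test_divergence_threshold_matches_hand_computation(self):
        # mean 57.5, sample sd 95: no term deviates by more than 2 sd,
        # so nothing is binned (the 2-sd rule is deliberately conservative)
        terms = [10, 10, 10, 200]
        mean = statistics.fmean(terms)
        sd = statistics.stdev(terms)
        expected_divergent = [t for t in terms if abs(t - mean) > 2 * sd]
        F, B, E = bin_terms(_seq(terms))
        assert list(F) == expected_divergent == []

    def test_genuinely_divergent_positive_term_goes_to_F(self):
        terms = [10, 10, 10, 10, 10, 10, 10, 10, 10, 500]
        mean = statistics.fmean(terms)
        sd = statistics.stdev(terms)
        assert abs(500 - mean) > 2 * sd  # oracle for the fixture itself
        F, B, E = bin_terms(_seq(terms))
        assert F == (500,) and B == () and E == ()

    def test_fallback_bins_every_term_by_sign(self):
        F, B, E = bin_terms(_seq([2, 3, -1]), at_cap=True)
        assert F == (2, 3) and B == (-1,) and E == ()


class TestMapSums:
    def test_strong_forward_evidence_is_identity(self):
        ov = map_sums(2.5, 0.0, 0.0)
        assert ov.eta == 2.5 and ov.case_label == "forward_case1"
        assert ov.outcome == "forward"

    def test_weak_forward_evidence_maps_above_one(self):
        ov = map_sums(0.4, 0.0, 0.0)
        assert ov.eta == pytest.approx(0.4 + math.exp(-0.4))
        assert ov.eta > 1 and ov.case_label == "forward_case2"

    def test_strong_reverse_evidence_maps_into_unit_interval(self):
        ov = map_sums(0.0, -2.0, 0.0)
        assert ov.eta == pytest.approx(math.exp(-2))
        assert 0 < ov.eta < 1 and ov.outcome == "reverse"

    def test_weak_reverse_evidence_closes_symmetrically(self):
        ov = map_sums(0.0, -0.5, 0.0)
        assert ov.eta == pytest.approx(math.exp(-0.5))
        assert ov.case_label == "reverse_case1"

    def test_zero_equivalent_evidence_gives_eta_exactly_one(self):
        ov = map_sums(0.0, 0.0, 0.0)
        assert ov.eta == 1.0 and ov.outcome == "equivalent"
        assert ov.y_E == 1.0

    def test_mixed_evidence_sums_before_casing(self):
        ov = map_sums(3.0, -1.0, 0.0)  # net s = 2 -> forward
        assert ov.eta == 2.0 and ov.outcome == "forward"

    def test_p1_norm_equals_component_sum(self):
        for ov in (map_sums(2.5, 0, 0), map_sums(0.4, 0, 0), map_sums(0, 0, 0)):
            assert p1_norm(ov) == pytest.approx(ov.y_F + ov.y_B + ov.y_E)
            assert p1_norm(ov) == pytest.approx(ov.eta)

    @settings(max_examples=300, derandomize=True)
    @given(s=st.floats(min_value=-50, max_value=50, allow_nan=False))
    def test_eta_range_partitions_by_outcome(self, s):
        """Forward <=> eta > 1, reverse <=> eta in (0,1), equivalent <=> eta ~ 1."""
        config = RunConfig()
        ov = map_sums(s if s > 0 else 0.0, s if s <= 0 else 0.0, 0.0)
        assert ov.eta > 0
        if ov.outcome == "forward":
            assert ov.eta > 1
        elif ov.outcome == "reverse":
            assert 0 < ov.eta < 1
        else:
            assert abs(ov.eta - 1) <= config.eps_eq

    def test_weak_forward_map_exceeds_one_and_is_monotone(self):
        xs = np.linspace(1e-6, 1 - 1e-6, 1000)
        etas = xs + np.exp(-xs)
        assert (etas > 1).all()
        assert (np.diff(etas) > 0).all()


class TestIsUnambiguous:
    def test_lower_bound_above_one_means_forward(self):
        assert is_unambiguous(_seq([1.2, 3, 8])) == (True, "forward")

    def test_upper_bound_below_minus_one_means_reverse(self):
        assert is_unambiguous(_seq([-2, -5])) == (True, "reverse")

    def test_balanced_signs_mean_equivalent(self):
        assert is_unambiguous(_seq([4, -4, 3, -3])) == (True, "equivalent")

    def test_unbalanced_bounded_terms_are_ambiguous(self):
        ok, outcome = is_unambiguous(_seq([0.5, 2, 3, 4]))
        assert not ok and outcome is None


class TestAnnotateNetwork:
    def test_every_reaction_gets_a_positive_eta_and_label(self, simple_matrix):
        result = annotate_network(simple_matrix)
        assert len(result) == simple_matrix.n_reactions
        for a in result:
            assert a.eta > 0
            assert a.outcome in ("forward", "reverse", "equivalent", "ambiguous")
            if a.outcome == "forward":
                assert a.eta > 1
            elif a.outcome == "reverse":
                assert 0 < a.eta < 1

    def test_strictly_positive_null_row_is_annotated_forward(self, positive_row_matrix):
        basis = compute_null_space(positive_row_matrix)
        assert all(v[0] > 1 for v in basis.vectors)  # fixture precondition
        result = annotate_network(positive_row_matrix)
        assert result[0].outcome == "forward"
        assert result[0].eta > 1

    def test_rerun_is_identical(self, simple_matrix):
        r1 = annotate_network(simple_matrix)
        r2 = annotate_network(simple_matrix)
        assert [(a.reaction_id, a.eta, a.outcome, a.iteration_annotated) for a in r1] \
            == [(a.reaction_id, a.eta, a.outcome, a.iteration_annotated) for a in r2]

    def test_validation_failure_carries_the_report(self, simple_matrix):
        S = StoichiometryMatrix(simple_matrix.entries[:, :5],
                                reactant_ids=simple_matrix.reactant_ids,
                                reaction_ids=simple_matrix.reaction_ids[:5])
        with pytest.raises(NetworkValidationError) as exc:
            annotate_network(S)
        assert not exc.value.report.passed

    def test_half_reactions_are_collapsed_before_analysis(self, half_reaction_matrix):
        # 3 surviving reactions < 6 -> validation must fail after deduplication
        with pytest.raises(NetworkValidationError) as exc:
            annotate_network(half_reaction_matrix)
        assert exc.value.report.I_redirection == 3
        assert exc.value.report.I_user == 6

    def test_annotation_table_has_the_contract_columns(self, simple_matrix):
        df = annotations_to_dataframe(annotate_network(simple_matrix))
        assert list(df.columns) == ["reaction_id", "eta", "outcome",
                                    "iteration_annotated", "n_terms",
                                    "x_F", "x_B", "x_E", "case_label"]


class TestCompleteReverseAnnotations:
    def _ann(self, rid, eta, outcome):
        return ReactionAnnotation(reaction_id=rid, eta=eta, outcome=outcome,
                                  iteration_annotated=3, n_terms=10)

    def test_doubles_the_annotation_count(self):
        anns = [self._ann(f"r{i}", 2.5, "forward") for i in range(1, 7)]
        out = complete_reverse_annotations(anns)
        assert len(out) == 12

    def test_complement_carries_eta_one(self):
        out = complete_reverse_annotations([self._ann("r1", 2.5, "forward")])
        assert out[0].eta == 2.5
        assert out[1].eta == 1.0
        assert out[1].reaction_id == "r1_rev"

    def test_uses_the_recorded_half_reaction_id(self):
        out = complete_reverse_annotations([self._ann("r1", 0.5, "reverse")],
                                           removed_pairs=[("r1", "r9")])
        assert out[1].reaction_id == "r9"

    def test_empty_input_gives_empty_output(self):
        assert complete_reverse_annotations([]) == []
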