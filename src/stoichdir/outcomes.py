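"""Per-reaction sequence vectors, outcome binning and the probable
dissociation constant.

Row ``i`` of the grown subspace — one term per pool vector — is the
reaction-specific sequence vector of reaction ``i``.  Terms that diverge
from the row mean by more than ``sd_multiplier`` standard deviations are
binned as forward (positive), reverse (negative) or equivalent (near-zero)
evidence.  The binned sums are mapped to a non-negative outcome vector
``(y_F, y_B, y_E)`` whose p1-norm is the probable dissociation constant
``eta``:

* net evidence ``s = x_F + x_B > 1``       ->  ``eta = s``              (forward)
* ``s`` in (0, 1]                          ->  ``eta = s + exp(-s) > 1`` (forward)
* ``s < -1``                               ->  ``eta = exp(s) < 1``      (reverse)
* ``s`` in [-1, 0)                         ->  ``eta = exp(s) < 1``      (reverse)
* ``|s| ~ 0`` with near-zero evidence only ->  ``eta = exp(mean E) ~ 1`` (equivalent)

so that the ranges partition cleanly: eta > 1 is forward, eta in (0, 1) is
reverse, and eta = 1 (within ``eps_eq``) is equivalent.  A reaction is also
decided directly from its bounds — every term above 1 (forward), every term
below -1 (reverse) — or from an almost-equal count of positive and negative
terms (equivalent).
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Sequence

from .config import DEFAULT_CONFIG, RunConfig
from .errors import NetworkValidationError
from .network_model import (StoichiometryMatrix, ValidationReport,
                            remove_half_reactions, validate)
from .subspace import SubspaceState, compute_null_space, iterate_subspace

__all__ = [
    "ReactionSequenceVector",
    "OutcomeVector",
    "ReactionAnnotation",
    "AnnotationResult",
    "sequence_vector",
    "bin_terms",
    "map_sums",
    "p1_norm",
    "is_unambiguous",
    "annotate_network",
    "complete_reverse_annotations",
    "annotations_to_dataframe",
]

import pandas as pd

_CASE_OUTCOME = {
    "forward_case1": "forward",
    "forward_case2": "forward",
    "reverse_case1": "reverse",
    "reverse_case2": "reverse",
    "equivalent": "equivalent",
}


@dataclass(frozen=True)
class ReactionSequenceVector:
    """Row ``i`` of the subspace pool with its numerical descriptors."""

    reaction_index: int
    terms: tuple
    n_terms: int
    sum: float
    mean: float
    sd: float          # sample standard deviation (0 for a single term)
    min: float
    max: float
    n_positive: int
    n_negative: int
    n_near_zero: int


def sequence_vector(state: SubspaceState, i: int,
                    config: RunConfig = DEFAULT_CONFIG) -> ReactionSequenceVector:
    """Extract the i-th reaction's sequence vector from a subspace state."""
    if not state.pool:
        raise ValueError("subspace pool is empty")
    n_components = len(state.pool[0])
    if not (0 <= i < n_components):
        raise IndexError(f"reaction index {i} out of range [0, {n_components})")
    terms = tuple(v[i] for v in state.pool)
    tol = config.resolved_zero_tol
    floats = [float(t) for t in terms]
    mean = statistics.fmean(floats)
    sd = statistics.stdev(floats) if len(floats) > 1 else 0.0
    n_pos = sum(1 for t in floats if t > tol)
    n_neg = sum(1 for t in floats if t < -tol)
    return ReactionSequenceVector(
        reaction_index=i, terms=terms, n_terms=len(terms), sum=float(sum(floats)),
        mean=mean, sd=sd, min=min(floats), max=max(floats),
        n_positive=n_pos, n_negative=n_neg,
        n_near_zero=len(floats) - n_pos - n_neg)


def bin_terms(seq: ReactionSequenceVector, config: RunConfig = DEFAULT_CONFIG,
              at_cap: bool = False) -> tuple[tuple, tuple, tuple]:
    """Bin divergent terms into the forward/reverse/equivalent subsets.

    A term diverges when ``|t - mean| > sd_multiplier * sd``; divergent terms
    are binned by sign (F positive, B negative, E near-zero).  Non-divergent
    terms stay unbinned, except in the ``at_cap`` fallback — used when no
    further subspace growth is possible — where every term is binned by the
    same sign rule.
    """
    tol = config.resolved_zero_tol
    threshold = config.sd_multiplier * seq.sd
    divergent = [t for t in seq.terms if abs(float(t) - seq.mean) > threshold]
    if not divergent and at_cap:
        divergent = list(seq.terms)
    F = tuple(t for t in divergent if float(t) > tol)
    B = tuple(t for t in divergent if float(t) < -tol)
    E = tuple(t for t in divergent if abs(float(t)) <= tol)
    return F, B, E


@dataclass(frozen=True)
class OutcomeVector:
    """Binned subset sums, their non-negative images and the p1-norm eta."""

    x_F: float
    x_B: float
    x_E: float
    y_F: float
    y_B: float
    y_E: float
    case_label: str
    eta: float

    @property
    def outcome(self) -> str:
        return _CASE_OUTCOME[self.case_label]


def map_sums(x_F: float, x_B: float, x_E: float, n_E: int = 0,
             config: RunConfig = DEFAULT_CONFIG) -> OutcomeVector:
    """Map the outcome-subset sums to a non-negative vector and its p1-norm.

    The net directional evidence ``s = x_F + x_B`` selects the case; when it
    vanishes the (near-zero) equivalent evidence takes over and the mean of
    the E subset keeps eta pinned to 1 regardless of how many near-zero
    terms were binned.
    """
    tol = config.resolved_zero_tol
    s = float(x_F) + float(x_B)
    if s > 1.0:
        y = (s, 0.0, 0.0)
        case = "forward_case1"
    elif s > tol:
        y = (s, math.exp(-s), 0.0)
        case = "forward_case2"
    elif s < -1.0:
        y = (0.0, math.exp(s), 0.0)
        case = "reverse_case2"
    elif s < -tol:
        y = (0.0, math.exp(s), 0.0)
        case = "reverse_case1"
    else:
        e_mean = (float(x_E) / n_E) if n_E else float(x_E)
        y = (0.0, 0.0, math.exp(e_mean))
        case = "equivalent"
    eta = y[0] + y[1] + y[2]
    return OutcomeVector(x_F=float(x_F), x_B=float(x_B), x_E=float(x_E),
                         y_F=y[0], y_B=y[1], y_E=y[2], case_label=case, eta=eta)


def p1_norm(o: OutcomeVector) -> float:
    """Sum of the mapped non-negative components; strictly positive."""
    return o.y_F + o.y_B + o.y_E


def is_unambiguous(seq: ReactionSequenceVector,
                   config: RunConfig = DEFAULT_CONFIG) -> tuple[bool, str | None]:
    """Bound/sign test for a directly decidable reaction.

    Forward when every term exceeds 1, reverse when every term is below -1,
    equivalent when the positive and negative term counts are almost equal
    (within ``sign_balance_frac`` of the term count).
    """
    if seq.min > 1.0:
        return True, "forward"
    if seq.max < -1.0:
        return True, "reverse"
    if abs(seq.n_positive - seq.n_negative) <= config.sign_balance_frac * seq.n_terms:
        return True, "equivalent"
    return False, None


@dataclass(frozen=True)
class ReactionAnnotation:
    """Final annotation of one reaction."""

    reaction_id: str
    eta: float
    outcome: str            # forward | reverse | equivalent | ambiguous
    iteration_annotated: int
    outcome_vector: OutcomeVector | None = None
    n_terms: int = 0

    def __post_init__(self) -> None:
        if self.eta <= 0:
            raise ValueError("eta must be strictly positive")
        if self.outcome == "forward" and not self.eta > 1:
            raise ValueError("forward annotation requires eta > 1")
        if self.outcome == "reverse" and not (0 < self.eta < 1):
            raise ValueError("reverse annotation requires eta in (0, 1)")
        if self.outcome == "equivalent" and abs(self.eta - 1.0) > DEFAULT_CONFIG.eps_eq:
            raise ValueError("equivalent annotation requires eta ~ 1")


class AnnotationResult(list):
    """List of :class:`ReactionAnnotation` with pipeline metadata attached."""

    def __init__(self, annotations: Sequence[ReactionAnnotation],
                 report: ValidationReport, status: str, n_iterations: int,
                 iteration_log: list[dict]):
        super().__init__(annotations)
        self.report = report
        self.status = status  # complete | cardinality_guard | iteration_guard
        self.n_iterations = n_iterations
        self.iteration_log = iteration_log

    @property
    def fully_decided(self) -> bool:
        return all(a.outcome != "ambiguous" for a in self)


def _decide(seq: ReactionSequenceVector, config: RunConfig,
            final_pass: bool) -> tuple[str, OutcomeVector] | None:
    """One decision attempt for a reaction; None when still undecided."""
    unamb, tentative = is_unambiguous(seq, config)
    if unamb:
        if tentative == "equivalent":
            F, B, E = bin_terms(seq, config)
            ov = map_sums(0.0, 0.0, float(sum(float(t) for t in E)), n_E=len(E),
                          config=config)
        else:
            F, B, E = bin_terms(seq, config)
            if not (F or B or E):
                F, B, E = bin_terms(seq, config, at_cap=True)
            ov = map_sums(sum(float(t) for t in F), sum(float(t) for t in B),
                          sum(float(t) for t in E), n_E=len(E), config=config)
        # bound-based and sum-based outcomes agree by construction
        assert ov.outcome == tentative, (ov.outcome, tentative)
        return tentative, ov
    F, B, E = bin_terms(seq, config)
    if F or B or E:
        ov = map_sums(sum(float(t) for t in F), sum(float(t) for t in B),
                      sum(float(t) for t in E), n_E=len(E), config=config)
        return ov.outcome, ov
    if final_pass:
        F, B, E = bin_terms(seq, config, at_cap=True)
        ov = map_sums(sum(float(t) for t in F), sum(float(t) for t in B),
                      sum(float(t) for t in E), n_E=len(E), config=config)
        return "ambiguous", ov
    return None


def annotate_network(S: StoichiometryMatrix,
                     config: RunConfig = DEFAULT_CONFIG) -> AnnotationResult:
    """Run the full pipeline on a stoichiometry matrix.

    Deduplicates half-reactions, validates, computes the null-space basis,
    grows the combinatorial subspace and annotates every reaction.  After the
    warm-up iterations each pass tries to decide the still-open reactions;
    the run stops when all are decided or a growth guard trips, in which
    case the remaining reactions are labelled ``ambiguous`` with the eta of
    their sign-binned terms.

    Raises :class:`NetworkValidationError` when the matrix fails validation.
    """
    S_red, removed = remove_half_reactions(S)
    report = validate(S_red, i_user=S.n_reactions, removed_pairs=removed)
    if not report.passed:
        raise NetworkValidationError(report)
    basis = compute_null_space(S_red, mode=config.basis_mode)

    decided: dict[int, ReactionAnnotation] = {}
    n_reactions = S_red.n_reactions
    last_state: SubspaceState | None = None
    status = "iteration_guard"
    log: list[dict] = []

    for state in iterate_subspace(basis, config):
        log.append(_state_summary(state))
        if state.status == "cardinality_guard":
            status = "cardinality_guard"
            break
        last_state = state
        if state.iteration > config.warmup_iterations:
            _decision_pass(state, S_red, decided, config, final_pass=False)
            if len(decided) == n_reactions:
                status = "complete"
                break
        if state.status == "iteration_guard":
            status = "iteration_guard"

    if last_state is None:
        # the guard tripped before any growth; decide from the basis itself
        last_state = SubspaceState(iteration=0, pool=basis.vectors, H_size=0,
                                   dup_group_count=0, dup_member_count=0,
                                   L_count=0, tau=0, tau_bar=0, w=0,
                                   cardinality=len(basis.vectors), status=status)
    if len(decided) < n_reactions:
        _decision_pass(last_state, S_red, decided, config, final_pass=True)

    annotations = [decided[i] for i in range(n_reactions)]
    if all(a.outcome != "ambiguous" for a in annotations) and status != "complete":
        status = "complete"
    result = AnnotationResult(annotations, report=report, status=status,
                              n_iterations=last_state.iteration if last_state else 0,
                              iteration_log=log)
    if config.emit_reverse_pairs:
        return AnnotationResult(
            complete_reverse_annotations(annotations, removed_pairs=removed),
            report=report, status=result.status,
            n_iterations=result.n_iterations, iteration_log=log)
    return result


def _state_summary(state: SubspaceState) -> dict:
    return {"iteration": state.iteration, "cardinality": state.cardinality,
            "H_size": state.H_size, "dup_groups": state.dup_group_count,
            "L": state.L_count, "tau": state.tau, "tau_bar": state.tau_bar,
            "w": state.w, "status": state.status}


def _decision_pass(state: SubspaceState, S_red: StoichiometryMatrix,
                   decided: dict[int, ReactionAnnotation], config: RunConfig,
                   final_pass: bool) -> None:
    for i in range(S_red.n_reactions):
        if i in decided:
            continue
        seq = sequence_vector(state, i, config)
        verdict = _decide(seq, config, final_pass)
        if verdict is None:
            continue
        outcome, ov = verdict
        decided[i] = ReactionAnnotation(
            reaction_id=S_red.reaction_ids[i], eta=ov.eta, outcome=outcome,
            iteration_annotated=state.iteration, outcome_vector=ov,
            n_terms=seq.n_terms)


def complete_reverse_annotations(annotations: Sequence[ReactionAnnotation],
                                 removed_pairs: Sequence[tuple[str, str]] = (),
                                 ) -> list[ReactionAnnotation]:
    """Re-emit each annotation together with its complementary half-reaction.

    The analysed half of a reversible pair carries the computed eta; its
    complement — needed e.g. by stochastic simulators that require both
    writings of every reaction — is emitted with eta = 1.0.  Output length is
    exactly twice the input length.
    """
    complement_of = {kept: dropped for kept, dropped in removed_pairs}
    out: list[ReactionAnnotation] = []
    for a in annotations:
        out.append(a)
        rev_id = complement_of.get(a.reaction_id, f"{a.reaction_id}_rev")
        out.append(ReactionAnnotation(
            reaction_id=rev_id, eta=1.0, outcome="equivalent",
            iteration_annotated=a.iteration_annotated, outcome_vector=None,
            n_terms=a.n_terms))
    return out


def annotations_to_dataframe(annotations: Sequence[ReactionAnnotation]) -> pd.DataFrame:
    """Tabulate annotations for TSV output."""
    rows = []
    for a in annotations:
        ov = a.outcome_vector
        rows.append({
            "reaction_id": a.reaction_id,
            "eta": a.eta,
            "outcome": a.outcome,
            "iteration_annotated": a.iteration_annotated,
            "n_terms": a.n_terms,
            "x_F": ov.x_F if ov else "",
            "x_B": ov.x_B if ov else "",
            "x_E": ov.x_E if ov else "",
            "case_label": ov.case_label if ov else "",
        })
    return pd.DataFrame(rows)
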