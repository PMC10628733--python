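"""Constrained synthetic networks and the feasibility-study harness.

The generator emulates the simulated matrices of the method's feasibility
study: small integer stoichiometry numbers, every reaction with at least one
positive and one negative coefficient, a reaction count of at least ``J + 2``
and a controlled nullity.  Construction draws ``I - nullity`` random
full-rank columns and extends them with small integer combinations of those
columns (rejected and re-drawn until the entry bound, the two-sign rule and
the no-negated-pair rule all hold), then permutes the column order.

A study run annotates each generated network under a wall-clock budget and
scores the outcomes with the usual truth-table indices, where a network is a
study "positive" when its nullity lies in the tractable window [2, 4]:

* TP — nullity in [2, 4], finished within the budget;
* FP — nullity  >  4,     finished within the budget;
* FN — nullity in [2, 4], exceeded the budget;
* TN — nullity  >  4,     exceeded the budget.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import GenerationError
from .network_model import StoichiometryMatrix, exact_rank
from .outcomes import annotate_network

__all__ = [
    "SimulatedNetworkSpec",
    "FeasibilityRecord",
    "TruthTableMetrics",
    "generate_network",
    "label_outcome",
    "score_truth_table",
    "run_feasibility_study",
    "records_to_dataframe",
]


@dataclass(frozen=True)
class SimulatedNetworkSpec:
    """Parameters of one synthetic network."""

    J: int
    I: int
    target_nullity: int
    entry_magnitude_max: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.I < self.J + 2:
            raise ValueError(f"need I >= J + 2 (got I={self.I}, J={self.J})")
        if self.I < 6:
            raise ValueError("need at least 6 reactions")
        if not (2 <= self.target_nullity <= self.I - 1):
            raise ValueError("target_nullity must lie in [2, I - 1]")
        if self.entry_magnitude_max < 1:
            raise ValueError("entry_magnitude_max must be >= 1")


def _both_signs(col: np.ndarray) -> bool:
    return bool((col > 0).any() and (col < 0).any())


def _clashes(col: np.ndarray, existing: list[np.ndarray]) -> bool:
    return any(np.array_equal(col, c) or np.array_equal(col, -c) for c in existing)


def generate_network(spec: SimulatedNetworkSpec) -> StoichiometryMatrix:
    """Generate a deterministic random network with the requested nullity."""
    r = spec.I - spec.target_nullity
    if r > spec.J:
        raise GenerationError(
            f"rank {r} = I - nullity exceeds the reactant count J={spec.J}; "
            "no such matrix exists")
    rng = np.random.default_rng(spec.seed)
    m = spec.entry_magnitude_max

    for attempt in range(50):
        base: list[np.ndarray] = []
        tries = 0
        while len(base) < r and tries < 2000:
            tries += 1
            col = rng.integers(-m, m + 1, size=spec.J)
            if _both_signs(col) and not _clashes(col, base):
                base.append(col)
        if len(base) < r:
            continue
        B = np.column_stack(base)
        if exact_rank(B) != r:
            continue
        ext: list[np.ndarray] = []
        ok = True
        for _ in range(spec.target_nullity):
            for _ in range(2000):
                coeff = rng.integers(-2, 3, size=r)
                if not coeff.any():
                    continue
                col = B @ coeff
                if (np.abs(col).max() <= m and _both_signs(col)
                        and not _clashes(col, base + ext)):
                    ext.append(col)
                    break
            else:
                ok = False
                break
        if not ok:
            continue
        cols = base + ext
        order = rng.permutation(spec.I)
        entries = np.column_stack([cols[k] for k in order])
        return StoichiometryMatrix(
            entries,
            reactant_ids=tuple(f"M{j + 1}" for j in range(spec.J)),
            reaction_ids=tuple(f"R{i + 1}" for i in range(spec.I)),
        )
    raise GenerationError(
        f"could not satisfy constraints for J={spec.J}, I={spec.I}, "
        f"nullity={spec.target_nullity}, |entry| <= {m} after bounded retries")


def label_outcome(nullity: int, elapsed, budget: float = 20.0) -> str:
    """Truth-table label for one run.

    ``elapsed`` is in minutes and may be a float, ``math.inf`` or a censored
    string such as ``">20"`` (meaning the run exceeded the budget).
    """
    if budget <= 0:
        raise ValueError("budget must be positive")
    if nullity < 2:
        raise ValueError("nullity below 2 is outside the method's domain")
    if isinstance(elapsed, str):
        text = elapsed.strip()
        if not text.startswith(">"):
            raise ValueError(f"cannot interpret elapsed time '{elapsed}'")
        over = float(text[1:]) >= budget
    else:
        over = float(elapsed) > budget
    tractable = 2 <= nullity <= 4
    if tractable:
        return "FN" if over else "TP"
    return "TN" if over else "FP"


@dataclass
class FeasibilityRecord:
    """One simulated network's run in the feasibility study."""

    J: int
    I: int
    nullity: int
    elapsed_min: float          # censored at the budget when ``censored``
    censored: bool
    label: str | None
    seed: int | None = None
    error: str | None = None

    @property
    def elapsed_display(self) -> str:
        return f">{self.elapsed_min:g}" if self.censored else f"{self.elapsed_min:g}"


@dataclass(frozen=True)
class TruthTableMetrics:
    """Truth-table counts and the derived fractions.

    A metric whose denominator is zero is ``None`` (undefined), never an
    exception.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float | None
    recall: float | None
    specificity: float | None
    accuracy: float | None

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int, tn: int) -> "TruthTableMetrics":
        total = tp + fp + fn + tn

        def ratio(num, den):
            return num / den if den else None

        return cls(tp=tp, fp=fp, fn=fn, tn=tn,
                   precision=ratio(tp, tp + fp),
                   recall=ratio(tp, tp + fn),
                   specificity=(1.0 - fp / (fp + tn)) if (fp + tn) else None,
                   accuracy=ratio(tp + tn, total))

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
                "precision": self.precision, "recall": self.recall,
                "specificity": self.specificity, "accuracy": self.accuracy}


def score_truth_table(records: Sequence) -> TruthTableMetrics:
    """Score labelled feasibility records (or bare label strings)."""
    if not len(records):
        raise ValueError("no records to score")
    labels = [r if isinstance(r, str) else r.label for r in records]
    counts = {k: labels.count(k) for k in ("TP", "FP", "FN", "TN")}
    return TruthTableMetrics.from_counts(counts["TP"], counts["FP"],
                                         counts["FN"], counts["TN"])


def run_feasibility_study(specs: Sequence[SimulatedNetworkSpec],
                          budget: float = 20.0,
                          config: RunConfig | None = None) -> list[FeasibilityRecord]:
    """Generate, annotate and label each spec; failures never abort the sweep.

    Elapsed time is censored at the budget rather than measured precisely
    past it.  The annotation pipeline's own growth guards keep individual
    runs finite, so in practice censoring occurs only with very small
    budgets.
    """
    records: list[FeasibilityRecord] = []
    for spec in specs:
        try:
            S = generate_network(spec)
            t0 = time.perf_counter()
            run_config = config if config is not None else RunConfig()
            result = annotate_network(S, run_config)
            elapsed = (time.perf_counter() - t0) / 60.0
            nullity = result.report.nullity
            censored = elapsed > budget
            records.append(FeasibilityRecord(
                J=spec.J, I=spec.I, nullity=nullity,
                elapsed_min=budget if censored else elapsed, censored=censored,
                label=label_outcome(nullity, math.inf if censored else elapsed, budget),
                seed=spec.seed))
        except Exception as exc:  # recorded, never raised out of the sweep
            records.append(FeasibilityRecord(
                J=spec.J, I=spec.I, nullity=spec.target_nullity,
                elapsed_min=0.0, censored=False, label=None,
                seed=spec.seed, error=f"{type(exc).__name__}: {exc}"))
    return records


def records_to_dataframe(records: Sequence[FeasibilityRecord]) -> pd.DataFrame:
    """Tabulate records in the study's column layout."""
    return pd.DataFrame({
        "s_no": range(1, len(records) + 1),
        "J": [r.J for r in records],
        "I": [r.I for r in records],
        "nullity": [r.nullity for r in records],
        "T_min": [r.elapsed_display for r in records],
        "label": [r.label if r.label else f"ERROR:{r.error}" for r in records],
    })
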