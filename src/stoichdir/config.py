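"""Run-time configuration shared by the whole annotation pipeline."""

from __future__ import annotations

from dataclasses import dataclass, asdict

#: zero tolerance used when the null-space basis is exact (integer arithmetic)
ZERO_TOL_RATIONAL = 1e-9
#: zero tolerance used with a floating-point (orthonormal) basis
ZERO_TOL_FLOAT = 1e-6


@dataclass
class RunConfig:
    """Tunable parameters of the directionality pipeline.

    Defaults follow the method's fixed constants: divergent terms are those
    beyond 2 standard deviations from the row mean, annotation starts after a
    2-iteration warm-up of subspace growth, and feasibility runs are judged
    against a 20-minute wall-clock budget.
    """

    reactions_as: str = "columns"           # orientation of the input table
    basis_mode: str = "rational_primitive"  # or "orthonormal_float"
    sd_multiplier: float = 2.0              # divergence threshold, in SDs
    zero_tol: float | None = None           # resolved per basis_mode when None
    eps_eq: float = 1e-3                    # half-width of the "equivalent" band around eta = 1
    sign_balance_frac: float = 0.05         # max |n_pos - n_neg| / n_terms for "equivalent"
    warmup_iterations: int = 2              # subspace growth before any annotation
    max_iterations: int = 10
    max_cardinality: int = 50_000           # guard on combinatorial growth (method is NP-hard)
    time_budget_min: float = 20.0
    seed: int | None = None
    emit_reverse_pairs: bool = False

    def __post_init__(self) -> None:
        if self.reactions_as not in ("rows", "columns"):
            raise ValueError("reactions_as must be 'rows' or 'columns'")
        if self.basis_mode not in ("rational_primitive", "orthonormal_float"):
            raise ValueError("basis_mode must be 'rational_primitive' or 'orthonormal_float'")
        for name in ("sd_multiplier", "eps_eq", "sign_balance_frac", "time_budget_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.zero_tol is not None and self.zero_tol <= 0:
            raise ValueError("zero_tol must be > 0")
        if not (0 <= self.warmup_iterations < self.max_iterations):
            raise ValueError("require 0 <= warmup_iterations < max_iterations")
        if self.max_cardinality < 10:
            raise ValueError("max_cardinality is too small to grow any subspace")

    @property
    def resolved_zero_tol(self) -> float:
        """The effective near-zero tolerance for the configured basis mode."""
        if self.zero_tol is not None:
            return self.zero_tol
        return ZERO_TOL_RATIONAL if self.basis_mode == "rational_primitive" else ZERO_TOL_FLOAT

    def to_dict(self) -> dict:
        d = asdict(self)
        d["resolved_zero_tol"] = self.resolved_zero_tol
        return d


DEFAULT_CONFIG = RunConfig()
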