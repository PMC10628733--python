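"""Exact null-space computation and combinatorial subspace growth.

The steady-state condition ``S v = 0`` defines the right null space of the
J x I stoichiometry matrix; its vectors are indexed by reactions.  Starting
from a basis, the comprehensive null-space-generated subspace is grown by
element-wise summation of every subset (size >= 2) of the current vector
pool.  After each round of sums the candidates are partitioned into

* ``L`` — trivial (zero) vectors, discarded;
* ``H`` — distinct new non-trivial vectors;
* ``H-bar`` groups — identical vectors, of which one representative per
  group is kept (``tau`` groups reassign ``tau_bar = tau`` representatives).

Sums of null vectors stay in the null space, so every pool vector satisfies
``S v = 0`` at every iteration — exactly so in the default rational mode,
where basis vectors are scaled to coprime integers and all arithmetic is on
Python integers.

Subset-sum enumeration is exponential (the underlying decision problem is
NP-hard), so growth is bounded by ``max_iterations`` and ``max_cardinality``;
hitting a bound is reported through the state's ``status`` field, never an
exception.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterator, Sequence

import scipy.linalg
import sympy as sp

from .config import DEFAULT_CONFIG, RunConfig
from .errors import NullityError
from .network_model import StoichiometryMatrix

__all__ = [
    "NullSpaceBasis",
    "SubspaceState",
    "DuplicateGroup",
    "compute_null_space",
    "combinatorial_sums",
    "partition_vectors",
    "reassign_duplicates",
    "tau_upper_bound",
    "iterate_subspace",
]

Vector = tuple  # tuple[int, ...] in rational mode, tuple[float, ...] in float mode


@dataclass(frozen=True)
class NullSpaceBasis:
    """A basis of the right null space, indexed by reactions.

    In ``rational_primitive`` mode each vector is integer, component-wise
    coprime, with its first nonzero component positive, which makes
    duplicate and zero detection exact.  ``orthonormal_float`` mirrors the
    numerics of SVD-based null spaces (unit vectors, float entries).
    """

    vectors: tuple[Vector, ...]
    nullity: int
    basis_mode: str = "rational_primitive"

    def __post_init__(self) -> None:
        if self.nullity != len(self.vectors):
            raise ValueError("nullity must equal the number of basis vectors")


def _primitive(vec: Sequence[sp.Rational]) -> tuple[int, ...]:
    """Scale a rational vector to coprime integers, first nonzero positive."""
    fracs = [sp.Rational(x) for x in vec]
    denoms = [f.q for f in fracs]
    lcm = math.lcm(*denoms)
    ints = [int(f * lcm) for f in fracs]
    g = math.gcd(*ints)
    if g:
        ints = [x // g for x in ints]
    for x in ints:
        if x:
            if x < 0:
                ints = [-v for v in ints]
            break
    return tuple(ints)


def compute_null_space(S: StoichiometryMatrix,
                       mode: str = "rational_primitive") -> NullSpaceBasis:
    """Compute a basis of ``{v : S v = 0}``.

    Raises :class:`NullityError` when the nullity is below 2 — with fewer
    than two spanning vectors there is no combinatorial subspace to grow and
    directionality cannot be inferred.
    """
    if mode not in ("rational_primitive", "orthonormal_float"):
        raise ValueError(f"unknown basis mode '{mode}'")
    M = sp.Matrix(S.entries.tolist())
    nullity = S.n_reactions - M.rank()
    if nullity < 2:
        raise NullityError(
            f"null space has dimension {nullity}; at least 2 spanning vectors are required")
    if mode == "rational_primitive":
        vectors = tuple(_primitive(v) for v in M.nullspace())
    else:
        basis = scipy.linalg.null_space(S.entries.astype(float))
        cols = []
        for k in range(basis.shape[1]):
            v = basis[:, k]
            for x in v:
                if abs(x) > 1e-12:
                    if x < 0:
                        v = -v
                    break
            cols.append(tuple(float(x) for x in v))
        vectors = tuple(cols)
    return NullSpaceBasis(vectors=vectors, nullity=nullity, basis_mode=mode)


def combinatorial_sums(pool: Sequence[Vector]) -> list[Vector]:
    """Element-wise sums of every subset of size 2..A of ``pool``.

    Enumeration is lexicographic over index tuples, so the output order is
    deterministic; the list has ``2**A - A - 1`` entries before filtering.
    """
    A = len(pool)
    if A < 2:
        raise ValueError("combinatorial summation needs a pool of at least 2 vectors")
    n = len(pool[0])
    out: list[Vector] = []
    for t in range(2, A + 1):
        for idx in combinations(range(A), t):
            out.append(tuple(sum(pool[k][c] for k in idx) for c in range(n)))
    return out


def _identity_key(v: Vector, tol: float) -> tuple:
    """Hashable identity of a vector: exact for ints, quantized for floats."""
    if v and isinstance(v[0], float):
        decimals = max(0, round(-math.log10(tol)))
        return tuple(0.0 if x == 0 else round(x, decimals) for x in v)
    return v


def _is_zero(v: Vector, tol: float) -> bool:
    if v and isinstance(v[0], float):
        return all(abs(x) <= tol for x in v)
    return not any(v)


@dataclass(frozen=True)
class DuplicateGroup:
    """One set of identical candidate vectors (an H-bar group)."""

    vectors: tuple[Vector, ...]
    matches_pool: bool  # True when the shared value already sits in the pool

    @property
    def size(self) -> int:
        return len(self.vectors)


def partition_vectors(candidates: Sequence[Vector],
                      existing_pool: Sequence[Vector] = (),
                      tol: float = 1e-9,
                      ) -> tuple[list[Vector], list[Vector], list[DuplicateGroup]]:
    """Split candidate vectors into trivial L, unique H and duplicate groups.

    A candidate lands in a duplicate group when it is identical to another
    candidate or to a vector already in the pool; identity is exact in
    rational mode and component-wise within ``tol`` in float mode.
    """
    pool_keys = {_identity_key(v, tol) for v in existing_pool}
    L: list[Vector] = []
    buckets: dict[tuple, list[Vector]] = {}
    order: list[tuple] = []
    for v in candidates:
        if _is_zero(v, tol):
            L.append(v)
            continue
        key = _identity_key(v, tol)
        if key not in buckets:
            buckets[key] = []
            order.append(key)
        buckets[key].append(v)
    H: list[Vector] = []
    groups: list[DuplicateGroup] = []
    for key in order:
        members = buckets[key]
        in_pool = key in pool_keys
        if in_pool or len(members) > 1:
            groups.append(DuplicateGroup(vectors=tuple(members), matches_pool=in_pool))
        else:
            H.append(members[0])
    return L, H, groups


def reassign_duplicates(H: Sequence[Vector],
                        groups: Sequence[DuplicateGroup],
                        ) -> tuple[list[Vector], int, int, dict]:
    """Move one representative of each reassignable duplicate group into H.

    ``tau`` counts the groups that contribute a representative (groups whose
    value already exists in the pool are bookkept but add nothing), and
    ``tau_bar = tau``.  The returned counters verify the bookkeeping
    ``#H_new = #H_old + tau_bar`` and ``#dup_new = #dup_old - tau_bar``.
    """
    H_new = list(H)
    tau = 0
    dup_members = sum(g.size for g in groups)
    for g in groups:
        if g.matches_pool:
            continue
        tau += 1
        H_new.append(g.vectors[0])
    tau_bar = tau
    counters = {
        "h_before": len(H),
        "h_after": len(H_new),
        "dup_members_before": dup_members,
        "dup_members_after": dup_members - tau_bar,
        "tau": tau,
        "tau_bar": tau_bar,
    }
    return H_new, tau, tau_bar, counters


def tau_upper_bound(dup_count: int) -> int:
    """Literal combinatorial bound ``1 + sum_{t=2}^{n-2} C(n, t)`` on the
    number of identical-vector subsets formable from ``n`` duplicates.

    Equals 1 for n in {2, 3}.  This is an upper bound only; the algorithm
    itself uses the observed group count.
    """
    if dup_count < 2:
        raise ValueError("a duplicate set has at least 2 members")
    return 1 + sum(math.comb(dup_count, t) for t in range(2, dup_count - 1))


@dataclass
class SubspaceState:
    """Snapshot of the comprehensive subspace after one growth iteration."""

    iteration: int
    pool: tuple[Vector, ...]          # spanning basis plus distinct non-trivial sums
    H_size: int                       # unique vectors found this iteration (incl. representatives)
    dup_group_count: int              # H-bar groups observed this iteration
    dup_member_count: int             # total members across those groups
    L_count: int                      # trivial vectors excluded this iteration
    tau: int
    tau_bar: int
    w: int                            # candidates excluded this iteration
    cardinality: int                  # current pool size
    status: str = "ok"                # ok | cardinality_guard | iteration_guard

    def to_json(self) -> str:
        return json.dumps({
            "iteration": self.iteration,
            "cardinality": self.cardinality,
            "H_size": self.H_size,
            "dup_groups": self.dup_group_count,
            "dup_members": self.dup_member_count,
            "L": self.L_count,
            "tau": self.tau,
            "tau_bar": self.tau_bar,
            "w": self.w,
            "status": self.status,
        })


def iterate_subspace(basis: NullSpaceBasis,
                     config: RunConfig = DEFAULT_CONFIG) -> Iterator[SubspaceState]:
    """Grow the comprehensive subspace iteratively, yielding one state per pass.

    Iteration ``u = 1`` starts from the spanning basis; each pass sums all
    subsets of the current pool, filters trivial and duplicate vectors and
    unions the survivors (the basis itself is always retained).  The stream
    ends when ``max_iterations`` is reached or when the next enumeration
    would push past ``max_cardinality``; in the latter case a final state
    with ``status='cardinality_guard'`` and an unchanged pool is yielded.
    """
    tol = config.resolved_zero_tol
    pool: list[Vector] = list(basis.vectors)
    u = 0
    while u < config.max_iterations:
        u += 1
        A = len(pool)
        n_sums = (1 << A) - A - 1
        if A + n_sums > config.max_cardinality:
            yield SubspaceState(iteration=u, pool=tuple(pool), H_size=0,
                                dup_group_count=0, dup_member_count=0, L_count=0,
                                tau=0, tau_bar=0, w=0, cardinality=len(pool),
                                status="cardinality_guard")
            return
        candidates = combinatorial_sums(pool)
        L, H, groups = partition_vectors(candidates, pool, tol=tol)
        H_full, tau, tau_bar, _ = reassign_duplicates(H, groups)
        pool.extend(H_full)
        w = len(candidates) - len(H_full)
        status = "ok" if u < config.max_iterations else "iteration_guard"
        yield SubspaceState(iteration=u, pool=tuple(pool), H_size=len(H_full),
                            dup_group_count=len(groups),
                            dup_member_count=sum(g.size for g in groups),
                            L_count=len(L), tau=tau, tau_bar=tau_bar, w=w,
                            cardinality=len(pool), status=status)
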