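"""Loading, orienting, deduplicating and validating stoichiometry number matrices.

A biochemical network is modelled as an integer matrix ``S`` of stoichiometry
numbers with reactants/products on the rows (J of them) and reactions on the
columns (I of them); products carry positive and substrates negative
coefficients.  The canonical in-memory orientation is always J x I, whatever
orientation the user's file is in.

Before any algebra runs the matrix is screened:

* reversible reactions entered twice (a column and its exact negation, a
  "half-reaction pair") are collapsed to a single representative;
* hard structural bounds are checked: ``I >= J + 2``, ``I >= 6``,
  ``I > rank(S)`` and every reaction must consume and produce something
  (at least one negative and one positive coefficient);
* a reaction count above ``J + 4`` is flagged as a warning — feasibility of
  the combinatorial search degrades quickly beyond that band — but is not an
  error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import sympy as sp

from .errors import MatrixFormatError, MatrixParseError

__all__ = [
    "StoichiometryMatrix",
    "ValidationReport",
    "load_matrix",
    "remove_half_reactions",
    "validate",
]


@dataclass(frozen=True)
class StoichiometryMatrix:
    """An integer reactant x reaction grid with identifiers.

    ``entries[j, i]`` is the stoichiometry number of reactant ``j`` in
    reaction ``i``.  ``user_orientation`` records how the source table was
    oriented on disk ("rows" means reactions were rows there).
    """

    entries: np.ndarray
    reactant_ids: tuple[str, ...]
    reaction_ids: tuple[str, ...]
    user_orientation: str = "columns"

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=np.int64)
        if entries.ndim != 2 or entries.size == 0:
            raise MatrixFormatError("stoichiometry matrix must be a non-empty 2-D grid")
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "reactant_ids", tuple(str(r) for r in self.reactant_ids))
        object.__setattr__(self, "reaction_ids", tuple(str(r) for r in self.reaction_ids))
        if len(self.reactant_ids) != entries.shape[0]:
            raise MatrixFormatError("number of reactant ids does not match row count")
        if len(self.reaction_ids) != entries.shape[1]:
            raise MatrixFormatError("number of reaction ids does not match column count")

    @property
    def n_reactants(self) -> int:
        return self.entries.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.entries.shape[1]

    def reaction_column(self, i: int) -> np.ndarray:
        return self.entries[:, i]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, index=list(self.reactant_ids),
                            columns=list(self.reaction_ids))


@dataclass
class ValidationReport:
    """Outcome of the structural checks on a (deduplicated) matrix."""

    passed: bool
    I_user: int
    I_redirection: int
    removed_pairs: list[tuple[str, str]]
    rank: int
    nullity: int
    failures: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "passed": self.passed,
            "I_user": self.I_user,
            "I_redirection": self.I_redirection,
            "removed_pairs": [list(p) for p in self.removed_pairs],
            "rank": self.rank,
            "nullity": self.nullity,
            "failures": self.failures,
            "warnings": self.warnings,
        }, indent=2)

    def to_text(self) -> str:
        lines = [
            f"validation: {'PASSED' if self.passed else 'FAILED'}",
            f"  reactions as loaded : {self.I_user}",
            f"  reactions analysed  : {self.I_redirection}",
            f"  half-reaction pairs : {len(self.removed_pairs)}",
            f"  rank                : {self.rank}",
            f"  nullity             : {self.nullity}",
        ]
        for f_ in self.failures:
            lines.append(f"  FAIL: {f_}")
        for w in self.warnings:
            lines.append(f"  warn: {w}")
        return "\n".join(lines)


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def load_matrix(path, reactions_as: str = "columns",
                delimiter: str | None = None) -> StoichiometryMatrix:
    """Read a delimited integer table and return the canonical J x I matrix.

    The file must carry one header row and one identifier column.  When
    ``reactions_as='rows'`` the table is transposed so that the canonical
    form always has reactions on the columns.
    """
    if reactions_as not in ("rows", "columns"):
        raise ValueError("reactions_as must be 'rows' or 'columns'")
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    try:
        table = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=object)
    except pd.errors.EmptyDataError as exc:
        raise MatrixFormatError(f"{path}: empty table") from exc
    except pd.errors.ParserError as exc:
        raise MatrixFormatError(f"{path}: malformed (ragged?) table: {exc}") from exc
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise MatrixFormatError(f"{path}: table has no data cells")

    values = np.empty(table.shape, dtype=np.int64)
    for jj, row_label in enumerate(table.index):
        for ii, col_label in enumerate(table.columns):
            cell = table.iat[jj, ii]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                raise MatrixFormatError(
                    f"{path}: missing cell at row '{row_label}', column '{col_label}' "
                    "(ragged table?)")
            text = str(cell).strip()
            try:
                value = int(text)
            except ValueError:
                raise MatrixParseError(
                    f"{path}: non-integer cell '{text}' at row '{row_label}', "
                    f"column '{col_label}'", row=str(row_label), column=str(col_label),
                ) from None
            values[jj, ii] = value

    index_ids = tuple(str(x) for x in table.index)
    column_ids = tuple(str(x) for x in table.columns)
    if reactions_as == "rows":
        return StoichiometryMatrix(values.T, reactant_ids=column_ids,
                                   reaction_ids=index_ids, user_orientation="rows")
    return StoichiometryMatrix(values, reactant_ids=index_ids,
                               reaction_ids=column_ids, user_orientation="columns")


def remove_half_reactions(S: StoichiometryMatrix) -> tuple[StoichiometryMatrix, list[tuple[str, str]]]:
    """Collapse exactly-negated reaction column pairs to one representative.

    A reversible reaction written both ways appears as two columns ``r_x``
    and ``r_y`` with ``r_y = -r_x`` (exact integer negation).  Of every such
    pair the column with the smaller index is kept.  Returns the reduced
    matrix and the list of ``(kept_id, dropped_id)`` pairs.
    """
    cols = S.entries
    removed: set[int] = set()
    pairs: list[tuple[str, str]] = []
    for x in range(S.n_reactions):
        if x in removed:
            continue
        for y in range(x + 1, S.n_reactions):
            if y in removed:
                continue
            if np.array_equal(cols[:, y], -cols[:, x]):
                removed.add(y)
                pairs.append((S.reaction_ids[x], S.reaction_ids[y]))
    if not removed:
        return S, []
    keep = [i for i in range(S.n_reactions) if i not in removed]
    reduced = StoichiometryMatrix(cols[:, keep],
                                  reactant_ids=S.reactant_ids,
                                  reaction_ids=tuple(S.reaction_ids[i] for i in keep),
                                  user_orientation=S.user_orientation)
    return reduced, pairs


def exact_rank(entries: np.ndarray) -> int:
    """Rank of an integer matrix by exact (rational) elimination."""
    return sp.Matrix(entries.tolist()).rank()


def validate(S: StoichiometryMatrix,
             i_user: int | None = None,
             removed_pairs: list[tuple[str, str]] | None = None) -> ValidationReport:
    """Check the structural constraints on a half-reaction-free matrix.

    All problems are reported, never thrown; ``passed`` is true iff no hard
    rule is violated.  ``i_user`` and ``removed_pairs`` let the caller carry
    the pre-deduplication bookkeeping into the report.
    """
    removed_pairs = list(removed_pairs or [])
    J, I = S.n_reactants, S.n_reactions
    if i_user is None:
        i_user = I + len(removed_pairs)
    rank = exact_rank(S.entries)
    nullity = I - rank

    failures: list[str] = []
    warnings: list[str] = []
    if I < J + 2:
        failures.append(f"reaction count {I} below lower bound J+2 = {J + 2}")
    if I < 6:
        failures.append(f"reaction count {I} below absolute lower bound 6")
    if I <= rank:
        failures.append(f"reaction count {I} must exceed rank {rank} (empty null space)")
    for i in range(I):
        col = S.entries[:, i]
        if not ((col > 0).any() and (col < 0).any()):
            failures.append(
                f"reaction '{S.reaction_ids[i]}' lacks differently signed stoichiometry numbers")
    for j in range(J):
        if not S.entries[j, :].any():
            warnings.append(f"reactant '{S.reactant_ids[j]}' participates in no reaction")
    if I > J + 4:
        warnings.append(
            f"reaction count {I} above recommended band [J+2, J+4] = "
            f"[{J + 2}, {J + 4}]; run time may be impractical")

    return ValidationReport(passed=not failures, I_user=i_user, I_redirection=I,
                            removed_pairs=removed_pairs, rank=rank, nullity=nullity,
                            failures=failures, warnings=warnings)
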