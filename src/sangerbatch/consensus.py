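"""Consensus calling over a reference-anchored MSA.

Per column, the agreement rules are:

1. Point mutations, insertions and deletions relative to the reference
   are called only when *all* covering reads agree (a single covering
   read satisfies this vacuously and is flagged as single-read
   evidence downstream).
2. When only some reads carry an insertion — or the inserting reads
   disagree on the base — the column is an ambiguous insertion, shown
   as ``?`` and excluded from coverage, identity and translation.
3. In every other disagreement the reference base is kept and coverage
   at that column is reduced to the reads that match it.

N calls and masked positions never count as covering.  A read's ``-``
inside its aligned span is deletion evidence and does count; ``.``
(outside the span) does not.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .align import GAP, Msa, NOT_COVERED


class PositionStatus(str, Enum):
    MATCH = "match"
    POINT_MUTATION = "point_mutation"
    DELETION = "deletion"
    INSERTION = "insertion"
    AMBIGUOUS_INSERTION = "ambiguous_insertion"
    DISAGREEMENT_KEPT_REF = "disagreement_kept_ref"
    UNCOVERED = "uncovered"


AMBIGUOUS = "?"


@dataclass(frozen=True)
class ConsensusPosition:
    """One MSA column of the consensus."""

    column: int
    ref_base: str  # letter, or '-' at insertion columns
    consensus_base: str  # letter, '-', or '?'
    covering_reads: int
    agreeing_reads: int
    status: PositionStatus
    read_bases: tuple[str, ...] = ()

    @property
    def is_reference_position(self) -> bool:
        return self.ref_base != GAP


def _call_column(ref_base: str, symbols: list[str]) -> tuple[str, int, int, PositionStatus]:
    """Apply the agreement rules to one column.

    ``symbols`` holds one character per read: a base letter, ``-`` for a
    deletion inside the read's span, ``.`` for not covered, ``N`` for an
    ambiguous call.  Returns (consensus, covering, agreeing, status).
    """
    participants = [s for s in symbols if s not in (NOT_COVERED, "N")]
    letters = [s for s in participants if s != GAP]

    if ref_base == GAP:
        if not letters:
            # vacuous insertion column (no read inserts here)
            return GAP, 0, 0, PositionStatus.MATCH
        if len(letters) == len(participants) and len(set(letters)) == 1:
            return letters[0], len(participants), len(participants), PositionStatus.INSERTION
        return AMBIGUOUS, len(participants), 0, PositionStatus.AMBIGUOUS_INSERTION

    if not participants:
        return ref_base, 0, 0, PositionStatus.UNCOVERED
    distinct = set(participants)
    if distinct == {GAP}:
        return GAP, len(participants), len(participants), PositionStatus.DELETION
    if len(distinct) == 1:
        base = participants[0]
        status = PositionStatus.MATCH if base == ref_base else PositionStatus.POINT_MUTATION
        return base, len(participants), len(participants), status
    agreeing = sum(1 for s in participants if s == ref_base)
    return ref_base, len(participants), agreeing, PositionStatus.DISAGREEMENT_KEPT_REF


def build_consensus(msa: Msa) -> list[ConsensusPosition]:
    """Column-wise consensus of an MSA under the agreement rules."""
    positions = []
    for col in range(msa.n_columns):
        ref_base = msa.ref_row[col]
        symbols = [row[col] for row in msa.read_rows]
        base, covering, agreeing, status = _call_column(ref_base, symbols)
        positions.append(
            ConsensusPosition(
                column=col,
                ref_base=ref_base,
                consensus_base=base,
                covering_reads=covering,
                agreeing_reads=agreeing,
                status=status,
                read_bases=tuple(symbols),
            )
        )
    return positions


@dataclass(frozen=True)
class AlignmentStats:
    """Per-reference summary row."""

    coverage_pct: float
    identity_pct: float
    n_silent: int
    n_missense: int
    n_nonsense: int
    n_frameshift: int
    trace_names: tuple[str, ...]
    vacuous_identity: bool = False  # no covered positions at all

    def __post_init__(self) -> None:
        for v in (self.coverage_pct, self.identity_pct):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"percentage out of range: {v}")


def alignment_stats(
    positions: list[ConsensusPosition],
    mutations: list,
    trace_names: list[str],
) -> AlignmentStats:
    """Coverage and identity over reference positions, plus mutation
    tallies.

    Coverage is the fraction of reference positions seen by at least one
    read; identity is the fraction of *covered* reference positions
    whose consensus equals the reference (ambiguous-insertion columns
    sit at reference gaps and are excluded by construction).
    """
    ref_positions = [p for p in positions if p.is_reference_position]
    n_ref = len(ref_positions)
    covered = [p for p in ref_positions if p.covering_reads >= 1]
    coverage = 100.0 * len(covered) / n_ref if n_ref else 0.0
    vacuous = not covered
    identity = (
        100.0 * sum(1 for p in covered if p.consensus_base == p.ref_base) / len(covered)
        if covered
        else 100.0
    )
    counts = {"silent": 0, "missense": 0, "nonsense": 0, "frameshift": 0}
    for call in mutations:
        counts[call.mclass] += 1
    return AlignmentStats(
        coverage_pct=coverage,
        identity_pct=identity,
        n_silent=counts["silent"],
        n_missense=counts["missense"],
        n_nonsense=counts["nonsense"],
        n_frameshift=counts["frameshift"],
        trace_names=tuple(trace_names),
        vacuous_identity=vacuous,
    )
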