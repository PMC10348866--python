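"""Assignment of trace reads to reference sequences.

A read whose file name contains a reference id (case-insensitive
substring; the longest id wins, then alphabetical) is assigned to that
reference directly.  Any other read is aligned to every reference in
both orientations with the shared global scorer and the highest score
wins, ties broken by reference file order.  Sequencing direction is
detected the same way: the orientation with the higher alignment score
against the assigned reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from Bio import Align

from .align import make_aligner
from .preprocess import FORWARD, REVERSE, TraceRead, reverse_complement_read
from .trace_io import ReferenceRecord

logger = logging.getLogger(__name__)

DEFAULT_SCORE_FLOOR_PER_BASE = 0.5  # below this mean score a match is flagged low-confidence


@dataclass(frozen=True)
class Assignment:
    """The reference, orientation and provenance chosen for one read."""

    trace: TraceRead
    ref_id: str
    orientation: str
    method: str  # "filename" | "score"
    score: Optional[float] = None
    group_label: Optional[str] = None
    low_confidence: bool = False


def match_by_filename(source_name: str, refs: list[ReferenceRecord]) -> Optional[str]:
    """Reference id contained in the file name, if any (longest id wins,
    then alphabetical; matching is case-insensitive)."""
    if not refs:
        raise ValueError("no references supplied")
    name = source_name.lower()
    hits = [r.ref_id for r in refs if r.ref_id.lower() in name]
    if not hits:
        return None
    return sorted(hits, key=lambda rid: (-len(rid), rid))[0]


def detect_orientation(
    read: TraceRead, ref: ReferenceRecord, aligner: Optional[Align.PairwiseAligner] = None
) -> tuple[str, float]:
    """Score the read and its reverse complement against the reference;
    the higher score decides the orientation (tie goes to forward)."""
    if read.n_kept == 0:
        raise ValueError(f"{read.source_name}: no kept bases, cannot detect orientation")
    aligner = aligner or make_aligner()
    fwd = float(aligner.score(ref.sequence, read.retained_sequence))
    rev = float(aligner.score(ref.sequence, reverse_complement_read(read).retained_sequence))
    if rev > fwd:
        return REVERSE, rev
    return FORWARD, fwd


def assign_reference(
    read: TraceRead,
    refs: list[ReferenceRecord],
    aligner: Optional[Align.PairwiseAligner] = None,
    score_floor_per_base: float = DEFAULT_SCORE_FLOOR_PER_BASE,
    group_label: Optional[str] = None,
) -> Assignment:
    """Assign one read to a reference.

    A filename match short-circuits the search (orientation is still
    detected by alignment against that reference).  Otherwise all
    |refs| x 2 alignments are scored and the maximum wins, ties broken
    by reference file order.  The assignment is flagged low-confidence
    when the winning score falls below ``score_floor_per_base`` per
    kept read base.
    """
    if not refs:
        raise ValueError("no references supplied")
    aligner = aligner or make_aligner()
    by_id = {r.ref_id: r for r in refs}

    named = match_by_filename(read.source_name, refs)
    if named is not None:
        orientation, score = detect_orientation(read, by_id[named], aligner)
        return Assignment(read, named, orientation, "filename", score=score,
                          group_label=group_label,
                          low_confidence=_is_low(score, read, score_floor_per_base))

    best: Optional[tuple[float, int, str]] = None  # (score, ref index, orientation)
    for idx, ref in enumerate(refs):
        orientation, score = detect_orientation(read, ref, aligner)
        if best is None or score > best[0]:
            best = (score, idx, orientation)
    score, idx, orientation = best
    return Assignment(read, refs[idx].ref_id, orientation, "score", score=score,
                      group_label=group_label,
                      low_confidence=_is_low(score, read, score_floor_per_base))


def _is_low(score: float, read: TraceRead, floor_per_base: float) -> bool:
    n = max(read.n_kept, 1)
    return score / n < floor_per_base
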