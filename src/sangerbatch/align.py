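"""Pairwise and reference-anchored multiple alignment.

Pairwise alignment is global with affine gap penalties (match +2,
mismatch -1, gap open -5, gap extend -1 by default) via Biopython's
``PairwiseAligner``; the identical scorer is used for reference
assignment and orientation detection so scores are comparable
everywhere.

The multiple alignment of a read group against its reference can shell
out to a Clustal-Omega-compatible executable when one is on PATH; the
builtin backend needs no external binary.  It aligns each read to the
reference pairwise and merges the read-specific insertions into shared
columns: insertions hanging off the same reference position share a
column block, padded with gaps for reads without them.  A read's
leading and trailing gaps denote "not covered" rather than deletions
and are stored as ``.`` in its row.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align, SeqIO

from .errors import SangerBatchError
from .preprocess import TraceRead
from .trace_io import ReferenceRecord

logger = logging.getLogger(__name__)

NOT_COVERED = "."
GAP = "-"

DEFAULT_SCORING = {
    "match_score": 2.0,
    "mismatch_score": -1.0,
    "open_gap_score": -5.0,
    "extend_gap_score": -1.0,
}


def make_aligner(**overrides: float) -> Align.PairwiseAligner:
    params = {**DEFAULT_SCORING, **overrides}
    aligner = Align.PairwiseAligner(mode="global", **params)
    return aligner


@dataclass
class Msa:
    """A reference-anchored multiple alignment.

    ``ref_row`` carries a gap wherever any read inserts relative to the
    reference; ``column_map[i]`` is the alignment column of ungapped
    reference position ``i``.  Read rows use ``-`` for deletions inside
    the read's aligned span and ``.`` outside it (not covered).
    """

    ref_id: str
    ref_row: str
    read_rows: list[str]
    read_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.ref_row)
        if any(len(r) != n for r in self.read_rows):
            raise ValueError("all MSA rows must share one column count")

    @property
    def n_columns(self) -> int:
        return len(self.ref_row)

    @property
    def column_map(self) -> list[int]:
        return [i for i, c in enumerate(self.ref_row) if c != GAP]

    @property
    def reference_sequence(self) -> str:
        return self.ref_row.replace(GAP, "")


def pairwise_align(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> tuple[str, str, float]:
    """Globally align two sequences; returns the two gapped rows and the
    alignment score (deterministic: the aligner's first optimal path)."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = aligner or make_aligner()
    alignments = aligner.align(a, b)
    best = alignments[0]
    return str(best[0]), str(best[1]), float(alignments.score)


def _mark_uncovered(gapped_read: str) -> str:
    """Replace leading/trailing gap runs of a read row with '.'."""
    stripped = gapped_read.lstrip(GAP)
    lead = len(gapped_read) - len(stripped)
    stripped = stripped.rstrip(GAP)
    trail = len(gapped_read) - lead - len(stripped)
    return NOT_COVERED * lead + stripped + NOT_COVERED * trail


def _decompose(gapped_ref: str, gapped_read: str) -> tuple[list[str], list[str]]:
    """Split one pairwise alignment into per-reference-slot pieces.

    Returns (insertions, aligned) where ``insertions[p]`` is the read
    sequence inserted before reference position ``p`` (len(ref)+1 slots)
    and ``aligned[p]`` is the read symbol aligned to reference position
    ``p`` ('-' for deletion).
    """
    ref_len = len(gapped_ref.replace(GAP, ""))
    insertions = ["" for _ in range(ref_len + 1)]
    aligned = [GAP] * ref_len
    p = 0
    for rc, qc in zip(gapped_ref, gapped_read):
        if rc == GAP:
            if qc != GAP:
                insertions[p] += qc
        else:
            aligned[p] = qc
            p += 1
    return insertions, aligned


def _builtin_msa(ref: ReferenceRecord, reads: list[TraceRead], aligner: Align.PairwiseAligner) -> Msa:
    per_read: list[tuple[list[str], list[str], int, int]] = []
    refseq = ref.sequence
    for read in reads:
        seq = read.retained_sequence
        g_ref, g_read, _ = pairwise_align(refseq, seq, aligner)
        g_read = _mark_uncovered(g_read)
        ins, aligned = _decompose(g_ref, g_read)
        # covered span of the read over reference positions
        covered = [p for p, c in enumerate(aligned) if c not in (GAP, NOT_COVERED)]
        span = (covered[0], covered[-1] + 1) if covered else (0, 0)
        per_read.append((ins, aligned, *span))

    ref_len = len(refseq)
    ins_width = [max((len(pr[0][p]) for pr in per_read), default=0) for p in range(ref_len + 1)]

    ref_row_parts: list[str] = []
    row_parts: list[list[str]] = [[] for _ in per_read]
    for p in range(ref_len + 1):
        w = ins_width[p]
        if w:
            ref_row_parts.append(GAP * w)
            for k, (ins, aligned, lo, hi) in enumerate(per_read):
                block = ins[p]
                # the slot is spanned by a read iff it covers the ref base on both sides
                inside = lo < p < hi
                pad = GAP if inside or block else NOT_COVERED
                # insertions left-justified in the shared block
                row_parts[k].append(block + pad * (w - len(block)))
        if p < ref_len:
            ref_row_parts.append(refseq[p])
            for k, (ins, aligned, lo, hi) in enumerate(per_read):
                c = aligned[p]
                if c == GAP and not (lo <= p < hi):
                    c = NOT_COVERED
                row_parts[k].append(c)

    return Msa(
        ref_id=ref.ref_id,
        ref_row="".join(ref_row_parts),
        read_rows=["".join(parts) for parts in row_parts],
        read_names=[r.source_name for r in reads],
    )


def _external_msa(ref: ReferenceRecord, reads: list[TraceRead], executable: str) -> Msa:
    """Run a Clustal-Omega-compatible aligner over reference + reads and
    re-anchor the result on the reference row."""
    with tempfile.TemporaryDirectory() as tmp:
        infile = Path(tmp) / "in.fasta"
        outfile = Path(tmp) / "out.fasta"
        with open(infile, "w") as fh:
            fh.write(f">__ref__\n{ref.sequence}\n")
            for i, read in enumerate(reads):
                fh.write(f">read{i}\n{read.retained_sequence}\n")
        subprocess.run(
            [executable, "-i", str(infile), "-o", str(outfile), "--force"],
            check=True, capture_output=True,
        )
        rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(outfile), "fasta")}
    ref_row = rows.pop("__ref__")
    read_rows = [_mark_uncovered(rows[f"read{i}"]) for i in range(len(reads))]
    return Msa(
        ref_id=ref.ref_id,
        ref_row=ref_row,
        read_rows=read_rows,
        read_names=[r.source_name for r in reads],
    )


def msa_group(
    ref: ReferenceRecord,
    reads: list[TraceRead],
    backend: str = "auto",
    aligner: Align.PairwiseAligner | None = None,
) -> Msa:
    """Multiple alignment of one reference group.

    ``backend`` is ``builtin``, ``external`` or ``auto`` (external when a
    ``clustalo`` executable is found, otherwise builtin).  Reads must be
    pre-oriented to the forward strand and have at least one kept base.
    """
    usable = [r for r in reads if r.n_kept > 0]
    if not usable:
        raise SangerBatchError(f"reference {ref.ref_id!r}: no reads with kept bases to align")
    aligner = aligner or make_aligner()
    if backend not in ("auto", "external", "builtin"):
        raise ValueError(f"unknown alignment backend {backend!r}")
    if backend in ("auto", "external"):
        exe = shutil.which("clustalo")
        if exe:
            return _external_msa(ref, usable, exe)
        if backend == "external":
            logger.warning("external aligner requested but no clustalo executable found; using builtin")
    return _builtin_msa(ref, usable, aligner)
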