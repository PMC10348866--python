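"""Frame-aware translation and mutation classification.

The coding sequence is translated continuously from its first codon
with the standard genetic code; a trailing partial codon is dropped and
translation does not stop at internal stop codons (rendered ``*``).
Codons containing an N translate to ``X``.  Ambiguous-insertion columns
(``?``) are removed before codons are formed.

Mutations are classified into the four classes silent (same amino
acid), missense (different amino acid), nonsense (introduces a stop)
and frameshift.  An insertion or deletion whose length is not divisible
by 3 shifts the reading frame: every downstream position is flagged as
frameshifted — and any variant there is counted only as frameshift —
until a compensating indel restores the frame or the CDS ends, with
translation continuing in the shifted frame throughout.  In-frame
indels (length divisible by 3) have no class of their own and are
reported as missense with an ``inframe_indel`` note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Data import CodonTable

from .align import GAP
from .consensus import AMBIGUOUS, ConsensusPosition, PositionStatus
from .trace_io import ReferenceRecord

_TABLE = CodonTable.standard_dna_table
_STOPS = set(_TABLE.stop_codons)

SILENT = "silent"
MISSENSE = "missense"
NONSENSE = "nonsense"
FRAMESHIFT = "frameshift"


def translate_codon(codon: str) -> str:
    codon = codon.upper()
    if codon in _STOPS:
        return "*"
    aa = _TABLE.forward_table.get(codon)
    return aa if aa is not None else "X"


def translate_frame_aware(seq: str, cds_start: int = 0, cds_end: Optional[int] = None) -> str:
    """Translate ``seq[cds_start:cds_end]`` codon by codon.

    ``?`` placeholders are removed before codon grouping; a trailing
    1–2 nt partial codon is ignored; internal stops do not terminate
    translation.
    """
    cds = seq[cds_start : cds_end if cds_end is not None else len(seq)]
    cds = cds.replace(AMBIGUOUS, "").replace(GAP, "").upper()
    return "".join(translate_codon(cds[i : i + 3]) for i in range(0, len(cds) - 2, 3))


@dataclass(frozen=True)
class MutationCall:
    """One mutation event in the consensus relative to the reference.

    ``ref_position`` is 1-based (report convention): the substituted or
    first deleted base, or the reference base immediately preceding an
    insertion.  ``shift_end`` (frameshift calls only) is the 1-based
    last reference position in the shifted frame.
    """

    ref_position: int
    ref_bases: str
    alt_bases: str
    mclass: str
    codon_index: Optional[int] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    note: str = ""
    frameshifted_from: Optional[int] = None
    shift_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mclass == SILENT and self.ref_aa != self.alt_aa:
            raise ValueError("silent call with differing amino acids")
        if self.mclass == NONSENSE and self.alt_aa != "*":
            raise ValueError("nonsense call without a stop codon")


@dataclass
class _Event:
    kind: str  # "sub" | "ins" | "del"
    ref_pos: int  # 0-based; for ins, the slot index (insertion before this ref position)
    ref_bases: str
    alt_bases: str


def _collect_events(ref: ReferenceRecord, positions: list[ConsensusPosition]) -> list[_Event]:
    """Turn consensus columns into nucleotide-level events inside the CDS,
    one per substituted base and one per contiguous indel run."""
    events: list[_Event] = []
    ref_pos = 0  # ungapped reference index of the current column
    run: Optional[_Event] = None

    def flush() -> None:
        nonlocal run
        if run is not None:
            events.append(run)
            run = None

    for p in positions:
        if p.ref_base == GAP:
            slot = ref_pos  # insertion before this reference position
            if p.status == PositionStatus.INSERTION and ref.cds_start < slot < ref.cds_end:
                if run is not None and run.kind == "ins" and run.ref_pos == slot:
                    run.alt_bases += p.consensus_base
                else:
                    flush()
                    run = _Event("ins", slot, "", p.consensus_base)
            # '?' and vacuous insertion columns carry no event
            continue
        in_cds = ref.cds_start <= ref_pos < ref.cds_end
        if in_cds and p.status == PositionStatus.DELETION:
            if run is not None and run.kind == "del" and run.ref_pos + len(run.ref_bases) == ref_pos:
                run.ref_bases += p.ref_base
            else:
                flush()
                run = _Event("del", ref_pos, p.ref_base, "")
        else:
            flush()
            if in_cds and p.status == PositionStatus.POINT_MUTATION:
                events.append(_Event("sub", ref_pos, p.ref_base, p.consensus_base))
        ref_pos += 1
    flush()
    return events


def consensus_base_at_ref(positions: list[ConsensusPosition], ref_len: int) -> list[str]:
    """Per ungapped reference position, the effective consensus letter
    (the reference base where it was kept; '-' where deleted)."""
    out = [""] * ref_len
    ref_pos = 0
    for p in positions:
        if p.ref_base == GAP:
            continue
        out[ref_pos] = p.consensus_base if p.consensus_base != AMBIGUOUS else p.ref_base
        ref_pos += 1
    return out


def classify_mutations(ref: ReferenceRecord, positions: list[ConsensusPosition]) -> list[MutationCall]:
    """Classify every consensus mutation event within the CDS."""
    events = _collect_events(ref, positions)
    cons_at_ref = consensus_base_at_ref(positions, len(ref.sequence))
    calls: list[MutationCall] = []

    shift = 0  # cumulative net indel length (mod 3 matters)
    shift_origin: Optional[int] = None  # 1-based position where frame was lost
    open_shift_calls: list[int] = []  # indices into calls awaiting shift_end

    def close_shift(end_pos_1based: int) -> None:
        nonlocal shift_origin
        for idx in open_shift_calls:
            calls[idx] = MutationCall(
                **{**calls[idx].__dict__, "shift_end": end_pos_1based}
            )
        open_shift_calls.clear()
        shift_origin = None

    for ev in events:
        pos1 = ev.ref_pos + 1 if ev.kind != "ins" else ev.ref_pos  # preceding base for insertions
        if ev.kind == "sub":
            if shift % 3 != 0:
                calls.append(
                    MutationCall(pos1, ev.ref_bases, ev.alt_bases, FRAMESHIFT,
                                 frameshifted_from=shift_origin)
                )
                open_shift_calls.append(len(calls) - 1)
                continue
            off = ev.ref_pos - ref.cds_start
            codon_index = off // 3
            codon_start = ref.cds_start + 3 * codon_index
            ref_codon = ref.sequence[codon_start : codon_start + 3]
            if len(ref_codon) < 3:
                calls.append(MutationCall(pos1, ev.ref_bases, ev.alt_bases, SILENT,
                                          note="beyond_last_codon"))
                continue
            alt_codon = "".join(
                (cons_at_ref[i] if cons_at_ref[i] not in ("", GAP) else ref.sequence[i])
                for i in range(codon_start, codon_start + 3)
            )
            ref_aa, alt_aa = translate_codon(ref_codon), translate_codon(alt_codon)
            if alt_aa == "*" and ref_aa != "*":
                mclass = NONSENSE
            elif ref_aa == alt_aa:
                mclass = SILENT
            else:
                mclass = MISSENSE
            note = "stop_loss" if ref_aa == "*" and alt_aa != "*" else ""
            calls.append(MutationCall(pos1, ev.ref_bases, ev.alt_bases, mclass,
                                      codon_index=codon_index, ref_aa=ref_aa, alt_aa=alt_aa,
                                      note=note))
        else:
            length = len(ev.ref_bases) or len(ev.alt_bases)
            delta = len(ev.alt_bases) - len(ev.ref_bases)
            was_shifted = shift % 3 != 0
            shift += delta
            now_shifted = shift % 3 != 0
            if length % 3 == 0 and not was_shifted and not now_shifted:
                calls.append(MutationCall(pos1, ev.ref_bases, ev.alt_bases, MISSENSE,
                                          note="inframe_indel"))
                continue
            if not was_shifted and now_shifted:
                shift_origin = pos1
            calls.append(MutationCall(pos1, ev.ref_bases, ev.alt_bases, FRAMESHIFT,
                                      frameshifted_from=shift_origin))
            open_shift_calls.append(len(calls) - 1)
            if was_shifted and not now_shifted:
                close_shift(pos1)
    if shift % 3 != 0:
        close_shift(ref.cds_end)  # frame never restored: shifted to CDS end
    return calls


def frameshifted_ref_intervals(calls: list[MutationCall]) -> list[tuple[int, int]]:
    """1-based inclusive reference intervals rendered in the shifted frame."""
    intervals = []
    for c in calls:
        if c.mclass == FRAMESHIFT and c.frameshifted_from is not None and c.shift_end is not None:
            intervals.append((c.frameshifted_from, c.shift_end))
    if not intervals:
        return []
    intervals.sort()
    merged = [intervals[0]]
    for lo, hi in intervals[1:]:
        if lo <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged
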