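"""Result assembly and spreadsheet export.

The overview sheet holds one alignment per row — reference id, coverage
and identity percentages, mutation counts by class and the aligned
trace files — with internal hyperlinks to two sheets per alignment: the
alignment sheet (reference, consensus and every trace sequence, one
character per cell, with amino-acid translations and colour-coded
coverage/mutation cells) and a positions sheet listing all mismatching
positions plus zero-coverage regions in 1-based inclusive reference
coordinates.

A plain-TSV mirror of the same numeric content is written next to the
workbook; colour is style-only metadata, the TSV carries the identical
information as status columns, so downstream diffs never parse styles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
from openpyxl import Workbook
from openpyxl.styles import Font, PatternFill

from . import __version__
from .align import GAP, Msa, NOT_COVERED
from .annotate import FRAMESHIFT, MutationCall, frameshifted_ref_intervals, translate_frame_aware
from .assign import Assignment
from .consensus import AMBIGUOUS, AlignmentStats, ConsensusPosition, PositionStatus
from .peakcall import MixedPeak
from .trace_io import ReferenceRecord

# cell colours (ARGB); background encodes coverage, font encodes mutation class
PALETTE = {
    "uncovered_fill": "FFD9D9D9",
    "low_coverage_fill": "FFFFF2CC",  # single-read evidence
    "ambiguous_fill": "FFFFE599",
    "point_mutation_font": "FF1F4E99",
    "silent_font": "FF2E7D32",
    "missense_font": "FFE65100",
    "nonsense_font": "FFC62828",
    "frameshift_font": "FF8E24AA",
}

OVERVIEW_COLUMNS = [
    "reference",
    "group",
    "coverage_pct",
    "identity_pct",
    "n_silent",
    "n_missense",
    "n_nonsense",
    "n_frameshift",
    "n_traces",
    "trace_names",
    "low_confidence",
]


@dataclass
class ReferenceResult:
    """Everything computed for one reference group."""

    ref: ReferenceRecord
    assignments: list[Assignment] = field(default_factory=list)
    msa: Optional[Msa] = None
    positions: list[ConsensusPosition] = field(default_factory=list)
    calls: list[MutationCall] = field(default_factory=list)
    stats: Optional[AlignmentStats] = None
    mixed_peaks: dict[str, list[MixedPeak]] = field(default_factory=dict)
    group_label: Optional[str] = None

    @property
    def label(self) -> str:
        return self.ref.ref_id if not self.group_label else f"{self.ref.ref_id}@{self.group_label}"


@dataclass
class RunResult:
    """The full outcome of one batch run."""

    references: list[ReferenceResult]
    parameters: dict = field(default_factory=dict)
    version: str = __version__


def summarize(results: RunResult) -> pd.DataFrame:
    """One row per alignment, in reference file order."""
    rows = []
    for rr in results.references:
        s = rr.stats
        rows.append({
            "reference": rr.ref.ref_id,
            "group": rr.group_label or "",
            "coverage_pct": round(s.coverage_pct, 1) if s else 0.0,
            "identity_pct": round(s.identity_pct, 1) if s else 100.0,
            "n_silent": s.n_silent if s else 0,
            "n_missense": s.n_missense if s else 0,
            "n_nonsense": s.n_nonsense if s else 0,
            "n_frameshift": s.n_frameshift if s else 0,
            "n_traces": len(rr.assignments),
            "trace_names": ";".join(a.trace.source_name for a in rr.assignments),
            "low_confidence": any(a.low_confidence for a in rr.assignments),
        })
    return pd.DataFrame(rows, columns=OVERVIEW_COLUMNS)


def zero_coverage_intervals(positions: list[ConsensusPosition]) -> list[tuple[int, int]]:
    """1-based inclusive reference intervals with no covering read."""
    intervals = []
    ref_pos = 0
    start = None
    for p in positions:
        if p.ref_base == GAP:
            continue
        ref_pos += 1
        if p.covering_reads == 0:
            if start is None:
                start = ref_pos
        elif start is not None:
            intervals.append((start, ref_pos - 1))
            start = None
    if start is not None:
        intervals.append((start, ref_pos))
    return intervals


def mismatch_table(rr: ReferenceResult) -> pd.DataFrame:
    """All mismatching positions of one alignment, 1-based."""
    rows = [
        {
            "ref_position": c.ref_position,
            "ref_bases": c.ref_bases,
            "alt_bases": c.alt_bases,
            "class": c.mclass,
            "ref_aa": c.ref_aa or "",
            "alt_aa": c.alt_aa or "",
            "note": c.note,
        }
        for c in rr.calls
    ]
    return pd.DataFrame(rows, columns=["ref_position", "ref_bases", "alt_bases", "class", "ref_aa", "alt_aa", "note"])


def _sheet_name(base: str, suffix: str, used: set[str]) -> str:
    name = f"{base}_{suffix}"[:31]
    n = 1
    while name in used:
        name = f"{base[:25]}~{n}_{suffix}"[:31]
        n += 1
    used.add(name)
    return name


def _aa_row(seq_cells: list[str], cds_start: int, cds_end: int) -> list[str]:
    """Amino-acid letters spread over their codons' middle cells."""
    letters = [c for c in seq_cells]
    aa = translate_frame_aware("".join(seq_cells), cds_start, cds_end)
    out = [""] * len(seq_cells)
    # map each translated codon onto its middle nucleotide cell
    coding = [i for i, c in enumerate(letters) if cds_start <= i < cds_end]
    for k, a in enumerate(aa):
        codon_cells = coding[3 * k : 3 * k + 3]
        if codon_cells:
            out[codon_cells[min(1, len(codon_cells) - 1)]] = a
    return out


def _write_alignment_sheet(ws, rr: ReferenceResult) -> None:
    msa, positions = rr.msa, rr.positions
    shift_intervals = frameshifted_ref_intervals(rr.calls)

    def shifted(ref_pos_1: int) -> bool:
        return any(lo <= ref_pos_1 <= hi for lo, hi in shift_intervals)

    sub_class = {c.ref_position: c.mclass for c in rr.calls if c.codon_index is not None}

    header = ["track"]
    ref_pos = 0
    col_refpos = []
    for p in positions:
        if p.ref_base != GAP:
            ref_pos += 1
            col_refpos.append(ref_pos)
        else:
            col_refpos.append(None)
    ws.append(header + [rp or "" for rp in col_refpos])

    ref_cells = [p.ref_base for p in positions]
    cons_cells = [p.consensus_base for p in positions]
    ws.append(["ref_aa"] + _aa_row(
        [c if c != GAP else "" for c in ref_cells], rr.ref.cds_start, rr.ref.cds_end))
    ws.append(["reference"] + ref_cells)
    ws.append(["consensus"] + cons_cells)
    cons_seq = "".join(c for c in cons_cells if c not in (GAP, AMBIGUOUS))
    ws.append(["consensus_aa"] + list(translate_frame_aware(cons_seq, rr.ref.cds_start).ljust(len(positions)))[: len(positions)])
    if msa is not None:
        for name, row in zip(msa.read_names, msa.read_rows):
            ws.append([name] + [c if c != NOT_COVERED else "" for c in row])

    cons_row = 4
    for j, p in enumerate(positions, start=2):
        cell = ws.cell(row=cons_row, column=j)
        if p.status == PositionStatus.UNCOVERED:
            cell.fill = PatternFill("solid", fgColor=PALETTE["uncovered_fill"])
        elif p.status == PositionStatus.AMBIGUOUS_INSERTION:
            cell.fill = PatternFill("solid", fgColor=PALETTE["ambiguous_fill"])
        elif p.covering_reads == 1:
            cell.fill = PatternFill("solid", fgColor=PALETTE["low_coverage_fill"])
        rp = col_refpos[j - 2]
        if rp is not None and shifted(rp):
            cell.font = Font(color=PALETTE["frameshift_font"][2:])
        elif rp is not None and rp in sub_class:
            cell.font = Font(color=PALETTE[f"{sub_class[rp]}_font"][2:])
        elif p.status == PositionStatus.POINT_MUTATION:
            cell.font = Font(color=PALETTE["point_mutation_font"][2:])


def export_workbook(
    results: RunResult,
    dest: Path,
    tsv_dir: Optional[Path] = None,
    only_reference: Optional[str] = None,
) -> None:
    """Write the spreadsheet report (and its TSV mirror).

    ``only_reference`` restricts the export to a single alignment's
    sheets (the per-alignment download).
    """
    dest = Path(dest)
    dest.parent.mkdir(parents=True, exist_ok=True)
    selected = [
        rr for rr in results.references
        if only_reference is None or rr.ref.ref_id == only_reference
    ]

    wb = Workbook()
    overview = wb.active
    overview.title = "Overview"
    df = summarize(results if only_reference is None else RunResult(selected, results.parameters))
    overview.append(list(df.columns))
    for _, row in df.iterrows():
        overview.append(list(row))

    used: set[str] = {"Overview"}
    for i, rr in enumerate(selected):
        aln_name = _sheet_name(rr.label, "aln", used)
        pos_name = _sheet_name(rr.label, "pos", used)
        ws = wb.create_sheet(aln_name)
        if rr.msa is not None:
            _write_alignment_sheet(ws, rr)
        else:
            ws.append(["no traces assigned"])
        ws2 = wb.create_sheet(pos_name)
        ws2.append(["mismatching positions"])
        mt = mismatch_table(rr)
        ws2.append(list(mt.columns))
        for _, row in mt.iterrows():
            ws2.append(list(row))
        ws2.append([])
        ws2.append(["zero-coverage regions (1-based inclusive)"])
        for lo, hi in zero_coverage_intervals(rr.positions):
            ws2.append([f"{lo}-{hi}"])
        # overview row links to this alignment's sheet
        link_cell = overview.cell(row=2 + i, column=1)
        link_cell.hyperlink = f"#'{aln_name}'!A1"
        link_cell.style = "Hyperlink"

    wb.save(dest)

    if tsv_dir is not None:
        write_tsv_mirror(results if only_reference is None else RunResult(selected, results.parameters), Path(tsv_dir))


def write_tsv_mirror(results: RunResult, tsv_dir: Path) -> None:
    """Plain-text mirror of the workbook's numeric content."""
    tsv_dir = Path(tsv_dir)
    tsv_dir.mkdir(parents=True, exist_ok=True)
    summarize(results).to_csv(tsv_dir / "overview.tsv", sep="\t", index=False)
    for rr in results.references:
        prefix = rr.label.replace("/", "_")
        pos_df = pd.DataFrame(
            [
                {
                    "column": p.column,
                    "ref_base": p.ref_base,
                    "consensus_base": p.consensus_base,
                    "covering_reads": p.covering_reads,
                    "agreeing_reads": p.agreeing_reads,
                    "status": p.status.value,
                }
                for p in rr.positions
            ],
            columns=["column", "ref_base", "consensus_base", "covering_reads", "agreeing_reads", "status"],
        )
        pos_df.to_csv(tsv_dir / f"{prefix}_positions.tsv", sep="\t", index=False)
        mismatch_table(rr).to_csv(tsv_dir / f"{prefix}_mismatches.tsv", sep="\t", index=False)
        zc = zero_coverage_intervals(rr.positions)
        with open(tsv_dir / f"{prefix}_zero_coverage.tsv", "w") as fh:
            fh.write("start\tend\n")
            for lo, hi in zc:
                fh.write(f"{lo}\t{hi}\n")
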