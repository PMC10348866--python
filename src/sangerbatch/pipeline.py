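"""The batch pipeline: traces + references in, consensus report out.

Stages run in a fixed order — trace parsing, quality processing,
mixed-peak detection, reference assignment and orientation detection,
per-reference multiple alignment, consensus calling, mutation
classification, report export.  The run is a pure function of the input
files and the configuration: identical reruns produce identical TSV
output.
"""

from __future__ import annotations

import logging
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .align import make_aligner, msa_group
from .annotate import classify_mutations
from .assign import Assignment, assign_reference
from .consensus import alignment_stats, build_consensus
from .errors import EmptyInputError, ReferenceFormatError, SangerBatchError
from .peakcall import DEFAULT_NOISE_K, DEFAULT_PEAK_FACTOR, detect_mixed_peaks
from .preprocess import (
    REVERSE,
    TraceRead,
    apply_quality_mask,
    read_from_chromatogram,
    reverse_complement_read,
    trim_ends,
)
from .report import ReferenceResult, RunResult, export_workbook
from .trace_io import Chromatogram, read_ab1, read_references, read_trace_archive

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_EMPTY_INPUT = 2
EXIT_FORMAT_ERROR = 3


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one batch run."""

    traces: Path
    references: Path
    output: Path
    quality_threshold: Optional[int] = None
    trim_threshold: Optional[int] = None
    peak_factor: float = DEFAULT_PEAK_FACTOR
    noise_k: float = DEFAULT_NOISE_K
    groups: Optional[Path] = None
    aligner: str = "auto"  # auto | external | builtin
    seed: Optional[int] = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.peak_factor < 1.0:
            raise ValueError("peak factor must lie strictly between 0 and 1")
        for t in (self.quality_threshold, self.trim_threshold):
            if t is not None and t < 0:
                raise ValueError("thresholds must be >= 0")


def load_traces(path: Path) -> list[Chromatogram]:
    """Read all AB1 files from a directory or a zip archive."""
    path = Path(path)
    if path.is_dir():
        chroms = []
        for f in sorted(path.glob("*.ab1")):
            chroms.append(read_ab1(f.read_bytes(), f.stem))
        if not chroms:
            raise EmptyInputError(f"no .ab1 files in {path}")
        return chroms
    if zipfile.is_zipfile(path):
        return read_trace_archive(path.read_bytes())
    if path.suffix.lower() == ".ab1":
        return [read_ab1(path.read_bytes(), path.stem)]
    raise EmptyInputError(f"{path}: not a directory, zip archive or .ab1 file")


def load_groups(path: Optional[Path]) -> dict[str, str]:
    if path is None:
        return {}
    df = pd.read_csv(path, dtype=str)
    cols = {c.strip().lower(): c for c in df.columns}
    if "trace_name" not in cols or "group" not in cols:
        raise ReferenceFormatError("groups file needs columns trace_name,group")
    return dict(zip(df[cols["trace_name"]], df[cols["group"]]))


def preprocess_read(chrom: Chromatogram, config: RunConfig) -> TraceRead:
    read = read_from_chromatogram(chrom)
    if config.trim_threshold is not None:
        read = trim_ends(read, config.trim_threshold)
    if config.quality_threshold is not None:
        read = apply_quality_mask(read, config.quality_threshold)
    return read


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full batch pipeline and write the report."""
    logging.basicConfig(level=config.log_level)
    logger.info(
        "run parameters: peak_factor=%s noise_k=%s quality_threshold=%s trim_threshold=%s aligner=%s",
        config.peak_factor, config.noise_k, config.quality_threshold,
        config.trim_threshold, config.aligner,
    )
    refs = read_references(Path(config.references).read_bytes())
    chroms = load_traces(Path(config.traces))
    groups = load_groups(config.groups)
    shared_aligner = make_aligner()

    mixed_by_trace = {
        c.source_name: detect_mixed_peaks(c, f=config.peak_factor, noise_k=config.noise_k)
        for c in chroms
    }

    assignments: list[Assignment] = []
    for chrom in chroms:
        read = preprocess_read(chrom, config)
        if read.n_kept == 0:
            logger.warning("%s: no bases survive filtering; skipping", chrom.source_name)
            continue
        assignments.append(
            assign_reference(read, refs, shared_aligner,
                             group_label=groups.get(chrom.source_name))
        )

    backend = {"auto": "auto", "external": "external", "builtin": "builtin"}[config.aligner]
    group_labels = sorted({a.group_label for a in assignments}, key=lambda g: (g is not None, g or ""))
    results: list[ReferenceResult] = []
    for ref in refs:
        for label in group_labels or [None]:
            members = [a for a in assignments if a.ref_id == ref.ref_id and a.group_label == label]
            if not members and label is not None:
                continue
            rr = ReferenceResult(ref=ref, assignments=members, group_label=label)
            if members:
                oriented = [
                    reverse_complement_read(a.trace) if a.orientation == REVERSE else a.trace
                    for a in members
                ]
                rr.msa = msa_group(ref, oriented, backend=backend, aligner=shared_aligner)
                rr.positions = build_consensus(rr.msa)
                rr.calls = classify_mutations(ref, rr.positions)
                rr.mixed_peaks = {
                    a.trace.source_name: mixed_by_trace.get(a.trace.source_name, [])
                    for a in members
                }
            else:
                # an unmatched reference still gets a row: zero coverage
                from .consensus import ConsensusPosition, PositionStatus
                rr.positions = [
                    ConsensusPosition(i, b, b, 0, 0, PositionStatus.UNCOVERED)
                    for i, b in enumerate(ref.sequence)
                ]
            rr.stats = alignment_stats(
                rr.positions, rr.calls, [a.trace.source_name for a in members]
            )
            results.append(rr)

    run = RunResult(
        references=results,
        parameters={
            "peak_factor": config.peak_factor,
            "noise_k": config.noise_k,
            "quality_threshold": config.quality_threshold,
            "trim_threshold": config.trim_threshold,
            "aligner": config.aligner,
            "seed": config.seed,
            "version": __version__,
        },
    )
    out = Path(config.output)
    out.mkdir(parents=True, exist_ok=True)
    export_workbook(run, out / "report.xlsx", tsv_dir=out / "tsv")
    return run
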