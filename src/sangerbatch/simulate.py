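"""Synthetic chromatogram and dataset generation.

Emulates the analysed signal of a Sanger run: one Gaussian peak per
called base on that base's channel, evenly spaced centres, optional
baseline noise, and optional planted events — substitutions, indels,
secondary ("mixed") peaks at a chosen amplitude fraction, and locally
degraded qualities.  Generated traces are written as real AB1 files so
the whole pipeline, including ABIF parsing, is exercised end to end.

Defaults (12 samples/base spacing, sigma 3, amplitude 1000, noise sd
10) keep adjacent peaks essentially non-overlapping so integrated peak
areas are clean.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .preprocess import reverse_complement
from .trace_io import BASES, Chromatogram, write_ab1

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"
MIXED_PEAK = "mixed_peak"
DEGRADE = "degrade"


@dataclass(frozen=True)
class SimParams:
    """Signal-model parameters of the generator."""

    peak_spacing: int = 12  # samples per base
    peak_sigma: float = 3.0  # Gaussian width, samples
    peak_height: int = 1000  # main peak amplitude
    noise_sd: float = 10.0  # baseline Gaussian noise, clipped at zero
    mixed_ratio: float = 0.4  # default secondary amplitude fraction
    quality_high: int = 50
    quality_low: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_spacing < 2 or self.peak_sigma <= 0:
            raise ValueError("need peak_spacing >= 2 and peak_sigma > 0")
        if not 0.0 <= self.mixed_ratio <= 1.0:
            raise ValueError("mixed_ratio must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedEvent:
    """A deliberate deviation planted into one read.

    ``position`` is 0-based into the template sequence (for mixed peaks
    and degradations: into the read after sequence edits).  ``detail``
    holds the new base(s) for substitutions/insertions, the secondary
    channel for mixed peaks, and is unused for deletions/degradations.
    ``expected_class`` (optional) records the mutation class the event
    should produce, for truth manifests.
    """

    kind: str
    position: int
    detail: str = ""
    length: int = 1
    expected_class: str = ""
    ratio: Optional[float] = None  # mixed peaks: overrides SimParams.mixed_ratio


def _apply_sequence_events(seq: str, events: list[PlantedEvent]) -> str:
    seq_events = [e for e in events if e.kind in (SUBSTITUTION, INSERTION, DELETION)]
    if len({e.position for e in seq_events}) != len(seq_events):
        raise ValueError("overlapping planted sequence events at one position")
    out = seq
    # apply right-to-left so earlier positions stay valid
    for ev in sorted(seq_events, key=lambda e: -e.position):
        if not 0 <= ev.position <= len(out) - (ev.length if ev.kind == DELETION else 0):
            raise ValueError(f"planted event position {ev.position} outside sequence")
        if ev.kind == SUBSTITUTION:
            out = out[: ev.position] + ev.detail + out[ev.position + len(ev.detail) :]
        elif ev.kind == INSERTION:
            out = out[: ev.position] + ev.detail + out[ev.position :]
        elif ev.kind == DELETION:
            out = out[: ev.position] + out[ev.position + ev.length :]
    return out


def simulate_chromatogram(
    seq: str,
    params: SimParams = SimParams(),
    planted: Optional[list[PlantedEvent]] = None,
    name: str = "synthetic",
) -> Chromatogram:
    """Render a nucleotide sequence as a four-channel chromatogram.

    Deterministic for a fixed ``params.seed``.
    """
    planted = planted or []
    if any(b not in BASES for b in seq):
        raise ValueError("template sequence must be over ACGT")
    read_seq = _apply_sequence_events(seq, planted)
    n = len(read_seq)
    spacing, sigma = params.peak_spacing, params.peak_sigma
    length = spacing * max(n, 1)
    centres = np.arange(n) * spacing + spacing // 2

    x = np.arange(length, dtype=float)
    signals = {b: np.zeros(length, dtype=float) for b in BASES}

    def add_peak(channel: str, centre: int, amplitude: float) -> None:
        lo = max(0, int(centre - 4 * sigma))
        hi = min(length, int(centre + 4 * sigma) + 1)
        signals[channel][lo:hi] += amplitude * np.exp(-0.5 * ((x[lo:hi] - centre) / sigma) ** 2)

    for i, base in enumerate(read_seq):
        add_peak(base, int(centres[i]), params.peak_height)
    for ev in planted:
        if ev.kind == MIXED_PEAK:
            if not 0 <= ev.position < n:
                raise ValueError(f"mixed peak position {ev.position} outside read")
            channel = ev.detail or "A"
            if channel == read_seq[ev.position]:
                raise ValueError("mixed peak channel equals the called base")
            ratio = params.mixed_ratio if ev.ratio is None else ev.ratio
            add_peak(channel, int(centres[ev.position]), ratio * params.peak_height)

    rng = np.random.default_rng(params.seed)
    if params.noise_sd > 0:
        for b in BASES:
            signals[b] += rng.normal(0.0, params.noise_sd, size=length)
    channels = {
        b: np.clip(np.rint(np.clip(signals[b], 0, None)), 0, 32767).astype(np.int64)
        for b in BASES
    }

    qualities = np.full(n, params.quality_high, dtype=np.int64)
    for ev in planted:
        if ev.kind == DEGRADE:
            lo, hi = ev.position, min(n, ev.position + ev.length)
            qualities[lo:hi] = params.quality_low

    return Chromatogram(
        source_name=name,
        channel_order="GATC",
        channels=channels,
        peak_positions=centres,
        bases=read_seq,
        qualities=qualities,
    )


@dataclass(frozen=True)
class ManifestRow:
    """Ground truth for one generated trace file."""

    file_name: str
    ref_id: str
    orientation: str
    events: tuple[PlantedEvent, ...]


def synth_dataset(
    refs: list,
    reads_per_ref: int,
    mutation_plan: Optional[dict[str, list[PlantedEvent]]] = None,
    reverse_fraction: float = 0.0,
    params: SimParams = SimParams(),
    dest: Optional[Path] = None,
    name_by_ref: bool = True,
) -> list[ManifestRow]:
    """Generate a full synthetic dataset: AB1 files, reference files and
    a truth manifest.

    Every read of a reference carries that reference's planted events
    (so consensus unanimity holds).  A deterministic ``reverse_fraction``
    of each reference's reads is emitted reverse-complemented.  With
    ``name_by_ref`` False, files get generic names, forcing score-based
    assignment downstream.
    """
    if reads_per_ref < 1:
        raise ValueError("reads_per_ref must be >= 1")
    mutation_plan = mutation_plan or {}
    dest = Path(dest) if dest is not None else None
    if dest is not None:
        dest.mkdir(parents=True, exist_ok=True)

    manifest: list[ManifestRow] = []
    counter = 0
    for ref in refs:
        events = tuple(mutation_plan.get(ref.ref_id, []))
        n_reverse = int(round(reverse_fraction * reads_per_ref))
        for k in range(reads_per_ref):
            counter += 1
            name = f"{ref.ref_id}_{k + 1}" if name_by_ref else f"sample{counter:03d}"
            chrom = simulate_chromatogram(
                ref.sequence,
                replace(params, seed=params.seed + counter),
                planted=list(events),
                name=name,
            )
            orientation = "reverse" if k < n_reverse else "forward"
            if orientation == "reverse":
                chrom = _reverse_chromatogram(chrom)
            if dest is not None:
                write_ab1(chrom, str(dest / f"{name}.ab1"))
            manifest.append(ManifestRow(f"{name}.ab1", ref.ref_id, orientation, events))

    if dest is not None:
        with open(dest / "references.fasta", "w") as fh:
            for ref in refs:
                fh.write(f">{ref.ref_id}\n{ref.sequence}\n")
        with open(dest / "references.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "sequence"])
            for ref in refs:
                w.writerow([ref.ref_id, ref.sequence])
        with open(dest / "manifest.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["file", "ref_id", "orientation", "events"])
            for row in manifest:
                w.writerow([
                    row.file_name, row.ref_id, row.orientation,
                    json.dumps([e.__dict__ for e in row.events]),
                ])
    return manifest


def validation_dataset(
    seed: int = 1,
    dest: Optional[Path] = None,
    reads_per_ref: int = 4,
    with_events: bool = True,
) -> tuple[list, dict, dict, list[ManifestRow]]:
    """The canonical five-reference validation dataset.

    Five 120-nt references (ATG-led random sequences), four reads each,
    30% of reads reverse-complemented, generic file names (so assignment
    must go through alignment scores), and one planted event per
    reference covering each mutation class plus a mixed peak:

    * ref1 — silent substitution (GAA -> GAG, Glu unchanged)
    * ref2 — missense substitution (GCC -> GTC, Ala -> Val)
    * ref3 — nonsense substitution (TGG -> TAG, Trp -> stop)
    * ref4 — 1-base deletion (frameshift to the CDS end)
    * ref5 — mixed peak at read position 20, amplitude ratio 0.4

    Returns (references, mutation plan, expected truth, manifest); the
    truth maps each reference to its expected (1-based position, class)
    mutation calls, and ref5 to its planted mixed peak.  With
    ``with_events`` False the same references are rendered clean.
    """
    from .trace_io import ReferenceRecord

    rng = np.random.default_rng(seed)

    def random_ref(rid: str, forced: dict[int, str]) -> ReferenceRecord:
        s = list("ATG") + list(rng.choice(list(BASES), size=117))
        for pos, codon in forced.items():
            s[pos : pos + 3] = list(codon)
        seq = "".join(s)
        return ReferenceRecord(rid, seq, 0, len(seq), "table")

    refs = [
        random_ref("ref1", {3: "GAA"}),
        random_ref("ref2", {3: "GCC"}),
        random_ref("ref3", {6: "TGG"}),
        # distinct bases around position 30 pin the deletion gap placement
        random_ref("ref4", {29: "ACG"}),
        random_ref("ref5", {}),
    ]
    mixed_channel = "A" if refs[4].sequence[20] != "A" else "C"
    plan = {
        "ref1": [PlantedEvent(SUBSTITUTION, 5, "G", expected_class="silent")],
        "ref2": [PlantedEvent(SUBSTITUTION, 4, "T", expected_class="missense")],
        "ref3": [PlantedEvent(SUBSTITUTION, 7, "A", expected_class="nonsense")],
        "ref4": [PlantedEvent(DELETION, 30, expected_class="frameshift")],
        "ref5": [PlantedEvent(MIXED_PEAK, 20, mixed_channel, ratio=0.4)],
    }
    truth = {
        "ref1": [(6, "silent")],
        "ref2": [(5, "missense")],
        "ref3": [(8, "nonsense")],
        "ref4": [(31, "frameshift")],
        "ref5": [],
        "mixed_peak": {"ref_id": "ref5", "position": 20, "channel": mixed_channel},
    }
    manifest = synth_dataset(
        refs,
        reads_per_ref=reads_per_ref,
        mutation_plan=plan if with_events else {},
        reverse_fraction=0.3,
        params=SimParams(seed=seed),
        dest=dest,
        name_by_ref=False,
    )
    return refs, plan, truth, manifest


def _reverse_chromatogram(chrom: Chromatogram) -> Chromatogram:
    """Physically reverse a trace: as if the template was sequenced from
    the opposite end (signals flipped and complemented)."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    length = chrom.signal_length
    return Chromatogram(
        source_name=chrom.source_name,
        channel_order=chrom.channel_order,
        channels={b: chrom.channels[comp[b]][::-1].copy() for b in BASES},
        peak_positions=(length - 1 - chrom.peak_positions[::-1]).copy(),
        bases=reverse_complement(chrom.bases),
        qualities=chrom.qualities[::-1].copy(),
    )
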