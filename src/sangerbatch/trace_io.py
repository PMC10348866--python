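"""Reading and writing trace and reference files.

AB1 chromatograms use the ABIF container: a tagged directory of typed,
big-endian entries.  Only the analysed-data tags are handled here — the
four per-channel signals (``DATA9``–``DATA12``, ordered by the ``FWO_``
channel-order string), the called peak locations (``PLOC``), base calls
(``PBAS``) and Phred-style qualities (``PCON``).  The writer emits a
minimal but standards-conformant dialect of the same container so that
synthetic chromatograms round-trip exactly and remain readable by other
ABIF parsers (e.g. Biopython's ``abi`` reader).

References may arrive as FASTA, GenBank (the first CDS feature defines
the coding interval), or a two-column ``id,sequence`` table (CSV or the
first sheet of an XLSX workbook).
"""

from __future__ import annotations

import io
import logging
import struct
import zipfile
from dataclasses import dataclass, field
from typing import BinaryIO, Iterable, Optional, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    ArchiveError,
    EmptyInputError,
    ReferenceFormatError,
    TraceFormatError,
    TraceIntegrityError,
    TraceTagError,
)

logger = logging.getLogger(__name__)

BASES = "ACGT"
MAX_QUALITY = 93

# ABIF element type codes
_TYPE_BYTE = 1
_TYPE_CHAR = 2
_TYPE_SHORT = 4
_TYPE_DIR = 1023

_DIR_STRUCT = struct.Struct(">4sihhiiii")
_HEADER_STRUCT = struct.Struct(">4sH")


def normalize_base(b: str) -> str:
    """Map any non-ACGT letter to the ambiguity placeholder N."""
    b = b.upper()
    return b if b in BASES else "N"


@dataclass(eq=False)
class Chromatogram:
    """A processed Sanger trace.

    ``channels`` maps each nucleotide letter to its analysed signal
    array; all four arrays share one length (the signal axis).  The
    per-base arrays (``peak_positions``, ``bases``, ``qualities``) share
    a second length (the base axis) and ``peak_positions`` indexes into
    the signal axis, strictly increasing.
    """

    source_name: str
    channel_order: str
    channels: dict[str, np.ndarray]
    peak_positions: np.ndarray
    bases: str
    qualities: np.ndarray

    def __post_init__(self) -> None:
        if sorted(self.channel_order) != sorted(BASES):
            raise ValueError(f"channel_order must be a permutation of GATC, got {self.channel_order!r}")
        self.channels = {b: np.asarray(v, dtype=np.int64) for b, v in self.channels.items()}
        self.peak_positions = np.asarray(self.peak_positions, dtype=np.int64)
        self.qualities = np.asarray(self.qualities, dtype=np.int64)
        self.bases = "".join(normalize_base(b) for b in self.bases)
        self.validate()

    @property
    def n_bases(self) -> int:
        return len(self.bases)

    @property
    def signal_length(self) -> int:
        return len(next(iter(self.channels.values())))

    def validate(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if set(self.channels) != set(BASES) or len(lengths) != 1:
            raise TraceIntegrityError(f"{self.source_name}: need four equal-length channel arrays")
        if not (len(self.peak_positions) == len(self.bases) == len(self.qualities)):
            raise TraceIntegrityError(
                f"{self.source_name}: per-base arrays disagree "
                f"(PLOC {len(self.peak_positions)}, PBAS {len(self.bases)}, PCON {len(self.qualities)})"
            )
        if len(self.peak_positions) and (
            np.any(np.diff(self.peak_positions) <= 0)
            or self.peak_positions[0] < 0
            or self.peak_positions[-1] >= self.signal_length
        ):
            raise TraceIntegrityError(f"{self.source_name}: peak positions not strictly increasing in range")
        if np.any(self.qualities < 0) or np.any(self.qualities > MAX_QUALITY):
            raise ValueError(f"{self.source_name}: qualities outside [0, {MAX_QUALITY}]")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Chromatogram):
            return NotImplemented
        return (
            self.source_name == other.source_name
            and self.channel_order == other.channel_order
            and self.bases == other.bases
            and all(np.array_equal(self.channels[b], other.channels[b]) for b in BASES)
            and np.array_equal(self.peak_positions, other.peak_positions)
            and np.array_equal(self.qualities, other.qualities)
        )


@dataclass(frozen=True)
class ReferenceRecord:
    """A reference sequence with its coding interval (0-based half-open)."""

    ref_id: str
    sequence: str
    cds_start: int
    cds_end: int
    source_format: str

    def __post_init__(self) -> None:
        if not self.ref_id:
            raise ReferenceFormatError("reference id must be non-empty")
        if not self.sequence:
            raise ReferenceFormatError(f"reference {self.ref_id!r} has an empty sequence")
        if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
            raise ReferenceFormatError(
                f"reference {self.ref_id!r}: CDS interval [{self.cds_start}, {self.cds_end}) "
                f"outside sequence of length {len(self.sequence)}"
            )

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start : self.cds_end]


# ---------------------------------------------------------------------------
# ABIF reading
# ---------------------------------------------------------------------------


def _parse_directory(blob: bytes, name: str) -> dict[tuple[str, int], tuple[int, int, int, bytes]]:
    """Return {(tag, number): (elem_type, elem_size, n_elements, raw data)}."""
    if len(blob) < 34:
        raise TraceFormatError(f"{name}: truncated ABIF header")
    magic, _version = _HEADER_STRUCT.unpack_from(blob, 0)
    if magic != b"ABIF":
        raise TraceFormatError(f"{name}: not an ABIF file (bad magic {magic!r})")
    tname, tnum, ttype, tsize, tcount, tdsize, toffset, _ = _DIR_STRUCT.unpack_from(blob, 6)
    if tname != b"tdir":
        raise TraceFormatError(f"{name}: missing tdir root directory entry")
    entries: dict[tuple[str, int], tuple[int, int, int, bytes]] = {}
    for i in range(tcount):
        off = toffset + 28 * i
        if off + 28 > len(blob):
            raise TraceFormatError(f"{name}: directory extends past end of file")
        ename, enum, etype, esize, ecount, edsize, eoffset, _ = _DIR_STRUCT.unpack_from(blob, off)
        if edsize <= 4:
            # small payloads live inline in the offset field
            data = _DIR_STRUCT.pack(ename, enum, etype, esize, ecount, edsize, eoffset, 0)[20:24][:edsize]
        else:
            data = blob[eoffset : eoffset + edsize]
        entries[(ename.decode("ascii", "replace"), enum)] = (etype, esize, ecount, data)
    return entries


def _get_tag(entries: dict, tag: str, name: str, numbers: Iterable[int] = (2, 1)) -> tuple[int, int, int, bytes]:
    for num in numbers:
        if (tag, num) in entries:
            return entries[(tag, num)]
    raise TraceTagError(f"{name}: required ABIF tag {tag!r} missing")


def read_ab1(raw_bytes: bytes, name: str) -> Chromatogram:
    """Parse an AB1 blob into a :class:`Chromatogram`.

    Per-base tags are read from tag number 2 with a fallback to number 1
    (instruments and third-party writers disagree on which is present).
    """
    entries = _parse_directory(raw_bytes, name)

    fwo = _get_tag(entries, "FWO_", name, numbers=(1, 2))[3].decode("ascii")
    channels: dict[str, np.ndarray] = {}
    for i, base in enumerate(fwo):
        _, _, count, data = _get_tag(entries, f"DATA", name, numbers=(9 + i,))
        channels[normalize_base(base)] = np.frombuffer(data, dtype=">i2", count=count).astype(np.int64)

    _, _, _, pbas = _get_tag(entries, "PBAS", name)
    bases = pbas.decode("ascii")
    _, _, ploc_n, ploc = _get_tag(entries, "PLOC", name)
    peak_positions = np.frombuffer(ploc, dtype=">i2", count=ploc_n).astype(np.int64)
    _, _, _, pcon = _get_tag(entries, "PCON", name)
    qualities = np.frombuffer(pcon, dtype=np.uint8).astype(np.int64)

    if not (len(bases) == len(peak_positions) == len(qualities)):
        raise TraceIntegrityError(
            f"{name}: PBAS/PLOC/PCON length mismatch "
            f"({len(bases)}/{len(peak_positions)}/{len(qualities)})"
        )
    return Chromatogram(
        source_name=name,
        channel_order=fwo,
        channels=channels,
        peak_positions=peak_positions,
        bases=bases,
        qualities=qualities,
    )


# ---------------------------------------------------------------------------
# ABIF writing
# ---------------------------------------------------------------------------


def write_ab1(chrom: Chromatogram, dest: Union[str, BinaryIO]) -> None:
    """Serialise a chromatogram as a minimal ABIF file.

    Per-base tags are written under both number 1 and number 2 because
    downstream parsers read either inconsistently; signals go to
    ``DATA9``–``DATA12`` in ``FWO_`` channel order.
    """
    chrom.validate()

    def i2(arr: np.ndarray) -> bytes:
        return np.asarray(arr, dtype=">i2").tobytes()

    records: list[tuple[bytes, int, int, int, int, bytes]] = []
    for i, base in enumerate(chrom.channel_order):
        sig = chrom.channels[normalize_base(base)]
        records.append((b"DATA", 9 + i, _TYPE_SHORT, 2, len(sig), i2(sig)))
    records.append((b"FWO_", 1, _TYPE_CHAR, 1, 4, chrom.channel_order.encode("ascii")))
    for number in (1, 2):
        records.append((b"PLOC", number, _TYPE_SHORT, 2, chrom.n_bases, i2(chrom.peak_positions)))
        records.append((b"PBAS", number, _TYPE_CHAR, 1, chrom.n_bases, chrom.bases.encode("ascii")))
        # char-typed like instrument files, so third-party ABIF readers decode it
        records.append((b"PCON", number, _TYPE_CHAR, 1, chrom.n_bases, np.asarray(chrom.qualities, dtype=np.uint8).tobytes()))

    header_len = 128  # standard ABIF header block
    body = io.BytesIO()
    placed: list[tuple[bytes, int, int, int, int, int, int]] = []  # entry fields + offset
    for tag, number, etype, esize, count, data in records:
        dsize = len(data)
        if dsize <= 4:
            inline = int.from_bytes((data + b"\x00" * 4)[:4], "big")
            placed.append((tag, number, etype, esize, count, dsize, inline))
        else:
            offset = header_len + body.tell()
            body.write(data)
            placed.append((tag, number, etype, esize, count, dsize, offset))

    dir_offset = header_len + body.tell()
    directory = b"".join(
        _DIR_STRUCT.pack(tag, number, etype, esize, count, dsize, off if off < (1 << 31) else off - (1 << 32), 0)
        for tag, number, etype, esize, count, dsize, off in placed
    )

    header = _HEADER_STRUCT.pack(b"ABIF", 101)
    header += _DIR_STRUCT.pack(b"tdir", 1, _TYPE_DIR, 28, len(placed), 28 * len(placed), dir_offset, 0)
    header = header.ljust(header_len, b"\x00")

    payload = header + body.getvalue() + directory
    if isinstance(dest, (str, bytes)):
        with open(dest, "wb") as fh:
            fh.write(payload)
    else:
        dest.write(payload)


# ---------------------------------------------------------------------------
# References
# ---------------------------------------------------------------------------


def _check_unique(records: list[ReferenceRecord]) -> list[ReferenceRecord]:
    seen: set[str] = set()
    for r in records:
        if r.ref_id in seen:
            raise ReferenceFormatError(f"duplicate reference id {r.ref_id!r}")
        seen.add(r.ref_id)
    if not records:
        raise ReferenceFormatError("reference file contains no sequences")
    return records


def _clean_seq(seq: str, ref_id: str) -> str:
    seq = "".join(seq.split()).upper()
    if not seq:
        raise ReferenceFormatError(f"reference {ref_id!r} has an empty sequence")
    return seq


def _refs_from_fasta(text: str) -> list[ReferenceRecord]:
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = _clean_seq(str(rec.seq), rec.id)
        records.append(ReferenceRecord(rec.id, seq, 0, len(seq), "fasta"))
    return _check_unique(records)


def _refs_from_genbank(text: str) -> list[ReferenceRecord]:
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "genbank"):
        seq = _clean_seq(str(rec.seq), rec.id)
        cds_feats = [f for f in rec.features if f.type == "CDS"]
        if not cds_feats:
            logger.warning("GenBank record %s has no CDS feature; using the full sequence", rec.id)
            start, end = 0, len(seq)
        else:
            if len(cds_feats) > 1:
                logger.warning("GenBank record %s has %d CDS features; using the first", rec.id, len(cds_feats))
            feat = cds_feats[0]
            if len(feat.location.parts) > 1:
                raise ReferenceFormatError(
                    f"GenBank record {rec.id!r}: spliced (joined) CDS features are not supported"
                )
            start, end = int(feat.location.start), int(feat.location.end)
        records.append(ReferenceRecord(rec.id, seq, start, end, "genbank"))
    return _check_unique(records)


def _refs_from_frame(df: pd.DataFrame) -> list[ReferenceRecord]:
    cols = {c.strip().lower(): c for c in df.columns}
    if "id" not in cols or "sequence" not in cols:
        raise ReferenceFormatError(f"reference table needs columns 'id' and 'sequence', got {list(df.columns)}")
    records = []
    for _, row in df.fillna("").iterrows():
        ref_id = str(row[cols["id"]]).strip()
        seq = _clean_seq(str(row[cols["sequence"]]), ref_id)
        records.append(ReferenceRecord(ref_id, seq, 0, len(seq), "table"))
    return _check_unique(records)


def _detect_format(raw: bytes) -> str:
    head = raw.lstrip()[:64]
    if raw[:4] == b"PK\x03\x04":
        return "xlsx"
    if head.startswith(b">"):
        return "fasta"
    if head.upper().startswith(b"LOCUS"):
        return "genbank"
    return "csv"


def read_references(raw: Union[str, bytes], format_hint: Optional[str] = None) -> list[ReferenceRecord]:
    """Parse a reference file in FASTA, GenBank, CSV or XLSX form.

    For FASTA and tabular input the whole sequence is treated as coding:
    translation later starts at the first codon and any trailing partial
    codon is dropped at translation time, not here.
    """
    data = raw.encode() if isinstance(raw, str) else raw
    if not data.strip():
        raise ReferenceFormatError("reference file is empty")
    fmt = format_hint or _detect_format(data)
    try:
        if fmt == "fasta":
            return _refs_from_fasta(data.decode())
        if fmt in ("genbank", "gb"):
            return _refs_from_genbank(data.decode())
        if fmt == "xlsx":
            return _refs_from_frame(pd.read_excel(io.BytesIO(data), sheet_name=0, dtype=str))
        if fmt in ("csv", "table"):
            return _refs_from_frame(pd.read_csv(io.BytesIO(data), dtype=str))
    except ReferenceFormatError:
        raise
    except Exception as exc:
        raise ReferenceFormatError(f"could not parse reference file as {fmt}: {exc}") from exc
    raise ReferenceFormatError(f"unknown reference format {fmt!r}")


# ---------------------------------------------------------------------------
# Archives
# ---------------------------------------------------------------------------


def read_trace_archive(zip_bytes: bytes) -> list[Chromatogram]:
    """Extract every ``.ab1`` member of a zip archive, in archive order."""
    try:
        zf = zipfile.ZipFile(io.BytesIO(zip_bytes))
        names = zf.namelist()
    except zipfile.BadZipFile as exc:
        raise ArchiveError(f"corrupt zip archive: {exc}") from exc
    chroms = []
    for member in names:
        if member.endswith("/"):
            continue
        stem = member.rsplit("/", 1)[-1]
        if not stem.lower().endswith(".ab1"):
            logger.warning("skipping non-AB1 archive member %r", member)
            continue
        chroms.append(read_ab1(zf.read(member), stem[: -len(".ab1")]))
    if not chroms:
        raise EmptyInputError("archive contains no .ab1 files")
    return chroms
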