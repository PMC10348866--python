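"""Quality filtering, end trimming and orientation handling of trace reads.

Both filters are opt-in.  End trimming removes low-quality read flanks:
each end is trimmed until a run of three consecutive bases with quality
strictly above the threshold is found, so isolated good bases inside a
bad flank do not stop the trim.  The quality mask then discards any
position whose quality is strictly below the mask threshold.  Ambiguous
base calls (N) are always masked out.

Trimmed and masked positions are retained in memory with ``kept=False``
rather than deleted, so positions still map 1:1 onto chromatogram peaks
for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

MIN_GOOD_RUN = 3  # consecutive above-threshold bases that stop end trimming

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FORWARD = "forward"
REVERSE = "reverse"


@dataclass(frozen=True)
class TraceRead:
    """A called read with its surviving-position mask.

    ``kept`` is False outside the retained interval
    [``trim_start``, ``trim_end``) and at every N call.
    """

    source_name: str
    bases: str
    qualities: np.ndarray
    orientation: str = FORWARD
    kept: np.ndarray = None  # type: ignore[assignment]
    trim_start: int = 0
    trim_end: int = -1

    def __post_init__(self) -> None:
        object.__setattr__(self, "qualities", np.asarray(self.qualities, dtype=np.int64))
        if self.trim_end < 0:
            object.__setattr__(self, "trim_end", len(self.bases))
        if self.kept is None:
            object.__setattr__(self, "kept", np.ones(len(self.bases), dtype=bool))
        kept = np.asarray(self.kept, dtype=bool).copy()
        idx = np.arange(len(self.bases))
        kept &= (idx >= self.trim_start) & (idx < self.trim_end)
        kept &= np.frombuffer(self.bases.encode("ascii"), dtype=np.uint8) != ord("N")
        object.__setattr__(self, "kept", kept)
        if not (len(self.bases) == len(self.qualities) == len(kept)):
            raise ValueError(f"{self.source_name}: bases/qualities/kept length mismatch")

    @property
    def retained_sequence(self) -> str:
        """Bases inside the trim interval (masked interior positions keep
        their letter; they are excluded later at consensus level)."""
        return self.bases[self.trim_start : self.trim_end]

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TraceRead):
            return NotImplemented
        return (
            self.source_name == other.source_name
            and self.bases == other.bases
            and self.orientation == other.orientation
            and (self.trim_start, self.trim_end) == (other.trim_start, other.trim_end)
            and np.array_equal(self.qualities, other.qualities)
            and np.array_equal(self.kept, other.kept)
        )


def read_from_chromatogram(chrom) -> TraceRead:
    """Lift a chromatogram's base calls into a TraceRead."""
    return TraceRead(source_name=chrom.source_name, bases=chrom.bases, qualities=chrom.qualities.copy())


def _good_runs(qualities: np.ndarray, threshold: int) -> list[tuple[int, int]]:
    """Half-open intervals of >= MIN_GOOD_RUN consecutive quals > threshold."""
    good = qualities > threshold
    runs = []
    start = None
    for i, g in enumerate(list(good) + [False]):
        if g and start is None:
            start = i
        elif not g and start is not None:
            if i - start >= MIN_GOOD_RUN:
                runs.append((start, i))
            start = None
    return runs


def trim_ends(read: TraceRead, trim_threshold: int) -> TraceRead:
    """Trim both read ends up to the outermost runs of three consecutive
    above-threshold bases; a read without any such run is fully trimmed."""
    if trim_threshold < 0:
        raise ValueError("trim threshold must be >= 0")
    runs = _good_runs(read.qualities, trim_threshold)
    if not runs:
        start, end = 0, 0
    else:
        start, end = runs[0][0], runs[-1][1]
    new_start = max(read.trim_start, start)
    new_end = min(read.trim_end, end)
    if new_start >= new_end:
        new_start = new_end = 0
    return replace(read, trim_start=new_start, trim_end=new_end, kept=read.kept)


def apply_quality_mask(read: TraceRead, quality_threshold: int) -> TraceRead:
    """Mask out every position with quality strictly below the threshold;
    a base exactly at the threshold passes."""
    kept = read.kept & (read.qualities >= quality_threshold)
    return replace(read, kept=kept)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def reverse_complement_read(read: TraceRead) -> TraceRead:
    """Reverse-complement a read, flipping mask, trim bounds and the
    orientation flag consistently; applying twice is the identity."""
    n = len(read.bases)
    return TraceRead(
        source_name=read.source_name,
        bases=reverse_complement(read.bases),
        qualities=read.qualities[::-1].copy(),
        orientation=REVERSE if read.orientation == FORWARD else FORWARD,
        kept=read.kept[::-1].copy(),
        trim_start=n - read.trim_end,
        trim_end=n - read.trim_start,
    )
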