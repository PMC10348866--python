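"""Mixed (secondary) peak detection in chromatograms.

A position is reported as a mixed peak when a channel other than the
called base shows a genuine peak under the main one: its area and its
height must each be at least a factor ``f`` (default 0.15) of the main
peak's, the candidate trace must be concave at the main-peak centre, and
the candidate peak must clear a per-channel noise gate derived from the
trace itself.  The gate is ``k`` times the median signal of that channel
at peak centres where it is not the called base — i.e. its typical
off-peak background — so low-complexity, noisy regions are ignored.

Peak areas are integrated over the window bounded by the midpoints to
the neighbouring called peaks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .trace_io import BASES, Chromatogram

logger = logging.getLogger(__name__)

DEFAULT_PEAK_FACTOR = 0.15
DEFAULT_NOISE_K = 2.0


@dataclass(frozen=True)
class PeakWindow:
    """Half-open signal interval [lo, hi) around a called peak centre."""

    centre: int
    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not (self.lo <= self.centre < self.hi):
            raise ValueError(f"invalid peak window [{self.lo}, {self.hi}) around {self.centre}")


@dataclass(frozen=True)
class MixedPeak:
    """A secondary peak call at one base position."""

    base_index: int
    primary_base: str
    secondary_base: str
    area_ratio: float
    height_ratio: float
    passes_noise_gate: bool = True

    def __post_init__(self) -> None:
        if self.primary_base == self.secondary_base:
            raise ValueError("secondary channel equals the called base")


def peak_window(chrom: Chromatogram, base_index: int) -> PeakWindow:
    """Integration bounds for the peak at ``base_index``: midpoints to the
    neighbouring peaks, rounded toward the centre; trace ends for the
    outermost peaks."""
    n = chrom.n_bases
    if not 0 <= base_index < n:
        raise IndexError(f"base index {base_index} out of range [0, {n})")
    centre = int(chrom.peak_positions[base_index])
    if base_index == 0:
        lo = 0
    else:
        prev = int(chrom.peak_positions[base_index - 1])
        lo = min(centre, math.ceil((prev + centre) / 2))
    if base_index == n - 1:
        hi = chrom.signal_length
    else:
        nxt = int(chrom.peak_positions[base_index + 1])
        hi = max(centre + 1, math.floor((centre + nxt) / 2))
    return PeakWindow(centre=centre, lo=lo, hi=hi)


def _concave_at(signal: np.ndarray, centre: int) -> bool:
    """Non-positive discrete second derivative at the main-peak centre.

    Measured on a 3-sample moving average with a stencil of spacing 2:
    the raw 3-sample stencil has noise ~sigma*sqrt(6), comparable to the
    curvature of a genuine secondary peak, and would reject real mixed
    peaks at typical baseline noise levels.
    """
    n = len(signal)
    if n < 3:
        return False

    def smooth(i: int) -> float:
        i = min(max(i, 1), n - 2)
        return float(signal[i - 1] + signal[i] + signal[i + 1]) / 3.0

    c = min(max(centre, 2), n - 3)
    return smooth(c - 2) - 2 * smooth(c) + smooth(c + 2) <= 0


def secondary_peak_metrics(
    chrom: Chromatogram, base_index: int, channel: str
) -> tuple[float, float, bool]:
    """Area ratio, height ratio and concavity of ``channel`` relative to
    the called base's peak at ``base_index``.

    Degenerate main peaks (zero area or height) yield ``(0, 0, False)``.
    """
    called = chrom.bases[base_index]
    if channel == called:
        raise ValueError(f"channel {channel} is the called base at position {base_index}")
    win = peak_window(chrom, base_index)
    main = chrom.channels[called] if called in BASES else None
    if main is None:
        return 0.0, 0.0, False
    cand = chrom.channels[channel]
    main_area = float(main[win.lo : win.hi].sum())
    main_height = float(main[win.centre])
    if main_area <= 0 or main_height <= 0:
        logger.warning(
            "%s: degenerate main peak at base %d (area %.1f, height %.1f)",
            chrom.source_name, base_index, main_area, main_height,
        )
        return 0.0, 0.0, False
    cand_area = float(cand[win.lo : win.hi].sum())
    cand_height = float(cand[win.lo : win.hi].max())
    if cand_height <= 0:
        return 0.0, 0.0, False
    concave = bool(_concave_at(cand, win.centre))
    return cand_area / main_area, cand_height / main_height, concave


def noise_threshold(chrom: Chromatogram, k: float = DEFAULT_NOISE_K) -> dict[str, float]:
    """Per-channel noise gate: ``k`` times the median of the channel's
    signal at called peak centres where that channel is not the called base."""
    if chrom.n_bases == 0:
        raise ValueError(f"{chrom.source_name}: no called bases, cannot derive noise threshold")
    thresholds: dict[str, float] = {}
    for base in BASES:
        off = [
            float(chrom.channels[base][pos])
            for pos, called in zip(chrom.peak_positions, chrom.bases)
            if called != base
        ]
        thresholds[base] = k * float(np.median(off)) if off else 0.0
    return thresholds


def candidate_peak_height(chrom: Chromatogram, base_index: int, channel: str) -> float:
    win = peak_window(chrom, base_index)
    return float(chrom.channels[channel][win.lo : win.hi].max())


def detect_mixed_peaks(
    chrom: Chromatogram,
    f: float = DEFAULT_PEAK_FACTOR,
    noise_k: float = DEFAULT_NOISE_K,
) -> list[MixedPeak]:
    """All mixed-peak calls in a trace at factor ``f``.

    At most one call per base position; ties between candidate channels
    go to the larger area ratio, then alphabetically.
    """
    if not 0.0 < f < 1.0:
        raise ValueError(f"peak factor must lie strictly between 0 and 1, got {f}")
    if chrom.n_bases == 0:
        return []
    gates = noise_threshold(chrom, k=noise_k)
    calls: list[MixedPeak] = []
    for i, called in enumerate(chrom.bases):
        if called not in BASES:
            continue
        best: MixedPeak | None = None
        for channel in BASES:
            if channel == called:
                continue
            area, height, concave = secondary_peak_metrics(chrom, i, channel)
            if not (area >= f and height >= f and concave):
                continue
            if not candidate_peak_height(chrom, i, channel) > gates[channel]:
                continue
            peak = MixedPeak(
                base_index=i,
                primary_base=called,
                secondary_base=channel,
                area_ratio=min(area, 1.0),
                height_ratio=min(height, 1.0),
            )
            if best is None or peak.area_ratio > best.area_ratio:
                best = peak
        if best is not None:
            calls.append(best)
    return calls
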