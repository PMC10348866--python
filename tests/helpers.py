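"""Independent oracles used to cross-check the implementation.

Deliberately naive: brute-force scans and quadratic DP, kept separate
from the library code paths they validate.
"""

from __future__ import annotations

import numpy as np


def trim_interval_oracle(qualities: list[int], threshold: int, min_run: int = 3) -> tuple[int, int]:
    """Scan all positions for runs of >=min_run above-threshold bases."""
    n = len(qualities)
    window_starts = [
        s for s in range(n - min_run + 1)
        if all(qualities[s + j] > threshold for j in range(min_run))
    ]
    if not window_starts:
        return (0, 0)
    return (window_starts[0], window_starts[-1] + min_run)


def gotoh_score(a: str, b: str, match: float = 2, mismatch: float = -1,
                gap_open: float = -5, gap_extend: float = -1) -> float:
    """Quadratic-space affine-gap global alignment score (Gotoh).

    Gap of length k costs gap_open + (k - 1) * gap_extend, matching the
    Biopython PairwiseAligner convention.
    """
    n, m = len(a), len(b)
    neg = -1e18
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (deletion from a)
    Y = np.full((n + 1, m + 1), neg)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend, Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend, X[i, j - 1] + gap_open)
    return float(max(M[n, m], X[n, m], Y[n, m]))


def consensus_column_oracle(ref_base: str, symbols: list[str]) -> tuple[str, str]:
    """Literal reading of the agreement rules for one column.

    ``symbols``: one char per read out of A/C/G/T/N/'-'/'.'.
    Returns (consensus_base, status_name).
    """
    reads = [s for s in symbols if s not in ("N", ".")]
    bases = [s for s in reads if s != "-"]
    if ref_base == "-":
        # insertion column
        if not bases:
            return "-", "match"
        if len(bases) == len(reads) and all(b == bases[0] for b in bases):
            # all reads agree on the inserted base
            return bases[0], "insertion"
        # only some reads insert, or they disagree
        return "?", "ambiguous_insertion"
    if not reads:
        return ref_base, "uncovered"
    if all(s == reads[0] for s in reads):
        if reads[0] == "-":
            return "-", "deletion"
        if reads[0] == ref_base:
            return ref_base, "match"
        return reads[0], "point_mutation"
    return ref_base, "disagreement_kept_ref"


def translate_oracle(seq: str) -> str:
    """Dict-free translation via Biopython Seq, codon by codon."""
    from Bio.Seq import Seq

    out = []
    seq = seq.replace("?", "").replace("-", "")
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            out.append("X")
        else:
            out.append(str(Seq(codon).translate()))
    return "".join(out)
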