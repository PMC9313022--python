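"""Intra-sequence direct-repeat (duplication) detection.

Finds pairs of equal-length, non-overlapping intervals within one sequence
whose substrings match up to a Hamming mismatch budget — the signature of an
intra-exon duplication such as the 33-nt block duplicated in expanded
Olduvai first exons.  Only direct repeats are considered (no inverted
repeats, no gaps): the target event is a tandem-like duplication whose
copies are near-identical, so mismatch-tolerant Hamming extension suffices.

Definition of a reported pair at offset ``d = b_start - a_start``:

* the two intervals have equal length ``L`` with ``min_len <= L <= d``
  (``L <= d`` keeps the copies non-overlapping; tandem repeats abut);
* the copies differ at ``<= max_mismatch`` positions;
* the pair is maximal — extending both intervals one base left or right
  would exceed the mismatch budget, run out of sequence, or make the
  intervals overlap;
* pairs fully contained in a longer reported pair at the same offset are
  suppressed (different offsets are independent repeat structures).

The scan is exhaustive over offsets, deterministic, and sorted by
(length desc, a_start asc, b_start asc).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .g4scan import purine_fraction

__all__ = ["DuplicationPair", "SeparatorReport", "find_intraexon_duplications",
           "annotate_separator"]

_NORM = str.maketrans("acgtuU", "ACGTTT")


@dataclass
class DuplicationPair:
    """Two matched same-length intervals (0-based half-open) in one sequence."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    length: int
    mismatches: int

    @property
    def interval_a(self) -> tuple[int, int]:
        return (self.a_start, self.a_end)

    @property
    def interval_b(self) -> tuple[int, int]:
        return (self.b_start, self.b_end)

    @property
    def separator(self) -> tuple[int, int]:
        """The interval strictly between the copies (possibly empty)."""
        return (self.a_end, self.b_start)

    @property
    def offset(self) -> int:
        return self.b_start - self.a_start


@dataclass
class SeparatorReport:
    start: int
    end: int
    length: int
    purine_fraction: float | None


def find_intraexon_duplications(
    seq: str, min_len: int = 20, max_mismatch: int = 2
) -> list[DuplicationPair]:
    """All maximal duplication pairs in *seq* (see module docstring).

    ``min_len`` defaults to 20 so a 33-nt duplication is found while random
    ~100-nt sequences rarely produce hits; ``max_mismatch`` defaults to 2
    for near-identical copies.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    s = seq.translate(_NORM)
    n = len(s)
    if n < 2 * min_len:
        raise ValueError(f"sequence length {n} < 2*min_len = {2 * min_len}")
    arr = np.frombuffer(s.encode(), dtype="S1")
    pairs: list[DuplicationPair] = []
    for d in range(min_len, n - min_len + 1):
        mism = (arr[: n - d] != arr[d:]).astype(int)
        m = mism.size  # comparison positions 0 .. m-1
        csum = np.concatenate(([0], np.cumsum(mism)))
        # two-pointer: for each start s0, furthest budget-feasible end
        prev_end = -1
        e = 0
        for s0 in range(m):
            if e < s0:
                e = s0
            while e < m and csum[e + 1] - csum[s0] <= max_mismatch:
                e += 1
            end = min(e, s0 + d)  # cap at d: keeps copies non-overlapping
            # containment/maximality: keep only starts whose interval is not
            # inside the previous one (end is nondecreasing in s0)
            if end - s0 >= min_len and end > prev_end:
                pairs.append(
                    DuplicationPair(
                        a_start=s0,
                        a_end=end,
                        b_start=s0 + d,
                        b_end=end + d,
                        length=end - s0,
                        mismatches=int(csum[end] - csum[s0]),
                    )
                )
            if end - s0 >= min_len:
                prev_end = max(prev_end, end)
    pairs.sort(key=lambda p: (-p.length, p.a_start, p.b_start))
    return pairs


def annotate_separator(pair: DuplicationPair, seq: str) -> SeparatorReport:
    """Report the interval between the two copies and its purine content.

    An empty separator (tandem pair) has length 0 and a missing purine
    fraction (None).
    """
    a, b = pair.separator
    if b < a or b > len(seq):
        raise ValueError("pair is not valid for this sequence")
    if b == a:
        return SeparatorReport(a, b, 0, None)
    return SeparatorReport(a, b, b - a, purine_fraction(seq, (a, b)))
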