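"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result from first principles, by direct
enumeration or numerical integration, sharing no code path with the
implementation it checks.
"""

from __future__ import annotations

import math

from scipy import integrate


def brute_force_profile(seq: str, table):
    """Per-position overlap-average scores by direct enumeration.

    For every in-bounds hexamer start j, add its score to positions
    j..j+5; divide by per-position contributor counts.  Positions with no
    scorable contributor are None.
    """
    from splicescan.hexamers import UnscorableHexamerError

    n = len(seq)
    totals = [0.0] * n
    counts = [0] * n
    for j in range(n - 5):
        try:
            s = table.score_of(seq[j : j + 6])
        except UnscorableHexamerError:
            continue
        for i in range(j, j + 6):
            totals[i] += s
            counts[i] += 1
    return [totals[i] / counts[i] if counts[i] else None for i in range(n)]


def brute_force_duplications(seq: str, min_len: int, max_mismatch: int):
    """All maximal same-offset duplication pairs by exhaustive enumeration.

    Enumerates every (a_start, offset, length) triple with early exit on
    the mismatch budget, keeps triples with no legal one-base extension
    (legal = in bounds, length+1 <= offset so the copies stay
    non-overlapping, and within the mismatch budget), then drops pairs
    fully contained in a longer kept pair at the same offset.  Returns a
    set of (a_start, a_end, b_start, b_end, mismatches) tuples.
    """
    s = seq.upper().replace("U", "T")
    n = len(s)

    def mism(a: int, b: int, length: int) -> int:
        return sum(1 for i in range(length) if s[a + i] != s[b + i])

    kept: list[tuple[int, int, int, int]] = []  # (a, d, L, k)
    for d in range(min_len, n - min_len + 1):
        for a in range(n - d - min_len + 1):
            b = a + d
            k = mism(a, b, min_len)
            if k <= max_mismatch:
                length, kk = min_len, k
                max_len = min(d, n - b)
                while length < max_len:
                    nxt = kk + (s[a + length] != s[b + length])
                    if nxt > max_mismatch:
                        break
                    length, kk = length + 1, nxt
            else:
                continue
            # maximality: no legal extension either way
            left_ok = (
                a >= 1
                and length + 1 <= d
                and mism(a - 1, b - 1, length + 1) <= max_mismatch
            )
            right_ok = (
                b + length + 1 <= n
                and length + 1 <= d
                and mism(a, b, length + 1) <= max_mismatch
            )
            if not left_ok and not right_ok:
                kept.append((a, d, length, kk))
    reported = []
    for a, d, length, k in kept:
        contained = any(
            d2 == d and a2 <= a and a2 + l2 >= a + length and l2 > length
            for a2, d2, l2, _ in kept
        )
        if not contained:
            reported.append((a, a + length, a + d, a + d + length, k))
    return set(reported)


def t_p_two_sided_numeric(t: float, df: float) -> float:
    """Two-sided p by numerical integration of the t density."""
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))

    def pdf(x: float) -> float:
        return c * (1 + x * x / df) ** (-(df + 1) / 2)

    tail, _ = integrate.quad(pdf, abs(t), math.inf)
    return 2 * tail
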