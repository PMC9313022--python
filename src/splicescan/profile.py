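"""Per-nucleotide splicing-activity profiles.

Each position of a sequence receives the arithmetic mean of the ESE/ESSseq
scores of every scorable hexamer overlapping it (up to six).  Positions at
the sequence edges are covered by fewer hexamers; only in-bounds hexamers
contribute (no padding).  Positions covered by no scorable hexamer carry NaN
plus coverage 0 — never a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hexamers import HexamerScoreTable, UnscorableHexamerError

__all__ = ["NucleotideProfile", "Peak", "per_nucleotide_profile", "region_mean",
           "find_peaks"]


@dataclass
class NucleotideProfile:
    """A sequence with one score and one coverage count per position.

    ``scores[i]`` is the mean score of the scorable hexamers covering
    position ``i`` (NaN where coverage is 0); ``coverage[i]`` counts those
    hexamers (0–6).  ``offset`` shifts reported coordinates: a profile built
    with 20 nt of 5' intronic flank has ``offset = -20`` so position 0 is
    the first exonic base in reports.
    """

    sequence: str
    scores: np.ndarray
    coverage: np.ndarray
    seq_id: str = ""
    offset: int = 0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=int)
        n = len(self.sequence)
        if len(self.scores) != n or len(self.coverage) != n:
            raise ValueError("scores, coverage and sequence lengths differ")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Peak:
    """A local maximum of the smoothed profile above a baseline.

    ``left``/``right`` bound (half-open) the maximal run of positions whose
    smoothed score exceeds the baseline; ``position`` is the run's maximum
    (ties broken by the centre of the tied stretch).
    """

    position: int
    value: float
    left: int
    right: int


def per_nucleotide_profile(
    seq: str,
    table: HexamerScoreTable,
    seq_id: str = "",
    offset: int = 0,
) -> NucleotideProfile:
    """Paint per-position mean hexamer scores onto *seq*.

    Every in-bounds hexamer start ``j`` contributes ``score(seq[j:j+6])`` to
    positions ``j..j+5``; each position's score is the mean over its
    contributors.  Hexamers containing ambiguity codes are skipped (they
    reduce coverage).  Case and U/T differences in *seq* do not affect the
    result.
    """
    n = len(seq)
    if n < 6:
        raise ValueError(f"sequence length {n} < 6: no hexamer fits")
    totals = np.zeros(n)
    cover = np.zeros(n, dtype=int)
    for j in range(n - 5):
        try:
            s = table.score_of(seq[j : j + 6])
        except UnscorableHexamerError:
            continue
        totals[j : j + 6] += s
        cover[j : j + 6] += 1
    with np.errstate(invalid="ignore"):
        scores = np.where(cover > 0, totals / np.maximum(cover, 1), np.nan)
    return NucleotideProfile(seq, scores, cover, seq_id=seq_id, offset=offset)


def region_mean(profile: NucleotideProfile, interval: tuple[int, int]) -> tuple[float, int]:
    """Mean score over a 0-based half-open interval, with the count used.

    Missing positions (coverage 0) are excluded; an empty or all-missing
    interval is a hard error.  Returns ``(mean, n_contributing)``.
    """
    a, b = interval
    n = len(profile)
    if not (0 <= a < b <= n):
        raise ValueError(f"interval [{a}, {b}) invalid for length-{n} profile")
    vals = profile.scores[a:b]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError(f"interval [{a}, {b}) has no covered positions")
    return float(vals.mean()), int(vals.size)


def _moving_average(scores: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average using only in-bounds, non-missing values."""
    n = scores.size
    half = window // 2
    out = np.full(n, np.nan)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        vals = scores[lo:hi]
        vals = vals[~np.isnan(vals)]
        if vals.size:
            out[i] = vals.mean()
    return out


def find_peaks(
    profile: NucleotideProfile,
    baseline: float,
    smooth_window: int = 7,
) -> list[Peak]:
    """Call peaks of the (optionally smoothed) profile above *baseline*.

    The profile is smoothed by a centred moving average of odd width
    ``smooth_window`` (1 = no smoothing).  Peaks are the maxima of maximal
    runs where the smoothed value strictly exceeds the baseline, one per
    run; a tie on the maximum is resolved to the centre of the tied stretch
    so a rectangular bump peaks at its middle.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be an odd integer >= 1")
    if smooth_window > len(profile):
        raise ValueError("smooth_window exceeds profile length")
    smoothed = (
        profile.scores if smooth_window == 1 else _moving_average(profile.scores, smooth_window)
    )
    above = np.zeros(len(profile), dtype=bool)
    valid = ~np.isnan(smoothed)
    above[valid] = smoothed[valid] > baseline
    peaks: list[Peak] = []
    i, n = 0, len(profile)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        run = smoothed[i:j]
        peak_val = np.nanmax(run)
        tied = np.flatnonzero(run == peak_val)
        pos = i + int(tied[(len(tied) - 1) // 2])
        peaks.append(Peak(position=pos, value=float(peak_val), left=i, right=j))
        i = j
    return peaks
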