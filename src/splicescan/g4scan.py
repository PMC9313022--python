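"""G-quadruplex propensity scanning.

Three sequence-based predictors of RNA/DNA G-quadruplex (G4) formation:

* **G4Hunter (G4H)** — mean per-base score where each base in a maximal run
  of ``k`` guanines contributes ``+min(k, 4)``, each base in a run of ``k``
  cytosines ``-min(k, 4)``, and everything else 0.  Scores the G-richness
  *and* C-poorness of a window; the working threshold is > 0.9.
* **cGcC** — ratio of run-length-weighted consecutive-G content over
  consecutive-C content (pseudocount 1 when no C is present); threshold
  > 4.5.  The run weights live in ``data/cgcc_weights.json``.
* **canonical motif** — the stringent four-tetrad pattern
  G≥3 N1–7 G≥3 N1–7 G≥3 N1–7 G≥3, matched leftmost-shortest without
  overlap.

``scan`` tiles a sequence with fixed-length windows (default 60 nt, step
10 nt) and applies both scorers plus the motif search; purine-rich segments
with G-runs capped at two can exceed both score thresholds while never
matching the canonical pattern — the situation the pG4 insertion of
expanded Olduvai first exons exemplifies.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "G4ScanConfig",
    "G4WindowRecord",
    "G4ScanResult",
    "g4hunter_score",
    "cgcc_score",
    "canonical_g4_scan",
    "scan",
    "purine_fraction",
    "reverse_complement",
    "window_starts",
]

_NORM = str.maketrans("acgtunU", "ACGTTNN")
_VALID = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: G4NN (neural-network) threshold from the same screening tool, recorded
#: for documentation only; the trained model is not re-implemented here.
G4NN_THRESHOLD_DOC = 0.5

_CANONICAL_RE = re.compile(
    "G{3,}?" + "[ACGTN]{1,7}?G{3,}?" * 3
)


def _normalize(seq: str) -> str:
    s = seq.translate(_NORM)
    bad = set(s) - _VALID
    if bad:
        raise ValueError(f"invalid nucleotide symbols {sorted(bad)!r}")
    return s


def reverse_complement(seq: str) -> str:
    return _normalize(seq).translate(_COMPLEMENT)[::-1]


def _runs(seq: str, base: str):
    """Yield (start, length) of maximal runs of *base* in *seq*."""
    for m in re.finditer(f"{base}+", seq):
        yield m.start(), m.end() - m.start()


def g4hunter_score(seq: str) -> float:
    """Mean per-base G4Hunter value of *seq*.

    N breaks runs and scores 0.  Antisymmetric under reverse complement.
    """
    s = _normalize(seq)
    if not s:
        raise ValueError("empty sequence")
    vals = np.zeros(len(s))
    for start, k in _runs(s, "G"):
        vals[start : start + k] = min(k, 4)
    for start, k in _runs(s, "C"):
        vals[start : start + k] = -min(k, 4)
    return float(vals.mean())


class _CgccWeights:
    """Run-length weight table for the cGcC score, loaded from package data."""

    def __init__(self, run_weights: dict[int, float], unit: float):
        self.run_weights = run_weights
        self.unit = unit

    @classmethod
    def default(cls) -> "_CgccWeights":
        text = resources.files("splicescan.data").joinpath("cgcc_weights.json").read_text()
        raw = json.loads(text)
        return cls({int(k): float(v) for k, v in raw["run_weights"].items()},
                   float(raw["unit"]))

    def weight(self, run_len: int) -> float:
        if run_len in self.run_weights:
            return self.run_weights[run_len]
        return self.unit * run_len * run_len


_DEFAULT_WEIGHTS: _CgccWeights | None = None


def _default_weights() -> _CgccWeights:
    global _DEFAULT_WEIGHTS
    if _DEFAULT_WEIGHTS is None:
        _DEFAULT_WEIGHTS = _CgccWeights.default()
    return _DEFAULT_WEIGHTS


def cgcc_score(seq: str, weights: _CgccWeights | None = None) -> float:
    """cG/cC ratio of *seq*.

    cG (cC) sums a run-length-dependent weight over maximal G-runs
    (C-runs).  When the sequence contains no C-run, the denominator is the
    pseudocount 1, so the score equals cG exactly.
    """
    s = _normalize(seq)
    if not s:
        raise ValueError("empty sequence")
    w = weights or _default_weights()
    cg = sum(w.weight(k) for _, k in _runs(s, "G"))
    cc = sum(w.weight(k) for _, k in _runs(s, "C"))
    return cg / (cc if cc > 0 else 1.0)


def canonical_g4_scan(seq: str) -> list[tuple[int, int]]:
    """Leftmost non-overlapping matches of G≥3(N1–7G≥3)×3, half-open.

    Lazy quantifiers give the shortest match at each leftmost start; loops
    admit any nucleotide including N.
    """
    s = _normalize(seq)
    return [(m.start(), m.end()) for m in _CANONICAL_RE.finditer(s)]


def purine_fraction(seq: str, interval: tuple[int, int] | None = None) -> float:
    """(A + G) / length over *interval* (whole sequence when None)."""
    s = _normalize(seq)
    if interval is not None:
        a, b = interval
        if not (0 <= a < b <= len(s)):
            raise ValueError(f"empty or out-of-bounds interval [{a}, {b})")
        s = s[a:b]
    if not s:
        raise ValueError("empty interval")
    return (s.count("A") + s.count("G")) / len(s)


@dataclass
class G4ScanConfig:
    """Windowed-scan settings; defaults are the screening tool's defaults."""

    window_length: int = 60
    window_step: int = 10
    cgcc_threshold: float = 4.5
    g4h_threshold: float = 0.9

    def __post_init__(self) -> None:
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")
        if not (1 <= self.window_step <= self.window_length):
            raise ValueError("window_step must be in [1, window_length]")
        for name in ("cgcc_threshold", "g4h_threshold"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")


@dataclass
class G4WindowRecord:
    start: int
    end: int
    g4h: float
    cgcc: float
    g4h_call: bool
    cgcc_call: bool
    strand: str = "+"


@dataclass
class G4ScanResult:
    windows: list[G4WindowRecord]
    canonical_matches: list[tuple[int, int]]
    config: G4ScanConfig
    seq_id: str = ""


def window_starts(length: int, window: int, step: int) -> list[int]:
    """Start positions tiling [0, length) with fixed-width windows.

    Windows anchor at 0, step, 2·step, ...; if the remainder does not land
    a window flush with the 3' end, one extra full-length window at
    ``length - window`` is appended.  A sequence shorter than the window
    yields the single whole-sequence window start 0.
    """
    if length <= window:
        return [0]
    starts = list(range(0, length - window + 1, step))
    if (length - window) % step != 0:
        starts.append(length - window)
    return starts


def scan(seq: str, config: G4ScanConfig | None = None,
         both_strands: bool = False, seq_id: str = "") -> G4ScanResult:
    """Score fixed windows of *seq* with G4Hunter and cGcC and call them.

    Calls are strict (> threshold).  With ``both_strands`` the reverse
    complement's windows are appended with strand '-' (coordinates remain
    on the forward sequence).
    """
    cfg = config or G4ScanConfig()
    s = _normalize(seq)
    if not s:
        raise ValueError("empty sequence")
    n = len(s)
    records: list[G4WindowRecord] = []

    def add_windows(strand_seq: str, strand: str) -> None:
        for start in window_starts(n, cfg.window_length, cfg.window_step):
            end = min(start + cfg.window_length, n)
            sub = strand_seq[start:end]
            if strand == "-":
                fwd_start, fwd_end = n - end, n - start
            else:
                fwd_start, fwd_end = start, end
            g4h = g4hunter_score(sub)
            cg = cgcc_score(sub)
            records.append(
                G4WindowRecord(
                    start=fwd_start,
                    end=fwd_end,
                    g4h=g4h,
                    cgcc=cg,
                    g4h_call=g4h > cfg.g4h_threshold,
                    cgcc_call=cg > cfg.cgcc_threshold,
                    strand=strand,
                )
            )

    add_windows(s, "+")
    if both_strands:
        add_windows(reverse_complement(s), "-")
    return G4ScanResult(records, canonical_g4_scan(s), cfg, seq_id=seq_id)
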