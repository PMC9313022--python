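"""Hexamer splicing-activity score tables.

An ESE/ESSseq score table maps every DNA hexamer (4096 six-mers over
``{A,C,G,T}``) to a single real splicing-activity score: positive values mark
enhancer-like hexamers (ESE), negative values silencer-like ones (ESS).  The
strongest known enhancer hexamer is AGAAGA.  Lookups are case-insensitive and
accept U as a synonym for T so RNA and DNA sequences share one table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

__all__ = [
    "HexamerScoreTable",
    "UnscorableHexamerError",
    "ScoreTableError",
    "all_hexamers",
    "load_score_table",
    "write_score_table",
]

_ALPHABET = "ACGT"
_N_HEXAMERS = 4 ** 6

_TRANS = str.maketrans("acgtuU", "ACGTTT")


def all_hexamers():
    """Yield the 4096 DNA hexamers in lexicographic (A<C<G<T) order."""
    for tup in itertools.product(_ALPHABET, repeat=6):
        yield "".join(tup)


class ScoreTableError(ValueError):
    """Raised when a score table file violates the table contract."""


class UnscorableHexamerError(ValueError):
    """Raised when a hexamer contains symbols outside {A,C,G,T,U}.

    Callers that paint per-nucleotide profiles catch this and record a
    coverage gap instead of a score.
    """


def normalize_hexamer(hexamer: str) -> str:
    """Uppercase a 6-mer and map U to T; raise on anything unscorable."""
    if len(hexamer) != 6:
        raise UnscorableHexamerError(
            f"expected a 6-mer, got {len(hexamer)}-mer {hexamer!r}"
        )
    key = hexamer.translate(_TRANS)
    for ch in key:
        if ch not in _ALPHABET:
            raise UnscorableHexamerError(f"unscorable hexamer {hexamer!r}")
    return key


@dataclass
class HexamerScoreTable:
    """Complete map of the 4096 DNA hexamers to one real score each.

    Parameters
    ----------
    entries
        Mapping hexamer -> score.  Must contain exactly one finite score for
        every hexamer over ``{A,C,G,T}**6``.
    source_label
        Free-text provenance (file path, generator seed, ...).
    """

    entries: dict[str, float]
    source_label: str = ""
    #: raw score strings as read from file, for exact text round-trips
    raw_text: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n = len(self.entries)
        if n != _N_HEXAMERS:
            missing = _N_HEXAMERS - n
            raise ScoreTableError(
                f"score table must cover all {_N_HEXAMERS} hexamers: "
                f"missing {missing} hexamer{'s' if missing != 1 else ''}"
                if n < _N_HEXAMERS
                else f"score table has {n} entries, expected {_N_HEXAMERS}"
            )
        for hexamer, score in self.entries.items():
            if len(hexamer) != 6 or any(c not in _ALPHABET for c in hexamer):
                raise ScoreTableError(f"invalid hexamer key {hexamer!r}")
            if not _isfinite(score):
                raise ScoreTableError(f"non-finite score for {hexamer}: {score!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def score_of(self, hexamer: str) -> float:
        """Score of *hexamer*; case-insensitive, U treated as T.

        Raises :class:`UnscorableHexamerError` for ambiguity codes (N, ...)
        or wrong length.
        """
        return self.entries[normalize_hexamer(hexamer)]

    def max_scoring(self) -> tuple[list[str], float]:
        """All hexamers attaining the maximum score, and that score."""
        best = max(self.entries.values())
        return sorted(h for h, s in self.entries.items() if s == best), best

    def min_scoring(self) -> tuple[list[str], float]:
        """All hexamers attaining the minimum score, and that score."""
        worst = min(self.entries.values())
        return sorted(h for h, s in self.entries.items() if s == worst), worst


def _isfinite(x: float) -> bool:
    try:
        return x == x and abs(x) != float("inf")
    except TypeError:
        return False


def score_of(table: HexamerScoreTable, hexamer: str) -> float:
    """Functional alias for :meth:`HexamerScoreTable.score_of`."""
    return table.score_of(hexamer)


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def load_score_table(path) -> HexamerScoreTable:
    """Load a two-column tab-separated hexamer score table.

    Column 1 is the hexamer (over ``[ACGTU]``, any case; U is stored as T),
    column 2 the decimal score.  A header line is auto-detected by a
    non-numeric second field on the first data line; ``#``-prefixed comment
    lines and blank lines are ignored.

    Raises
    ------
    ScoreTableError
        On duplicate hexamers (naming the hexamer), malformed keys (naming
        the line number), or an incomplete table (with the missing count).
    """
    entries: dict[str, float] = {}
    raw: dict[str, str] = {}
    first_data_line = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 2:
                raise ScoreTableError(
                    f"line {lineno}: expected 2 columns, got {len(fields)}"
                )
            key_text, score_text = fields
            if first_data_line:
                first_data_line = False
                if not _looks_numeric(score_text):
                    continue  # header line
            try:
                key = normalize_hexamer(key_text)
            except UnscorableHexamerError:
                raise ScoreTableError(
                    f"line {lineno}: key {key_text!r} does not match [ACGTU]{{6}}"
                ) from None
            if key in entries:
                raise ScoreTableError(f"duplicate hexamer {key}")
            if not _looks_numeric(score_text):
                raise ScoreTableError(f"line {lineno}: non-numeric score {score_text!r}")
            entries[key] = float(score_text)
            raw[key] = score_text
    return HexamerScoreTable(entries, source_label=str(path), raw_text=raw)


def write_score_table(table: HexamerScoreTable, path) -> None:
    """Write a table back to two-column tab-separated text.

    Scores loaded from a file are emitted with their original text so a
    load/write cycle reproduces every (hexamer, score) pair exactly.
    """
    with open(path, "w") as fh:
        for hexamer, score in table.entries.items():
            text = table.raw_text.get(hexamer, repr(score))
            fh.write(f"{hexamer}\t{text}\n")
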