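"""Readers and writers for the standard formats used by the pipeline.

FASTA via Biopython; BED as 0-based half-open intervals; tab-separated
report tables for profiles, G4 windows and duplication pairs.  All on-disk
coordinates are 0-based half-open (BED convention); 1-based coordinates
appear only in human-readable summaries.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

from Bio import SeqIO

from .dupfind import DuplicationPair, annotate_separator
from .g4scan import G4ScanResult
from .profile import NucleotideProfile, Peak

__all__ = [
    "BedRecord",
    "read_fasta",
    "read_bed",
    "write_bed",
    "write_profile_tsv",
    "write_peaks_bed",
    "write_g4_windows_tsv",
    "write_canonical_bed",
    "write_duplications_tsv",
    "write_duplications_bed",
    "file_md5",
]


@dataclass
class BedRecord:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: str = "."
    strand: str = "."

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def read_fasta(path) -> dict[str, str]:
    """Sequences by id, case preserved; empty files yield an empty dict."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_bed(path) -> list[BedRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            start, end = int(fields[1]), int(fields[2])
            if start < 0 or end <= start:
                raise ValueError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            records.append(
                BedRecord(
                    chrom=fields[0],
                    start=start,
                    end=end,
                    name=fields[3] if len(fields) > 3 else ".",
                    score=fields[4] if len(fields) > 4 else ".",
                    strand=fields[5] if len(fields) > 5 else ".",
                )
            )
    return records


def write_bed(records, path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.score}\t{r.strand}\n")


def write_profile_tsv(profile: NucleotideProfile, path) -> None:
    """Columns: seq_id, position (0-based, offset-shifted), base, score, coverage.

    Missing scores (coverage 0) are written as ``NA``.
    """
    with open(path, "w") as fh:
        fh.write("seq_id\tposition\tbase\tscore\tcoverage\n")
        for i, base in enumerate(profile.sequence):
            score = profile.scores[i]
            text = "NA" if score != score else f"{score:.6g}"
            fh.write(
                f"{profile.seq_id}\t{i + profile.offset}\t{base}\t{text}\t"
                f"{profile.coverage[i]}\n"
            )


def write_peaks_bed(peaks: list[Peak], seq_id: str, path, offset: int = 0) -> None:
    """Peaks as BED: the exceedance run as the interval, value in score."""
    with open(path, "w") as fh:
        for k, p in enumerate(peaks):
            fh.write(
                f"{seq_id}\t{p.left + offset}\t{p.right + offset}\t"
                f"peak_{k + 1}_at_{p.position + offset}\t{p.value:.6g}\t.\n"
            )


def write_g4_windows_tsv(result: G4ScanResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tend\tstrand\tg4h\tcgcc\tg4h_call\tcgcc_call\n")
        for w in result.windows:
            fh.write(
                f"{result.seq_id}\t{w.start}\t{w.end}\t{w.strand}\t"
                f"{w.g4h:.6g}\t{w.cgcc:.6g}\t{int(w.g4h_call)}\t{int(w.cgcc_call)}\n"
            )


def write_canonical_bed(result: G4ScanResult, path) -> None:
    with open(path, "w") as fh:
        for k, (a, b) in enumerate(result.canonical_matches):
            fh.write(f"{result.seq_id}\t{a}\t{b}\tcanonical_g4_{k + 1}\t.\t+\n")


def write_duplications_tsv(pairs: list[DuplicationPair], seq: str, seq_id: str, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "seq_id\ta_start\ta_end\tb_start\tb_end\tlength\tmismatches\t"
            "separator_purine_fraction\n"
        )
        for p in pairs:
            sep = annotate_separator(p, seq)
            frac = "NA" if sep.purine_fraction is None else f"{sep.purine_fraction:.6g}"
            fh.write(
                f"{seq_id}\t{p.a_start}\t{p.a_end}\t{p.b_start}\t{p.b_end}\t"
                f"{p.length}\t{p.mismatches}\t{frac}\n"
            )


def write_duplications_bed(pairs: list[DuplicationPair], seq_id: str, path) -> None:
    """Each pair as copy-A, separator (if any) and copy-B intervals."""
    with open(path, "w") as fh:
        for k, p in enumerate(pairs, start=1):
            fh.write(f"{seq_id}\t{p.a_start}\t{p.a_end}\tdup_{k}_a\t{p.mismatches}\t.\n")
            sa, sb = p.separator
            if sb > sa:
                fh.write(f"{seq_id}\t{sa}\t{sb}\tdup_{k}_separator\t.\t.\n")
            fh.write(f"{seq_id}\t{p.b_start}\t{p.b_end}\tdup_{k}_b\t{p.mismatches}\t.\n")


def file_md5(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
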