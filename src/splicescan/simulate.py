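"""Seeded generator of Olduvai-like exon-doublet gene models.

An Olduvai protein domain is encoded by an exon doublet: a small first exon
(most often 52 nt) and a larger second exon, separated by a short intron.
In expanded human-lineage-specific (HLS1) sub-types the first exon is 109 nt
because it carries a 57-nt purine-rich insertion created by an intra-exon
duplication: a 33-nt block present in the unexpanded exon reappears as a
near-identical copy, separated by a short purine-rich motif, followed by a
purine tail.  The region around the duplication behaves as a predicted RNA
G-quadruplex (the 68-nt "pG4" segment) even though its G-runs are too short
for the canonical G≥3 motif.

The generator plants exactly this architecture into otherwise uniform
random sequence so every pipeline stage (profiling, G4 scanning,
duplication detection, region statistics) can be exercised end to end with
known ground truth:

* unexpanded first exon = [prefix 19 nt][block A 33 nt] = 52 nt;
* expanded first exon inserts [separator 7 nt][block A' 33 nt][tail 17 nt]
  directly after A, giving 109 nt; A' differs from A by a planted number of
  purine-to-purine substitutions (default 1);
* the pG4-like region is the final 68 nt of the expanded exon (optionally
  shifted into the intron), built from G-run-capped purine tiles with a
  single planted cytosine near its centre, so its G4Hunter score exceeds
  0.9 while the canonical G4 pattern never matches;
* the insertion's purine fraction is hit exactly by composition
  bookkeeping (default 0.95 of 57 nt → 54 purines).

Generation is deterministic per seed, self-checks every invariant (exact
duplication recovery, canonical-scan emptiness, G4Hunter call, purine
fraction) and retries with a derived attempt seed on the rare random
violation, failing hard after a bounded number of attempts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np

from . import dupfind as _dupfind
from . import g4scan as _g4scan
from .hexamers import HexamerScoreTable, all_hexamers

__all__ = [
    "DoubletSpec",
    "GeneModel",
    "generate_doublet_gene",
    "generate_score_table",
    "generate_cohort",
    "derive_seed",
    "PURINE_HEXAMER_SCORE",
    "TOP_HEXAMER",
    "TOP_HEXAMER_SCORE",
]

#: strongest enhancer hexamer and its score on the published scale
TOP_HEXAMER = "AGAAGA"
TOP_HEXAMER_SCORE = 1.034
#: default planted score for the remaining purine-only hexamers
PURINE_HEXAMER_SCORE = 0.8

_MAX_ATTEMPTS = 50


def derive_seed(master_seed: int, index: int) -> int:
    """Splitmix64-style per-item seed derivation (stable, subset-reproducible)."""
    z = (master_seed + (index + 1) * 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return (z ^ (z >> 31)) & 0x7FFFFFFF


@dataclass
class DoubletSpec:
    """Architecture parameters of one synthetic exon doublet (lengths in nt)."""

    first_exon_len: int = 52
    expanded: bool = True
    insertion_len: int = 57
    dup_block_len: int = 33
    separator_len: int = 7
    pg4_len: int = 68
    insertion_purine_fraction: float = 0.95
    g_run_max: int = 2
    second_exon_len: int = 150
    intron_len: int = 300
    seed: int = 0
    planted_mismatches: int = 1
    flank_len: int = 60
    #: shift of the pG4 region 3' end past the exon 3' end, into the intron
    pg4_exon_overhang: int = 0

    def __post_init__(self) -> None:
        lengths = (
            self.first_exon_len, self.insertion_len, self.dup_block_len,
            self.separator_len, self.pg4_len, self.second_exon_len,
            self.intron_len,
        )
        if any(v <= 0 for v in lengths):
            raise ValueError("all architecture lengths must be positive")
        if self.flank_len < 0 or self.pg4_exon_overhang < 0:
            raise ValueError("flank_len and pg4_exon_overhang must be >= 0")
        if not (0.0 <= self.insertion_purine_fraction <= 1.0):
            raise ValueError("insertion_purine_fraction must be in [0, 1]")
        if self.g_run_max < 1:
            raise ValueError("g_run_max must be >= 1 (purine segments need G)")
        if self.dup_block_len > self.first_exon_len:
            raise ValueError("dup_block_len must fit inside the first exon")
        # the duplication spans insertion plus the pre-existing block copy
        if 2 * self.dup_block_len + self.separator_len > (
            self.insertion_len + self.dup_block_len
        ):
            raise ValueError(
                "2*dup_block_len + separator_len must fit in "
                "insertion_len + dup_block_len"
            )
        if self.expanded:
            purine_span = self.dup_block_len + self.insertion_len + self.pg4_exon_overhang
            if self.pg4_len > purine_span:
                raise ValueError(
                    "pg4_len exceeds the purine segment "
                    f"({purine_span} nt: duplication block + insertion + overhang)"
                )
            if self.pg4_exon_overhang > self.intron_len:
                raise ValueError("pg4_exon_overhang exceeds intron length")
        n_nonpur = self.insertion_len - round(
            self.insertion_purine_fraction * self.insertion_len
        )
        tail_len = self.insertion_len - self.separator_len - self.dup_block_len
        if self.expanded and n_nonpur > tail_len + 1:
            raise ValueError(
                "insertion_purine_fraction too low: non-purines do not fit "
                "in the duplication-free part of the insertion"
            )
        if self.planted_mismatches < 0 or self.planted_mismatches >= self.dup_block_len:
            raise ValueError("planted_mismatches must be in [0, dup_block_len)")

    @property
    def expanded_exon_len(self) -> int:
        return self.first_exon_len + (self.insertion_len if self.expanded else 0)


@dataclass
class GeneModel:
    """A synthetic pre-mRNA with named 0-based half-open annotations.

    Exonic sequence is upper case, intronic/flanking sequence lower case.
    Annotation keys: ``flank5, exon1, intron, exon2, flank3`` always;
    ``dup_a, separator, dup_b, insertion, pg4`` for expanded genes.
    """

    sequence: str
    annotations: dict[str, tuple[int, int]]
    spec: DoubletSpec
    seed: int
    gene_id: str = "synthetic_doublet"
    attempt: int = 0

    def interval(self, name: str) -> tuple[int, int]:
        return self.annotations[name]

    def subsequence(self, name: str) -> str:
        a, b = self.annotations[name]
        return self.sequence[a:b]


# purine tiles end in A so concatenation never extends a G-run across seams;
# weights favour GG doublets so the segment's G4Hunter mean sits well above
# the 0.9 call threshold (expected ~1.17) despite the planted cytosine
_TILES = ("GGA", "GGA", "GGA", "GGA", "GGAA", "GA")


def _purine_block(rng: np.random.Generator, length: int,
                  nonpurines: str = "", g_run_max: int = 2) -> str:
    """Random purine-rich block of *length* nt with G-runs <= g_run_max.

    The characters of *nonpurines* (C/T) replace random purines afterwards,
    which can only shorten G-runs.
    """
    if g_run_max == 1:
        tiles = ("GA", "GAA", "GA")
    else:
        tiles = _TILES
    parts: list[str] = []
    total = 0
    while total < length:
        t = tiles[rng.integers(len(tiles))]
        parts.append(t)
        total += len(t)
    s = list("".join(parts)[:length])
    if nonpurines:
        pos = rng.choice(length, size=len(nonpurines), replace=False)
        for p, ch in zip(sorted(int(i) for i in pos), nonpurines):
            s[p] = ch
    return "".join(s)


def _uniform_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _plant_mismatches(rng: np.random.Generator, block: str, k: int,
                      g_run_max: int) -> str:
    """Copy *block* with k purine<->purine substitutions (A<->G).

    Positions are drawn away from the block edges when possible and
    re-drawn if an A->G swap would create a G-run over the cap.
    """
    if k == 0:
        return block
    chars = list(block)
    purine_pos = [i for i, c in enumerate(chars) if c in "AG"]
    inner = [i for i in purine_pos if 2 <= i < len(chars) - 2] or purine_pos
    chosen: list[int] = []
    for _ in range(200):
        chosen = sorted(int(i) for i in rng.choice(inner, size=k, replace=False))
        trial = chars[:]
        ok = True
        for i in chosen:
            trial[i] = "G" if trial[i] == "A" else "A"
        run = 0
        for c in trial:
            run = run + 1 if c == "G" else 0
            if run > g_run_max:
                ok = False
                break
        if ok:
            return "".join(trial)
    raise RuntimeError("could not place planted mismatches under the G-run cap")


def _build_expanded_exon(rng: np.random.Generator, spec: DoubletSpec):
    """Return (exon_seq, relative annotations dict) for the expanded exon."""
    prefix_len = spec.first_exon_len - spec.dup_block_len
    tail_len = spec.insertion_len - spec.separator_len - spec.dup_block_len
    n_nonpur_ins = spec.insertion_len - round(
        spec.insertion_purine_fraction * spec.insertion_len
    )
    # one planted C sits in block A' (mid-pG4, per the single-cytosine motif);
    # remaining non-purines are T's in the tail
    n_in_block = 1 if n_nonpur_ins >= 1 else 0
    n_in_tail = n_nonpur_ins - n_in_block
    block_nonpur = "C" * n_in_block
    block_a = _purine_block(rng, spec.dup_block_len, block_nonpur, spec.g_run_max)
    block_a2 = _plant_mismatches(rng, block_a, spec.planted_mismatches, spec.g_run_max)
    # the separator starts with A while every tile starts with G, and the
    # prefix is forced to end off the separator's last base: the positions
    # flanking the duplication pair then always mismatch, so a
    # budget-exhausted Hamming extension stops exactly at the planted
    # block boundaries
    separator = "A" + _purine_block(rng, spec.separator_len - 1, "", spec.g_run_max)
    tail = _purine_block(rng, tail_len, "T" * n_in_tail, spec.g_run_max)
    prefix = _uniform_seq(rng, prefix_len)
    if prefix and prefix[-1] == separator[-1]:
        others = [b for b in "ACGT" if b != separator[-1]]
        prefix = prefix[:-1] + others[rng.integers(len(others))]
    exon = prefix + block_a + separator + block_a2 + tail
    ann = {
        "dup_a": (prefix_len, prefix_len + spec.dup_block_len),
        "separator": (
            prefix_len + spec.dup_block_len,
            prefix_len + spec.dup_block_len + spec.separator_len,
        ),
        "dup_b": (
            prefix_len + spec.dup_block_len + spec.separator_len,
            prefix_len + 2 * spec.dup_block_len + spec.separator_len,
        ),
        "insertion": (spec.first_exon_len, spec.first_exon_len + spec.insertion_len),
    }
    return exon, ann


def _self_check(model: GeneModel) -> None:
    spec = model.spec
    seq_upper = model.sequence.upper()
    if not spec.expanded:
        a, b = model.annotations["exon1"]
        assert b - a == spec.first_exon_len
        return
    a, b = model.annotations["exon1"]
    assert b - a == spec.expanded_exon_len
    # exact insertion purine fraction (composition bookkeeping)
    ins = model.subsequence("insertion").upper()
    target = round(spec.insertion_purine_fraction * spec.insertion_len)
    if ins.count("A") + ins.count("G") != target:
        raise _RetryGeneration("insertion purine count off target")
    # planted mismatch count between the copies
    da, db = model.annotations["dup_a"], model.annotations["dup_b"]
    copy_a = seq_upper[da[0] : da[1]]
    copy_b = seq_upper[db[0] : db[1]]
    mism = sum(1 for x, y in zip(copy_a, copy_b) if x != y)
    if mism != spec.planted_mismatches:
        raise _RetryGeneration("planted mismatch count drifted")
    # duplication detector must recover the planted coordinates exactly and
    # rank them first (budget == planted mismatches pins the extension)
    pairs = _dupfind.find_intraexon_duplications(
        seq_upper, min_len=min(20, spec.dup_block_len),
        max_mismatch=spec.planted_mismatches,
    )
    if not pairs:
        raise _RetryGeneration("planted duplication not found")
    top = pairs[0]
    if (top.interval_a, top.interval_b) != (da, db) or top.mismatches != mism:
        raise _RetryGeneration("planted duplication not recovered exactly")
    # pG4-like region: canonical motif absent, G4Hunter prone
    pa, pb = model.annotations["pg4"]
    pg4 = seq_upper[pa:pb]
    if _g4scan.canonical_g4_scan(pg4):
        raise _RetryGeneration("canonical G4 motif slipped into pG4 region")
    if _g4scan.g4hunter_score(pg4) <= 0.9:
        raise _RetryGeneration("pG4 region G4Hunter score too low")
    result = _g4scan.scan(seq_upper)
    overlapping = [
        w for w in result.windows if w.start < pb and w.end > pa
    ]
    if not any(w.g4h_call for w in overlapping):
        raise _RetryGeneration("no G4Hunter-positive window over pG4 region")


class _RetryGeneration(Exception):
    pass


def generate_doublet_gene(spec: DoubletSpec) -> GeneModel:
    """Generate one gene model; deterministic for a given ``spec.seed``.

    Layout: [flank5][EXON1][intron][EXON2][flank3]; flanks and intron are
    lower case.  Self-checks the planted invariants and retries with a
    derived attempt seed (bounded) when a random background breaks one.
    """
    last_err: Exception | None = None
    for attempt in range(_MAX_ATTEMPTS):
        rng = np.random.default_rng(derive_seed(spec.seed, attempt))
        try:
            model = _generate_once(spec, rng, attempt)
            _self_check(model)
            return model
        except _RetryGeneration as err:
            last_err = err
    raise RuntimeError(
        f"could not satisfy gene-model invariants in {_MAX_ATTEMPTS} attempts "
        f"(seed {spec.seed}): {last_err}"
    )


def _generate_once(spec: DoubletSpec, rng: np.random.Generator,
                   attempt: int) -> GeneModel:
    if spec.expanded:
        exon1, rel = _build_expanded_exon(rng, spec)
    else:
        prefix = _uniform_seq(rng, spec.first_exon_len - spec.dup_block_len)
        block_a = _purine_block(rng, spec.dup_block_len, "C", spec.g_run_max)
        exon1 = prefix + block_a
        rel = {}
    intron = _uniform_seq(rng, spec.intron_len)
    if spec.expanded and spec.pg4_exon_overhang:
        # continue the purine vocabulary into the intron so the pG4 region
        # can straddle the exon 3' boundary
        ext = _purine_block(rng, spec.pg4_exon_overhang, "", spec.g_run_max)
        intron = ext + intron[spec.pg4_exon_overhang:]
    exon2 = _uniform_seq(rng, spec.second_exon_len)
    flank5 = _uniform_seq(rng, spec.flank_len)
    flank3 = _uniform_seq(rng, spec.flank_len)

    e1 = spec.flank_len
    e1_end = e1 + len(exon1)
    i_end = e1_end + spec.intron_len
    e2_end = i_end + spec.second_exon_len
    ann: dict[str, tuple[int, int]] = {
        "flank5": (0, e1),
        "exon1": (e1, e1_end),
        "intron": (e1_end, i_end),
        "exon2": (i_end, e2_end),
        "flank3": (e2_end, e2_end + spec.flank_len),
    }
    if spec.expanded:
        for name, (a, b) in rel.items():
            ann[name] = (e1 + a, e1 + b)
        pg4_end = e1_end + spec.pg4_exon_overhang
        ann["pg4"] = (pg4_end - spec.pg4_len, pg4_end)
    sequence = (
        flank5.lower() + exon1.upper() + intron.lower() + exon2.upper()
        + flank3.lower()
    )
    return GeneModel(sequence, ann, spec, seed=spec.seed, attempt=attempt)


def _purine_hexamers() -> list[str]:
    return [h for h in all_hexamers() if set(h) <= {"A", "G"}]


def generate_score_table(
    seed: int,
    planted: dict[str, float] | None = None,
    background_sd: float = 0.05,
) -> HexamerScoreTable:
    """Synthetic hexamer score table with planted high-scoring motifs.

    Background scores are i.i.d. normal(0, *background_sd*) truncated to
    [-1, 1].  The default planting puts the top enhancer hexamer AGAAGA at
    1.034 and every other purine-only hexamer — the vocabulary of the
    generator's insertion and separator — at 0.8, so planted purine regions
    profile far above background.  Planted scores must stay within
    [-1.05, 1.05], the scale of the published table.
    """
    if planted is None:
        planted = {h: PURINE_HEXAMER_SCORE for h in _purine_hexamers()}
        planted[TOP_HEXAMER] = TOP_HEXAMER_SCORE
    for h, s in planted.items():
        if len(h) != 6 or set(h) - set("ACGT"):
            raise ValueError(f"planted key {h!r} is not a DNA hexamer")
        if not (-1.05 <= s <= 1.05):
            raise ValueError(
                f"planted score {s} for {h} outside [-1.05, 1.05]"
            )
    rng = np.random.default_rng(seed)
    scores = np.clip(rng.normal(0.0, background_sd, size=4096), -1.0, 1.0)
    entries = {h: float(s) for h, s in zip(all_hexamers(), scores)}
    entries.update({h: float(s) for h, s in planted.items()})
    return HexamerScoreTable(entries, source_label=f"synthetic(seed={seed})")


def generate_cohort(
    n_genes: int, spec_template: DoubletSpec | None = None, seed: int = 0
) -> list[GeneModel]:
    """Generate *n_genes* models, alternating expanded / unexpanded.

    Per-gene seeds derive from the master seed by splitmix64, so any subset
    regenerates identically regardless of cohort size.
    """
    if n_genes < 2 or n_genes % 2 != 0:
        raise ValueError("n_genes must be even and >= 2")
    template = spec_template or DoubletSpec()
    models = []
    for i in range(n_genes):
        spec = replace(
            template, expanded=(i % 2 == 0), seed=derive_seed(seed, i)
        )
        model = generate_doublet_gene(spec)
        model.gene_id = f"synthetic_doublet_{i:03d}"
        models.append(model)
    return models


def write_gene_model(model: GeneModel, fasta_path, bed_path, manifest_path=None) -> None:
    """Write a model as FASTA (case-preserving) + BED, plus a manifest."""
    with open(fasta_path, "w") as fh:
        fh.write(f">{model.gene_id} seed={model.seed}\n")
        seq = model.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")
    with open(bed_path, "w") as fh:
        for name, (a, b) in sorted(model.annotations.items(), key=lambda kv: kv[1]):
            fh.write(f"{model.gene_id}\t{a}\t{b}\t{name}\n")
    if manifest_path is not None:
        with open(manifest_path, "w") as fh:
            fh.write(f"gene_id={model.gene_id}\n")
            fh.write(f"attempt={model.attempt}\n")
            for key, value in asdict(model.spec).items():
                fh.write(f"{key}={value}\n")
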