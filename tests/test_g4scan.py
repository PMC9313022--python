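import re

import pytest
from hypothesis import given, settings, strategies as st

from splicescan.g4scan import (
    G4ScanConfig,
    canonical_g4_scan,
    cgcc_score,
    g4hunter_score,
    purine_fraction,
    reverse_complement,
    scan,
    window_starts,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=80)


class TestG4Hunter:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("GGGG", 4.0),                    # every G in a run of 4 scores 4
            ("GGGGCCCC", 0.0),                # G/C symmetry cancels
            ("GGAT", 1.0),                    # (2+2+0+0)/4
            ("GGGGG", 4.0),                   # run scores cap at 4
            ("CCC", -3.0),
            ("ATAT", 0.0),
            ("GNGG", (1 + 0 + 2 + 2) / 4),    # N breaks runs and scores 0
        ],
    )
    def test_run_scoring_rule(self, seq, expected):
        assert g4hunter_score(seq) == pytest.approx(expected)

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            g4hunter_score("")

    @settings(derandomize=True, max_examples=200)
    @given(seq=dna)
    def test_antisymmetric_under_reverse_complement(self, seq):
        assert g4hunter_score(reverse_complement(seq)) == pytest.approx(
            -g4hunter_score(seq), abs=1e-12
        )

    def test_extending_a_g_run_never_decreases_the_score(self, rng):
        # turning a base adjacent to a G into G extends that run; at fixed
        # window length the score must not decrease
        for _ in range(50):
            seq = list("".join("ACGT"[i] for i in rng.integers(0, 4, size=30)))
            edges = [
                i for i, c in enumerate(seq)
                if c != "G"
                and ((i > 0 and seq[i - 1] == "G")
                     or (i < len(seq) - 1 and seq[i + 1] == "G"))
            ]
            if not edges:
                continue
            before = g4hunter_score("".join(seq))
            seq[edges[int(rng.integers(len(edges)))]] = "G"
            assert g4hunter_score("".join(seq)) >= before - 1e-12


class TestCgcc:
    def test_no_g_runs_scores_zero(self):
        assert cgcc_score("AAAAAAAA") == 0.0

    def test_c_free_sequence_equals_cg_exactly(self):
        # pseudocount branch: denominator 1, score = sum of run weights
        # (10 per base times run length: G->10, GG->40, GGG->90)
        assert cgcc_score("GAGGAGGG") == 10 + 40 + 90

    def test_run_weights_apply_to_both_strands_of_the_ratio(self):
        # cG = 90 (GGG), cC = 40 (CC)
        assert cgcc_score("GGGACC") == pytest.approx(90 / 40)

    def test_symmetric_sequence_scores_one(self):
        assert cgcc_score("GGGCCC") == pytest.approx(1.0)

    def test_fixed_window_score(self):
        # synthetic 60-nt fixture with hand-summed run weights:
        # G-runs G, GG, GGG -> 10 + 40 + 90 = 140
        # C-runs C, CC      -> 10 + 40 = 50
        seq = "AGAA" "GG" "AAAA" "GGG" "TTTT" "C" "TTTT" "CC" + "A" * 36
        assert len(seq) == 60
        assert cgcc_score(seq) == pytest.approx(140 / 50)

    @settings(derandomize=True, max_examples=100)
    @given(seq=st.text(alphabet="AGT", min_size=1, max_size=60))
    def test_c_free_property(self, seq):
        runs = map(len, re.findall("G+", seq))
        assert cgcc_score(seq) == sum(10 * k * k for k in runs)


class TestCanonicalScan:
    def test_minimal_canonical_motif_matches_whole_string(self):
        assert canonical_g4_scan("GGGAGGGAGGGAGGG") == [(0, 15)]

    def test_runs_of_two_never_match(self):
        assert canonical_g4_scan("GGAGGAGGAGG") == []

    def test_matches_are_leftmost_shortest_and_non_overlapping(self):
        seq = "GGGGAGGGAGGGAGGGAGGGAGGG"  # 6 G-runs; one shortest match
        matches = canonical_g4_scan(seq)
        assert matches[0][0] == 0
        a, b = matches[0]
        assert b - a <= 16  # shortest match, not the greedy full span

    def test_loops_admit_any_nucleotide_including_n(self):
        assert canonical_g4_scan("GGGNNGGGTTGGGACGGG") == [(0, 18)]

    def test_long_loops_break_the_pattern(self):
        assert canonical_g4_scan("GGG" + "A" * 8 + "GGG" + "A" * 8 + "GGGAGGG") == []

    def test_g4hunter_saturated_windows_contain_a_canonical_match(self):
        # whenever a window of length >= 15 made of G-runs >= 3 scores 4.0,
        # the canonical pattern must fire
        for seq in ["GGGG" * 4, "G" * 15, "GGGGG" + "A" + "GGG" + "C" + "GGGAGGG"]:
            window = seq[:15]
            if g4hunter_score(window) == 4.0:
                assert canonical_g4_scan(window)


class TestScan:
    def test_single_window_for_window_sized_sequence(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=60))
        result = scan(seq, G4ScanConfig())
        assert [(w.start, w.end) for w in result.windows] == [(0, 60)]

    def test_100nt_sequence_tiles_five_windows(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=100))
        result = scan(seq, G4ScanConfig())
        assert [(w.start, w.end) for w in result.windows] == [
            (0, 60), (10, 70), (20, 80), (30, 90), (40, 100)
        ]

    def test_truncated_tail_emits_final_full_window(self):
        assert window_starts(105, 60, 10) == [0, 10, 20, 30, 40, 45]
        assert window_starts(30, 60, 10) == [0]

    def test_all_a_sequence_makes_no_calls(self):
        result = scan("A" * 200, G4ScanConfig())
        assert all(w.g4h == 0 and w.cgcc == 0 for w in result.windows)
        assert not any(w.g4h_call or w.cgcc_call for w in result.windows)

    def test_calls_are_strict_inequalities(self):
        cfg = G4ScanConfig(window_length=4, window_step=4, g4h_threshold=1.0)
        result = scan("GGAT", cfg)  # g4h exactly 1.0
        assert result.windows[0].g4h == 1.0 and not result.windows[0].g4h_call

    def test_both_strands_doubles_window_records(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=100))
        single = scan(seq, G4ScanConfig())
        double = scan(seq, G4ScanConfig(), both_strands=True)
        assert len(double.windows) == 2 * len(single.windows)
        assert {w.strand for w in double.windows} == {"+", "-"}

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            G4ScanConfig(window_length=0)
        with pytest.raises(ValueError):
            G4ScanConfig(window_length=10, window_step=11)


class TestPurineFraction:
    @pytest.mark.parametrize(
        "seq, interval, expected",
        [("AGAGAG", None, 1.0), ("ACGT", None, 0.5), ("ACGT", (1, 3), 0.5),
         ("CCTT", None, 0.0)],
    )
    def test_examples(self, seq, interval, expected):
        assert purine_fraction(seq, interval) == pytest.approx(expected)

    def test_empty_interval_is_an_error(self):
        with pytest.raises(ValueError):
            purine_fraction("ACGT", (2, 2))

    def test_generator_insertion_hits_target_exactly(self, expanded_gene):
        spec = expanded_gene.spec
        frac = purine_fraction(
            expanded_gene.sequence.upper(), expanded_gene.annotations["insertion"]
        )
        target = round(spec.insertion_purine_fraction * spec.insertion_len)
        assert frac == pytest.approx(target / spec.insertion_len)
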