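"""Tests for segmentation, bridging, and multi-pass correction."""

import random

import numpy as np
import pytest

import _oracles
from conftest import random_dna, tiling_reads
from fmpolish import (
    PolishParams,
    Polisher,
    bridge,
    build_index,
    choose_candidate,
    correct_pass,
    dynamic_threshold,
    extend_end,
    polish,
    segment_solid_weak,
    simulate_genome,
    simulate_short_reads,
)


class TestParams:
    def test_defaults_and_eukaryote_preset(self):
        p = PolishParams()
        assert p.k_list == (21, 59) and p.min_count == 5
        assert p.min_frac == 0.1 and p.branch_factor == 4 and p.cache_size == 8
        e = PolishParams.eukaryote()
        assert e.k_list == (21, 59, 80) and e.min_frac == 0.0
        assert e.min_count == 5  # preset changes k_list and min_frac only

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"k_list": ()},
            {"k_list": (21, 21)},
            {"k_list": (59, 21)},
            {"k_list": (4, 21)},  # k below cache depth
            {"min_frac": 1.5},
            {"min_count": 0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PolishParams(**kwargs)


class TestThreshold:
    def test_absolute_floor_dominates(self):
        assert dynamic_threshold(np.full(50, 10), 5, 0.1) == 5

    def test_relative_component(self):
        assert dynamic_threshold(np.full(50, 100), 5, 0.1) == 10

    def test_min_frac_zero_is_absolute_only(self):
        assert dynamic_threshold(np.full(50, 10_000), 5, 0.0) == 5

    def test_zero_counts_fall_back_to_floor(self):
        assert dynamic_threshold(np.zeros(10), 5, 0.1) == 5

    def test_median_ignores_zero_counts(self):
        counts = np.array([0] * 90 + [100] * 10)
        assert dynamic_threshold(counts, 5, 0.1) == 10

    def test_empty_profile_is_an_error(self):
        with pytest.raises(ValueError):
            dynamic_threshold(np.zeros(0), 5, 0.1)


class TestSegmentation:
    def test_all_solid_single_block(self):
        seg = segment_solid_weak(np.full(6, 9), k=3, seq_len=8, threshold=5)
        assert [(b.start, b.end, b.solid) for b in seg.blocks] == [(0, 8, True)]

    def test_all_weak_single_block(self):
        seg = segment_solid_weak(np.full(6, 1), k=3, seq_len=8, threshold=5)
        assert [(b.start, b.end, b.solid) for b in seg.blocks] == [(0, 8, False)]

    def test_weak_bases_are_those_covered_by_no_solid_kmer(self):
        # solid 3-mers start at 0,1,4,5 and jointly cover bases 0..7,
        # so by direct enumeration no base is weak despite two weak k-mers
        seg = segment_solid_weak(
            np.array([9, 9, 1, 1, 9, 9]), k=3, seq_len=8, threshold=5
        )
        assert [(b.start, b.end, b.solid) for b in seg.blocks] == [(0, 8, True)]

    def test_uncovered_gap_becomes_weak_block(self):
        counts = np.array([9, 1, 1, 1, 1, 1, 1, 9])  # k=3, seq_len=10
        seg = segment_solid_weak(counts, k=3, seq_len=10, threshold=5)
        assert seg.weak_regions() == [(3, 7)]

    def test_empty_profile_whole_sequence_weak(self):
        seg = segment_solid_weak(np.zeros(0), k=5, seq_len=4, threshold=5)
        assert seg.weak_regions() == [(0, 4)]

    def test_blocks_partition_and_alternate(self):
        rng = random.Random(2)
        counts = np.array([rng.choice([1, 9]) for _ in range(40)])
        seg = segment_solid_weak(counts, k=4, seq_len=43, threshold=5)
        assert seg.blocks[0].start == 0 and seg.blocks[-1].end == 43
        for a, b in zip(seg.blocks, seg.blocks[1:]):
            assert a.end == b.start and a.solid != b.solid


class TestBridge:
    TEXT = "ACGTTTGCAAC"

    def _index(self):
        reads = [self.TEXT[i : i + 8] for i in range(len(self.TEXT) - 7)]
        return build_index(reads, cache_size=0), reads

    def test_candidates_match_bruteforce_enumeration(self):
        # both orientations are indexed, so the enumeration may contain
        # reverse-strand detours besides the tiled text itself
        idx, reads = self._index()
        res = bridge(idx, "ACGT", "CAAC", threshold=1, branch_factor=4, max_length=7)
        oracle = _oracles.enumerate_bridges(reads, "ACGT", "CAAC", 1, 7)
        assert set(res.sequences()) == oracle
        assert self.TEXT in oracle
        assert choose_candidate(res.candidates, self.TEXT) == self.TEXT

    def test_unreachable_target_gives_empty_truncated(self):
        # CCCC is indexed (separate read) but no supported path leads to it
        reads = [self.TEXT[i : i + 8] for i in range(len(self.TEXT) - 7)]
        reads.append("CCCCCCCC")
        idx = build_index(reads, cache_size=0)
        res = bridge(idx, "ACGT", "CCCC", threshold=1, branch_factor=4, max_length=7)
        assert res.sequences() == [] and res.truncated

    def test_two_variants_both_found(self):
        texts = ["AACGTTTACCGGA", "AACGTTCACCGGA"]  # differ at one base
        reads = [t[i : i + 7] for t in texts for i in range(len(t) - 6)]
        idx = build_index(reads, cache_size=0)
        res = bridge(idx, "AACG", "CGGA", threshold=1, branch_factor=8, max_length=12)
        oracle = _oracles.enumerate_bridges(reads, "AACG", "CGGA", 1, 12)
        assert set(res.sequences()) == oracle
        assert set(texts) <= oracle

    def test_low_count_anchor_rejected(self):
        idx, _ = self._index()
        with pytest.raises(ValueError):
            bridge(idx, "ACGT", "CAAC", threshold=99, branch_factor=4, max_length=7)

    def test_all_candidate_kmers_meet_threshold(self):
        idx, reads = self._index()
        res = bridge(idx, "ACGT", "CAAC", threshold=1, branch_factor=4, max_length=7)
        for cand in res.sequences():
            for i in range(len(cand) - 3):
                assert idx.count(cand[i : i + 4]) >= 1


class TestExtendEnd:
    def test_zero_target_single_empty_extension(self, tiny_index):
        idx, reads = tiny_index
        anchor = reads[0][:4]
        res = extend_end(idx, anchor, "right", 0, threshold=1, branch_factor=4)
        assert [c.sequence for c in res.candidates] == [""]

    def test_unique_path_recovers_flank(self):
        text = "ACGTTTGCAACGGT"
        reads = [text[i : i + 8] for i in range(len(text) - 7)]
        idx = build_index(reads, cache_size=0)
        # extend right from the 4-mer ending 4 bases before the end
        res = extend_end(idx, text[6:10], "right", 4, threshold=1, branch_factor=4)
        assert text[10:] in [c.sequence for c in res.candidates]
        # extend left towards the start
        res_l = extend_end(idx, text[4:8], "left", 4, threshold=1, branch_factor=4)
        assert text[0:4] in [c.sequence for c in res_l.candidates]

    def test_unsupported_anchor_end_gives_no_candidates(self):
        # the anchor sits at the very end of the only read: no right extension
        idx = build_index(["ACGTACC"], cache_size=0)
        res = extend_end(idx, "TACC", "right", 5, threshold=1, branch_factor=4)
        assert res.candidates == []


class TestChooseCandidate:
    def test_single_candidate_chosen(self):
        assert choose_candidate(["ACGT"], "ACGA") == "ACGT"

    def test_minimum_distance_wins(self):
        assert choose_candidate(["ACGA", "TTTT"], "ACGT") == "ACGA"

    def test_equal_distance_shorter_wins(self):
        orig = "AAAAACCCCC"
        near = "AAAAACCCC"  # distance 1, length 9
        far = "AAAAACCCCCT"  # distance 1, length 11
        assert choose_candidate([far, near], orig) == near

    def test_empty_gives_none(self):
        assert choose_candidate([], "ACGT") is None


class TestCorrectPass:
    K = 21

    def _setup(self, seed=0, length=1000, errors=()):
        rng = random.Random(seed)
        genome = random_dna(rng, length)
        reads = tiling_reads(genome, 150, 3)  # ~50x, covers the ends evenly
        idx = build_index(reads)
        draft = genome
        for pos, repl in sorted(errors, reverse=True):
            draft = draft[:pos] + repl + draft[pos + 1 :]
        return genome, idx, draft

    def test_error_free_sequence_unchanged(self):
        genome, idx, _ = self._setup()
        out, rep = correct_pass(idx, genome, self.K, PolishParams())
        assert out == genome and rep.regions_found == 0

    def test_single_substitution_corrected(self):
        genome, idx, draft = self._setup(errors=[(500, "X")])
        draft = draft[:500] + ("A" if genome[500] != "A" else "C") + draft[501:]
        out, rep = correct_pass(idx, draft, self.K, PolishParams())
        assert out == genome
        assert rep.regions_found == rep.regions_bridged == 1

    def test_homopolymer_deletion_corrected(self):
        rng = random.Random(4)
        genome = random_dna(rng, 480) + "AAAAAA" + random_dna(rng, 480)
        reads = tiling_reads(genome, 150, 3)
        idx = build_index(reads)
        draft = genome[:482] + genome[483:]  # delete one A inside the run
        out, rep = correct_pass(idx, draft, self.K, PolishParams())
        assert out == genome
        assert rep.regions_bridged == 1

    def test_sequence_shorter_than_k_untouched(self, tiny_index):
        idx, _ = tiny_index
        out, rep = correct_pass(idx, "ACGT", 21, PolishParams())
        assert out == "ACGT" and rep.regions_found == 0

    def test_report_counts_are_consistent(self):
        genome, idx, draft = self._setup(seed=9, errors=[(200, "A"), (700, "G")])
        _, rep = correct_pass(idx, draft, self.K, PolishParams())
        assert rep.regions_bridged + rep.regions_failed == rep.regions_found


class TestPolish:
    def _dataset(self, seed=0, length=6000):
        rng = random.Random(seed)
        genome = random_dna(rng, length)
        idx = build_index(tiling_reads(genome, 150, 3))
        return genome, idx

    def test_error_free_assembly_identical(self):
        genome, idx = self._dataset()
        out, rep = polish(idx, [("c1", genome)])
        assert out == [("c1", genome)]
        assert rep.bases_changed == 0

    def test_n_runs_preserved_verbatim(self):
        genome, idx = self._dataset(seed=1)
        contig = genome[:3000] + "NNNN" + genome[3000:]
        out, _ = polish(idx, {"c": contig})
        assert out[0][1] == contig

    def test_names_and_order_preserved(self):
        genome, idx = self._dataset(seed=2)
        contigs = [("b", genome[:2500]), ("a", genome[2500:])]
        out, _ = polish(idx, contigs)
        assert [n for n, _ in out] == ["b", "a"]

    def test_multi_error_draft_fully_corrected(self):
        genome, idx = self._dataset(seed=3)
        draft = (
            genome[:1000]
            + genome[1001:2004]  # deletion at 1000
            + "T"
            + genome[2004:4000]  # insertion
            + ("C" if genome[4000] != "C" else "G")
            + genome[4001:]  # substitution
        )
        out, rep = polish(idx, [("c", draft)])
        assert out[0][1] == genome
        assert rep.bases_changed >= 3

    def test_lowercase_and_odd_symbols_normalized(self):
        genome, idx = self._dataset(seed=4)
        out, _ = polish(idx, [("c", genome[:500].lower() + "R" + genome[501:1000])])
        assert out[0][1] == genome[:500] + "N" + genome[501:1000]

    def test_determinism(self):
        genome, idx = self._dataset(seed=5)
        draft = genome[:800] + genome[801:]
        out1, _ = polish(idx, [("c", draft)])
        out2, _ = polish(idx, [("c", draft)])
        assert out1 == out2


class TestPolisherEstimator:
    def test_fit_transform_roundtrip(self):
        rng = random.Random(6)
        genome = random_dna(rng, 3000)
        reads = tiling_reads(genome, 150, 3)
        model = Polisher().fit(reads)
        assert model.n_strings_ == 2 * len(reads)
        draft = genome[:1500] + genome[1501:]
        out = model.transform([draft])
        assert out == [genome]
        assert model.report_.bases_changed == 1

    def test_get_params_roundtrip(self):
        model = Polisher(min_count=7)
        params = model.get_params()
        assert params["min_count"] == 7
        clone = Polisher(**params)
        assert clone.get_params() == params

    def test_eukaryote_flag_overrides_k_and_frac(self):
        model = Polisher(eukaryote=True)
        p = model._params()
        assert p.k_list == (21, 59, 80) and p.min_frac == 0.0

    def test_transform_before_fit_is_an_error(self):
        with pytest.raises(RuntimeError):
            Polisher().transform(["ACGT"])
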