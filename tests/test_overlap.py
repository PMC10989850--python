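"""Overlap analysis, adapter clipping, base correction, merging, insert size."""

from collections import Counter

import numpy as np
import pytest

from seqscrub.fastq import ReadPair, ReadRecord, reverse_complement
from seqscrub.overlap import (
    InsertSizeHistogram,
    analyze_overlap,
    clip_adapters_from_overlap,
    correct_bases,
    merge_pair,
    record_insert_size,
)
from seqscrub.simulate import SimConfig, simulate

from conftest import random_read


def pair_from_fragment(rng, insert, read_len, name="p"):
    """Construct an error-free pair as sequencing would: R1 the fragment 5'
    prefix, R2 the reverse complement of the 3' suffix; read-through pads
    with random (adapter-like) bases."""
    frag = "".join(rng.choice(list("ACGT"), size=insert))
    r1 = frag[:read_len]
    r2 = reverse_complement(frag)[:read_len]
    if insert < read_len:
        r1 = r1 + "".join(rng.choice(list("ACGT"), size=read_len - insert))
        r2 = r2 + "".join(rng.choice(list("ACGT"), size=read_len - insert))
    qual = "I" * read_len
    return ReadPair(ReadRecord(name, r1, qual), ReadRecord(name, r2, qual)), frag


def brute_force_overlap(pair, min_overlap=30, max_mismatch=5, max_frac=0.20):
    """Quadratic all-offset scorer, same candidate ordering as the search."""
    s1 = pair.r1.sequence
    s2 = reverse_complement(pair.r2.sequence)
    len1, len2 = len(s1), len(s2)
    candidates = []
    for k in range(0, max(len1, len2) + 1):
        for o in (k, -k) if k else (0,):
            if o >= 0 and o <= len1 - min_overlap:
                candidates.append(o)
            elif o < 0 and o >= -(len2 - min_overlap):
                candidates.append(o)
    for o in candidates:
        if o >= 0:
            window = list(zip(s1[o:], s2))
        else:
            window = list(zip(s1, s2[-o:]))
        ovl = len(window)
        if ovl < min_overlap:
            continue
        mism = sum(a != b for a, b in window)
        if mism <= min(max_mismatch, int(max_frac * ovl)):
            return o, ovl, mism
    return None


class TestAnalyzeOverlap:
    def test_full_overlap_exact_reverse_complement(self, rng):
        r1 = random_read(rng, 100)
        r2 = ReadRecord("r", reverse_complement(r1.sequence), r1.quality[::-1])
        ov = analyze_overlap(ReadPair(r1, r2))
        assert (ov.found, ov.offset, ov.overlap_len, ov.mismatches) == (True, 0, 100, 0)

    def test_positive_offset_from_long_fragment(self, rng):
        pair, _ = pair_from_fragment(rng, 150, 100)
        ov = analyze_overlap(pair)
        assert (ov.found, ov.offset, ov.overlap_len) == (True, 50, 50)

    def test_negative_offset_from_read_through(self, rng):
        pair, _ = pair_from_fragment(rng, 80, 100)
        ov = analyze_overlap(pair)
        assert (ov.found, ov.offset, ov.overlap_len) == (True, -20, 80)

    def test_overlap_length_invariant(self, rng):
        for insert in (50, 120, 151, 200, 260):
            pair, _ = pair_from_fragment(rng, insert, 150)
            ov = analyze_overlap(pair)
            len1 = len2 = 150
            assert ov.found
            if ov.offset >= 0:
                assert ov.overlap_len == min(len1 - ov.offset, len2)
            else:
                assert ov.overlap_len == min(len1, len2 + ov.offset)

    def test_random_pairs_agree_with_brute_force_oracle(self, rng):
        for i in range(300):
            insert = int(rng.integers(35, 280))
            pair, _ = pair_from_fragment(rng, insert, 150)
            # sprinkle a few substitution errors
            for _ in range(int(rng.integers(0, 3))):
                p = int(rng.integers(0, 150))
                s = list(pair.r1.sequence)
                s[p] = str(rng.choice([b for b in "ACGT" if b != s[p]]))
                pair = ReadPair(
                    ReadRecord("p", "".join(s), pair.r1.quality), pair.r2
                )
            ov = analyze_overlap(pair)
            expected = brute_force_overlap(pair)
            if expected is None:
                assert not ov.found
            else:
                assert ov.found
                assert (ov.offset, ov.overlap_len, ov.mismatches) == expected

    def test_unrelated_reads_not_found(self, rng):
        pair = ReadPair(random_read(rng, 150), random_read(rng, 150))
        assert not analyze_overlap(pair).found


class TestClip:
    def test_read_through_clipped_to_fragment(self, rng):
        pair, frag = pair_from_fragment(rng, 80, 100)
        ov = analyze_overlap(pair)
        out = clip_adapters_from_overlap(pair, ov)
        assert out.r1.sequence == frag
        assert out.r2.sequence == reverse_complement(frag)
        assert len(out.r1.quality) == len(out.r2.quality) == 80

    def test_non_negative_offset_is_noop(self, rng):
        pair, _ = pair_from_fragment(rng, 150, 100)
        ov = analyze_overlap(pair)
        assert clip_adapters_from_overlap(pair, ov) == pair

    def test_bulk_read_through_removal_rate(self, rng):
        pairs, truth = simulate(
            SimConfig(seed=21, n_pairs=2000, insert_mean=100, insert_sd=20,
                      error_rate=0.005)
        )
        planted = removed = 0
        for p, t in zip(pairs, truth):
            if t.insert_size >= 150:
                continue
            planted += 2 * (150 - t.insert_size)
            ov = analyze_overlap(p)
            clipped = clip_adapters_from_overlap(p, ov)
            removed += (len(p.r1) - len(clipped.r1)) + (len(p.r2) - len(clipped.r2))
        assert planted > 0
        assert removed / planted >= 0.99


class TestCorrectBases:
    def make_mismatch_pair(self, rng, q1, q2):
        pair, frag = pair_from_fragment(rng, 100, 100)
        # plant a disagreement at fragment position 40: corrupt R2
        p2 = 100 - 1 - 40
        s2 = list(pair.r2.sequence)
        s2[p2] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s2[p2]]
        qual1 = pair.r1.quality[:40] + chr(q1 + 33) + pair.r1.quality[41:]
        qual2 = pair.r2.quality[:p2] + chr(q2 + 33) + pair.r2.quality[p2 + 1 :]
        return (
            ReadPair(
                ReadRecord("p", pair.r1.sequence, qual1),
                ReadRecord("p", "".join(s2), qual2),
            ),
            frag,
        )

    def test_asymmetric_quality_corrected(self, rng):
        pair, frag = self.make_mismatch_pair(rng, 40, 8)
        ov = analyze_overlap(pair)
        assert ov.mismatches == 1
        out, n = correct_bases(pair, ov, 30, 15)
        assert n == 1
        assert out.r2.sequence == reverse_complement(frag)
        assert out.r2.quality[100 - 1 - 40] == chr(40 + 33)

    def test_symmetric_quality_untouched(self, rng):
        pair, _ = self.make_mismatch_pair(rng, 20, 20)
        ov = analyze_overlap(pair)
        out, n = correct_bases(pair, ov, 30, 15)
        assert n == 0 and out == pair

    def test_low_r1_corrected_from_r2(self, rng):
        pair, frag = self.make_mismatch_pair(rng, 8, 40)
        # here R2 carries the corrupted base with high quality, R1 is low:
        # R1's (correct) base gets overwritten toward R2's call
        ov = analyze_overlap(pair)
        out, n = correct_bases(pair, ov, 30, 15)
        assert n == 1
        assert out.r1.sequence[40] == reverse_complement(out.r2.sequence)[40]

    def test_never_changes_bases_outside_overlap(self, rng):
        pair, _ = pair_from_fragment(rng, 150, 100)  # overlap covers r1[50:]
        s1 = list(pair.r1.sequence)
        s1[60] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s1[60]]
        q1 = pair.r1.quality[:60] + chr(2 + 33) + pair.r1.quality[61:]
        pair = ReadPair(ReadRecord("p", "".join(s1), q1), pair.r2)
        ov = analyze_overlap(pair)
        out, n = correct_bases(pair, ov, 30, 15)
        assert n == 1
        assert out.r1.sequence[:50] == pair.r1.sequence[:50]
        assert out.r2 == pair.r2  # the low-quality side was R1


class TestMerge:
    def test_error_free_pair_merges_to_fragment(self, rng):
        pair, frag = pair_from_fragment(rng, 150, 100)
        ov = analyze_overlap(pair)
        merged = merge_pair(pair, ov)
        assert merged.sequence == frag and len(merged) == 150
        assert merged.comment == "merged_100_100"

    def test_read_through_pair_merges_to_fragment(self, rng):
        pair, frag = pair_from_fragment(rng, 80, 100)
        merged = merge_pair(pair, analyze_overlap(pair))
        assert merged.sequence == frag and len(merged) == 80

    def test_full_overlap_identical_pair(self, rng):
        r1 = random_read(rng, 100)
        r2 = ReadRecord("r", reverse_complement(r1.sequence), r1.quality[::-1])
        merged = merge_pair(ReadPair(r1, r2), analyze_overlap(ReadPair(r1, r2)))
        assert merged.sequence == r1.sequence

    def test_disagreement_resolved_by_quality_and_tie_to_r1(self, rng):
        pair, frag = pair_from_fragment(rng, 100, 100)
        p2 = 100 - 1 - 40
        s2 = list(pair.r2.sequence)
        s2[p2] = {"A": "C", "C": "A", "G": "T", "T": "G"}[s2[p2]]
        # R1 at Q40, corrupted R2 at Q10 -> merged base is R1's
        q2 = pair.r2.quality[:p2] + chr(10 + 33) + pair.r2.quality[p2 + 1 :]
        pair2 = ReadPair(pair.r1, ReadRecord("p", "".join(s2), q2))
        merged = merge_pair(pair2, analyze_overlap(pair2))
        assert merged.sequence[40] == pair.r1.sequence[40]
        # equal qualities -> tie goes to R1
        pair3 = ReadPair(pair.r1, ReadRecord("p", "".join(s2), pair.r2.quality))
        merged3 = merge_pair(pair3, analyze_overlap(pair3))
        assert merged3.sequence[40] == pair.r1.sequence[40]

    def test_merged_length_equals_recorded_insert(self, rng):
        for insert in (45, 80, 100, 151, 199, 240):
            pair, _ = pair_from_fragment(rng, insert, 150)
            ov = analyze_overlap(pair)
            hist = InsertSizeHistogram()
            record_insert_size(ov, 150, 150, hist)
            (size,) = hist.counts
            assert len(merge_pair(pair, ov)) == size == insert


class TestInsertSize:
    def test_offset_arithmetic(self):
        hist = InsertSizeHistogram()
        from seqscrub.overlap import OverlapResult

        record_insert_size(OverlapResult(True, 50, 100, 0), 150, 100, hist)
        assert hist.counts == Counter({150: 1})

    def test_not_found_counts_unknown(self):
        from seqscrub.overlap import OverlapResult

        hist = InsertSizeHistogram()
        record_insert_size(OverlapResult(False), 150, 150, hist)
        assert hist.unknown == 1 and hist.total == 1

    def test_histogram_matches_simulation_truth(self):
        # mean 220 keeps nearly all inserts within the 2*150 - 30 = 270
        # bases the mates can span, so the histogram is fully populated;
        # longer fragments fall in the "unknown" category below
        cfg = SimConfig(seed=31, n_pairs=4000, insert_mean=220, insert_sd=30,
                        error_rate=0.0)
        pairs, truth = simulate(cfg)
        hist = InsertSizeHistogram()
        for p in pairs:
            record_insert_size(analyze_overlap(p), len(p.r1), len(p.r2), hist)
        max_est = 150 + 150 - 30  # longest insert the mates can span
        expected = Counter(t.insert_size for t in truth if t.insert_size <= max_est)
        assert hist.counts == expected
        assert hist.unknown == sum(t.insert_size > max_est for t in truth)
        # sample mode of a discretized Normal(220, 30) wobbles a few bins
        assert abs(hist.peak() - 220) <= 10
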