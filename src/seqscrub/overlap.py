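"""Paired-end overlap analysis and the features built on it.

Aligning read 1 against the reverse complement of read 2 (substitutions
only, no gaps) recovers the fragment geometry of a pair. A non-negative
offset means the fragment is longer than the reads overlap-free prefix; a
negative offset means the fragment is shorter than the reads, i.e. both
reads ran through the fragment into adapter. The single overlap result is
shared by adapter clipping, quality-aware base correction, pair merging and
insert-size estimation, so the pair is analysed once.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

from .fastq import ReadPair, ReadRecord, reverse_complement

__all__ = [
    "OverlapResult",
    "InsertSizeHistogram",
    "analyze_overlap",
    "clip_adapters_from_overlap",
    "correct_bases",
    "merge_pair",
    "record_insert_size",
]

DEFAULT_MIN_OVERLAP = 30
DEFAULT_MAX_MISMATCH = 5
DEFAULT_MAX_MISMATCH_FRACTION = 0.20

_COMP = str.maketrans("ACGTN", "TGCAN")


@dataclass(slots=True)
class OverlapResult:
    """Result of the pairwise overlap search.

    ``offset`` is the position, in read-1 coordinates, where the
    reverse-complemented read 2 begins; negative offsets indicate
    read-through into adapter. ``mismatch_positions`` are read-1 coordinates.
    """

    found: bool
    offset: int = 0
    overlap_len: int = 0
    mismatches: int = 0
    mismatch_positions: tuple[int, ...] = ()


@dataclass(slots=True)
class InsertSizeHistogram:
    """Tally of evaluated insert sizes; pairs whose mates do not overlap
    (fragment too long to estimate) fall in ``unknown``."""

    counts: Counter = field(default_factory=Counter)
    unknown: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.unknown

    def peak(self) -> int | None:
        """Most frequent insert size (smallest wins a tie); None if empty."""
        if not self.counts:
            return None
        best = max(self.counts.values())
        return min(size for size, cnt in self.counts.items() if cnt == best)

    def merge(self, other: "InsertSizeHistogram") -> "InsertSizeHistogram":
        out = InsertSizeHistogram(Counter(self.counts), self.unknown)
        out.counts.update(other.counts)
        out.unknown += other.unknown
        return out


def _offset_candidates(lo: int, hi: int):
    """Offsets ordered by increasing |o|, non-negative first at equal |o|."""
    for k in range(0, max(hi, -lo) + 1):
        if 0 <= k <= hi:
            yield k
        if k > 0 and lo <= -k < 0:
            yield -k


def analyze_overlap(
    pair: ReadPair,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    max_mismatch_fraction: float = DEFAULT_MAX_MISMATCH_FRACTION,
) -> OverlapResult:
    """Find the relative offset of a read pair by mismatch-only alignment.

    Candidate offsets are scanned outward from 0 (non-negative before
    negative at equal magnitude — deterministic tie-break) and the first
    offset whose overlap spans at least ``min_overlap`` bases with at most
    ``min(max_mismatch, floor(max_mismatch_fraction * overlap_len))``
    mismatches is accepted.
    """
    s1 = pair.r1.sequence
    s2rc = reverse_complement(pair.r2.sequence)
    len1, len2 = len(s1), len(s2rc)
    if len1 == 0 or len2 == 0:
        return OverlapResult(False)
    a1 = np.frombuffer(s1.encode("ascii"), dtype=np.uint8)
    a2 = np.frombuffer(s2rc.encode("ascii"), dtype=np.uint8)
    lo = -(len2 - min_overlap)
    hi = len1 - min_overlap
    for o in _offset_candidates(lo, hi):
        if o >= 0:
            ovl = min(len1 - o, len2)
            diff = a1[o : o + ovl] != a2[:ovl]
        else:
            ovl = min(len1, len2 + o)
            diff = a1[:ovl] != a2[-o : -o + ovl]
        if ovl < min_overlap:
            continue
        budget = min(max_mismatch, int(max_mismatch_fraction * ovl))
        m = int(np.count_nonzero(diff))
        if m <= budget:
            pos = np.nonzero(diff)[0]
            if o > 0:
                pos = pos + o
            return OverlapResult(True, o, ovl, m, tuple(int(i) for i in pos))
    return OverlapResult(False)


def clip_adapters_from_overlap(pair: ReadPair, ov: OverlapResult) -> ReadPair:
    """Remove read-through adapter tails implied by a negative offset.

    Both mates are truncated at the fragment end: read 1 keeps its first
    ``len2 + offset`` bases, read 2 its first ``len1 + offset`` bases. With a
    non-negative offset there is no read-through and the pair is returned
    unchanged (no-op by contract).
    """
    if not ov.found or ov.offset >= 0:
        return pair
    keep1 = max(0, len(pair.r2) + ov.offset)
    keep2 = max(0, len(pair.r1) + ov.offset)
    return ReadPair(pair.r1.slice(0, keep1), pair.r2.slice(0, keep2))


def _r2_index(c: int, offset: int, len2: int) -> int:
    """Map a read-1 overlap coordinate to the corresponding read-2 position."""
    j = c - offset  # index into reverse-complemented r2
    return len2 - 1 - j


def correct_bases(
    pair: ReadPair,
    ov: OverlapResult,
    high_q: int = 30,
    low_q: int = 15,
) -> tuple[ReadPair, int]:
    """Correct overlap mismatches with strongly asymmetric base qualities.

    At each mismatch, when one mate's base has quality >= ``high_q`` and the
    other's < ``low_q``, the low-quality base is replaced by the
    strand-consistent base of the high-quality mate and inherits its quality.
    Symmetric-quality mismatches are left untouched.
    """
    if not ov.found or not ov.mismatch_positions:
        return pair, 0
    s1 = list(pair.r1.sequence)
    q1 = list(pair.r1.quality)
    s2 = list(pair.r2.sequence)
    q2 = list(pair.r2.quality)
    len2 = len(s2)
    corrected = 0
    for c in ov.mismatch_positions:
        p2 = _r2_index(c, ov.offset, len2)
        phred1 = ord(q1[c]) - 33
        phred2 = ord(q2[p2]) - 33
        if phred1 >= high_q and phred2 < low_q:
            s2[p2] = s1[c].translate(_COMP)
            q2[p2] = q1[c]
            corrected += 1
        elif phred2 >= high_q and phred1 < low_q:
            s1[c] = s2[p2].translate(_COMP)
            q1[c] = q2[p2]
            corrected += 1
    if corrected == 0:
        return pair, 0
    new_pair = ReadPair(
        replace(pair.r1, sequence="".join(s1), quality="".join(q1)),
        replace(pair.r2, sequence="".join(s2), quality="".join(q2)),
    )
    return new_pair, corrected


def merge_pair(pair: ReadPair, ov: OverlapResult) -> ReadRecord:
    """Merge an overlapped pair into a single read in read-1 orientation.

    The merged read covers the union of both mates restricted to the
    fragment (read-through adapter bases are excluded). Inside the overlap
    the higher-quality base wins (tie -> read 1's base); the merged quality
    is the max of the two where the bases agree, the winner's quality where
    they disagree. Merged length equals the evaluated insert size.
    """
    if not ov.found:
        raise ValueError("merge_pair requires a found overlap")
    s1, q1 = pair.r1.sequence, pair.r1.quality
    s2rc = reverse_complement(pair.r2.sequence)
    q2rc = pair.r2.quality[::-1]
    len1, len2 = len(s1), len(s2rc)
    o = ov.offset
    seq: list[str] = []
    qual: list[str] = []
    if o >= 0:
        seq.append(s1[:o])
        qual.append(q1[:o])
        start1, start2 = o, 0
    else:
        start1, start2 = 0, -o
    ovl = ov.overlap_len
    for i in range(ovl):
        b1, c1 = s1[start1 + i], q1[start1 + i]
        b2, c2 = s2rc[start2 + i], q2rc[start2 + i]
        if b1 == b2:
            seq.append(b1)
            qual.append(max(c1, c2))
        elif c2 > c1:
            seq.append(b2)
            qual.append(c2)
        else:
            seq.append(b1)
            qual.append(c1)
    if o >= 0:
        if len1 - o > len2:  # read 1 extends past read 2's end
            seq.append(s1[o + ovl :])
            qual.append(q1[o + ovl :])
        else:
            seq.append(s2rc[start2 + ovl :])
            qual.append(q2rc[start2 + ovl :])
    return ReadRecord(
        name=pair.r1.name,
        sequence="".join(seq),
        quality="".join(qual),
        comment=f"merged_{len1}_{len2}",
    )


def record_insert_size(
    ov: OverlapResult, len1: int, len2: int, hist: InsertSizeHistogram
) -> InsertSizeHistogram:
    """Add one pair's evaluated insert size to the histogram.

    offset >= 0: insert = offset + len2; offset < 0 (read-through):
    insert = overlap length; no overlap found: the pair is counted as
    ``unknown`` (fragment presumably longer than the mates can span).
    """
    if not ov.found:
        hist.unknown += 1
    elif ov.offset >= 0:
        hist.counts[ov.offset + len2] += 1
    else:
        hist.counts[ov.overlap_len] += 1
    return hist
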