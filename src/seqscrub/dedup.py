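"""FASTQ-level duplicate detection with parallel bloom-filter bit arrays.

A read sequence (for pairs, the two sequences joined by a separator) is
hashed by B independent seeded hash functions into B bit arrays of L bits
each. If all B addressed bits are already set the read is flagged as a
duplicate; otherwise the bits are set and the read is unique. Bits only
ever transition 0 -> 1, so an exact repeat of a seen key is *always*
flagged (no false negatives); false positives occur at the usual bloom
rate, and the reported duplication rate can subtract their expected count.

Memory is B * L / 8 bytes, independent of how many reads are processed.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass

import numpy as np

from .fastq import ReadPair

__all__ = [
    "DedupIndex",
    "hash_sequence",
    "pair_key",
    "check_and_insert",
    "duplication_rate",
    "ACCURACY_LEVELS",
]

DEFAULT_NUM_ARRAYS = 3
DEFAULT_BITS_PER_ARRAY = 2**32
# fixed seeds: run-to-run identical hashing is part of the reproducibility
# contract; override only for experiments
DEFAULT_SEEDS = (0x9E3779B97F4A7C15, 0xC2B2AE3D27D4EB4F, 0x165667B19E3779F9,
                 0x27D4EB2F165667C5, 0x85EBCA77C2B2AE63, 0xFF51AFD7ED558CCD,
                 0xC4CEB9FE1A85EC53, 0x2545F4914F6CDD1D)

PAIR_SEPARATOR = "|"

# --dup_calc_accuracy level -> (bits per array, number of arrays)
ACCURACY_LEVELS = {
    1: (2**20, 2),
    2: (2**22, 2),
    3: (2**24, 3),
    4: (2**26, 3),
    5: (2**28, 4),
    6: (2**32, 4),
}


def hash_sequence(sequence: str, seed: int, bits: int) -> int:
    """Map a sequence to an integer p in [0, bits) with a seeded hash.

    Deterministic for equal (sequence, seed, bits); different seeds give
    empirically independent mappings (seeded 64-bit blake2b reduced mod L).
    """
    if bits < 1:
        raise ValueError("bits must be >= 1")
    digest = hashlib.blake2b(
        sequence.encode("ascii"),
        digest_size=8,
        key=(seed & 0xFFFFFFFFFFFFFFFF).to_bytes(8, "little"),
    ).digest()
    return int.from_bytes(digest, "little") % bits


def pair_key(pair: ReadPair) -> str:
    """Combined key for a read pair: the two sequences joined by a separator
    outside the base alphabet, hashed exactly like a single-end sequence."""
    return f"{pair.r1.sequence}{PAIR_SEPARATOR}{pair.r2.sequence}"


class DedupIndex:
    """B bloom-filter bit arrays of L bits with B seeded hash functions."""

    def __init__(
        self,
        num_arrays: int = DEFAULT_NUM_ARRAYS,
        bits_per_array: int = DEFAULT_BITS_PER_ARRAY,
        seeds: tuple[int, ...] | None = None,
    ) -> None:
        if not 1 <= num_arrays <= 8:
            raise ValueError("num_arrays must be in 1..8")
        if bits_per_array < 1:
            raise ValueError("bits_per_array must be >= 1")
        if seeds is None:
            seeds = DEFAULT_SEEDS[:num_arrays]
        if len(seeds) != num_arrays or len(set(seeds)) != num_arrays:
            raise ValueError("need num_arrays distinct hash seeds")
        self.num_arrays = num_arrays
        self.bits_per_array = bits_per_array
        self.seeds = tuple(seeds)
        self.arrays = [
            np.zeros((bits_per_array + 7) // 8, dtype=np.uint8)
            for _ in range(num_arrays)
        ]
        self.reads_seen = 0
        self.duplicates_flagged = 0
        self.unique_count = 0
        self.expected_false_positives = 0.0
        self._log1m = math.log1p(-1.0 / bits_per_array)

    @property
    def memory_bytes(self) -> int:
        """Actual bit-array allocation; constant in the number of reads."""
        return sum(a.nbytes for a in self.arrays)

    @classmethod
    def from_accuracy(cls, level: int) -> "DedupIndex":
        """Build an index from a 1..6 accuracy level (larger = fewer false
        positives, more memory)."""
        if level not in ACCURACY_LEVELS:
            raise ValueError("accuracy level must be in 1..6")
        bits, arrays = ACCURACY_LEVELS[level]
        return cls(num_arrays=arrays, bits_per_array=bits)

    def check_and_insert(self, key: str) -> bool:
        """Insert a key; return True when it was flagged as a duplicate.

        All B bits set -> duplicate (bits unchanged); otherwise every
        addressed bit is set and the key is unique.
        """
        # expected bloom false-positive probability for this insertion,
        # given the unique keys inserted so far
        fp = (1.0 - math.exp(self.unique_count * self._log1m)) ** self.num_arrays
        self.expected_false_positives += fp
        hits = []
        duplicate = True
        for arr, seed in zip(self.arrays, self.seeds):
            p = hash_sequence(key, seed, self.bits_per_array)
            byte, mask = p >> 3, 1 << (p & 7)
            hits.append((arr, byte, mask))
            if not arr[byte] & mask:
                duplicate = False
        self.reads_seen += 1
        if duplicate:
            self.duplicates_flagged += 1
        else:
            for arr, byte, mask in hits:
                arr[byte] |= mask
            self.unique_count += 1
        return duplicate

    def duplication_rate(self, correct_fp: bool = True) -> float:
        """Fraction of reads flagged duplicate, optionally subtracting the
        expected bloom false-positive count."""
        if self.reads_seen == 0:
            raise ValueError("duplication_rate undefined before any read")
        flagged = self.duplicates_flagged
        if correct_fp:
            flagged = flagged - self.expected_false_positives
        return min(1.0, max(0.0, flagged / self.reads_seen))


def check_and_insert(index: DedupIndex, key: str) -> str:
    """Functional wrapper: returns "duplicate" or "unique"."""
    return "duplicate" if index.check_and_insert(key) else "unique"


def duplication_rate(index: DedupIndex, correct_fp: bool = True) -> float:
    return index.duplication_rate(correct_fp=correct_fp)
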