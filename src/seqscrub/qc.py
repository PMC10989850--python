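"""One-pass, mergeable quality-control statistics.

:class:`QcAccumulator` collects per-cycle base counts and quality sums,
overall Q20/Q30/GC tallies and 5-mer counts from a single pass over the
reads. Accumulators merge associatively and commutatively, which is what
lets per-worker statistics from the pack pipeline combine into one report
regardless of scheduling. Overrepresented-sequence analysis samples reads
and is finalized separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fastq import ReadRecord

__all__ = [
    "QcAccumulator",
    "OverrepresentationTracker",
    "quality_curves",
    "content_curves",
    "detect_overrepresented",
]

KMER_K = 5
_N_KMERS = 4**KMER_K

_BASES = "ACGTN"
_CODE_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE_LUT[ord(_b)] = _i


class QcAccumulator:
    """Mergeable per-cycle / per-base / k-mer counters.

    Cycle indexing is 0-based internally (reports present it 1-based).
    Arrays grow on demand when a longer read arrives; nothing is truncated.
    """

    def __init__(self, max_cycles: int = 0) -> None:
        self.max_cycles = 0
        self.base_counts = np.zeros((0, 5), dtype=np.int64)
        self.qual_sum = np.zeros(0, dtype=np.int64)
        self.qual_base_sum = np.zeros((0, 5), dtype=np.int64)
        self.cycle_count = np.zeros(0, dtype=np.int64)
        self.total_reads = 0
        self.total_bases = 0
        self.q20_bases = 0
        self.q30_bases = 0
        self.gc_bases = 0
        self.n_bases = 0
        self.kmer_counts = np.zeros(_N_KMERS, dtype=np.int64)
        if max_cycles:
            self._ensure(max_cycles)

    def _ensure(self, n: int) -> None:
        if n <= self.max_cycles:
            return
        grow = n - self.max_cycles
        self.base_counts = np.vstack([self.base_counts, np.zeros((grow, 5), np.int64)])
        self.qual_base_sum = np.vstack(
            [self.qual_base_sum, np.zeros((grow, 5), np.int64)]
        )
        self.qual_sum = np.concatenate([self.qual_sum, np.zeros(grow, np.int64)])
        self.cycle_count = np.concatenate([self.cycle_count, np.zeros(grow, np.int64)])
        self.max_cycles = n

    def accumulate(self, read: ReadRecord) -> "QcAccumulator":
        """Add one read; every counter is updated exactly once per base."""
        n = len(read)
        self.total_reads += 1
        if n == 0:
            return self
        self._ensure(n)
        codes = _CODE_LUT[np.frombuffer(read.sequence.encode("ascii"), np.uint8)]
        quals = (
            np.frombuffer(read.quality.encode("ascii"), np.uint8).astype(np.int64) - 33
        )
        idx = np.arange(n)
        # each (cycle, base) index occurs at most once per read, so fancy
        # in-place addition is safe here
        self.base_counts[idx, codes] += 1
        self.qual_base_sum[idx, codes] += quals
        self.qual_sum[:n] += quals
        self.cycle_count[:n] += 1
        self.total_bases += n
        self.q20_bases += int(np.count_nonzero(quals >= 20))
        self.q30_bases += int(np.count_nonzero(quals >= 30))
        self.gc_bases += int(np.count_nonzero((codes == 1) | (codes == 2)))
        self.n_bases += int(np.count_nonzero(codes == 4))
        if n >= KMER_K:
            c = codes.astype(np.int64)
            k = (
                c[: n - 4] * 256
                + c[1 : n - 3] * 64
                + c[2 : n - 2] * 16
                + c[3 : n - 1] * 4
                + c[4:]
            )
            bad = np.concatenate(([0], np.cumsum(codes == 4)))
            valid = (bad[KMER_K:] - bad[: n - 4]) == 0
            if valid.any():
                self.kmer_counts += np.bincount(k[valid], minlength=_N_KMERS)
        return self

    def merge(self, other: "QcAccumulator") -> "QcAccumulator":
        """Fieldwise sum of two accumulators (associative, commutative)."""
        out = QcAccumulator(max(self.max_cycles, other.max_cycles))
        for acc in (self, other):
            m = acc.max_cycles
            out.base_counts[:m] += acc.base_counts
            out.qual_base_sum[:m] += acc.qual_base_sum
            out.qual_sum[:m] += acc.qual_sum
            out.cycle_count[:m] += acc.cycle_count
            out.total_reads += acc.total_reads
            out.total_bases += acc.total_bases
            out.q20_bases += acc.q20_bases
            out.q30_bases += acc.q30_bases
            out.gc_bases += acc.gc_bases
            out.n_bases += acc.n_bases
            out.kmer_counts += acc.kmer_counts
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, QcAccumulator):
            return NotImplemented
        m = max(self.max_cycles, other.max_cycles)

        def pad(a: np.ndarray, shape) -> np.ndarray:
            out = np.zeros(shape, dtype=np.int64)
            out[: a.shape[0]] = a
            return out

        return (
            self.total_reads == other.total_reads
            and self.total_bases == other.total_bases
            and self.q20_bases == other.q20_bases
            and self.q30_bases == other.q30_bases
            and self.gc_bases == other.gc_bases
            and self.n_bases == other.n_bases
            and np.array_equal(pad(self.base_counts, (m, 5)), pad(other.base_counts, (m, 5)))
            and np.array_equal(pad(self.qual_base_sum, (m, 5)), pad(other.qual_base_sum, (m, 5)))
            and np.array_equal(pad(self.qual_sum, m), pad(other.qual_sum, m))
            and np.array_equal(pad(self.cycle_count, m), pad(other.cycle_count, m))
            and np.array_equal(self.kmer_counts, other.kmer_counts)
        )


def quality_curves(acc: QcAccumulator) -> dict[str, list[float]]:
    """Per-cycle mean Phred, overall and conditioned on each base call."""
    used = acc.cycle_count > 0
    n = int(np.max(np.nonzero(used)[0]) + 1) if used.any() else 0
    curves: dict[str, list[float]] = {}
    for i, base in enumerate(_BASES[:4]):
        vals = acc.qual_base_sum[:n, i] / np.maximum(acc.base_counts[:n, i], 1)
        # cycles with no call of this base have no defined mean -> None
        curves[base] = [
            round(float(v), 6) if c > 0 else None
            for v, c in zip(vals, acc.base_counts[:n, i])
        ]
    curves["mean"] = [
        round(float(s / c), 6)
        for s, c in zip(acc.qual_sum[:n], acc.cycle_count[:n])
    ]
    return curves


def content_curves(acc: QcAccumulator) -> dict[str, list[float]]:
    """Per-cycle base-content fractions (sum to 1 per cycle) plus GC."""
    used = acc.cycle_count > 0
    n = int(np.max(np.nonzero(used)[0]) + 1) if used.any() else 0
    total = np.maximum(acc.cycle_count[:n], 1).astype(np.float64)
    curves: dict[str, list[float]] = {}
    for i, base in enumerate(_BASES):
        curves[base] = [round(float(v), 8) for v in acc.base_counts[:n, i] / total]
    gc = (acc.base_counts[:n, 1] + acc.base_counts[:n, 2]) / total
    curves["GC"] = [round(float(v), 8) for v in gc]
    return curves


def kmer_table(acc: QcAccumulator) -> dict[str, int]:
    """Counts of all 4^5 5-mers (N-containing windows excluded)."""
    out = {}
    for idx in range(_N_KMERS):
        kmer = "".join(
            "ACGT"[(idx >> (2 * (KMER_K - 1 - j))) & 3] for j in range(KMER_K)
        )
        out[kmer] = int(acc.kmer_counts[idx])
    return out


@dataclass
class OverrepresentationTracker:
    """Samples every s-th read for overrepresented-sequence analysis.

    Sampling keys on the *global* read index, so the sampled set — and the
    candidate collection that depends on its order — is identical however
    reads are sharded across workers. The sampled reads are stored (a
    1-in-``sampling`` subset is small) and analysed at finalization by
    :func:`detect_overrepresented`.
    """

    sampling: int = 20
    _entries: list[tuple[int, ReadRecord]] = field(default_factory=list)

    def offer(self, read: ReadRecord, index: int) -> None:
        if index % self.sampling == 0:
            self._entries.append((index, read))

    @property
    def sampled(self) -> list[ReadRecord]:
        return [r for _, r in sorted(self._entries, key=lambda e: e[0])]

    def merge(self, other: "OverrepresentationTracker") -> "OverrepresentationTracker":
        out = OverrepresentationTracker(self.sampling)
        out._entries = self._entries + other._entries
        return out


DEFAULT_OVERREP_LENGTHS = (10, 20, 40, 100)
CANDIDATE_SEED_READS = 50


def detect_overrepresented(
    sampled_reads: list[ReadRecord],
    lengths: tuple[int, ...] | None = None,
    multiplier: float = 10.0,
    read_len_hint: int | None = None,
) -> list[dict]:
    """Flag substrings occurring far above chance in the sampled reads.

    Candidate substrings of the configured lengths are collected from the
    first few sampled reads and counted across all sampled reads. A
    sequence is overrepresented when its count reaches
    ``max(10, expected * multiplier)`` where the expectation assumes uniform
    base composition (0.25^len per scanned position). Flagged sequences
    carry their per-cycle (start-position) hit distribution.
    """
    if not sampled_reads:
        return []
    if lengths is None:
        max_len = read_len_hint or max(len(r) for r in sampled_reads)
        lengths = tuple(
            sorted({l for l in DEFAULT_OVERREP_LENGTHS + (max_len // 2,) if l >= 2})
        )
    candidates: dict[str, int] = {}
    for read in sampled_reads[:CANDIDATE_SEED_READS]:
        seq = read.sequence
        for ln in lengths:
            for p in range(0, len(seq) - ln + 1):
                candidates[seq[p : p + ln]] = 0
    positions_scanned = {ln: 0 for ln in lengths}
    for read in sampled_reads:
        seq = read.sequence
        for ln in lengths:
            span = len(seq) - ln + 1
            if span > 0:
                positions_scanned[ln] += span
            for p in range(0, span):
                sub = seq[p : p + ln]
                if sub in candidates:
                    candidates[sub] += 1
    flagged = []
    for sub, count in candidates.items():
        ln = len(sub)
        expected = (0.25**ln) * positions_scanned[ln]
        if count >= max(10, expected * multiplier):
            flagged.append((sub, count, expected))
    flagged.sort(key=lambda t: (-t[1], t[0]))
    max_cycles = max(len(r) for r in sampled_reads)
    results = []
    for sub, count, expected in flagged:
        hits = [0] * max_cycles
        for read in sampled_reads:
            seq = read.sequence
            start = 0
            while True:
                p = seq.find(sub, start)
                if p < 0:
                    break
                hits[p] += 1
                start = p + 1
        results.append(
            {
                "sequence": sub,
                "count": count,
                "expected": round(expected, 6),
                "per_cycle_hits": hits,
            }
        )
    return results
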