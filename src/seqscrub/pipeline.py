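"""Deterministic pack-based pipeline orchestration.

Input reads are split into fixed-capacity packs; each pack is routed to a
worker purely by ``pack_index mod worker_count`` (with two workers this is
exactly the odd/even split) and transformed by a pure per-pack function
into output candidates plus worker-local statistics. Outputs are
reassembled strictly in ascending pack index, so results are byte-identical
for any worker count and across repeated runs. Duplicate marking is the
one order-sensitive stage and therefore runs at the reassembly point, never
inside a worker.

The scheduler here is sequential: the routing/reassembly contract is what
guarantees reproducibility, and a thread pool could only change timing,
which by construction never reaches the results.
"""

from __future__ import annotations

import sys
from collections import Counter
from dataclasses import dataclass, field, fields
from itertools import zip_longest
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

from .dedup import DedupIndex, pair_key
from .fastq import (
    FastqFormatError,
    ReadPair,
    ReadRecord,
    format_record,
    mate_stem,
    parse_fastq_stream,
)
from . import trim as _trim
from .trim import ConfigError, FilterConfig, FilterStatus
from .overlap import (
    InsertSizeHistogram,
    analyze_overlap,
    clip_adapters_from_overlap,
    correct_bases,
    merge_pair,
    record_insert_size,
)
from .qc import OverrepresentationTracker, QcAccumulator, detect_overrepresented

__all__ = [
    "ReadPack",
    "PipelineConfig",
    "PipelineResult",
    "partition_packs",
    "assign_worker",
    "run_pipeline",
]


@dataclass(slots=True)
class ReadPack:
    """Fixed-capacity ordered batch of records: the unit of worker routing
    and of in-order output reassembly."""

    pack_index: int
    records: list

    def __len__(self) -> int:
        return len(self.records)


def partition_packs(records: Iterable, capacity: int) -> Iterator[ReadPack]:
    """Split a record stream into consecutive packs of ``capacity`` items;
    only the final pack may be short."""
    if capacity < 1:
        raise ConfigError("pack capacity must be >= 1")
    batch: list = []
    index = 0
    for item in records:
        batch.append(item)
        if len(batch) == capacity:
            yield ReadPack(index, batch)
            index += 1
            batch = []
    if batch:
        yield ReadPack(index, batch)


def assign_worker(pack_index: int, worker_count: int) -> int:
    """Fixed pack->worker routing: ``pack_index mod worker_count``.

    A pure function of its arguments — never of runtime timing — which is
    what makes the output order reproducible.
    """
    if worker_count < 1:
        raise ConfigError("worker_count must be >= 1")
    if pack_index < 0:
        raise ConfigError("pack_index must be >= 0")
    return pack_index % worker_count


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; defaults mirror common practice."""

    # orchestration
    pack_capacity: int = 1000
    worker_count: int = 2
    reads_to_process: int = 0  # 0 = all
    gzip_level: int = 4
    # global trimming
    trim_front1: int = 0
    trim_tail1: int = 0
    trim_front2: int = 0
    trim_tail2: int = 0
    # sliding-window trimming
    cut_front: bool = False
    cut_tail: bool = False
    cut_right: bool = False
    cut_window_size: int = 4
    cut_mean_quality: float = 20.0
    # polyG / polyX
    trim_poly_g: bool = False
    poly_g_min_len: int = 10
    trim_poly_x: bool = False
    poly_x_min_len: int = 10
    # adapters
    disable_adapter_trimming: bool = False
    adapter_sequence: str | None = None
    adapter_sequence_r2: str | None = None
    adapter_mismatch_fraction: float = 0.2
    # filtering
    disable_quality_filtering: bool = False
    disable_length_filtering: bool = False
    qualified_phred: int = 15
    max_unqualified_fraction: float = 0.40
    max_n_count: int = 5
    min_length: int = 15
    length_limit: int = 0
    # UMI
    umi: bool = False
    umi_loc: str = "read1"
    umi_len: int = 0
    umi_skip: int = 0
    # overlap / correction / merging
    overlap_len_require: int = 30
    overlap_diff_limit: int = 5
    overlap_diff_percent_limit: float = 0.20
    disable_correction: bool = False
    correction_high_q: int = 30
    correction_low_q: int = 15
    merge: bool = False
    include_unmerged: bool = False
    # deduplication
    dedup: bool = False
    dup_calc_accuracy: int = 3
    dedup_pre_trim: bool = False
    # overrepresentation
    overrepresentation_analysis: bool = False
    overrepresentation_sampling: int = 20
    report_title: str = "seqscrub report"

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            qualified_phred=0 if self.disable_quality_filtering else self.qualified_phred,
            max_unqualified_fraction=1.0
            if self.disable_quality_filtering
            else self.max_unqualified_fraction,
            max_n_count=10**9 if self.disable_quality_filtering else self.max_n_count,
            min_length=0 if self.disable_length_filtering else self.min_length,
            max_length=0 if self.disable_length_filtering else self.length_limit,
        )


@dataclass
class WorkerState:
    """Worker-local, mergeable statistics (merged after the last pack)."""

    acc_before_r1: QcAccumulator = field(default_factory=QcAccumulator)
    acc_before_r2: QcAccumulator = field(default_factory=QcAccumulator)
    insert_hist: InsertSizeHistogram = field(default_factory=InsertSizeHistogram)
    adapter_trimmed_reads: int = 0
    adapter_trimmed_bases: int = 0
    corrected_bases: int = 0
    corrected_reads: int = 0
    overlap_found_pairs: int = 0
    overrep_r1: OverrepresentationTracker | None = None
    overrep_r2: OverrepresentationTracker | None = None


@dataclass
class PipelineResult:
    """Counters, accumulators and payload-ready statistics of one run."""

    paired: bool
    reads_in: int = 0
    reads_written: int = 0
    merged_pairs: int = 0
    unmerged_pairs_written: int = 0
    unmerged_pairs_dropped: int = 0
    filter_counts: Counter = field(default_factory=Counter)
    acc_before_r1: QcAccumulator = field(default_factory=QcAccumulator)
    acc_before_r2: QcAccumulator = field(default_factory=QcAccumulator)
    acc_after_r1: QcAccumulator = field(default_factory=QcAccumulator)
    acc_after_r2: QcAccumulator = field(default_factory=QcAccumulator)
    acc_merged: QcAccumulator = field(default_factory=QcAccumulator)
    insert_hist: InsertSizeHistogram = field(default_factory=InsertSizeHistogram)
    adapter_trimmed_reads: int = 0
    adapter_trimmed_bases: int = 0
    corrected_bases: int = 0
    corrected_reads: int = 0
    overlap_found_pairs: int = 0
    duplication_rate_raw: float = 0.0
    duplication_rate: float = 0.0
    duplicates_flagged: int = 0
    overrep_r1: list = field(default_factory=list)
    overrep_r2: list = field(default_factory=list)
    config: PipelineConfig | None = None

    @property
    def reads_filtered(self) -> int:
        return sum(
            c for s, c in self.filter_counts.items() if s != FilterStatus.PASS
        )


def _paired_reader(in1, in2) -> Iterator[ReadPair]:
    it1 = parse_fastq_stream(in1)
    it2 = parse_fastq_stream(in2)
    for i, (r1, r2) in enumerate(zip_longest(it1, it2)):
        if r1 is None or r2 is None:
            raise FastqFormatError(
                f"pair {i}: mate files desynchronized (unequal record counts)"
            )
        if mate_stem(r1.name) != mate_stem(r2.name):
            raise FastqFormatError(
                f"pair {i}: mate name mismatch '{r1.name}' vs '{r2.name}'"
            )
        yield ReadPair(r1, r2)


def _limit(iterator: Iterator, limit: int) -> Iterator:
    if limit <= 0:
        yield from iterator
        return
    for i, item in enumerate(iterator):
        if i >= limit:
            return
        yield item


@dataclass(slots=True)
class _OutItem:
    """One processed unit, ready for the reassembly stage."""

    verdict: FilterStatus
    r1: ReadRecord | None = None
    r2: ReadRecord | None = None
    merged: ReadRecord | None = None
    dedup_key: str | None = None
    drop_unmerged: bool = False


def _trim_read(
    read: ReadRecord, cfg: PipelineConfig, front: int, tail: int
) -> ReadRecord:
    if front or tail:
        read = _trim.trim_global(read, front, tail)
    if cfg.trim_poly_x:
        read = _trim.trim_polyx(read, None, cfg.poly_x_min_len)
    if cfg.trim_poly_g:
        read = _trim.trim_polyx(read, "G", cfg.poly_g_min_len)
    if cfg.cut_front:
        read = _trim.cut_by_window(read, "front", cfg.cut_window_size, cfg.cut_mean_quality)
    if cfg.cut_tail:
        read = _trim.cut_by_window(read, "tail", cfg.cut_window_size, cfg.cut_mean_quality)
    if cfg.cut_right:
        read = _trim.cut_by_window(read, "right", cfg.cut_window_size, cfg.cut_mean_quality)
    return read


def _process_pair(
    pair: ReadPair,
    cfg: PipelineConfig,
    fcfg: FilterConfig,
    state: WorkerState,
    global_index: int,
) -> _OutItem:
    state.acc_before_r1.accumulate(pair.r1)
    state.acc_before_r2.accumulate(pair.r2)
    if state.overrep_r1 is not None:
        state.overrep_r1.offer(pair.r1, global_index)
        state.overrep_r2.offer(pair.r2, global_index)
    pre_trim_key = pair_key(pair) if cfg.dedup_pre_trim else None
    if cfg.umi:
        pair = _trim.extract_umi(pair, cfg.umi_loc, cfg.umi_len, cfg.umi_skip)
    r1 = _trim_read(pair.r1, cfg, cfg.trim_front1, cfg.trim_tail1)
    r2 = _trim_read(pair.r2, cfg, cfg.trim_front2, cfg.trim_tail2)
    pair = ReadPair(r1, r2)

    ov = None
    if len(r1) and len(r2):
        ov = analyze_overlap(
            pair,
            cfg.overlap_len_require,
            cfg.overlap_diff_limit,
            cfg.overlap_diff_percent_limit,
        )
    if ov is not None:
        record_insert_size(ov, len(r1), len(r2), state.insert_hist)
        if ov.found:
            state.overlap_found_pairs += 1
            if not cfg.disable_correction:
                pair, ncorr = correct_bases(
                    pair, ov, cfg.correction_high_q, cfg.correction_low_q
                )
                if ncorr:
                    state.corrected_bases += ncorr
                    state.corrected_reads += 1
    unclipped = pair
    if not cfg.disable_adapter_trimming:
        if ov is not None and ov.found and ov.offset < 0:
            clipped = clip_adapters_from_overlap(pair, ov)
            removed = (len(pair.r1) - len(clipped.r1)) + (len(pair.r2) - len(clipped.r2))
            if removed:
                state.adapter_trimmed_bases += removed
                state.adapter_trimmed_reads += 2
            pair = clipped
        elif (ov is None or not ov.found) and cfg.adapter_sequence:
            a2 = cfg.adapter_sequence_r2 or cfg.adapter_sequence
            r1, t1 = _trim.trim_adapter_by_sequence(
                pair.r1, cfg.adapter_sequence, cfg.adapter_mismatch_fraction
            )
            r2, t2 = _trim.trim_adapter_by_sequence(
                pair.r2, a2, cfg.adapter_mismatch_fraction
            )
            state.adapter_trimmed_bases += t1 + t2
            state.adapter_trimmed_reads += (t1 > 0) + (t2 > 0)
            pair = ReadPair(r1, r2)

    verdict = _trim.evaluate_filters(pair, fcfg)
    if verdict is not FilterStatus.PASS:
        return _OutItem(verdict)
    key = pre_trim_key if pre_trim_key is not None else pair_key(pair)
    if cfg.merge and ov is not None and ov.found:
        merged = merge_pair(unclipped, ov)
        return _OutItem(FilterStatus.PASS, merged=merged, dedup_key=key)
    drop = cfg.merge and not cfg.include_unmerged
    return _OutItem(
        FilterStatus.PASS, r1=pair.r1, r2=pair.r2, dedup_key=key, drop_unmerged=drop
    )


def _process_single(
    read: ReadRecord,
    cfg: PipelineConfig,
    fcfg: FilterConfig,
    state: WorkerState,
    global_index: int,
) -> _OutItem:
    state.acc_before_r1.accumulate(read)
    if state.overrep_r1 is not None:
        state.overrep_r1.offer(read, global_index)
    pre_trim_key = read.sequence if cfg.dedup_pre_trim else None
    if cfg.umi:
        read = _trim.extract_umi(read, cfg.umi_loc, cfg.umi_len, cfg.umi_skip)
    read = _trim_read(read, cfg, cfg.trim_front1, cfg.trim_tail1)
    if not cfg.disable_adapter_trimming and cfg.adapter_sequence and len(read):
        read, trimmed = _trim.trim_adapter_by_sequence(
            read, cfg.adapter_sequence, cfg.adapter_mismatch_fraction
        )
        state.adapter_trimmed_bases += trimmed
        state.adapter_trimmed_reads += trimmed > 0
    verdict = _trim.evaluate_filters(read, fcfg)
    if verdict is not FilterStatus.PASS:
        return _OutItem(verdict)
    key = pre_trim_key if pre_trim_key is not None else read.sequence
    return _OutItem(FilterStatus.PASS, r1=read, dedup_key=key)


class _Sink:
    """Output file that is opened lazily and gzips when the name ends .gz."""

    def __init__(self, path: str | Path | None, gzip_level: int) -> None:
        self.path = path
        self.gzip_level = gzip_level
        self._fh: IO[bytes] | None = None

    def write(self, record: ReadRecord) -> None:
        if self.path is None:
            return
        if self._fh is None:
            import gzip as _gzip

            if str(self.path).endswith(".gz"):
                raw = open(self.path, "wb")
                self._fh = _gzip.GzipFile(
                    fileobj=raw, mode="wb", compresslevel=self.gzip_level, mtime=0
                )
            else:
                self._fh = open(self.path, "wb")
        self._fh.write(format_record(record).encode("ascii"))

    def close(self) -> None:
        if self._fh is not None:
            self._fh.close()
            self._fh = None


def run_pipeline(
    in1: str | Path | IO[bytes],
    in2: str | Path | IO[bytes] | None = None,
    out1: str | Path | None = None,
    out2: str | Path | None = None,
    merged_out: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full preprocessing pipeline over one input (pair of) file(s).

    Returns a :class:`PipelineResult`; report rendering is a separate step
    (:mod:`seqscrub.report`). Output files are written in ascending pack
    order, so repeated runs and different worker counts produce identical
    bytes.
    """
    cfg = config or PipelineConfig()
    paired = in2 is not None
    fcfg = cfg.filter_config()
    workers = [WorkerState() for _ in range(cfg.worker_count)]
    if cfg.overrepresentation_analysis:
        for w in workers:
            w.overrep_r1 = OverrepresentationTracker(cfg.overrepresentation_sampling)
            w.overrep_r2 = OverrepresentationTracker(cfg.overrepresentation_sampling)
    index = DedupIndex.from_accuracy(cfg.dup_calc_accuracy)
    result = PipelineResult(paired=paired, config=cfg)

    stream: Iterator = (
        _paired_reader(in1, in2) if paired else parse_fastq_stream(in1)
    )
    stream = _limit(stream, cfg.reads_to_process)

    sink1 = _Sink(out1, cfg.gzip_level)
    sink2 = _Sink(out2, cfg.gzip_level)
    sink_m = _Sink(merged_out, cfg.gzip_level)
    try:
        for pack in partition_packs(stream, cfg.pack_capacity):
            state = workers[assign_worker(pack.pack_index, cfg.worker_count)]
            base = pack.pack_index * cfg.pack_capacity
            items = [
                _process_pair(p, cfg, fcfg, state, base + pos)
                if paired
                else _process_single(p, cfg, fcfg, state, base + pos)
                for pos, p in enumerate(pack.records)
            ]
            # ---- in-order reassembly: dedup decision, post-QC, output ----
            for item in items:
                n_reads = 2 if paired else 1
                result.reads_in += n_reads
                if item.verdict is not FilterStatus.PASS:
                    result.filter_counts[item.verdict] += n_reads
                    continue
                duplicate = index.check_and_insert(item.dedup_key)
                if duplicate and cfg.dedup:
                    result.filter_counts[FilterStatus.DUPLICATE] += n_reads
                    continue
                if item.drop_unmerged:
                    result.filter_counts[FilterStatus.PASS] += n_reads
                    result.unmerged_pairs_dropped += 1
                    continue
                result.filter_counts[FilterStatus.PASS] += n_reads
                if item.merged is not None:
                    result.acc_merged.accumulate(item.merged)
                    result.merged_pairs += 1
                    sink_m.write(item.merged)
                    result.reads_written += 1
                    continue
                if item.r1 is not None:
                    result.acc_after_r1.accumulate(item.r1)
                    sink1.write(item.r1)
                    result.reads_written += 1
                if item.r2 is not None:
                    result.acc_after_r2.accumulate(item.r2)
                    sink2.write(item.r2)
                    result.reads_written += 1
                if paired and item.r1 is not None:
                    result.unmerged_pairs_written += 1
    finally:
        sink1.close()
        sink2.close()
        sink_m.close()

    # merge worker-local statistics (associative & commutative)
    for w in workers:
        result.acc_before_r1 = result.acc_before_r1.merge(w.acc_before_r1)
        result.acc_before_r2 = result.acc_before_r2.merge(w.acc_before_r2)
        result.insert_hist = result.insert_hist.merge(w.insert_hist)
        result.adapter_trimmed_reads += w.adapter_trimmed_reads
        result.adapter_trimmed_bases += w.adapter_trimmed_bases
        result.corrected_bases += w.corrected_bases
        result.corrected_reads += w.corrected_reads
        result.overlap_found_pairs += w.overlap_found_pairs
    if cfg.overrepresentation_analysis:
        tr1 = workers[0].overrep_r1
        tr2 = workers[0].overrep_r2
        for w in workers[1:]:
            tr1 = tr1.merge(w.overrep_r1)
            tr2 = tr2.merge(w.overrep_r2)
        result.overrep_r1 = detect_overrepresented(tr1.sampled)
        if paired:
            result.overrep_r2 = detect_overrepresented(tr2.sampled)

    result.duplicates_flagged = index.duplicates_flagged
    if index.reads_seen:
        result.duplication_rate_raw = index.duplication_rate(correct_fp=False)
        result.duplication_rate = index.duplication_rate(correct_fp=True)
    return result
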