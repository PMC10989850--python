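"""Per-read trimming, read filtering and UMI extraction.

Covers global (fixed-length) trimming, sliding-window quality trimming,
polyG/polyX artifact removal, adapter trimming by known sequence, the
qualified-quality / N-count / length filters, and UMI transfer into read
names. All trims remove bases only, truncating sequence and quality in
lockstep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Union

import numpy as np

from .fastq import ReadRecord, ReadPair, phred_scores

__all__ = [
    "TrimConfig",
    "FilterConfig",
    "FilterStatus",
    "ConfigError",
    "trim_global",
    "cut_by_window",
    "trim_polyx",
    "trim_adapter_by_sequence",
    "evaluate_filters",
    "extract_umi",
]


class ConfigError(ValueError):
    """Invalid trimming/filtering configuration."""


@dataclass(slots=True)
class TrimConfig:
    """Trimming parameters (defaults follow common preprocessing practice).

    ``front_trim``/``tail_trim`` are unconditional base counts removed from
    the 5'/3' ends. The sliding-window cuts use ``window_size`` bases and an
    arithmetic-mean Phred threshold ``window_mean_quality``.
    """

    front_trim: int = 0
    tail_trim: int = 0
    window_size: int = 4
    window_mean_quality: float = 20.0
    cut_front: bool = False
    cut_tail: bool = False
    cut_right: bool = False
    polyg_min_len: int = 10
    polyx_min_len: int = 10
    adapter_r1: str | None = None
    adapter_r2: str | None = None
    adapter_mismatch_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.front_trim < 0 or self.tail_trim < 0:
            raise ConfigError("front_trim/tail_trim must be >= 0")
        if self.window_size < 1:
            raise ConfigError("window_size must be >= 1")
        if self.window_mean_quality < 0:
            raise ConfigError("window_mean_quality must be >= 0")
        if self.polyg_min_len < 1 or self.polyx_min_len < 1:
            raise ConfigError("poly run min length must be >= 1")
        if not 0.0 <= self.adapter_mismatch_fraction <= 1.0:
            raise ConfigError("adapter_mismatch_fraction must be in [0, 1]")


@dataclass(slots=True)
class FilterConfig:
    """Read filtering thresholds.

    A read is low-quality when the fraction of bases below ``qualified_phred``
    exceeds ``max_unqualified_fraction``. ``max_length`` of 0 disables the
    upper length bound.
    """

    qualified_phred: int = 15
    max_unqualified_fraction: float = 0.40
    max_n_count: int = 5
    min_length: int = 15
    max_length: int = 0

    def __post_init__(self) -> None:
        if self.qualified_phred < 0:
            raise ConfigError("qualified_phred must be >= 0")
        if not 0.0 <= self.max_unqualified_fraction <= 1.0:
            raise ConfigError("max_unqualified_fraction must be in [0, 1]")
        if self.max_n_count < 0 or self.min_length < 0 or self.max_length < 0:
            raise ConfigError("filter thresholds must be >= 0")


class FilterStatus(str, Enum):
    """Verdict for one read or pair; exactly one status applies."""

    PASS = "pass"
    LOW_QUALITY = "low_quality"
    TOO_MANY_N = "too_many_N"
    TOO_SHORT = "too_short"
    TOO_LONG = "too_long"
    DUPLICATE = "duplicate"


# check order: first failure wins, both for a single read and across a pair
_STATUS_ORDER = (
    FilterStatus.LOW_QUALITY,
    FilterStatus.TOO_MANY_N,
    FilterStatus.TOO_SHORT,
    FilterStatus.TOO_LONG,
)


def trim_global(read: ReadRecord, front: int, tail: int) -> ReadRecord:
    """Remove ``front`` bases from the 5' end and ``tail`` from the 3' end."""
    if front < 0 or tail < 0:
        raise ConfigError("front/tail must be >= 0")
    if front == 0 and tail == 0:
        return read
    stop = len(read) - tail
    if stop <= front:
        return read.slice(0, 0)
    return read.slice(front, stop)


def _window_means(q: np.ndarray, window: int) -> np.ndarray:
    """Mean quality of the window starting at each position (length shrinks
    to the read end)."""
    n = len(q)
    cs = np.concatenate(([0], np.cumsum(q)))
    starts = np.arange(n)
    stops = np.minimum(starts + window, n)
    return (cs[stops] - cs[starts]) / (stops - starts)


def cut_by_window(
    read: ReadRecord, mode: str, window: int, mean_q: float
) -> ReadRecord:
    """Sliding-window quality trimming.

    ``front``: drop 5' bases up to the first window whose mean Phred is
    >= ``mean_q``. ``tail``: the mirror image from the 3' end. ``right``:
    scan 5'->3' and truncate from the start of the first window whose mean
    falls below ``mean_q``. May return an empty read.
    """
    if window < 1:
        raise ConfigError("window must be >= 1")
    n = len(read)
    if n == 0:
        return read
    q = phred_scores(read.quality)
    if mode == "front":
        means = _window_means(q, window)
        good = np.nonzero(means >= mean_q)[0]
        return read.slice(int(good[0])) if len(good) else read.slice(0, 0)
    if mode == "tail":
        means = _window_means(q[::-1], window)
        good = np.nonzero(means >= mean_q)[0]
        return read.slice(0, n - int(good[0])) if len(good) else read.slice(0, 0)
    if mode == "right":
        means = _window_means(q, window)
        bad = np.nonzero(means < mean_q)[0]
        return read.slice(0, int(bad[0])) if len(bad) else read
    raise ConfigError(f"unknown window-cut mode: {mode!r}")


def trim_polyx(
    read: ReadRecord,
    base: str | None,
    min_len: int,
    *,
    allow_mismatches: bool = True,
) -> ReadRecord:
    """Remove a 3'-terminal mononucleotide run of ``base`` (or of any single
    base when ``base`` is None).

    A run of length L tolerates up to L // 8 mismatching bases when
    ``allow_mismatches`` (sequencing errors inside artifact runs are common);
    the run must begin and end on a matching base. Runs shorter than
    ``min_len`` are kept.
    """
    if min_len < 1:
        raise ConfigError("min_len must be >= 1")
    seq = read.sequence
    n = len(seq)
    if n == 0:
        return read
    target = base if base is not None else seq[-1]
    if seq[-1] != target:
        return read
    mismatches = 0
    best = 0
    length = 0
    for i in range(n - 1, -1, -1):
        if seq[i] == target:
            length += 1
            if mismatches <= length // 8:
                best = length
        else:
            # a mismatch counts as part of the run only when the run
            # clearly continues past it: the next 8 bases toward the 5'
            # end must all match the target
            if not allow_mismatches:
                break
            if i < 8 or any(c != target for c in seq[i - 8 : i]):
                break
            mismatches += 1
            length += 1
    if best >= min_len:
        return read.slice(0, n - best)
    return read


def trim_adapter_by_sequence(
    read: ReadRecord, adapter: str, mismatch_fraction: float = 0.2
) -> tuple[ReadRecord, int]:
    """Trim a known adapter sequence from the 3' end of a read.

    Finds the leftmost position ``p`` where the adapter prefix of length
    ``min(len(adapter), len(read) - p)`` matches with at most
    ``floor(mismatch_fraction * matchlen)`` mismatches, requiring at least 4
    matched bases, and truncates the read there. Returns the trimmed read and
    the number of bases removed (0 when no hit).
    """
    if not adapter:
        raise ConfigError("adapter must be non-empty")
    seq = read.sequence
    n, alen = len(seq), len(adapter)
    for p in range(0, n - 3):
        matchlen = min(alen, n - p)
        if matchlen < 4:
            break
        allowed = int(mismatch_fraction * matchlen)
        mismatches = 0
        for i in range(matchlen):
            if seq[p + i] != adapter[i]:
                mismatches += 1
                if mismatches > allowed:
                    break
        else:
            return read.slice(0, p), n - p
    return read, 0


def _read_status(read: ReadRecord, cfg: FilterConfig) -> FilterStatus:
    n = len(read)
    if n > 0:
        q = phred_scores(read.quality)
        unqualified = int(np.count_nonzero(q < cfg.qualified_phred))
        if unqualified / n > cfg.max_unqualified_fraction:
            return FilterStatus.LOW_QUALITY
    if read.sequence.count("N") > cfg.max_n_count:
        return FilterStatus.TOO_MANY_N
    if n < cfg.min_length:
        return FilterStatus.TOO_SHORT
    if cfg.max_length and n > cfg.max_length:
        return FilterStatus.TOO_LONG
    return FilterStatus.PASS


def evaluate_filters(
    item: Union[ReadRecord, ReadPair], cfg: FilterConfig
) -> FilterStatus:
    """Apply the quality/N/length filters; first failing rule wins.

    For a pair the verdict is the earliest-ordered failing rule across both
    mates (a pair fails when either mate fails).
    """
    reads = (item.r1, item.r2) if isinstance(item, ReadPair) else (item,)
    statuses = [_read_status(r, cfg) for r in reads]
    for status in _STATUS_ORDER:
        if status in statuses:
            return status
    return FilterStatus.PASS


def _take_umi(read: ReadRecord, umi_len: int, skip: int) -> tuple[str, ReadRecord]:
    umi = read.sequence[:umi_len]
    return umi, read.slice(umi_len + skip)


def _index_umi(read: ReadRecord, which: int) -> str:
    comment = read.comment or ""
    index_field = comment.rsplit(":", 1)[-1] if comment else ""
    parts = index_field.split("+")
    if len(parts) <= which or not parts[which] or not set(parts[which]) <= set("ACGTN"):
        raise ValueError(
            f"record '{read.name}': comment {comment!r} has no index {which + 1} field"
        )
    return parts[which]


def _append_umi(read: ReadRecord, umi: str) -> ReadRecord:
    from dataclasses import replace

    return replace(read, name=f"{read.name}:{umi}")


def extract_umi(
    item: Union[ReadRecord, ReadPair],
    scheme: str,
    umi_len: int = 0,
    skip: int = 0,
) -> Union[ReadRecord, ReadPair]:
    """Move a unique molecular identifier into the read name(s).

    Read-derived schemes (``read1``, ``read2``, ``per_read``) remove the
    first ``umi_len`` bases (plus ``skip`` discarded bases after them) from
    the designated read(s); the UMI is appended to BOTH mates' names as
    ``:UMI`` (``per_read`` joins the two UMIs with ``_``). Index schemes
    (``index1``, ``index2``) copy the UMI from the comment's index field
    without touching sequences.
    """
    if scheme in ("read1", "read2", "per_read") and umi_len < 1:
        raise ConfigError("umi_len must be >= 1 for read-derived schemes")
    if isinstance(item, ReadRecord):
        if scheme == "read1":
            umi, read = _take_umi(item, umi_len, skip)
            return _append_umi(read, umi)
        if scheme == "index1":
            return _append_umi(item, _index_umi(item, 0))
        raise ConfigError(f"scheme {scheme!r} requires paired-end input")
    r1, r2 = item.r1, item.r2
    if scheme == "read1":
        umi, r1 = _take_umi(r1, umi_len, skip)
    elif scheme == "read2":
        umi, r2 = _take_umi(r2, umi_len, skip)
    elif scheme == "per_read":
        umi1, r1 = _take_umi(r1, umi_len, skip)
        umi2, r2 = _take_umi(r2, umi_len, skip)
        umi = f"{umi1}_{umi2}"
    elif scheme == "index1":
        umi = _index_umi(r1, 0)
    elif scheme == "index2":
        umi = _index_umi(r1, 1)
    else:
        raise ConfigError(f"unknown UMI scheme: {scheme!r}")
    return ReadPair(_append_umi(r1, umi), _append_umi(r2, umi))
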