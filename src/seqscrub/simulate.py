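"""Ground-truthed synthetic paired-end read generator.

Emulates a short-fragment paired-end sequencing library: fragments are
drawn from a fresh random reference with a truncated-normal insert-size
distribution; read 1 is the fragment 5' prefix and read 2 the reverse
complement of its 3' suffix; fragments shorter than the read length run
through into adapter (and random bases beyond it); substitution errors are
planted at a configurable per-base rate and assigned low quality scores;
per-cycle mean quality decays linearly; an exact-duplicate fraction copies
earlier pairs verbatim. Every generated read is reconstructible from the
returned truth table, which is what the pipeline's recovery tests compare
against.

Randomness comes from a single numpy Generator with a fixed draw order
per pair (documented in :func:`simulate`), so a seed fully determines the
corpus.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .fastq import ReadPair, ReadRecord, reverse_complement

__all__ = [
    "SimConfig",
    "PairTruth",
    "simulate",
    "truth_metrics",
    "write_truth_tsv",
    "DEFAULT_ADAPTER_R1",
    "DEFAULT_ADAPTER_R2",
]

# standard Illumina TruSeq adapter sequences (data, not logic)
DEFAULT_ADAPTER_R1 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
DEFAULT_ADAPTER_R2 = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(slots=True)
class SimConfig:
    """Study conditions for the synthetic library.

    Defaults model a modern short-fragment (cfDNA-like) paired-end run:
    150-cycle reads over inserts ~ Normal(170, 35) truncated at 1, 0.1%
    substitution error, per-cycle mean quality decaying 36 -> 32 with sd 2,
    and error bases down-weighted to quality ~ N(8, 2) clipped to [2, 12].
    """

    seed: int = 0
    n_pairs: int = 1000
    read_len: int = 150
    insert_mean: float = 170.0
    insert_sd: float = 35.0
    adapter_r1: str = DEFAULT_ADAPTER_R1
    adapter_r2: str = DEFAULT_ADAPTER_R2
    error_rate: float = 0.001
    qual_start: float = 36.0
    qual_end: float = 32.0
    qual_noise_sd: float = 2.0
    error_qual_mean: float = 8.0
    error_qual_sd: float = 2.0
    duplication_rate: float = 0.0
    polyg_rate: float = 0.0
    polyg_len: int = 12
    umi_len: int = 0
    # reference complexity proxy: long enough that two independent fragments
    # rarely coincide (natural duplicates stay rare, as in a real genome)
    ref_len: int = 200_000

    def __post_init__(self) -> None:
        for name in ("error_rate", "duplication_rate", "polyg_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_pairs < 0 or self.read_len < 1 or self.ref_len < 1:
            raise ValueError("n_pairs/read_len/ref_len out of range")
        if self.umi_len >= self.read_len:
            raise ValueError("umi_len must be smaller than read_len")
        if self.insert_sd < 0:
            raise ValueError("insert_sd must be >= 0")


@dataclass(slots=True)
class PairTruth:
    """Ground truth for one generated pair."""

    index: int
    fragment: str
    insert_size: int
    adapter_start_r1: int | None
    adapter_start_r2: int | None
    is_duplicate: bool
    source_index: int | None
    errors_r1: tuple[int, ...]
    errors_r2: tuple[int, ...]
    umi: str | None
    polyg: bool


def _random_bases(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _quality_string(
    rng: np.random.Generator, cfg: SimConfig, error_positions: np.ndarray
) -> str:
    n = cfg.read_len
    profile = np.linspace(cfg.qual_start, cfg.qual_end, n)
    q = rng.normal(profile, cfg.qual_noise_sd)
    if len(error_positions):
        q[error_positions] = np.clip(
            rng.normal(cfg.error_qual_mean, cfg.error_qual_sd, len(error_positions)),
            2,
            12,
        )
    q = np.clip(np.rint(q), 2, 40).astype(np.uint8) + 33
    return q.tobytes().decode("ascii")


def _inject_errors(
    rng: np.random.Generator, seq: str, error_rate: float
) -> tuple[str, np.ndarray]:
    n = len(seq)
    mask = rng.random(n) < error_rate
    positions = np.nonzero(mask)[0]
    if not len(positions):
        return seq, positions
    chars = list(seq)
    for p in positions:
        original = chars[p]
        choices = [b for b in "ACGT" if b != original]
        chars[p] = choices[int(rng.integers(0, len(choices)))]
    return "".join(chars), positions


def simulate(cfg: SimConfig) -> tuple[list[ReadPair], list[PairTruth]]:
    """Generate a paired-end corpus with its truth table.

    Draw order per pair (fixed so fixtures stay stable as features are
    toggled off): duplicate coin [+ source index], insert size, fragment
    start, adapter-padding bases for each mate (when read-through), UMI
    bases, polyG coin, then per mate: error mask, substituted bases,
    quality noise. The reference itself is drawn first, before any pair.
    """
    rng = np.random.default_rng(cfg.seed)
    reference = _random_bases(rng, cfg.ref_len)
    pairs: list[ReadPair] = []
    truths: list[PairTruth] = []
    eff_len = cfg.read_len - cfg.umi_len  # fragment bases carried per read
    for i in range(cfg.n_pairs):
        if i > 0 and cfg.duplication_rate > 0 and rng.random() < cfg.duplication_rate:
            src = int(rng.integers(0, i))
            origin = truths[src]
            source = pairs[src]
            name = f"sr{i}"
            pairs.append(
                ReadPair(
                    ReadRecord(name, source.r1.sequence, source.r1.quality),
                    ReadRecord(name, source.r2.sequence, source.r2.quality),
                )
            )
            truths.append(
                PairTruth(
                    index=i,
                    fragment=origin.fragment,
                    insert_size=origin.insert_size,
                    adapter_start_r1=origin.adapter_start_r1,
                    adapter_start_r2=origin.adapter_start_r2,
                    is_duplicate=True,
                    source_index=src,
                    errors_r1=origin.errors_r1,
                    errors_r2=origin.errors_r2,
                    umi=origin.umi,
                    polyg=origin.polyg,
                )
            )
            continue
        insert = int(
            np.clip(np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd)), 1, cfg.ref_len)
        )
        start = int(rng.integers(0, cfg.ref_len - insert + 1))
        fragment = reference[start : start + insert]
        # mate cores in their own orientations
        core1 = fragment[:eff_len]
        core2 = reverse_complement(fragment)[:eff_len]
        adapter_start_r1 = adapter_start_r2 = None
        if insert < eff_len:
            pad1 = _random_bases(
                rng, max(0, eff_len - insert - len(cfg.adapter_r1))
            )
            pad2 = _random_bases(
                rng, max(0, eff_len - insert - len(cfg.adapter_r2))
            )
            core1 = (core1 + cfg.adapter_r1 + pad1)[:eff_len]
            core2 = (core2 + cfg.adapter_r2 + pad2)[:eff_len]
            adapter_start_r1 = insert + cfg.umi_len
            adapter_start_r2 = insert
        umi = None
        if cfg.umi_len:
            umi = _random_bases(rng, cfg.umi_len)
            core1 = umi + core1
        polyg = bool(cfg.polyg_rate and rng.random() < cfg.polyg_rate)
        if polyg:
            core1 = core1[: cfg.read_len - cfg.polyg_len] + "G" * cfg.polyg_len
            core2 = core2[: cfg.read_len - cfg.polyg_len] + "G" * cfg.polyg_len
        seq1, err1 = _inject_errors(rng, core1, cfg.error_rate)
        qual1 = _quality_string(rng, cfg, err1)
        seq2, err2 = _inject_errors(rng, core2, cfg.error_rate)
        qual2 = _quality_string(rng, cfg, err2)
        name = f"sr{i}"
        pairs.append(ReadPair(ReadRecord(name, seq1, qual1), ReadRecord(name, seq2, qual2)))
        truths.append(
            PairTruth(
                index=i,
                fragment=fragment,
                insert_size=insert,
                adapter_start_r1=adapter_start_r1,
                adapter_start_r2=adapter_start_r2,
                is_duplicate=False,
                source_index=None,
                errors_r1=tuple(int(p) for p in err1),
                errors_r2=tuple(int(p) for p in err2),
                umi=umi,
                polyg=polyg,
            )
        )
    return pairs, truths


def truth_metrics(truths: list[PairTruth], cfg: SimConfig) -> dict:
    """Closed-form expected values implied by the truth table."""
    n = len(truths)
    duplicates = sum(t.is_duplicate for t in truths)
    insert_hist = Counter(t.insert_size for t in truths)
    adapter_bases = sum(
        2 * max(0, (cfg.read_len - cfg.umi_len) - t.insert_size)
        for t in truths
        if t.adapter_start_r1 is not None
    )
    error_count = sum(len(t.errors_r1) + len(t.errors_r2) for t in truths)
    return {
        "n_pairs": n,
        "duplication_rate": duplicates / n if n else 0.0,
        "insert_histogram": insert_hist,
        "adapter_base_count": adapter_bases,
        "error_count": error_count,
    }


_TRUTH_COLUMNS = (
    "index",
    "insert_size",
    "adapter_start_r1",
    "adapter_start_r2",
    "is_duplicate",
    "source_index",
    "errors_r1",
    "errors_r2",
    "umi",
    "polyg",
    "fragment",
)


def write_truth_tsv(truths: Iterable[PairTruth], path: str | Path) -> None:
    """Write the truth table as TSV (columns documented in the header row)."""
    with open(path, "w", encoding="ascii") as fh:
        fh.write("\t".join(_TRUTH_COLUMNS) + "\n")
        for t in truths:
            fh.write(
                "\t".join(
                    [
                        str(t.index),
                        str(t.insert_size),
                        "" if t.adapter_start_r1 is None else str(t.adapter_start_r1),
                        "" if t.adapter_start_r2 is None else str(t.adapter_start_r2),
                        "1" if t.is_duplicate else "0",
                        "" if t.source_index is None else str(t.source_index),
                        ",".join(map(str, t.errors_r1)),
                        ",".join(map(str, t.errors_r2)),
                        t.umi or "",
                        "1" if t.polyg else "0",
                        t.fragment,
                    ]
                )
                + "\n"
            )
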