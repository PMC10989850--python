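"""FASTQ record model and streaming I/O.

Reads and writes 4-line FASTQ records (Phred+33), transparently handling
gzip-compressed streams detected by their magic bytes. Parsing is strict:
wrapped (multi-line) records, non-ACGTN sequence characters and quality
characters outside the printable Phred+33 range are hard errors that name
the offending record, because silent repair of a corrupt FASTQ poisons
every downstream statistic.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np

__all__ = [
    "ReadRecord",
    "ReadPair",
    "FastqFormatError",
    "parse_fastq_stream",
    "write_fastq_stream",
    "open_fastq",
    "reverse_complement",
    "mate_stem",
    "phred_scores",
]

_GZIP_MAGIC = b"\x1f\x8b"
_UPPER = str.maketrans("acgtn", "ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_SEQ_RE = re.compile(r"[ACGTN]*\Z")


class FastqFormatError(ValueError):
    """Raised for malformed FASTQ input or an invalid record on output."""


@dataclass(slots=True)
class ReadRecord:
    """One FASTQ record.

    ``name`` excludes the leading ``@``; ``comment`` is everything after the
    first whitespace of the header (or ``None``). ``sequence`` is uppercase
    over {A,C,G,T,N} and ``quality`` is the same length, Phred+33.
    """

    name: str
    sequence: str
    quality: str
    comment: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise FastqFormatError(
                f"record '{self.name}': sequence length {len(self.sequence)} "
                f"!= quality length {len(self.quality)}"
            )
        if _SEQ_RE.match(self.sequence) is None:
            raise FastqFormatError(
                f"record '{self.name}': sequence contains characters outside ACGTN"
            )
        try:
            q = self.quality.encode("ascii")
        except UnicodeEncodeError:
            raise FastqFormatError(
                f"record '{self.name}': non-ASCII quality string"
            ) from None
        if q and (min(q) < 33 or max(q) > 126):
            raise FastqFormatError(
                f"record '{self.name}': quality character outside Phred+33 "
                "printable range [33, 126]"
            )

    def header(self) -> str:
        return self.name if self.comment is None else f"{self.name} {self.comment}"

    def slice(self, start: int, stop: int | None = None) -> "ReadRecord":
        """Return a copy truncated to ``sequence[start:stop]`` (quality in lockstep)."""
        return replace(
            self, sequence=self.sequence[start:stop], quality=self.quality[start:stop]
        )


@dataclass(slots=True)
class ReadPair:
    """A synchronized mate pair; both records share the same name stem."""

    r1: ReadRecord
    r2: ReadRecord

    def validate(self) -> None:
        self.r1.validate()
        self.r2.validate()
        if mate_stem(self.r1.name) != mate_stem(self.r2.name):
            raise FastqFormatError(
                f"mate name mismatch: '{self.r1.name}' vs '{self.r2.name}'"
            )


def mate_stem(name: str) -> str:
    """Read name with any trailing ``/1`` or ``/2`` mate suffix stripped."""
    if name.endswith("/1") or name.endswith("/2"):
        return name[:-2]
    return name


def phred_scores(quality: str) -> np.ndarray:
    """Phred scores of a Phred+33 quality string as an int array."""
    return np.frombuffer(quality.encode("ascii"), dtype=np.uint8).astype(np.int64) - 33


def reverse_complement(sequence: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N. Involution."""
    if _SEQ_RE.match(sequence) is None:
        raise ValueError("sequence contains characters outside ACGTN")
    return sequence.translate(_COMPLEMENT)[::-1]


def open_fastq(source: str | Path | IO[bytes]) -> IO[bytes]:
    """Open ``source`` for reading, transparently decompressing gzip.

    gzip is detected from the RFC 1952 magic bytes, never from the filename.
    """
    if isinstance(source, (str, Path)):
        raw: IO[bytes] = open(source, "rb")
    else:
        raw = source
    buffered = raw if isinstance(raw, io.BufferedReader) else io.BufferedReader(raw)  # type: ignore[arg-type]
    if buffered.peek(2)[:2] == _GZIP_MAGIC:
        return gzip.open(buffered, "rb")  # type: ignore[return-value]
    return buffered


def parse_fastq_stream(source: str | Path | IO[bytes]) -> Iterator[ReadRecord]:
    """Yield :class:`ReadRecord` from a plain or gzip FASTQ byte stream.

    Records are strictly 4 lines. Lowercase bases are uppercased. Truncated
    records, missing ``@``/``+`` sentinels, length mismatches and invalid
    characters raise :class:`FastqFormatError` naming the record index.
    """
    stream = open_fastq(source)
    text = io.TextIOWrapper(stream, encoding="ascii", errors="strict")
    index = 0
    while True:
        header = text.readline()
        if header == "":
            return
        lines = [header, text.readline(), text.readline(), text.readline()]
        if "" in lines[1:]:
            raise FastqFormatError(
                f"record {index}: truncated record (line count not divisible by 4)"
            )
        header, seq, plus, qual = (ln.rstrip("\r\n") for ln in lines)
        if not header.startswith("@"):
            raise FastqFormatError(
                f"record {index}: header line does not start with '@' "
                "(wrapped multi-line FASTQ is not supported)"
            )
        if not plus.startswith("+"):
            raise FastqFormatError(
                f"record {index}: separator line does not start with '+'"
            )
        name, _, comment = header[1:].partition(" ")
        if not name:
            # header may use a tab separator instead of a space
            name, _, comment = header[1:].partition("\t")
        record = ReadRecord(
            name=name,
            sequence=seq.translate(_UPPER),
            quality=qual,
            comment=comment or None,
        )
        try:
            record.validate()
        except FastqFormatError as exc:
            raise FastqFormatError(f"record {index}: {exc}") from None
        yield record
        index += 1


def format_record(record: ReadRecord) -> str:
    return f"@{record.header()}\n{record.sequence}\n+\n{record.quality}\n"


def write_fastq_stream(
    records: Iterable[ReadRecord],
    sink: str | Path | IO[bytes],
    *,
    gzip_output: bool = False,
    gzip_level: int = 4,
) -> int:
    """Write records as 4-line FASTQ; returns the number of records written.

    Each record is validated before any of its bytes are written, so an
    invalid record never leaves a partial entry in the output.
    """
    own = isinstance(sink, (str, Path))
    raw: IO[bytes] = open(sink, "wb") if own else sink  # type: ignore[assignment]
    out: IO[bytes]
    if gzip_output:
        # fixed mtime keeps gzip output byte-identical across runs
        out = gzip.GzipFile(fileobj=raw, mode="wb", compresslevel=gzip_level, mtime=0)  # type: ignore[assignment]
    else:
        out = raw
    count = 0
    try:
        for record in records:
            record.validate()
            out.write(format_record(record).encode("ascii"))
            count += 1
    finally:
        if gzip_output:
            out.close()
        if own:
            raw.close()
    return count
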