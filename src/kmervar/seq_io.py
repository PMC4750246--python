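"""Reading and writing of FASTA/FASTQ read sets, gzip-transparent.

Records are streamed (never slurped) so memory use is independent of
file size.  Sequences are uppercased on input and any letter outside
{A, C, G, T} is normalized to ``N``; the k-mer layer skips windows
containing ``N`` uniformly.  Quality strings are carried verbatim but
never interpreted: all downstream methods operate on raw reads without
pretreatment.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass
from typing import IO, Iterable, Iterator

__all__ = [
    "SequenceRecord",
    "FormatError",
    "read_sequences",
    "write_fasta",
    "write_fastq",
]

_GZIP_MAGIC = b"\x1f\x8b"

# uppercase + normalize non-ACGT letters to N
_NORMALIZE = bytes.maketrans(
    bytes(range(256)),
    bytes(
        ord(chr(b).upper()) if chr(b).upper() in "ACGT" else ord("N")
        for b in range(256)
    ),
)


class FormatError(ValueError):
    """Raised for malformed FASTA/FASTQ content."""


@dataclass
class SequenceRecord:
    """One read or sequence: identifier, bases, optional quality.

    ``identifier`` is the header token up to the first whitespace.
    ``quality`` is present iff the record came from / goes to FASTQ and
    has the same length as ``sequence``.
    """

    identifier: str
    sequence: str
    quality: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)


def _normalize(seq: str) -> str:
    return seq.translate(_NORMALIZE)


def _open_text(path: str | os.PathLike) -> IO[str]:
    """Open ``path`` for text reading, unwrapping gzip by magic bytes."""
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == _GZIP_MAGIC:
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw))
    return io.TextIOWrapper(raw)


def _parse_fasta(handle: IO[str], path: str) -> Iterator[SequenceRecord]:
    ident: str | None = None
    chunks: list[str] = []
    ordinal = 0
    for line in handle:
        line = line.rstrip("\n").rstrip("\r")
        if not line:
            continue
        if line.startswith(">"):
            if ident is not None:
                ordinal += 1
                yield _make_fasta_record(ident, chunks, ordinal, path)
            ident = line[1:].split()[0] if len(line) > 1 else ""
            chunks = []
        else:
            if ident is None:
                raise FormatError(f"{path}: sequence data before first header")
            chunks.append(line)
    if ident is not None:
        ordinal += 1
        yield _make_fasta_record(ident, chunks, ordinal, path)


def _make_fasta_record(
    ident: str, chunks: list[str], ordinal: int, path: str
) -> SequenceRecord:
    seq = _normalize("".join(chunks))
    if not seq:
        raise FormatError(f"{path}: record {ordinal} ({ident!r}) has empty sequence")
    if not ident:
        raise FormatError(f"{path}: record {ordinal} has empty identifier")
    return SequenceRecord(ident, seq)


def _parse_fastq(handle: IO[str], path: str) -> Iterator[SequenceRecord]:
    ordinal = 0
    while True:
        header = handle.readline()
        if not header:
            return
        header = header.rstrip("\n").rstrip("\r")
        if not header:
            continue
        ordinal += 1
        if not header.startswith("@"):
            raise FormatError(
                f"{path}: record {ordinal} header does not start with '@'"
            )
        ident = header[1:].split()[0] if len(header) > 1 else ""
        seq = handle.readline().rstrip("\n").rstrip("\r")
        plus = handle.readline()
        qual = handle.readline().rstrip("\n").rstrip("\r")
        if not plus.startswith("+"):
            raise FormatError(f"{path}: record {ordinal} missing '+' separator line")
        if not seq:
            raise FormatError(f"{path}: record {ordinal} ({ident!r}) has empty sequence")
        if len(qual) != len(seq):
            raise FormatError(
                f"{path}: record {ordinal} ({ident!r}) quality length "
                f"{len(qual)} != sequence length {len(seq)}"
            )
        if not ident:
            raise FormatError(f"{path}: record {ordinal} has empty identifier")
        yield SequenceRecord(ident, _normalize(seq), qual)


def read_sequences(path: str | os.PathLike) -> Iterator[SequenceRecord]:
    """Stream records from a FASTA or FASTQ file, gzipped or not.

    The format is auto-detected from the first byte after the optional
    gzip layer ('>' means FASTA, '@' means FASTQ) — never from the file
    extension.  Records are yielded in file order; multi-line FASTA
    sequences are joined; sequences are uppercased with non-ACGT letters
    turned into ``N``.
    """
    handle = _open_text(path)
    try:
        # skip '#' comment/header lines before sniffing the format byte
        pos = handle.tell()
        line = handle.readline()
        while line and (line.startswith("#") or not line.strip()):
            pos = handle.tell()
            line = handle.readline()
        if not line:
            return
        handle.seek(pos)
        first = line[0]
        if first == ">":
            yield from _parse_fasta(handle, str(path))
        elif first == "@":
            yield from _parse_fastq(handle, str(path))
        else:
            raise FormatError(
                f"{path}: unrecognized format (first byte {first!r}; "
                "expected '>' for FASTA or '@' for FASTQ)"
            )
    finally:
        handle.close()


def write_fasta(
    records: Iterable[SequenceRecord],
    path: str | os.PathLike,
    line_width: int = 0,
    header_lines: Iterable[str] = (),
) -> int:
    """Write records as FASTA; return the number written.

    ``line_width`` 0 writes each sequence on a single line; otherwise
    sequences are wrapped at ``line_width`` characters.  ``header_lines``
    are emitted first, each prefixed by ``#`` (parsers here skip them).
    """
    if line_width < 0:
        raise ValueError("line_width must be >= 0")
    n = 0
    with open(path, "w") as out:
        for line in header_lines:
            out.write(f"#{line}\n")
        for rec in records:
            out.write(f">{rec.identifier}\n")
            if line_width == 0:
                out.write(rec.sequence + "\n")
            else:
                for i in range(0, len(rec.sequence), line_width):
                    out.write(rec.sequence[i : i + line_width] + "\n")
            n += 1
    return n


def write_fastq(
    records: Iterable[SequenceRecord], path: str | os.PathLike
) -> int:
    """Write records as 4-line FASTQ; return the number written.

    Records lacking a quality string get a constant maximal quality.
    """
    n = 0
    with open(path, "w") as out:
        for rec in records:
            qual = rec.quality if rec.quality is not None else "I" * len(rec.sequence)
            out.write(f"@{rec.identifier}\n{rec.sequence}\n+\n{qual}\n")
            n += 1
    return n
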