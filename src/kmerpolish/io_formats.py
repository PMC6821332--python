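"""Readers and writers for the plain-text formats the pipeline touches.

FASTA/FASTQ parsing is streaming and gzip-transparent, and parse errors carry
the offending line number.  FASTQ quality strings are read for validation and
then discarded — the polisher uses no base qualities.  The change log is a
tab-separated file; edits can also be exported as left-anchored VCF 4.2.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from .editor import EditRecord

log = logging.getLogger(__name__)

__all__ = [
    "SeqRecord",
    "FastxParseError",
    "read_fasta",
    "read_fastq",
    "read_fastx",
    "write_fasta",
    "write_fastq",
    "write_changes_tsv",
    "read_changes_tsv",
    "write_vcf",
]

CHANGES_COLUMNS = ("contig", "position", "kind", "ref", "alt", "n_missing", "n_support")


class FastxParseError(ValueError):
    """Malformed FASTA/FASTQ input; the message names the line."""


@dataclass
class SeqRecord:
    """One sequence: id is the first whitespace-delimited header token."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be nonempty")
        if not self.seq:
            warnings.warn(f"record {self.id!r} has an empty sequence", stacklevel=2)

    def __len__(self) -> int:
        return len(self.seq)


def _open_text(path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b" or path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _split_header(line: str) -> tuple[str, str]:
    parts = line[1:].strip().split(None, 1)
    if not parts:
        raise FastxParseError("empty header")
    return parts[0], parts[1] if len(parts) > 1 else ""


def read_fasta(path) -> Iterator[SeqRecord]:
    """Stream records from a (possibly gzipped, possibly CRLF) FASTA file."""
    with _open_text(path) as fh:
        name = desc = None
        chunks: list[str] = []
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    yield SeqRecord(name, "".join(chunks), desc)
                try:
                    name, desc = _split_header(line)
                except FastxParseError as exc:
                    raise FastxParseError(f"{path}: line {lineno}: {exc}") from None
                chunks = []
            else:
                if name is None:
                    raise FastxParseError(
                        f"{path}: line {lineno}: sequence data before any '>' header"
                    )
                chunks.append(line)
        if name is not None:
            yield SeqRecord(name, "".join(chunks), desc)


def read_fastq(path) -> Iterator[SeqRecord]:
    """Stream records from a 4-line FASTQ file; qualities validated, then dropped."""
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\r\n")
            if not header:
                continue
            if not header.startswith("@"):
                raise FastxParseError(
                    f"{path}: line {lineno}: expected '@' record header, got {header[:20]!r}"
                )
            seq = fh.readline().rstrip("\r\n")
            plus = fh.readline().rstrip("\r\n")
            qual = fh.readline().rstrip("\r\n")
            if not qual and not plus:
                raise FastxParseError(f"{path}: line {lineno}: truncated FASTQ record")
            lineno += 3
            if not plus.startswith("+"):
                raise FastxParseError(f"{path}: line {lineno - 1}: expected '+' separator")
            if len(seq) != len(qual):
                raise FastxParseError(
                    f"{path}: line {lineno}: quality length {len(qual)} != "
                    f"sequence length {len(seq)}"
                )
            name, desc = _split_header(header)
            yield SeqRecord(name, seq, desc)


def read_fastx(path) -> Iterator[SeqRecord]:
    """FASTA or FASTQ, sniffed from the first record character."""
    with _open_text(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line[0]
                break
    if first == ">":
        return read_fasta(path)
    if first == "@":
        return read_fastq(path)
    raise FastxParseError(f"{path}: not FASTA or FASTQ (first record char {first!r})")


def write_fasta(records: Iterable[SeqRecord], path, wrap: int = 60) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), wrap):
                fh.write(rec.seq[i : i + wrap] + "\n")


def write_fastq(records: Iterable[SeqRecord], path, quality_char: str = "I") -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{quality_char * len(rec.seq)}\n")


# -- change log -----------------------------------------------------------

def _field(value: str) -> str:
    # empty ref/alt (insertions/deletions) are written as "." in the TSV
    return value if value else "."


def write_changes_tsv(records: Iterable[EditRecord], path) -> None:
    with open(path, "wt") as fh:
        fh.write("\t".join(CHANGES_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.contig}\t{r.position}\t{r.kind}\t{_field(r.ref)}\t{_field(r.alt)}"
                f"\t{r.n_missing}\t{r.n_support}\n"
            )


def read_changes_tsv(path) -> list[EditRecord]:
    out: list[EditRecord] = []
    with open(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != CHANGES_COLUMNS:
            raise ValueError(f"{path}: unexpected change-log header {header}")
        for line in fh:
            if not line.strip():
                continue
            contig, pos, kind, ref, alt, n_miss, n_sup = line.rstrip("\n").split("\t")
            out.append(
                EditRecord(
                    contig=contig,
                    position=int(pos),
                    kind=kind,
                    ref="" if ref == "." else ref,
                    alt="" if alt == "." else alt,
                    n_missing=int(n_miss),
                    n_support=int(n_sup),
                )
            )
    return out


# -- VCF ------------------------------------------------------------------

def _check_ref(draft_seq: str, record: EditRecord) -> None:
    start = record.position - 1
    observed = draft_seq[start : start + len(record.ref)]
    if observed != record.ref:
        raise ValueError(
            f"edit at {record.contig}:{record.position} claims ref {record.ref!r} "
            f"but draft has {observed!r}"
        )


def write_vcf(records: Iterable[EditRecord], draft: Iterable[SeqRecord], path) -> None:
    """Emit edits as VCF 4.2 against the original draft.

    Indels follow the VCF convention: anchored on the base before the event
    (or the base after, for events at position 1).  Every line is validated
    against the draft sequence before it is written.
    """
    seqs = {rec.id: rec.seq for rec in draft}
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=kmerpolish\n")
        fh.write('##INFO=<ID=TYPE,Number=1,Type=String,Description="Edit kind">\n')
        for name, seq in seqs.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            if r.contig not in seqs:
                raise ValueError(f"edit references unknown contig {r.contig!r}")
            seq = seqs[r.contig]
            _check_ref(seq, r)
            if r.kind == "substitution":
                pos, ref, alt = r.position, r.ref, r.alt
            elif r.kind == "deletion":
                if r.position > 1:
                    anchor = seq[r.position - 2]
                    pos, ref, alt = r.position - 1, anchor + r.ref, anchor
                else:  # deletion at contig start: anchor on the following base
                    anchor = seq[r.position - 1 + len(r.ref)]
                    pos, ref, alt = 1, r.ref + anchor, anchor
            elif r.kind == "insertion":
                if r.position > 1:
                    anchor = seq[r.position - 2]
                    pos, ref, alt = r.position - 1, anchor, anchor + r.alt
                else:
                    anchor = seq[0]
                    pos, ref, alt = 1, anchor, r.alt + anchor
            else:
                raise ValueError(f"unknown edit kind {r.kind!r}")
            fh.write(
                f"{r.contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\tTYPE={r.kind}\n"
            )
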