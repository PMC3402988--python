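"""FASTA input/output and tabular writers.

Parsing goes through Biopython's SeqIO (line-wrap and CRLF tolerant);
sequences are uppercased and validated against {A, C, G, T}.  The
``ambiguous`` policy decides what happens to other symbols:

* ``error`` (default) — reject, naming the record and 1-based position;
* ``split`` — break the record at ambiguous symbols into maximal clean
  runs, each becoming its own record with the original interval recorded
  in its id (``<id>:<start>-<end>``, 1-based inclusive).

All library coordinates are 1-based inclusive; the BED writers convert
to 0-based half-open at this boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .encoding import CgrIndex
from .sequences import SequenceError, split_ambiguous, validate

__all__ = [
    "FastaRecord",
    "read_fasta",
    "write_fasta",
    "to_bed",
    "from_bed",
    "dump_coords",
]


@dataclass(frozen=True)
class FastaRecord:
    id: str
    sequence: str


def read_fasta(path, ambiguous: str = "error") -> list[FastaRecord]:
    """Parse a (multi-record) FASTA file into validated records."""
    if ambiguous not in ("error", "split"):
        raise ValueError(f"unknown ambiguity policy {ambiguous!r}")
    records: list[FastaRecord] = []
    seen: set[str] = set()
    try:
        raw = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise SequenceError(f"{path}: not a valid FASTA file ({exc})") from exc
    if not raw:
        with open(path) as fh:
            if fh.read().strip():
                raise SequenceError(f"{path}: not a FASTA file (no '>' header found)")
    for rec in raw:
        if not rec.id:
            raise SequenceError(f"{path}: record with empty id")
        if rec.id in seen:
            raise SequenceError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if ambiguous == "error":
            records.append(FastaRecord(rec.id, validate(seq, record=rec.id)))
        else:
            runs = split_ambiguous(seq)
            if len(runs) == 1 and runs[0][0] == 1 and len(runs[0][1]) == len(seq):
                records.append(FastaRecord(rec.id, runs[0][1]))
            else:
                for start, run in runs:
                    rid = f"{rec.id}:{start}-{start + len(run) - 1}"
                    records.append(FastaRecord(rid, run))
    return records


def write_fasta(records: Iterable[FastaRecord], path, width: int = 70) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def to_bed(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return (start - 1, end)


def from_bed(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return (start + 1, end)


def dump_coords(index: CgrIndex, out: TextIO) -> None:
    """TSV coordinate dump: position, symbol, x1, x2 (digit strings on
    the exact backend).  Row 0 is the initial point x0."""
    out.write("# position\tsymbol\tx1\tx2\n")
    if index.backend == "exact":
        for i in range(index.N + 1):
            sym = index.seq[i - 1] if i else "."
            c = index.exact_coordinate(i)
            out.write(f"{i}\t{sym}\t{c.digits(1)}\t{c.digits(2)}\n")
    else:
        for i in range(index.N + 1):
            sym = index.seq[i - 1] if i else "."
            x, y = index.coordinate(i)
            out.write(f"{i}\t{sym}\t{x:.17g}\t{y:.17g}\n")
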