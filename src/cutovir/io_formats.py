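"""Readers and writers for the formats the pipeline exchanges.

Genomes travel as FASTA; everything derived (alignments, abundance
matrices, host links, VHR tables) travels as plain TSV with a fixed
header so that runs are bit-reproducible and diffable.  All genomic
coordinates are 0-based, half-open.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

VALID_ROLES = ("viral_bin", "rmag", "contig")
_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    """A named nucleotide sequence: a viral bin, an rMAG, or a contig."""

    id: str
    seq: str
    role: str = "contig"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("GenomeRecord id must be nonempty")
        if not self.seq:
            raise ValueError(f"GenomeRecord {self.id!r}: empty sequence")
        bad = set(self.seq) - _ALPHABET
        if bad:
            raise ValueError(
                f"GenomeRecord {self.id!r}: invalid characters {sorted(bad)!r}"
            )
        if self.role not in VALID_ROLES:
            raise ValueError(f"GenomeRecord {self.id!r}: unknown role {self.role!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-to-reference alignment, the tabular stand-in for a BAM line.

    ``matches / aligned_len`` is the percent identity of the alignment and
    ``aligned_len / query_len`` the aligned fraction of the read; the
    coverage filters are predicates over those two ratios.
    """

    query_id: str
    target_id: str
    query_len: int
    target_start: int
    target_end: int
    aligned_len: int
    matches: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.target_start < self.target_end):
            raise ValueError(
                f"alignment {self.query_id}->{self.target_id}: bad interval "
                f"[{self.target_start}, {self.target_end})"
            )
        if self.matches > self.aligned_len:
            raise ValueError(
                f"alignment {self.query_id}->{self.target_id}: "
                f"matches {self.matches} > aligned_len {self.aligned_len}"
            )
        if self.aligned_len < 1 or self.query_len < 1:
            raise ValueError("aligned_len and query_len must be positive")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_len

    @property
    def query_fraction(self) -> float:
        return self.aligned_len / self.query_len


ALIGNMENT_COLUMNS = (
    "query_id",
    "target_id",
    "query_len",
    "target_start",
    "target_end",
    "aligned_len",
    "matches",
    "strand",
)


def read_fasta(path: str | Path, role: str = "contig") -> list[GenomeRecord]:
    """Read a multi-record FASTA file into GenomeRecords.

    Sequences are upper-cased, record order is preserved, and duplicate
    ids raise a ValueError naming the offending id.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for FASTA id {rec.id!r} in {path}")
        records.append(GenomeRecord(rec.id, seq, role))
    return records


def write_fasta(
    records: Sequence[GenomeRecord], path: str | Path, width: int = 80
) -> None:
    """Write records as wrapped FASTA; byte-deterministic for fixed input."""
    if width < 1:
        raise ValueError("width must be >= 1")
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_alignment_table(path: str | Path) -> list[AlignmentRecord]:
    """Parse the 8-column alignment TSV (header optional).

    Malformed rows raise a ValueError carrying the 1-based line number.
    """
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0] == "query_id":
                continue  # header
            if len(parts) != 8:
                raise ValueError(
                    f"{path}:{lineno}: expected 8 tab-separated fields, "
                    f"got {len(parts)}"
                )
            try:
                rec = AlignmentRecord(
                    query_id=parts[0],
                    target_id=parts[1],
                    query_len=int(parts[2]),
                    target_start=int(parts[3]),
                    target_end=int(parts[4]),
                    aligned_len=int(parts[5]),
                    matches=int(parts[6]),
                    strand=parts[7],
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def _format_value(value: object) -> str:
    if isinstance(value, float):
        return repr(value)  # full precision round-trip
    if isinstance(value, (set, frozenset)):
        return ",".join(str(v) for v in sorted(value))
    if isinstance(value, (tuple, list)):
        return ",".join(str(v) for v in value)
    return str(value)


def write_table(rows: Sequence, path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write homogeneous records (dataclasses or dicts) as a headered TSV.

    Column order follows dataclass field order (or the first dict's key
    order); floats are serialized with repr so numbers round-trip.
    Empty input yields a header-only file when columns are given, or an
    empty file otherwise.
    """
    if columns is None:
        if rows:
            first = rows[0]
            if dataclasses.is_dataclass(first):
                columns = [f.name for f in dataclasses.fields(first)]
            else:
                columns = list(first.keys())
        else:
            columns = []
    with open(path, "w") as fh:
        if columns:
            fh.write("\t".join(columns) + "\n")
        for row in rows:
            if dataclasses.is_dataclass(row):
                row = dataclasses.asdict(row)
            fh.write("\t".join(_format_value(row[c]) for c in columns) + "\n")


def read_table(path: str | Path) -> list[dict]:
    """Read a headered TSV back into dicts with int/float inference."""
    out: list[dict] = []
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            return out
        columns = header_line.split("\t")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            row: dict = {}
            for key, raw in zip(columns, parts):
                row[key] = _infer(raw)
            out.append(row)
    return out


def _infer(raw: str):
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            continue
    return raw
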