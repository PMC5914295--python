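"""Readers/writers for the sequence, alignment, interval and tabular formats
used by the pipeline, plus region-string/coordinate conversion.

Conventions
-----------
* Internal coordinates are 0-based half-open everywhere.
* Region strings at CLI/report boundaries are 1-based inclusive
  (``chrom:start-end``).
* The SAM reader accepts a minimal dialect: optional header, the 11
  mandatory columns, CIGAR ops restricted to ``M I D S N = X``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "GenomicInterval",
    "SampleDesign",
    "AlignedRead",
    "FastqRead",
    "ParseError",
    "parse_region",
    "format_region",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_alignments",
    "write_alignments",
    "read_site_mask",
    "read_design_table",
    "write_design_table",
]

_CIGAR_OPS = set("MIDSN=X")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


class ParseError(ValueError):
    """Raised when an input file or region string cannot be parsed."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named reference sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def __len__(self) -> int:
        return self.length()


@dataclass(frozen=True)
class SampleDesign:
    """One sample in the experimental design: id, genotype label, data path."""

    sample_id: str
    genotype: str
    path: str = ""


@dataclass
class AlignedRead:
    """A mapped (or unmapped) read in SAM orientation.

    ``seq``/``quals`` are stored reference-forward, as in SAM: for a
    reverse-strand read they are the reverse complement / reversal of the
    sequenced bases.
    """

    name: str
    flag: int
    chrom: str
    start: int  # 0-based leftmost mapped position
    mapq: int
    cigar: str
    seq: str
    quals: list[int] = field(default_factory=list)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & 0x4)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & 0x10)

    @property
    def strand(self) -> str:
        return "-" if self.is_reverse else "+"

    def cigar_tuples(self) -> list[tuple[str, int]]:
        return parse_cigar(self.cigar)


@dataclass
class FastqRead:
    name: str
    seq: str
    quals: list[int]


# ---------------------------------------------------------------------------
# region strings
# ---------------------------------------------------------------------------

_REGION_RE = re.compile(r"^(?P<chrom>[^:\s]+):(?P<a>-?\d+)-(?P<b>-?\d+)$")


def parse_region(text: str) -> GenomicInterval:
    """Parse a ``chrom:a-b`` region string (1-based inclusive) to an interval.

    >>> parse_region("chrX:147169590-147169767").length()
    178
    """
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise ParseError(f"malformed region string: {text!r}")
    a, b = int(m.group("a")), int(m.group("b"))
    if a <= 0 or b <= 0:
        bad = m.group("a") if a <= 0 else m.group("b")
        raise ParseError(f"non-positive coordinate {bad!r} in region {text!r}")
    if a > b:
        raise ParseError(f"start {a} exceeds end {b} in region {text!r}")
    return GenomicInterval(m.group("chrom"), a - 1, b)


def format_region(interval: GenomicInterval) -> str:
    """Inverse of :func:`parse_region`: 1-based inclusive display form."""
    return f"{interval.chrom}:{interval.start + 1}-{interval.end}"


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} map."""
    seqs: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                if name is None:
                    raise ParseError(f"{path}: sequence before first header")
                chunks.append(line.strip())
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    """Iterate over a 4-line-record FASTQ file (Sanger Phred+33 qualities)."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\n")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ParseError(f"{path}: malformed FASTQ record at {header!r}")
            if len(seq) != len(qual):
                raise ParseError(f"{path}: quality/sequence length mismatch at {header!r}")
            yield FastqRead(header[1:].split()[0], seq, [ord(c) - 33 for c in qual])


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.name}\n{r.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# SAM (minimal dialect)
# ---------------------------------------------------------------------------


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    """Parse a CIGAR string into (op, length) tuples, validating the dialect."""
    if cigar == "*":
        return []
    out: list[tuple[str, int]] = []
    pos = 0
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != pos:
            raise ParseError(f"malformed CIGAR {cigar!r}")
        op = m.group(2)
        if op not in _CIGAR_OPS:
            raise ParseError(f"unsupported CIGAR op {op!r} in {cigar!r}")
        out.append((op, int(m.group(1))))
        pos = m.end()
    if pos != len(cigar):
        raise ParseError(f"malformed CIGAR {cigar!r}")
    return out


class AlignmentReader:
    """Iterate SAM records, skipping (and counting) unmapped/malformed ones."""

    def __init__(self, path: str | Path, reference: Mapping[str, str] | None = None):
        self.path = Path(path)
        self.reference = reference
        self.n_unmapped = 0
        self.n_malformed = 0
        self.n_yielded = 0

    def __iter__(self) -> Iterator[AlignedRead]:
        with open(self.path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("@"):
                    continue
                fields = line.split("\t")
                if len(fields) < 11:
                    self.n_malformed += 1
                    continue
                try:
                    rec = self._parse_fields(fields)
                except ParseError:
                    self.n_malformed += 1
                    continue
                if rec.is_unmapped or rec.chrom == "*":
                    self.n_unmapped += 1
                    continue
                if self.reference is not None and rec.chrom not in self.reference:
                    raise ParseError(
                        f"{self.path}:{lineno}: reference {rec.chrom!r} not in FASTA"
                    )
                self.n_yielded += 1
                yield rec

    @staticmethod
    def _parse_fields(fields: list[str]) -> AlignedRead:
        try:
            flag = int(fields[1])
            pos1 = int(fields[3])
            mapq = int(fields[4])
        except ValueError as exc:
            raise ParseError(str(exc)) from exc
        cigar = fields[5]
        parse_cigar(cigar)  # dialect check
        seq = fields[9]
        qual = fields[10]
        quals = [] if qual == "*" else [ord(c) - 33 for c in qual]
        if quals and len(quals) != len(seq):
            raise ParseError("quality length mismatch")
        return AlignedRead(
            name=fields[0],
            flag=flag,
            chrom=fields[2],
            start=pos1 - 1,
            mapq=mapq,
            cigar=cigar,
            seq=seq,
            quals=quals,
        )


def read_alignments(
    path: str | Path, reference: Mapping[str, str] | None = None
) -> AlignmentReader:
    """Open a SAM file for iteration; skip counts live on the returned reader."""
    return AlignmentReader(path, reference)


def write_alignments(
    records: Iterable[AlignedRead],
    path: str | Path,
    reference: Mapping[str, str] | None = None,
) -> None:
    """Write records as SAM with an @SQ header when a reference is given."""
    with open(path, "w") as fh:
        if reference is not None:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            for name, seq in reference.items():
                fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for r in records:
            qual = "".join(chr(q + 33) for q in r.quals) if r.quals else "*"
            chrom = r.chrom if r.chrom else "*"
            pos1 = r.start + 1 if not r.is_unmapped else 0
            fh.write(
                "\t".join(
                    [
                        r.name,
                        str(r.flag),
                        chrom,
                        str(pos1),
                        str(r.mapq),
                        r.cigar if r.cigar else "*",
                        "*",
                        "0",
                        "0",
                        r.seq,
                        qual,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# site masks and design tables
# ---------------------------------------------------------------------------


def read_site_mask(path: str | Path) -> set[tuple[str, int]]:
    """Read a known-variant mask into a set of (chrom, 0-based position).

    Autodetects by column count: 3+ columns are BED intervals (0-based
    half-open); 2 columns are chrom plus a 1-based position.
    """
    mask: set[tuple[str, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) >= 3:
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
                if start >= end:
                    raise ParseError(
                        f"{path}:{lineno}: start {start} >= end {end}"
                    )
                mask.update((fields[0], p) for p in range(start, end))
            elif len(fields) == 2:
                try:
                    pos1 = int(fields[1])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: {exc}") from exc
                if pos1 <= 0:
                    raise ParseError(f"{path}:{lineno}: non-positive position {pos1}")
                mask.add((fields[0], pos1 - 1))
            else:
                raise ParseError(f"{path}:{lineno}: expected >= 2 columns")
    return mask


def read_design_table(path: str | Path) -> list[SampleDesign]:
    """Read a TSV design table with header ``sample_id\\tgenotype\\tpath``."""
    designs: list[SampleDesign] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["sample_id", "genotype"]:
            raise ParseError(
                f"{path}: expected header starting 'sample_id\\tgenotype', got {header}"
            )
        has_path = len(header) >= 3 and header[2] == "path"
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected >= 2 columns")
            designs.append(
                SampleDesign(
                    sample_id=fields[0],
                    genotype=fields[1],
                    path=fields[2] if has_path and len(fields) > 2 else "",
                )
            )
    ids = [d.sample_id for d in designs]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate sample_id values")
    return designs


def write_design_table(designs: Iterable[SampleDesign], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgenotype\tpath\n")
        for d in designs:
            fh.write(f"{d.sample_id}\t{d.genotype}\t{d.path}\n")
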