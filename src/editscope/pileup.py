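"""Fixture-scale ungapped aligner and strand-resolved pileup engine.

The aligner places reads by exact-match anchor search over both strands and
reports the placement maximizing matches; it exists so fixture data can be
pushed through the pipeline without an external aligner. Real data enters
via SAM (see :mod:`editscope.io_formats`). The pileup engine tallies
per-position, per-strand base counts with per-observation quality, in-read
offset and distance to the nearest read end.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

from editscope.io_formats import AlignedRead, FastqRead
from editscope.synthetic_data import revcomp

__all__ = [
    "Observation",
    "PileupColumn",
    "align_fixture_reads",
    "build_pileup",
    "write_pileup_tsv",
    "read_pileup_tsv",
]

DEFAULT_MIN_BASE_QUALITY = 20
_BASES = "ACGT"


class Observation(NamedTuple):
    """One read base at one reference position."""

    base: str
    quality: int
    offset: int  # in-read offset in sequencing order (cycle index)
    dist_end: int  # distance to the nearest read end
    strand: str


@dataclass
class PileupColumn:
    """Strand-resolved base tallies at one reference position."""

    chrom: str
    position: int  # 0-based
    ref_base: str
    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    observations: list[Observation] = field(default_factory=list)
    n_filtered: int = 0

    def count(self, strand: str, base: str) -> int:
        return self.counts.get((strand, base), 0)

    def depth(self) -> int:
        """Quality-passed coverage (all bases, both strands)."""
        return sum(self.counts.values())

    def base_count(self, base: str) -> int:
        return self.count("+", base) + self.count("-", base)

    def add(self, obs: Observation) -> None:
        self.observations.append(obs)
        key = (obs.strand, obs.base)
        self.counts[key] = self.counts.get(key, 0) + 1


# ---------------------------------------------------------------------------
# fixture aligner
# ---------------------------------------------------------------------------


def _anchor_index(
    reference: Mapping[str, str], anchor_len: int
) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for chrom, seq in reference.items():
        seq = seq.upper()
        for i in range(len(seq) - anchor_len + 1):
            index[seq[i : i + anchor_len]].append((chrom, i))
    return index


def _count_matches(read: str, ref: str, start: int) -> int:
    segment = ref[start : start + len(read)]
    return sum(a == b for a, b in zip(read, segment))


def align_fixture_reads(
    reads: Iterable[FastqRead],
    reference: Mapping[str, str],
    anchor_len: int = 20,
    max_mismatch_frac: float = 0.2,
) -> list[AlignedRead]:
    """Ungapped placement of substitution-only reads on a small reference.

    Every non-overlapping ``anchor_len`` window of the read is looked up in
    an exact-match index of both reference strands; candidate placements are
    scored by match count and the unique maximum wins. Reads with no anchor
    hit, an ambiguous best placement, or too many mismatches are emitted
    unmapped (flag 0x4) so callers can count them.
    """
    refs_upper = {c: s.upper() for c, s in reference.items()}
    index = _anchor_index(refs_upper, anchor_len)
    out: list[AlignedRead] = []
    for read in reads:
        rec = _place_read(read, refs_upper, index, anchor_len, max_mismatch_frac)
        out.append(rec)
    return out


def _place_read(
    read: FastqRead,
    refs: Mapping[str, str],
    index: Mapping[str, list[tuple[str, int]]],
    anchor_len: int,
    max_mismatch_frac: float,
) -> AlignedRead:
    n = len(read.seq)
    if anchor_len > n:
        raise ValueError(f"anchor_len {anchor_len} exceeds read length {n}")
    candidates: set[tuple[str, int, str]] = set()
    for strand in ("+", "-"):
        seq = read.seq.upper() if strand == "+" else revcomp(read.seq.upper())
        offs = list(range(0, n - anchor_len + 1, anchor_len))
        if offs[-1] != n - anchor_len:
            offs.append(n - anchor_len)
        for off in offs:
            for chrom, hit in index.get(seq[off : off + anchor_len], ()):
                start = hit - off
                if start >= 0 and start + n <= len(refs[chrom]):
                    candidates.add((chrom, start, strand))
    if not candidates:
        return _unmapped(read)
    scored: list[tuple[int, str, int, str]] = []
    for chrom, start, strand in candidates:
        seq = read.seq.upper() if strand == "+" else revcomp(read.seq.upper())
        scored.append((_count_matches(seq, refs[chrom], start), chrom, start, strand))
    scored.sort(reverse=True)
    best = scored[0]
    if len(scored) > 1 and scored[1][0] == best[0]:
        return _unmapped(read)  # ambiguous best placement
    if n - best[0] > max_mismatch_frac * n:
        return _unmapped(read)
    _, chrom, start, strand = best
    if strand == "+":
        seq, quals = read.seq.upper(), list(read.quals)
        flag = 0
    else:
        seq, quals = revcomp(read.seq.upper()), list(reversed(read.quals))
        flag = 0x10
    return AlignedRead(
        name=read.name, flag=flag, chrom=chrom, start=start,
        mapq=60, cigar=f"{n}M", seq=seq, quals=quals,
    )


def _unmapped(read: FastqRead) -> AlignedRead:
    return AlignedRead(
        name=read.name, flag=0x4, chrom="*", start=-1,
        mapq=0, cigar="*", seq=read.seq, quals=list(read.quals),
    )


# ---------------------------------------------------------------------------
# pileup engine
# ---------------------------------------------------------------------------


def build_pileup(
    alignments: Iterable[AlignedRead],
    reference: Mapping[str, str],
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
) -> list[PileupColumn]:
    """Tally strand-resolved base observations per covered reference position.

    Bases below ``min_base_quality`` are excluded from counts but tallied in
    ``n_filtered``. Deletions, skips and clips contribute nothing. For
    reverse-strand reads the in-read offset is restored to sequencing order
    (SAM stores the sequence reference-forward).

    Returns columns sorted by (chrom, position).
    """
    columns: dict[tuple[str, int], PileupColumn] = {}
    for rec in alignments:
        if rec.is_unmapped:
            continue
        _walk_read(rec, reference, columns, min_base_quality)
    return [columns[k] for k in sorted(columns)]


def _walk_read(
    rec: AlignedRead,
    reference: Mapping[str, str],
    columns: dict[tuple[str, int], PileupColumn],
    min_bq: int,
) -> None:
    ref_seq = reference.get(rec.chrom)
    if ref_seq is None:
        raise ValueError(f"read {rec.name!r}: unknown reference {rec.chrom!r}")
    read_len = len(rec.seq)
    ref_pos = rec.start
    seq_pos = 0
    for op, length in rec.cigar_tuples():
        if op in ("M", "=", "X"):
            if ref_pos + length > len(ref_seq):
                raise ValueError(
                    f"read {rec.name!r}: CIGAR walks off end of {rec.chrom}"
                )
            for i in range(length):
                pos = ref_pos + i
                base = rec.seq[seq_pos + i].upper()
                qual = rec.quals[seq_pos + i] if rec.quals else 40
                stored_off = seq_pos + i
                # sequencing-order offset: reverse reads are stored flipped
                offset = (
                    read_len - 1 - stored_off if rec.is_reverse else stored_off
                )
                dist_end = min(offset, read_len - 1 - offset)
                key = (rec.chrom, pos)
                col = columns.get(key)
                if col is None:
                    col = PileupColumn(rec.chrom, pos, ref_seq[pos].upper())
                    columns[key] = col
                if base not in _BASES and base != "N":
                    continue
                if qual < min_bq or base == "N":
                    col.n_filtered += 1
                else:
                    col.add(Observation(base, qual, offset, dist_end, rec.strand))
            ref_pos += length
            seq_pos += length
        elif op in ("D", "N"):
            ref_pos += length
        elif op in ("I", "S"):
            seq_pos += length
        else:  # pragma: no cover - dialect enforced at parse time
            raise ValueError(f"unsupported CIGAR op {op!r}")


# ---------------------------------------------------------------------------
# TSV round-trip (CLI surface)
# ---------------------------------------------------------------------------

_TSV_COLS = (
    ["chrom", "pos_1based", "ref"]
    + [f"{b}+" for b in _BASES]
    + [f"{b}-" for b in _BASES]
    + ["filtered"]
)


def write_pileup_tsv(
    columns: Sequence[PileupColumn],
    path: str | Path,
    with_observations: bool = True,
) -> None:
    """Serialize columns as TSV; the optional trailing column preserves the
    per-observation detail (base:qual:offset:dist_end:strand) that the bias
    filters need."""
    cols = _TSV_COLS + (["observations"] if with_observations else [])
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for col in columns:
            row = [col.chrom, str(col.position + 1), col.ref_base]
            row += [str(col.count("+", b)) for b in _BASES]
            row += [str(col.count("-", b)) for b in _BASES]
            row.append(str(col.n_filtered))
            if with_observations:
                row.append(
                    ";".join(
                        f"{o.base}:{o.quality}:{o.offset}:{o.dist_end}:{o.strand}"
                        for o in col.observations
                    )
                )
            fh.write("\t".join(row) + "\n")


def read_pileup_tsv(path: str | Path) -> list[PileupColumn]:
    out: list[PileupColumn] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_TSV_COLS)] != _TSV_COLS:
            raise ValueError(f"{path}: unexpected pileup header {header}")
        has_obs = len(header) > len(_TSV_COLS) and header[len(_TSV_COLS)] == "observations"
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < len(_TSV_COLS):
                continue
            col = PileupColumn(f[0], int(f[1]) - 1, f[2])
            col.n_filtered = int(f[11])
            if has_obs and len(f) > 12 and f[12]:
                for token in f[12].split(";"):
                    base, qual, off, dist, strand = token.split(":")
                    col.add(Observation(base, int(qual), int(off), int(dist), strand))
            else:
                for i, b in enumerate(_BASES):
                    if int(f[3 + i]):
                        col.counts[("+", b)] = int(f[3 + i])
                    if int(f[7 + i]):
                        col.counts[("-", b)] = int(f[7 + i])
            out.append(col)
    return out
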