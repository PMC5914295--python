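"""Combinatorial multi-site editing-isoform quantification.

For an amplicon with k editable adenosines, all 2^k edited haplotypes are
enumerated as synthetic reference sequences ("artificial chromosomes"),
reads are assigned by their exact base pattern at the k editable positions,
and haplotype, transcript-group and per-site marginal frequencies are
estimated and compared across genotypes by one-way ANOVA.

The canonical use case is the 5-site serotonin 2C receptor exon 5 motif
(sites named A, B, E, C, D in genomic order), whose 2^5 = 32 haplotypes are
labelled by length-5 a/g strings such as ``aaaaa`` (unedited) or ``ggaag``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from editscope.io_formats import FastqRead
from editscope.synthetic_data import revcomp

__all__ = [
    "EditingHaplotype",
    "HaplotypeCounts",
    "DEFAULT_SITE_NAMES",
    "SEROTONIN_EXON5_MOTIF",
    "editable_adenosines",
    "make_motif_amplicon",
    "enumerate_haplotypes",
    "build_artificial_reference",
    "assign_reads",
    "merge_read_pairs",
    "site_marginals",
    "group_frequencies",
    "anova_across_genotypes",
    "canonical_groupings",
]

DEFAULT_SITE_NAMES = ("A", "B", "E", "C", "D")  # genomic order, 5-HT2CR convention

# the 5-HT2CR exon 5 editing motif; its adenosines are the editable sites
SEROTONIN_EXON5_MOTIF = "ATACGTAATCCTA"


def editable_adenosines(seq: str) -> list[int]:
    """0-based positions of every adenosine in a sequence."""
    return [i for i, b in enumerate(seq.upper()) if b == "A"]


def make_motif_amplicon(
    length: int = 178,
    motif: str = SEROTONIN_EXON5_MOTIF,
    seed: int = 0,
) -> tuple[str, list[int]]:
    """Embed an editing motif at the centre of a random amplicon.

    Flanking bases are drawn from {C, G, T} so the motif's adenosines are
    the only editable positions. Returns (amplicon, absolute positions of
    the motif's adenosines).
    """
    if length < len(motif):
        raise ValueError("amplicon shorter than motif")
    rng = np.random.default_rng([seed, 0x5117])
    flank_len = length - len(motif)
    left = flank_len // 2
    bases = np.array(list("CGT"))
    lflank = "".join(rng.choice(bases, size=left))
    rflank = "".join(rng.choice(bases, size=flank_len - left))
    amplicon = lflank + motif.upper() + rflank
    positions = [left + i for i in editable_adenosines(motif)]
    return amplicon, positions


@dataclass(frozen=True)
class EditingHaplotype:
    """One of 2^k combinatorial edited variants of an amplicon."""

    bitmask: int
    label: str  # a/g string in site order; label[i] == 'g' iff bit i set
    sequence: str

    def is_edited_at(self, i: int) -> bool:
        return bool(self.bitmask >> i & 1)


@dataclass
class HaplotypeCounts:
    """Per-sample read counts over all 2^k haplotypes plus failure tallies."""

    labels: list[str]
    counts: dict[str, np.ndarray]  # sample -> int vector over haplotypes
    ambiguous: dict[str, int] = field(default_factory=dict)
    unassigned: dict[str, int] = field(default_factory=dict)

    def total(self, sample: str) -> int:
        return (
            int(self.counts[sample].sum())
            + self.ambiguous.get(sample, 0)
            + self.unassigned.get(sample, 0)
        )

    def assigned(self, sample: str) -> int:
        return int(self.counts[sample].sum())

    def frequencies(self, sample: str) -> np.ndarray:
        assigned = self.assigned(sample)
        if assigned == 0:
            raise ValueError(f"sample {sample!r} has zero assigned reads")
        return self.counts[sample] / assigned


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------


def enumerate_haplotypes(
    amplicon: str, editable_positions: Sequence[int]
) -> list[EditingHaplotype]:
    """Enumerate all 2^k edited haplotypes of an amplicon.

    ``editable_positions`` are strictly increasing 0-based positions that
    each carry an A in the amplicon. Output is in bitmask order 0..2^k - 1;
    haplotype 0 is the unedited amplicon.
    """
    amplicon = amplicon.upper()
    positions = list(editable_positions)
    if positions != sorted(set(positions)):
        raise ValueError("editable positions must be strictly increasing")
    for pos in positions:
        if not (0 <= pos < len(amplicon)):
            raise ValueError(f"editable position {pos} outside amplicon")
        if amplicon[pos] != "A":
            raise ValueError(
                f"editable position {pos} is {amplicon[pos]!r}, not 'A'"
            )
    k = len(positions)
    out: list[EditingHaplotype] = []
    for mask in range(1 << k):
        seq = list(amplicon)
        label = []
        for i, pos in enumerate(positions):
            if mask >> i & 1:
                seq[pos] = "G"
                label.append("g")
            else:
                label.append("a")
        out.append(EditingHaplotype(mask, "".join(label), "".join(seq)))
    return out


def build_artificial_reference(
    haplotypes: Sequence[EditingHaplotype],
) -> dict[str, str]:
    """One FASTA record per haplotype, named by its a/g label."""
    if not haplotypes:
        raise ValueError("need at least one haplotype")
    ref: dict[str, str] = {}
    for h in haplotypes:
        if h.label in ref:
            raise ValueError(f"duplicate haplotype label {h.label!r}")
        ref[h.label] = h.sequence
    return ref


# ---------------------------------------------------------------------------
# read assignment
# ---------------------------------------------------------------------------


def _best_placement(
    seq: str, amplicon: str, editable: Sequence[int]
) -> tuple[int, str, int] | None:
    """Best ungapped placement of a read on the unedited amplicon.

    Scans all offsets in both orientations, scoring mismatches at
    non-editable positions only. Returns (offset, oriented_seq,
    offsite_mismatches) for the unique best placement, or None when no
    placement covers all editable sites or the best is tied.
    """
    editable_set = set(editable)
    best: tuple[int, int, str] | None = None
    tied = False
    for oriented in (seq, revcomp(seq)):
        n = len(oriented)
        if n > len(amplicon):
            continue
        for off in range(len(amplicon) - n + 1):
            if any(not (off <= p < off + n) for p in editable_set):
                continue
            mism = sum(
                1
                for i in range(n)
                if oriented[i] != amplicon[off + i] and (off + i) not in editable_set
            )
            if best is None or mism < best[0]:
                best = (mism, off, oriented)
                tied = False
            elif mism == best[0] and (off, oriented) != (best[1], best[2]):
                tied = True
    if best is None or tied:
        return None
    return best[1], best[2], best[0]


def assign_reads(
    reads_by_sample: Mapping[str, Iterable[FastqRead]],
    haplotypes: Sequence[EditingHaplotype],
    editable_positions: Sequence[int],
    max_offsite_mismatches: int = 2,
) -> HaplotypeCounts:
    """Assign each read to the haplotype matching its bases at the k sites.

    A read is placed on the unedited amplicon frame (both orientations
    tried), its base at every editable position is extracted, and it is
    counted under the unique haplotype whose bitmask those bases spell.
    Reads failing placement (no coverage of all sites, or a tied best
    placement) are ambiguous; reads with a non-A/G base at an editable site
    or more than ``max_offsite_mismatches`` off-site mismatches are
    unassigned. assigned + ambiguous + unassigned == total input reads.
    """
    amplicon = haplotypes[0].sequence
    label_of_mask = {h.bitmask: i for i, h in enumerate(haplotypes)}
    k = len(editable_positions)
    if len(haplotypes) != 1 << k:
        raise ValueError(
            f"expected {1 << k} haplotypes for {k} sites, got {len(haplotypes)}"
        )
    result = HaplotypeCounts(
        labels=[h.label for h in haplotypes],
        counts={},
    )
    for sample, reads in reads_by_sample.items():
        counts = np.zeros(len(haplotypes), dtype=np.int64)
        ambiguous = 0
        unassigned = 0
        for read in reads:
            placed = _best_placement(read.seq.upper(), amplicon, editable_positions)
            if placed is None:
                ambiguous += 1
                continue
            off, oriented, offsite = placed
            if offsite > max_offsite_mismatches:
                unassigned += 1
                continue
            mask = 0
            ok = True
            for i, pos in enumerate(editable_positions):
                base = oriented[pos - off]
                if base == "G":
                    mask |= 1 << i
                elif base != "A":
                    ok = False
                    break
            if not ok:
                unassigned += 1
                continue
            counts[label_of_mask[mask]] += 1
        result.counts[sample] = counts
        result.ambiguous[sample] = ambiguous
        result.unassigned[sample] = unassigned
    return result


def merge_read_pairs(
    reads1: Sequence[FastqRead],
    reads2: Sequence[FastqRead],
    min_overlap: int = 10,
) -> list[FastqRead]:
    """Merge fully or partially overlapping mate pairs into single reads.

    Mate 2 is reverse-complemented and slid against mate 1 for the exact
    overlap maximizing agreement; disagreeing overlap bases take the
    higher-quality call with the minimum of the two qualities, so a
    disagreement at an editable site is quality-flagged rather than trusted.
    Pairs with no overlap of at least ``min_overlap`` are returned as mate 1
    alone.
    """
    merged: list[FastqRead] = []
    for r1, r2 in zip(reads1, reads2):
        s2 = revcomp(r2.seq.upper())
        q2 = list(reversed(r2.quals))
        s1 = r1.seq.upper()
        best_shift, best_score = None, -1
        for shift in range(-(len(s2) - min_overlap), len(s1) - min_overlap + 1):
            lo, hi = max(0, shift), min(len(s1), shift + len(s2))
            if hi - lo < min_overlap:
                continue
            agree = sum(s1[i] == s2[i - shift] for i in range(lo, hi))
            if agree > best_score:
                best_score, best_shift = agree, shift
        if best_shift is None:
            merged.append(r1)
            continue
        shift = best_shift
        start = min(0, shift)
        end = max(len(s1), shift + len(s2))
        seq: list[str] = []
        quals: list[int] = []
        for pos in range(start, end):
            in1 = 0 <= pos < len(s1)
            in2 = 0 <= pos - shift < len(s2)
            if in1 and in2:
                b1, b2 = s1[pos], s2[pos - shift]
                ql, qr = r1.quals[pos], q2[pos - shift]
                if b1 == b2:
                    seq.append(b1)
                    quals.append(max(ql, qr))
                else:
                    seq.append(b1 if ql >= qr else b2)
                    quals.append(min(ql, qr))
            elif in1:
                seq.append(s1[pos])
                quals.append(r1.quals[pos])
            else:
                seq.append(s2[pos - shift])
                quals.append(q2[pos - shift])
        merged.append(FastqRead(r1.name, "".join(seq), quals))
    return merged


# ---------------------------------------------------------------------------
# marginals, groups, ANOVA
# ---------------------------------------------------------------------------


def site_marginals(
    counts: HaplotypeCounts, haplotypes: Sequence[EditingHaplotype]
) -> dict[str, np.ndarray]:
    """Per-site editing frequency: sum of frequencies of haplotypes with the
    site's bit set. Returns {sample: vector over the k sites}."""
    k = len(haplotypes[0].label)
    out: dict[str, np.ndarray] = {}
    for sample in counts.counts:
        freqs = counts.frequencies(sample)
        marg = np.zeros(k)
        for h, f in zip(haplotypes, freqs):
            for i in range(k):
                if h.is_edited_at(i):
                    marg[i] += f
        out[sample] = marg
    return out


def group_frequencies(
    counts: HaplotypeCounts,
    haplotypes: Sequence[EditingHaplotype],
    groups: Mapping[str, Callable[[int], bool]],
) -> dict[str, dict[str, float]]:
    """Summed haplotype frequencies per named group, per sample.

    ``groups`` maps a group name to a predicate on the bitmask; the
    predicates must partition the haplotype set (every bitmask in exactly
    one group).
    """
    for h in haplotypes:
        hits = [name for name, pred in groups.items() if pred(h.bitmask)]
        if len(hits) != 1:
            raise ValueError(
                f"haplotype {h.label!r} matched groups {hits}; "
                "grouping must be a partition"
            )
    out: dict[str, dict[str, float]] = {}
    for sample in counts.counts:
        freqs = counts.frequencies(sample)
        row = {name: 0.0 for name in groups}
        for h, f in zip(haplotypes, freqs):
            for name, pred in groups.items():
                if pred(h.bitmask):
                    row[name] += float(f)
                    break
        out[sample] = row
    return out


def canonical_groupings(
    site_names: Sequence[str] = DEFAULT_SITE_NAMES,
) -> dict[str, Callable[[int], bool]]:
    """Transcript groups keyed on the first two sites (A and B by default):
    both unedited, both edited, or mixed."""
    ia, ib = 0, 1

    def both_unedited(mask: int) -> bool:
        return not (mask >> ia & 1) and not (mask >> ib & 1)

    def both_edited(mask: int) -> bool:
        return bool(mask >> ia & 1) and bool(mask >> ib & 1)

    def mixed(mask: int) -> bool:
        return not both_unedited(mask) and not both_edited(mask)

    a, b = site_names[ia], site_names[ib]
    return {
        f"unedited_{a}{b}": both_unedited,
        f"edited_{a}{b}": both_edited,
        f"mixed_{a}{b}": mixed,
    }


def anova_across_genotypes(
    frequencies: Mapping[str, Mapping[str, float] | np.ndarray],
    design: Sequence,
    names: Sequence[str] | None = None,
) -> dict[str, tuple[float, float]]:
    """One-way ANOVA of each haplotype/group frequency across genotypes.

    ``frequencies`` maps sample -> (name -> frequency) or sample -> vector
    (with ``names`` giving the vector's labels). Returns
    {name: (F, p)}. Degenerate inputs (all values identical) give F = 0,
    p = 1 by convention.
    """
    by_geno: dict[str, list[str]] = {}
    for d in design:
        by_geno.setdefault(d.genotype, []).append(d.sample_id)
    if any(len(v) < 2 for v in by_geno.values()) or len(by_geno) < 2:
        raise ValueError("need >= 2 genotype levels with >= 2 samples each")

    first = next(iter(frequencies.values()))
    if names is None:
        if not isinstance(first, Mapping):
            raise ValueError("names required when frequencies are vectors")
        names = list(first)

    def value(sample: str, name: str) -> float:
        row = frequencies[sample]
        if isinstance(row, Mapping):
            return float(row[name])
        return float(row[list(names).index(name)])

    out: dict[str, tuple[float, float]] = {}
    for name in names:
        samples_by_group = [
            [value(s, name) for s in ids] for ids in by_geno.values()
        ]
        flat = [v for grp in samples_by_group for v in grp]
        if np.allclose(flat, flat[0]):
            out[name] = (0.0, 1.0)
            continue
        f_stat, p = stats.f_oneway(*samples_by_group)
        if not np.isfinite(f_stat):
            out[name] = (float("inf"), 0.0)
        else:
            out[name] = (float(f_stat), float(p))
    return out
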