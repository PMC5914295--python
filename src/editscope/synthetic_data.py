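"""Synthetic-data generation with fully known editing truth.

Everything downstream (pileup, site calling, differential testing, isoform
quantification) is validated by parameter recovery against the truth files
emitted here. All generators are pure functions of (parameters, seed); each
sample draws from an RNG stream derived from (master seed, sample_id) so
per-sample output is independent of sample order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from editscope.io_formats import AlignedRead, FastqRead, SampleDesign

__all__ = [
    "EditingSite",
    "EditingProfile",
    "SimTruth",
    "sample_rng",
    "make_reference",
    "simulate_rnaseq",
    "plant_artifact",
    "simulate_amplicon",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def sample_rng(master_seed: int, sample_id: str) -> np.random.Generator:
    """Per-sample RNG stream derived from (master seed, sample_id hash)."""
    return np.random.default_rng([master_seed, zlib.crc32(sample_id.encode())])


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EditingSite:
    """One editable position with per-genotype true editing rates."""

    chrom: str
    position: int  # 0-based
    strand: str  # '+' (reference A) or '-' (reference T)
    rates: Mapping[str, float]  # genotype -> epsilon in [0, 1]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"site strand must be +/-, got {self.strand!r}")
        for g, eps in self.rates.items():
            if not (0.0 <= eps <= 1.0):
                raise ValueError(f"rate for genotype {g!r} out of [0,1]: {eps}")


@dataclass
class EditingProfile:
    """Per-site, per-genotype true editing rates over a reference."""

    sites: list[EditingSite]

    def validate(self, reference: Mapping[str, str]) -> None:
        """Every + site must sit on a reference A, every - site on a T."""
        for s in self.sites:
            if s.chrom not in reference:
                raise ValueError(f"profile site on unknown reference {s.chrom!r}")
            base = reference[s.chrom][s.position].upper()
            want = "A" if s.strand == "+" else "T"
            if base != want:
                raise ValueError(
                    f"profile site {s.chrom}:{s.position} strand {s.strand} "
                    f"requires reference {want}, found {base}"
                )


@dataclass
class SimTruth:
    """Ground truth serialized alongside simulated reads."""

    profile: EditingProfile
    snp_positions: list[tuple[str, int]] = field(default_factory=list)
    artifact_positions: list[tuple[str, int, str]] = field(default_factory=list)
    sample_seeds: dict[str, int] = field(default_factory=dict)
    haplotype_labels: list[str] = field(default_factory=list)
    haplotype_freqs: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.haplotype_freqs:
            total = float(np.sum(self.haplotype_freqs))
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"haplotype frequencies sum to {total}, not 1")

    # -- serialization (plain TSV so tests never reconstruct truth from logs)

    def write_sites(self, path: str | Path) -> None:
        genotypes = sorted(
            {g for s in self.profile.sites for g in s.rates}
        )
        with open(path, "w") as fh:
            cols = ["chrom", "pos_1based", "strand", "kind"] + [
                f"eps_{g}" for g in genotypes
            ]
            fh.write("\t".join(cols) + "\n")
            for s in self.profile.sites:
                row = [s.chrom, str(s.position + 1), s.strand, "edit"] + [
                    repr(float(s.rates.get(g, 0.0))) for g in genotypes
                ]
                fh.write("\t".join(row) + "\n")
            for chrom, pos in self.snp_positions:
                row = [chrom, str(pos + 1), "+", "snp"] + ["1.0"] * len(genotypes)
                fh.write("\t".join(row) + "\n")
            for chrom, pos, mode in self.artifact_positions:
                row = [chrom, str(pos + 1), "+", f"artifact:{mode}"] + ["0.0"] * len(
                    genotypes
                )
                fh.write("\t".join(row) + "\n")

    def write_haplotypes(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("label\tfrequency\n")
            for label, freq in zip(self.haplotype_labels, self.haplotype_freqs):
                fh.write(f"{label}\t{freq!r}\n")

    @staticmethod
    def read_sites(path: str | Path) -> "SimTruth":
        sites: list[EditingSite] = []
        snps: list[tuple[str, int]] = []
        artifacts: list[tuple[str, int, str]] = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            genotypes = [c[4:] for c in header if c.startswith("eps_")]
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if not fields or not fields[0]:
                    continue
                chrom, pos1, strand, kind = fields[:4]
                pos = int(pos1) - 1
                if kind == "edit":
                    rates = {
                        g: float(v) for g, v in zip(genotypes, fields[4:])
                    }
                    sites.append(EditingSite(chrom, pos, strand, rates))
                elif kind == "snp":
                    snps.append((chrom, pos))
                elif kind.startswith("artifact:"):
                    artifacts.append((chrom, pos, kind.split(":", 1)[1]))
        return SimTruth(
            profile=EditingProfile(sites),
            snp_positions=snps,
            artifact_positions=artifacts,
        )

    @staticmethod
    def read_haplotypes(path: str | Path) -> tuple[list[str], list[float]]:
        labels: list[str] = []
        freqs: list[float] = []
        with open(path) as fh:
            fh.readline()
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) >= 2:
                    labels.append(fields[0])
                    freqs.append(float(fields[1]))
        return labels, freqs


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------


def make_reference(
    n_transcripts: int, length: int, gc: float, seed: int
) -> dict[str, str]:
    """Generate a deterministic random reference with plantable adenosines.

    Each 20-bp window is guaranteed at least one A so editing sites can be
    planted anywhere.
    """
    if n_transcripts < 0:
        raise ValueError("n_transcripts must be >= 0")
    if n_transcripts and length < 50:
        raise ValueError("length must be >= 50")
    if not (0.0 < gc < 1.0):
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng([seed, 0xED17])
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    seqs: dict[str, str] = {}
    for i in range(n_transcripts):
        arr = rng.choice(bases, size=length, p=probs)
        # force >= 1 A per 20-bp window
        for w in range(0, length, 20):
            window = arr[w : w + 20]
            if not np.any(window == "A"):
                j = int(rng.integers(len(window)))
                window[j] = "A"
        seqs[f"tx{i + 1}"] = "".join(arr)
    return seqs


# ---------------------------------------------------------------------------
# stranded RNA-seq simulation
# ---------------------------------------------------------------------------


def _apply_errors(seq_arr: np.ndarray, error_rate: float, rng: np.random.Generator) -> None:
    if error_rate <= 0:
        return
    hits = np.flatnonzero(rng.random(seq_arr.size) < error_rate)
    if hits.size == 0:
        return
    alphabet = np.array(list("ACGT"))
    for i in hits:
        choices = alphabet[alphabet != seq_arr[i]]
        seq_arr[i] = choices[rng.integers(3)]


def simulate_rnaseq(
    reference: Mapping[str, str],
    profile: EditingProfile,
    design: Sequence[SampleDesign],
    depth: float = 50.0,
    read_len: int = 75,
    error_rate: float = 0.001,
    seed: int = 0,
    snp_positions: Sequence[tuple[str, int]] = (),
    base_quality: int = 37,
) -> tuple[dict[str, list[FastqRead]], SimTruth]:
    """Simulate stranded RNA-seq reads with per-site, per-genotype editing.

    Reads are drawn from uniformly placed fragments on uniformly chosen
    transcripts. At each profiled site every covering read is independently
    edited with probability eps(genotype): A->G for + sites, T->C (in
    reference-forward letters) for - sites. Homozygous SNPs are planted as
    genotype-independent substitutions present on every read. Sequencing
    errors are applied after editing (biology precedes machine noise).

    Returns ({sample_id: [FastqRead, ...]}, SimTruth). Read names encode the
    true origin as ``sample|index|chrom|start|strand`` for debugging only.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not (0.0 <= error_rate < 0.05):
        raise ValueError("error_rate must be in [0, 0.05)")
    profile.validate(reference)
    snp_set = set(snp_positions)
    for chrom, pos in snp_set:
        if chrom not in reference or not (0 <= pos < len(reference[chrom])):
            raise ValueError(f"SNP position {chrom}:{pos} outside reference")

    site_map: dict[str, list[EditingSite]] = {}
    for s in profile.sites:
        site_map.setdefault(s.chrom, []).append(s)

    chroms = list(reference)
    reads_by_sample: dict[str, list[FastqRead]] = {}
    truth = SimTruth(profile=profile, snp_positions=sorted(snp_set))
    for d in design:
        rng = sample_rng(seed, d.sample_id)
        truth.sample_seeds[d.sample_id] = seed
        reads: list[FastqRead] = []
        for chrom in chroms:
            ref_seq = reference[chrom]
            if len(ref_seq) < read_len:
                continue
            n_reads = int(round(depth * len(ref_seq) / read_len))
            starts = rng.integers(0, len(ref_seq) - read_len + 1, size=n_reads)
            orients = rng.random(n_reads) < 0.5
            for idx in range(n_reads):
                start = int(starts[idx])
                frag = np.array(list(ref_seq[start : start + read_len]))
                for site in site_map.get(chrom, ()):
                    off = site.position - start
                    if 0 <= off < read_len:
                        eps = site.rates.get(d.genotype, 0.0)
                        if eps > 0 and rng.random() < eps:
                            frag[off] = "G" if site.strand == "+" else "C"
                for schrom, spos in snp_set:
                    if schrom == chrom and 0 <= spos - start < read_len:
                        frag[spos - start] = "G"
                _apply_errors(frag, error_rate, rng)
                seq = "".join(frag)
                strand = "+" if orients[idx] else "-"
                if strand == "-":
                    seq = revcomp(seq)
                name = f"{d.sample_id}|{len(reads)}|{chrom}|{start}|{strand}"
                reads.append(FastqRead(name, seq, [base_quality] * read_len))
        reads_by_sample[d.sample_id] = reads
    return reads_by_sample, truth


# ---------------------------------------------------------------------------
# artifact planting
# ---------------------------------------------------------------------------


def plant_artifact(
    alignments: Sequence[AlignedRead],
    chrom: str,
    position: int,
    mode: str,
    reference: Mapping[str, str],
    seed: int = 0,
    end_window: int = 5,
) -> list[AlignedRead]:
    """Plant a biased-artifact alt allele at a covered reference position.

    ``strand_skew``: every + strand read covering the position gets the alt
    base, every - strand read keeps the reference (maximally imbalanced 2x2
    strand table). ``end_cluster``: only reads where the position falls
    within ``end_window`` bases of a read end get the alt base.

    Operates on ungapped (all-M) alignments; returns modified copies.
    """
    if mode not in ("strand_skew", "end_cluster"):
        raise ValueError(f"unknown artifact mode {mode!r}")
    ref_base = reference[chrom][position].upper()
    alt = "G" if ref_base == "A" else "C" if ref_base == "T" else "G"
    out: list[AlignedRead] = []
    n_cover = 0
    n_alt = 0
    for rec in alignments:
        off = position - rec.start
        if rec.chrom != chrom or not (0 <= off < len(rec.seq)):
            out.append(rec)
            continue
        n_cover += 1
        dist_end = min(off, len(rec.seq) - 1 - off)
        if mode == "strand_skew":
            make_alt = rec.strand == "+"
        else:
            make_alt = dist_end < end_window
        new_seq = rec.seq[:off] + (alt if make_alt else ref_base) + rec.seq[off + 1 :]
        n_alt += make_alt
        out.append(
            AlignedRead(
                rec.name, rec.flag, rec.chrom, rec.start, rec.mapq,
                rec.cigar, new_seq, list(rec.quals),
            )
        )
    if n_cover < 20:
        raise ValueError(
            f"artifact position {chrom}:{position} covered by only {n_cover} reads"
        )
    if n_alt == 0:
        raise ValueError(
            f"artifact mode {mode!r} planted no alt bases at {chrom}:{position}"
        )
    return out


# ---------------------------------------------------------------------------
# amplicon simulation
# ---------------------------------------------------------------------------


def simulate_amplicon(
    haplotype_seqs: Sequence[str],
    haplotype_labels: Sequence[str],
    pi: Sequence[float],
    depth: int,
    error_rate: float = 0.001,
    seed: int = 0,
    base_quality: int = 37,
) -> tuple[list[FastqRead], SimTruth]:
    """Simulate full-length amplicon reads from a haplotype mixture.

    Each read covers the whole amplicon; its haplotype is drawn i.i.d. from
    ``pi``; sequencing errors are applied afterwards; half the reads are
    emitted reverse-complemented. Truth stores pi.
    """
    pi_arr = np.asarray(pi, dtype=float)
    if len(pi_arr) != len(haplotype_seqs):
        raise ValueError(
            f"pi has {len(pi_arr)} entries for {len(haplotype_seqs)} haplotypes"
        )
    if abs(float(pi_arr.sum()) - 1.0) > 1e-9:
        raise ValueError(f"pi sums to {pi_arr.sum()}, not 1")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng([seed, 0xA3B])
    picks = rng.choice(len(pi_arr), size=depth, p=pi_arr / pi_arr.sum())
    orients = rng.random(depth) < 0.5
    reads: list[FastqRead] = []
    for i in range(depth):
        seq_arr = np.array(list(haplotype_seqs[picks[i]]))
        _apply_errors(seq_arr, error_rate, rng)
        seq = "".join(seq_arr)
        if orients[i]:
            seq = revcomp(seq)
        reads.append(
            FastqRead(
                f"amp|{i}|{haplotype_labels[picks[i]]}",
                seq,
                [base_quality] * len(seq),
            )
        )
    truth = SimTruth(
        profile=EditingProfile([]),
        haplotype_labels=list(haplotype_labels),
        haplotype_freqs=[float(p) for p in pi_arr],
    )
    return reads, truth
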