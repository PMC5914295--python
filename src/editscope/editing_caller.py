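"""Editing-site detection, known-variant masking, bias filters, and the
amplicon quantification mode.

A position is an editing candidate only for the two strand-aware patterns
A->G (forward-strand editing) and T->C in reference-forward letters
(reverse-strand editing). Candidates require coverage of at least
``min_cov`` reads in every sample and a mean mismatch frequency of at least
``min_mean_freq`` across samples, then pass through three artifact filters:

* strand bias      — two-sided Fisher exact test on the {ref,alt} x {+,-} table
* read position    — two-sided rank-sum test on in-read offsets of alt vs ref
* variant distance — the same rank-sum test on distance-to-nearest-read-end

A filter p-value below the threshold (default 0.01) fails the site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from editscope.pileup import PileupColumn

__all__ = [
    "CandidateSite",
    "FilterReport",
    "EDITING_PATTERNS",
    "detect_candidates",
    "mask_known_variants",
    "strand_bias_test",
    "rank_sum_u",
    "read_position_bias_test",
    "variant_distance_bias_test",
    "apply_filters",
    "amplicon_site_frequencies",
    "write_candidates_tsv",
    "read_candidates_tsv",
]

DEFAULT_MIN_COVERAGE = 20
DEFAULT_MIN_MEAN_FREQ = 0.05
DEFAULT_FILTER_P = 0.01

# ref base (reference-forward) -> (alt base, inferred editing strand)
EDITING_PATTERNS: dict[str, tuple[str, str]] = {"A": ("G", "+"), "T": ("C", "-")}


@dataclass
class FilterReport:
    strand_bias_p: float = 1.0
    read_position_p: float = 1.0
    variant_distance_p: float = 1.0
    masked_snp: bool = False
    untestable: bool = False
    threshold: float = DEFAULT_FILTER_P

    @property
    def passed(self) -> bool:
        return (not self.masked_snp) and all(
            p >= self.threshold
            for p in (self.strand_bias_p, self.read_position_p, self.variant_distance_p)
        )


@dataclass
class CandidateSite:
    """A putative editing position with per-sample evidence."""

    chrom: str
    position: int  # 0-based
    strand: str  # inferred editing strand
    ref_base: str  # reference-forward
    alt_base: str
    coverage: dict[str, int] = field(default_factory=dict)  # sample -> depth
    edited: dict[str, int] = field(default_factory=dict)  # sample -> alt count
    filter_report: FilterReport | None = None

    @property
    def sample_frequencies(self) -> dict[str, float]:
        return {
            s: self.edited[s] / cov
            for s, cov in self.coverage.items()
            if cov > 0
        }

    @property
    def mean_frequency(self) -> float:
        """Unweighted mean of per-sample frequencies (coverage > 0 samples)."""
        freqs = self.sample_frequencies
        return sum(freqs.values()) / len(freqs) if freqs else 0.0

    @property
    def pooled_frequency(self) -> float:
        """Pooled-count frequency, reported alongside the mean."""
        total_cov = sum(self.coverage.values())
        return sum(self.edited.values()) / total_cov if total_cov else 0.0

    @property
    def masked(self) -> bool:
        return self.filter_report is not None and self.filter_report.masked_snp

    @property
    def passed(self) -> bool:
        return self.filter_report is not None and self.filter_report.passed


# ---------------------------------------------------------------------------
# candidate detection
# ---------------------------------------------------------------------------


def detect_candidates(
    pileups: Mapping[str, Sequence[PileupColumn]],
    min_cov: int = DEFAULT_MIN_COVERAGE,
    min_mean_freq: float = DEFAULT_MIN_MEAN_FREQ,
) -> list[CandidateSite]:
    """Call candidate editing sites from per-sample pileups.

    A position is retained iff its mismatch pattern is an editing pattern,
    every sample covers it with at least ``min_cov`` quality-passed reads,
    and the unweighted mean per-sample alt frequency is at least
    ``min_mean_freq``.
    """
    if not pileups:
        raise ValueError("at least one sample pileup required")
    if min_cov <= 0 or min_mean_freq <= 0:
        raise ValueError("thresholds must be positive")

    by_pos: dict[tuple[str, int], dict[str, PileupColumn]] = {}
    for sample, cols in pileups.items():
        for col in cols:
            by_pos.setdefault((col.chrom, col.position), {})[sample] = col

    samples = list(pileups)
    candidates: list[CandidateSite] = []
    for (chrom, pos), cols in sorted(by_pos.items()):
        refs = {c.ref_base for c in cols.values()}
        if len(refs) != 1:
            raise ValueError(
                f"inconsistent reference bases {sorted(refs)} at {chrom}:{pos + 1}"
            )
        ref = refs.pop()
        if ref not in EDITING_PATTERNS:
            continue
        alt, strand = EDITING_PATTERNS[ref]
        if set(cols) != set(samples):
            continue  # untestable: not covered in every sample
        coverage = {s: cols[s].depth() for s in samples}
        if any(cov < min_cov for cov in coverage.values()):
            continue
        edited = {s: cols[s].base_count(alt) for s in samples}
        site = CandidateSite(chrom, pos, strand, ref, alt, coverage, edited)
        if site.mean_frequency < min_mean_freq:
            continue
        candidates.append(site)
    return candidates


def mask_known_variants(
    candidates: Sequence[CandidateSite], mask: set[tuple[str, int]]
) -> list[CandidateSite]:
    """Flag candidates at known-variant positions; returns all candidates
    with ``filter_report.masked_snp`` set where applicable."""
    for site in candidates:
        if site.filter_report is None:
            site.filter_report = FilterReport()
        site.filter_report.masked_snp = (site.chrom, site.position) in mask
    return list(candidates)


# ---------------------------------------------------------------------------
# bias filters
# ---------------------------------------------------------------------------


def strand_bias_test(column: PileupColumn, alt_base: str | None = None) -> float:
    """Two-sided Fisher exact p on the {ref, alt} x {+, -} table."""
    alt = alt_base or EDITING_PATTERNS.get(column.ref_base, ("G", "+"))[0]
    table = [
        [column.count("+", column.ref_base), column.count("-", column.ref_base)],
        [column.count("+", alt), column.count("-", alt)],
    ]
    if min(sum(row) for row in table) == 0 or min(
        table[0][j] + table[1][j] for j in range(2)
    ) == 0:
        return 1.0  # an all-zero margin carries no strand information
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def rank_sum_u(alt_values: Sequence[float], ref_values: Sequence[float]) -> float:
    """Mann-Whitney U of the first sample, computed via rank sums."""
    n1 = len(alt_values)
    pooled = np.concatenate(
        [np.asarray(alt_values, float), np.asarray(ref_values, float)]
    )
    ranks = stats.rankdata(pooled)
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def _ranksum_p(alt_values: Sequence[int], ref_values: Sequence[int]) -> float:
    """Two-sided Mann-Whitney p, normal approximation with tie correction.

    Implemented from the definition (rank-sum U, tie-corrected variance) so
    the contract is explicit; validated against brute-force enumeration in
    the test suite.
    """
    n1, n2 = len(alt_values), len(ref_values)
    if n1 < 2 or n2 < 2:
        return 1.0
    pooled = np.concatenate([np.asarray(alt_values, float), np.asarray(ref_values, float)])
    u1 = rank_sum_u(alt_values, ref_values)
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0  # all observations tied
    z = (u1 - mu) / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def read_position_bias_test(
    column: PileupColumn, alt_base: str | None = None
) -> tuple[float, bool]:
    """Rank-sum test on in-read offsets of alt vs ref observations.

    Returns (p, untestable): with fewer than 2 alt or 2 ref observations the
    test is untestable and p = 1.
    """
    alt = alt_base or EDITING_PATTERNS.get(column.ref_base, ("G", "+"))[0]
    alt_vals = [o.offset for o in column.observations if o.base == alt]
    ref_vals = [o.offset for o in column.observations if o.base == column.ref_base]
    if len(alt_vals) < 2 or len(ref_vals) < 2:
        return 1.0, True
    return _ranksum_p(alt_vals, ref_vals), False


def variant_distance_bias_test(
    column: PileupColumn, alt_base: str | None = None
) -> tuple[float, bool]:
    """Rank-sum test on distance-to-nearest-read-end of alt vs ref."""
    alt = alt_base or EDITING_PATTERNS.get(column.ref_base, ("G", "+"))[0]
    alt_vals = [o.dist_end for o in column.observations if o.base == alt]
    ref_vals = [o.dist_end for o in column.observations if o.base == column.ref_base]
    if len(alt_vals) < 2 or len(ref_vals) < 2:
        return 1.0, True
    return _ranksum_p(alt_vals, ref_vals), False


def _pool_columns(cols: Sequence[PileupColumn]) -> PileupColumn:
    pooled = PileupColumn(cols[0].chrom, cols[0].position, cols[0].ref_base)
    for col in cols:
        for obs in col.observations:
            pooled.add(obs)
        pooled.n_filtered += col.n_filtered
    return pooled


def apply_filters(
    candidates: Sequence[CandidateSite],
    pileups: Mapping[str, Sequence[PileupColumn]],
    p_threshold: float = DEFAULT_FILTER_P,
    mask: set[tuple[str, int]] | None = None,
) -> list[CandidateSite]:
    """Attach a FilterReport to each candidate from pooled observations.

    Observations are pooled across samples before testing; a site passes iff
    it is not masked and all three p-values are >= ``p_threshold``.
    """
    col_index: dict[tuple[str, int], list[PileupColumn]] = {}
    for cols in pileups.values():
        for col in cols:
            col_index.setdefault((col.chrom, col.position), []).append(col)
    for site in candidates:
        pooled = _pool_columns(col_index[(site.chrom, site.position)])
        report = FilterReport(threshold=p_threshold)
        if site.filter_report is not None:
            report.masked_snp = site.filter_report.masked_snp
        if mask is not None:
            report.masked_snp = (site.chrom, site.position) in mask
        report.strand_bias_p = strand_bias_test(pooled, site.alt_base)
        report.read_position_p, untest_rp = read_position_bias_test(
            pooled, site.alt_base
        )
        report.variant_distance_p, untest_vd = variant_distance_bias_test(
            pooled, site.alt_base
        )
        report.untestable = untest_rp or untest_vd
        site.filter_report = report
    return list(candidates)


# ---------------------------------------------------------------------------
# amplicon mode
# ---------------------------------------------------------------------------


def amplicon_site_frequencies(
    columns: Sequence[PileupColumn],
    min_freq: float = 0.01,
) -> list[dict]:
    """Per-site editing frequencies from a targeted-amplicon pileup.

    Reports every A->G (and reference-forward T->C) position whose alt
    frequency among quality-passed bases is at least ``min_freq``.
    """
    if not columns or all(c.depth() == 0 for c in columns):
        import warnings

        warnings.warn("zero-coverage amplicon: empty frequency table")
        return []
    rows: list[dict] = []
    for col in sorted(columns, key=lambda c: (c.chrom, c.position)):
        if col.ref_base not in EDITING_PATTERNS:
            continue
        alt, strand = EDITING_PATTERNS[col.ref_base]
        depth = col.depth()
        if depth == 0:
            continue
        freq = col.base_count(alt) / depth
        if freq >= min_freq:
            rows.append(
                {
                    "chrom": col.chrom,
                    "position": col.position,
                    "strand": strand,
                    "ref": col.ref_base,
                    "alt": alt,
                    "coverage": depth,
                    "edited": col.base_count(alt),
                    "frequency": freq,
                }
            )
    return rows


# ---------------------------------------------------------------------------
# TSV surface
# ---------------------------------------------------------------------------


def write_candidates_tsv(
    candidates: Sequence[CandidateSite],
    path: str | Path,
    samples: Sequence[str] | None = None,
) -> None:
    if samples is None:
        samples = sorted({s for c in candidates for s in c.coverage})
    cols = ["chrom", "pos_1based", "strand", "ref", "alt"]
    for s in samples:
        cols += [f"cov_{s}", f"edit_{s}"]
    cols += [
        "mean_freq", "pooled_freq", "strand_bias_p", "read_position_p",
        "variant_distance_p", "masked", "pass",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in candidates:
            rep = c.filter_report or FilterReport()
            row = [c.chrom, str(c.position + 1), c.strand, c.ref_base, c.alt_base]
            for s in samples:
                row += [str(c.coverage.get(s, 0)), str(c.edited.get(s, 0))]
            row += [
                f"{c.mean_frequency:.6g}", f"{c.pooled_frequency:.6g}",
                f"{rep.strand_bias_p:.6g}", f"{rep.read_position_p:.6g}",
                f"{rep.variant_distance_p:.6g}",
                str(int(rep.masked_snp)), str(int(rep.passed)),
            ]
            fh.write("\t".join(row) + "\n")


def read_candidates_tsv(path: str | Path) -> list[CandidateSite]:
    out: list[CandidateSite] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        samples = [c[4:] for c in header if c.startswith("cov_")]
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) != len(header):
                continue
            site = CandidateSite(
                chrom=f[idx["chrom"]],
                position=int(f[idx["pos_1based"]]) - 1,
                strand=f[idx["strand"]],
                ref_base=f[idx["ref"]],
                alt_base=f[idx["alt"]],
                coverage={s: int(f[idx[f"cov_{s}"]]) for s in samples},
                edited={s: int(f[idx[f"edit_{s}"]]) for s in samples},
            )
            site.filter_report = FilterReport(
                strand_bias_p=float(f[idx["strand_bias_p"]]),
                read_position_p=float(f[idx["read_position_p"]]),
                variant_distance_p=float(f[idx["variant_distance_p"]]),
                masked_snp=bool(int(f[idx["masked"]])),
            )
            out.append(site)
    return out
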