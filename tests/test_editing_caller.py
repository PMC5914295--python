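"""Unit and oracle tests for candidate detection, masking and bias filters."""

import math
from itertools import product

import numpy as np
import pytest

from editscope import editing_caller as ec
from editscope import pileup as pu
from editscope import synthetic_data as sd
from editscope.io_formats import SampleDesign
from editscope.pileup import Observation, PileupColumn

from conftest import a_positions


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    Sums the point probabilities of every table with the observed margins
    whose probability does not exceed the observed table's (with a relative
    tolerance for float comparison, as conventional).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> float:
        # table [[x, r1-x], [c1-x, r2-(c1-x)]]
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


def brute_force_u(xs, ys) -> float:
    """U = #{(x,y): x > y} + 0.5 * #ties, straight from the definition."""
    u = 0.0
    for x in xs:
        for y in ys:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def exact_ranksum_pvalue(xs, ys) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments."""
    from itertools import combinations

    pooled = list(xs) + list(ys)
    n1 = len(xs)
    u_obs = brute_force_u(xs, ys)
    mu = n1 * len(ys) / 2.0
    dev_obs = abs(u_obs - mu)
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), n1):
        grp = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(brute_force_u(grp, rest) - mu) >= dev_obs - 1e-12:
            count += 1
    return count / total


def make_column(
    ref="A", alt="G", n_ref=10, n_alt=10,
    ref_strands=None, alt_strands=None,
    ref_offsets=None, alt_offsets=None,
    read_len=50,
):
    col = PileupColumn("c", 100, ref)
    ref_strands = ref_strands or ["+", "-"] * (n_ref // 2) + ["+"] * (n_ref % 2)
    alt_strands = alt_strands or ["+", "-"] * (n_alt // 2) + ["+"] * (n_alt % 2)
    ref_offsets = ref_offsets if ref_offsets is not None else list(range(n_ref))
    alt_offsets = alt_offsets if alt_offsets is not None else list(range(n_alt))
    for i in range(n_ref):
        off = ref_offsets[i]
        col.add(Observation(ref, 37, off, min(off, read_len - 1 - off), ref_strands[i]))
    for i in range(n_alt):
        off = alt_offsets[i]
        col.add(Observation(alt, 37, off, min(off, read_len - 1 - off), alt_strands[i]))
    return col


# ---------------------------------------------------------------------------
# detect_candidates
# ---------------------------------------------------------------------------


def column_from_counts(chrom, pos, ref, alt, n_ref, n_alt, read_len=50):
    col = PileupColumn(chrom, pos, ref)
    for i in range(n_ref):
        off = i % read_len
        col.add(Observation(ref, 37, off, min(off, read_len - 1 - off), "+-"[i % 2]))
    for i in range(n_alt):
        off = (i * 7 + 3) % read_len
        col.add(Observation(alt, 37, off, min(off, read_len - 1 - off), "+-"[i % 2]))
    return col


class TestDetectCandidates:
    def test_boundary_retained_cov20_freq5(self):
        pileups = {
            s: [column_from_counts("c", 9, "A", "G", 19, 1)] for s in ("s1", "s2")
        }
        cands = ec.detect_candidates(pileups)
        assert len(cands) == 1
        assert cands[0].mean_frequency == pytest.approx(0.05)
        assert (cands[0].strand, cands[0].alt_base) == ("+", "G")

    def test_coverage_19_excluded(self):
        pileups = {
            "s1": [column_from_counts("c", 9, "A", "G", 18, 1)],  # cov 19
            "s2": [column_from_counts("c", 9, "A", "G", 30, 10)],
        }
        assert ec.detect_candidates(pileups) == []

    def test_mean_freq_below_threshold_excluded(self):
        pileups = {
            s: [column_from_counts("c", 9, "A", "G", 960, 40)] for s in ("s1",)
        }  # 4% < 5%
        assert ec.detect_candidates(pileups) == []

    def test_non_editing_mismatch_never_returned(self):
        pileups = {"s1": [column_from_counts("c", 9, "A", "C", 10, 10)]}
        assert ec.detect_candidates(pileups) == []
        pileups = {"s1": [column_from_counts("c", 9, "G", "A", 10, 10)]}
        assert ec.detect_candidates(pileups) == []

    def test_t_to_c_is_reverse_strand_candidate(self):
        pileups = {"s1": [column_from_counts("c", 9, "T", "C", 15, 15)]}
        [cand] = ec.detect_candidates(pileups)
        assert (cand.strand, cand.ref_base, cand.alt_base) == ("-", "T", "C")

    def test_planted_fixture_exact_recovery(self):
        # 10 positions; exactly 4 clear both thresholds in both samples
        cases = [
            # (pos, (n_ref, n_alt) per sample, retained?)
            (0, (19, 1), (19, 1), True),   # cov 20, freq 5%
            (1, (18, 1), (19, 1), False),  # cov 19 in s1
            (2, (100, 1), (100, 1), False),  # freq ~1%
            (3, (50, 50), (50, 50), True),  # high signal
            (4, (20, 0), (20, 0), False),  # no alt
            (5, (10, 10), (10, 10), True),  # cov 20, freq 50%
            (6, (400, 10), (400, 10), False),  # freq 2.4%
            (7, (90, 10), (90, 10), True),  # 10%
            (8, (19, 0), (19, 0), False),
            (9, (300, 5), (300, 5), False),  # 1.6%
        ]
        pileups = {"s1": [], "s2": []}
        expected = set()
        for pos, c1, c2, keep in cases:
            pileups["s1"].append(column_from_counts("c", pos, "A", "G", *c1))
            pileups["s2"].append(column_from_counts("c", pos, "A", "G", *c2))
            if keep:
                expected.add(pos)
        got = {c.position for c in ec.detect_candidates(pileups)}
        assert got == expected

    def test_position_missing_in_one_sample_dropped(self):
        pileups = {
            "s1": [column_from_counts("c", 9, "A", "G", 50, 50)],
            "s2": [],
        }
        assert ec.detect_candidates(pileups) == []

    def test_inconsistent_reference_is_error(self):
        pileups = {
            "s1": [column_from_counts("c", 9, "A", "G", 50, 50)],
            "s2": [column_from_counts("c", 9, "T", "C", 50, 50)],
        }
        with pytest.raises(ValueError, match="inconsistent"):
            ec.detect_candidates(pileups)

    def test_thresholds_must_be_positive(self):
        pileups = {"s1": [column_from_counts("c", 9, "A", "G", 50, 50)]}
        with pytest.raises(ValueError):
            ec.detect_candidates(pileups, min_cov=0)


class TestMaskKnownVariants:
    def _cands(self, positions):
        pileups = {
            "s1": [column_from_counts("c", p, "A", "G", 50, 50) for p in positions]
        }
        return ec.detect_candidates(pileups)

    def test_masked_position_flagged(self):
        cands = ec.mask_known_variants(self._cands([5]), {("c", 5)})
        assert cands[0].masked

    def test_empty_mask_all_pass(self):
        cands = ec.mask_known_variants(self._cands([5, 6]), set())
        assert not any(c.masked for c in cands)

    def test_partial_masking_bookkeeping(self):
        cands = ec.mask_known_variants(
            self._cands([1, 2, 3, 4, 5]), {("c", 2), ("c", 4)}
        )
        assert sum(c.masked for c in cands) == 2
        assert [c.position for c in cands if not c.masked] == [1, 3, 5]


# ---------------------------------------------------------------------------
# bias tests vs oracles
# ---------------------------------------------------------------------------


class TestStrandBias:
    def test_perfect_balance(self):
        col = make_column(
            n_ref=20, n_alt=20,
            ref_strands=["+"] * 10 + ["-"] * 10,
            alt_strands=["+"] * 10 + ["-"] * 10,
        )
        assert ec.strand_bias_test(col) == 1.0

    def test_maximally_imbalanced_5v5(self):
        col = make_column(
            n_ref=5, n_alt=5, ref_strands=["+"] * 5, alt_strands=["-"] * 5
        )
        assert ec.strand_bias_test(col) == pytest.approx(2 / 252, rel=1e-9)

    def test_zero_margin_convention(self):
        col = make_column(n_ref=10, n_alt=0)
        assert ec.strand_bias_test(col) == 1.0

    def test_exhaustive_oracle_margins_le_12(self):
        for r1, r2 in product(range(13), repeat=2):
            for a in range(r1 + 1):
                for c in range(r2 + 1):
                    b, d = r1 - a, r2 - c
                    if min(r1, r2) == 0 or min(a + c, b + d) == 0:
                        continue
                    col = PileupColumn("c", 0, "A")
                    col.counts = {
                        ("+", "A"): a, ("-", "A"): b,
                        ("+", "G"): c, ("-", "G"): d,
                    }
                    got = ec.strand_bias_test(col)
                    want = fisher_oracle(a, b, c, d)
                    assert got == pytest.approx(want, rel=1e-7, abs=1e-12), (
                        a, b, c, d,
                    )

    def test_two_sided_symmetry(self):
        col1 = make_column(
            n_ref=8, n_alt=6, ref_strands=["+"] * 6 + ["-"] * 2,
            alt_strands=["+"] * 1 + ["-"] * 5,
        )
        col2 = make_column(
            n_ref=6, n_alt=8, ref_strands=["+"] * 1 + ["-"] * 5,
            alt_strands=["+"] * 6 + ["-"] * 2,
        )
        # swapping ref/alt row labels leaves the two-sided p unchanged
        assert ec.strand_bias_test(col1) == pytest.approx(
            ec.strand_bias_test(col2, alt_base="G"), rel=1e-12
        )


class TestRankSumTests:
    def test_identical_offset_multisets(self):
        col = make_column(
            n_ref=6, n_alt=6, ref_offsets=[1, 2, 3, 4, 5, 6],
            alt_offsets=[1, 2, 3, 4, 5, 6],
        )
        p, untestable = ec.read_position_bias_test(col)
        assert p == 1.0 and not untestable

    def test_extreme_separation_10v10(self):
        col = make_column(
            n_ref=10, n_alt=10,
            alt_offsets=list(range(10)), ref_offsets=list(range(20, 30)),
        )
        p, _ = ec.read_position_bias_test(col)
        # exact two-sided p for complete separation at 10v10 is 2/C(20,10)
        assert p < 0.001

    def test_untestable_below_two_observations(self):
        col = make_column(n_ref=10, n_alt=1)
        p, untestable = ec.read_position_bias_test(col)
        assert p == 1.0 and untestable

    def test_u_statistic_matches_brute_force_50_random(self, rng):
        for _ in range(50):
            n1 = int(rng.integers(2, 12))
            n2 = int(rng.integers(2, 12))
            xs = rng.integers(0, 10, size=n1).tolist()
            ys = rng.integers(0, 10, size=n2).tolist()
            assert ec.rank_sum_u(xs, ys) == pytest.approx(brute_force_u(xs, ys))

    def test_normal_approx_close_to_exact_enumeration(self, rng):
        # calibration: asymptotic p within 0.08 of the exact permutation p
        for _ in range(10):
            xs = rng.integers(0, 30, size=7).tolist()
            ys = rng.integers(0, 30, size=7).tolist()
            col = make_column(
                n_ref=7, n_alt=7, ref_offsets=ys, alt_offsets=xs, read_len=64
            )
            p, _ = ec.read_position_bias_test(col)
            assert abs(p - exact_ranksum_pvalue(xs, ys)) < 0.08

    def test_variant_distance_same_contract(self):
        col = make_column(
            n_ref=10, n_alt=10,
            alt_offsets=[0, 1, 2, 3, 4, 45, 46, 47, 48, 49],  # dist_end <= 4
            ref_offsets=list(range(15, 25)),  # dist_end >= 15
        )
        p, _ = ec.variant_distance_bias_test(col)
        assert p < 0.001
        p_rp, _ = ec.read_position_bias_test(col)
        assert p_rp > 0.5  # offsets are balanced: only the distance test fires


# ---------------------------------------------------------------------------
# apply_filters
# ---------------------------------------------------------------------------


def simulate_candidate_pipeline(
    reference, profile, design, depth, error_rate, seed,
    min_cov=20, min_freq=0.05, artifact=None, mask=None,
):
    reads, truth = sd.simulate_rnaseq(
        reference, profile, design, depth=depth, error_rate=error_rate, seed=seed
    )
    pileups = {}
    for d in design:
        aln = pu.align_fixture_reads(reads[d.sample_id], reference)
        if artifact is not None:
            aln = sd.plant_artifact(aln, *artifact, reference, seed=seed)
        pileups[d.sample_id] = pu.build_pileup(aln, reference)
    cands = ec.detect_candidates(pileups, min_cov=min_cov, min_mean_freq=min_freq)
    ec.apply_filters(cands, pileups, mask=mask or set())
    return cands


class TestApplyFilters:
    def test_strand_skew_artifact_fails_strand_filter(self, small_reference):
        pos = a_positions(small_reference["tx1"], 100, 300)[0]
        cands = simulate_candidate_pipeline(
            small_reference, sd.EditingProfile([]), [SampleDesign("s", "WT")],
            depth=80, error_rate=0.0, seed=3,
            artifact=("tx1", pos, "strand_skew"),
        )
        cand = next(c for c in cands if c.position == pos)
        assert cand.filter_report.strand_bias_p < ec.DEFAULT_FILTER_P
        assert not cand.passed

    def test_end_cluster_artifact_fails_distance_filter(self, small_reference):
        pos = a_positions(small_reference["tx1"], 100, 300)[1]
        cands = simulate_candidate_pipeline(
            small_reference, sd.EditingProfile([]), [SampleDesign("s", "WT")],
            depth=80, error_rate=0.0, seed=3,
            artifact=("tx1", pos, "end_cluster"),
        )
        cand = next(c for c in cands if c.position == pos)
        assert cand.filter_report.variant_distance_p < 0.001
        assert not cand.passed

    def test_masked_site_fails_regardless(self, small_reference):
        pos = a_positions(small_reference["tx1"], 100, 300)[0]
        profile = sd.EditingProfile([sd.EditingSite("tx1", pos, "+", {"WT": 0.4})])
        cands = simulate_candidate_pipeline(
            small_reference, profile, [SampleDesign("s", "WT")],
            depth=80, error_rate=0.0, seed=3, mask={("tx1", pos)},
        )
        cand = next(c for c in cands if c.position == pos)
        assert cand.masked and not cand.passed

    def test_unbiased_sites_pass_at_nominal_level(self):
        # 200 synthetic unbiased columns; expected joint false-fail rate
        # ~3 x 1% at threshold 0.01, so >= 95% passing has slack
        rng = np.random.default_rng(99)
        read_len = 50
        n_pass = 0
        for _ in range(200):
            cov = 100
            edited = rng.random(cov) < 0.3
            col = PileupColumn("c", 7, "A")
            for e in edited:
                off = int(rng.integers(read_len))
                col.add(Observation(
                    "G" if e else "A", 37, off,
                    min(off, read_len - 1 - off), "+-"[rng.integers(2)],
                ))
            p_sb = ec.strand_bias_test(col)
            p_rp, _ = ec.read_position_bias_test(col)
            p_vd, _ = ec.variant_distance_bias_test(col)
            if min(p_sb, p_rp, p_vd) >= ec.DEFAULT_FILTER_P:
                n_pass += 1
        assert n_pass >= 190

    def test_perfect_precision_recall_error_free(self, small_reference):
        seq = small_reference["tx1"]
        above = a_positions(seq, 100, 280)[:3]
        below = a_positions(seq, 100, 280)[4:6]
        sites = [sd.EditingSite("tx1", p, "+", {"WT": 0.3, "KO": 0.3}) for p in above]
        sites += [sd.EditingSite("tx1", p, "+", {"WT": 0.01, "KO": 0.01}) for p in below]
        design = [SampleDesign(f"s{i}", "WT") for i in range(2)]
        cands = simulate_candidate_pipeline(
            small_reference, sd.EditingProfile(sites), design,
            depth=300, error_rate=0.0, seed=17,
        )
        called = {c.position for c in cands if c.passed}
        assert called == set(above)


# ---------------------------------------------------------------------------
# amplicon mode
# ---------------------------------------------------------------------------


class TestAmpliconSiteFrequencies:
    def _columns(self, freqs_by_pos, depth=10000):
        cols = []
        for pos, freq in freqs_by_pos.items():
            n_alt = round(freq * depth)
            cols.append(column_from_counts("amp", pos, "A", "G", depth - n_alt, n_alt))
        return cols

    def test_one_percent_boundary(self):
        cols = self._columns({10: 0.009, 20: 0.011, 30: 0.01})
        rows = ec.amplicon_site_frequencies(cols, min_freq=0.01)
        assert [r["position"] for r in rows] == [20, 30]

    def test_error_free_frequency_is_exact(self):
        cols = self._columns({10: 0.30}, depth=1000)
        [row] = ec.amplicon_site_frequencies(cols)
        assert row["frequency"] == pytest.approx(300 / 1000)
        assert row["coverage"] == 1000

    def test_zero_coverage_warns_empty(self):
        with pytest.warns(UserWarning, match="zero-coverage"):
            assert ec.amplicon_site_frequencies([PileupColumn("amp", 1, "A")]) == []

    def test_planted_near_threshold_site_detected(self, haplotypes_motif):
        amp, positions, haps = haplotypes_motif
        # single-site editing at 1.1%: binomial at depth 10000 clears 1% a.s.
        pi = np.zeros(32)
        pi[0] = 1 - 0.011
        pi[1] = 0.011  # first site edited
        reads, _ = sd.simulate_amplicon(
            [h.sequence for h in haps], [h.label for h in haps],
            pi, depth=10000, error_rate=0.0, seed=5,
        )
        ref = {"amp": amp}
        aln = pu.align_fixture_reads(reads, ref)
        cols = pu.build_pileup(aln, ref)
        rows = ec.amplicon_site_frequencies(cols, min_freq=0.01)
        assert positions[0] in [r["position"] for r in rows]


@pytest.fixture(scope="module")
def haplotypes_motif():
    from editscope.isoform_quant import enumerate_haplotypes, make_motif_amplicon

    amp, positions = make_motif_amplicon(length=120, seed=4)
    return amp, positions, enumerate_haplotypes(amp, positions)
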