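"""Diversity/differentiation statistics, exact tests, filters, summaries."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from fissionkit.formats import RegionSpec, VariantRecord
from fissionkit.popgen import (
    AncestrySegment,
    FilterConfig,
    GenotypeMatrix,
    SVRecord,
    ancestry_fraction_by_window,
    classify_windows,
    da_and_time,
    filter_variants,
    gene_density,
    hwe_exact_p,
    mann_whitney_p,
    region_contrast,
    selected_site_density,
    site_stats,
    sv_fixation_screen,
    window_stats,
)
from oracles import anova_fst_components, hwe_enumeration_p, mw_exact_bruteforce, pairwise_dxy, pairwise_pi


class TestSiteStats:
    def test_both_fixed_ref(self):
        g = np.zeros((3, 2), int)
        pi_x, pi_y, dxy, _ = site_stats(g, g)
        assert pi_x == pi_y == dxy == 0.0

    def test_fixed_difference_is_maximal(self):
        gx = np.zeros((2, 2), int)
        gy = np.ones((2, 2), int)
        pi_x, pi_y, dxy, (a, b, c) = site_stats(gx, gy)
        assert dxy == 1.0 and pi_x == pi_y == 0.0
        assert a / (a + b + c) == pytest.approx(1.0)

    def test_pi_matches_pairwise_definition(self):
        # j=2 alt of 4 chromosomes: 2*2*2/(4*3) = 2/3, the average over all
        # 6 chromosome pairs (4 of which differ)
        gx = np.array([[1, 1], [0, 0]])
        pi_x, *_ = site_stats(gx, np.zeros((2, 2), int))
        assert pi_x == pytest.approx(2 / 3)
        assert pi_x == pytest.approx(pairwise_pi(gx))

    def test_oracle_equivalence_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(150):
            nx, ny = rng.integers(2, 21, 2)
            gx = rng.integers(0, 2, (nx, 2))
            gy = rng.integers(0, 2, (ny, 2))
            pi_x, pi_y, dxy, (a, b, c) = site_stats(gx, gy)
            assert pi_x == pytest.approx(pairwise_pi(gx), abs=1e-12)
            assert pi_y == pytest.approx(pairwise_pi(gy), abs=1e-12)
            assert dxy == pytest.approx(pairwise_dxy(gx, gy), abs=1e-12)
            ao, bo, co = anova_fst_components(gx, gy)
            assert a == pytest.approx(ao, abs=1e-12)
            assert b == pytest.approx(bo, abs=1e-12)
            assert c == pytest.approx(co, abs=1e-12)

    def test_missingness_handled(self):
        gx = np.array([[0, 1], [-1, -1], [1, -1]])
        gy = np.array([[0, 0], [0, 0]])
        pi_x, _, dxy, _ = site_stats(gx, gy)
        # called X alleles: 0,1,1 -> pi = 2*2*1/(3*2) = 2/3; p_x = 2/3
        assert pi_x == pytest.approx(2 / 3)
        assert dxy == pytest.approx(2 / 3)


class TestWindowStats:
    def _matrix(self, positions, gx, gy):
        return GenotypeMatrix("chr1", np.array(positions), np.array(gx), np.array(gy))

    def test_fixed_difference_over_ten_callable_sites(self):
        m = self._matrix([3], [[[0, 0], [0, 0]]], [[[1, 1], [1, 1]]])
        (w,) = window_stats(
            m, window_size=10, chrom_length=10,
            callable_regions=[RegionSpec("chr1", 0, 10)],
        )
        assert w.dxy == pytest.approx(0.1)
        assert w.da == pytest.approx(0.1)

    def test_monomorphic_matrix_all_zero(self):
        m = self._matrix(
            [5, 25], [[[0, 0]] * 3] * 2, [[[0, 0]] * 3] * 2
        )
        wins = window_stats(m, window_size=20, chrom_length=40)
        assert all(w.pi_x == 0 and w.dxy == 0 for w in wins)

    def test_ratio_of_sums_concatenation_identity(self):
        rng = np.random.default_rng(5)
        gx = rng.integers(0, 2, (30, 4, 2))
        gy = rng.integers(0, 2, (30, 5, 2))
        positions = np.arange(30) * 10
        m = self._matrix(positions, gx, gy)
        two = window_stats(m, window_size=150, chrom_length=300)
        one = window_stats(m, window_size=300, chrom_length=300)
        from fissionkit.popgen import sitewise_stats

        ps = sitewise_stats(m.gx, m.gy)
        direct = ps.a.sum() / (ps.a + ps.b + ps.c).sum()
        assert one[0].fst == pytest.approx(direct, abs=1e-12)
        num = dent = 0.0
        for w in two:
            pass  # windowed values are per-site ratios; recombine via components
        sub1 = ps[(positions < 150)]
        sub2 = ps[(positions >= 150)]
        recombined = (sub1.a.sum() + sub2.a.sum()) / (
            (sub1.a + sub1.b + sub1.c).sum() + (sub2.a + sub2.b + sub2.c).sum()
        )
        assert recombined == pytest.approx(direct, abs=1e-12)

    def test_empty_window_emitted_with_nan(self):
        m = self._matrix([5], [[[0, 1]] * 2], [[[0, 0]] * 2])
        wins = window_stats(
            m, window_size=10, chrom_length=20,
            callable_regions=[RegionSpec("chr1", 0, 10)],
        )
        assert len(wins) == 2
        assert math.isnan(wins[1].dxy) and wins[1].n_callable == 0

    def test_classify_windows(self):
        m = self._matrix([5], [[[0, 0]]], [[[0, 0]]])
        wins = window_stats(m, window_size=10, chrom_length=30)
        classed = classify_windows(
            wins, [RegionSpec("chr1", 0, 10, "breakpoint_flank")]
        )
        assert [w.region_class for w in classed] == [
            "breakpoint_flank", "other", "other",
        ]


class TestDaTime:
    def test_zero_da_undefined(self):
        est = da_and_time(0.01, 0.01, 0.01, mu=3.03e-9)
        assert est.da == pytest.approx(0.0) and not est.defined

    def test_direct_evaluation_at_study_mu(self):
        est = da_and_time(6.06e-4, 0.0, 0.0, mu=3.03e-9)
        assert est.t_generations == pytest.approx(1e5)
        assert est.t_years == pytest.approx(1e5)  # 1 yr per generation

    def test_linearity(self):
        t1 = da_and_time(2e-4, 0, 0, mu=1e-8).t_generations
        t2 = da_and_time(4e-4, 0, 0, mu=1e-8).t_generations
        assert t2 == pytest.approx(2 * t1)

    def test_negative_da_reported_raw(self):
        est = da_and_time(0.001, 0.004, 0.002, mu=1e-8)
        assert est.da == pytest.approx(-0.002) and est.t_generations is None

    def test_bad_mu_rejected(self):
        with pytest.raises(ValueError):
            da_and_time(0.01, 0, 0, mu=0)


class TestHwe:
    def test_monomorphic_p_is_one(self):
        assert hwe_exact_p(5, 0, 0) == pytest.approx(1.0)

    def test_two_hets_enumeration(self):
        assert hwe_exact_p(0, 2, 0) == pytest.approx(hwe_enumeration_p(0, 2, 0))

    def test_allele_label_symmetry(self):
        for aa, ab, bb in [(3, 1, 7), (0, 5, 2), (4, 4, 4)]:
            assert hwe_exact_p(aa, ab, bb) == pytest.approx(hwe_exact_p(bb, ab, aa))

    def test_matches_enumeration_many_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(80):
            aa, ab, bb = rng.integers(0, 11, 3)
            if aa + ab + bb == 0:
                continue
            assert hwe_exact_p(aa, ab, bb) == pytest.approx(
                hwe_enumeration_p(aa, ab, bb), abs=1e-9
            )


class TestMannWhitney:
    def test_identical_multisets_p_one(self):
        assert mann_whitney_p([1, 2], [1, 2]) == pytest.approx(1.0)
        assert mann_whitney_p([1, 2], [1, 2]) == pytest.approx(
            mw_exact_bruteforce([1, 2], [1, 2])
        )

    def test_fully_separated_small_samples(self):
        assert mann_whitney_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_exact_matches_bruteforce_with_ties(self):
        rng = np.random.default_rng(13)
        for _ in range(15):
            x = rng.integers(0, 4, rng.integers(2, 6)).tolist()
            y = rng.integers(0, 4, rng.integers(2, 6)).tolist()
            assert mann_whitney_p(x, y) == pytest.approx(
                mw_exact_bruteforce(x, y), abs=1e-9
            )

    def test_exact_close_to_normal_approximation_at_n12(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            x = rng.normal(size=12)
            y = rng.normal(loc=0.3, size=12)
            exact = mann_whitney_p(x, y, exact_max_n=12)
            approx = mann_whitney_p(x, y, exact_max_n=0)
            assert abs(exact - approx) <= 0.02


class TestRegionContrast:
    def _win(self, fst, cls):
        return type(
            "W", (), {"region_class": cls, "fst": fst}
        )()

    def test_summaries_and_pairwise_p(self):
        wins = (
            [self._win(v, "fissioned") for v in [1.0, 2.0, 3.0]]
            + [self._win(v, "other") for v in [4.0, 5.0, 6.0]]
        )
        rep = region_contrast(wins, statistic="fst")
        assert rep["classes"]["fissioned"] == {"n": 3, "mean": 2.0, "median": 2.0}
        assert rep["classes"]["other"]["mean"] == pytest.approx(5.0)
        (cmp_,) = rep["comparisons"]
        assert cmp_["p"] == pytest.approx(0.1)

    def test_small_class_omitted_with_note(self):
        wins = [self._win(1.0, "a")] + [self._win(v, "b") for v in [1, 2, 3]]
        rep = region_contrast(wins, statistic="fst")
        assert rep["comparisons"] == []
        assert any("omitted" in n for n in rep["notes"])


class TestFilter:
    def _rec(self, pos, alts=("G",), gts=None, dp=30, gq=99, n=4):
        gts = gts if gts is not None else [(0, 1)] * n
        return VariantRecord(
            "chr1", pos, "A", alts, gts, [dp] * n, [gq] * n,
            [f"S{i}" for i in range(n)],
        )

    def test_low_maf_removed_with_reason(self):
        # 1 alt allele among 24 -> MAF 0.042 < 0.05
        rec = self._rec(10, gts=[(0, 1)] + [(0, 0)] * 11, n=12)
        kept, removed = filter_variants([rec])
        assert kept == [] and removed[0][1] == "maf"

    def test_low_gq_masks_genotype(self):
        rec = self._rec(10, gq=19, gts=[(0, 1)] * 4)
        _, removed = filter_variants([rec])
        # every genotype masked -> site fails the missingness rule
        assert removed[0][1] == "missing"
        assert all(g == (-1, -1) for g in removed[0][0].genotypes)

    def test_each_rule_trips_once_with_one_survivor(self):
        # alternating hom pattern keeps MAF=0.5 with an in-HWE configuration
        balanced = [(0, 1)] * 8
        records = [
            self._rec(100, alts=("G", "T"), gts=balanced, n=8),     # multiallelic
            self._rec(200, gts=balanced, n=8),                      # near indel (pos 203)
            self._rec(300, gts=[(-1, -1)] * 4 + balanced[:4], n=8), # missing
            self._rec(400, gts=[(0, 1)] + [(0, 0)] * 11, n=12),     # maf 1/24
            self._rec(500, gts=[(0, 1)] * 8, n=8),                  # all-het: HWE fails
            self._rec(600, gts=[(0, 0), (0, 1), (0, 1), (1, 1)] * 2, n=8),  # survivor
        ]
        cfg = FilterConfig(hwe_alpha=0.05)
        kept, removed = filter_variants(records, cfg, {"chr1": [203]})
        assert len(kept) == 1 and kept[0].pos == 600
        assert sorted(r for _, r in removed) == sorted(
            ["multiallelic", "near_indel", "missing", "maf", "hwe"]
        )

    def test_indel_proximity_boundary(self):
        near = self._rec(100, gts=[(0, 0), (0, 1), (0, 1), (1, 1)])
        far = self._rec(200, gts=[(0, 0), (0, 1), (0, 1), (1, 1)])
        kept, removed = filter_variants(
            [near, far], FilterConfig(), {"chr1": [105, 206]}
        )
        assert [r.pos for r in kept] == [200]  # distance 6 survives, 5 does not
        assert removed[0][1] == "near_indel"

    def test_idempotence(self):
        rng = np.random.default_rng(3)
        records = [
            self._rec(
                int(p),
                gts=[tuple(rng.integers(0, 2, 2)) for _ in range(8)],
                dp=int(rng.integers(1, 60)),
                gq=int(rng.integers(5, 99)),
                n=8,
            )
            for p in rng.choice(10_000, 30, replace=False)
        ]
        kept1, _ = filter_variants(records)
        kept2, removed2 = filter_variants(kept1)
        assert removed2 == []
        assert [r.pos for r in kept2] == [r.pos for r in kept1]


class TestSvScreen:
    def _sv(self, sv_id, length, focal, others):
        return SVRecord(sv_id, length, {"focal_sp": focal, "other_sp": others})

    def test_fixed_in_focal_absent_elsewhere_flagged(self):
        sv = self._sv("sv1", 1129, [2] * 14, [0] * 159)
        assert sv_fixation_screen([sv], "focal_sp") == ["sv1"]

    def test_one_nonfixed_focal_individual_blocks(self):
        sv = self._sv("sv1", 1129, [2] * 13 + [1], [0] * 159)
        assert sv_fixation_screen([sv], "focal_sp") == []

    def test_short_sv_excluded_before_screening(self):
        sv = self._sv("sv1", 49, [2] * 14, [0] * 159)
        assert sv_fixation_screen([sv], "focal_sp") == []

    def test_high_missing_rate_excluded(self):
        sv = self._sv("sv1", 100, [2] * 10 + [None] * 4, [0] * 20)
        assert sv_fixation_screen([sv], "focal_sp") == []

    def test_unknown_species_rejected(self):
        sv = self._sv("sv1", 100, [2], [0])
        with pytest.raises(ValueError, match="nope"):
            sv_fixation_screen([sv], "nope")


class TestDensities:
    def test_selected_site_density(self):
        pos = np.array([10, 20, 30, 150_000, 250_000])
        scores = np.array([2.5, 2.1, 1.9, -2.5, 0.0])
        df = selected_site_density(pos, scores, chrom_length=300_000)
        assert df.focal_density.tolist() == [2.0, 0.0, 0.0]
        assert df.other_density.tolist() == [0.0, 1.0, 0.0]
        assert df.focal_density.sum() + df.other_density.sum() == 3  # conservation

    def test_gene_density_counts_by_start(self):
        genes = [
            RegionSpec("chr1", 10, 100),
            RegionSpec("chr1", 20, 30),
            RegionSpec("chr1", 49_990, 60_000),  # spans boundary: counted once, left
        ]
        res = gene_density(genes, window=50_000, chrom_lengths={"chr1": 100_000})
        assert res["counts"]["chr1"].tolist() == [3, 0]
        assert sum(c.sum() for c in res["counts"].values()) == res["total_genes"]
        assert res["mean_genome"] == pytest.approx(1.5)


class TestAncestry:
    def _w(self):
        return RegionSpec("chr1", 100_000, 140_000)

    def test_all_self_is_zero(self):
        segs = [AncestrySegment("h1", "chr1", 0, 200_000, "self"),
                AncestrySegment("h2", "chr1", 0, 200_000, "self")]
        assert ancestry_fraction_by_window(segs, self._w()) == 0.0

    def test_one_of_two_haplotypes_fully_foreign(self):
        segs = [AncestrySegment("h1", "chr1", 0, 200_000, "foreign"),
                AncestrySegment("h2", "chr1", 0, 200_000, "self")]
        assert ancestry_fraction_by_window(segs, self._w()) == pytest.approx(0.5)

    def test_partial_overlap_base_counting(self):
        segs = [AncestrySegment("h1", "chr1", 110_000, 120_000, "foreign"),
                AncestrySegment("h2", "chr1", 0, 200_000, "self")]
        assert ancestry_fraction_by_window(segs, self._w()) == pytest.approx(0.125)

    def test_overlapping_segments_rejected(self):
        segs = [AncestrySegment("h1", "chr1", 0, 50_000, "self"),
                AncestrySegment("h1", "chr1", 40_000, 90_000, "foreign")]
        with pytest.raises(ValueError, match="overlap"):
            ancestry_fraction_by_window(segs, self._w())
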