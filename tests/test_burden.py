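"""Read-depth genotype calling, QC, CAST/SKAT, genomic control and the
orthogonal age-of-onset / familiality tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regmod.burden import (
    bonferroni_threshold,
    age_onset_test,
    call_genotype_from_depth,
    call_genotypes_from_depth_table,
    cast_test,
    direction_from_theta,
    familiality_test,
    fisher_combine,
    gc_correct,
    gene_burden_scan,
    genomic_control,
    global_shift_test,
    hwe_exact_test,
    module_burden_test,
    sample_qc,
    skat_test,
    variant_qc,
)
from regmod.containers import MISSING
from regmod.synth import RareVariantSpec, simulate_rare_variants


def _variant_table(n, gene="G1", category="damaging", maf=0.003):
    return pd.DataFrame(
        {
            "variant_id": [f"{gene}_v{i}" for i in range(n)],
            "gene": gene,
            "category": category,
            "maf": maf,
        }
    )


class TestGenotypeFromDepth:
    @pytest.mark.parametrize(
        "ref, alt, expected",
        [
            (28, 2, 0),     # fraction 0.067 -> homozygote reference
            (15, 15, 1),    # fraction 0.5 -> heterozygote
            (2, 28, 2),     # fraction 0.93 -> homozygote alternate
            (10, 8, MISSING),   # depth 18 < 20
            (24, 6, MISSING),   # fraction 0.20 outside the intervals
            (0, 0, MISSING),    # no reads at all
            (17, 3, 0),     # fraction exactly 0.15, boundary inclusive
            (15, 5, 1),     # fraction exactly 0.25
            (3, 17, 2),     # fraction exactly 0.85
        ],
    )
    def test_interval_mapping(self, ref, alt, expected):
        assert call_genotype_from_depth(ref, alt) == expected

    def test_depth_table_pivot(self):
        depths = pd.DataFrame(
            {
                "sample": ["s1", "s1", "s2"],
                "variant": ["v1", "v2", "v1"],
                "ref_reads": [30, 15, 2],
                "alt_reads": [0, 15, 28],
            }
        )
        samples, variants, geno = call_genotypes_from_depth_table(depths)
        assert samples == ["s1", "s2"] and variants == ["v1", "v2"]
        assert geno[0, 0] == 0 and geno[0, 1] == 1 and geno[1, 0] == 2
        assert geno[1, 1] == MISSING  # absent pair


class TestHweExact:
    def _oracle(self, n0, n1, n2):
        # independent integer-arithmetic enumeration of the conditional
        # distribution of heterozygote counts
        n = n0 + n1 + n2
        rare = min(2 * n0 + n1, 2 * n2 + n1)

        def weight(h):
            nr = (rare - h) // 2
            nc = n - h - nr
            return (
                2**h
                * math.factorial(n)
                // (math.factorial(nr) * math.factorial(h) * math.factorial(nc))
            )

        hs = list(range(rare % 2, rare + 1, 2))
        ws = [weight(h) for h in hs]
        total = sum(ws)
        obs = ws[hs.index(n1)]
        return sum(w for w in ws if w <= obs) / total

    @pytest.mark.parametrize("counts", [(25, 50, 25), (90, 0, 10), (57, 14, 50), (5, 1, 0)])
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(self._oracle(*counts), rel=1e-9)

    def test_equilibrium_counts_retained(self):
        assert hwe_exact_test(25, 50, 25) > 0.05

    def test_strong_departure_detected(self):
        assert hwe_exact_test(90, 0, 10) < 1e-6


class TestQc:
    def test_call_rate_filter(self, rng):
        variants = _variant_table(2)
        geno = rng.integers(0, 2, size=(100, 2)).astype(np.int8)
        geno[:6, 0] = MISSING  # call rate 0.94
        kept, g = variant_qc(variants, geno)
        assert list(kept["variant_id"]) == ["G1_v1"]

    def test_hwe_filter(self):
        variants = _variant_table(2)
        good = np.r_[np.zeros(25), np.ones(50), np.full(25, 2)].astype(np.int8)
        bad = np.r_[np.zeros(90), np.full(10, 2)].astype(np.int8)
        geno = np.column_stack([good, bad])
        kept, g = variant_qc(variants, geno)
        assert list(kept["variant_id"]) == ["G1_v0"]

    def test_sample_qc_rules(self):
        coverage = np.array([0.99, 0.94, 0.99, 0.99])
        panel = np.array([[0, 0], [0, 0], [1, 0], [1, 1]], dtype=np.int8)
        kept = sample_qc(coverage, panel)
        # sample 1 fails coverage; sample 3 carries 2 panel minor alleles
        assert list(kept) == [0, 2]


class TestCast:
    def test_no_carriers_gives_one(self, rng):
        status = np.r_[np.ones(50), np.zeros(50)]
        assert cast_test(np.zeros(100, dtype=bool), status, "cases", 200, rng) == 1.0

    def test_matches_hypergeometric_oracle(self):
        # 8 carriers among 100 cases vs 1 among 100 controls
        carrier = np.zeros(200, dtype=bool)
        carrier[:8] = True
        carrier[100] = True
        status = np.r_[np.ones(100), np.zeros(100)]
        n_perm = 20_000
        p = cast_test(carrier, status, "cases", n_perm, np.random.default_rng(0))
        exact = stats.hypergeom.sf(7, 200, 9, 100)
        se = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(p - exact) < 3 * se + 2 / n_perm

    def test_label_and_direction_flip_symmetry(self):
        rng_a = np.random.default_rng(42)
        rng_b = np.random.default_rng(42)
        carrier = np.zeros(200, dtype=bool)
        carrier[[0, 1, 2, 150, 151]] = True
        status = np.r_[np.ones(100), np.zeros(100)]
        p1 = cast_test(carrier, status, "cases", 2000, rng_a)
        p2 = cast_test(carrier, 1 - status, "controls", 2000, rng_b)
        assert p1 == p2

    def test_direction_mapping_from_theta(self):
        assert direction_from_theta(-0.8) == "cases"
        assert direction_from_theta(0.8) == "controls"


class TestSkat:
    def test_single_variant_matches_two_sided_permutation(self):
        # with one variant, Q is a monotone function of the squared score,
        # so its permutation p equals a two-sided single-variant carrier test
        rng = np.random.default_rng(1)
        g = np.zeros(300, dtype=np.int8)
        g[rng.choice(300, 12, replace=False)] = 1
        status = np.r_[np.ones(150), np.zeros(150)]
        n_perm = 10_000
        p_skat = skat_test(g[:, None], [0.02], status, n_perm, np.random.default_rng(5))
        # two-sided oracle by direct permutation of the score
        obs = abs(np.sum(g * (status - status.mean())))
        r = np.random.default_rng(5)
        perm = np.array(
            [abs(np.sum(g * (r.permutation(status) - 0.5))) for _ in range(n_perm)]
        )
        p_oracle = (1 + np.sum(perm >= obs)) / (n_perm + 1)
        se = np.sqrt(p_oracle * (1 - p_oracle) / n_perm)
        assert abs(p_skat - p_oracle) < 3 * se + 2 / n_perm

    def test_tiny_cohort_matches_exhaustive_enumeration(self):
        from itertools import combinations

        rng = np.random.default_rng(2)
        n = 10
        g = np.array([[1, 0], [0, 1], [1, 1], [0, 0], [2, 0],
                      [0, 0], [1, 0], [0, 0], [0, 1], [0, 0]], dtype=np.int8)
        status = np.r_[np.ones(5), np.zeros(5)]
        w = np.ones(2)
        def q_of(y):
            yc = y - y.mean()
            return float(np.sum((g.T.astype(float) @ yc) ** 2))
        q_obs = q_of(status)
        qs = []
        for cases in combinations(range(n), 5):
            y = np.zeros(n)
            y[list(cases)] = 1
            qs.append(q_of(y))
        exact = np.mean(np.array(qs) >= q_obs - 1e-12)
        p = skat_test(g, [0.1, 0.1], status, 20_000, rng)
        assert abs(p - exact) < 0.02

    def test_singleton_exclusion(self, rng):
        g = np.zeros((100, 2), dtype=np.int8)
        g[0, 0] = 1          # singleton
        g[[1, 2, 3], 1] = 1  # three carriers
        status = np.r_[np.ones(50), np.zeros(50)]
        p_all = skat_test(g, [0.01, 0.01], status, 500, np.random.default_rng(3))
        p_excl = skat_test(
            g, [0.01, 0.01], status, 500, np.random.default_rng(3),
            include_singletons=False,
        )
        assert not np.isnan(p_all) and not np.isnan(p_excl)
        only_singleton = skat_test(
            g[:, [0]], [0.01], status, 500, rng, include_singletons=False
        )
        assert np.isnan(only_singleton)


class TestGenomicControl:
    def test_uniform_grid_gives_unit_lambda(self):
        p = (np.arange(1, 1000) - 0.5) / 999
        lam, corrected = genomic_control(p)
        assert lam == pytest.approx(1.0, abs=1e-3)

    def test_closed_form_value(self):
        lam, _ = genomic_control(np.full(11, 0.05))
        assert lam == pytest.approx(stats.chi2.isf(0.05, 1) / stats.chi2.isf(0.5, 1), rel=1e-6)
        assert lam == pytest.approx(8.445, abs=0.01)

    def test_unit_lambda_is_identity(self, rng):
        p = rng.uniform(size=20)
        np.testing.assert_allclose(gc_correct(p, 1.0), p, rtol=1e-9)

    def test_order_preserving(self, rng):
        p = np.sort(rng.uniform(size=50))
        corrected = gc_correct(p, 1.73)
        assert np.all(np.diff(corrected) >= -1e-15)


class TestFisherCombine:
    def test_single_p_recovered(self):
        stat, p = fisher_combine([0.07])
        assert p == pytest.approx(0.07, rel=1e-9)

    def test_all_ones_give_one(self):
        stat, p = fisher_combine([1.0, 1.0, 1.0])
        assert stat == 0.0 and p == 1.0

    def test_hand_computed_pair(self):
        stat, p = fisher_combine([0.05, 0.05])
        assert stat == pytest.approx(-4 * np.log(0.05), rel=1e-12)
        assert p == pytest.approx(stats.chi2.sf(stat, 4), rel=1e-12)


def _null_cohort(n_genes, n_cases, n_controls, seed, rr=1.0, n_causal=0):
    rng = np.random.default_rng(seed)
    frames, cols = [], []
    for k in range(n_genes):
        gene_rr = rr if k < n_causal else 1.0
        spec = RareVariantSpec(
            n_variants={"damaging": 12, "synonymous": 12},
            relative_risk={"LoF": gene_rr, "damaging": gene_rr},
            maf_range=(0.0005, 0.004),
        )
        v, g = simulate_rare_variants(n_cases, n_controls, spec, rng, gene=f"G{k}")
        frames.append(v)
        cols.append(g)
    variants = pd.concat(frames, ignore_index=True)
    genotypes = np.column_stack(cols)
    status = np.r_[np.ones(n_cases, dtype=int), np.zeros(n_controls, dtype=int)]
    return variants, genotypes, status, rng


class TestGeneScanAndGlobalShift:
    def test_null_scan_is_calibrated(self):
        ps_cast, ps_skat = [], []
        for seed in range(60):
            variants, genotypes, status, rng = _null_cohort(1, 300, 300, seed)
            scan = gene_burden_scan(
                variants, genotypes, status, {}, n_perm=200, rng=rng, lambda_gc=1.0
            )
            ps_cast.append(scan.results[0].cast_p)
            ps_skat.append(scan.results[0].skat_p_raw)
        for ps in (ps_cast, ps_skat):
            assert np.mean(np.array(ps) <= 0.05) <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 60)

    def test_common_variant_never_qualifies(self):
        variants, genotypes, status, rng = _null_cohort(1, 300, 300, 5)
        scan1 = gene_burden_scan(
            variants, genotypes, status, {}, n_perm=300,
            rng=np.random.default_rng(9), lambda_gc=1.0,
        )
        extra = pd.DataFrame(
            {"variant_id": ["common"], "gene": ["G0"], "category": ["damaging"], "maf": [0.05]}
        )
        variants2 = pd.concat([variants, extra], ignore_index=True)
        genotypes2 = np.column_stack(
            [genotypes, np.random.default_rng(0).binomial(2, 0.05, size=len(status))]
        )
        scan2 = gene_burden_scan(
            variants2, genotypes2, status, {}, n_perm=300,
            rng=np.random.default_rng(9), lambda_gc=1.0,
        )
        assert scan1.results[0].cast_p == scan2.results[0].cast_p
        assert scan1.results[0].skat_p_raw == scan2.results[0].skat_p_raw

    def test_planted_burden_shifts_distribution(self):
        variants, genotypes, status, rng = _null_cohort(
            10, 2000, 2000, seed=1, rr=3.0, n_causal=3
        )
        scan = gene_burden_scan(variants, genotypes, status, {}, n_perm=400, rng=rng)
        shift = global_shift_test(scan)
        assert shift["shift_p"] < 0.05
        assert shift["observed_ranked"].shape == shift["rank_median"].shape
        assert np.all(shift["rank_lo"] <= shift["rank_hi"])

    def test_shift_null_is_uniformish(self):
        ps = []
        for seed in range(25):
            variants, genotypes, status, rng = _null_cohort(6, 300, 300, seed + 100)
            scan = gene_burden_scan(
                variants, genotypes, status, {}, n_perm=200, rng=rng, lambda_gc=1.0
            )
            ps.append(global_shift_test(scan)["shift_p"])
        assert np.mean(np.array(ps) <= 0.05) <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 25)
        assert 0.2 < np.mean(ps) < 0.8


class TestModuleBurden:
    def test_single_gene_module_equals_gene_p(self):
        variants, genotypes, status, rng = _null_cohort(3, 400, 400, 7)
        scan = gene_burden_scan(
            variants, genotypes, status, {}, n_perm=300, rng=rng, lambda_gc=1.0
        )
        table = module_burden_test(scan, {"m0": ["G0"]})
        i = scan.genes.index("G0")
        # identical permutation pool: the module p is the gene's pool rank
        pool = scan.best_p_pool[i]
        expected = (1 + np.sum(-2 * np.log(pool[1:]) >= -2 * np.log(pool[0]))) / pool.size
        assert table["p_value"].iloc[0] == pytest.approx(expected)

    def test_bonferroni_thresholds(self):
        assert bonferroni_threshold(45) == pytest.approx(0.05 / 90)
        assert bonferroni_threshold(30) == pytest.approx(0.05 / 60)


class TestOrthogonalTests:
    def test_no_carriers_untested(self, rng):
        assert np.isnan(age_onset_test(np.zeros(10, bool), np.arange(10.0), "cases", 100, rng))
        assert np.isnan(familiality_test(np.zeros(10, bool), np.zeros(10, bool), "cases", 100, rng))

    def test_youngest_carriers_hit_floor(self, rng):
        onsets = np.arange(10.0, 110.0)
        carriers = np.zeros(100, bool)
        carriers[:5] = True  # the five youngest cases
        p = age_onset_test(carriers, onsets, "cases", n_draw=3000, rng=rng)
        assert p == pytest.approx(1 / 3001)

    def test_all_cases_familial_is_uninformative(self, rng):
        carriers = np.zeros(50, bool)
        carriers[:4] = True
        p = familiality_test(carriers, np.ones(50, bool), "cases", 500, rng)
        assert p == 1.0

    def test_familiality_matches_hypergeometric(self):
        familial = np.zeros(100, bool)
        familial[:20] = True  # base rate 0.2
        carriers = np.zeros(100, bool)
        carriers[:10] = True  # all carriers familial
        n_draw = 20_000
        p = familiality_test(carriers, familial, "cases", n_draw, np.random.default_rng(8))
        exact = stats.hypergeom.sf(9, 100, 20, 10) + stats.hypergeom.pmf(10, 100, 20, 10)
        se = np.sqrt(exact * (1 - exact) / n_draw)
        assert abs(p - exact) < 3 * se + 2 / n_draw

    def test_null_onset_calibration(self):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(100):
            onsets = rng.normal(30, 8, size=80)
            carriers = np.zeros(80, bool)
            carriers[rng.choice(80, 6, replace=False)] = True
            ps.append(age_onset_test(carriers, onsets, "cases", 300, rng))
        assert abs(np.mean(ps) - 0.5) < 3 / np.sqrt(12 * 100) + 0.02
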