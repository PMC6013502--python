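"""Sequencing QC and eQTL-informed rare-variant burden tests.

Genotypes are called from per-sample read depths, filtered on call rate,
Hardy-Weinberg equilibrium and ancestry-panel carriage, and qualifying
variants (LoF + damaging, MAF <= 0.005 over cases + controls) are tested
per gene with two complementary statistics:

* CAST — collapsing test on the carrier-frequency difference, one-sided
  with the side chosen by the sign of the gene's theta with the disease
  (theta < 0: enrichment in cases; theta > 0: enrichment in controls);
* SKAT-style variance-component score Q = sum_j w_j^2 (G_j' (y - ybar))^2,
  which is sensitive to mixed-direction effects.

All p values come from phenotype permutation (add-one convention).  SKAT p
values are deflated by a median-based genomic-control lambda, estimated on
the synonymous control category when available.  Per-gene best p values
feed a Fisher-combination global-shift test (with per-rank confidence
bands), a module-level combination test, and orthogonal age-of-onset and
familiality tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .containers import MISSING

logger = logging.getLogger(__name__)

QUALIFYING_CATEGORIES = ("LoF", "damaging")
CHI2_MEDIAN_1DF = float(stats.chi2.isf(0.5, 1))  # 0.4549...


# ---------------------------------------------------------------------------
# genotype calling and QC


def call_genotype_from_depth(ref_reads: int, alt_reads: int, min_depth: int = 20) -> int:
    """Genotype from the alternate-allele read fraction.

    [0, 0.15] -> 0, [0.25, 0.75] -> 1, [0.85, 1] -> 2; anything else, or
    total depth below ``min_depth``, is missing.
    """
    depth = ref_reads + alt_reads
    if depth < min_depth:
        return MISSING
    frac = alt_reads / depth
    if frac <= 0.15:
        return 0
    if 0.25 <= frac <= 0.75:
        return 1
    if frac >= 0.85:
        return 2
    return MISSING


def call_genotypes_from_depth_table(
    depths: pd.DataFrame, min_depth: int = 20
) -> tuple[list[str], list[str], np.ndarray]:
    """Pivot a (sample, variant, ref_reads, alt_reads) table into a
    genotype matrix; absent pairs are missing.

    Returns (sample ids, variant ids, genotype matrix).
    """
    samples = sorted(depths["sample"].unique())
    variants = sorted(depths["variant"].unique())
    s_idx = {s: i for i, s in enumerate(samples)}
    v_idx = {v: j for j, v in enumerate(variants)}
    geno = np.full((len(samples), len(variants)), MISSING, dtype=np.int8)
    for row in depths.itertuples(index=False):
        geno[s_idx[row.sample], v_idx[row.variant]] = call_genotype_from_depth(
            row.ref_reads, row.alt_reads, min_depth
        )
    return samples, variants, geno


def hwe_exact_test(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Exact Hardy-Weinberg test (conditional on allele counts).

    Sums the probabilities of all heterozygote counts no more likely than
    the observed one.
    """
    n = n_homref + n_het + n_homalt
    if n == 0:
        return 1.0
    rare = min(2 * n_homref + n_het, 2 * n_homalt + n_het)
    hs = np.arange(rare % 2, rare + 1, 2)
    n_rare_hom = (rare - hs) // 2
    n_common_hom = n - hs - n_rare_hom
    logp = (
        hs * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(n_rare_hom + 1)
        - gammaln(hs + 1)
        - gammaln(n_common_hom + 1)
        + gammaln(rare + 1)
        + gammaln(2 * n - rare + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[np.flatnonzero(hs == n_het)[0]]
    return float(np.sum(probs[probs <= obs * (1 + 1e-12)]))


def variant_qc(
    variants: pd.DataFrame,
    genotypes: np.ndarray,
    call_rate_min: float = 0.95,
    hwe_alpha: float = 1e-6,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Drop variants with low call rate or strong HWE departure (pooled)."""
    called = genotypes != MISSING
    call_rate = called.mean(axis=0)
    keep = call_rate >= call_rate_min
    for j in np.flatnonzero(keep):
        g = genotypes[called[:, j], j]
        p_hwe = hwe_exact_test(int(np.sum(g == 0)), int(np.sum(g == 1)), int(np.sum(g == 2)))
        if p_hwe < hwe_alpha:
            keep[j] = False
            logger.info("variant %s fails HWE (p=%.2e)", variants["variant_id"].iloc[j], p_hwe)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("variant QC removed %d of %d variants", n_drop, keep.size)
    return variants[keep].reset_index(drop=True), genotypes[:, keep]


def sample_qc(
    coverage_fraction: np.ndarray,
    panel_genotypes: np.ndarray,
    min_fraction: float = 0.95,
    panel_allele_max: int = 1,
) -> np.ndarray:
    """Kept sample indices: adequate target coverage and at most
    ``panel_allele_max`` minor alleles across the ancestry panel."""
    cov_ok = np.asarray(coverage_fraction) >= min_fraction
    panel = np.asarray(panel_genotypes)
    panel_counts = np.where(panel == MISSING, 0, panel).sum(axis=1)
    return np.flatnonzero(cov_ok & (panel_counts <= panel_allele_max))


def qualifying_mask(
    variants: pd.DataFrame,
    maf_max: float = 0.005,
    categories=QUALIFYING_CATEGORIES,
) -> np.ndarray:
    """LoF/damaging variants at MAF <= maf_max over the full cohort."""
    return (
        variants["category"].isin(categories) & (variants["maf"] <= maf_max)
    ).values


def direction_from_theta(theta: float) -> str:
    """theta < 0 (reduced expression raises risk): disruptive variants are
    expected in cases; theta > 0: in controls."""
    return "cases" if theta < 0 else "controls"


# ---------------------------------------------------------------------------
# permutation machinery


def _label_matrix(status: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """(n, n_perm+1) float32 case indicators; column 0 is observed."""
    status = np.asarray(status)
    cols = np.empty((status.size, n_perm + 1), dtype=np.float32)
    cols[:, 0] = status
    for k in range(1, n_perm + 1):
        cols[:, k] = rng.permutation(status)
    return cols


def _pool_pvalues(stats_vec: np.ndarray) -> np.ndarray:
    """Each labeling's add-one permutation p against the remaining pool."""
    s = np.asarray(stats_vec, dtype=float)
    order = np.sort(s)
    count_ge = s.size - np.searchsorted(order, s, side="left")
    return count_ge / s.size  # (1 + #{j != k: s_j >= s_k}) / (n_perm + 1)


def cast_statistics(carrier: np.ndarray, labels: np.ndarray, direction: str) -> np.ndarray:
    """Signed carrier-frequency difference per labeling column."""
    c = carrier.astype(np.float32)
    n1 = labels[:, 0].sum()
    n2 = labels.shape[0] - n1
    freq_case = c @ labels / n1
    freq_ctrl = (c.sum() - c @ labels) / n2
    diff = freq_case - freq_ctrl
    return diff if direction == "cases" else -diff


def skat_statistics(
    genotypes: np.ndarray, labels: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Q per labeling column (missing dosages count as non-carriers)."""
    g = np.where(genotypes == MISSING, 0, genotypes).astype(np.float32)
    centered = labels - labels.mean(axis=0, keepdims=True)
    scores = g.T @ centered  # (m, K)
    return np.asarray((weights[:, None] ** 2 * scores**2).sum(axis=0), dtype=float)


def skat_weights(mafs: np.ndarray, scheme: str = "flat") -> np.ndarray:
    if scheme == "flat":
        return np.ones(len(mafs))
    if scheme == "beta":
        return stats.beta.pdf(np.asarray(mafs, float), 1, 25)
    raise ValueError(f"unknown weight scheme {scheme!r}")


def cast_test(
    carrier: np.ndarray,
    status: np.ndarray,
    direction: str,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """One-sided collapsing test by phenotype permutation."""
    if not np.any(carrier):
        return 1.0
    rng = rng or np.random.default_rng()
    labels = _label_matrix(status, n_perm, rng)
    s = cast_statistics(np.asarray(carrier), labels, direction)
    return (1 + int(np.sum(s[1:] >= s[0]))) / (n_perm + 1)


def skat_test(
    genotypes: np.ndarray,
    mafs: np.ndarray,
    status: np.ndarray,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
    weights: str = "flat",
    include_singletons: bool = True,
) -> float:
    """Variance-component score test by phenotype permutation.

    ``include_singletons=False`` drops variants with a single carrier
    allele before testing; returns NaN when no variants remain.
    """
    g = np.asarray(genotypes)
    if not include_singletons:
        allele_counts = np.where(g == MISSING, 0, g).sum(axis=0)
        keep = allele_counts > 1
        g = g[:, keep]
        mafs = np.asarray(mafs)[keep]
    if g.shape[1] == 0:
        return np.nan
    rng = rng or np.random.default_rng()
    labels = _label_matrix(status, n_perm, rng)
    q = skat_statistics(g, labels, skat_weights(mafs, weights))
    return (1 + int(np.sum(q[1:] >= q[0]))) / (n_perm + 1)


# ---------------------------------------------------------------------------
# genomic control and p-value combination


def genomic_control(p_values) -> tuple[float, np.ndarray]:
    """Median-based inflation factor and deflated p values.

    lambda = median(chi2_1(p)) / 0.4549; corrected p = SF(chi2/lambda).
    """
    p = np.asarray(p_values, dtype=float)
    chi2 = stats.chi2.isf(p, 1)
    lam = float(np.median(chi2) / CHI2_MEDIAN_1DF)
    corrected = stats.chi2.sf(chi2 / lam, 1)
    return lam, corrected


def gc_correct(p_values, lam: float) -> np.ndarray:
    return stats.chi2.sf(stats.chi2.isf(np.asarray(p_values, float), 1) / lam, 1)


def fisher_combine(p_values) -> tuple[float, float]:
    """Fisher's method: statistic -2 sum ln(p), chi-square with 2m df."""
    p = np.asarray(p_values, dtype=float)
    stat = float(-2.0 * np.sum(np.log(p)))
    return stat, float(stats.chi2.sf(stat, 2 * p.size))


# ---------------------------------------------------------------------------
# gene-level scan and global analyses


@dataclass
class BurdenResult:
    unit: str
    cast_p: float
    skat_p_raw: float
    skat_p_corrected: float
    direction: str
    n_qualifying: int
    n_carriers: int

    @property
    def best_p(self) -> float:
        candidates = [p for p in (self.cast_p, self.skat_p_corrected) if np.isfinite(p)]
        return min(candidates) if candidates else np.nan


@dataclass
class BurdenScan:
    """Per-gene burden results plus the shared permutation pool.

    ``cast_p_pool`` / ``best_p_pool`` are (n_genes, n_perm+1) arrays of
    per-labeling p values (column 0 observed), reused by the global-shift
    and module tests so that no nested permutation loop is needed: each
    phenotype permutation, shared across genes, serves once as the
    pseudo-observed dataset and its p value is its rank within the pool.
    """

    genes: list[str]
    results: list[BurdenResult]
    best_p_pool: np.ndarray
    lambda_gc: float

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "cast_p": [r.cast_p for r in self.results],
                "skat_p_raw": [r.skat_p_raw for r in self.results],
                "skat_p_corrected": [r.skat_p_corrected for r in self.results],
                "best_p": [r.best_p for r in self.results],
                "direction": [r.direction for r in self.results],
                "n_qualifying": [r.n_qualifying for r in self.results],
                "n_carriers": [r.n_carriers for r in self.results],
            }
        )


def gene_burden_scan(
    variants: pd.DataFrame,
    genotypes: np.ndarray,
    status: np.ndarray,
    theta_by_gene: dict[str, float],
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
    maf_max: float = 0.005,
    categories=QUALIFYING_CATEGORIES,
    lambda_gc: float | None = None,
    weights: str = "flat",
) -> BurdenScan:
    """CAST + SKAT per gene on one shared set of phenotype permutations.

    ``lambda_gc`` defaults to an estimate from the same scan run on the
    synonymous category (the control logic); pass 1.0 to disable.
    """
    rng = rng or np.random.default_rng()
    status = np.asarray(status)
    labels = _label_matrix(status, n_perm, rng)
    qual = qualifying_mask(variants, maf_max, categories)
    genes = sorted(variants.loc[qual, "gene"].unique())
    if lambda_gc is None:
        lambda_gc = _lambda_from_synonymous(variants, genotypes, labels, maf_max, weights)
    cast_pool, skat_pool = [], []
    results = []
    for gene in genes:
        vmask = qual & (variants["gene"] == gene).values
        g = genotypes[:, vmask]
        carrier = (np.where(g == MISSING, 0, g) > 0).any(axis=1)
        direction = direction_from_theta(theta_by_gene.get(gene, -1.0))
        if carrier.any():
            cast_p = _pool_pvalues(cast_statistics(carrier, labels, direction))
        else:
            cast_p = np.ones(labels.shape[1])
        w = skat_weights(variants.loc[vmask, "maf"].values, weights)
        skat_p = _pool_pvalues(skat_statistics(g, labels, w))
        cast_pool.append(cast_p)
        skat_pool.append(skat_p)
        results.append(
            BurdenResult(
                gene,
                float(cast_p[0]),
                float(skat_p[0]),
                float(gc_correct([skat_p[0]], lambda_gc)[0]),
                direction,
                int(vmask.sum()),
                int(carrier.sum()),
            )
        )
    cast_arr = np.array(cast_pool) if cast_pool else np.empty((0, labels.shape[1]))
    skat_arr = np.array(skat_pool) if skat_pool else np.empty((0, labels.shape[1]))
    best = np.minimum(cast_arr, gc_correct(skat_arr, lambda_gc)) if cast_pool else cast_arr
    return BurdenScan(genes, results, best, lambda_gc)


def _lambda_from_synonymous(variants, genotypes, labels, maf_max, weights) -> float:
    syn = qualifying_mask(variants, maf_max, categories=("synonymous",))
    genes = sorted(variants.loc[syn, "gene"].unique())
    ps = []
    for gene in genes:
        vmask = syn & (variants["gene"] == gene).values
        w = skat_weights(variants.loc[vmask, "maf"].values, weights)
        ps.append(_pool_pvalues(skat_statistics(genotypes[:, vmask], labels, w))[0])
    if len(ps) < 3:
        logger.warning("too few synonymous genes for lambda_GC; using 1.0")
        return 1.0
    lam, _ = genomic_control(ps)
    return max(lam, 1e-3)


def global_shift_test(scan: BurdenScan) -> dict:
    """Departure of the per-gene best p distribution from its permutation
    expectation: Fisher statistic over genes vs the permuted pool, plus
    per-rank medians and 95% bands of -log10(best p)."""
    pool = scan.best_p_pool
    if pool.size == 0:
        raise ValueError("no genes scanned")
    fisher = -2.0 * np.log(pool).sum(axis=0)
    shift_p = (1 + int(np.sum(fisher[1:] >= fisher[0]))) / pool.shape[1]
    ranked = np.sort(-np.log10(pool), axis=0)[::-1]  # rank 0 = strongest gene
    perm = ranked[:, 1:]
    return {
        "shift_p": float(shift_p),
        "observed_fisher": float(fisher[0]),
        "observed_ranked": ranked[:, 0],
        "rank_median": np.median(perm, axis=1),
        "rank_lo": np.quantile(perm, 0.025, axis=1),
        "rank_hi": np.quantile(perm, 0.975, axis=1),
    }


def module_burden_test(scan: BurdenScan, modules_genes: dict[str, list[str]]) -> pd.DataFrame:
    """Fisher-combine member-gene best p within each module; significance
    by the shared phenotype permutations."""
    gene_row = {g: i for i, g in enumerate(scan.genes)}
    rows = []
    for module_id, genes in modules_genes.items():
        idx = [gene_row[g] for g in genes if g in gene_row]
        if not idx:
            continue
        stat = -2.0 * np.log(scan.best_p_pool[idx]).sum(axis=0)
        p = (1 + int(np.sum(stat[1:] >= stat[0]))) / scan.best_p_pool.shape[1]
        rows.append((module_id, len(idx), float(stat[0]), float(p)))
    return pd.DataFrame(rows, columns=["module_id", "n_genes", "fisher_stat", "p_value"])


# ---------------------------------------------------------------------------
# orthogonal tests


def age_onset_test(
    carrier_mask: np.ndarray,
    onsets: np.ndarray,
    direction: str,
    n_draw: int = 10_000,
    rng: np.random.Generator | None = None,
    two_sided: bool = False,
) -> float:
    """Is the summed age-of-onset of carrier cases unusually low (risk
    direction, 'cases') or high ('controls')?  Random draws of the same
    number of cases form the reference; NaN when there are no carriers."""
    rng = rng or np.random.default_rng()
    onsets = np.asarray(onsets, float)
    carrier_mask = np.asarray(carrier_mask, bool)
    n_c = int(carrier_mask.sum())
    if n_c == 0:
        return np.nan
    observed = onsets[carrier_mask].sum()
    draws = np.array(
        [onsets[rng.choice(onsets.size, n_c, replace=False)].sum() for _ in range(n_draw)]
    )
    lo = (1 + int(np.sum(draws <= observed))) / (n_draw + 1)
    hi = (1 + int(np.sum(draws >= observed))) / (n_draw + 1)
    if two_sided:
        return min(1.0, 2 * min(lo, hi))
    return lo if direction == "cases" else hi


def familiality_test(
    carrier_mask: np.ndarray,
    familial: np.ndarray,
    direction: str,
    n_draw: int = 10_000,
    rng: np.random.Generator | None = None,
    two_sided: bool = False,
) -> float:
    """Is the familial fraction among carrier cases unusually high (risk
    direction) or low?  Hypergeometric-style draws without replacement."""
    rng = rng or np.random.default_rng()
    familial = np.asarray(familial, bool)
    carrier_mask = np.asarray(carrier_mask, bool)
    n_c = int(carrier_mask.sum())
    if n_c == 0:
        return np.nan
    observed = familial[carrier_mask].mean()
    draws = np.array(
        [familial[rng.choice(familial.size, n_c, replace=False)].mean() for _ in range(n_draw)]
    )
    hi = (1 + int(np.sum(draws >= observed))) / (n_draw + 1)
    lo = (1 + int(np.sum(draws <= observed))) / (n_draw + 1)
    if two_sided:
        return min(1.0, 2 * min(lo, hi))
    return hi if direction == "cases" else lo


def bonferroni_threshold(n_units: int, n_tests: int = 2, alpha: float = 0.05) -> float:
    """Experiment-wide significance threshold alpha / (n_units * n_tests)."""
    return alpha / (n_units * n_tests)
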