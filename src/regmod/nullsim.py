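"""Simulation nulls: variance-matched in-silico eQTL and the case-control
allele-frequency algebra used to plant or emulate disease associations.

The in-silico eQTL construction fixes the three genotype-class means of a
chosen causal variant at -1, 0, +1 and draws Gaussian residuals whose
variance is set so that the variant explains a target fraction ``h2`` of the
total expression variance.  The case-control algebra converts a
between/within-cohort variance ratio ``F`` into the case and control
allele-frequency shifts ``d`` and ``delta`` (and the implied odds ratio),
which is how a disease association of calibrated strength is planted on an
arbitrary variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)


class InfeasibleDesignError(ValueError):
    """Requested design implies an allele frequency outside [0, 1]."""


class DegenerateInputError(ValueError):
    """Input carries no usable variation (e.g. monomorphic variant)."""


# ---------------------------------------------------------------------------
# variance components of a single-variant additive eQTL


@dataclass
class VarianceComponents:
    sigma2_T: float
    sigma2_eqtl: float
    h2: float
    sigma2_res: float | None = None


def eqtl_variance_components(beta0, beta1, counts, expression) -> VarianceComponents:
    """Variance decomposition of an additive single-variant fit.

    ``counts`` are the genotype-class counts (n_homref, n_het, n_homalt).
    The class variance uses the /n_T denominator while the total variance
    uses /(n_T - 1); a slight mismatch accepted deliberately (see
    ``consistent_denominators`` switch).
    """
    n11, n12, n22 = (int(c) for c in counts)
    n_t = n11 + n12 + n22
    if n_t <= 1:
        raise DegenerateInputError("need more than one genotyped individual")
    z = np.asarray(expression, dtype=float)
    z_bar = z.mean()
    sigma2_t = float(np.sum((z - z_bar) ** 2) / (len(z) - 1))
    sigma2_eqtl = (
        n11 * (beta0 - z_bar) ** 2
        + n12 * (beta0 + beta1 - z_bar) ** 2
        + n22 * (beta0 + 2 * beta1 - z_bar) ** 2
    ) / n_t
    if sigma2_t == 0:
        raise DegenerateInputError("zero total expression variance")
    return VarianceComponents(sigma2_t, float(sigma2_eqtl), float(sigma2_eqtl / sigma2_t))


def class_mean_variance(counts, consistent_denominators: bool = False) -> tuple[float, float]:
    """(z_bar_T, sigma2_eqtl) for class means fixed at -1, 0, +1."""
    n11, n12, n22 = (int(c) for c in counts)
    n_t = n11 + n12 + n22
    z_bar = (n22 - n11) / n_t
    denom = (n_t - 1) if consistent_denominators else n_t
    s2 = (n11 * (-1 - z_bar) ** 2 + n12 * (0 - z_bar) ** 2 + n22 * (1 - z_bar) ** 2) / denom
    return z_bar, s2


def residual_variance(sigma2_eqtl: float, h2_target: float) -> float:
    if not 0 < h2_target <= 1:
        raise InfeasibleDesignError("h2_target must be in (0, 1]")
    return sigma2_eqtl * (1.0 / h2_target - 1.0)


def simulate_matched_eqtl(
    dosage: np.ndarray,
    h2_target: float,
    rng: np.random.Generator,
    consistent_denominators: bool = False,
) -> np.ndarray:
    """Expression vector with the causal variant explaining ``h2_target``.

    Genotype-class means are -1/0/+1; residuals are N(0, sigma2_res) with
    sigma2_res chosen from the class-mean variance of this variant's
    genotype counts.
    """
    dosage = np.asarray(dosage)
    counts = (np.sum(dosage == 0), np.sum(dosage == 1), np.sum(dosage == 2))
    if sum(c > 0 for c in counts) < 2:
        raise DegenerateInputError("causal variant is monomorphic")
    _, s2_eqtl = class_mean_variance(counts, consistent_denominators)
    s2_res = residual_variance(s2_eqtl, h2_target)
    means = dosage.astype(float) - 1.0
    return means + rng.normal(0.0, np.sqrt(s2_res), size=dosage.shape)


# ---------------------------------------------------------------------------
# case-control allele-frequency algebra


@dataclass
class CaseControlDesign:
    """Planted disease-association design for one causal variant.

    ``p`` is the pooled (cases + controls) alternate-allele frequency; cases
    have frequency ``p + d`` and controls ``p + delta`` with
    ``delta = -d * n1/n2`` so the pooled frequency is conserved.
    """

    n1: int
    n2: int
    p: float
    d: float
    delta: float
    F: float
    odds_ratio: float

    def case_freq(self) -> float:
        return self.p + self.d

    def control_freq(self) -> float:
        return self.p + self.delta


def compute_F(p: float, d: float, n1: int, n2: int) -> float:
    """Between- over within-cohort variance ratio for frequency shift ``d``."""
    if not 0 < p < 1:
        raise InfeasibleDesignError("p must be in (0, 1)")
    num = d**2 * (1 + n1 / n2)
    den = (1 + n2 / n1) * (p - p**2) - d**2 * (1 + n1 / n2)
    if den <= 0:
        raise InfeasibleDesignError("within-cohort variance non-positive")
    return num / den


def odds_ratio(p: float, d: float, delta: float) -> float:
    return ((p + d) * (1 - p - delta)) / ((p + delta) * (1 - p - d))


def solve_case_freq_shift(
    p: float, F: float, n1: int, n2: int, sign: int = +1
) -> CaseControlDesign:
    """Invert ``compute_F``: shift ``d`` producing variance ratio ``F``.

    Quadratic in d with alpha = (1 + n1/n2)(1 + F), beta = 0,
    gamma = -(p - p^2)(1 + n2/n1) F, hence d = sign * sqrt(-gamma/alpha).
    """
    if F < 0:
        raise InfeasibleDesignError("F must be non-negative")
    if not 0 < p < 1:
        raise InfeasibleDesignError("p must be in (0, 1)")
    alpha = (1 + n1 / n2) * (1 + F)
    gamma = -(p - p**2) * (1 + n2 / n1) * F
    d = sign * np.sqrt(-gamma / alpha)
    delta = -d * n1 / n2
    for name, freq in (("case", p + d), ("control", p + delta)):
        if not 0 <= freq <= 1:
            raise InfeasibleDesignError(f"{name} frequency {freq:.4f} outside [0, 1]")
    return CaseControlDesign(n1, n2, p, float(d), float(delta), float(F), float(odds_ratio(p, d, delta)))


def hwe_genotype_freqs(q: float) -> np.ndarray:
    """Hardy-Weinberg genotype frequencies for alt-allele frequency ``q``."""
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])


# ---------------------------------------------------------------------------
# simulated disease association patterns


def allelic_scan(case_dosages: np.ndarray, ctrl_dosages: np.ndarray):
    """1-df allelic chi-square per variant on case/control allele counts.

    Returns (neg_log10_p, sign) arrays; sign is the sign of the case minus
    control alternate-allele frequency difference (0 when undefined).
    """
    a1 = case_dosages.sum(axis=0).astype(float)  # alt alleles in cases
    a2 = ctrl_dosages.sum(axis=0).astype(float)
    m1 = 2.0 * case_dosages.shape[0]
    m2 = 2.0 * ctrl_dosages.shape[0]
    b1, b2 = m1 - a1, m2 - a2
    n = m1 + m2
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = n * (a1 * b2 - a2 * b1) ** 2 / ((a1 + a2) * (b1 + b2) * m1 * m2)
    chi2 = np.where(np.isfinite(chi2), chi2, 0.0)
    neg_log10_p = -stats.chi2.logsf(chi2, df=1) / np.log(10)
    sign = np.sign(a1 / m1 - a2 / m2)
    return neg_log10_p, sign


def sample_case_control_indices(
    geno: GenotypeMatrix,
    causal_index: int,
    design: CaseControlDesign,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample individuals (with replacement) by causal-variant genotype.

    Case genotypes follow HWE at frequency p + d, controls at p + delta;
    each drawn genotype class is filled by an individual of that class from
    the pool, carrying the whole local haplotype (hence LD) along.
    """
    dosage = geno.dosages[:, causal_index]
    pools = [np.flatnonzero(dosage == g) for g in (0, 1, 2)]
    out = []
    for n_cohort, freq in ((design.n1, design.case_freq()), (design.n2, design.control_freq())):
        probs = hwe_genotype_freqs(freq)
        counts = rng.multinomial(n_cohort, probs)
        needed = [g for g in (0, 1, 2) if counts[g] > 0 and pools[g].size == 0]
        if needed:
            raise InfeasibleDesignError(
                f"pool lacks genotype class(es) {needed} required by the design"
            )
        idx = np.concatenate(
            [rng.choice(pools[g], size=counts[g], replace=True) for g in (0, 1, 2) if counts[g] > 0]
        )
        out.append(rng.permutation(idx))
    return out[0], out[1]


def simulate_dap(
    geno: GenotypeMatrix,
    causal_index: int,
    F_target: float,
    n1: int,
    n2: int,
    rng: np.random.Generator,
    sign: int = +1,
):
    """Simulate a disease association pattern driven by one causal variant.

    Returns (AssociationPattern, CaseControlDesign). Raises
    InfeasibleDesignError when the variant is too rare for the design.
    """
    from .theta import AssociationPattern  # deferred: avoids import cycle

    p = float(geno.alt_freq()[causal_index])
    if not 0 < p < 1:
        raise DegenerateInputError("causal variant is monomorphic")
    design = solve_case_freq_shift(p, F_target, n1, n2, sign=sign)
    case_idx, ctrl_idx = sample_case_control_indices(geno, causal_index, design, rng)
    neg_log10_p, signs = allelic_scan(geno.dosages[case_idx], geno.dosages[ctrl_idx])
    v = geno.variants
    anchor = (str(v["chrom"].iloc[causal_index]), int(v["pos"].iloc[causal_index]))
    pattern = AssociationPattern(
        trait="simulated_disease",
        variants=v[["variant_id", "chrom", "pos", "ref", "alt", "maf"]].copy(),
        neg_log10_p=np.asarray(neg_log10_p),
        sign=np.asarray(signs),
        anchor=anchor,
    )
    return pattern, design


def _maf_matched_candidates(
    geno: GenotypeMatrix, target_maf: float, n_needed: int, window: float = 0.05
) -> np.ndarray:
    maf = geno.maf_from_dosages()
    while True:
        cand = np.flatnonzero(np.abs(maf - target_maf) <= window)
        if cand.size >= n_needed or window >= 0.5:
            if cand.size < n_needed:
                logger.warning(
                    "only %d MAF-matched candidates for target %.3f", cand.size, target_maf
                )
            return cand
        window *= 2
        logger.warning("widening MAF-matching window to %.3f", window)


def empirical_theta_pvalue(
    fixed_pattern,
    observed_theta: float,
    geno: GenotypeMatrix,
    h2_target: float,
    rng: np.random.Generator,
    n_sim: int = 100,
    maf_match: bool = True,
    causal_maf: float | None = None,
    theta_params=None,
) -> float:
    """Empirical p for |theta| against matched in-silico eQTL nulls.

    Draws ``n_sim`` candidate causal variants from the locus (MAF-matched to
    ``causal_maf`` when requested), simulates a variance-matched eQTL for
    each, scans the locus, and compares |theta| with ``fixed_pattern``
    against the observed value.  Add-one convention.
    """
    from .eqtl import pattern_from_values
    from .theta import ThetaParams, compare_patterns

    params = theta_params or ThetaParams()
    if maf_match and causal_maf is not None:
        cand = _maf_matched_candidates(geno, causal_maf, n_sim)
    else:
        cand = np.arange(geno.n_variants)
    maf = geno.maf_from_dosages()
    cand = cand[(maf[cand] > 0) & (maf[cand] < 0.5 + 1e-12)]
    if cand.size == 0:
        raise DegenerateInputError("no polymorphic candidate variants in locus")
    draws = rng.choice(cand, size=n_sim, replace=cand.size < n_sim)
    exceed = 0
    for j in draws:
        expr = simulate_matched_eqtl(geno.dosages[:, j], h2_target, rng)
        sim = pattern_from_values(expr, geno, trait=f"insilico@{j}")
        cmp = compare_patterns(sim, fixed_pattern, params=params)
        if cmp.defined and abs(cmp.theta) >= abs(observed_theta):
            exceed += 1
    return (1 + exceed) / (n_sim + 1)
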