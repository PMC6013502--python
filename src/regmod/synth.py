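"""Synthetic cohort generator with the statistical structure the pipeline
assumes: block-LD genotypes in Hardy-Weinberg equilibrium, expression with
planted cis-eQTL of chosen heritability, case-control cohorts with planted
common disease variants of chosen strength (F), and rare damaging /
synonymous variants with chosen case enrichment.

The LD model is haplotype copying: within a block every haplotype copies a
shared block allele and each variant is independently refreshed with a
small probability, which yields valid {0,1,2} genotypes, exact HWE, and a
tunable within-block r^2 of (1 - eps)^4.  Blocks are mutually independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nullsim
from .containers import ExpressionMatrix, GenotypeMatrix


class ConfigurationError(ValueError):
    pass


@dataclass
class PlantedEqtl:
    probe_id: str
    causal_index: int
    h2: float
    tissues: tuple[str, ...] = ("T1",)


@dataclass
class RareVariantSpec:
    """Per-category rare-variant layout for a burden-test cohort.

    ``relative_risk`` multiplies the per-allele carrier frequency in cases;
    synonymous variants should use 1.0 (no differential).
    """

    n_variants: dict[str, int] = field(
        default_factory=lambda: {"LoF": 5, "damaging": 25, "benign": 20, "synonymous": 35}
    )
    maf_range: tuple[float, float] = (0.0002, 0.005)
    relative_risk: dict[str, float] = field(default_factory=dict)


@dataclass
class SimulationConfig:
    n_samples: int = 300
    n_variants: int = 400
    block_len: int = 20
    block_r2: float = 0.8
    maf_range: tuple[float, float] = (0.1, 0.5)
    chrom: str = "1"
    pos_start: int = 1_000_000
    pos_spacing: int = 2_500
    planted_eqtl: list[PlantedEqtl] = field(default_factory=list)
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2 or self.n_variants < 1 or self.block_len < 1:
            raise ConfigurationError("invalid cohort dimensions")
        if not 0 < self.block_r2 <= 1:
            raise ConfigurationError("block_r2 must be in (0, 1]")
        for pe in self.planted_eqtl:
            if not 0 < pe.h2 <= 1:
                raise ConfigurationError("planted h2 must be in (0, 1]")


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Block-LD genotypes; deterministic given the config (incl. seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_variants
    eps = 1.0 - config.block_r2**0.25
    haplos = np.empty((2 * n, m), dtype=np.int8)
    lo, hi = config.maf_range
    start = 0
    while start < m:
        width = min(config.block_len, m - start)
        f = rng.uniform(lo, hi)
        block_allele = rng.random(2 * n) < f  # one draw per haplotype
        keep = rng.random((2 * n, width)) > eps
        fresh = rng.random((2 * n, width)) < f
        haplos[:, start : start + width] = np.where(keep, block_allele[:, None], fresh)
        start += width
    dosages = (haplos[0::2] + haplos[1::2]).astype(np.int8)
    if config.missing_rate > 0:
        miss = rng.random(dosages.shape) < config.missing_rate
        dosages[miss] = -1
    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{j}" for j in range(m)],
            "chrom": config.chrom,
            "pos": config.pos_start + np.arange(m) * config.pos_spacing,
            "ref": "A",
            "alt": "G",
            "maf": 0.0,
        }
    )
    geno = GenotypeMatrix([f"S{i}" for i in range(n)], variants, dosages)
    geno.variants["maf"] = geno.maf_from_dosages()
    # realized-MAF QC mirror: common-variant panels carry MAF > 0.05 only
    keep = np.flatnonzero(geno.variants["maf"].values > 0.05)
    if keep.size < m:
        geno = geno.take_variants(keep)
    return geno


def plant_eqtl(
    geno: GenotypeMatrix, causal_index: int, h2_target: float, rng: np.random.Generator
) -> np.ndarray:
    """Expression vector with the chosen variant explaining ``h2_target``
    of the variance (genotype-class means -1/0/+1, Gaussian residuals)."""
    return nullsim.simulate_matched_eqtl(geno.dosages[:, causal_index], h2_target, rng)


def simulate_expression(
    geno: GenotypeMatrix,
    config: SimulationConfig,
    tissues: tuple[str, ...] = ("T1",),
    n_null_probes: int = 0,
    rng: np.random.Generator | None = None,
) -> dict[str, ExpressionMatrix]:
    """Per-tissue expression with the configured planted eQTL.

    A shared planted eQTL uses the same causal variant in every listed
    tissue with independent residual draws per tissue; null probes are
    i.i.d. standard normal.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    out: dict[str, ExpressionMatrix] = {}
    mid = geno.n_variants // 2
    for tissue in tissues:
        cols, meta = [], []
        for pe in config.planted_eqtl:
            if tissue in pe.tissues:
                cols.append(plant_eqtl(geno, pe.causal_index, pe.h2, rng))
                anchor = int(geno.variants["pos"].iloc[pe.causal_index])
            else:
                cols.append(rng.normal(size=geno.n_samples))
                anchor = int(geno.variants["pos"].iloc[mid])
            meta.append((pe.probe_id, pe.probe_id.replace("probe", "GENE"), anchor))
        for k in range(n_null_probes):
            cols.append(rng.normal(size=geno.n_samples))
            meta.append((f"null{k}", f"NULLG{k}", int(geno.variants["pos"].iloc[mid])))
        probes = pd.DataFrame(meta, columns=["probe_id", "gene", "pos"])
        probes.insert(2, "chrom", config.chrom)
        out[tissue] = ExpressionMatrix(
            list(geno.sample_ids), probes, tissue, np.column_stack(cols)
        )
    return out


# ---------------------------------------------------------------------------
# case-control cohorts and orthogonal phenotypes


@dataclass
class PhenotypeModel:
    onset_mean: float = 28.0
    onset_sd: float = 10.0
    onset_min: float = 5.0
    familial_fraction: float = 0.2
    carrier_onset_shift: float = 0.0
    carrier_familial_fraction: float | None = None


def simulate_case_control(
    geno: GenotypeMatrix,
    causal_index: int,
    F_target: float,
    n1: int,
    n2: int,
    rng: np.random.Generator,
    sign: int = +1,
    phenotype_model: PhenotypeModel | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, nullsim.CaseControlDesign]:
    """Resample a case-control cohort with a planted association of strength F.

    Returns the resampled cohort genotypes, a phenotype table (sample,
    status, age_of_onset, familial) and the realised design (p, d, delta,
    OR).  F_target = 0 produces a null cohort.
    """
    pm = phenotype_model or PhenotypeModel()
    p = float(geno.alt_freq()[causal_index])
    design = nullsim.solve_case_freq_shift(p, F_target, n1, n2, sign=sign)
    case_idx, ctrl_idx = nullsim.sample_case_control_indices(geno, causal_index, design, rng)
    cohort = geno.take_samples(np.concatenate([case_idx, ctrl_idx]), suffix=True)
    status = np.r_[np.ones(n1, dtype=int), np.zeros(n2, dtype=int)]
    onset = np.full(n1 + n2, np.nan)
    onset[:n1] = _truncated_normal(pm.onset_mean, pm.onset_sd, pm.onset_min, n1, rng)
    familial = np.zeros(n1 + n2, dtype=bool)
    familial[:n1] = rng.random(n1) < pm.familial_fraction
    pheno = pd.DataFrame(
        {
            "sample": cohort.sample_ids,
            "status": status,
            "age_of_onset": onset,
            "familial": familial,
        }
    )
    return cohort, pheno, design


def _truncated_normal(mu, sd, lo, size, rng):
    x = rng.normal(mu, sd, size=size)
    while True:
        bad = x < lo
        if not bad.any():
            return x
        x[bad] = rng.normal(mu, sd, size=int(bad.sum()))


# ---------------------------------------------------------------------------
# rare variants


def simulate_rare_variants(
    n_cases: int,
    n_controls: int,
    spec: RareVariantSpec,
    rng: np.random.Generator,
    gene: str = "GENE1",
    pheno: pd.DataFrame | None = None,
    phenotype_model: PhenotypeModel | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Rare-variant genotype table with per-category case enrichment.

    Control per-allele frequency q is drawn from ``maf_range``; the case
    frequency is q times the category's relative risk.  Returns
    (variant annotation, genotype matrix over cases-then-controls).
    When ``pheno`` and a carrier model are given, carrier cases get the
    configured onset shift / familial fraction applied in place.
    """
    lo, hi = spec.maf_range
    if not 0 < lo <= hi <= 0.005:
        raise ConfigurationError("qualifying MAF range must lie within (0, 0.005]")
    rows, cols = [], []
    for category, count in spec.n_variants.items():
        rr = spec.relative_risk.get(category, 1.0)
        if rr < 0:
            raise ConfigurationError("relative risk must be non-negative")
        for k in range(count):
            q = rng.uniform(lo, hi)
            g_case = rng.binomial(2, min(q * rr, 0.5), size=n_cases)
            g_ctrl = rng.binomial(2, q, size=n_controls)
            g = np.r_[g_case, g_ctrl]
            rows.append((f"{gene}:{category}:{k}", gene, category, g.sum() / (2 * len(g))))
            cols.append(g)
    variants = pd.DataFrame(rows, columns=["variant_id", "gene", "category", "maf"])
    genotypes = np.column_stack(cols).astype(np.int8)
    if pheno is not None and phenotype_model is not None:
        _apply_carrier_effects(variants, genotypes, pheno, phenotype_model, rng)
    return variants, genotypes


def _apply_carrier_effects(variants, genotypes, pheno, pm: PhenotypeModel, rng):
    qualifying = variants["category"].isin(["LoF", "damaging"]).values
    carrier = (genotypes[:, qualifying] > 0).any(axis=1)
    cases = pheno["status"].values == 1
    touched = carrier & cases
    if pm.carrier_onset_shift:
        pheno.loc[touched, "age_of_onset"] += pm.carrier_onset_shift
    if pm.carrier_familial_fraction is not None:
        pheno.loc[touched, "familial"] = rng.random(int(touched.sum())) < pm.carrier_familial_fraction
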