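"""Matching disease association patterns (DAP) to regulatory modules and
testing whether the observed amount of DAP-EAP matching exceeds chance.

Three matching criteria are implemented: naive (lead variants in LD,
r^2 >= 0.8), frequentist (conditioning on the disease lead drops the
eQTL signal more than 95% of locus variants do), and theta-based
(|theta| > 0.6 between the two patterns).  Enrichment over chance is
assessed by redrawing a random common variant per risk locus (for theta,
the random variant becomes an in-silico causal variant for a simulated
DAP) and counting matching loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nullsim
from .containers import GenomicInterval, GenotypeMatrix
from .eqtl import _neg_log10_p_from_r
from .theta import AssociationPattern, ThetaParams, compare_patterns

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# theta-based matching of a DAP against module members


def match_dap_to_modules(
    dap: AssociationPattern,
    modules,
    patterns: dict[str, AssociationPattern],
    locus: GenomicInterval,
    threshold: float = 0.6,
    params: ThetaParams | None = None,
) -> pd.DataFrame:
    """theta of the DAP against every module member anchored in the locus.

    Returns a member-level table (module_id, pattern_id, theta, matched);
    a module matches when any member exceeds the threshold.  The DAP is
    given the locus as its variant-selection interval.
    """
    params = params or ThetaParams()
    dap = AssociationPattern(
        dap.trait, dap.variants, dap.neg_log10_p, dap.sign,
        anchor=(locus.chrom, locus.midpoint),
        interval=(locus.chrom, locus.start0 + 1, locus.end0),
    )
    rows = []
    for module in modules:
        for member in module.members:
            pat = patterns.get(member.pattern_id)
            if pat is None or not locus.contains(*pat.anchor):
                continue
            cmp = compare_patterns(dap, pat, params)
            theta = cmp.theta if cmp.defined else np.nan
            rows.append(
                (
                    module.module_id,
                    member.pattern_id,
                    member.gene,
                    member.tissue,
                    theta,
                    bool(cmp.defined and abs(theta) > threshold),
                )
            )
    table = pd.DataFrame(
        rows, columns=["module_id", "pattern_id", "gene", "tissue", "theta", "matched"]
    )
    return table.sort_values(["module_id", "pattern_id"]).reset_index(drop=True)


def best_theta_per_module(match_table: pd.DataFrame) -> pd.DataFrame:
    """Signed best theta (largest |theta|) per module, with match flag."""
    if match_table.empty:
        return pd.DataFrame(columns=["module_id", "best_theta", "matched"])

    def _best(grp):
        k = grp["theta"].abs().idxmax()
        return pd.Series(
            {"best_theta": grp.loc[k, "theta"], "matched": bool(grp["matched"].any())}
        )

    return match_table.groupby("module_id").apply(_best, include_groups=False).reset_index()


# ---------------------------------------------------------------------------
# naive and frequentist matching


def dosage_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors."""
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    if np.ptp(g1) == 0 or np.ptp(g2) == 0:
        return 0.0
    return float(np.corrcoef(g1, g2)[0, 1] ** 2)


def naive_overlap(
    disease_lead: np.ndarray, eqtl_lead: np.ndarray, r2_threshold: float = 0.8
) -> bool:
    """Lead variants in LD at r^2 >= threshold count as a match."""
    return dosage_r2(disease_lead, eqtl_lead) >= r2_threshold


def conditional_drops(
    y: np.ndarray,
    geno: GenotypeMatrix,
    top_index: int,
    maf_min: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Drop in the eQTL top variant's -log10(p) when conditioning on each
    locus variant in turn.

    Returns (candidate indices, drops, observed top -log10 p).  A variant
    collinear with the top variant gives the maximal possible drop.
    """
    y = np.asarray(y, float)
    g_top = geno.dosages[:, top_index].astype(float)
    n = y.size
    r_obs = np.corrcoef(g_top, y)[0, 1]
    obs_nlp = float(_neg_log10_p_from_r(np.array([r_obs]), n)[0])
    maf = geno.maf_from_dosages()
    cand = np.flatnonzero(maf > maf_min)
    drops = np.empty(cand.size)
    for k, c in enumerate(cand):
        g_c = geno.dosages[:, c].astype(float)
        gc = g_c - g_c.mean()
        denom = np.sum(gc**2)
        y_res = y - y.mean() - (np.sum(gc * (y - y.mean())) / denom) * gc
        t_res = g_top - g_top.mean() - (np.sum(gc * (g_top - g_top.mean())) / denom) * gc
        if np.sum(t_res**2) < 1e-12 * np.sum((g_top - g_top.mean()) ** 2):
            drops[k] = obs_nlp  # collinear conditioning removes the signal entirely
            continue
        r = np.sum(t_res * y_res) / np.sqrt(np.sum(t_res**2) * np.sum(y_res**2))
        drops[k] = obs_nlp - float(_neg_log10_p_from_r(np.array([r]), n - 1)[0])
    return cand, drops, obs_nlp


def frequentist_overlap(
    y: np.ndarray,
    geno: GenotypeMatrix,
    top_index: int,
    candidate_index: int,
    quantile: float = 0.95,
    maf_min: float = 0.05,
) -> bool:
    """Match if conditioning on the candidate drops the eQTL -log10(p)
    more than ``quantile`` of the common locus variants do."""
    cand, drops, _ = conditional_drops(y, geno, top_index, maf_min)
    k = np.flatnonzero(cand == candidate_index)
    if k.size == 0:
        raise ValueError("candidate variant below the MAF floor")
    cutoff = np.quantile(drops, quantile)
    return bool(drops[int(k[0])] >= cutoff)


# ---------------------------------------------------------------------------
# enrichment of matching over randomly drawn variants


@dataclass
class LocusContext:
    """Precomputed per-locus material for the enrichment resampling.

    ``eap_patterns`` are the locus EAPs; ``eap_leads`` their lead-variant
    column indices in ``geno``; ``eap_h2`` the variance each explains
    (used to scale simulated DAP comparisons); ``drop_tables`` optional
    per-EAP (candidate indices, drops, 95th-percentile cutoff).
    """

    locus: GenomicInterval
    geno: GenotypeMatrix
    eap_patterns: list[AssociationPattern]
    eap_leads: list[int]
    eap_h2: list[float] = field(default_factory=list)
    drop_tables: list[tuple[np.ndarray, np.ndarray, float]] = field(default_factory=list)
    n1: int = 2000
    n2: int = 2000
    F: float = 0.01


def _common_variants(geno: GenotypeMatrix, maf_min: float = 0.05) -> np.ndarray:
    return np.flatnonzero(geno.maf_from_dosages() > maf_min)


def _random_locus_match(
    ctx: LocusContext,
    method: str,
    rng: np.random.Generator,
    threshold: float = 0.6,
    r2_threshold: float = 0.8,
    params: ThetaParams | None = None,
) -> bool:
    pool = _common_variants(ctx.geno)
    if pool.size == 0:
        raise ValueError("empty common-variant pool")
    j = int(rng.choice(pool))
    if method == "naive":
        g = ctx.geno.dosages[:, j]
        return any(
            dosage_r2(g, ctx.geno.dosages[:, lead]) >= r2_threshold
            for lead in ctx.eap_leads
        )
    if method == "frequentist":
        for cand, drops, cutoff in ctx.drop_tables:
            k = np.flatnonzero(cand == j)
            if k.size and drops[int(k[0])] >= cutoff:
                return True
        return False
    if method == "theta":
        try:
            dap, _ = nullsim.simulate_dap(ctx.geno, j, ctx.F, ctx.n1, ctx.n2, rng)
        except nullsim.InfeasibleDesignError:
            return False
        dap.interval = (ctx.locus.chrom, ctx.locus.start0 + 1, ctx.locus.end0)
        for eap in ctx.eap_patterns:
            cmp = compare_patterns(dap, eap, params)
            if cmp.defined and abs(cmp.theta) > threshold:
                return True
        return False
    raise ValueError(f"unknown method {method!r}")


def overlap_enrichment(
    contexts: list[LocusContext],
    observed_matches: int,
    method: str,
    n_sims: int = 1000,
    rng: np.random.Generator | None = None,
    threshold: float = 0.6,
    r2_threshold: float = 0.8,
    params: ThetaParams | None = None,
) -> tuple[float, np.ndarray]:
    """Permutation p (add-one) for the observed number of matching loci."""
    rng = rng or np.random.default_rng()
    counts = np.empty(n_sims, dtype=int)
    for s in range(n_sims):
        c = 0
        for ctx in contexts:
            try:
                c += _random_locus_match(ctx, method, rng, threshold, r2_threshold, params)
            except ValueError:
                logger.warning("locus %s skipped: empty pool", ctx.locus.name)
        counts[s] = c
    p = (1 + int(np.sum(counts >= observed_matches))) / (n_sims + 1)
    return p, counts


# ---------------------------------------------------------------------------
# multigenic enrichment among DAP-matching modules


def multigenic_enrichment(
    match_tables: list[pd.DataFrame],
    modules,
    n_resamples: int = 10_000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Is the multigenic fraction among DAP-matching modules elevated?

    ``match_tables`` are member-level tables (one per analysed DAP/locus)
    from :func:`match_dap_to_modules`.  The resampling null represents
    each module by one random member EAP and recomputes which modules
    match, recording the multigenic fraction each time.  The reported p is
    the fraction of resamples whose multigenic fraction falls to or below
    the genome-wide baseline.
    """
    rng = rng or np.random.default_rng()
    is_multi = {m.module_id: len(m.genes) > 1 for m in modules}
    baseline = sum(is_multi.values()) / len(is_multi)
    table = pd.concat(match_tables, ignore_index=True)
    obs_matched = set(table.loc[table["matched"], "module_id"])
    obs_frac = (
        sum(is_multi[mid] for mid in obs_matched) / len(obs_matched) if obs_matched else 0.0
    )
    groups = {
        mid: grp["matched"].values
        for mid, grp in table.groupby("module_id", sort=True)
    }
    fracs = np.empty(n_resamples)
    for s in range(n_resamples):
        matched = [
            mid for mid, flags in groups.items() if flags[rng.integers(len(flags))]
        ]
        fracs[s] = (
            sum(is_multi[mid] for mid in matched) / len(matched) if matched else 0.0
        )
    p = (1 + int(np.sum(fracs <= baseline))) / (n_resamples + 1)
    return {
        "observed_fraction": obs_frac,
        "baseline_fraction": baseline,
        "n_matching": len(obs_matched),
        "resample_mean": float(fracs.mean()),
        "resample_min": float(fracs.min()),
        "p_value": p,
    }


# ---------------------------------------------------------------------------
# size/chromosome matched control loci


def locus_matched_control_draw(
    loci: list[GenomicInterval],
    module_positions: pd.DataFrame,
    n_sets: int,
    rng: np.random.Generator | None = None,
) -> list[list[GenomicInterval]]:
    """Control locus sets centred on random modules, matched for interval
    length and chromosome.  ``module_positions`` needs chrom and pos
    (1-based anchor) columns."""
    rng = rng or np.random.default_rng()
    by_chrom = {c: grp["pos"].values for c, grp in module_positions.groupby("chrom")}
    sets = []
    for _ in range(n_sets):
        controls = []
        for locus in loci:
            pool = by_chrom.get(locus.chrom)
            if pool is None or len(pool) == 0:
                logger.warning(
                    "no modules on chromosome %s; drawing genome-wide", locus.chrom
                )
                pool = module_positions["pos"].values
            center = int(rng.choice(pool))
            half = locus.length // 2
            controls.append(
                GenomicInterval(
                    locus.chrom, max(center - half, 0), max(center - half, 0) + locus.length,
                    name=f"ctrl_{locus.name}",
                )
            )
        sets.append(controls)
    return sets
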