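"""Additive-model cis-eQTL scan with permutation correction and FDR.

Expression is pre-corrected for known covariates and for principal
components of the residual matrix (the PC count can be chosen to maximise
the number of strong cis-eQTL).  Each probe is then tested against every
variant in a 2-Mb window centred on the probe midpoint by per-variant
least squares; the window-wide minimum p is corrected for multiplicity by
permuting sample labels of expression, and per-tissue q-values are
computed from the corrected p values by Benjamini-Hochberg (optionally
with a Storey-style pi0 estimate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import MISSING, ExpressionMatrix, GenotypeMatrix
from .theta import AssociationPattern

logger = logging.getLogger(__name__)

LOG10 = np.log(10.0)


class NumericalDesignError(ValueError):
    """Covariate design matrix is rank deficient."""


# ---------------------------------------------------------------------------
# expression preprocessing


def _residualize(values: np.ndarray, design: np.ndarray) -> np.ndarray:
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise NumericalDesignError("rank-deficient covariate design")
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    return values - design @ coef


def _remove_pcs(values: np.ndarray, n_pcs: int) -> np.ndarray:
    if n_pcs == 0:
        return values
    centered = values - values.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(n_pcs, len(s))
    return values - (u[:, :k] * s[:k]) @ vt[:k]


def preprocess_expression(
    raw: ExpressionMatrix,
    covariates: np.ndarray | None = None,
    n_pcs: int | str = 0,
    geno: GenotypeMatrix | None = None,
    pc_grid: tuple[int, ...] = tuple(range(0, 61, 5)),
    strong_p: float = 1e-6,
) -> ExpressionMatrix:
    """Residualize expression on covariates, then on leading PCs.

    ``n_pcs="auto"`` scans ``pc_grid`` and keeps the count that maximises
    the number of probes with a window-minimum nominal p <= ``strong_p``
    (requires ``geno``).
    """
    values = np.asarray(raw.values, dtype=float)
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != raw.n_samples:
            cov = cov.T
        design = np.column_stack([np.ones(raw.n_samples), cov])
        values = _residualize(values, design)
    if n_pcs == "auto":
        if geno is None:
            raise ValueError("auto PC selection requires genotypes")
        n_pcs = select_n_pcs(
            ExpressionMatrix(raw.sample_ids, raw.probes, raw.tissue, values),
            geno, pc_grid=pc_grid, strong_p=strong_p,
        )[0]
        logger.info("auto-selected %d expression PCs", n_pcs)
    if not 0 <= int(n_pcs) < raw.n_samples:
        raise ValueError("n_pcs must be in [0, n_samples)")
    values = _remove_pcs(values, int(n_pcs))
    return ExpressionMatrix(list(raw.sample_ids), raw.probes.copy(), raw.tissue, values)


def select_n_pcs(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    pc_grid: tuple[int, ...] = tuple(range(0, 61, 5)),
    strong_p: float = 1e-6,
    window_half_width: int = 1_000_000,
) -> tuple[int, dict[int, int]]:
    """PC count maximising the number of strong cis-eQTL (ties -> fewest PCs)."""
    counts: dict[int, int] = {}
    grid = [k for k in pc_grid if k < expr.n_samples]
    threshold_nlp = -np.log10(strong_p)
    for k in grid:
        vals = _remove_pcs(np.asarray(expr.values, float), k)
        n_hits = 0
        for pi in range(expr.n_probes):
            row = expr.probes.iloc[pi]
            idx = geno.window(
                str(row["chrom"]),
                int(row["pos"]) - window_half_width,
                int(row["pos"]) + window_half_width,
            )
            if idx.size == 0:
                continue
            nlp, _, _, _ = association_scan(vals[:, pi], geno.dosages[:, idx])
            if np.nanmax(nlp) >= threshold_nlp:
                n_hits += 1
        counts[k] = n_hits
    best = max(grid, key=lambda k: (counts[k], -k))
    return best, counts


def filter_probes_by_detection(
    expr: ExpressionMatrix,
    detection_p: np.ndarray,
    p_max: float = 0.05,
    min_fraction: float = 0.25,
) -> ExpressionMatrix:
    """Keep probes detected (p <= p_max) in at least ``min_fraction`` samples."""
    frac = np.mean(np.asarray(detection_p) <= p_max, axis=0)
    keep = np.flatnonzero(frac >= min_fraction)
    return ExpressionMatrix(
        list(expr.sample_ids),
        expr.probes.iloc[keep].reset_index(drop=True),
        expr.tissue,
        expr.values[:, keep],
    )


# ---------------------------------------------------------------------------
# per-variant additive fits


def association_scan(y: np.ndarray, dosages: np.ndarray):
    """Vectorised per-variant simple regression of ``y`` on dosage.

    Returns (neg_log10_p, sign, beta0, beta1); monomorphic variants and
    variants with missing dosages are handled per-variant (complete case)
    and yield NaN betas with neg_log10_p = 0 when untestable.
    """
    y = np.asarray(y, dtype=float)
    d = np.asarray(dosages)
    if np.any(d == MISSING):
        return _scan_complete_case(y, d)
    g = d.astype(float)
    n = g.shape[0]
    gm = g.mean(axis=0)
    gc = g - gm
    yc = y - y.mean()
    sg2 = np.sum(gc**2, axis=0)
    sy2 = float(np.sum(yc**2))
    poly = sg2 > 0
    if not poly.all():
        logger.info("skipping %d monomorphic variants", int((~poly).sum()))
    cov = gc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        beta1 = cov / sg2
        r = cov / np.sqrt(sg2 * sy2)
    beta0 = y.mean() - beta1 * gm
    nlp = _neg_log10_p_from_r(r, n)
    nlp = np.where(poly & (sy2 > 0), nlp, 0.0)
    beta0 = np.where(poly, beta0, np.nan)
    beta1 = np.where(poly, beta1, np.nan)
    return nlp, np.sign(np.where(poly, beta1, 0.0)), beta0, beta1


def _neg_log10_p_from_r(r: np.ndarray, n: int | np.ndarray) -> np.ndarray:
    df = np.maximum(np.asarray(n) - 2, 1)
    r2 = np.clip(np.abs(r), 0.0, 1.0) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r) * np.sqrt(df / (1.0 - r2))
    t = np.where(r2 >= 1.0, np.inf, t)
    # two-sided p via the log survival function, safe against underflow
    nlp = -(np.log(2.0) + stats.t.logsf(t, df)) / LOG10
    return np.where(np.isfinite(nlp), nlp, 320.0)


def _scan_complete_case(y: np.ndarray, d: np.ndarray):
    m = d.shape[1]
    nlp = np.zeros(m)
    sign = np.zeros(m)
    beta0 = np.full(m, np.nan)
    beta1 = np.full(m, np.nan)
    for j in range(m):
        called = d[:, j] != MISSING
        g = d[called, j].astype(float)
        yj = y[called]
        if g.size < 3 or np.ptp(g) == 0 or np.ptp(yj) == 0:
            continue
        gc, yc = g - g.mean(), yj - yj.mean()
        sg2, sy2 = np.sum(gc**2), np.sum(yc**2)
        cov = np.sum(gc * yc)
        b1 = cov / sg2
        beta1[j] = b1
        beta0[j] = yj.mean() - b1 * g.mean()
        nlp[j] = float(_neg_log10_p_from_r(np.array([cov / np.sqrt(sg2 * sy2)]), g.size)[0])
        sign[j] = np.sign(b1)
    return nlp, sign, beta0, beta1


# ---------------------------------------------------------------------------
# cis scan per probe


@dataclass
class CisEqtlResult:
    probe_id: str
    tissue: str
    chrom: str
    window: tuple[int, int]
    table: pd.DataFrame = field(repr=False)
    top_variant_id: str | None = None
    top_neg_log10_p: float = np.nan
    corrected_p: float | None = None
    q_value: float | None = None

    @property
    def empty(self) -> bool:
        return len(self.table) == 0


def cis_scan(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    probe_id: str,
    window_half_width: int = 1_000_000,
) -> CisEqtlResult:
    """Test all variants within +-``window_half_width`` of the probe midpoint."""
    pi = expr.probe_index(probe_id)
    row = expr.probes.iloc[pi]
    chrom, pos = str(row["chrom"]), int(row["pos"])
    lo, hi = pos - window_half_width, pos + window_half_width
    idx = geno.window(chrom, lo, hi)
    if idx.size == 0:
        logger.warning("no variants in cis window of probe %s", probe_id)
        empty = pd.DataFrame(
            columns=["variant_id", "chrom", "pos", "maf", "beta0", "beta1", "neg_log10_p", "sign"]
        )
        return CisEqtlResult(probe_id, expr.tissue, chrom, (lo, hi), empty)
    y = expr.values[:, pi]
    nlp, sign, beta0, beta1 = association_scan(y, geno.dosages[:, idx])
    v = geno.variants.iloc[idx]
    table = pd.DataFrame(
        {
            "variant_id": v["variant_id"].values,
            "chrom": v["chrom"].values,
            "pos": v["pos"].values,
            "ref": v["ref"].values,
            "alt": v["alt"].values,
            "maf": v["maf"].values,
            "beta0": beta0,
            "beta1": beta1,
            "neg_log10_p": nlp,
            "sign": sign,
        }
    )
    top = int(np.argmax(nlp))
    return CisEqtlResult(
        probe_id, expr.tissue, chrom, (lo, hi), table,
        top_variant_id=str(table["variant_id"].iloc[top]),
        top_neg_log10_p=float(nlp[top]),
    )


def permutation_correct(
    result: CisEqtlResult,
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Window-wide corrected p by shuffling expression sample labels.

    corrected p = (1 + #{permutation min p <= observed min p}) / (n_perm+1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = rng or np.random.default_rng()
    if result.empty:
        return np.nan
    pi = expr.probe_index(result.probe_id)
    y = np.asarray(expr.values[:, pi], dtype=float)
    idx = geno.window(result.chrom, *result.window)
    d = geno.dosages[:, idx]
    if np.any(d == MISSING):
        exceed = 0
        for _ in range(n_perm):
            nlp, *_ = association_scan(rng.permutation(y), d)
            if np.max(nlp) >= result.top_neg_log10_p:
                exceed += 1
        corrected = (1 + exceed) / (n_perm + 1)
    else:
        # with complete data, min p <=> max |correlation| at fixed n
        g = d.astype(float)
        gc = g - g.mean(axis=0)
        sg = np.sqrt(np.sum(gc**2, axis=0))
        poly = sg > 0
        yc = y - y.mean()
        sy = np.sqrt(np.sum(yc**2))
        obs = np.max(np.abs(gc[:, poly].T @ yc) / (sg[poly] * sy))
        perm_idx = np.argsort(rng.random((n_perm, y.size)), axis=1)
        yp = yc[perm_idx.T]  # (n, n_perm); centering is permutation-invariant
        rmax = np.max(np.abs(gc[:, poly].T @ yp) / (sg[poly, None] * sy), axis=0)
        corrected = (1 + int(np.sum(rmax >= obs - 1e-15))) / (n_perm + 1)
    result.corrected_p = float(corrected)
    return result.corrected_p


def fdr(corrected_ps, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg q-values; ``method="storey"`` rescales by a
    pi0 estimate (fraction of p values above 0.5, doubled, capped at 1)."""
    p = np.asarray(corrected_ps, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        pi0 = min(1.0, 2.0 * float(np.mean(p > 0.5)))
        q = np.minimum(q * pi0, 1.0)
    elif method != "bh":
        raise ValueError(f"unknown FDR method {method!r}")
    return q


def run_tissue_scan(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
    window_half_width: int = 1_000_000,
    fdr_method: str = "bh",
) -> tuple[pd.DataFrame, dict[str, CisEqtlResult]]:
    """Scan every probe of a tissue; returns (per-probe summary, results)."""
    rng = rng or np.random.default_rng()
    results: dict[str, CisEqtlResult] = {}
    for probe_id in expr.probes["probe_id"]:
        res = cis_scan(expr, geno, probe_id, window_half_width)
        if not res.empty:
            permutation_correct(res, expr, geno, n_perm=n_perm, rng=rng)
        results[probe_id] = res
    tested = [r for r in results.values() if not r.empty]
    qs = fdr([r.corrected_p for r in tested], method=fdr_method)
    for r, q in zip(tested, qs):
        r.q_value = float(q)
    summary = pd.DataFrame(
        {
            "probe_id": [r.probe_id for r in tested],
            "tissue": expr.tissue,
            "top_variant_id": [r.top_variant_id for r in tested],
            "top_neg_log10_p": [r.top_neg_log10_p for r in tested],
            "corrected_p": [r.corrected_p for r in tested],
            "q_value": [r.q_value for r in tested],
        }
    )
    return summary, results


# ---------------------------------------------------------------------------
# association patterns from scans


def pattern_from_result(result: CisEqtlResult, probe_pos: int | None = None) -> AssociationPattern:
    """EAP from a cis scan: -log10(p) plus slope signs, anchored at the probe."""
    t = result.table
    anchor_pos = probe_pos if probe_pos is not None else int(
        (result.window[0] + result.window[1]) // 2
    )
    return AssociationPattern(
        trait=f"{result.probe_id}@{result.tissue}",
        variants=t[["variant_id", "chrom", "pos", "ref", "alt", "maf"]].reset_index(drop=True),
        neg_log10_p=t["neg_log10_p"].values.copy(),
        sign=t["sign"].values.copy(),
        anchor=(result.chrom, anchor_pos),
    )


def pattern_from_values(
    y: np.ndarray,
    geno: GenotypeMatrix,
    trait: str,
    anchor: tuple[str, int] | None = None,
) -> AssociationPattern:
    """Scan a raw expression vector against every variant of a locus."""
    nlp, sign, _, _ = association_scan(y, geno.dosages)
    v = geno.variants
    if anchor is None:
        anchor = (str(v["chrom"].iloc[0]), int(np.median(v["pos"].values)))
    return AssociationPattern(
        trait=trait,
        variants=v[["variant_id", "chrom", "pos", "ref", "alt", "maf"]].copy(),
        neg_log10_p=nlp,
        sign=sign,
        anchor=anchor,
    )
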