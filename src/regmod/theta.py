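"""The theta similarity statistic for pairs of association patterns.

An association pattern is the vector of per-variant -log10(p) values (with
effect signs) from either a cis-eQTL scan (EAP) or a case-control disease
scan (DAP).  Two patterns driven by the same regulatory variant(s) are
expected to have correlated -log10(p) profiles with consistent effect-sign
relationships.  theta combines a peak-weighted correlation r_w with its
sign-aware counterpart r_ws, shrinking r_ws towards zero through a logistic
link when r_w is low:

    w_i  = (max(x_i/x_max, y_i/y_max))^p
    r_w  = weighted Pearson correlation of (x, y) with weights w
    r_ws = the same after negating y_i on sign-discordant variants
    theta = r_ws / (1 + exp(-k (r_w - T)))

Defaults: weight exponent p = 1, steepness k = 30, midpoint T = 0.3, and
variants qualify when -log10(p) > 1.3 (p < 0.05) in at least one pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class UndefinedComparisonError(ValueError):
    """The comparison has no defined value (too few variants or no variance)."""


@dataclass
class AssociationPattern:
    """Per-variant association strengths and effect signs for one trait.

    ``sign`` is the sign of the per-variant effect (slope for expression,
    log odds ratio for disease) relative to the alternate allele.  ``anchor``
    is (chrom, pos) of the probe midpoint (eQTL) or locus midpoint
    (disease); ``interval`` optionally carries the full risk-locus interval
    (chrom, start, end; 1-based inclusive), which then replaces the 1-Mb
    anchor-distance rule when selecting variants.
    """

    trait: str
    variants: pd.DataFrame
    neg_log10_p: np.ndarray
    sign: np.ndarray
    anchor: tuple[str, int]
    interval: tuple[str, int, int] | None = None

    def __post_init__(self):
        self.neg_log10_p = np.asarray(self.neg_log10_p, dtype=float)
        self.sign = np.asarray(self.sign, dtype=float)
        if np.any(self.neg_log10_p < 0):
            raise ValueError("neg_log10_p must be non-negative")

    def flipped(self) -> "AssociationPattern":
        """Copy with every effect sign negated."""
        return AssociationPattern(
            self.trait, self.variants, self.neg_log10_p.copy(), -self.sign,
            self.anchor, self.interval,
        )


@dataclass
class ThetaParams:
    weight_exponent: float = 1.0
    steepness: float = 30.0
    midpoint: float = 0.3
    threshold: float = 1.3
    max_distance: float = 1_000_000.0
    min_informative: int = 2
    warn_informative: int = 10
    drop_ambiguous: bool = False


@dataclass
class ThetaComparison:
    trait_a: str
    trait_b: str
    r_w: float
    r_ws: float
    theta: float
    n_informative: int
    defined: bool = True
    reason: str = ""
    variant_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# harmonization of two summary-statistics sources


def harmonize(
    a: AssociationPattern, b: AssociationPattern, drop_ambiguous: bool = False
) -> pd.DataFrame:
    """Pair variants of two patterns on chrom+pos+allele identity.

    When the ref/alt labels are swapped between the sources, the second
    pattern's effect sign is flipped so both signs refer to the same allele.
    Variants with incompatible allele pairs are dropped (logged); strand-
    ambiguous A/T and C/G variants are dropped when ``drop_ambiguous``.
    """
    ta = a.variants.assign(x=a.neg_log10_p, sign_x=a.sign)
    tb = b.variants.assign(y=b.neg_log10_p, sign_y=b.sign)
    m = ta.merge(tb, on=["chrom", "pos"], suffixes=("_a", "_b"))
    if m.empty:
        return m.assign(flip=[])
    same = (m["ref_a"] == m["ref_b"]) & (m["alt_a"] == m["alt_b"])
    swapped = (m["ref_a"] == m["alt_b"]) & (m["alt_a"] == m["ref_b"])
    bad = ~(same | swapped)
    if bad.any():
        logger.info("dropping %d variants with incompatible alleles", int(bad.sum()))
    m = m[~bad].copy()
    swapped = (m["ref_a"] == m["alt_b"]) & (m["alt_a"] == m["ref_b"])
    m["sign_y"] = np.where(swapped, -m["sign_y"], m["sign_y"])
    if drop_ambiguous:
        amb = [
            (r, l) in AMBIGUOUS_PAIRS for r, l in zip(m["ref_a"], m["alt_a"])
        ]
        m = m[~np.asarray(amb)].copy()
    m = m.rename(columns={"variant_id_a": "variant_id", "ref_a": "ref", "alt_a": "alt"})
    return m.reset_index(drop=True)


def _within(pattern: AssociationPattern, chrom, pos, max_distance: float) -> np.ndarray:
    if pattern.interval is not None:
        c, start, end = pattern.interval
        return (chrom == c) & (pos >= start) & (pos <= end)
    ac, ap = pattern.anchor
    return (chrom == ac) & (np.abs(pos - ap) <= max_distance)


def select_informative(
    paired: pd.DataFrame,
    a: AssociationPattern,
    b: AssociationPattern,
    params: ThetaParams,
) -> pd.DataFrame:
    """Variants near either trait's anchor (or inside its risk interval)
    with -log10(p) above threshold for at least one of the two traits."""
    chrom = paired["chrom"].values
    pos = paired["pos"].values.astype(float)
    near = _within(a, chrom, pos, params.max_distance) | _within(
        b, chrom, pos, params.max_distance
    )
    strong = np.maximum(paired["x"].values, paired["y"].values) > params.threshold
    return paired[near & strong].reset_index(drop=True)


# ---------------------------------------------------------------------------
# weighted correlations


def pattern_weights(x: np.ndarray, y: np.ndarray, exponent: float = 1.0) -> np.ndarray:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    x_max, y_max = x.max(), y.max()
    if x_max <= 0 or y_max <= 0:
        raise UndefinedComparisonError("a pattern is identically zero")
    return np.maximum(x / x_max, y / y_max) ** exponent


def weighted_correlation_w(x, y, w) -> float:
    """Weighted Pearson correlation with /sum(w) moment normalisation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    sw = w.sum()
    xm = np.sum(w * x) / sw
    ym = np.sum(w * y) / sw
    sx = np.sqrt(np.sum(w * (x - xm) ** 2) / sw)
    sy = np.sqrt(np.sum(w * (y - ym) ** 2) / sw)
    if sx == 0 or sy == 0:
        raise UndefinedComparisonError("zero weighted variance")
    r = np.sum(w * ((x - xm) / sx) * ((y - ym) / sy)) / sw
    return float(np.clip(r, -1.0, 1.0))


def weighted_correlation(x, y, exponent: float = 1.0) -> float:
    return weighted_correlation_w(x, y, pattern_weights(x, y, exponent))


def signed_weighted_correlation(x, y, sign_x, sign_y, exponent: float = 1.0) -> float:
    """r_ws: y is negated on sign-discordant variants before correlating.

    Weights come from the unflipped magnitudes; a variant with a missing
    sign (0) on either side is treated as concordant.
    """
    w = pattern_weights(x, y, exponent)
    discordant = np.asarray(sign_x) * np.asarray(sign_y) < 0
    y_signed = np.where(discordant, -np.asarray(y, float), np.asarray(y, float))
    return weighted_correlation_w(x, y_signed, w)


def theta_score(r_ws: float, r_w: float, k: float = 30.0, T: float = 0.3) -> float:
    """Logistic shrinkage of r_ws by r_w."""
    return r_ws / (1.0 + np.exp(-k * (r_w - T)))


# ---------------------------------------------------------------------------
# the full pairwise comparison


def compare_patterns(
    a: AssociationPattern, b: AssociationPattern, params: ThetaParams | None = None
) -> ThetaComparison:
    """harmonize -> select informative -> r_w -> r_ws -> theta.

    The sign-flip step of r_ws is not exactly exchange-symmetric, so the
    pair is put in a canonical orientation (lexicographic trait id) first;
    theta(a, b) and theta(b, a) are then identical by construction.
    """
    params = params or ThetaParams()
    swap = b.trait < a.trait
    first, second = (b, a) if swap else (a, b)
    paired = harmonize(first, second, drop_ambiguous=params.drop_ambiguous)
    if paired.empty:
        return _undefined(a, b, 0, "no shared variants")
    sel = select_informative(paired, first, second, params)
    n = len(sel)
    if n < params.min_informative:
        return _undefined(a, b, n, f"only {n} informative variants")
    if n < params.warn_informative:
        logger.warning(
            "theta(%s, %s) based on only %d informative variants", a.trait, b.trait, n
        )
    x, y = sel["x"].values, sel["y"].values
    try:
        w = pattern_weights(x, y, params.weight_exponent)
        r_w = weighted_correlation_w(x, y, w)
        r_ws = signed_weighted_correlation(
            x, y, sel["sign_x"].values, sel["sign_y"].values, params.weight_exponent
        )
    except UndefinedComparisonError as exc:
        return _undefined(a, b, n, str(exc))
    th = theta_score(r_ws, r_w, params.steepness, params.midpoint)
    return ThetaComparison(
        a.trait, b.trait, r_w, r_ws, float(th), n,
        variant_ids=list(sel["variant_id"]),
    )


def _undefined(a, b, n, reason) -> ThetaComparison:
    return ThetaComparison(
        a.trait, b.trait, np.nan, np.nan, np.nan, n, defined=False, reason=reason
    )
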