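"""In-memory containers shared across the pipeline.

Genotypes are stored as alternate-allele dosages (0/1/2, ``MISSING`` = -1)
in a samples x variants integer matrix; expression as a samples x probes
float matrix with per-probe genomic annotation. Variant positions are
1-based base pairs, as in VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1


@dataclass(frozen=True)
class GenomicInterval:
    """Internal 0-based half-open interval; file boundaries are 1-based
    inclusive (VCF convention) and converted exactly once at I/O."""

    chrom: str
    start0: int
    end0: int
    name: str = ""

    @classmethod
    def from_1based(cls, chrom: str, start1: int, end1: int, name: str = "") -> "GenomicInterval":
        return cls(str(chrom), int(start1) - 1, int(end1), name)

    def to_1based(self) -> tuple[str, int, int]:
        return self.chrom, self.start0 + 1, self.end0

    @property
    def length(self) -> int:
        return self.end0 - self.start0

    @property
    def midpoint(self) -> int:
        """1-based midpoint position."""
        return (self.start0 + 1 + self.end0) // 2

    def contains(self, chrom: str, pos1: int) -> bool:
        return chrom == self.chrom and self.start0 < pos1 <= self.end0

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt", "maf"]
PROBE_COLUMNS = ["probe_id", "gene", "chrom", "pos"]


class ValidationError(ValueError):
    """A container violates one of its structural invariants."""


@dataclass
class GenotypeMatrix:
    """Dosage matrix plus variant annotation.

    Attributes
    ----------
    sample_ids : list of str
    variants : pandas.DataFrame
        Columns ``variant_id, chrom, pos, ref, alt, maf``; ``pos`` strictly
        increasing within each chromosome; ``maf`` is the minor-allele
        fraction recomputed from the dosages.
    dosages : ndarray of int8, shape (n_samples, n_variants)
        Alternate-allele counts in {0, 1, 2}, ``MISSING`` for no-calls.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def alt_freq(self) -> np.ndarray:
        """Per-variant alternate-allele frequency over called genotypes."""
        d = np.ma.masked_equal(self.dosages, MISSING)
        return np.asarray(d.mean(axis=0) / 2.0)

    def maf_from_dosages(self) -> np.ndarray:
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)

    def genotype_counts(self, j: int) -> tuple[int, int, int]:
        """(n_homref, n_het, n_homalt) for variant column ``j``."""
        d = self.dosages[:, j]
        return (int(np.sum(d == 0)), int(np.sum(d == 1)), int(np.sum(d == 2)))

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of variants with 1-based pos in the closed [start, end]."""
        v = self.variants
        mask = (v["chrom"].values == chrom) & (v["pos"].values >= start) & (
            v["pos"].values <= end
        )
        return np.flatnonzero(mask)

    def take_samples(self, idx: np.ndarray, suffix: bool = False) -> "GenotypeMatrix":
        """Row-subset (possibly with replacement, e.g. cohort resampling)."""
        idx = np.asarray(idx)
        if suffix:
            ids = [f"{self.sample_ids[i]}#{k}" for k, i in enumerate(idx)]
        else:
            ids = [self.sample_ids[i] for i in idx]
        out = GenotypeMatrix(ids, self.variants.copy(), self.dosages[idx].copy())
        out.variants["maf"] = out.maf_from_dosages()
        return out

    def take_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids),
            self.variants.iloc[idx].reset_index(drop=True),
            self.dosages[:, idx].copy(),
        )

    def validate(self) -> None:
        if self.dosages.shape != (self.n_samples, self.n_variants):
            raise ValidationError("dosage shape does not match annotation")
        vals = np.unique(self.dosages)
        if not np.all(np.isin(vals, [MISSING, 0, 1, 2])):
            raise ValidationError("dosages outside {0,1,2,missing}")
        for _, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].values
            if np.any(np.diff(pos) <= 0):
                raise ValidationError("positions not strictly increasing")
        tol = 1.0 / (2 * max(self.n_samples, 1))
        if np.any(np.abs(self.maf_from_dosages() - self.variants["maf"].values) > tol):
            raise ValidationError("stored maf inconsistent with dosages")


@dataclass
class ExpressionMatrix:
    """Samples x probes expression values for one tissue (log scale)."""

    sample_ids: list[str]
    probes: pd.DataFrame
    tissue: str
    values: np.ndarray = field(repr=False)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def probe_index(self, probe_id: str) -> int:
        hits = np.flatnonzero(self.probes["probe_id"].values == probe_id)
        if hits.size != 1:
            raise KeyError(f"probe {probe_id!r} not found exactly once")
        return int(hits[0])

    def probe_values(self, probe_id: str) -> np.ndarray:
        return self.values[:, self.probe_index(probe_id)]

    def validate(self) -> None:
        if self.values.shape != (self.n_samples, self.n_probes):
            raise ValidationError("value shape does not match annotation")
        if self.probes["probe_id"].duplicated().any():
            raise ValidationError("duplicated probe_id within tissue")
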