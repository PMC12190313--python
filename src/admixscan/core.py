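"""Core containers shared across the pipeline.

Genotypes are stored as diploid alternate-allele dosages in a dense float
array with ``numpy.nan`` marking missing calls.  Variant identity follows the
gnomAD convention ``chrom:pos:ref:alt`` with chromosome labels normalised to
the prefix-free dialect (``"7"``, not ``"chr7"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["VariantRecord", "GenotypeMatrix", "ValidationError"]


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


def _strip_chr(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True)
class VariantRecord:
    """Canonical identity of a biallelic variant.

    ``pos`` is 1-based (VCF convention).  ``build`` tags the genome build the
    coordinates refer to; no liftover is performed anywhere in the package.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: str | None = None
    build: str = "hg38"

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", _strip_chr(str(self.chrom)))
        if not self.ref or not self.alt:
            raise ValidationError("ref and alt alleles must be non-empty")
        if self.ref == self.alt:
            raise ValidationError(
                f"ref and alt are identical ({self.ref}) at {self.chrom}:{self.pos}"
            )
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")

    @property
    def canonical_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def swapped(self) -> "VariantRecord":
        """The record with ref and alt exchanged."""
        return replace(self, ref=self.alt, alt=self.ref)


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix.

    ``dosages[i, j]`` is the alternate-allele count (0, 1 or 2) of sample *i*
    at variant *j*; missing calls are ``nan``.  Sample ids and variant
    canonical ids are unique within a matrix.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    records: list[VariantRecord]
    build: str = "hg38"
    _id_index: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValidationError("dosages must be 2-D (samples x variants)")
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.records):
            raise ValidationError(
                f"shape {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples / {len(self.records)} variants"
            )
        if len(set(self.sample_ids)) != n:
            raise ValidationError("sample ids are not unique")
        vids = self.variant_ids
        if len(set(vids)) != m:
            raise ValidationError("variant canonical ids are not unique")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            raise ValidationError("dosages must lie in {0, 1, 2} or be missing")
        self._id_index = {v: j for j, v in enumerate(vids)}

    @property
    def variant_ids(self) -> list[str]:
        return [r.canonical_id for r in self.records]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_index(self, canonical_id: str) -> int:
        try:
            return self._id_index[canonical_id]
        except KeyError:
            raise ValidationError(f"unknown variant id {canonical_id!r}") from None

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def sample_missingness(self) -> np.ndarray:
        """Fraction of missing calls per sample."""
        return np.isnan(self.dosages).mean(axis=1)

    def site_missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency per variant over non-missing alleles."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def take_samples(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            self.dosages[idx, :],
            [self.sample_ids[i] for i in idx],
            list(self.records),
            self.build,
        )

    def take_variants(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            self.dosages[:, idx],
            list(self.sample_ids),
            [self.records[j] for j in idx],
            self.build,
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages.copy(), list(self.sample_ids), list(self.records), self.build
        )
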