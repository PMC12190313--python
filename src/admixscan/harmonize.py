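"""Multi-source genotype harmonization and quality control.

Covers the intake side of the pipeline: reading per-dataset VCFs into
dosage matrices, canonicalizing variant identities to the gnomAD
``chrom:pos:ref:alt`` convention, recovering (or dropping) allele-swapped
records against a truth dictionary, union-merging datasets on canonical id,
and the standard sample/site filters — sample missingness, duplicate and
first-degree-relative removal via the KING-robust kinship estimator, site
missingness and minor-allele-frequency thresholds, sliding-window LD
pruning, and seeded site subsampling.

Every removal is recorded with a machine-readable reason code so the
pipeline manifest can account for samples_in = samples_out + removed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, ValidationError, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "read_vcf",
    "normalize_variant_id",
    "resolve_allele_swap",
    "apply_allele_swaps",
    "merge_datasets",
    "filter_sample_missingness",
    "king_kinship",
    "kinship_filter",
    "site_filters",
    "ld_prune",
    "subsample_sites",
    "KinshipTable",
]

# Reason codes used in removal logs.
R_SAMPLE_MISSING = "sample_missingness"
R_KINSHIP = "kinship"
R_SITE_MISSING = "site_missingness"
R_SITE_MAF = "site_maf"
R_LD = "ld_prune"
R_SWAP_DROP = "allele_irreconcilable"


def read_vcf(path: str, build: str = "hg38", dataset_prefix: str | None = None) -> GenotypeMatrix:
    """Read a diploid, biallelic VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records are skipped with a warning.  ``dataset_prefix``
    (if given) is prepended to every sample id as ``prefix.sample`` so that
    ids stay globally unique across merged datasets.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    if dataset_prefix:
        samples = [f"{dataset_prefix}.{s}" for s in samples]
    records: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    for v in vcf:
        if len(v.ALT) != 1:
            logger.warning("skipping non-biallelic record %s:%s", v.CHROM, v.POS)
            continue
        rsid = v.ID if v.ID and v.ID != "." else None
        records.append(VariantRecord(v.CHROM, v.POS, v.REF, v.ALT[0], rsid, build))
        dos = np.full(len(samples), np.nan)
        for i, gt in enumerate(v.genotypes):
            a, b = gt[0], gt[1]
            if a >= 0 and b >= 0:
                dos[i] = a + b
        rows.append(dos)
    dosages = (
        np.column_stack(rows) if rows else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(dosages, samples, records, build)


def normalize_variant_id(record: VariantRecord) -> str:
    """Canonical ``chrom:pos:ref:alt`` id, chromosome dialect prefix-free."""
    return record.canonical_id


@dataclass
class SwapResolution:
    action: str  # "keep" | "swap" | "drop"
    record: VariantRecord | None


def resolve_allele_swap(
    record: VariantRecord, truth_ref: str, truth_alt: str
) -> SwapResolution:
    """Reconcile a record against truth alleles.

    Matching alleles pass through; exactly swapped alleles are fixed (the
    caller must flip dosages ``g -> 2 - g``); anything else is
    irreconcilable and dropped.
    """
    if (record.ref, record.alt) == (truth_ref, truth_alt):
        return SwapResolution("keep", record)
    if (record.ref, record.alt) == (truth_alt, truth_ref):
        return SwapResolution("swap", record.swapped())
    return SwapResolution("drop", None)


def apply_allele_swaps(
    matrix: GenotypeMatrix, truth: dict[str, tuple[str, str]]
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Fix or drop allele-swapped variants against a truth dictionary.

    ``truth`` maps ``chrom:pos`` to (ref, alt).  Variants absent from the
    dictionary are kept unchanged.  Returns the fixed matrix and a log of
    per-variant actions.
    """
    keep_idx: list[int] = []
    new_records: list[VariantRecord] = []
    flip: list[bool] = []
    log_rows = []
    for j, rec in enumerate(matrix.records):
        key = f"{rec.chrom}:{rec.pos}"
        if key not in truth:
            keep_idx.append(j)
            new_records.append(rec)
            flip.append(False)
            continue
        res = resolve_allele_swap(rec, *truth[key])
        if res.action == "drop":
            log_rows.append({"variant_id": rec.canonical_id, "reason": R_SWAP_DROP})
            continue
        keep_idx.append(j)
        new_records.append(res.record)
        flip.append(res.action == "swap")
    dos = matrix.dosages[:, keep_idx].copy()
    flip_mask = np.asarray(flip, dtype=bool)
    dos[:, flip_mask] = 2.0 - dos[:, flip_mask]  # nan stays nan
    fixed = GenotypeMatrix(dos, list(matrix.sample_ids), new_records, matrix.build)
    return fixed, pd.DataFrame(log_rows, columns=["variant_id", "reason"])


def merge_datasets(matrices: list[GenotypeMatrix]) -> GenotypeMatrix:
    """Union-merge datasets on canonical variant id.

    The merged variant set is the union of canonical ids ordered by
    (chrom, pos, ref, alt); entries absent from a source dataset are
    missing.  Sample ids must be globally unique (prefix datasets first).
    """
    if not matrices:
        raise ValidationError("nothing to merge")
    builds = {m.build for m in matrices}
    if len(builds) > 1:
        raise ValidationError(f"mixed genome builds {sorted(builds)}")
    all_samples: list[str] = []
    for m in matrices:
        all_samples.extend(m.sample_ids)
    if len(set(all_samples)) != len(all_samples):
        raise ValidationError("duplicate sample ids across datasets; prefix them")

    def _chrom_key(c: str):
        return (0, int(c)) if c.isdigit() else (1, c)

    union: dict[str, VariantRecord] = {}
    for m in matrices:
        for rec in m.records:
            prev = union.get(rec.canonical_id)
            if prev is not None and (prev.chrom, prev.pos, prev.ref, prev.alt) != (
                rec.chrom,
                rec.pos,
                rec.ref,
                rec.alt,
            ):
                raise ValidationError(f"conflicting records for {rec.canonical_id}")
            if prev is None:
                union[rec.canonical_id] = rec
    ordered = sorted(
        union.values(), key=lambda r: (_chrom_key(r.chrom), r.pos, r.ref, r.alt)
    )
    col_of = {r.canonical_id: j for j, r in enumerate(ordered)}
    out = np.full((len(all_samples), len(ordered)), np.nan)
    row0 = 0
    for m in matrices:
        cols = [col_of[v] for v in m.variant_ids]
        out[row0 : row0 + m.n_samples, cols] = m.dosages
        row0 += m.n_samples
    return GenotypeMatrix(out, all_samples, ordered, matrices[0].build)


def filter_sample_missingness(
    matrix: GenotypeMatrix, threshold: float = 0.99
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop samples whose missing-call fraction exceeds ``threshold``."""
    if not 0.0 < threshold <= 1.0:
        raise ValidationError("threshold must lie in (0, 1]")
    frac = matrix.sample_missingness()
    keep = frac <= threshold
    if not keep.any():
        raise ValidationError(
            f"all {matrix.n_samples} samples exceed missingness {threshold}"
        )
    log = pd.DataFrame(
        {
            "sample_id": [s for s, k in zip(matrix.sample_ids, keep) if not k],
            "reason": R_SAMPLE_MISSING,
        },
        columns=["sample_id", "reason"],
    )
    return matrix.take_samples(np.flatnonzero(keep)), log


@dataclass
class KinshipTable:
    """Pairwise KING-robust kinship estimates."""

    table: pd.DataFrame  # sample_i, sample_j, phi, n_shared

    def phi(self, a: str, b: str) -> float:
        t = self.table
        hit = t[((t.sample_i == a) & (t.sample_j == b)) | ((t.sample_i == b) & (t.sample_j == a))]
        if hit.empty:
            raise KeyError(f"no kinship entry for ({a}, {b})")
        return float(hit.phi.iloc[0])


def king_kinship(matrix: GenotypeMatrix, min_shared: int = 50) -> KinshipTable:
    """KING-robust between-family kinship for every sample pair.

    phi_ij = (N_het,het - 2 N_opp-hom) / (N_het(i) + N_het(j)), all counts
    over sites non-missing in both samples.  Pairs sharing fewer than
    ``min_shared`` such sites are skipped with a warning; a zero denominator
    is guarded to phi = 0.
    """
    G = matrix.dosages
    valid = ~np.isnan(G)
    het = np.where(valid & (G == 1.0), 1.0, 0.0)
    hom0 = np.where(valid & (G == 0.0), 1.0, 0.0)
    hom2 = np.where(valid & (G == 2.0), 1.0, 0.0)
    validf = valid.astype(float)
    n_hethet = het @ het.T
    n_opp = hom0 @ hom2.T + hom2 @ hom0.T
    het_in_shared = het @ validf.T  # (i, j): sample i's hets at sites valid in j
    denom = het_in_shared + het_in_shared.T
    shared = validf @ validf.T
    rows = []
    n = matrix.n_samples
    for i in range(n):
        for j in range(i + 1, n):
            if shared[i, j] < min_shared:
                warnings.warn(
                    f"pair ({matrix.sample_ids[i]}, {matrix.sample_ids[j]}) shares "
                    f"only {int(shared[i, j])} sites; kinship skipped"
                )
                continue
            d = denom[i, j]
            phi = (n_hethet[i, j] - 2.0 * n_opp[i, j]) / d if d > 0 else 0.0
            rows.append(
                {
                    "sample_i": matrix.sample_ids[i],
                    "sample_j": matrix.sample_ids[j],
                    "phi": phi,
                    "n_shared": int(shared[i, j]),
                }
            )
    return KinshipTable(
        pd.DataFrame(rows, columns=["sample_i", "sample_j", "phi", "n_shared"])
    )


def kinship_filter(
    matrix: GenotypeMatrix, phi_threshold: float = 0.177, min_shared: int = 50
) -> tuple[GenotypeMatrix, KinshipTable, pd.DataFrame]:
    """Remove one member of every pair closer than first-degree.

    phi > 0.354 flags duplicates/MZ twins, phi in (0.177, 0.354] first-degree
    relatives; with the default threshold both are removed.  The member with
    more missing calls goes; ties break toward the later sample id.
    """
    if matrix.n_samples < 2:
        raise ValidationError("kinship filtering needs at least 2 samples")
    kin = king_kinship(matrix, min_shared=min_shared)
    miss = dict(zip(matrix.sample_ids, matrix.sample_missingness()))
    removed: set[str] = set()
    flagged = kin.table[kin.table.phi > phi_threshold].sort_values(
        "phi", ascending=False
    )
    for _, row in flagged.iterrows():
        a, b = row.sample_i, row.sample_j
        if a in removed or b in removed:
            continue
        if miss[a] > miss[b]:
            removed.add(a)
        elif miss[b] > miss[a]:
            removed.add(b)
        else:
            removed.add(max(a, b))
    keep = [i for i, s in enumerate(matrix.sample_ids) if s not in removed]
    log = pd.DataFrame(
        {"sample_id": sorted(removed), "reason": R_KINSHIP},
        columns=["sample_id", "reason"],
    )
    return matrix.take_samples(keep), kin, log


def site_filters(
    matrix: GenotypeMatrix, max_missing: float = 0.75, min_maf: float = 0.05
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop variants with missingness above ``max_missing`` or MAF below ``min_maf``."""
    if not (0.0 < max_missing < 1.0 and 0.0 < min_maf < 1.0):
        raise ValidationError("thresholds must lie in (0, 1)")
    missing = matrix.site_missingness()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing columns
        maf = matrix.maf()
    drop_missing = missing > max_missing
    drop_maf = ~drop_missing & (np.isnan(maf) | (maf < min_maf))
    keep = ~(drop_missing | drop_maf)
    vids = matrix.variant_ids
    log = pd.DataFrame(
        [
            {"variant_id": vids[j], "reason": R_SITE_MISSING}
            for j in np.flatnonzero(drop_missing)
        ]
        + [
            {"variant_id": vids[j], "reason": R_SITE_MAF}
            for j in np.flatnonzero(drop_maf)
        ],
        columns=["variant_id", "reason"],
    )
    return matrix.take_variants(np.flatnonzero(keep)), log


def _pairwise_r2(block: np.ndarray) -> np.ndarray:
    """Squared dosage correlation between columns, mean-imputing missing calls."""
    X = block.copy()
    mu = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mu, inds[1])
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X /= sd
    r = (X.T @ X) / X.shape[0]
    return r**2


def ld_prune(
    matrix: GenotypeMatrix, window: int = 50, step: int = 5, r2_max: float = 0.1
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Greedy sliding-window LD pruning on dosage correlation.

    Within each window of ``window`` variants (per chromosome, ordered by
    position) any pair with r^2 above ``r2_max`` loses its lower-MAF member
    (tie: later position goes); the window then advances by ``step``.
    """
    def _ck(c: str):
        return (0, int(c), "") if c.isdigit() else (1, 0, c)

    m = matrix.n_variants
    order = np.array(
        sorted(range(m), key=lambda j: (_ck(matrix.records[j].chrom), matrix.records[j].pos))
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        maf = matrix.maf()
    keep = np.ones(m, dtype=bool)
    chroms = np.array([matrix.records[j].chrom for j in order])
    for chrom in pd.unique(chroms):
        idx = order[chroms == chrom]
        start = 0
        while start < len(idx):
            win = [j for j in idx[start : start + window] if keep[j]]
            if len(win) > 1:
                r2 = _pairwise_r2(matrix.dosages[:, win])
                for a in range(len(win)):
                    if not keep[win[a]]:
                        continue
                    for b in range(a + 1, len(win)):
                        if not keep[win[b]]:
                            continue
                        if r2[a, b] > r2_max:
                            ja, jb = win[a], win[b]
                            if maf[ja] < maf[jb]:
                                keep[ja] = False
                            elif maf[jb] < maf[ja]:
                                keep[jb] = False
                            else:  # tie: drop the later position
                                keep[max(ja, jb, key=lambda j: matrix.records[j].pos)] = False
            if start + window >= len(idx):
                break
            start += step
    vids = matrix.variant_ids
    log = pd.DataFrame(
        [{"variant_id": vids[j], "reason": R_LD} for j in np.flatnonzero(~keep)],
        columns=["variant_id", "reason"],
    )
    return matrix.take_variants(np.flatnonzero(keep)), log


def subsample_sites(
    matrix: GenotypeMatrix, n_sites: int = 250_000, seed: int = 0
) -> GenotypeMatrix:
    """Seeded uniform draw of ``n_sites`` variants without replacement.

    Requesting at least as many sites as exist returns the matrix unchanged.
    """
    if n_sites >= matrix.n_variants:
        if n_sites > matrix.n_variants:
            warnings.warn(
                f"requested {n_sites} sites but only {matrix.n_variants} available; keeping all"
            )
        return matrix
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(matrix.n_variants, size=n_sites, replace=False))
    return matrix.take_variants(idx)
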