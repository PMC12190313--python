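"""Clinical and pharmacogenomic annotation joins and diagnostic yield.

Annotations come from local TSV snapshots of two kinds: ClinVar-like
records carrying one of three pathogenicity classes (uncertain,
conflicting, pathogenic/likely pathogenic) and PharmGKB-like records
carrying an evidence level (1A strongest .. 4).  Scan results are
left-joined on the canonical variant id; the diagnostic yield D_ip of
ancestry group i and pathogenicity class p is the percentage of the
group's observed variants (>= 1 alternate allele seen in the group)
annotated with that class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, ValidationError

__all__ = [
    "CLINVAR_SEVERITY",
    "PHARMGKB_SEVERITY",
    "load_annotations",
    "join_scan",
    "diagnostic_yield",
]

# Severity orders used to collapse duplicate rows (most severe kept).
CLINVAR_SEVERITY = ["pathogenic/likely pathogenic", "conflicting", "uncertain"]
PHARMGKB_SEVERITY = ["1A", "1B", "2A", "2B", "3", "4"]

_REQUIRED = {
    "clinvar-like": ["variant_id", "classification"],
    "pharmgkb-like": ["variant_id", "evidence_level"],
}
_VOCAB = {
    "clinvar-like": ("classification", set(CLINVAR_SEVERITY)),
    "pharmgkb-like": ("evidence_level", set(PHARMGKB_SEVERITY)),
}


def load_annotations(path: str, source: str) -> pd.DataFrame:
    """Read and validate an annotation snapshot TSV.

    Unknown classifications are rejected with their line number; duplicate
    rows for one variant collapse to the most severe classification.
    """
    if source not in _REQUIRED:
        raise ValidationError(f"unknown annotation source {source!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED[source] if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    col, vocab = _VOCAB[source]
    bad = ~df[col].isin(vocab)
    if bad.any():
        lineno = int(df.index[bad][0]) + 2  # header is line 1
        raise ValidationError(
            f"{path}:{lineno}: unknown {col} {df.loc[bad, col].iloc[0]!r}"
        )
    order = CLINVAR_SEVERITY if source == "clinvar-like" else PHARMGKB_SEVERITY
    rank = {c: i for i, c in enumerate(order)}
    df = df.assign(_rank=df[col].map(rank)).sort_values(
        ["variant_id", "_rank"], kind="stable"
    )
    df = df.drop_duplicates("variant_id", keep="first").drop(columns="_rank")
    df["source"] = source
    return df.reset_index(drop=True)


def join_scan(
    results: pd.DataFrame,
    clinvar: pd.DataFrame | None = None,
    pharmgkb: pd.DataFrame | None = None,
    evidence_filter: set[str] = frozenset({"1A", "1B", "2A", "2B"}),
) -> pd.DataFrame:
    """Left-join annotations onto scan results, flagging high-evidence rows.

    Every scan row survives.  Pharmacogenomic rows whose evidence level is
    in ``evidence_filter`` are flagged ``high_evidence``.  Output keeps the
    scan's Fisher-p ordering.
    """
    out = results.copy()
    if clinvar is not None and not clinvar.empty:
        cv = clinvar[["variant_id", "classification"]].rename(
            columns={"classification": "clinvar_class"}
        )
        if "gene" in clinvar.columns:
            cv = cv.assign(clinvar_gene=clinvar["gene"].values)
        if "phenotype" in clinvar.columns:
            cv = cv.assign(phenotype=clinvar["phenotype"].values)
        out = out.merge(cv, on="variant_id", how="left")
    else:
        out["clinvar_class"] = pd.NA
    if pharmgkb is not None and not pharmgkb.empty:
        pg = pharmgkb[["variant_id", "evidence_level"]]
        if "gene" in pharmgkb.columns:
            pg = pg.assign(pgx_gene=pharmgkb["gene"].values)
        if "drug" in pharmgkb.columns:
            pg = pg.assign(drug=pharmgkb["drug"].values)
        out = out.merge(pg, on="variant_id", how="left")
    else:
        out["evidence_level"] = pd.NA
    out["high_evidence"] = out["evidence_level"].isin(evidence_filter)
    return out.sort_values("fisher_p", kind="stable").reset_index(drop=True)


def diagnostic_yield(
    matrix: GenotypeMatrix,
    labels: np.ndarray,
    clinvar: pd.DataFrame,
    global_denominator: bool = False,
) -> pd.DataFrame:
    """Diagnostic yield per ancestry group and pathogenicity class.

    The variant universe of group i is the set of variants with at least
    one observed alternate allele among the group's samples (or, with
    ``global_denominator``, all cohort variants); D_ip is the percentage of
    that universe annotated with class p.  Groups with an empty universe
    report missing yields.
    """
    labels = np.asarray(labels)
    if len(labels) != matrix.n_samples:
        raise ValidationError("one group label per sample required")
    class_of = (
        dict(zip(clinvar["variant_id"], clinvar["classification"]))
        if clinvar is not None and not clinvar.empty
        else {}
    )
    vids = np.array(matrix.variant_ids)
    rows = []
    for group in pd.unique(labels):
        sub = matrix.dosages[labels == group]
        with np.errstate(invalid="ignore"):
            seen = np.nansum(sub, axis=0) > 0
        if global_denominator:
            universe = vids
        else:
            universe = vids[seen]
        denom = len(universe)
        for cls in CLINVAR_SEVERITY:
            num = sum(1 for v in universe if class_of.get(v) == cls)
            rows.append(
                {
                    "group": str(group),
                    "classification": cls,
                    "numerator": num,
                    "denominator": denom,
                    "percent": 100.0 * num / denom if denom else np.nan,
                }
            )
    return pd.DataFrame(rows)
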