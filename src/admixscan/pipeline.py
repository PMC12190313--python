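"""End-to-end pipeline: simulate → harmonize → ancestry → scan → annotate → AFA.

A single TOML config drives the run; every stage writes TSV outputs plus a
JSON manifest entry (parameters, sample/variant counts in and out, files
written), and identical (config, seed) pairs produce byte-identical
outputs.  Stages can be toggled; a stage whose upstream outputs are absent
fails fast with the missing stage named.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import afa as afa_mod
from . import ancestry as anc_mod
from . import annotate as ann_mod
from . import harmonize as harm_mod
from . import scan as scan_mod
from . import simdata
from .core import GenotypeMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "make_report", "StageError"]

STAGES = ["simulate", "harmonize", "ancestry", "scan", "annotate", "afa"]

_SCHEMA: dict[str, set[str]] = {
    "run": {"output_dir", "seed", "stages"},
    "inputs": {
        "vcfs", "dataset_prefixes", "reference_vcf", "reference_labels",
        "clinvar", "pharmgkb", "region_weights", "build",
    },
    "simulate": {
        "n_samples", "n_variants", "n_planted", "missingness", "concentration",
        "clinvar_fraction", "n_reference_per_pop", "n_regions",
    },
    "harmonize": {
        "sample_missingness", "phi_threshold", "kinship_min_shared", "max_missing",
        "min_maf", "ld_window", "ld_step", "ld_r2", "n_sites",
    },
    "ancestry": {
        "K", "tol", "max_iter", "n_init", "k_range", "restarts", "n_pcs",
        "predominant",
    },
    "scan": {"threshold", "method", "mc_reps"},
    "annotate": {"evidence_filter", "global_denominator"},
    "afa": {"tol", "max_iter"},
}

_DEFAULTS: dict[str, dict] = {
    "run": {"output_dir": "admixscan_out", "seed": 0, "stages": STAGES},
    "inputs": {},
    "simulate": {
        "n_samples": 200, "n_variants": 2000, "n_planted": 10, "missingness": 0.02,
        "concentration": 100.0, "clinvar_fraction": 0.10,
        "n_reference_per_pop": 50, "n_regions": 8,
    },
    "harmonize": {
        "sample_missingness": 0.99, "phi_threshold": 0.177, "kinship_min_shared": 50,
        "max_missing": 0.75, "min_maf": 0.05,
        "ld_window": 50, "ld_step": 5, "ld_r2": 0.1, "n_sites": 250_000,
    },
    "ancestry": {
        "K": 3, "tol": 1e-4, "max_iter": 2000, "n_init": 3,
        "k_range": [1, 10], "restarts": 10, "n_pcs": 10, "predominant": 0.75,
    },
    "scan": {"threshold": 5e-8, "method": "auto", "mc_reps": 100_000},
    "annotate": {"evidence_filter": ["1A", "1B", "2A", "2B"], "global_denominator": False},
    "afa": {"tol": 1e-6, "max_iter": 1000},
}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    sections: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        merged: dict = {}
        for section, defaults in _DEFAULTS.items():
            merged[section] = dict(defaults)
        for section, values in raw.items():
            if section not in _SCHEMA:
                raise ValidationError(f"unknown config section [{section}]")
            if not isinstance(values, dict):
                raise ValidationError(f"config section [{section}] must be a table")
            unknown = set(values) - _SCHEMA[section]
            if unknown:
                raise ValidationError(
                    f"unknown keys in [{section}]: {sorted(unknown)}"
                )
            merged[section].update(values)
        bad = [s for s in merged["run"]["stages"] if s not in STAGES]
        if bad:
            raise ValidationError(f"unknown stages {bad}")
        return cls(merged)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def __getitem__(self, section: str) -> dict:
        return self.sections[section]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class _State:
    """In-memory hand-off between stages."""

    cohort: GenotypeMatrix | None = None
    reference: GenotypeMatrix | None = None
    reference_labels: pd.DataFrame | None = None
    scan_matrix: GenotypeMatrix | None = None
    pruned: GenotypeMatrix | None = None
    Q: np.ndarray | None = None
    cluster_names: np.ndarray | None = None
    scan_results: pd.DataFrame | None = None
    clinvar: pd.DataFrame | None = None
    pharmgkb: pd.DataFrame | None = None
    region_weights: pd.DataFrame | None = None


def _require(value, what: str, stage: str):
    if value is None:
        raise StageError(
            f"stage '{stage}' needs {what}, which no earlier stage produced; "
            "enable the producing stage or supply it under [inputs]"
        )
    return value


def run_pipeline(config: RunConfig | dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    if isinstance(config, (str, Path)):
        config = RunConfig.from_toml(config)
    elif isinstance(config, dict):
        config = RunConfig.from_dict(config)
    run = config["run"]
    seed = int(run["seed"])
    out = Path(out_dir if out_dir is not None else run["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.sections, indent=2, sort_keys=True))
    manifest: dict = {"seed": seed, "stages": {}}
    state = _State()
    stages = run["stages"]
    for stage in STAGES:
        if stage not in stages:
            continue
        logger.info("stage=%s event=start", stage)
        try:
            entry = _STAGE_FUNCS[stage](config, state, out, seed)
        except (ValidationError, StageError):
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError(f"stage '{stage}' failed: {exc}") from exc
        manifest["stages"][stage] = entry
        logger.info("stage=%s event=done", stage)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _stage_simulate(config: RunConfig, state: _State, out: Path, seed: int) -> dict:
    p = config["simulate"]
    sdir = out / "simulate"
    sdir.mkdir(exist_ok=True)
    spec = simdata.CohortSpec(
        n_samples=int(p["n_samples"]),
        n_variants=int(p["n_variants"]),
        n_planted=int(p["n_planted"]),
        missingness=float(p["missingness"]),
        concentration=float(p["concentration"]),
        seed=seed,
    )
    cohort = simdata.simulate_cohort(spec)
    ref, ref_labels = simdata.draw_reference_panel(
        cohort.freqs, n_per_pop=int(p["n_reference_per_pop"]), seed=seed + 101
    )
    clinvar, pharmgkb = simdata.make_annotation_fixtures(
        cohort.matrix.variant_ids,
        cohort.planted_ids,
        clinvar_fraction=float(p["clinvar_fraction"]),
        seed=seed + 202,
    )
    weights = simdata.make_region_weights(int(p["n_regions"]), seed=seed + 303)
    simdata.write_cohort_vcf(cohort.matrix, str(sdir / "cohort.vcf"))
    simdata.write_cohort_vcf(ref, str(sdir / "reference.vcf"))
    simdata.write_truth_table(
        cohort.q_truth, cohort.cluster_truth, cohort.matrix.sample_ids,
        str(sdir / "truth.tsv"),
    )
    _write_tsv(ref_labels, sdir / "reference_labels.tsv")
    _write_tsv(clinvar, sdir / "clinvar.tsv")
    _write_tsv(pharmgkb, sdir / "pharmgkb.tsv")
    _write_tsv(weights, sdir / "region_weights.tsv")
    state.cohort = cohort.matrix
    state.reference = ref
    state.reference_labels = ref_labels
    state.clinvar = clinvar
    state.pharmgkb = pharmgkb
    state.region_weights = weights
    return {
        "params": dict(p),
        "n_samples": cohort.matrix.n_samples,
        "n_variants": cohort.matrix.n_variants,
        "n_planted": int(spec.n_planted),
        "files": {f.name: _sha256(f) for f in sorted(sdir.iterdir())},
    }


def _stage_harmonize(config: RunConfig, state: _State, out: Path, seed: int) -> dict:
    p = config["harmonize"]
    inp = config["inputs"]
    hdir = out / "harmonize"
    hdir.mkdir(exist_ok=True)
    if state.cohort is None:
        vcfs = inp.get("vcfs")
        if not vcfs:
            raise StageError(
                "stage 'harmonize' needs a cohort: enable 'simulate' or list "
                "VCFs under [inputs]"
            )
        prefixes = inp.get("dataset_prefixes") or [f"DS{i}" for i in range(len(vcfs))]
        mats = [
            harm_mod.read_vcf(v, build=inp.get("build", "hg38"), dataset_prefix=pref)
            for v, pref in zip(vcfs, prefixes)
        ]
        state.cohort = harm_mod.merge_datasets(mats) if len(mats) > 1 else mats[0]
    if state.reference is None and inp.get("reference_vcf"):
        state.reference = harm_mod.read_vcf(inp["reference_vcf"], build=inp.get("build", "hg38"))
        state.reference_labels = pd.read_csv(inp["reference_labels"], sep="\t", dtype=str)
    n_in, m_in = state.cohort.n_samples, state.cohort.n_variants
    mat, miss_log = harm_mod.filter_sample_missingness(
        state.cohort, float(p["sample_missingness"])
    )
    mat, kin, kin_log = harm_mod.kinship_filter(
        mat, float(p["phi_threshold"]), int(p["kinship_min_shared"])
    )
    mat, site_log = harm_mod.site_filters(
        mat, float(p["max_missing"]), float(p["min_maf"])
    )
    state.scan_matrix = mat
    pruned, ld_log = harm_mod.ld_prune(
        mat, int(p["ld_window"]), int(p["ld_step"]), float(p["ld_r2"])
    )
    pruned = harm_mod.subsample_sites(pruned, int(p["n_sites"]), seed=seed + 11)
    state.pruned = pruned
    sample_log = pd.concat([miss_log, kin_log], ignore_index=True)
    variant_log = pd.concat([site_log, ld_log], ignore_index=True)
    _write_tsv(sample_log, hdir / "removed_samples.tsv")
    _write_tsv(variant_log, hdir / "removed_variants.tsv")
    _write_tsv(kin.table, hdir / "kinship.tsv")
    return {
        "params": dict(p),
        "samples_in": n_in,
        "samples_out": mat.n_samples,
        "samples_removed": int(len(sample_log)),
        "variants_in": m_in,
        "variants_out_scan": mat.n_variants,
        "variants_out_pruned": pruned.n_variants,
        "files": {f.name: _sha256(f) for f in sorted(hdir.iterdir())},
    }


def _stage_ancestry(config: RunConfig, state: _State, out: Path, seed: int) -> dict:
    p = config["ancestry"]
    adir = out / "ancestry"
    adir.mkdir(exist_ok=True)
    pruned = _require(state.pruned, "a harmonized cohort", "ancestry")
    ref = _require(state.reference, "a reference panel", "ancestry")
    labels_df = _require(state.reference_labels, "reference labels", "ancestry")
    ref_ids = set(pruned.variant_ids) & set(ref.variant_ids)
    keep = [j for j, v in enumerate(ref.variant_ids) if v in ref_ids]
    ref_sub = ref.take_variants(keep)
    keep_c = [j for j, v in enumerate(pruned.variant_ids) if v in ref_ids]
    coh_sub = pruned.take_variants(keep_c)
    # PCA: fit on the reference panel, project the cohort
    pca = anc_mod.ReferencePCA(n_components=int(p["n_pcs"])).fit(ref_sub)
    coords = pca.transform(coh_sub)
    pc_df = pd.DataFrame(
        coords, columns=[f"PC{i+1}" for i in range(coords.shape[1])]
    )
    pc_df.insert(0, "sample_id", coh_sub.sample_ids)
    _write_tsv(pc_df, adir / "pc_coordinates.tsv")
    # joint unsupervised admixture on cohort + reference, aligned by panel labels
    stacked = harm_mod.merge_datasets([coh_sub, ref_sub])
    est = anc_mod.AdmixtureEM(
        n_components=int(p["K"]),
        tol=float(p["tol"]),
        max_iter=int(p["max_iter"]),
        n_init=int(p["n_init"]),
        random_state=seed + 21,
    ).fit(stacked)
    pop_of = dict(zip(labels_df["sample_id"], labels_df["population"]))
    pops = np.array([pop_of.get(s, "") for s in stacked.sample_ids], dtype=object)
    Q, F, _ = anc_mod.align_components(est.Q_, est.components_, pops)
    n_cohort = coh_sub.n_samples
    state.Q = Q[:n_cohort]
    anc_labels = simdata.ANCESTRY_LABELS
    q_df = pd.DataFrame(state.Q, columns=[f"q_{a}" for a in anc_labels])
    q_df.insert(0, "sample_id", coh_sub.sample_ids)
    _write_tsv(q_df, adir / "ancestry_fractions.tsv")
    km = anc_mod.ElbowKMeans(
        k_range=tuple(p["k_range"]), n_init=int(p["restarts"]), random_state=seed + 31
    ).fit(state.Q)
    names = anc_mod.name_clusters(km.cluster_means_, anc_labels, float(p["predominant"]))
    state.cluster_names = np.array([names[c] for c in km.labels_], dtype=object)
    cl_df = pd.DataFrame(
        {"sample_id": coh_sub.sample_ids, "cluster": km.labels_, "name": state.cluster_names}
    )
    _write_tsv(cl_df, adir / "clusters.tsv")
    _write_tsv(
        pd.DataFrame({"k": km.k_values_, "sse": km.sse_}), adir / "elbow.tsv"
    )
    return {
        "params": dict(p),
        "n_clusters": int(km.n_clusters_),
        "cluster_names": sorted(set(names)),
        "loglik": est.loglik_trace_[-1],
        "em_converged": bool(est.converged_),
        "files": {f.name: _sha256(f) for f in sorted(adir.iterdir())},
    }


def _stage_scan(config: RunConfig, state: _State, out: Path, seed: int) -> dict:
    p = config["scan"]
    sdir = out / "scan"
    sdir.mkdir(exist_ok=True)
    mat = _require(state.scan_matrix, "a harmonized cohort", "scan")
    Q = _require(state.Q, "ancestry fractions", "scan")
    names = _require(state.cluster_names, "cluster assignments", "scan")
    results = scan_mod.genome_scan(
        mat, names, Q,
        threshold=float(p["threshold"]),
        method=str(p["method"]),
        mc_reps=int(p["mc_reps"]),
        seed=seed + 41,
    )
    state.scan_results = results
    _write_tsv(results, sdir / "scan_results.tsv")
    with open(sdir / "scan_results.jsonl", "w") as fh:
        for _, row in results.iterrows():
            fh.write(json.dumps({k: (None if pd.isna(v) else v) for k, v in row.items()},
                                default=str) + "\n")
    return {
        "params": dict(p),
        "n_variants": int(len(results)),
        "n_significant": int(results["significant"].sum()),
        "files": {f.name: _sha256(f) for f in sorted(sdir.iterdir())},
    }


def _stage_annotate(config: RunConfig, state: _State, out: Path, seed: int) -> dict:
    p = config["annotate"]
    inp = config["inputs"]
    adir = out / "annotate"
    adir.mkdir(exist_ok=True)
    results = _require(state.scan_results, "scan results", "annotate")
    mat = _require(state.scan_matrix, "a harmonized cohort", "annotate")
    names = _require(state.cluster_names, "cluster assignments", "annotate")
    if state.clinvar is None and inp.get("clinvar"):
        state.clinvar = ann_mod.load_annotations(inp["clinvar"], "clinvar-like")
    if state.pharmgkb is None and inp.get("pharmgkb"):
        state.pharmgkb = ann_mod.load_annotations(inp["pharmgkb"], "pharmgkb-like")
    joined = ann_mod.join_scan(
        results, state.clinvar, state.pharmgkb,
        evidence_filter=set(p["evidence_filter"]),
    )
    yield_table = ann_mod.diagnostic_yield(
        mat, names, state.clinvar, global_denominator=bool(p["global_denominator"])
    )
    _write_tsv(joined, adir / "annotated_results.tsv")
    _write_tsv(yield_table, adir / "diagnostic_yield.tsv")
    high = joined[joined["significant"] & joined["high_evidence"]]
    _write_tsv(high, adir / "high_evidence_hits.tsv")
    return {
        "params": dict(p),
        "n_high_evidence": int(len(high)),
        "files": {f.name: _sha256(f) for f in sorted(adir.iterdir())},
    }


def _stage_afa(config: RunConfig, state: _State, out: Path, seed: int) -> dict:
    p = config["afa"]
    inp = config["inputs"]
    adir = out / "afa"
    adir.mkdir(exist_ok=True)
    mat = _require(state.scan_matrix, "a harmonized cohort", "afa")
    Q = _require(state.Q, "ancestry fractions", "afa")
    est = afa_mod.AncestrySpecificAF(tol=float(p["tol"]), max_iter=int(p["max_iter"]))
    est.fit(mat, Q)
    anc = simdata.ANCESTRY_LABELS
    f_df = pd.DataFrame(est.freqs_.T, columns=[f"f_{a}" for a in anc])
    f_df.insert(0, "variant_id", mat.variant_ids)
    for k, a in enumerate(anc):
        f_df[f"reliable_{a}"] = bool(est.reliable_[k])
    _write_tsv(f_df, adir / "ancestral_frequencies.tsv")
    if state.region_weights is None and inp.get("region_weights"):
        state.region_weights = pd.read_csv(inp["region_weights"], sep="\t")
    if state.region_weights is not None:
        reg = afa_mod.region_freq(est.freqs_, state.region_weights)
        reg["variant_id"] = [mat.variant_ids[j] for j in reg["variant_index"]]
        _write_tsv(
            reg[["region", "variant_id", "ref_freq", "alt_freq"]],
            adir / "region_frequencies.tsv",
        )
    return {
        "params": dict(p),
        "n_variants": mat.n_variants,
        "files": {f.name: _sha256(f) for f in sorted(adir.iterdir())},
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "harmonize": _stage_harmonize,
    "ancestry": _stage_ancestry,
    "scan": _stage_scan,
    "annotate": _stage_annotate,
    "afa": _stage_afa,
}

_TOP_HIT_COLS = [
    "clinvar_gene", "pgx_gene", "chrom", "pos", "rsid", "clinvar_class",
    "evidence_level", "drug", "phenotype", "allele_count", "fisher_p", "fst",
    "enriched_cluster",
]


def make_report(out_dir: str | Path) -> list[Path]:
    """Summarize a completed run: top hits, ternary coordinates, yield, elbow."""
    out = Path(out_dir)
    rdir = out / "report"
    rdir.mkdir(exist_ok=True)
    written: list[Path] = []

    ann = out / "annotate" / "annotated_results.tsv"
    if ann.exists():
        df = pd.read_csv(ann, sep="\t")
        hits = df[df["significant"] == True]  # noqa: E712 - TSV round-trip bools
        cols = [c for c in _TOP_HIT_COLS if c in hits.columns]
        path = rdir / "top_hits.tsv"
        _write_tsv(hits[cols], path)
        written.append(path)
    else:
        logger.warning("report: no annotated results; top-hits section skipped")

    q = out / "ancestry" / "ancestry_fractions.tsv"
    if q.exists():
        path = rdir / "ternary_coordinates.tsv"
        _write_tsv(pd.read_csv(q, sep="\t"), path)
        written.append(path)
    else:
        logger.warning("report: no ancestry fractions; ternary section skipped")

    for src, name in [
        (out / "annotate" / "diagnostic_yield.tsv", "diagnostic_yield.tsv"),
        (out / "ancestry" / "elbow.tsv", "elbow.tsv"),
    ]:
        if src.exists():
            path = rdir / name
            path.write_bytes(src.read_bytes())
            written.append(path)
        else:
            logger.warning("report: %s missing; section skipped", src.name)
    return written
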