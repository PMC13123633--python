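"""File formats, configuration and end-to-end pipeline orchestration.

All tabular interchange is TSV (tab-separated, UTF-8, mandatory header,
"." for missing). Genotypes travel as VCF v4.2 with FORMAT GT:DP:GQ; the
reader is backed by cyvcf2, the writer emits the fixed subset this pipeline
produces. Coordinate conventions live in :mod:`wolfscan.coords`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from wolfscan import expression_screen as es
from wolfscan import genotype_qc as qc
from wolfscan import selection_scan as scan
from wolfscan.deconvolution import compare_celltype_proportions, deconvolve
from wolfscan.errors import PipelineError
from wolfscan.genotype_qc import MISSING, GenotypeMatrix
from wolfscan.radiometrics import AnimalDoseRecord, DoseCoefficients, compare_groups, dose_rates

logger = logging.getLogger("wolfscan")

NA = "."

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_tsv",
    "write_tsv",
    "read_records_tsv",
    "write_records_tsv",
    "write_dose_results",
    "assign_populations",
    "PipelineConfig",
    "run_pipeline",
]

# ---------------------------------------------------------------- TSV helpers


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=True, **kwargs)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", na_rep=NA, index=index)


# ------------------------------------------------------------------ VCF I/O

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=wolfscan
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##INFO=<ID=ANN,Number=1,Type=String,Description="Annotation tag">
"""

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write the GT:DP:GQ subset as VCF v4.2 (annotation tag in INFO)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in gm.sites["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        cols = "\t".join(gm.samples["sample_id"])
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        has_ann = "annotation" in gm.sites.columns
        for i in range(gm.n_sites):
            site = gm.sites.iloc[i]
            info = f"ANN={site['annotation']}" if has_ann else NA
            calls = "\t".join(
                f"{_GT[int(d)]}:{int(dp)}:{int(gq)}"
                for d, dp, gq in zip(gm.dosages[i], gm.depth[i], gm.quality[i])
            )
            fh.write(
                f"{site['chrom']}\t{site['pos']}\t.\t{site['ref']}\t{site['alt']}"
                f"\t.\tPASS\t{info}\tGT:DP:GQ\t{calls}\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Parse a VCF into a GenotypeMatrix (populations unassigned).

    Multi-allelic records are retained with a comma-joined ALT (dropped later
    by ``site_filters``); half-calls and missing genotypes become missing
    dosages. Parse failures report the record number.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ValueError(f"cannot open VCF {path!r}: {exc}") from exc
    sample_ids = list(vcf.samples)
    chroms, poss, refs, alts, anns = [], [], [], [], []
    dosages, depths, quals = [], [], []
    for rec_no, var in enumerate(vcf, start=1):
        try:
            chroms.append(var.CHROM)
            poss.append(var.POS)
            refs.append(var.REF)
            alts.append(",".join(var.ALT) if var.ALT else NA)
            ann = var.INFO.get("ANN")
            anns.append(ann if ann is not None else NA)
            gts = var.genotypes  # [[a, b, phased], ...]
            row = np.full(len(sample_ids), MISSING, dtype=np.int16)
            for j, g in enumerate(gts):
                a, b = g[0], g[1]
                if a >= 0 and b >= 0:
                    row[j] = int(a > 0) + int(b > 0)
            dosages.append(row)
            dp = var.format("DP")
            gq = var.format("GQ")
            depths.append(
                np.where(dp is None, 0, np.nan_to_num(dp, nan=0)).astype(np.int32).ravel()
                if dp is not None
                else np.zeros(len(sample_ids), dtype=np.int32)
            )
            quals.append(
                np.where(gq is None, 0, np.nan_to_num(gq, nan=0)).astype(np.int32).ravel()
                if gq is not None
                else np.zeros(len(sample_ids), dtype=np.int32)
            )
        except Exception as exc:
            raise ValueError(f"malformed VCF record #{rec_no} in {path!r}: {exc}") from exc
    sites = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts, "annotation": anns}
    )
    samples = pd.DataFrame({"sample_id": sample_ids, "population": ""})
    n = len(sites)
    shape = (n, len(sample_ids))
    return GenotypeMatrix(
        sites=sites,
        dosages=np.vstack(dosages) if n else np.empty(shape, dtype=np.int16),
        depth=np.vstack(depths) if n else np.empty(shape, dtype=np.int32),
        quality=np.vstack(quals) if n else np.empty(shape, dtype=np.int32),
        samples=samples,
    )


def assign_populations(gm: GenotypeMatrix, pops: pd.DataFrame) -> GenotypeMatrix:
    """Fill sample populations from a (sample_id, population) table."""
    mapping = dict(zip(pops["sample_id"], pops["population"]))
    unknown = [s for s in gm.samples["sample_id"] if s not in mapping]
    if unknown:
        raise ValueError(f"samples without population assignment: {unknown[:5]}")
    samples = gm.samples.copy()
    samples["population"] = samples["sample_id"].map(mapping)
    return dataclasses.replace(gm, samples=samples)


# -------------------------------------------------------- radiometrics I/O

_RECORD_COLS = [
    "animal_id",
    "population",
    "age_years",
    "activity_bqkg_wet",
    "activity_bqg_dry",
    "wet_dry_ratio",
    "soil_cs137_kbqm2",
    "soil_sr90_kbqm2",
    "ext_rate_ugyh",
]


def read_records_tsv(path) -> List[AnimalDoseRecord]:
    df = read_tsv(path)
    missing = set(_RECORD_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"records TSV missing columns: {sorted(missing)}")

    def opt(v):
        return None if pd.isna(v) else float(v)

    return [
        AnimalDoseRecord(
            animal_id=str(r["animal_id"]),
            population=str(r["population"]),
            age=float(r["age_years"]),
            internal_cs137_activity=opt(r["activity_bqkg_wet"]),
            dry_activity=opt(r["activity_bqg_dry"]),
            wet_dry_ratio=opt(r["wet_dry_ratio"]),
            soil_cs137=opt(r["soil_cs137_kbqm2"]),
            soil_sr90=opt(r["soil_sr90_kbqm2"]),
            measured_external_rate=opt(r["ext_rate_ugyh"]),
        )
        for _, r in df.iterrows()
    ]


def write_records_tsv(records: Sequence[AnimalDoseRecord], path) -> None:
    rows = [
        {
            "animal_id": r.animal_id,
            "population": r.population,
            "age_years": r.age,
            "activity_bqkg_wet": r.internal_cs137_activity,
            "activity_bqg_dry": r.dry_activity,
            "wet_dry_ratio": r.wet_dry_ratio,
            "soil_cs137_kbqm2": r.soil_cs137,
            "soil_sr90_kbqm2": r.soil_sr90,
            "ext_rate_ugyh": r.measured_external_rate,
        }
        for r in records
    ]
    write_tsv(pd.DataFrame(rows, columns=_RECORD_COLS), path)


def write_dose_results(results, path) -> None:
    write_tsv(pd.DataFrame([dataclasses.asdict(r) for r in results]), path)


# ------------------------------------------------------------- pipeline

_KNOWN_KEYS = {
    "vcf",
    "populations",
    "counts",
    "traits",
    "reference_profiles",
    "annotations",
    "out_dir",
    "dp_min",
    "gq_min",
    "max_missing",
    "autosomes",
    "annotation_tag",
    "ld_prune",
    "ld_window",
    "ld_step",
    "ld_r2_max",
    "thr_outlier",
    "thr_extreme",
    "mean_min",
    "gs_method",
    "gs_quantile",
    "gs_alpha",
    "outlier_k_sd",
    "n_signature_genes",
    "log_level",
}


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration; defaults are the study's values."""

    vcf: str
    populations: str
    counts: str
    traits: str
    reference_profiles: str
    annotations: str
    out_dir: str
    dp_min: int = 8
    gq_min: int = 20
    max_missing: float = 0.20
    autosomes: List[str] = field(default_factory=lambda: [f"chr{i}" for i in range(1, 39)])
    annotation_tag: Optional[str] = None
    ld_prune: bool = False
    ld_window: int = 50
    ld_step: int = 10
    ld_r2_max: float = 0.1
    thr_outlier: float = 8.0
    thr_extreme: float = 15.0
    mean_min: float = 10.0
    gs_method: str = "spearman"
    gs_quantile: float = 0.95
    gs_alpha: float = 0.05
    outlier_k_sd: float = 2.5
    n_signature_genes: int = 50
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> Dict:
    """QC → (prune) → PBE scan → annotate; normalize → screen → deconvolve.

    Writes every stage TSV plus ``summary.json`` and a resolved-config copy
    into ``cfg.out_dir`` and returns the summary dict. Any stage error aborts
    with the stage name.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: Dict = {"stages": {}}
    state: Dict = {}

    def stage(name, fn):
        try:
            result = fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc
        logger.info("stage %s: %s", name, result)
        summary["stages"][name] = result
        return result

    cfg.to_yaml(out / "resolved_config.yaml")

    # --- genotype arm -----------------------------------------------------
    def _load():
        gm = read_vcf(cfg.vcf)
        pops = read_tsv(cfg.populations)
        state["gm"] = assign_populations(gm, pops)
        return {"sites": gm.n_sites, "samples": gm.n_samples}

    stage("read_vcf", _load)

    def _mask():
        state["gm"] = qc.mask_low_quality(state["gm"], cfg.dp_min, cfg.gq_min)
        return {"masked_calls": int((state["gm"].dosages == MISSING).sum())}

    stage("mask_low_quality", _mask)

    def _sites():
        filtered = qc.site_filters(state["gm"], cfg.max_missing, cfg.autosomes)
        if filtered.n_sites == 0:
            raise ValueError("no sites survive the site filters")
        state["gm"] = filtered
        return {"sites_retained": filtered.n_sites}

    stage("site_filters", _sites)

    if cfg.annotation_tag:

        def _ann():
            state["gm"] = qc.annotation_subset(state["gm"], cfg.annotation_tag)
            return {"sites_retained": state["gm"].n_sites}

        stage("annotation_subset", _ann)

    if cfg.ld_prune:

        def _prune():
            kept = qc.ld_prune(state["gm"], cfg.ld_window, cfg.ld_step, cfg.ld_r2_max)
            pruned = state["gm"].subset_sites(kept)
            pruned.site_filtered = True
            state["gm"] = pruned
            write_tsv(pruned.sites[["chrom", "pos"]], out / "kept_sites.tsv")
            return {"sites_retained": len(kept)}

        stage("ld_prune", _prune)

    write_vcf(state["gm"], out / "filtered.vcf")

    def _scan():
        res = scan.PBEScan(state["gm"]).fit(cfg.thr_outlier, cfg.thr_extreme)
        state["scan"] = res
        write_tsv(res.table, out / "pbe.tsv")
        return {
            "analyzed": res.n_analyzed,
            "outliers": res.n_outliers,
            "extreme": res.n_extreme,
        }

    stage("pbe_scan", _scan)

    def _annot():
        ann = read_tsv(cfg.annotations)
        report = scan.annotate_outliers(state["scan"].table, ann)
        write_tsv(report, out / "outlier_genes.tsv")
        return {"annotated_outliers": len(report)}

    stage("annotate_outliers", _annot)

    # --- expression arm ---------------------------------------------------
    def _norm():
        counts = read_tsv(cfg.counts, index_col=0)
        kept = es.filter_low_expression(counts, cfg.mean_min)
        norm = es.cpm_normalize(kept)
        flagged = es.flag_outlier_samples(norm, cfg.outlier_k_sd)
        state["norm"] = norm.drop(columns=flagged)
        write_tsv(state["norm"], out / "normalized.tsv", index=True)
        return {
            "genes_in": len(counts),
            "genes_kept": len(kept),
            "samples_flagged": flagged,
        }

    stage("normalize", _norm)

    def _gs():
        traits = read_tsv(cfg.traits, index_col=0)
        norm = state["norm"]
        traits = traits.loc[norm.columns]
        gs = es.gene_significance(norm, traits["dose_rate"], cfg.gs_method)
        selected = es.dose_correlated_set(gs, cfg.gs_quantile, cfg.gs_alpha)
        gs["selected"] = gs.index.isin(selected)
        write_tsv(gs.reset_index(names="gene"), out / "gene_significance.tsv")
        return {"genes_tested": int(gs["defined"].sum()), "selected": len(selected)}

    stage("gene_significance", _gs)

    def _deconv():
        ref = read_tsv(cfg.reference_profiles, index_col=0)
        counts = read_tsv(cfg.counts, index_col=0)
        cpm = counts.div(counts.sum(axis=0), axis=1) * 1e6
        props = deconvolve(cpm, ref, cfg.n_signature_genes)
        write_tsv(props.reset_index(names="sample_id"), out / "proportions.tsv")
        return {"samples": len(props), "cell_types": list(props.columns)}

    stage("deconvolution", _deconv)

    # --- bookkeeping ------------------------------------------------------
    # resolved_config.yaml embeds absolute paths, so it is excluded from the
    # checksum manifest (which must be seed-reproducible across directories)
    outputs = sorted(
        p for p in out.iterdir()
        if p.name not in ("summary.json", "resolved_config.yaml")
    )
    summary["outputs"] = {p.name: _sha256(p) for p in outputs}
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
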