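"""File I/O, pipeline configuration and orchestration.

Reads the standard inputs of a case-control exome scan — a multi-sample VCF
with GT/GQ/AD, a TSV sample sheet, a per-variant annotation table, optional
gene lists — and drives the full pipeline in its fixed stage order:
genotype-support filtering, sample QC, track-specific variant QC, class
building, then the single-variant and burden scans.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from . import annotate, burden, qc, single_variant
from .qc import MISSING
from .simulate import Cohort, CohortTruth

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "read_vcf",
    "read_sample_sheet",
    "read_annotation_table",
    "read_gene_list",
    "read_cohort",
    "run_pipeline",
]

SAMPLE_SHEET_COLUMNS = ["sample_id", "status", "reported_sex"]
ANNOTATION_COLUMNS = [
    "variant_key", "gene", "consequence", "condel", "alignability",
    "repeat_distance", "tranche", "is_snv",
]

# cyvcf2 gt_types code: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
_GT_TYPE_MAP = np.array([0, 1, MISSING, 2], dtype=np.int8)


def read_vcf(path: str | Path) -> dict:
    """Parse a VCF v4.x into genotype/GQ/AD arrays and a variant table.

    Only normalised biallelic records are accepted; a multi-allelic record
    aborts with guidance to split it upstream. Positions stay 1-based.
    Gzipped and plain files are both handled (delegated to htslib).
    """
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    genotypes, gqs, ads, rows = [], [], [], []
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            raise ValueError(
                f"record {i + 1} at {rec.CHROM}:{rec.POS} is multi-allelic; "
                "split and normalise (e.g. `bcftools norm -m-`) before input"
            )
        genotypes.append(_GT_TYPE_MAP[rec.gt_types])
        gq = rec.gt_quals
        gqs.append(np.where(np.isfinite(gq), gq, -1).astype(np.int16)
                   if gq is not None else np.full(len(samples), -1, np.int16))
        ad = rec.format("AD")
        if ad is None:
            ads.append(np.full((len(samples), 2), -1, np.int32))
        else:
            ads.append(np.where(ad < 0, -1, ad)[:, :2].astype(np.int32))
        rows.append(
            {"chrom": rec.CHROM, "pos": rec.POS, "ref": rec.REF,
             "alt": rec.ALT[0],
             "variant_key": f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"}
        )
    if not rows:
        return {
            "genotypes": np.zeros((0, len(samples)), np.int8),
            "gq": np.zeros((0, len(samples)), np.int16),
            "ad": np.zeros((0, len(samples), 2), np.int32),
            "variants": pd.DataFrame(
                columns=["chrom", "pos", "ref", "alt", "variant_key"]
            ),
            "samples": samples,
        }
    return {
        "genotypes": np.vstack(genotypes),
        "gq": np.vstack(gqs),
        "ad": np.stack(ads),
        "variants": pd.DataFrame(rows),
        "samples": samples,
    }


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read the TSV sample sheet (sample_id, status, reported_sex)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(SAMPLE_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet lacks columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in sheet: {dups}")
    bad = ~df["status"].isin(["case", "control"])
    if bad.any():
        raise ValueError(
            f"unknown status values: {sorted(df.loc[bad, 'status'].unique())}"
        )
    df["reported_sex"] = df["reported_sex"].fillna("unknown")
    return df


def read_annotation_table(
    path: str | Path, known_keys: set[str] | None = None
) -> pd.DataFrame:
    """Read the per-variant annotation TSV; warn-and-drop unknown variants."""
    df = pd.read_csv(path, sep="\t")
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table lacks columns: {sorted(missing)}")
    if known_keys is not None:
        unknown = ~df["variant_key"].isin(known_keys)
        if unknown.any():
            logger.warning(
                "%d annotation rows reference variants absent from the VCF; "
                "excluded", int(unknown.sum()),
            )
            df = df[~unknown].reset_index(drop=True)
    return df


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments skipped."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return list(dict.fromkeys(genes))


def read_cohort(directory: str | Path) -> Cohort:
    """Load a cohort previously written by :func:`burdenscan.simulate.write_cohort`."""
    d = Path(directory)
    parsed = read_vcf(d / "cohort.vcf")
    samples = read_sample_sheet(d / "samples.tsv")
    order = {s: i for i, s in enumerate(parsed["samples"])}
    samples = samples.sort_values(
        "sample_id", key=lambda s: s.map(order), kind="mergesort"
    ).reset_index(drop=True)
    annotations = read_annotation_table(
        d / "annotations.tsv",
        known_keys=set(parsed["variants"]["variant_key"]),
    )
    truth_path = d / "truth.json"
    truth = (
        CohortTruth.from_json(truth_path.read_text())
        if truth_path.exists()
        else CohortTruth()
    )
    variants = parsed["variants"].copy()
    # recover subset designations from the annotation table
    subset = pd.Series("rare", index=variants.index)
    gene_of = annotations.set_index("variant_key")["gene"]
    is_x = variants["chrom"] == "X"
    no_gene = variants["variant_key"].map(gene_of).fillna(".") == "."
    subset[no_gene & ~is_x] = "common_snv"
    subset[is_x] = "x_check"
    variants["subset"] = subset
    return Cohort(
        genotypes=parsed["genotypes"],
        gq=parsed["gq"],
        ad=parsed["ad"].astype(np.int32),
        variants=variants,
        samples=samples,
        annotations=annotations,
        truth=truth,
    )


@dataclass
class PipelineConfig:
    """Paths, thresholds and run options for the full pipeline."""

    vcf: str
    sample_sheet: str
    annotation_table: str
    out_dir: str = "results"
    csg_list: str | None = None
    ancestry_exclusions: str | None = None

    # thresholds (defaults are the analysis' canonical values)
    min_gq: int = 30
    min_alt_depth_exclusive: int = 3
    max_tranche_snv: float = 99.5
    max_tranche_indel: float = 99.0
    sample_outlier_sd: float = 3.0
    duplicate_concordance: float = 0.95
    maf_threshold: float = 0.01
    maf_max_single: float = 0.05
    alpha: float = 0.05
    min_samples: int = 10
    trim: float = 0.10

    # run options
    seed: int = 0
    perm_B: int = 1_000_000
    pvalue_convention: str = "midp"
    dry_run: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run QC, class building and both association scans; write reports.

    Stage order is fixed: genotype-support filter -> sample QC -> variant QC
    per track -> gene-class building -> scans. Every sample or variant
    exclusion is logged with its reason; the summary JSON records all
    thresholds actually applied.
    """
    for p in (config.vcf, config.sample_sheet, config.annotation_table,
              config.csg_list, config.ancestry_exclusions):
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(p)
    if config.dry_run:
        return {"status": "inputs validated", "config": asdict(config)}

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    parsed = read_vcf(config.vcf)
    samples = read_sample_sheet(config.sample_sheet)
    if set(samples["sample_id"]) != set(parsed["samples"]):
        raise ValueError("sample sheet and VCF disagree on sample ids")
    order = {s: i for i, s in enumerate(parsed["samples"])}
    samples = samples.sort_values(
        "sample_id", key=lambda s: s.map(order), kind="mergesort"
    ).reset_index(drop=True)
    annotations = read_annotation_table(
        config.annotation_table, known_keys=set(parsed["variants"]["variant_key"])
    )
    ann_by_key = annotations.drop_duplicates("variant_key").set_index("variant_key")
    vmeta = parsed["variants"].join(ann_by_key, on="variant_key")
    if vmeta[["alignability", "repeat_distance", "tranche", "is_snv"]].isna().any().any():
        raise ValueError("every VCF variant needs a complete annotation row")

    # stage 1: genotype support -------------------------------------------
    genotypes = qc.apply_genotype_support_filter(
        parsed["genotypes"], parsed["gq"], parsed["ad"][:, :, 1],
        vmeta["tranche"].to_numpy(), vmeta["is_snv"].to_numpy(dtype=bool),
        qc.GenotypeSupportThresholds(
            config.min_gq, config.min_alt_depth_exclusive,
            config.max_tranche_snv, config.max_tranche_indel,
        ),
    )

    # stage 2: sample QC ---------------------------------------------------
    gene_of = vmeta["gene"].fillna(".")
    is_x = (vmeta["chrom"] == "X").to_numpy()
    common_rows = np.flatnonzero((gene_of == ".").to_numpy() & ~is_x)
    x_rows = np.flatnonzero(is_x)
    ancestry = (
        set(read_gene_list(config.ancestry_exclusions))
        if config.ancestry_exclusions
        else None
    )
    sqc = qc.sample_qc(
        genotypes, common_rows, genotypes[x_rows], samples,
        ancestry_exclusions=ancestry, k_sd=config.sample_outlier_sd,
        concordance_threshold=config.duplicate_concordance,
    )
    keep_samples = ~sqc.table["excluded"].to_numpy()
    genotypes = genotypes[:, keep_samples]
    gq_kept = parsed["gq"][:, keep_samples]
    ad_kept = parsed["ad"][:, keep_samples]
    samples_kept = samples[keep_samples].reset_index(drop=True)
    case_mask = (samples_kept["status"] == "case").to_numpy()

    exonic_rows = np.flatnonzero((gene_of != ".").to_numpy())
    keys = vmeta["variant_key"].to_numpy()

    # stage 3a: single-variant track QC + scan -----------------------------
    sv_rows = np.concatenate([exonic_rows, common_rows])
    sv_qc = qc.single_variant_qc(
        genotypes[sv_rows], case_mask, vmeta.iloc[sv_rows]
    )
    sv_scan = single_variant.single_variant_scan(
        genotypes[sv_rows], case_mask, keys[sv_rows],
        qc_pass=sv_qc["variant_pass"].to_numpy(),
        alpha=config.alpha, maf_max=config.maf_max_single,
    )
    # the inflation diagnostic uses the mid-P column: the plain exact P's
    # discreteness would read as spurious deflation
    lam = (
        single_variant.genomic_inflation_trimmed(
            sv_scan["table"]["p_mid"].to_numpy(), config.trim
        )
        if len(sv_scan["table"]) >= 10
        else float("nan")
    )

    # stage 3b: gene-centric track QC + burden scan ------------------------
    gc_geno = qc.apply_allele_balance_filter(
        genotypes[exonic_rows], ad_kept[exonic_rows, :, 0],
        ad_kept[exonic_rows, :, 1],
    )
    gc_qc = qc.gene_centric_qc(gc_geno, case_mask, vmeta.iloc[exonic_rows])
    gc_pass = gc_qc["variant_pass"].to_numpy()
    class_sets = annotate.build_gene_class_sets(
        gc_geno[gc_pass], keys[exonic_rows][gc_pass],
        annotations[annotations["gene"] != "."],
        case_mask, maf_threshold=config.maf_threshold,
    )
    burden_df = burden.burden_scan(
        class_sets, case_mask, min_samples=config.min_samples,
        alpha=config.alpha, convention=config.pvalue_convention,
        mc_B=config.perm_B, seed=config.seed,
    )

    panel = None
    if config.csg_list:
        panel = burden.csg_panel_test(
            burden_df, read_gene_list(config.csg_list), alpha=config.alpha
        )

    # reports --------------------------------------------------------------
    sqc.table.to_csv(out / "sample_qc.tsv", sep="\t", index=False)
    sv_qc.assign(variant_key=keys[sv_rows]).to_csv(
        out / "variant_qc_single.tsv", sep="\t", index=False
    )
    gc_qc.assign(variant_key=keys[exonic_rows]).to_csv(
        out / "variant_qc_gene.tsv", sep="\t", index=False
    )
    sv_scan["table"].to_csv(out / "single_variant.tsv", sep="\t", index=False)
    burden_df.to_csv(out / "burden.tsv", sep="\t", index=False)
    if panel is not None:
        panel["results"].to_csv(out / "csg_panel.tsv", sep="\t", index=False)

    summary = {
        "n_samples_input": int(len(samples)),
        "n_samples_excluded": int((~keep_samples).sum()),
        "sample_exclusions": sqc.exclusion_summary(),
        "n_variants_input": int(len(vmeta)),
        "n_single_variant_tested": int(len(sv_scan["table"])),
        "single_variant_threshold": sv_scan["threshold"],
        "genomic_inflation_trimmed": lam,
        "n_burden_tests": int(len(burden_df)),
        "burden_threshold": (
            float(burden_df["threshold"].iloc[0]) if len(burden_df) else None
        ),
        "csg_panel_threshold": panel["threshold"] if panel else None,
        "thresholds": {
            k: v for k, v in asdict(config).items()
            if not isinstance(v, str) and v is not None
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return {
        "summary": summary,
        "sample_qc": sqc,
        "single_variant": sv_scan,
        "burden": burden_df,
        "csg_panel": panel,
        "lambda": lam,
    }
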