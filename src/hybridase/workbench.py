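"""Pipeline driver: configuration, format IO, logging and the run manifest.

Everything here is plumbing around the analysis modules: typed readers
and writers for the plain-text interchange formats (plot CSV, gene ×
sample TSV, minimal AD-style VCF, BED junction intervals, annotation
TSV), a YAML-backed :class:`PipelineConfig`, and :func:`run_pipeline`,
which executes simulate → trial → de → ase → enrich with a single seed
and writes a JSON manifest recording the resolved configuration, input
checksums and record counts at every filter step.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import ase_bias, enrichment, expression_class, field_trial, synthetic_data

__all__ = [
    "SchemaError",
    "PipelineConfig",
    "read_plot_table",
    "write_plot_table",
    "read_expression",
    "write_expression",
    "read_allele_depth",
    "write_vcf",
    "write_allele_depth_tsv",
    "read_junctions_bed",
    "write_junctions_bed",
    "run_pipeline",
]

logger = logging.getLogger("hybridase")

PLOT_REQUIRED = ["location", "block", "row", "column", "genotype", "entry_class"]
TRAIT_RANGES = {
    "lodging": (1.0, 5.0),
    "yield": (0.0, None),
    "height": (0.0, None),
    "seed_weight": (0.0, None),
}


class SchemaError(ValueError):
    """An input file does not match its documented schema."""


# ---------------------------------------------------------------------------
# Plot tables
# ---------------------------------------------------------------------------

def read_plot_table(path) -> pd.DataFrame:
    """Read and validate a plot-level agronomic CSV.

    Required columns: location, block, row, column, genotype,
    entry_class; any further numeric columns are traits. Rows violating
    documented trait ranges (lodging 1–5; yield, height, seed_weight
    non-negative) are reported together in one error.
    """
    df = pd.read_csv(path)
    missing = [c for c in PLOT_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"plot table is missing required column(s): {missing}")
    problems = []
    for col in df.columns:
        if col in PLOT_REQUIRED:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & vals.isna()
        for i in df.index[bad]:
            problems.append(f"row {i}: unparseable {col}={df.at[i, col]!r}")
        df[col] = vals
        if col in TRAIT_RANGES:
            lo, hi = TRAIT_RANGES[col]
            out = pd.Series(False, index=df.index)
            if lo is not None:
                out |= vals < lo
            if hi is not None:
                out |= vals > hi
            for i in df.index[out.fillna(False)]:
                problems.append(f"row {i}: {col}={vals[i]} outside [{lo}, {hi}]")
    if problems:
        raise SchemaError("plot table validation failed:\n" + "\n".join(problems))
    df["row"] = df["row"].astype(int) if df["row"].dtype != object else df["row"]
    df["column"] = df["column"].astype(int) if df["column"].dtype != object else df["column"]
    return df


def write_plot_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression(expr_path, meta_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene × sample TSV plus sample-metadata TSV."""
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    values.index.name = "gene"
    meta = pd.read_csv(meta_path, sep="\t")
    need = {"sample", "genotype", "location", "replicate"}
    if not need <= set(meta.columns):
        raise SchemaError(f"sample metadata needs columns {sorted(need)}")
    unknown = set(meta["sample"]) - set(values.columns)
    if unknown:
        raise SchemaError(f"metadata samples absent from matrix: {sorted(unknown)}")
    if (values.to_numpy() < 0).any():
        raise SchemaError("expression values must be non-negative")
    return values, meta


def write_expression(values: pd.DataFrame, meta: pd.DataFrame, expr_path, meta_path) -> None:
    values.to_csv(expr_path, sep="\t")
    meta.to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Allele depths: minimal VCF (AD per sample) and TSV dialects
# ---------------------------------------------------------------------------

def write_vcf(ad: pd.DataFrame, path) -> None:
    """Write the long allele-depth table as a minimal VCF with AD fields."""
    samples = sorted(ad["sample"].unique())
    wide = ad.pivot_table(
        index=ase_bias.SITE_KEY,
        columns="sample",
        values=["ref_count", "alt_count"],
        aggfunc="first",
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(ad["chrom"].unique()):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for (chrom, pos, ref, alt), row in wide.iterrows():
            fields = [str(chrom), str(int(pos)), ".", ref, alt, ".", "PASS", ".", "AD"]
            for s in samples:
                rc = row.get(("ref_count", s))
                ac = row.get(("alt_count", s))
                if pd.isna(rc) or pd.isna(ac):
                    fields.append(".")
                else:
                    fields.append(f"{int(rc)},{int(ac)}")
            fh.write("\t".join(fields) + "\n")


def write_allele_depth_tsv(ad: pd.DataFrame, path) -> None:
    cols = ase_bias.SITE_KEY + ["sample", "ref_count", "alt_count"]
    ad[cols].to_csv(path, sep="\t", index=False)


def read_allele_depth(path, samples: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Read allele depths from VCF or TSV (dialect by extension).

    Keeps biallelic SNVs only; multi-allelic and indel records are
    skipped and counted. Samples in the file must all appear in the
    sample sheet (hard error otherwise). Returns ``(ad, skipped)``.
    """
    path = Path(path)
    known = set(samples["sample"])
    skipped = {"multiallelic": 0, "indel": 0}
    if path.suffix.lower() == ".vcf":
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        unmatched = [s for s in vcf.samples if s not in known]
        if unmatched:
            raise SchemaError(f"VCF samples absent from sample sheet: {unmatched}")
        rows = []
        for v in vcf:
            if len(v.ALT) != 1:
                skipped["multiallelic"] += 1
                continue
            if len(v.REF) != 1 or len(v.ALT[0]) != 1:
                skipped["indel"] += 1
                continue
            adf = v.format("AD")
            for i, s in enumerate(vcf.samples):
                pair = adf[i]
                rc = int(pair[0]) if pair[0] >= 0 else 0
                ac = int(pair[1]) if len(pair) > 1 and pair[1] >= 0 else 0
                rows.append(
                    {
                        "chrom": v.CHROM,
                        "pos": v.POS,
                        "ref": v.REF,
                        "alt": v.ALT[0],
                        "sample": s,
                        "ref_count": rc,
                        "alt_count": ac,
                    }
                )
        ad = pd.DataFrame(
            rows, columns=ase_bias.SITE_KEY + ["sample", "ref_count", "alt_count"]
        )
    else:
        ad = pd.read_csv(path, sep="\t")
        need = set(ase_bias.SITE_KEY + ["sample", "ref_count", "alt_count"])
        if ad.empty and not need <= set(ad.columns):
            logger.warning("empty allele-depth file %s", path)
            return (
                pd.DataFrame(columns=ase_bias.SITE_KEY + ["sample", "ref_count", "alt_count"]),
                skipped,
            )
        if not need <= set(ad.columns):
            raise SchemaError(f"allele-depth TSV needs columns {sorted(need)}")
        snv = (ad["ref"].str.len() == 1) & (ad["alt"].str.len() == 1)
        multi = ad["alt"].str.contains(",")
        skipped["multiallelic"] = int(ad.loc[multi, ase_bias.SITE_KEY].drop_duplicates().shape[0])
        skipped["indel"] = int(
            ad.loc[~snv & ~multi, ase_bias.SITE_KEY].drop_duplicates().shape[0]
        )
        ad = ad[snv & ~multi]
        unmatched = sorted(set(ad["sample"]) - known)
        if unmatched:
            raise SchemaError(f"samples absent from sample sheet: {unmatched}")
    if ad.empty:
        logger.warning("no usable biallelic SNVs in %s", path)
    ad = ad.sort_values(ase_bias.SITE_KEY + ["sample"], ignore_index=True)
    ad["pos"] = ad["pos"].astype(int)
    return ad, skipped


def write_junctions_bed(introns: pd.DataFrame, path) -> None:
    """0-based half-open intron intervals -> 3-column BED."""
    introns[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def read_junctions_bed(path) -> pd.DataFrame:
    """3-column BED -> intron intervals (chrom, start, end)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    outdir: str = "hybridase_out"
    seed: int = 0
    # stage toggles
    simulate: bool = True
    trial: bool = True
    de: bool = True
    ase: bool = True
    enrich: bool = True
    # input paths (filled by the simulate stage when it runs)
    plots: str | None = None
    expression: str | None = None
    expression_meta: str | None = None
    vcf: str | None = None
    sample_sheet: str | None = None
    junctions: str | None = None
    annotation: str | None = None
    # thresholds
    alpha: float = 0.05
    min_log2_fold: float = 1.0
    pseudocount: float = 1.0
    min_expressed_level: float = 1.0
    bias_threshold: float = ase_bias.DEFAULT_BIAS_THRESHOLD
    min_depth: int = 8
    splice_margin: int = 2
    min_term_size: int = 5
    # synthetic truth overrides (passed to the generator dataclasses)
    trial_truth: dict = field(default_factory=dict)
    expression_truth: dict = field(default_factory=dict)
    ase_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.5 <= self.bias_threshold < 1:
            raise ValueError("bias_threshold must lie in [0.5, 1)")
        if self.min_depth < 0 or self.splice_margin < 0:
            raise ValueError("min_depth and splice_margin must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def validate_inputs(self) -> None:
        """Referenced input files must exist for enabled, non-simulated stages."""
        if self.simulate:
            return
        checks = {
            "plots": self.trial,
            "expression": self.de,
            "expression_meta": self.de,
            "vcf": self.ase,
            "sample_sheet": self.ase,
            "annotation": self.enrich,
        }
        for name, needed in checks.items():
            p = getattr(self, name)
            if needed and (p is None or not Path(p).exists()):
                raise SchemaError(f"config.{name} missing or not found: {p}")


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed, kept below 2**31."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the enabled stages in order and write the run manifest.

    Stage order: simulate → trial → de → ase → enrich. All randomness
    derives from ``config.seed`` through per-stage substreams. Analytic
    outputs are plain TSV/CSV; the manifest (JSON) records the resolved
    config, input checksums and per-stage record counts, including the
    telescoping in/removed/out counts of every ASE filter step. A stage
    failure is recorded and aborts downstream stages.
    """
    config.validate_inputs()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": config.to_dict(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "inputs": {},
    }
    logger.info("run: outdir=%s seed=%d", out, config.seed)

    def finish(status: str) -> dict[str, Any]:
        manifest["status"] = status
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        return manifest

    try:
        if config.simulate:
            _stage_simulate(config, out, manifest)
        for name in ("plots", "expression", "expression_meta", "vcf", "sample_sheet", "junctions", "annotation"):
            p = getattr(config, name)
            if p and Path(p).exists():
                manifest["inputs"][name] = _sha256(p)
        if config.trial:
            _stage_trial(config, out, manifest)
        if config.de:
            _stage_de(config, out, manifest)
        if config.ase:
            _stage_ase(config, out, manifest)
        if config.enrich:
            _stage_enrich(config, out, manifest)
    except Exception as err:  # manifest records partial completion
        logger.exception("stage failure")
        manifest["error"] = f"{type(err).__name__}: {err}"
        return finish("failed")
    return finish("ok")


def _write_tsv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", index=kw.pop("index", False), float_format="%.10g", **kw)


def _stage_simulate(config: PipelineConfig, out: Path, manifest: dict) -> None:
    sim = out / "sim"
    sim.mkdir(exist_ok=True)
    rec: dict[str, Any] = {}

    t_truth = synthetic_data.TrialTruth(
        seed=_stage_seed(config.seed, "trial"), **config.trial_truth
    )
    plots = synthetic_data.generate_trial(t_truth)
    write_plot_table(plots, sim / "plots.csv")
    (sim / "trial_truth.json").write_text(synthetic_data.truth_to_json(t_truth))
    config.plots = str(sim / "plots.csv")
    rec["plots"] = len(plots)

    e_truth = synthetic_data.ExpressionTruth(
        seed=_stage_seed(config.seed, "expression"), **config.expression_truth
    )
    values, meta, gene_truth = synthetic_data.generate_expression(e_truth)
    write_expression(values, meta, sim / "expression.tsv", sim / "expression_meta.tsv")
    _write_tsv(gene_truth.reset_index(), sim / "expression_truth.tsv")
    config.expression = str(sim / "expression.tsv")
    config.expression_meta = str(sim / "expression_meta.tsv")
    rec["genes"] = len(values)
    rec["samples"] = len(meta)

    a_truth = synthetic_data.AseTruth(seed=_stage_seed(config.seed, "ase"), **config.ase_truth)
    ad, samples, snp_truth, junctions = synthetic_data.generate_allele_counts(a_truth)
    write_vcf(ad, sim / "sites.vcf")
    _write_tsv(samples, sim / "sample_sheet.tsv")
    write_junctions_bed(junctions, sim / "junctions.bed")
    _write_tsv(snp_truth, sim / "ase_truth.tsv")
    config.vcf = str(sim / "sites.vcf")
    config.sample_sheet = str(sim / "sample_sheet.tsv")
    config.junctions = str(sim / "junctions.bed")
    rec["snps"] = len(snp_truth)

    annot = synthetic_data.generate_annotation(
        list(values.index), seed=_stage_seed(config.seed, "annotation")
    )
    _write_tsv(annot, sim / "annotation.tsv")
    # annotation TSV is headerless on read; rewrite without header
    annot.to_csv(sim / "annotation.tsv", sep="\t", header=False, index=False)
    config.annotation = str(sim / "annotation.tsv")
    rec["annotations"] = len(annot)

    manifest["stages"]["simulate"] = rec


def _stage_trial(config: PipelineConfig, out: Path, manifest: dict) -> None:
    plots = read_plot_table(config.plots)
    report = field_trial.heterosis_report(plots)
    _write_tsv(report.table, out / "trial_contrasts.tsv")
    (out / "trial_report.txt").write_text(report.formatted() + "\n")
    manifest["stages"]["trial"] = {
        "plots": len(plots),
        "outliers_dropped": 0 if report.dropped_outliers is None else len(report.dropped_outliers),
        "contrasts": len(report.table),
        "inbreeding_depression": report.inbreeding_depression,
        "gaps": report.gaps,
    }


def _stage_de(config: PipelineConfig, out: Path, manifest: dict) -> None:
    values, meta = read_expression(config.expression, config.expression_meta)
    rec: dict[str, Any] = {"genes": len(values)}
    counts_rows = []
    cats_frames = []
    calls_by = {}
    for location in sorted(meta["location"].unique()):
        calls_p1 = expression_class.differential_calls_table(
            values, meta, "F1_vs_P1", location, config.alpha, config.min_log2_fold, config.pseudocount
        )
        calls_p2 = expression_class.differential_calls_table(
            values, meta, "F1_vs_P2", location, config.alpha, config.min_log2_fold, config.pseudocount
        )
        calls_by[location] = (calls_p1, calls_p2)
        cats = expression_class.classify_table(calls_p1, calls_p2)
        cats_frames.append(cats.reset_index())
        counts = expression_class.category_counts(calls_p1, calls_p2)
        counts_rows.append(counts.rename(location))
    _write_tsv(pd.concat(cats_frames, ignore_index=True), out / "de_categories.tsv")
    counts_tab = pd.DataFrame(counts_rows)
    counts_tab.index.name = "location"
    _write_tsv(counts_tab.reset_index(), out / "de_counts.tsv")
    locs = sorted(calls_by)
    if len(locs) == 2:
        conc_rows = []
        for ci, comp in enumerate(("F1_vs_P1", "F1_vs_P2")):
            shared, agree, r2 = expression_class.cross_location_concordance(
                calls_by[locs[0]][ci], calls_by[locs[1]][ci]
            )
            conc_rows.append(
                {"comparison": comp, "shared_de": len(shared), "direction_agreement": agree, "r2": r2}
            )
        _write_tsv(pd.DataFrame(conc_rows), out / "de_concordance.tsv")
        rec["concordance"] = conc_rows
    manifest["stages"]["de"] = rec


def _stage_ase(config: PipelineConfig, out: Path, manifest: dict) -> None:
    samples = pd.read_csv(config.sample_sheet, sep="\t")
    ad, skipped = read_allele_depth(config.vcf, samples)
    sites = ad[ase_bias.SITE_KEY].drop_duplicates(ignore_index=True)
    rec: dict[str, Any] = {"skipped_records": skipped, "sites_in": len(sites)}

    if config.junctions and Path(config.junctions).exists():
        junctions = read_junctions_bed(config.junctions)
    else:
        junctions = pd.DataFrame(columns=["chrom", "start", "end"])
    kept, masked = ase_bias.mask_splice_proximal(sites, junctions, config.splice_margin)
    rec["splice_masked"] = len(masked)
    rec["sites_after_mask"] = len(kept)

    ad_kept = ad.merge(kept, on=ase_bias.SITE_KEY)
    snps = ase_bias.call_parent_specific_snps(ad_kept, samples, min_depth=config.min_depth)
    rec["parent_specific"] = len(snps)
    rec["filtered_non_specific"] = len(kept) - len(snps)

    calls = ase_bias.bias_call_table(
        ad_kept, samples, snps, min_depth=config.min_depth, threshold=config.bias_threshold
    )
    rec["calls"] = len(calls)
    rec["evaluable"] = int(calls["evaluable"].sum())
    rec["biased"] = int(calls["biased"].sum())
    _write_tsv(calls, out / "ase_calls.tsv")

    locs = sorted(calls["location"].unique())
    if len(locs) == 2:
        a = calls[calls["location"] == locs[0]]
        b = calls[calls["location"] == locs[1]]
        r2_all, r2_biased, switched = ase_bias.cross_location_bias_concordance(a, b)
        rec["concordance"] = {"r2_all": r2_all, "r2_biased": r2_biased, "switched": switched}

    hist = ase_bias.bias_histogram(calls)
    _write_tsv(hist, out / "ase_histogram.tsv")

    biased_sites = calls[calls["biased"]].drop_duplicates(subset=["chrom", "pos", "ref", "alt"])
    unbiased_sites = calls[calls["evaluable"] & ~calls["biased"]].drop_duplicates(
        subset=["chrom", "pos", "ref", "alt"]
    )
    unbiased_sites = unbiased_sites[
        ~unbiased_sites.set_index(["chrom", "pos"]).index.isin(
            biased_sites.set_index(["chrom", "pos"]).index
        )
    ]
    table, p, degenerate = ase_bias.substitution_class_test(biased_sites, unbiased_sites)
    rec["substitution_class"] = {
        "table": table.tolist(),
        "fisher_p": p,
        "degenerate": degenerate,
    }
    manifest["stages"]["ase"] = rec


def _stage_enrich(config: PipelineConfig, out: Path, manifest: dict) -> None:
    values, meta = read_expression(config.expression, config.expression_meta)
    annot = enrichment.read_annotation(config.annotation)
    reports = []
    rec: dict[str, Any] = {}
    for location in sorted(meta["location"].unique()):
        background = expression_class.detect_expressed(
            values, meta, config.min_expressed_level, location
        )
        for comp, parent in (("F1_vs_P1", "P1"), ("F1_vs_P2", "P2")):
            calls = expression_class.differential_calls_table(
                values, meta, comp, location, config.alpha, config.min_log2_fold, config.pseudocount
            )
            for direction, sign in (("gt", "up"), ("lt", "down")):
                study = set(calls.index[calls["direction"] == sign])
                res = enrichment.sea(study, background, annot, config.min_term_size)
                label = f"{location}:F1_{direction}_{parent}"
                reports.append(enrichment.enrichment_report(res, config.alpha, label))
                rec[label] = {"study": len(study), "terms_tested": len(res)}
    _write_tsv(pd.concat(reports, ignore_index=True), out / "enrichment.tsv")
    manifest["stages"]["enrich"] = rec
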