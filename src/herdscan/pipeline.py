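"""End-to-end pipeline: QC → structure summaries → sweep scan → twin screen.

One :class:`RunConfig` (YAML-loadable) drives the whole analysis and every
stage output is written under the output directory with a manifest.  Two QC
regimes feed two analysis tracks: the structure track (kinship, PCA, NJ,
ROH, LD) uses the full filter set including the MAF floor; the screen track
(windowed Fst/θπ and the rare-allele screen) omits the MAF floor, since the
screen explicitly targets alleles below 5% frequency which a pooled MAF
filter would remove by construction.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genio, kinship, ld, qc, roh, sweepscan, twinscreen
from .errors import CohortError, ConfigError, PipelineError
from .roh import DEFAULT_GENOME_BP, ROHParams


@dataclass
class RunConfig:
    """All pipeline inputs and parameters (defaults are the study's values)."""

    vcf: str = ""
    sample_sheet: str = ""
    gene_model: str = ""
    out_dir: str = "herdscan_out"
    # qc
    maf_min: float = 0.05
    site_missing_max: float = 0.20
    second_site_missing_max: float = 0.05
    hwe_p_min: float = 1e-6
    sample_missing_max: float = 0.10
    # roh
    roh_params: ROHParams = field(default_factory=ROHParams)
    genome_length_bp: int = DEFAULT_GENOME_BP
    # ld
    ld_max_dist_bp: int = 500_000
    ld_bin_width_bp: int = 1_000
    ld_populations: list[str] | None = None
    # scan
    window_bp: int = 50_000
    step_bp: int = 20_000
    quantile: float = 0.95
    combine: str = "union"
    # screen
    rare_threshold: float = 0.05
    mac: int = 10
    max_missing: float = 0.1
    near_bp: int = 100_000
    flank_bp: int = 1_000
    # misc
    pca_components: int = 10
    log_level: str = "INFO"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "roh_params" in raw and isinstance(raw["roh_params"], dict):
            raw["roh_params"] = ROHParams(**raw["roh_params"])
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns (and writes) the run report."""
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict[str, str] = {}
    report: dict = {"stages": [], "thresholds": {}, "counts": {}}

    def out(name: str) -> str:
        path = os.path.join(config.out_dir, name)
        manifest[name] = path
        return path

    def stage(name: str):
        report["stages"].append(name)

    try:
        stage("load")
        table = genio.read_vcf(config.vcf, config.sample_sheet)
        model = genio.read_gene_model(config.gene_model)
        report["counts"]["input_sites"] = table.n_variants
        report["counts"]["input_samples"] = table.n_samples
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise PipelineError("load", str(exc)) from exc

    try:
        stage("qc")
        criteria = qc.SiteFilterCriteria(
            maf_min=config.maf_min,
            site_missing_max=config.site_missing_max,
            hwe_p_min=config.hwe_p_min,
        )
        table_struct, reports = qc.apply_qc(
            table, criteria, config.sample_missing_max, config.second_site_missing_max
        )
        screen_criteria = qc.SiteFilterCriteria(
            maf_min=0.0,
            site_missing_max=config.site_missing_max,
            hwe_p_min=config.hwe_p_min,
        )
        table_screen, _ = qc.apply_qc(
            table, screen_criteria, config.sample_missing_max, config.second_site_missing_max
        )
        reports[0].to_tsv(out("qc_sites_pass1.tsv"))
        reports[-1].to_tsv(out("qc_sites_pass2.tsv"))
        report["counts"]["qc_structure_sites"] = table_struct.n_variants
        report["counts"]["qc_screen_sites"] = table_screen.n_variants
        report["counts"]["qc_samples"] = table_struct.n_samples
    except Exception as exc:
        raise PipelineError("qc", str(exc)) from exc

    try:
        stage("kinship")
        dist = kinship.ibs_distance_matrix(table_struct)
        dist.to_tsv(out("ibs_distance.tsv"))
        G = kinship.grm(table_struct)
        G.to_tsv(out("grm.tsv"))
        coords = kinship.pca(table_struct, k=config.pca_components)
        coords.to_tsv(out("pca.tsv"))
        with open(out("nj_tree.nwk"), "w") as fh:
            fh.write(kinship.nj_tree(dist) + "\n")
        report["counts"]["ibs_pairs"] = dist.n_pairs
    except Exception as exc:
        raise PipelineError("kinship", str(exc)) from exc

    try:
        stage("roh")
        segments = roh.detect_roh(table_struct, config.roh_params)
        roh.segments_to_frame(segments).to_csv(out("roh_segments.tsv"), sep="\t", index=False)
        records = roh.froh(segments, config.genome_length_bp, table_struct.sample_ids)
        roh.froh_to_frame(records).to_csv(out("froh.tsv"), sep="\t", index=False)
        report["counts"]["roh_segments"] = len(segments)
        report["counts"]["froh_mean"] = float(np.mean([r.f_roh for r in records]))
    except Exception as exc:
        raise PipelineError("roh", str(exc)) from exc

    try:
        stage("ld")
        curves = ld.population_decay_curves(
            table_struct,
            config.ld_max_dist_bp,
            config.ld_bin_width_bp,
            config.ld_populations,
        )
        for pop, curve in curves.items():
            curve.to_tsv(out(f"ld_decay_{pop}.tsv"))
        report["counts"]["ld_populations"] = len(curves)
    except Exception as exc:
        raise PipelineError("ld", str(exc)) from exc

    try:
        stage("sweepscan")
        twin = table_screen.sample_index(cohort="twin")
        ctrl = table_screen.sample_index(cohort="control")
        if len(twin) == 0 or len(ctrl) == 0:
            raise CohortError("twin or control cohort empty after QC")
        spec = sweepscan.WindowSpec(size_bp=config.window_bp, step_bp=config.step_bp)
        stats = sweepscan.scan_windows(table_screen, twin, ctrl, spec)
        stats.to_csv(out("window_stats.tsv"), sep="\t", index=False)
        fst_thr, fst_regions = sweepscan.select_top_windows(stats, "fst", config.quantile)
        pi_thr, pi_regions = sweepscan.select_top_windows(stats, "log2_ratio", config.quantile)
        fst_regions.to_bed(out("regions_fst.bed"))
        pi_regions.to_bed(out("regions_pi_ratio.bed"))
        combined = sweepscan.combine_regions(fst_regions, pi_regions, config.combine)
        combined.to_bed(out("regions_combined.bed"))
        report["thresholds"]["fst_top_quantile"] = fst_thr
        report["thresholds"]["log2_pi_ratio_top_quantile"] = pi_thr
        report["counts"]["windows"] = len(stats)
        report["counts"]["windows_defined_fst"] = int(stats["fst"].notna().sum())
        report["counts"]["top_windows_fst"] = int(
            (stats["fst"] > fst_thr).sum()
        )
        report["counts"]["top_windows_pi_ratio"] = int(
            (stats["log2_ratio"] > pi_thr).sum()
        )
        report["counts"]["regions_fst"] = len(fst_regions)
        report["counts"]["regions_pi_ratio"] = len(pi_regions)
        report["counts"]["regions_combined"] = len(combined)
        report["counts"]["regions_combined_bp"] = combined.total_bp()
    except Exception as exc:
        raise PipelineError("sweepscan", str(exc)) from exc

    try:
        stage("twinscreen")
        pops = sorted({s.population for s in table_screen.samples})
        control_freqs = {}
        for pop in pops:
            idx = [
                i
                for i, s in enumerate(table_screen.samples)
                if s.population == pop and s.cohort == "none"
            ]
            if idx:
                control_freqs[pop] = twinscreen.allele_freq(table_screen, np.array(idx))[
                    "freq"
                ].to_numpy()
        rare_mask = twinscreen.rare_in_all_controls(control_freqs, config.rare_threshold)
        candidates = twinscreen.screen_candidates(
            table_screen, twin, combined, rare_mask, config.mac, config.max_missing
        )
        candidates.to_csv(out("candidate_snps.tsv"), sep="\t", index=False)
        snp_table, gene_table = twinscreen.annotate_snps(
            candidates, model, config.near_bp, config.flank_bp
        )
        snp_table.to_csv(out("candidate_snp_annotation.tsv"), sep="\t", index=False)
        gene_table.to_csv(out("candidate_genes.tsv"), sep="\t", index=False)
        report["counts"]["region_snps"] = int(
            sum(
                combined.contains(c, table_screen.positions[table_screen.chroms == c]).sum()
                for c in table_screen.chromosomes()
            )
        )
        report["counts"]["rare_in_all_controls"] = int(rare_mask.sum())
        report["counts"]["candidate_snps"] = len(candidates)
        report["counts"]["candidate_snps_annotated"] = int(snp_table["gene"].notna().sum())
        report["counts"]["candidate_genes"] = len(gene_table)
    except Exception as exc:
        raise PipelineError("twinscreen", str(exc)) from exc

    report["manifest"] = sorted(manifest)
    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
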