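"""Shared fixtures: small genotype-table builders and the reference synthetic cohort."""

from __future__ import annotations

import numpy as np
import pytest

from herdscan.genio import GenotypeTable, SampleInfo, Variant
from herdscan.pipeline import RunConfig, run_pipeline
from herdscan.simulate import (
    PopulationSpec,
    RarePlantSpec,
    ROHPlantSpec,
    SimConfig,
    SweepSpec,
    simulate_cohort,
    write_fixture,
)


def make_table(
    dosage,
    positions=None,
    chrom="1",
    populations=None,
    cohorts=None,
) -> GenotypeTable:
    """Build a GenotypeTable from a dense dosage array (samples × variants)."""
    dosage = np.asarray(dosage)
    n, m = dosage.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    chroms = [chrom] * m if isinstance(chrom, str) else list(chrom)
    variants = [
        Variant(chroms[j], int(positions[j]), "A", "C") for j in range(m)
    ]
    populations = populations or ["pop"] * n
    cohorts = cohorts or ["none"] * n
    samples = [
        SampleInfo(f"s{i:03d}", populations[i], cohorts[i], 0) for i in range(n)
    ]
    return GenotypeTable(variants, samples, dosage)


def random_table(rng, n=20, m=50, missing_rate=0.05, chrom="1") -> GenotypeTable:
    p = rng.uniform(0.1, 0.9, m)
    dos = (rng.random((n, m)) < p).astype(np.int16) + (rng.random((n, m)) < p).astype(
        np.int16
    )
    dos[rng.random((n, m)) < missing_rate] = -1
    positions = np.sort(rng.choice(10 * m, size=m, replace=False)) + 1
    return make_table(dos, positions=positions, chrom=chrom)


# ---------------------------------------------------------------------------
# reference synthetic cohort (the analysis's study conditions) + pipeline run
# ---------------------------------------------------------------------------

COHORT_SEED = 11


@pytest.fixture(scope="session")
def cohort():
    """Full-scale reference cohort: table, gene model, planted truth."""
    config = SimConfig(seed=COHORT_SEED)
    table, model, truth = simulate_cohort(config)
    return {"config": config, "table": table, "model": model, "truth": truth}


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory, cohort):
    """Fixture files + a full pipeline run over the reference cohort."""
    fix_dir = tmp_path_factory.mktemp("cohort_fixture")
    out_dir = tmp_path_factory.mktemp("cohort_out")
    paths = write_fixture(fix_dir, cohort["config"])
    rc = RunConfig(
        vcf=paths["vcf"],
        sample_sheet=paths["sample_sheet"],
        gene_model=paths["gene_model"],
        out_dir=str(out_dir),
    )
    report = run_pipeline(rc)
    return {"paths": paths, "out_dir": str(out_dir), "report": report, **cohort}


def mini_config(seed=7, **overrides) -> SimConfig:
    """A quick-to-run scaled-down cohort used by pipeline-level tests."""
    defaults = dict(
        seed=seed,
        n_chrom=2,
        chrom_length_bp=1_500_000,
        n_snps_per_chrom=1_500,
        populations=[
            PopulationSpec("Xinjiang", 20, 60),
            PopulationSpec("Gansu", 12, 40),
            PopulationSpec("US", 10, 20),
        ],
        n_twin=30,
        n_control=12,
        sweeps=[SweepSpec("1", 400_001, 500_000), SweepSpec("2", 900_001, 1_000_000)],
        rare_plants=[RarePlantSpec(twin_count=tc) for tc in (10, 10, 11, 10)],
        roh_plants=[
            ROHPlantSpec("1", 700_001, 1_400_000),
            ROHPlantSpec("2", 100_001, 800_000),
        ],
        missing_rate=0.02,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def mini_run(tmp_path_factory):
    """Scaled-down fixture + pipeline run for orchestration tests."""
    config = mini_config()
    fix_dir = tmp_path_factory.mktemp("mini_fixture")
    out_dir = tmp_path_factory.mktemp("mini_out")
    paths = write_fixture(fix_dir, config)
    rc = RunConfig(
        vcf=paths["vcf"],
        sample_sheet=paths["sample_sheet"],
        gene_model=paths["gene_model"],
        out_dir=str(out_dir),
    )
    report = run_pipeline(rc)
    table, model, truth = simulate_cohort(config)
    return {
        "config": config,
        "paths": paths,
        "out_dir": str(out_dir),
        "report": report,
        "run_config": rc,
        "table": table,
        "truth": truth,
    }
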