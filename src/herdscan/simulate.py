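"""Synthetic structured cattle cohort generator with planted ground truth.

The generator emulates the statistical structure the downstream analyses
assume, without modeling real cattle demography:

* **Population structure** — each population's allele frequencies are a
  mixture over K ancestry components (default K = 5) with Balding–Nichols
  drift, giving PCA/NJ-separable populations and a realistic background Fst.
* **Linkage disequilibrium** — individuals are mosaics of a finite founder
  haplotype pool with geometrically distributed segment lengths; fewer
  founders means a smaller effective population and uniformly higher LD.
* **Selective sweeps** — inside configured intervals, a fraction of
  twin-cohort haplotypes is replaced by a single sweep haplotype (reducing
  diversity) and remaining twin alleles are pulled toward it (shifting
  frequencies), so planted windows carry elevated Fst and θπ-ratio.
* **Rare twin-enriched variants** — explicit genotype edits with exact
  allele counts: at least ``twin_count`` ALT alleles in the twin cohort but
  a frequency below ``max_control_freq`` in every control population, so
  screen recall has a deterministic denominator.
* **ROH tracts** — selected samples have one haplotype copied over the
  other inside a planted interval, creating long homozygous runs.
* **Missingness** — uniform random genotype dropout (planted rare sites are
  exempt so their counts stay exact).

Background variants are drawn common (per-population frequency clipped to
[0.10, 0.90]), emulating a post-QC common-SNP panel; the screen's rare
alleles exist only where planted.  Everything is deterministic under the
configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, InfeasibleConfigError, InvariantError
from .genio import (
    Gene,
    GeneModel,
    GenotypeTable,
    SampleInfo,
    Variant,
    write_gene_model_bed,
    write_sample_sheet,
    write_vcf,
)


@dataclass(frozen=True)
class PopulationSpec:
    """One control population: label, cohort size, founder-pool size."""

    label: str
    n_samples: int
    founders: int


@dataclass(frozen=True)
class SweepSpec:
    """A planted selective sweep acting on the twin cohort."""

    chrom: str
    start: int
    end: int
    fst_shift: float = 0.3
    diversity_reduction: float = 0.8


@dataclass(frozen=True)
class RarePlantSpec:
    """A planted rare twin-enriched variant.

    ``pos=None`` lets the generator pick a SNP inside a planted sweep
    (round-robin over sweeps, central 60% of the interval).
    """

    chrom: str | None = None
    pos: int | None = None
    twin_count: int = 10
    max_control_freq: float = 0.04


@dataclass(frozen=True)
class ROHPlantSpec:
    """A planted homozygous tract; ``sample=None`` → auto-assigned."""

    chrom: str
    start: int
    end: int
    sample: str | None = None


def _default_populations() -> list[PopulationSpec]:
    # Sizes follow the documented control-population composition where stated
    # (Gansu 26, Inner Mongolia 18, US 17, Canada 31); the Xinjiang control
    # population and the down-sampled Huaxi population are desk-scale choices.
    # Founder-pool sizes encode the LD-decay ordering: Xinjiang fastest decay
    # (largest effective size), US slowest.
    return [
        PopulationSpec("Xinjiang", 40, 160),
        PopulationSpec("Gansu", 26, 100),
        PopulationSpec("InnerMongolia", 18, 80),
        PopulationSpec("US", 17, 30),
        PopulationSpec("Canada", 31, 50),
        PopulationSpec("Huaxi", 30, 60),
    ]


def _default_sweeps() -> list[SweepSpec]:
    return [
        SweepSpec("1", 1_000_001, 1_100_000),
        SweepSpec("1", 3_200_001, 3_300_000),
        SweepSpec("2", 2_400_001, 2_500_000),
    ]


def _default_rare_plants() -> list[RarePlantSpec]:
    return [RarePlantSpec(twin_count=tc) for tc in (10, 10, 10, 11, 10, 12, 10, 10, 14, 10, 11, 10)]


def _default_roh_plants() -> list[ROHPlantSpec]:
    return [
        ROHPlantSpec("1", 1_800_001, 3_000_000),
        ROHPlantSpec("1", 3_500_001, 4_600_000),
        ROHPlantSpec("2", 200_001, 1_400_000),
        ROHPlantSpec("2", 3_000_001, 4_200_000),
        ROHPlantSpec("2", 1_500_001, 2_600_000),
    ]


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic cohort.

    Defaults reproduce the analysis's reference conditions: a 2-chromosome
    5-Mb genome at 1 SNP/kb, six control populations, a 57-sample twin
    cohort and 21-sample single-calving control cohort drawn from the
    Xinjiang founder pool, K = 5 ancestry components, three planted sweeps
    and twelve planted rare twin-enriched SNPs.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length_bp: int = 5_000_000
    n_snps_per_chrom: int = 5_000
    populations: list[PopulationSpec] = field(default_factory=_default_populations)
    ancestry_components: int = 5
    component_divergence: float = 0.15  # Balding–Nichols F between components
    population_drift: float = 0.03  # Balding–Nichols F per population
    segment_length_bp: float = 1_500_000.0  # mean founder-mosaic segment
    twin_source: str = "Xinjiang"
    n_twin: int = 57
    n_control: int = 21
    sweeps: list[SweepSpec] = field(default_factory=_default_sweeps)
    rare_plants: list[RarePlantSpec] = field(default_factory=_default_rare_plants)
    roh_plants: list[ROHPlantSpec] = field(default_factory=_default_roh_plants)
    missing_rate: float = 0.02
    rare_threshold: float = 0.05  # screen threshold the plants must beat
    freq_floor: float = 0.10
    gene_length_bp: int = 20_000
    gene_spacing_bp: int = 50_000

    def __post_init__(self):
        if self.n_chrom <= 0 or self.n_snps_per_chrom <= 0 or self.chrom_length_bp <= 0:
            raise ConfigError("genome dimensions must be positive")
        if self.n_twin <= 0 or self.n_control <= 0 or not self.populations:
            raise ConfigError("cohort sizes must be positive")
        if not any(p.label == self.twin_source for p in self.populations):
            raise ConfigError(f"twin_source {self.twin_source!r} not among populations")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")
        chroms = {str(i + 1) for i in range(self.n_chrom)}
        for sw in self.sweeps:
            if sw.chrom not in chroms or not 1 <= sw.start <= sw.end <= self.chrom_length_bp:
                raise ConfigError(f"sweep {sw} outside chromosome bounds")
        for rp in self.rare_plants:
            if rp.twin_count > 2 * self.n_twin:
                raise ConfigError(f"rare plant twin_count {rp.twin_count} exceeds 2x cohort")
            if rp.max_control_freq >= self.rare_threshold:
                raise InfeasibleConfigError(
                    "rare plant max_control_freq must be below the screen threshold"
                )
        for rh in self.roh_plants:
            if rh.chrom not in chroms or not 1 <= rh.start <= rh.end <= self.chrom_length_bp:
                raise ConfigError(f"ROH plant {rh} outside chromosome bounds")


@dataclass
class SimTruth:
    """Ground truth of all planted features, recomputable from the table."""

    sweeps: list[dict]
    rare_variants: list[dict]
    roh: list[dict]
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _mosaic_haplotypes(
    rng: np.random.Generator,
    founders: np.ndarray,
    n_haps: int,
    pos: np.ndarray,
    seg_len: float,
) -> np.ndarray:
    """Copy founder haplotypes in geometric-length segments."""
    F, m = founders.shape
    p_switch = 1.0 - np.exp(-np.diff(pos) / seg_len)
    switch = np.empty((n_haps, m), dtype=bool)
    switch[:, 0] = True
    switch[:, 1:] = rng.random((n_haps, m - 1)) < p_switch
    draws = rng.integers(0, F, size=(n_haps, m))
    last_switch = np.maximum.accumulate(np.where(switch, np.arange(m), -1), axis=1)
    founder_id = draws[np.arange(n_haps)[:, None], last_switch]
    return founders[founder_id, np.arange(m)]


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    if F <= 0:
        return p.copy()
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    return rng.beta(np.maximum(a, 1e-6), np.maximum(b, 1e-6))


def _admixture_weights(n_pops: int, K: int) -> np.ndarray:
    """Deterministic admixture matrix: each population dominated by one component."""
    W = np.full((n_pops, K), 0.3 / max(K - 1, 1))
    for i in range(n_pops):
        W[i, i % K] = 0.7
    if K == 1:
        W[:] = 1.0
    return W / W.sum(axis=1, keepdims=True)


def simulate_cohort(config: SimConfig) -> tuple[GenotypeTable, GeneModel, SimTruth]:
    """Generate the cohort, its gene model, and the planted-truth record."""
    rng = np.random.default_rng(config.seed)
    chroms = [str(i + 1) for i in range(config.n_chrom)]
    m_per = config.n_snps_per_chrom
    L = config.chrom_length_bp

    # -- variant coordinates ------------------------------------------------
    pos_by_chrom: dict[str, np.ndarray] = {}
    for c in chroms:
        pos = np.sort(rng.choice(L, size=m_per, replace=False)) + 1
        pos_by_chrom[c] = pos.astype(np.int64)

    # -- allele-frequency architecture -------------------------------------
    K = config.ancestry_components
    n_pops = len(config.populations)
    W = _admixture_weights(n_pops, K)
    pop_freq: dict[str, dict[str, np.ndarray]] = {c: {} for c in chroms}
    for c in chroms:
        p0 = rng.uniform(0.15, 0.85, size=m_per)
        comp = np.vstack(
            [_balding_nichols(rng, p0, config.component_divergence) for _ in range(K)]
        )
        mix = W @ comp  # (n_pops, m)
        for i, spec in enumerate(config.populations):
            pf = _balding_nichols(rng, mix[i], config.population_drift)
            pop_freq[c][spec.label] = np.clip(pf, config.freq_floor, 1 - config.freq_floor)

    # -- founder pools and haplotypes ---------------------------------------
    # Cohort layout: control populations in order, then twin cohort, then
    # single-calving control cohort (both from the twin-source founder pool).
    founder_pool: dict[str, dict[str, np.ndarray]] = {c: {} for c in chroms}
    hap_blocks: dict[str, list[np.ndarray]] = {c: [] for c in chroms}
    samples: list[SampleInfo] = []
    for spec in config.populations:
        for c in chroms:
            founders = rng.random((spec.founders, m_per)) < pop_freq[c][spec.label]
            founder_pool[c][spec.label] = founders
            haps = _mosaic_haplotypes(
                rng, founders, 2 * spec.n_samples, pos_by_chrom[c], config.segment_length_bp
            )
            hap_blocks[c].append(haps)
        for i in range(spec.n_samples):
            samples.append(
                SampleInfo(f"{spec.label}_{i:03d}", spec.label, "none", int(rng.integers(0, 8)))
            )
    twin_haps: dict[str, np.ndarray] = {}
    for c in chroms:
        twin_haps[c] = _mosaic_haplotypes(
            rng,
            founder_pool[c][config.twin_source],
            2 * config.n_twin,
            pos_by_chrom[c],
            config.segment_length_bp,
        )
    for i in range(config.n_twin):
        samples.append(
            SampleInfo(f"TWIN_{i:03d}", config.twin_source, "twin", int(rng.integers(1, 8)))
        )
    ctrl_haps: dict[str, np.ndarray] = {}
    for c in chroms:
        ctrl_haps[c] = _mosaic_haplotypes(
            rng,
            founder_pool[c][config.twin_source],
            2 * config.n_control,
            pos_by_chrom[c],
            config.segment_length_bp,
        )
    for i in range(config.n_control):
        samples.append(
            SampleInfo(f"CTRL_{i:03d}", config.twin_source, "control", int(rng.integers(4, 9)))
        )

    # -- planted sweeps (twin haplotypes only) ------------------------------
    truth_sweeps = []
    for sw in config.sweeps:
        pos = pos_by_chrom[sw.chrom]
        sm = (pos >= sw.start) & (pos <= sw.end)
        sweep_hap = founder_pool[sw.chrom][config.twin_source][0, sm]
        H = twin_haps[sw.chrom]
        replaced = rng.random(H.shape[0]) < sw.diversity_reduction
        H[np.ix_(replaced, np.flatnonzero(sm))] = sweep_hap
        others = np.flatnonzero(~replaced)
        if len(others) and sw.fst_shift > 0:
            pull = rng.random((len(others), int(sm.sum()))) < sw.fst_shift
            block = H[np.ix_(others, np.flatnonzero(sm))]
            block[pull] = np.broadcast_to(sweep_hap, block.shape)[pull]
            H[np.ix_(others, np.flatnonzero(sm))] = block
        truth_sweeps.append(dataclasses.asdict(sw))

    # -- assemble dosage -----------------------------------------------------
    variants: list[Variant] = []
    dose_cols: list[np.ndarray] = []
    col_of: dict[tuple[str, int], int] = {}
    ref_alt = np.array([["A", "G"], ["C", "T"], ["G", "A"], ["T", "C"]])
    offset = 0
    for ci, c in enumerate(chroms):
        pop_h = np.vstack(hap_blocks[c]) if hap_blocks[c] else np.zeros((0, m_per), bool)
        all_h = np.vstack([pop_h, twin_haps[c], ctrl_haps[c]])
        dos = (all_h[0::2].astype(np.int16) + all_h[1::2].astype(np.int16))
        dose_cols.append(dos)
        alleles = ref_alt[rng.integers(0, 4, size=m_per)]
        for j, p in enumerate(pos_by_chrom[c]):
            variants.append(Variant(c, int(p), alleles[j][0], alleles[j][1], None))
            col_of[(c, int(p))] = offset + j
        offset += m_per
    dosage = np.concatenate(dose_cols, axis=1)
    n_total = len(samples)
    if dosage.shape[0] != n_total:
        raise InvariantError("haplotype bookkeeping mismatch")

    sid = [s.sample_id for s in samples]
    pop_rows = {
        spec.label: np.array(
            [i for i, s in enumerate(samples) if s.population == spec.label and s.cohort == "none"]
        )
        for spec in config.populations
    }
    twin_rows = np.array([i for i, s in enumerate(samples) if s.cohort == "twin"])
    ctrl_rows = np.array([i for i, s in enumerate(samples) if s.cohort == "control"])

    # -- planted ROH tracts ---------------------------------------------------
    truth_roh = []
    auto_pool = [pop_rows[spec.label][0] for spec in config.populations]
    for k, rp in enumerate(config.roh_plants):
        if rp.sample is None:
            row = int(auto_pool[k % len(auto_pool)])
        else:
            row = sid.index(rp.sample)
        pos = pos_by_chrom[rp.chrom]
        sm = (pos >= rp.start) & (pos <= rp.end)
        cols = np.flatnonzero(sm) + sum(
            m_per for cc in chroms[: chroms.index(rp.chrom)]
        )
        # homozygose: collapse to one haplotype's allele (het -> hom ref side)
        dosage[row, cols] = np.where(dosage[row, cols] >= 1, 2, 0)
        truth_roh.append(
            {"sample": sid[row], "chrom": rp.chrom, "start": rp.start, "end": rp.end}
        )

    # -- missingness -----------------------------------------------------------
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
    else:
        mask = np.zeros(dosage.shape, dtype=bool)

    # -- planted rare twin-enriched variants ----------------------------------
    sweep_sites: dict[int, list[int]] = {}
    for si, sw in enumerate(config.sweeps):
        pos = pos_by_chrom[sw.chrom]
        span = sw.end - sw.start
        lo, hi = sw.start + 0.2 * span, sw.end - 0.2 * span
        sweep_sites[si] = [
            col_of[(sw.chrom, int(p))] for p in pos[(pos >= lo) & (pos <= hi)]
        ]
    used: set[int] = set()
    truth_rare = []
    for k, rp in enumerate(config.rare_plants):
        if rp.pos is not None:
            if (rp.chrom, rp.pos) not in col_of:
                raise ConfigError(f"rare plant position {rp.chrom}:{rp.pos} is not a SNP")
            col = col_of[(rp.chrom, rp.pos)]
        else:
            if not config.sweeps:
                raise ConfigError("auto-placed rare plants require sweeps")
            si = k % len(config.sweeps)
            avail = [c for c in sweep_sites[si] if c not in used]
            if not avail:
                raise InfeasibleConfigError("no free SNPs left inside sweep for rare plant")
            col = int(avail[rng.integers(0, len(avail))])
        used.add(col)
        dosage[:, col] = 0
        mask[:, col] = False  # exempt from missingness: counts stay exact
        control_counts = {}
        for spec in config.populations:
            rows = pop_rows[spec.label]
            n_alleles = 2 * len(rows)
            c_max = int(np.floor(rp.max_control_freq * n_alleles - 1e-9))
            cnt = int(rng.integers(0, max(c_max, 0) + 1))
            carriers = rng.choice(rows, size=cnt, replace=False) if cnt else []
            dosage[carriers, col] = 1
            control_counts[spec.label] = cnt
        cc = int(rng.integers(0, 2))
        if cc:
            dosage[rng.choice(ctrl_rows, size=cc, replace=False), col] = 1
        tc = rp.twin_count
        n_hom = max(0, tc - len(twin_rows))
        n_het = tc - 2 * n_hom
        chosen = rng.choice(twin_rows, size=n_het + n_hom, replace=False)
        dosage[chosen[:n_het], col] = 1
        dosage[chosen[n_het:], col] = 2
        v = variants[col]
        truth_rare.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "twin_count": tc,
                "control_counts": control_counts,
                "control_cohort_count": cc,
            }
        )

    dosage[mask] = -1  # genio.MISSING

    table = GenotypeTable(variants, samples, dosage)

    # verify realized control frequencies stay below the screen threshold
    for tr in truth_rare:
        col = col_of[(tr["chrom"], tr["pos"])]
        realized = {}
        for spec in config.populations:
            rows = pop_rows[spec.label]
            d = dosage[rows, col]
            f = float(d[d >= 0].sum() / (2 * (d >= 0).sum()))
            realized[spec.label] = f
            if not f < config.rare_threshold:
                raise InfeasibleConfigError(
                    f"planted variant {tr['chrom']}:{tr['pos']} realized control "
                    f"frequency {f:.3f} in {spec.label}"
                )
        tr["realized_control_freq"] = realized

    # -- gene model -------------------------------------------------------------
    genes = []
    for c in chroms:
        k = 0
        start = 10_001
        while start + config.gene_length_bp - 1 <= L:
            genes.append(
                Gene(
                    name=f"GENE{c}_{k:03d}",
                    chrom=c,
                    start=start,
                    end=start + config.gene_length_bp - 1,
                    strand="+" if k % 2 == 0 else "-",
                )
            )
            start += config.gene_spacing_bp
            k += 1
    model = GeneModel(genes=genes)

    truth = SimTruth(
        sweeps=truth_sweeps, rare_variants=truth_rare, roh=truth_roh, seed=config.seed
    )
    return table, model, truth


def write_fixture(
    out_dir: str | os.PathLike, config: SimConfig
) -> dict[str, str]:
    """Simulate and write VCF + sample sheet + gene model BED + truth JSON."""
    table, model, truth = simulate_cohort(config)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "cohort.vcf"),
        "sample_sheet": os.path.join(out_dir, "samples.tsv"),
        "gene_model": os.path.join(out_dir, "genes.bed"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    write_vcf(table, paths["vcf"])
    write_sample_sheet(table.samples, paths["sample_sheet"])
    write_gene_model_bed(model, paths["gene_model"])
    truth.to_json(paths["truth"])
    return paths
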