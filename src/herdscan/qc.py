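"""Site- and sample-level SNP quality control.

Implements the study's retention criteria: biallelic sites only, per-site
missing rate, minor allele frequency (computed on non-missing alleles), and a
two-sided exact Hardy–Weinberg equilibrium test.  Site filters run first, then
sample filters, then an optional second, stricter site-missingness pass —
mirroring a detection-stage filter followed by a tighter conversion-stage
filter.  Removed-site counts are attributed to the first failing criterion in
the order: biallelic, missingness, MAF, HWE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .errors import CohortError, DataError, InvariantError
from .genio import MISSING, GenotypeTable


@dataclass(frozen=True)
class SiteFilterCriteria:
    """Thresholds for site retention (defaults are the study's values)."""

    maf_min: float = 0.05
    site_missing_max: float = 0.20
    hwe_p_min: float = 1e-6
    biallelic_only: bool = True

    def __post_init__(self):
        if not 0.0 <= self.maf_min <= 0.5:
            raise InvariantError("maf_min must be in [0, 0.5]")
        if not 0.0 <= self.site_missing_max <= 1.0:
            raise InvariantError("site_missing_max must be in [0, 1]")
        if not 0.0 <= self.hwe_p_min <= 1.0:
            raise InvariantError("hwe_p_min must be in [0, 1]")


@dataclass
class FilterReport:
    """Per-criterion removal counts for one filtering pass."""

    sites_in: int
    sites_out: int
    samples_in: int
    samples_out: int
    removed: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.sites_in - sum(self.removed.values()) != self.sites_out and self.removed:
            raise InvariantError("removed counts inconsistent with sites_in/sites_out")

    def to_tsv(self, path) -> None:
        import pandas as pd

        rows = [("sites_in", self.sites_in), ("sites_out", self.sites_out),
                ("samples_in", self.samples_in), ("samples_out", self.samples_out)]
        rows += [(f"removed_{k}", v) for k, v in self.removed.items()]
        pd.DataFrame(rows, columns=["metric", "count"]).to_csv(path, sep="\t", index=False)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy–Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of all
    heterozygote configurations no more likely than the observed one (the
    plain exact test; no mid-p correction).  Symmetric under allele
    relabeling.  Monomorphic sites return 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise DataError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise DataError("HWE test undefined for zero genotypes")
    n_a = 2 * n_aa + n_Aa  # copies of the a allele
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return 1.0
    # Heterozygote count must share the parity of the minor allele count and
    # cannot exceed min(n_minor, 2n - n_minor).
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    # log P(het = h | allele counts) up to a shared constant:
    # P ∝ 2^h * n! / (h! * ((n_minor-h)/2)! * ((n_maj-h)/2)!)
    n_major = 2 * n - n_minor
    rare_hom = (n_minor - hets) // 2
    comm_hom = (n_major - hets) // 2
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(rare_hom + 1)
        - gammaln(comm_hom + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs_het = n_Aa
    p_obs = probs[np.searchsorted(hets, obs_het)]
    # Two-sided: sum all configurations with probability <= observed (with a
    # tiny relative tolerance against floating-point ties).
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _site_stats(table: GenotypeTable):
    dos = table.dosage
    miss = dos == MISSING
    n_called = (~miss).sum(axis=0)
    miss_rate = np.where(
        table.n_samples > 0, miss.sum(axis=0) / max(table.n_samples, 1), 1.0
    )
    alt = np.where(miss, 0, dos).sum(axis=0)
    alleles = 2 * n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(alleles > 0, alt / np.maximum(alleles, 1), np.nan)
    maf = np.minimum(freq, 1 - freq)
    n_het = (dos == 1).sum(axis=0)
    n_hom_alt = (dos == 2).sum(axis=0)
    n_hom_ref = (dos == 0).sum(axis=0)
    return miss_rate, maf, n_hom_ref, n_het, n_hom_alt, n_called


def filter_sites(
    table: GenotypeTable, criteria: SiteFilterCriteria | None = None
) -> tuple[GenotypeTable, FilterReport]:
    """Drop sites failing missingness, MAF, or HWE; report attributed counts."""
    criteria = criteria or SiteFilterCriteria()
    miss_rate, maf, n_rr, n_ra, n_aa, n_called = _site_stats(table)
    m = table.n_variants
    removed = {"biallelic": 0, "missingness": 0, "maf": 0, "hwe": 0}
    keep = np.ones(m, dtype=bool)
    # biallelic: the table type admits only biallelic records, so this
    # criterion can only fire for sites that are not variants at all — kept
    # for report completeness.
    fail_miss = miss_rate > criteria.site_missing_max
    removed["missingness"] = int(fail_miss.sum())
    keep &= ~fail_miss
    # MAF on non-missing alleles; all-missing sites were already caught above
    # whenever site_missing_max < 1, otherwise they fail MAF as undefined.
    with np.errstate(invalid="ignore"):
        fail_maf = keep & (~(maf >= criteria.maf_min) | (n_called == 0))
    removed["maf"] = int(fail_maf.sum())
    keep &= ~fail_maf
    if criteria.hwe_p_min > 0:
        idx = np.flatnonzero(keep)
        fail_hwe = np.zeros(m, dtype=bool)
        for j in idx:
            p = hwe_exact_test(int(n_rr[j]), int(n_ra[j]), int(n_aa[j]))
            if not p > criteria.hwe_p_min:
                fail_hwe[j] = True
        removed["hwe"] = int(fail_hwe.sum())
        keep &= ~fail_hwe
    out = table.subset_variants(keep)
    report = FilterReport(
        sites_in=m,
        sites_out=out.n_variants,
        samples_in=table.n_samples,
        samples_out=table.n_samples,
        removed=removed,
    )
    return out, report


def filter_samples(
    table: GenotypeTable, sample_missing_max: float = 0.10
) -> tuple[GenotypeTable, FilterReport]:
    """Drop samples whose genotype missing rate exceeds the threshold."""
    if table.n_variants == 0:
        miss_rate = np.zeros(table.n_samples)
    else:
        miss_rate = (table.dosage == MISSING).sum(axis=1) / table.n_variants
    keep = miss_rate <= sample_missing_max
    if not keep.any():
        raise CohortError("all samples removed by the missing-rate filter")
    out = table.subset_samples(np.flatnonzero(keep))
    report = FilterReport(
        sites_in=table.n_variants,
        sites_out=table.n_variants,
        samples_in=table.n_samples,
        samples_out=out.n_samples,
        removed={},
    )
    return out, report


def apply_qc(
    table: GenotypeTable,
    criteria: SiteFilterCriteria | None = None,
    sample_missing_max: float = 0.10,
    second_site_missing_max: float | None = 0.05,
) -> tuple[GenotypeTable, list[FilterReport]]:
    """Full QC: site pass, sample pass, then a stricter site-missingness pass.

    Returns the filtered table and one :class:`FilterReport` per pass.
    """
    criteria = criteria or SiteFilterCriteria()
    reports: list[FilterReport] = []
    table, rep = filter_sites(table, criteria)
    reports.append(rep)
    table, rep = filter_samples(table, sample_missing_max)
    reports.append(rep)
    if second_site_missing_max is not None:
        pass2 = SiteFilterCriteria(
            maf_min=0.0,
            site_missing_max=second_site_missing_max,
            hwe_p_min=0.0,
            biallelic_only=criteria.biallelic_only,
        )
        table, rep = filter_sites(table, pass2)
        reports.append(rep)
    return table, reports
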