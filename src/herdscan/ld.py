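"""Linkage disequilibrium: pairwise genotype r² and the binned decay curve.

r² is the squared Pearson correlation of dosage vectors over jointly
non-missing samples (genotype LD — phase is never assumed).  Only
intra-chromosome pairs within a physical distance cap (default 500 kb) are
computed.  The decay curve averages r² in fixed-width distance bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .genio import MISSING, GenotypeTable

DEFAULT_MAX_DIST_BP: int = 500_000


@dataclass
class LDPairs:
    """Flat arrays of (distance, r²) pairs plus a zero-variance skip count."""

    dist: np.ndarray
    r2: np.ndarray
    n_skipped: int = 0


@dataclass
class LDDecayCurve:
    """Mean r² per distance bin over (0, max_dist]."""

    bin_edges: np.ndarray  # length n_bins + 1, starting at 0
    mean_r2: np.ndarray  # NaN for empty bins
    n_pairs: np.ndarray
    max_dist_bp: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1].astype(int),
                "bin_end": self.bin_edges[1:].astype(int),
                "mean_r2": self.mean_r2,
                "n_pairs": self.n_pairs.astype(int),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def pairwise_r2(table: GenotypeTable, max_dist_bp: int = DEFAULT_MAX_DIST_BP) -> LDPairs:
    """All intra-chromosome SNP pairs within the distance cap.

    Pairs where either SNP has zero dosage variance over the jointly
    non-missing samples are skipped and counted.
    """
    if max_dist_bp <= 0:
        raise ConfigError("max_dist_bp must be positive")
    dists: list[np.ndarray] = []
    r2s: list[np.ndarray] = []
    n_skipped = 0
    chrom_arr = table.chroms
    any_pairs = False
    for chrom in table.chromosomes():
        cmask = chrom_arr == chrom
        pos = table.positions[cmask]
        X = table.dosage[:, cmask].astype(np.float64)
        ok = (table.dosage[:, cmask] != MISSING).astype(np.float64)
        Xz = np.where(ok > 0, X, 0.0)
        m = len(pos)
        if m >= 2:
            any_pairs = True
        hi = np.searchsorted(pos, pos + max_dist_bp, side="right")
        for j in range(m - 1):
            k = slice(j + 1, hi[j])
            if k.start >= k.stop:
                continue
            x, vx = Xz[:, j], ok[:, j]
            Y, vY = Xz[:, k], ok[:, k]
            v = vx[:, None] * vY  # joint non-missing indicator
            n = v.sum(axis=0)
            xs = x[:, None] * v
            sx = xs.sum(axis=0)
            sy = (Y * v).sum(axis=0)
            sxx = (xs * x[:, None]).sum(axis=0)
            syy = (Y * Y * v).sum(axis=0)
            sxy = (xs * Y).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                cov = sxy - sx * sy / n
                varx = sxx - sx * sx / n
                vary = syy - sy * sy / n
                r2 = (cov * cov) / (varx * vary)
            good = (n >= 2) & (varx > 1e-12) & (vary > 1e-12)
            n_skipped += int((~good).sum())
            if good.any():
                dists.append((pos[k] - pos[j])[good].astype(np.float64))
                r2s.append(np.clip(r2[good], 0.0, 1.0))
    if not any_pairs:
        raise DataError("no chromosome has >= 2 SNPs")
    dist = np.concatenate(dists) if dists else np.array([])
    r2 = np.concatenate(r2s) if r2s else np.array([])
    return LDPairs(dist=dist, r2=r2, n_skipped=n_skipped)


def ld_decay_curve(
    pairs: LDPairs,
    bin_width_bp: int = 1000,
    max_dist_bp: int | None = None,
) -> LDDecayCurve:
    """Bin (distance, r²) pairs into fixed-width distance bins and average."""
    if bin_width_bp <= 0:
        raise ConfigError("bin_width_bp must be positive")
    if pairs.dist.size == 0:
        raise DataError("empty pair stream")
    if max_dist_bp is None:
        max_dist_bp = int(np.ceil(pairs.dist.max() / bin_width_bp) * bin_width_bp)
    n_bins = int(np.ceil(max_dist_bp / bin_width_bp))
    edges = np.arange(n_bins + 1, dtype=np.int64) * bin_width_bp
    # bin b covers (edges[b], edges[b+1]]; distance 0 cannot occur (positions
    # are strictly increasing)
    idx = np.ceil(pairs.dist / bin_width_bp).astype(int) - 1
    keep = (idx >= 0) & (idx < n_bins)
    counts = np.bincount(idx[keep], minlength=n_bins)
    sums = np.bincount(idx[keep], weights=pairs.r2[keep], minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LDDecayCurve(
        bin_edges=edges, mean_r2=mean, n_pairs=counts, max_dist_bp=max_dist_bp
    )


def population_decay_curves(
    table: GenotypeTable,
    max_dist_bp: int = DEFAULT_MAX_DIST_BP,
    bin_width_bp: int = 1000,
    populations: list[str] | None = None,
) -> dict[str, LDDecayCurve]:
    """Per-population decay curves keyed off the sample sheet labels."""
    pops = populations or sorted({s.population for s in table.samples})
    out: dict[str, LDDecayCurve] = {}
    for pop in pops:
        idx = table.sample_index(population=pop)
        if len(idx) < 2:
            continue
        sub = table.subset_samples(idx)
        pairs = pairwise_r2(sub, max_dist_bp)
        if pairs.dist.size:
            out[pop] = ld_decay_curve(pairs, bin_width_bp, max_dist_bp)
    return out


def prune_ld(
    table: GenotypeTable,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.2,
) -> np.ndarray:
    """Greedy window-based r² pruning; returns a boolean keep mask.

    A light utility for thinning markers before structure analyses.  Within
    each sliding window, later SNPs correlated above ``r2_max`` with an
    earlier kept SNP are dropped.
    """
    keep = np.ones(table.n_variants, dtype=bool)
    dos = table.dosage.astype(np.float64)
    dos[table.dosage == MISSING] = np.nan
    chrom_arr = table.chroms
    for chrom in table.chromosomes():
        cidx = np.flatnonzero(chrom_arr == chrom)
        m = len(cidx)
        for start in range(0, max(m - 1, 1), step_snps):
            win = cidx[start : start + window_snps]
            live = [j for j in win if keep[j]]
            for ai in range(len(live)):
                if not keep[live[ai]]:
                    continue
                for bi in range(ai + 1, len(live)):
                    jb = live[bi]
                    if not keep[jb]:
                        continue
                    x, y = dos[:, live[ai]], dos[:, jb]
                    v = ~np.isnan(x) & ~np.isnan(y)
                    if v.sum() < 2:
                        continue
                    xv, yv = x[v], y[v]
                    if xv.std() == 0 or yv.std() == 0:
                        continue
                    r = np.corrcoef(xv, yv)[0, 1]
                    if r * r > r2_max:
                        keep[jb] = False
    return keep
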