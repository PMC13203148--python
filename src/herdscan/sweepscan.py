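"""Selection-signature scan: windowed Weir–Cockerham Fst and θπ-ratio.

Two sample groups (here: the twin-calving cohort and its single-calving
control group) are compared in sliding windows (default 50 kb windows,
20 kb step).  Per window the scan reports:

* the Weir–Cockerham (1984) weighted Fst — the ratio of summed variance
  components Σa / Σ(a+b+c) over the window's sites (never the mean of
  per-site ratios);
* nucleotide diversity θπ per group — per-site unbiased heterozygosity
  2·n_alt·n_ref / (n·(n−1)) summed over the window and divided by the
  window span in bp;
* log2(π_control / π_twin), oriented so that diversity loss in the twin
  cohort gives positive values.

Windows above the empirical 95th percentile of either statistic are merged
into candidate regions; regions from the two statistics can be intersected
or unioned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CohortError, ConfigError, DataError
from .genio import MISSING, GenotypeTable


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry (defaults: 50 kb windows, 20 kb step)."""

    size_bp: int = 50_000
    step_bp: int = 20_000

    def __post_init__(self):
        if self.size_bp <= 0 or self.step_bp <= 0:
            raise ConfigError("window size and step must be positive")
        if self.step_bp > self.size_bp:
            raise ConfigError("step must not exceed window size")


@dataclass
class RegionSet:
    """Sorted, merged genomic intervals (1-based inclusive) with provenance."""

    intervals: list[tuple[str, int, int]]
    provenance: str = ""

    def __post_init__(self):
        self.intervals = _merge(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def total_bp(self) -> int:
        return sum(e - s + 1 for _, s, e in self.intervals)

    def contains(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Vectorized membership for positions on one chromosome."""
        pos = np.asarray(pos)
        out = np.zeros(pos.shape, dtype=bool)
        for c, s, e in self.intervals:
            if c == chrom:
                out |= (pos >= s) & (pos <= e)
        return out

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for c, s, e in self.intervals:
                fh.write(f"{c}\t{s - 1}\t{e}\t{self.provenance or '.'}\n")

    @classmethod
    def from_bed(cls, path, provenance: str = "") -> "RegionSet":
        iv = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                parts = line.split("\t")
                iv.append((parts[0], int(parts[1]) + 1, int(parts[2])))
        return cls(intervals=iv, provenance=provenance)


def _merge(intervals: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Sort and merge overlapping or book-ended intervals."""
    if not intervals:
        return []
    iv = sorted(intervals)
    out = [iv[0]]
    for c, s, e in iv[1:]:
        pc, ps, pe = out[-1]
        if c == pc and s <= pe + 1:
            out[-1] = (pc, ps, max(pe, e))
        else:
            out.append((c, s, e))
    return out


# ----------------------------------------------------------------------------
# Weir–Cockerham variance components (two populations)
# ----------------------------------------------------------------------------

def site_fst_components(
    dosages_a: np.ndarray, dosages_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir–Cockerham (1984) variance components (a, b, c) per site.

    Inputs are dosage matrices (samples × sites) for the two groups, with
    :data:`MISSING` entries excluded per site.  Sites monomorphic across
    both groups, or with a group entirely missing, yield a = b = c = 0 (they
    contribute nothing to a windowed ratio-of-sums).

    Components for r = 2 populations with per-group genotyped sample sizes
    ``n_i``, ALT frequencies ``p_i`` and observed heterozygosities ``h_i``::

        n̄  = Σ n_i / r                 p̄ = Σ n_i p_i / (r n̄)
        n_c = (r n̄ − Σ n_i²/(r n̄)) / (r − 1)
        s²  = Σ n_i (p_i − p̄)² / ((r−1) n̄)
        h̄  = Σ n_i h_i / (r n̄)

        a = n̄/n_c · [s² − (p̄(1−p̄) − (r−1)/r·s² − h̄/4) / (n̄−1)]
        b = n̄/(n̄−1) · [p̄(1−p̄) − (r−1)/r·s² − (2n̄−1)/(4n̄)·h̄]
        c = h̄/2
    """
    da = np.atleast_2d(np.asarray(dosages_a))
    db = np.atleast_2d(np.asarray(dosages_b))
    oka = da != MISSING
    okb = db != MISSING
    n1 = oka.sum(axis=0).astype(np.float64)
    n2 = okb.sum(axis=0).astype(np.float64)
    alt1 = np.where(oka, da, 0).sum(axis=0).astype(np.float64)
    alt2 = np.where(okb, db, 0).sum(axis=0).astype(np.float64)
    het1 = (da == 1).sum(axis=0).astype(np.float64)
    het2 = (db == 1).sum(axis=0).astype(np.float64)

    valid = (n1 > 0) & (n2 > 0)
    n1s = np.maximum(n1, 1)
    n2s = np.maximum(n2, 1)
    p1 = alt1 / (2 * n1s)
    p2 = alt2 / (2 * n2s)
    h1 = het1 / n1s
    h2 = het2 / n2s

    r = 2.0
    nbar = (n1 + n2) / r
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4
        a = nbar / nc * (s2 - inner / (nbar - 1))
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2

    mono = (pbar <= 0) | (pbar >= 1)
    degenerate = ~valid | mono | (nbar <= 1) | ~np.isfinite(nc) | (nc <= 0)
    for arr in (a, b, c):
        arr[degenerate] = 0.0
    return a, b, c


# ----------------------------------------------------------------------------
# windows
# ----------------------------------------------------------------------------

def _windows_for_chrom(chrom_len: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """Windows anchored at 1, 1+step, …; trailing windows keep their true span."""
    out = []
    start = 1
    while start <= chrom_len:
        out.append((start, min(start + spec.size_bp - 1, chrom_len)))
        start += spec.step_bp
    return out


def _chrom_lengths(table: GenotypeTable, chrom_lengths: dict[str, int] | None) -> dict[str, int]:
    out = {}
    for chrom in table.chromosomes():
        last = int(table.positions[table.chroms == chrom].max())
        out[chrom] = chrom_lengths.get(chrom, last) if chrom_lengths else last
    return out


def window_fst(
    table: GenotypeTable,
    group_a: np.ndarray,
    group_b: np.ndarray,
    spec: WindowSpec | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Windowed weighted Fst = Σa / Σ(a+b+c) over each window's sites.

    Windows with no informative sites carry ``fst = NaN`` and are excluded
    from quantile computation downstream.  Negative window values are
    retained (clamping would distort the empirical threshold).
    """
    spec = spec or WindowSpec()
    group_a = np.asarray(group_a, dtype=int)
    group_b = np.asarray(group_b, dtype=int)
    if len(group_a) == 0 or len(group_b) == 0:
        raise CohortError("both sample groups must be non-empty")
    if set(group_a) & set(group_b):
        raise CohortError("sample groups must be disjoint")
    a, b, c = site_fst_components(table.dosage[group_a], table.dosage[group_b])
    abc = a + b + c
    rows = []
    lens = _chrom_lengths(table, chrom_lengths)
    for chrom in table.chromosomes():
        cmask = table.chroms == chrom
        pos = table.positions[cmask]
        ca, cabc = a[cmask], abc[cmask]
        cs_a = np.concatenate([[0.0], np.cumsum(ca)])
        cs_abc = np.concatenate([[0.0], np.cumsum(cabc)])
        for ws, we in _windows_for_chrom(lens[chrom], spec):
            lo = np.searchsorted(pos, ws, side="left")
            hi = np.searchsorted(pos, we, side="right")
            sum_a = cs_a[hi] - cs_a[lo]
            sum_abc = cs_abc[hi] - cs_abc[lo]
            fst = sum_a / sum_abc if sum_abc > 0 else np.nan
            rows.append((chrom, ws, we, hi - lo, fst))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "fst"])


def site_pi(dosages: np.ndarray) -> np.ndarray:
    """Per-site nucleotide diversity 2·n_alt·n_ref / (n(n−1)), n = allele count.

    Sites with fewer than two called alleles yield 0 (skipped).
    """
    d = np.atleast_2d(np.asarray(dosages))
    ok = d != MISSING
    n = (2 * ok.sum(axis=0)).astype(np.float64)
    n_alt = np.where(ok, d, 0).sum(axis=0).astype(np.float64)
    n_ref = n - n_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * n_alt * n_ref / (n * (n - 1.0))
    pi[n < 2] = 0.0
    return pi


def window_pi(
    table: GenotypeTable,
    group: np.ndarray,
    spec: WindowSpec | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Windowed θπ per bp: summed per-site diversity over the window span."""
    spec = spec or WindowSpec()
    group = np.asarray(group, dtype=int)
    if len(group) == 0:
        raise CohortError("group must be non-empty")
    pi = site_pi(table.dosage[group])
    rows = []
    lens = _chrom_lengths(table, chrom_lengths)
    for chrom in table.chromosomes():
        cmask = table.chroms == chrom
        pos = table.positions[cmask]
        cpi = pi[cmask]
        cs = np.concatenate([[0.0], np.cumsum(cpi)])
        for ws, we in _windows_for_chrom(lens[chrom], spec):
            lo = np.searchsorted(pos, ws, side="left")
            hi = np.searchsorted(pos, we, side="right")
            span = we - ws + 1
            rows.append((chrom, ws, we, hi - lo, (cs[hi] - cs[lo]) / span))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "pi"])


def log2_pi_ratio(pi_control: np.ndarray, pi_twin: np.ndarray) -> np.ndarray:
    """log2(π_control / π_twin); NaN where either diversity is non-positive.

    Positive values flag reduced diversity in the twin cohort.
    """
    pi_control = np.asarray(pi_control, dtype=np.float64)
    pi_twin = np.asarray(pi_twin, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where((pi_control > 0) & (pi_twin > 0), pi_control / pi_twin, np.nan)
        return np.log2(ratio)


def scan_windows(
    table: GenotypeTable,
    twin: np.ndarray,
    control: np.ndarray,
    spec: WindowSpec | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Joint window table: Fst, per-group π, and log2(θπ-ratio)."""
    spec = spec or WindowSpec()
    fst = window_fst(table, twin, control, spec, chrom_lengths)
    ptw = window_pi(table, twin, spec, chrom_lengths)
    pct = window_pi(table, control, spec, chrom_lengths)
    df = fst.copy()
    df["pi_twin"] = ptw["pi"].to_numpy()
    df["pi_control"] = pct["pi"].to_numpy()
    df["log2_ratio"] = log2_pi_ratio(df["pi_control"].to_numpy(), df["pi_twin"].to_numpy())
    return df


def select_top_windows(
    stats: pd.DataFrame, field: str, quantile: float = 0.95, min_windows: int = 20
) -> tuple[float, RegionSet]:
    """Empirical top-quantile window selection.

    The threshold is the type-7 empirical quantile over windows with a
    defined value; windows strictly above it are merged into a
    :class:`RegionSet`.  With fewer than ``min_windows`` defined windows the
    quantile is not meaningful and an error is raised.
    """
    if field not in ("fst", "log2_ratio"):
        raise ConfigError(f"field must be 'fst' or 'log2_ratio', got {field!r}")
    vals = stats[field].to_numpy(dtype=np.float64)
    defined = np.isfinite(vals)
    if defined.sum() < min_windows:
        raise DataError(
            f"only {int(defined.sum())} defined windows; need >= {min_windows} for quantiles"
        )
    threshold = float(np.quantile(vals[defined], quantile))
    sel = defined & (vals > threshold)
    if not sel.any():
        import warnings

        warnings.warn(f"no window strictly above the {field} threshold", stacklevel=2)
    iv = [
        (str(r.chrom), int(r.start), int(r.end))
        for r in stats.loc[sel].itertuples(index=False)
    ]
    return threshold, RegionSet(intervals=iv, provenance=field if field == "fst" else "pi_ratio")


def combine_regions(a: RegionSet, b: RegionSet, mode: str) -> RegionSet:
    """Interval intersection or union of two region sets."""
    if mode not in ("intersection", "union"):
        raise ConfigError(f"mode must be 'intersection' or 'union', got {mode!r}")
    if mode == "union":
        return RegionSet(intervals=a.intervals + b.intervals, provenance="union")
    out: list[tuple[str, int, int]] = []
    by_chrom_b: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in b.intervals:
        by_chrom_b.setdefault(c, []).append((s, e))
    for c, s, e in a.intervals:
        for s2, e2 in by_chrom_b.get(c, []):
            lo, hi = max(s, s2), min(e, e2)
            if lo <= hi:
                out.append((c, lo, hi))
    return RegionSet(intervals=out, provenance="intersection")
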