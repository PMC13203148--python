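"""Runs of homozygosity and the genomic inbreeding coefficient F_ROH.

The detector follows the PLINK sliding-window semantics: a fixed-size SNP
window slides along each chromosome; a window is homozygous-compatible if it
contains at most ``window_max_het`` heterozygous and ``window_max_missing``
missing calls; a SNP is part of a run when the fraction of compatible windows
covering it reaches ``hit_threshold``.  Maximal in-run stretches are split at
large inter-SNP gaps and then filtered by SNP count, physical length, and SNP
density.  F_ROH is the summed run length divided by the autosomal genome
length (default 2,489.39 Mb, overridable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, InvariantError
from .genio import MISSING, GenotypeTable

#: Default autosomal genome length in bp used for F_ROH.
DEFAULT_GENOME_BP: int = 2_489_390_000


@dataclass(frozen=True)
class ROHParams:
    """Sliding-window ROH parameters (defaults match the standard PLINK call)."""

    min_snps_per_run: int = 50
    min_run_kb: float = 500.0
    window_snps: int = 50
    window_max_het: int = 3
    window_max_missing: int = 5
    hit_threshold: float = 0.05
    max_gap_kb: float = 100.0
    min_density_kb_per_snp: float = 50.0

    def __post_init__(self):
        if min(self.min_snps_per_run, self.window_snps) <= 0:
            raise ConfigError("SNP counts must be positive")
        if min(self.min_run_kb, self.max_gap_kb, self.min_density_kb_per_snp) <= 0:
            raise ConfigError("lengths must be positive")
        if not 0 < self.hit_threshold <= 1:
            raise ConfigError("hit_threshold must be in (0, 1]")


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run, delimited by its first and last SNP."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class InbreedingRecord:
    """Per-sample genomic inbreeding: summed ROH length over genome length."""

    sample_id: str
    sum_roh_bp: int
    f_roh: float


def _sample_chrom_runs(
    hom: np.ndarray, miss: np.ndarray, pos: np.ndarray, params: ROHParams
) -> list[tuple[int, int, int, int]]:
    """Runs for one sample on one chromosome: (start_idx, end_idx, start_bp, end_bp)."""
    m = len(pos)
    W = min(params.window_snps, m)  # chromosomes shorter than one window are
    # evaluated with a single truncated window
    het = ~hom & ~miss
    ch = np.concatenate([[0], np.cumsum(het)])
    cm = np.concatenate([[0], np.cumsum(miss)])
    n_windows = m - W + 1
    starts = np.arange(n_windows)
    compatible = (
        (ch[starts + W] - ch[starts] <= params.window_max_het)
        & (cm[starts + W] - cm[starts] <= params.window_max_missing)
    ).astype(np.float64)
    # windows covering SNP j start in [j-W+1, j] clipped to [0, n_windows-1]
    cc = np.concatenate([[0.0], np.cumsum(compatible)])
    lo = np.clip(np.arange(m) - W + 1, 0, n_windows - 1)
    hi = np.clip(np.arange(m), 0, n_windows - 1)
    n_cover = hi - lo + 1
    n_compat = cc[hi + 1] - cc[lo]
    in_run = (n_compat / n_cover) >= params.hit_threshold
    # heterozygous or missing SNPs never terminate... they DO belong to runs
    # under window tolerance, but a run must start and end on a homozygous call
    runs: list[tuple[int, int]] = []
    j = 0
    while j < m:
        if in_run[j]:
            k = j
            while k + 1 < m and in_run[k + 1]:
                k += 1
            runs.append((j, k))
            j = k + 1
        else:
            j += 1
    # split at gaps, trim to homozygous ends
    max_gap_bp = params.max_gap_kb * 1000.0
    out: list[tuple[int, int, int, int]] = []
    for a, b in runs:
        piece_start = a
        for j in range(a + 1, b + 1):
            if pos[j] - pos[j - 1] > max_gap_bp:
                out.append((piece_start, j - 1, 0, 0))
                piece_start = j
        out.append((piece_start, b, 0, 0))
    trimmed = []
    for a, b, _, _ in out:
        while a <= b and not hom[a]:
            a += 1
        while b >= a and not hom[b]:
            b -= 1
        if a <= b:
            trimmed.append((a, b, int(pos[a]), int(pos[b])))
    return trimmed


def detect_roh(table: GenotypeTable, params: ROHParams | None = None) -> list[ROHSegment]:
    """Detect ROH segments for every sample, per chromosome."""
    params = params or ROHParams()
    segments: list[ROHSegment] = []
    chrom_arr = table.chroms
    for chrom in table.chromosomes():
        cmask = chrom_arr == chrom
        pos = table.positions[cmask]
        dsub = table.dosage[:, cmask]
        for i, sid in enumerate(table.sample_ids):
            d = dsub[i]
            miss = d == MISSING
            hom = (d == 0) | (d == 2)
            for a, b, sbp, ebp in _sample_chrom_runs(hom, miss, pos, params):
                n_snps = b - a + 1
                length_bp = ebp - sbp + 1
                if n_snps < params.min_snps_per_run:
                    continue
                if length_bp < params.min_run_kb * 1000.0:
                    continue
                if length_bp / 1000.0 / n_snps > params.min_density_kb_per_snp:
                    continue
                segments.append(
                    ROHSegment(sample_id=sid, chrom=chrom, start=sbp, end=ebp, n_snps=n_snps)
                )
    return segments


def froh(
    segments: list[ROHSegment],
    genome_length_bp: int = DEFAULT_GENOME_BP,
    sample_ids: list[str] | None = None,
) -> list[InbreedingRecord]:
    """Per-sample F_ROH = summed ROH length / genome length.

    ``sample_ids`` adds zero-ROH samples to the output.  Overlapping segments
    within one sample violate the disjointness invariant and raise.
    """
    if genome_length_bp <= 0:
        raise ConfigError("genome_length_bp must be positive")
    by_sample: dict[str, list[ROHSegment]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample_id, []).append(seg)
    ids = sample_ids if sample_ids is not None else sorted(by_sample)
    out: list[InbreedingRecord] = []
    for sid in ids:
        segs = sorted(by_sample.get(sid, []), key=lambda s: (s.chrom, s.start))
        prev_end: dict[str, int] = {}
        total = 0
        for s in segs:
            if s.chrom in prev_end and s.start <= prev_end[s.chrom]:
                raise InvariantError(f"overlapping ROH segments for sample {sid} on {s.chrom}")
            prev_end[s.chrom] = s.end
            total += s.length_bp
        f = total / genome_length_bp
        if not 0.0 <= f <= 1.0:
            raise InvariantError(f"F_ROH out of [0,1] for sample {sid}")
        out.append(InbreedingRecord(sample_id=sid, sum_roh_bp=total, f_roh=f))
    return out


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in segments],
            "chrom": [s.chrom for s in segments],
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "n_snps": [s.n_snps for s in segments],
            "kb": [s.length_bp / 1000.0 for s in segments],
        }
    )


def froh_to_frame(records: list[InbreedingRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "sum_roh_bp": [r.sum_roh_bp for r in records],
            "f_roh": [r.f_roh for r in records],
        }
    )
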