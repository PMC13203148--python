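"""Genotype and annotation I/O.

Reads diploid biallelic SNP genotypes from VCF into a dense dosage table, joins
per-sample metadata from a headered TSV sample sheet, and reads simple gene
models from BED4 or GFF3.  All internal coordinates are 1-based inclusive (the
VCF convention); BED's 0-based half-open intervals are converted at the
boundary.  Missing genotypes are encoded as :data:`MISSING` (−1) in the dosage
matrix, distinct from the valid dosages {0, 1, 2}.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import FormatError, InvariantError, MetadataError

#: Sentinel for a missing genotype in the dosage matrix.
MISSING: int = -1

_COHORTS = ("twin", "control", "none")


@dataclass(frozen=True)
class Variant:
    """One biallelic SNP: chromosome, 1-based position, REF/ALT alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise InvariantError(f"variant position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise InvariantError(f"REF and ALT identical at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class SampleInfo:
    """Per-sample metadata: population label, cohort assignment, parity count."""

    sample_id: str
    population: str
    cohort: str = "none"
    parity: int = 0

    def __post_init__(self):
        if self.cohort not in _COHORTS:
            raise MetadataError(
                f"cohort for {self.sample_id!r} must be one of {_COHORTS}, got {self.cohort!r}"
            )
        if self.parity < 0:
            raise MetadataError(f"parity for {self.sample_id!r} must be non-negative")


class GenotypeTable:
    """Samples × variants dosage matrix with coordinates and sample metadata.

    ``dosage[i, j]`` is the ALT-allele count of sample ``i`` at variant ``j``
    (0, 1, 2, or :data:`MISSING`).  Variants are sorted by (chrom, pos) with
    strictly increasing positions within each chromosome; chromosome labels
    are opaque strings and are not normalized.
    """

    def __init__(
        self,
        variants: Sequence[Variant],
        samples: Sequence[SampleInfo],
        dosage: np.ndarray,
    ):
        dosage = np.asarray(dosage, dtype=np.int16)
        if dosage.shape != (len(samples), len(variants)):
            raise InvariantError(
                f"dosage shape {dosage.shape} does not match "
                f"{len(samples)} samples x {len(variants)} variants"
            )
        bad = ~np.isin(dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise InvariantError("dosage entries must be in {0,1,2} or MISSING")
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise InvariantError("sample_id values must be unique")
        self.variants = list(variants)
        self.samples = list(samples)
        self.dosage = dosage
        self.chroms = np.array([v.chrom for v in self.variants], dtype=object)
        self.positions = np.array([v.pos for v in self.variants], dtype=np.int64)
        self._check_sorted()

    def _check_sorted(self):
        seen: dict[str, int] = {}
        order: list[str] = []
        for v in self.variants:
            if v.chrom not in seen:
                seen[v.chrom] = v.pos
                order.append(v.chrom)
            else:
                if order[-1] != v.chrom:
                    raise InvariantError(f"variants not grouped by chromosome at {v.chrom}:{v.pos}")
                if v.pos <= seen[v.chrom]:
                    raise InvariantError(
                        f"positions not strictly increasing on {v.chrom} at {v.pos}"
                    )
                seen[v.chrom] = v.pos

    # -- basic accessors ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for c in self.chroms:
            if not out or out[-1] != c:
                out.append(c)
        return out

    def sample_index(self, *, population: str | None = None, cohort: str | None = None) -> np.ndarray:
        """Indices of samples matching the given population and/or cohort."""
        keep = np.ones(self.n_samples, dtype=bool)
        if population is not None:
            keep &= np.array([s.population == population for s in self.samples])
        if cohort is not None:
            keep &= np.array([s.cohort == cohort for s in self.samples])
        return np.flatnonzero(keep)

    def subset_samples(self, index: Iterable[int]) -> "GenotypeTable":
        idx = np.asarray(list(index), dtype=int)
        return GenotypeTable(
            self.variants, [self.samples[i] for i in idx], self.dosage[idx, :]
        )

    def subset_variants(self, mask: np.ndarray) -> "GenotypeTable":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask.astype(int)
        return GenotypeTable(
            [self.variants[j] for j in idx], self.samples, self.dosage[:, idx]
        )

    def variant_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chroms,
                "pos": self.positions,
                "ref": [v.ref for v in self.variants],
                "alt": [v.alt for v in self.variants],
                "id": [v.id for v in self.variants],
            }
        )


@dataclass(frozen=True)
class Gene:
    """One gene interval, 1-based inclusive."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.end < self.start:
            raise FormatError(f"gene {self.name}: end {self.end} < start {self.start}")


@dataclass
class GeneModel:
    """A set of gene intervals, optionally with per-gene exon sub-intervals."""

    genes: list[Gene]
    exons: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self):
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise FormatError("gene names must be unique")

    def by_chrom(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        for gs in out.values():
            gs.sort(key=lambda g: (g.start, g.end))
        return out


# ----------------------------------------------------------------------------
# sample sheet
# ----------------------------------------------------------------------------

def read_sample_sheet(path: str | os.PathLike) -> list[SampleInfo]:
    """Read a headered TSV with columns sample_id, population, cohort, parity."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "population", "cohort", "parity"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"sample sheet must have columns {sorted(required)}, got {list(df.columns)}"
        )
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SampleInfo(
                sample_id=str(row.sample_id),
                population=str(row.population),
                cohort=str(row.cohort),
                parity=int(row.parity),
            )
        )
    return out


def write_sample_sheet(samples: Sequence[SampleInfo], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "population": [s.population for s in samples],
            "cohort": [s.cohort for s in samples],
            "parity": [s.parity for s in samples],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------------

def read_vcf(
    path: str | os.PathLike,
    sample_sheet: str | os.PathLike | Sequence[SampleInfo] | None = None,
    multiallelic: str = "skip",
) -> GenotypeTable:
    """Read a VCF v4.x with GT into a :class:`GenotypeTable`.

    Parameters
    ----------
    path
        VCF file (plain text or bgzipped).
    sample_sheet
        TSV path or a list of :class:`SampleInfo`.  Must cover every sample
        in the VCF.  If ``None``, samples get placeholder metadata
        (population ``"unknown"``, cohort ``"none"``).
    multiallelic
        ``"skip"`` drops records with more than one ALT allele (the count is
        available as ``table.n_multiallelic_skipped``); ``"error"`` raises.

    Only the GT FORMAT field is interpreted; phase is ignored.  ``./.`` maps
    to :data:`MISSING`.  Non-diploid GT entries raise :class:`FormatError`.
    """
    if multiallelic not in ("skip", "error"):
        raise FormatError(f"multiallelic must be 'skip' or 'error', got {multiallelic!r}")
    vcf = VCF(str(path), gts012=False)
    if "ID=GT" not in vcf.raw_header:
        raise FormatError(f"{path}: VCF has no GT FORMAT field")

    meta: dict[str, SampleInfo]
    if sample_sheet is None:
        meta = {s: SampleInfo(s, "unknown") for s in vcf.samples}
    else:
        infos = (
            read_sample_sheet(sample_sheet)
            if isinstance(sample_sheet, (str, os.PathLike))
            else list(sample_sheet)
        )
        meta = {s.sample_id: s for s in infos}
        absent = [s for s in vcf.samples if s not in meta]
        if absent:
            raise MetadataError(f"samples in VCF absent from sample sheet: {absent}")

    samples = [meta[s] for s in vcf.samples]
    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            if multiallelic == "error":
                raise FormatError(
                    f"multi-allelic record at {rec.CHROM}:{rec.POS} (ALT={rec.ALT})"
                )
            n_skipped += 1
            continue
        gts = rec.genotypes
        dos = np.empty(len(samples), dtype=np.int16)
        for i, g in enumerate(gts):
            if len(g) != 3:  # two alleles + phased flag
                raise FormatError(
                    f"non-diploid GT for sample {vcf.samples[i]} at {rec.CHROM}:{rec.POS}"
                )
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                dos[i] = MISSING
            else:
                dos[i] = a + b
        variants.append(
            Variant(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
                id=None if rec.ID in (None, ".") else rec.ID,
            )
        )
        rows.append(dos)
    dosage = (
        np.stack(rows, axis=1) if rows else np.zeros((len(samples), 0), dtype=np.int16)
    )
    table = GenotypeTable(variants, samples, dosage)
    table.n_multiallelic_skipped = n_skipped  # type: ignore[attr-defined]
    return table


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(table: GenotypeTable, path: str | os.PathLike) -> None:
    """Write a minimal VCF v4.2 that round-trips through :func:`read_vcf`."""
    contig_max: dict[str, int] = {}
    for v in table.variants:
        contig_max[v.chrom] = max(contig_max.get(v.chrom, 0), v.pos)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=herdscan\n")
        for chrom, mx in contig_max.items():
            fh.write(f"##contig=<ID={chrom},length={mx + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.sample_ids)
            + "\n"
        )
        dos = table.dosage
        for j, v in enumerate(table.variants):
            gts = "\t".join(_GT_CODE[int(d)] for d in dos[:, j])
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id or '.'}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n"
            )


# ----------------------------------------------------------------------------
# gene models
# ----------------------------------------------------------------------------

def read_gene_model(path: str | os.PathLike, format: str | None = None) -> GeneModel:
    """Read a gene model from BED4(+strand) or GFF3.

    BED intervals (0-based half-open) are converted to 1-based inclusive.
    GFF3 input also collects ``exon`` features keyed to their parent gene,
    enabling exonic/intronic classification downstream.
    """
    if format is None:
        ext = os.path.splitext(str(path))[1].lower()
        format = {"bed": "BED", "gff": "GFF3", "gff3": "GFF3"}.get(ext.lstrip("."), None)
        if format is None:
            raise FormatError(f"cannot infer gene-model format from {path}")
    format = format.upper()
    if format == "BED":
        return _read_bed(path)
    if format == "GFF3":
        return _read_gff3(path)
    raise FormatError(f"unknown gene-model format {format!r}")


def _read_bed(path: str | os.PathLike) -> GeneModel:
    genes: list[Gene] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{ln}: BED gene lines need >= 4 columns")
            chrom, start0, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else "+"
            if end < start0 + 1:
                raise FormatError(f"{path}:{ln}: empty or inverted interval")
            genes.append(Gene(name=name, chrom=chrom, start=start0 + 1, end=end, strand=strand))
    return GeneModel(genes=genes)


def _read_gff3(path: str | os.PathLike) -> GeneModel:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[Gene] = []
    exons: dict[str, list[tuple[int, int]]] = {}
    id_to_name: dict[str, str] = {}
    for f in db.features_of_type("gene", order_by=("seqid", "start")):
        name = (f.attributes.get("Name") or f.attributes.get("ID") or [f.id])[0]
        id_to_name[f.id] = name
        strand = f.strand if f.strand in ("+", "-") else "+"
        genes.append(Gene(name=name, chrom=f.seqid, start=f.start, end=f.end, strand=strand))
    for f in db.features_of_type("exon"):
        for parent in db.parents(f, featuretype="gene"):
            gname = id_to_name.get(parent.id)
            if gname is not None:
                exons.setdefault(gname, []).append((f.start, f.end))
    # exon features may also name the gene directly via Parent when no mRNA level exists
    for gs in exons.values():
        gs.sort()
    return GeneModel(genes=genes, exons=exons)


def write_gene_model_bed(model: GeneModel, path: str | os.PathLike) -> None:
    """Write genes as BED6 (coordinates converted back to 0-based half-open)."""
    with open(path, "w") as fh:
        for g in model.genes:
            fh.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.name}\t0\t{g.strand}\n")
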