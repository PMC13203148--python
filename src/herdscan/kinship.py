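"""Relatedness and structure: IBS distances, GRM, PCA, neighbor-joining tree.

The IBS distance between two individuals is one minus the proportion of
alleles shared identical-by-state across loci genotyped in both (large values
mean distant relatives).  The genomic relationship matrix standardizes each
dosage by the allele frequency of the analyzed table (VanRaden/GCTA-style),
averaging over pairwise-complete variants.  PCA operates on the
frequency-standardized, mean-imputed genotype matrix; the neighbor-joining
tree is built from the IBS distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, InvariantError
from .genio import MISSING, GenotypeTable


@dataclass
class DistanceMatrix:
    """Symmetric IBS distance matrix with pair bookkeeping.

    ``incomplete`` flags pairs with zero jointly non-missing loci, whose
    distance is undefined (stored as NaN).
    """

    ids: list[str]
    D: np.ndarray
    incomplete: np.ndarray

    def __post_init__(self):
        n = len(self.ids)
        if self.D.shape != (n, n):
            raise InvariantError("distance matrix shape mismatch")

    @property
    def n_pairs(self) -> int:
        """Number of unordered distinct sample pairs, n(n−1)/2."""
        n = len(self.ids)
        return n * (n - 1) // 2

    def pair_values(self) -> np.ndarray:
        """Upper-triangle distances (one value per unordered pair)."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.D[iu]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.D, index=self.ids, columns=self.ids).to_csv(path, sep="\t")


@dataclass
class RelationshipMatrix:
    """Genomic relationship matrix (allele-frequency standardized)."""

    ids: list[str]
    G: np.ndarray

    def pair_values(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.G[iu]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.G, index=self.ids, columns=self.ids).to_csv(path, sep="\t")


@dataclass
class PCACoordinates:
    """Top-k principal-component scores with explained-variance fractions."""

    ids: list[str]
    coordinates: np.ndarray  # (n_samples, k)
    explained: np.ndarray  # (k,), non-increasing, sums to <= 1

    def to_tsv(self, path) -> None:
        k = self.coordinates.shape[1]
        df = pd.DataFrame(
            self.coordinates, index=self.ids, columns=[f"PC{i+1}" for i in range(k)]
        )
        df.to_csv(path, sep="\t")


def pair_percent(n_pairs_in_class: int, n_pairs_total: int, digits: int = 3) -> float:
    """Percentage of pairs in a class, rounded as reported in pair-contingency summaries."""
    if n_pairs_total <= 0:
        raise DataError("total pair count must be positive")
    return round(100.0 * n_pairs_in_class / n_pairs_total, digits)


def ibs_distance_matrix(table: GenotypeTable) -> DistanceMatrix:
    """IBS genetic distance: 1 − shared alleles / (2 × jointly genotyped loci).

    Per locus, two diploid genotypes with dosages ``a`` and ``b`` share
    ``2 − |a − b|`` alleles identical-by-state.
    """
    if table.n_samples < 2 or table.n_variants < 1:
        raise DataError("IBS needs >= 2 samples and >= 1 variant")
    dos = table.dosage
    ok = (dos != MISSING)
    okf = ok.astype(np.float64)
    joint = okf @ okf.T  # jointly non-missing locus counts
    # sum over loci of |a−b| decomposes over the dosage classes {0,1,2}
    ind = [((dos == g) & ok).astype(np.float64) for g in (0, 1, 2)]
    absdiff = np.zeros_like(joint)
    for g in range(3):
        for h in range(3):
            w = abs(g - h)
            if w:
                absdiff += w * (ind[g] @ ind[h].T)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = absdiff / (2.0 * joint)
    incomplete = joint == 0
    D[incomplete] = np.nan
    np.fill_diagonal(D, 0.0)
    np.fill_diagonal(incomplete, False)
    return DistanceMatrix(ids=table.sample_ids, D=D, incomplete=incomplete)


def grm(table: GenotypeTable) -> RelationshipMatrix:
    """Allele-frequency-standardized genomic relationship matrix.

    ``G[i,k]`` is the mean over pairwise-complete variants of
    ``(x_i − 2p)(x_k − 2p) / (2p(1−p))`` with ``p`` estimated from the
    table's non-missing alleles.  Monomorphic sites are skipped.
    """
    dos = table.dosage.astype(np.float64)
    ok = table.dosage != MISSING
    n_called = ok.sum(axis=0)
    alt = np.where(ok, dos, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * np.maximum(n_called, 1)), np.nan)
    poly = ok.any(axis=0) & (p > 0) & (p < 1)
    if not poly.all():
        import warnings

        warnings.warn(
            f"{int((~poly).sum())} monomorphic/undefined sites skipped in GRM",
            stacklevel=2,
        )
    dos, ok, p = dos[:, poly], ok[:, poly], p[poly]
    denom = np.sqrt(2.0 * p * (1.0 - p))
    Z = np.where(ok, (dos - 2.0 * p) / denom, 0.0)
    okf = ok.astype(np.float64)
    counts = okf @ okf.T
    with np.errstate(invalid="ignore", divide="ignore"):
        G = (Z @ Z.T) / counts
    G[counts == 0] = np.nan
    return RelationshipMatrix(ids=table.sample_ids, G=G)


def pca(table: GenotypeTable, k: int = 10) -> PCACoordinates:
    """PCA of the frequency-standardized genotypes (SVD route).

    Each variant is centered by ``2p`` and scaled by ``1/sqrt(2p(1−p))``;
    missing dosages are mean-imputed (zero after standardization).  Scores
    are left singular vectors scaled by singular values; explained fractions
    are relative to the total variance of the standardized matrix.
    """
    if table.n_samples < 2:
        raise DataError("PCA needs >= 2 samples")
    dos = table.dosage.astype(np.float64)
    ok = table.dosage != MISSING
    n_called = ok.sum(axis=0)
    alt = np.where(ok, dos, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt / (2.0 * np.maximum(n_called, 1)), np.nan)
    poly = ok.any(axis=0) & (p > 0) & (p < 1)
    dos, ok, p = dos[:, poly], ok[:, poly], p[poly]
    Z = np.where(ok, (dos - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p)), 0.0)
    Z = Z - Z.mean(axis=0)  # recenter after imputation
    rank = min(Z.shape)
    if k > rank:
        import warnings

        warnings.warn(f"k={k} exceeds rank {rank}; truncating", stacklevel=2)
        k = rank
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    total = float((s**2).sum())
    coords = U[:, :k] * s[:k]
    explained = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return PCACoordinates(ids=table.sample_ids, coordinates=coords, explained=explained)


def nj_tree(dist: DistanceMatrix) -> str:
    """Neighbor-joining tree (Saitou–Nei) from a complete distance matrix.

    Returns a Newick string.  Negative branch lengths are clamped to zero
    (scikit-bio convention).  Raises if any pair's distance is undefined.
    """
    if len(dist.ids) < 3:
        raise DataError("NJ needs >= 3 samples")
    if dist.incomplete.any() or not np.isfinite(dist.D).all():
        raise DataError("NJ requires a complete, finite distance matrix")
    import skbio
    from skbio.tree import nj as _nj

    dm = skbio.DistanceMatrix(dist.D, ids=dist.ids)
    tree = _nj(dm)
    return str(tree).strip()
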