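"""Genomic relationship matrices and single-step (H) kernel assembly.

Implements the standard single-step GBLUP plumbing: VanRaden's method-1
genomic relationship matrix G* from 0/1/2 allele counts, blending with the
pedigree submatrix A22 (default G = 0.9 G* + 0.1 A22, which also guarantees
invertibility), and the H⁻¹ construction

    H⁻¹ = A⁻¹ + [[0, 0], [0, G⁻¹ − A22⁻¹]]

with the dense correction placed on the genotyped × genotyped block of the
sparse pedigree inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as la
import scipy.sparse as sp

from .pedigree import Pedigree, RelationshipMatrix, tabular_A


class GenomicError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Allele-count genotypes (animals × SNPs, coded 0/1/2)."""

    ids: list
    codes: np.ndarray  # shape (n_animals, n_snps), int

    def __post_init__(self):
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.ids):
            raise GenomicError("genotype matrix shape does not match animal ids")
        if not np.isin(self.codes, (0, 1, 2)).all():
            raise GenomicError("genotype codes must be 0, 1 or 2")
        if len(set(self.ids)) != len(self.ids):
            raise GenomicError("duplicate animal ids in genotype matrix")

    @property
    def n_animals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Observed allele frequency p_j of the counted allele, per SNP."""
        return self.codes.mean(axis=0) / 2.0


def qc_filter(geno: GenotypeMatrix, maf_min: float = 0.01) -> GenotypeMatrix:
    """Drop SNPs whose minor-allele frequency falls below ``maf_min``.

    Frequencies are recomputed from the observed animals; monomorphic SNPs are
    removed whenever ``maf_min > 0``.
    """
    p = geno.allele_frequencies()
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= maf_min if maf_min > 0 else maf > -1.0
    if maf_min > 0:
        keep &= maf > 0
    if not keep.any():
        raise GenomicError("no SNPs survive the MAF filter")
    return GenotypeMatrix(list(geno.ids), geno.codes[:, keep])


def vanraden_G(geno: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    G* = ZZ′ / (2 Σ_j p_j (1 − p_j)) with Z = M − 2p, allele frequencies p
    computed from the observed genotypes.
    """
    p = geno.allele_frequencies()
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise GenomicError("all SNPs monomorphic: VanRaden denominator is zero")
    Z = geno.codes.astype(float) - 2.0 * p
    G = (Z @ Z.T) / denom
    return RelationshipMatrix(G, list(geno.ids), kind="G")


def blend_G(Gstar: RelationshipMatrix, A22: RelationshipMatrix, w: float = 0.9) -> RelationshipMatrix:
    """Weighted blend G = w·G* + (1−w)·A22 on a shared animal ordering."""
    if list(Gstar.ids) != list(A22.ids):
        raise GenomicError("G* and A22 animal orderings differ")
    if not 0.0 <= w <= 1.0:
        raise GenomicError("blend weight must be in [0, 1]")
    G = w * Gstar.toarray() + (1.0 - w) * A22.toarray()
    return RelationshipMatrix(G, list(Gstar.ids), kind="Gblend")


def a22_from_pedigree(ped: Pedigree, genotyped_ids) -> RelationshipMatrix:
    """Pedigree relationship submatrix for the genotyped animals."""
    A = tabular_A(ped)
    sub = A.submatrix(list(genotyped_ids))
    sub.kind = "A22"
    return sub


def h_inverse(
    a_inv: RelationshipMatrix,
    G: RelationshipMatrix,
    A22: RelationshipMatrix,
    genotyped_ids=None,
) -> RelationshipMatrix:
    """Single-step relationship inverse H⁻¹.

    Adds the dense correction G⁻¹ − A22⁻¹ onto the genotyped block of the
    sparse pedigree inverse, permuted into the pedigree's canonical animal
    order.  Unknown-parent-group equations in ``a_inv`` (if any) carry through
    untouched.
    """
    if genotyped_ids is None:
        genotyped_ids = list(G.ids)
    if list(G.ids) != list(A22.ids):
        raise GenomicError("G and A22 must be indexed identically")
    if list(genotyped_ids) != list(G.ids):
        raise GenomicError("genotyped_ids must match G's ordering")
    if len(genotyped_ids) == 0:
        return RelationshipMatrix(
            a_inv.values.copy(), list(a_inv.ids), kind="Hinv", group_ids=list(a_inv.group_ids)
        )
    try:
        Ginv = la.inv(G.toarray())
    except la.LinAlgError as err:  # pragma: no cover
        raise GenomicError("G is singular; blend with A22 first") from err
    A22inv = la.inv(A22.toarray())
    corr = Ginv - A22inv
    idx = a_inv.index_of(genotyped_ids)
    dim = a_inv.values.shape[0]
    ng = len(idx)
    P = sp.coo_matrix((np.ones(ng), (idx, np.arange(ng))), shape=(dim, ng)).tocsr()
    H = (a_inv.values.tocsr() + P @ sp.csr_matrix(corr) @ P.T).tocsr()
    Hmat = RelationshipMatrix(H, list(a_inv.ids), kind="Hinv", group_ids=list(a_inv.group_ids))
    return Hmat
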