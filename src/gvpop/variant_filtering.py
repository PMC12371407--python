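"""Site-selection rules used by the downstream analyses.

Two filters matter: the biallelic minor-allele-frequency filter that feeds the
population-structure analysis (SNPs only, exactly two observed alleles, MAF
strictly above the threshold), and the segregating-site rule that feeds the
diversity and infection-pattern analyses (alternative allele carried by
strictly more than ``min_carriers`` consensus genomes).

Both operate on consensus-level calls, are idempotent, and preserve site order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VariantMatrix",
    "SegregatingSiteSet",
    "filter_biallelic_maf",
    "find_segregating_sites",
]

MISSING = -1


@dataclass
class VariantMatrix:
    """Sites x samples haploid genotype matrix with per-sample allele depths.

    genotypes[i, j] is the allele index of sample j at site i (0 = ref,
    k >= 1 = k-th alternative allele, -1 = missing). depths[i, j] is
    (ref_count, alt_count); -1 marks unknown depth.
    """

    positions: np.ndarray  # (S,) int64, 0-based, strictly increasing
    ref: list[str]
    alt: list[tuple[str, ...]]
    variant_class: np.ndarray  # (S,) object, "SNP" | "indel"
    genotypes: np.ndarray  # (S, N) int16
    depths: np.ndarray  # (S, N, 2) int32
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.genotypes.shape != self.depths.shape[:2]:
            raise ValueError("genotype and depth arrays must share one shape")
        if self.genotypes.shape[0] != len(self.positions):
            raise ValueError("positions and genotype rows disagree")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        for i, alts in enumerate(self.alt):
            row = self.genotypes[i]
            if row.size and row.max(initial=MISSING) > len(alts):
                raise ValueError(
                    f"site {int(self.positions[i])}: genotype index exceeds allele count"
                )

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    def take_sites(self, idx: np.ndarray) -> "VariantMatrix":
        """Subset to the given site indices (order preserved)."""
        idx = np.asarray(idx)
        return VariantMatrix(
            positions=self.positions[idx],
            ref=[self.ref[i] for i in idx],
            alt=[self.alt[i] for i in idx],
            variant_class=self.variant_class[idx],
            genotypes=self.genotypes[idx],
            depths=self.depths[idx],
            sample_ids=list(self.sample_ids),
        )

    def alt_frequency(self) -> np.ndarray:
        """Per-site fraction of non-missing consensus calls that are alternative."""
        called = self.genotypes != MISSING
        n_called = called.sum(axis=1)
        n_alt = (self.genotypes > 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, n_alt / np.maximum(n_called, 1), np.nan)


@dataclass(frozen=True)
class SegregatingSiteSet:
    """Positions whose alternative allele is carried by > min_carrier_count samples."""

    positions: np.ndarray
    min_carrier_count: int

    def __len__(self) -> int:
        return len(self.positions)


def filter_biallelic_maf(matrix: VariantMatrix, maf: float = 0.05) -> VariantMatrix:
    """Retain biallelic SNPs with minor allele frequency strictly above ``maf``.

    Mirrors the conventional ``--max-alleles 2 --maf 0.05 --remove-indels``
    site selection: indels out, sites with other than exactly two *observed*
    alleles out, and MAF computed over non-missing haploid calls only.
    """
    if matrix.n_sites == 0:
        return matrix
    keep = np.zeros(matrix.n_sites, dtype=bool)
    for i in range(matrix.n_sites):
        if matrix.variant_class[i] != "SNP":
            continue
        calls = matrix.genotypes[i]
        observed = calls[calls != MISSING]
        if observed.size == 0:
            continue
        alleles, counts = np.unique(observed, return_counts=True)
        if len(alleles) != 2:
            continue
        if counts.min() / observed.size > maf:
            keep[i] = True
    if not keep.any():
        warnings.warn("MAF filter removed every site", stacklevel=2)
    return matrix.take_sites(np.flatnonzero(keep))


def find_segregating_sites(
    matrix: VariantMatrix, min_carriers: int = 7
) -> SegregatingSiteSet:
    """Sites whose alternative allele is carried by strictly more than
    ``min_carriers`` samples (consensus-level calls; missing calls are not
    carriers). With ``min_carriers=0`` this returns exactly the polymorphic
    sites.
    """
    carriers = (matrix.genotypes > 0).sum(axis=1)
    keep = carriers > min_carriers
    return SegregatingSiteSet(
        positions=matrix.positions[keep].copy(), min_carrier_count=min_carriers
    )
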