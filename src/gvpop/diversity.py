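"""Nucleotide-diversity statistics for the epidemic cohort.

Between-host diversity is computed from consensus calls as the sample-size
corrected heterozygosity per site,

    pi_site = n/(n-1) * (1 - sum_a f_a^2),

averaged over a chosen site set; this is algebraically identical to the mean
number of pairwise differences per site, and the identity is used as the test
oracle. Within-host diversity is computed from read-level alternative-allele
frequencies with the unbiased read-pair correction

    pi_site = 2 p (1-p) * D/(D-1),

where D is the read depth at the site. Watterson's theta per ORF is the
segregating-site count scaled by the harmonic number of the sample size and
the ORF length: theta = S / (a_n * L), a_n = sum_{i=1}^{n-1} 1/i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import FunctionalGroup, OrfAnnotation
from .variant_filtering import MISSING, SegregatingSiteSet, VariantMatrix

__all__ = [
    "AlleleProfile",
    "DiversitySummary",
    "pi_between_hosts",
    "pi_within_host",
    "watterson_theta",
    "theta_per_orf",
    "dN_density_by_group",
    "profiles_from_matrix",
    "harmonic_number",
]


@dataclass
class AlleleProfile:
    """One isolate's alternative-allele frequencies and depths at chosen sites."""

    sample_id: str
    positions: np.ndarray  # (M,) int64
    p: np.ndarray  # (M,) float, alt frequency in [0, 1]
    depth: np.ndarray  # (M,) int, read depth >= 1

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.p = np.asarray(self.p, dtype=float)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if len(np.unique(self.positions)) != len(self.positions):
            raise ValueError(f"{self.sample_id}: duplicate positions in profile")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError(f"{self.sample_id}: allele frequency outside [0, 1]")
        if np.any(self.depth < 1):
            raise ValueError(f"{self.sample_id}: included entries need depth >= 1")


@dataclass
class DiversitySummary:
    pi_between: float
    pi_within: dict[str, float]
    pi_all_sites: float
    theta_per_orf: dict[str, float] = field(default_factory=dict)
    dN_per_orf: dict[str, int] = field(default_factory=dict)
    group_dN_density: dict[str, float] = field(default_factory=dict)


def harmonic_number(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i (Watterson's normalizer for n sequences)."""
    return float(np.sum(1.0 / np.arange(1, n)))


def _select_site_indices(
    matrix: VariantMatrix, sites: SegregatingSiteSet | Sequence[int] | None
) -> np.ndarray:
    if sites is None:
        return np.arange(matrix.n_sites)
    wanted = sites.positions if isinstance(sites, SegregatingSiteSet) else np.asarray(sites)
    idx = np.flatnonzero(np.isin(matrix.positions, wanted))
    return idx


def pi_between_hosts(
    matrix: VariantMatrix,
    sites: SegregatingSiteSet | Sequence[int] | None = None,
    total_length: int | None = None,
) -> float:
    """Mean per-site nucleotide diversity across hosts from consensus calls.

    ``sites`` restricts the calculation (e.g. to segregating sites); the mean
    is taken over those sites. If ``total_length`` is given, the per-site sum
    is divided by it instead — the genome-wide scale, where monomorphic
    positions contribute zero.

    Sites with fewer than two non-missing calls are skipped with a warning.
    """
    if matrix.n_samples < 2:
        raise ValueError("pi_between_hosts needs at least 2 samples")
    idx = _select_site_indices(matrix, sites)
    if idx.size == 0:
        raise ValueError("empty site set")
    per_site: list[float] = []
    skipped = 0
    for i in idx:
        calls = matrix.genotypes[i]
        observed = calls[calls != MISSING]
        n = observed.size
        if n < 2:
            skipped += 1
            continue
        _, counts = np.unique(observed, return_counts=True)
        f = counts / n
        per_site.append(n / (n - 1) * (1.0 - float(np.sum(f**2))))
    if skipped:
        warnings.warn(f"skipped {skipped} sites with < 2 non-missing calls", stacklevel=2)
    if not per_site:
        raise ValueError("no usable sites for pi_between_hosts")
    denom = total_length if total_length is not None else len(per_site)
    return float(np.sum(per_site) / denom)


def pi_within_host(
    profile: AlleleProfile,
    sites: SegregatingSiteSet | Sequence[int],
    corrected: bool = True,
) -> float:
    """Within-host nucleotide diversity over a site set.

    Per site, ``2 p (1-p) * D/(D-1)`` (the unbiased read-pair estimator;
    ``corrected=False`` drops the depth correction). Sites absent from the
    profile count as fixed reference (p = 0); sites with depth < 2 are
    skipped.
    """
    wanted = sites.positions if isinstance(sites, SegregatingSiteSet) else np.asarray(sites)
    if len(wanted) == 0:
        raise ValueError("empty site set: within-host pi undefined")
    pos_to_idx = {int(pos): k for k, pos in enumerate(profile.positions)}
    vals: list[float] = []
    for pos in wanted:
        k = pos_to_idx.get(int(pos))
        if k is None:
            vals.append(0.0)  # absent entry: fixed reference allele
            continue
        d = int(profile.depth[k])
        if d < 2:
            continue
        p = float(profile.p[k])
        h = 2.0 * p * (1.0 - p)
        vals.append(h * d / (d - 1) if corrected else h)
    if not vals:
        raise ValueError("no usable sites (all depths < 2)")
    return float(np.mean(vals))


def watterson_theta(S: int, n: int, L: int) -> float:
    """Watterson's theta per site: S / (a_n * L)."""
    if n < 2:
        raise ValueError("watterson_theta needs n >= 2 sequences")
    if L < 1:
        raise ValueError("sequence length must be >= 1")
    if S == 0:
        return 0.0
    return S / (harmonic_number(n) * L)


def count_segregating_in_span(
    matrix: VariantMatrix, start: int, end: int, snps_only: bool = True
) -> int:
    """Polymorphic columns (>= 2 observed alleles) within [start, end)."""
    in_span = (matrix.positions >= start) & (matrix.positions < end)
    count = 0
    for i in np.flatnonzero(in_span):
        if snps_only and matrix.variant_class[i] != "SNP":
            continue
        calls = matrix.genotypes[i]
        observed = calls[calls != MISSING]
        if observed.size and len(np.unique(observed)) > 1:
            count += 1
    return count


def theta_per_orf(
    matrix: VariantMatrix, orfs: Sequence[OrfAnnotation], n: int | None = None
) -> dict[str, float]:
    """Per-ORF Watterson's theta from the cohort variant matrix."""
    n = matrix.n_samples if n is None else n
    out: dict[str, float] = {}
    for orf in orfs:
        S = count_segregating_in_span(matrix, orf.start, orf.end)
        out[orf.name] = watterson_theta(S, n, orf.length)
    return out


def dN_density_by_group(
    dN_per_orf: Mapping[str, int], orfs: Sequence[OrfAnnotation]
) -> dict[str, float]:
    """Mean nonsynonymous-SNP density (per kbp) per functional group.

    Per ORF the density is count / (length in kbp); per group the mean over
    member ORFs. Groups without ORFs are omitted with a warning.
    """
    per_group: dict[str, list[float]] = {g.value: [] for g in FunctionalGroup}
    for orf in orfs:
        count = int(dN_per_orf.get(orf.name, 0))
        per_group[orf.functional_group.value].append(count / (orf.length / 1000.0))
    out: dict[str, float] = {}
    for group, vals in per_group.items():
        if not vals:
            warnings.warn(f"functional group {group!r} has no ORFs; omitted", stacklevel=2)
            continue
        out[group] = float(np.mean(vals))
    return out


def profiles_from_matrix(
    matrix: VariantMatrix, min_depth: int = 1
) -> dict[str, AlleleProfile]:
    """Build per-sample AlleleProfiles from the matrix's AD fields.

    p = alt_count / (ref_count + alt_count); sites with unknown or sub-minimum
    depth are omitted from that sample's profile.
    """
    profiles: dict[str, AlleleProfile] = {}
    ref_d = matrix.depths[:, :, 0]
    alt_d = matrix.depths[:, :, 1]
    total = ref_d + alt_d
    for j, sid in enumerate(matrix.sample_ids):
        ok = (ref_d[:, j] >= 0) & (total[:, j] >= min_depth) & (total[:, j] > 0)
        idx = np.flatnonzero(ok)
        profiles[sid] = AlleleProfile(
            sample_id=sid,
            positions=matrix.positions[idx],
            p=alt_d[idx, j] / total[idx, j],
            depth=total[idx, j],
        )
    return profiles
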