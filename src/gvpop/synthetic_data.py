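"""Synthetic multi-wave granulovirus epidemic cohorts.

The generator emulates the sampling design of a multi-year field study of a
granulovirus epidemic on double-cropped rice: a persistent soil reservoir of
virus strains, an annual starting pool that is a random subset of that
reservoir, two rice-growing seasons per year, and three epidemic waves per
season linked by transmission with founder bottlenecks. Hosts carry one, two,
or more strains (mixed infections) with Dirichlet proportions, and each host
is "sequenced" by Poisson read depths with binomial alternative-allele counts,
from which a consensus genome is taken as the per-site majority allele.

Every file the real-data path consumes (consensus FASTA, multi-sample VCF with
AD depths, metadata CSV, ORF GFF3) can be emitted, together with a ground-truth
JSON for recovery tests. One seeded generator drives all randomness.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (
    FunctionalGroup,
    GenomeRecord,
    IsolateMeta,
    OrfAnnotation,
    Season,
    Wave,
    write_consensus_set,
    write_metadata,
    write_orfs,
    write_variants,
)
from .variant_effects import HR_MOTIF
from .variant_filtering import VariantMatrix

__all__ = [
    "SimConfig",
    "Reservoir",
    "HostTruth",
    "SimTruth",
    "Cohort",
    "build_reservoir",
    "simulate_season",
    "simulate_cohort",
    "emit_cohort",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for the synthetic epidemic.

    Defaults mirror the field study's design: a ~112 kb, 35% GC circular
    genome, 4 years x 2 rice seasons x 3 waves, strong founder bottlenecks
    (20/5/2 are working values for recovery tests; the study reports no
    quantitative bottleneck sizes), and a single-/two-/multi-strain infection
    mix of roughly 61/14/25% matching the observed pattern frequencies.
    """

    genome_length: int = 112_000
    gc_content: float = 0.35
    n_years: int = 4
    start_year: int = 2017
    seasons_per_year: int = 2
    waves_per_season: int = 3
    reservoir_size: int = 80
    year_pool_size: int = 20
    reservoir_mutation_rate: float = 5e-4
    # the soil reservoir is structured into annual lineages (clades): each
    # clade carries shared substitutions at this rate on top of every
    # strain's private ones, so isolates from the same year are mutually
    # closer than isolates from different years. 0 gives an unstructured
    # (star-phylogeny) pool.
    clade_mutation_rate: float = 2.5e-3
    n_clades: int | None = None  # defaults to n_years
    # granuloviruses recombine freely during co-infection, so a lineage
    # behaves like a small recombining population: each lineage variant
    # segregates within its clade at an alt frequency drawn Beta(a, b)
    # (mass near fixation, a tail of intermediate frequencies) and strains
    # carry it independently per site. None fixes every lineage variant in
    # all clade members (clonal, non-recombining pool).
    clade_frequency_shape: tuple[float, float] | None = (5.0, 1.0)
    # co-infection recombination: each within-host lineage is a per-site
    # mosaic of two parent strains from the wave's founder pool, so every
    # isolate carries a fresh recombinant haplotype. False transmits intact
    # clonal haplotypes.
    recombination: bool = True
    # fraction of a year's starting pool drawn from other annual lineages:
    # the soil reservoir persists across years, so a minority of each
    # season's founders are older strains. Drives the divergent mixed
    # infections seen in the field.
    pool_migration: float = 0.1
    founder_count_per_wave: tuple[int, ...] = (20, 5, 2)
    hosts_per_wave: int = 6
    mixture_concentration: float = 1.0
    # P(1 strain), P(2 strains), P(>2 strains) per host; a tuple of three
    # tuples gives per-wave probabilities. Mixed infections are common in the
    # first wave (large environmental inoculum) and rare by the third
    # (faecal-transmission bottleneck); the cohort-wide average is the
    # observed ~61/14/25% single/two/multi split.
    multiplicity_probs: tuple = (
        (0.30, 0.25, 0.45),
        (0.45, 0.28, 0.27),
        (0.80, 0.12, 0.08),
    )
    min_strain_proportion: float = 0.0
    max_strains_per_host: int = 4
    read_depth: float = 200.0
    # per-read miscall probability; gives single-strain isolates the ~0.001
    # within-host diversity floor real sequencing shows
    sequencing_error_rate: float = 1e-3
    # per-host, per-site probability that the read pile-up reflects the wrong
    # template (mis-mapping / whole-genome-amplification artifact): the
    # sampled allele frequency flips to 1 - p. Gives each consensus genome
    # the idiosyncratic noise floor real assemblies show.
    artifact_rate: float = 5e-3
    n_hr_regions: int = 12
    hr_repeats_per_region: int = 4
    n_orfs: int = 120
    total_isolates: int | None = 138
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")
        for name in ("genome_length", "n_years", "seasons_per_year",
                     "waves_per_season", "reservoir_size", "hosts_per_wave"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 1 <= self.waves_per_season <= 3:
            raise ValueError("waves_per_season must be 1..3 (waves W1-W3)")
        if len(self.founder_count_per_wave) != self.waves_per_season:
            raise ValueError("founder_count_per_wave needs one entry per wave")
        probs = self.wave_multiplicity(0)
        for w in range(self.waves_per_season):
            p = self.wave_multiplicity(w)
            if abs(sum(p) - 1.0) > 1e-9:
                raise ValueError("multiplicity_probs must sum to 1")
        del probs

    def wave_multiplicity(self, wave_index: int) -> tuple[float, float, float]:
        mp = self.multiplicity_probs
        if mp and isinstance(mp[0], (tuple, list)):
            return tuple(mp[wave_index])  # type: ignore[return-value]
        return tuple(mp)  # type: ignore[return-value]


@dataclass
class Reservoir:
    """Soil-reservoir strain pool: one reference plus substitution haplotypes."""

    reference: str
    positions: np.ndarray  # (S,) polymorphic sites, sorted
    alt_bases: list[str]  # one alternative base per site
    carriers: np.ndarray  # (n_strains, S) bool: strain carries the alt allele
    orfs: list[OrfAnnotation]
    clade_of: np.ndarray | None = None  # (n_strains,) annual-lineage index

    @property
    def n_strains(self) -> int:
        return self.carriers.shape[0]

    @property
    def n_sites(self) -> int:
        return self.carriers.shape[1]

    def strain_sequence(self, strain: int) -> str:
        seq = np.frombuffer(self.reference.encode(), dtype=np.uint8).copy()
        for k in np.flatnonzero(self.carriers[strain]):
            seq[self.positions[k]] = ord(self.alt_bases[k])
        return seq.tobytes().decode()


@dataclass
class HostTruth:
    sample_id: str
    year: int
    season: str
    wave: str
    strains: list[int]  # reservoir strain indices
    proportions: list[float]

    @property
    def n_strains(self) -> int:
        return len(self.strains)


@dataclass
class SimTruth:
    seed: int
    hosts: list[HostTruth]
    positions: list[int]
    alt_bases: list[str]
    strain_carrier_sites: dict[int, list[int]] = field(default_factory=dict)


@dataclass
class Cohort:
    config: SimConfig
    reservoir: Reservoir
    matrix: VariantMatrix
    genomes: list[GenomeRecord]
    metas: list[IsolateMeta]
    truth: SimTruth


# ---------------------------------------------------------------------------
# Reference genome with planted features


def _random_reference(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = rng.choice(_BASES, size=config.genome_length, p=probs)
    return seq


def _plant_features(
    seq: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> list[OrfAnnotation]:
    """Overwrite hr clusters into the reference and lay ORFs between them."""
    L = config.genome_length
    motif = np.frombuffer(HR_MOTIF.encode(), dtype=np.uint8)
    spacer = 20
    hr_len = config.hr_repeats_per_region * (len(motif) + spacer)
    hr_spans: list[tuple[int, int]] = []
    if config.n_hr_regions > 0 and L > config.n_hr_regions * (hr_len + 600):
        anchors = np.linspace(0, L - hr_len - 1, config.n_hr_regions, dtype=int)
        for a in anchors:
            pos = int(a)
            for _ in range(config.hr_repeats_per_region):
                seq[pos : pos + len(motif)] = motif
                pos += len(motif) + spacer
            hr_spans.append((int(a), pos))
    # ORFs fill the gaps between hr regions, lengths a multiple of 3
    gaps: list[tuple[int, int]] = []
    prev = 0
    for s, e in hr_spans + [(L, L)]:
        if s - prev > 300:
            gaps.append((prev, s))
        prev = e
    total_gap = sum(e - s for s, e in gaps)
    orfs: list[OrfAnnotation] = []
    groups = list(FunctionalGroup)
    i = 0
    for gs, ge in gaps:
        n_here = max(1, round(config.n_orfs * (ge - gs) / total_gap))
        bounds = np.linspace(gs, ge, n_here + 1, dtype=int)
        jitter = rng.integers(-150, 151, size=len(bounds))
        jitter[0] = jitter[-1] = 0
        bounds = np.maximum.accumulate(bounds + jitter)
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            start = b0 + 15
            end = start + ((b1 - start - 15) // 3) * 3
            if end - start < 90:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            orf = OrfAnnotation(
                name=f"orf{i + 1:03d}",
                start=int(start),
                end=int(end),
                strand=strand,
                functional_group=groups[int(rng.integers(len(groups)))],
            )
            # give the ORF a proper start and stop codon in the reference
            atg = np.frombuffer(b"ATG", dtype=np.uint8)
            taa = np.frombuffer(b"TAA", dtype=np.uint8)
            cat = np.frombuffer(b"CAT", dtype=np.uint8)
            tta = np.frombuffer(b"TTA", dtype=np.uint8)
            if strand == "+":
                seq[orf.start : orf.start + 3] = atg
                seq[orf.end - 3 : orf.end] = taa
            else:
                seq[orf.end - 3 : orf.end] = cat  # revcomp(ATG)
                seq[orf.start : orf.start + 3] = tta  # revcomp(TAA)
            orfs.append(orf)
            i += 1
    return orfs


def build_reservoir(
    config: SimConfig, rng: np.random.Generator | None = None
) -> Reservoir:
    """Derive ``reservoir_size`` haplotypes from one random reference genome.

    Each strain receives substitutions at ``reservoir_mutation_rate`` per
    site; the truth table records every polymorphic site and which strains
    carry the alternative allele. Each site has a single pre-drawn alternative
    base, so the pool is biallelic.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    seq = _random_reference(config, rng)
    orfs = _plant_features(seq, config, rng)
    L = config.genome_length
    mu = config.reservoir_mutation_rate
    # one alternative base per genome position, distinct from the reference
    shift = rng.integers(1, 4, size=L)
    ref_idx = np.searchsorted(_BASES, seq)
    alt_all = _BASES[(ref_idx + shift) % 4]
    n_clades = config.n_clades if config.n_clades is not None else config.n_years
    clade_of = np.arange(config.reservoir_size) % max(n_clades, 1)
    clade_sites: list[np.ndarray] = []
    clade_freqs: list[np.ndarray] = []
    for _ in range(max(n_clades, 1)):
        n_mut = rng.binomial(L, config.clade_mutation_rate)
        sites = rng.choice(L, size=n_mut, replace=False) if n_mut else np.empty(0, int)
        clade_sites.append(np.sort(sites))
        if config.clade_frequency_shape is None:
            clade_freqs.append(np.ones(n_mut))
        else:
            a, b = config.clade_frequency_shape
            clade_freqs.append(rng.beta(a, b, size=n_mut))
    mutated: list[np.ndarray] = []
    for s in range(config.reservoir_size):
        n_mut = rng.binomial(L, mu)
        sites = rng.choice(L, size=n_mut, replace=False) if n_mut else np.empty(0, int)
        c = clade_of[s]
        carried = clade_sites[c][rng.random(len(clade_sites[c])) < clade_freqs[c]]
        mutated.append(np.unique(np.concatenate([sites, carried])))
    union = np.unique(np.concatenate(mutated)) if any(len(m) for m in mutated) else np.empty(0, int)
    if union.size == 0:
        warnings.warn(
            "zero polymorphic sites in reservoir; downstream diversity degenerates to 0",
            stacklevel=2,
        )
    carriers = np.zeros((config.reservoir_size, union.size), dtype=bool)
    for s, sites in enumerate(mutated):
        carriers[s, np.searchsorted(union, sites)] = True
    return Reservoir(
        reference=seq.tobytes().decode(),
        positions=union.astype(np.int64),
        alt_bases=[chr(b) for b in alt_all[union]],
        carriers=carriers,
        orfs=orfs,
        clade_of=clade_of,
    )


# ---------------------------------------------------------------------------
# Transmission and observation


def _draw_proportions(
    k: int, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    conc = np.full(k, config.mixture_concentration)
    for _ in range(500):
        p = rng.dirichlet(conc)
        if k == 1 or p.min() >= config.min_strain_proportion:
            return p
    return np.full(k, 1.0 / k)  # fallback: even mixture


def _observe_host(
    p_true: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(genotype, ref_reads, alt_reads) at every truth site."""
    e = config.sequencing_error_rate
    p_true = np.clip(p_true, 0.0, 1.0)  # guard float roundoff in proportion sums
    if config.artifact_rate > 0:
        flip = rng.random(p_true.shape) < config.artifact_rate
        p_true = np.where(flip, 1.0 - p_true, p_true)
    p_obs = p_true * (1 - e) + (1 - p_true) * e
    depth = rng.poisson(config.read_depth, size=p_true.shape)
    alt = rng.binomial(depth, p_obs)
    ref = depth - alt
    geno = np.where(depth == 0, -1, (alt * 2 > depth).astype(np.int16))
    return geno.astype(np.int16), ref, alt


def simulate_season(
    reservoir: Reservoir,
    pool_strains: Sequence[int],
    config: SimConfig,
    rng: np.random.Generator,
    year: int,
    season: Season,
    sample_prefix: str = "DH",
    start_index: int = 1,
) -> tuple[list[HostTruth], np.ndarray, np.ndarray, list[IsolateMeta]]:
    """Simulate one rice-growing season: waves linked by founder bottlenecks.

    Wave 1 founders are drawn from the season's pool; each later wave's
    founders are resampled multinomially from the realized strain content of
    the previous wave. Returns (host truths, genotype matrix (S x H),
    depth array (S x H x 2), metadata).
    """
    pool_strains = np.asarray(pool_strains, dtype=int)
    if pool_strains.size == 0:
        raise ValueError("empty strain pool")
    hosts: list[HostTruth] = []
    genos: list[np.ndarray] = []
    depths: list[np.ndarray] = []
    metas: list[IsolateMeta] = []
    waves = [Wave.W1, Wave.W2, Wave.W3][: config.waves_per_season]
    founder_strains = np.empty(0, int)
    founder_weights = np.empty(0, float)
    idx = start_index
    for w, wave in enumerate(waves):
        F = config.founder_count_per_wave[w]
        if w == 0:
            if F > pool_strains.size:
                warnings.warn(
                    f"founder count {F} exceeds pool size {pool_strains.size}; capped",
                    stacklevel=2,
                )
                F = pool_strains.size
            founders = rng.choice(pool_strains, size=F, replace=False)
            founder_strains, counts = np.unique(founders, return_counts=True)
            founder_weights = counts / counts.sum()
        else:
            draw = rng.choice(founder_strains, size=F, replace=True, p=founder_weights)
            founder_strains, counts = np.unique(draw, return_counts=True)
            founder_weights = counts / counts.sum()
        probs = config.wave_multiplicity(w)
        wave_content = np.zeros(founder_strains.size)
        for _ in range(config.hosts_per_wave):
            cat = rng.choice(3, p=probs)
            if cat == 0:
                k = 1
            elif cat == 1:
                k = 2
            else:
                k = int(rng.integers(3, config.max_strains_per_host + 1))
            k = min(k, founder_strains.size)
            chosen = rng.choice(
                founder_strains.size, size=k, replace=False, p=founder_weights
            )
            strains = founder_strains[chosen]
            props = _draw_proportions(k, config, rng)
            contrib = np.zeros(founder_strains.size)
            if config.recombination and founder_strains.size > 1:
                # each lineage is a per-site mosaic of its founder and a
                # second parent from the wave pool (co-infection recombination)
                lineages = np.empty((k, reservoir.n_sites), dtype=float)
                for li in range(k):
                    pb = rng.choice(founder_strains.size, p=founder_weights)
                    take_a = rng.random(reservoir.n_sites) < 0.5
                    lineages[li] = np.where(
                        take_a,
                        reservoir.carriers[founder_strains[chosen[li]]],
                        reservoir.carriers[founder_strains[pb]],
                    )
                    contrib[chosen[li]] += props[li] / 2
                    contrib[pb] += props[li] / 2
            else:
                lineages = reservoir.carriers[strains].astype(float)
                contrib[chosen] += props
            p_true = props @ lineages
            geno, ref_r, alt_r = _observe_host(p_true, config, rng)
            sid = f"{sample_prefix}{idx:03d}"
            idx += 1
            hosts.append(
                HostTruth(
                    sample_id=sid,
                    year=year,
                    season=season.value,
                    wave=wave.value,
                    strains=[int(s) for s in strains],
                    proportions=[float(x) for x in props],
                )
            )
            genos.append(geno)
            depths.append(np.stack([ref_r, alt_r], axis=-1))
            metas.append(IsolateMeta(sid, year, season, wave))
            wave_content += contrib
        total = wave_content.sum()
        if total > 0:
            keep = wave_content > 0
            founder_strains = founder_strains[keep]
            founder_weights = wave_content[keep] / total
    G = np.stack(genos, axis=1) if genos else np.empty((reservoir.n_sites, 0), np.int16)
    D = (
        np.stack(depths, axis=1)
        if depths
        else np.empty((reservoir.n_sites, 0, 2), np.int64)
    )
    return hosts, G, D.astype(np.int32), metas


def _consensus_genomes(
    reservoir: Reservoir, genotypes: np.ndarray, metas: Sequence[IsolateMeta]
) -> list[GenomeRecord]:
    ref = np.frombuffer(reservoir.reference.encode(), dtype=np.uint8)
    alt = np.frombuffer("".join(reservoir.alt_bases).encode(), dtype=np.uint8)
    out: list[GenomeRecord] = []
    for j, m in enumerate(metas):
        seq = ref.copy()
        carried = genotypes[:, j] == 1
        seq[reservoir.positions[carried]] = alt[carried]
        out.append(GenomeRecord(sample_id=m.sample_id, sequence=seq.tobytes().decode()))
    return out


def simulate_cohort(config: SimConfig, build_genomes: bool = True) -> Cohort:
    """Simulate the full multi-year cohort.

    Each year's starting pool is a random subset of the reservoir
    (non-overlapping across years while the reservoir lasts), every season
    runs the three-wave transmission chain, and the result is assembled into
    a VariantMatrix over all reservoir truth sites plus consensus genomes,
    metadata, and ground truth.
    """
    rng = np.random.default_rng(config.seed)
    reservoir = build_reservoir(config, rng)
    n_clades = config.n_clades if config.n_clades is not None else config.n_years
    all_hosts: list[HostTruth] = []
    all_G: list[np.ndarray] = []
    all_D: list[np.ndarray] = []
    all_meta: list[IsolateMeta] = []
    counter = 1
    for y in range(config.n_years):
        # each year's starting pool is a random subset of one annual lineage,
        # plus a minority of older strains persisting in the soil reservoir
        clade_strains = np.flatnonzero(reservoir.clade_of == (y % max(n_clades, 1)))
        other_strains = np.flatnonzero(reservoir.clade_of != (y % max(n_clades, 1)))
        n_mig = int(round(config.pool_migration * config.year_pool_size))
        n_mig = min(n_mig, other_strains.size)
        n_own = min(config.year_pool_size - n_mig, clade_strains.size)
        pool = np.concatenate(
            [
                rng.choice(clade_strains, size=n_own, replace=False),
                rng.choice(other_strains, size=n_mig, replace=False),
            ]
        )
        year = config.start_year + y
        for s in range(config.seasons_per_year):
            season = Season.EARLY if s == 0 else Season.LATE
            hosts, G, D, metas = simulate_season(
                reservoir, pool, config, rng, year, season, start_index=counter
            )
            counter += len(hosts)
            all_hosts.extend(hosts)
            all_G.append(G)
            all_D.append(D)
            all_meta.extend(metas)
    G = np.concatenate(all_G, axis=1)
    D = np.concatenate(all_D, axis=1)
    if config.total_isolates is not None and config.total_isolates < len(all_meta):
        keep = np.sort(
            rng.choice(len(all_meta), size=config.total_isolates, replace=False)
        )
        all_hosts = [all_hosts[i] for i in keep]
        all_meta = [all_meta[i] for i in keep]
        G = G[:, keep]
        D = D[:, keep]
    matrix = VariantMatrix(
        positions=reservoir.positions,
        ref=[reservoir.reference[p] for p in reservoir.positions],
        alt=[(b,) for b in reservoir.alt_bases],
        variant_class=np.array(["SNP"] * reservoir.n_sites, dtype=object),
        genotypes=G,
        depths=D,
        sample_ids=[m.sample_id for m in all_meta],
    )
    genomes = _consensus_genomes(reservoir, G, all_meta) if build_genomes else []
    truth = SimTruth(
        seed=config.seed,
        hosts=all_hosts,
        positions=[int(p) for p in reservoir.positions],
        alt_bases=list(reservoir.alt_bases),
        strain_carrier_sites={
            int(s): [int(i) for i in np.flatnonzero(reservoir.carriers[s])]
            for s in range(reservoir.n_strains)
        },
    )
    return Cohort(
        config=config,
        reservoir=reservoir,
        matrix=matrix,
        genomes=genomes,
        metas=all_meta,
        truth=truth,
    )


def emit_cohort(cohort: Cohort, outdir: str | Path, overwrite: bool = False) -> dict[str, Path]:
    """Write consensus.fasta, variants.vcf, metadata.csv, orfs.gff3, truth.json."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"{outdir} exists and is non-empty; pass overwrite=True")
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "consensus.fasta",
        "reference": outdir / "reference.fasta",
        "vcf": outdir / "variants.vcf",
        "metadata": outdir / "metadata.csv",
        "gff": outdir / "orfs.gff3",
        "truth": outdir / "truth.json",
    }
    genomes = cohort.genomes or _consensus_genomes(
        cohort.reservoir, cohort.matrix.genotypes, cohort.metas
    )
    write_consensus_set(genomes, paths["fasta"])
    write_consensus_set(
        [GenomeRecord(sample_id="CnmeGV_sim", sequence=cohort.reservoir.reference)],
        paths["reference"],
    )
    write_variants(
        cohort.matrix,
        paths["vcf"],
        contig="CnmeGV_sim",
        contig_length=cohort.config.genome_length,
    )
    write_metadata(cohort.metas, paths["metadata"])
    write_orfs(cohort.reservoir.orfs, paths["gff"], contig="CnmeGV_sim")
    truth = {
        "seed": cohort.truth.seed,
        "positions": cohort.truth.positions,
        "alt_bases": cohort.truth.alt_bases,
        "hosts": [asdict(h) for h in cohort.truth.hosts],
        "strain_carrier_sites": cohort.truth.strain_carrier_sites,
    }
    paths["truth"].write_text(json.dumps(truth))
    return paths
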