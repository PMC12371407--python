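"""Readers and writers for every external representation the pipeline touches.

Internal coordinates are 0-based half-open everywhere; VCF and GFF3 stay 1-based
at the file boundary, so ``internal = file_position - 1`` is the single
conversion point. Haploid genotypes are canonical (a granulovirus consensus is
effectively clonal); diploid GT input is accepted and collapsed to the
better-supported allele with a warning.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .variant_filtering import VariantMatrix

__all__ = [
    "Season",
    "Wave",
    "FunctionalGroup",
    "IsolateMeta",
    "GenomeRecord",
    "OrfAnnotation",
    "read_consensus_set",
    "write_consensus_set",
    "read_variants",
    "write_variants",
    "read_metadata",
    "write_metadata",
    "read_orfs",
    "write_orfs",
    "write_results",
    "read_results",
    "validate_cohort",
]

_DNA_ALPHABET = frozenset("ACGTN")


class Season(str, enum.Enum):
    """Rice-growing season within a year (double-cropped paddies)."""

    EARLY = "EARLY"
    LATE = "LATE"


class Wave(str, enum.Enum):
    """Successive epidemic waves within one rice-growing season."""

    W1 = "W1"
    W2 = "W2"
    W3 = "W3"

    @property
    def ordinal(self) -> int:
        return int(self.value[1])


class FunctionalGroup(str, enum.Enum):
    REPLICATION = "replication"
    TRANSCRIPTION = "transcription"
    PER_OS_INFECTION = "per_os_infection"
    VIRION_ASSEMBLY_PACKAGING = "virion_assembly_packaging"
    AUXILIARY = "auxiliary"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class IsolateMeta:
    """Sample id plus its epidemic labels (year, season, wave).

    Labels may be None for structure-only runs but never for trend analyses.
    """

    sample_id: str
    year: int | None
    season: Season | None
    wave: Wave | None


@dataclass
class GenomeRecord:
    """One consensus genome in reference coordinates."""

    sample_id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.sample_id!r}")
        seq = self.sequence.upper()
        bad = set(seq) - _DNA_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(seq) if c in bad)
            raise ValueError(
                f"record {self.sample_id!r}: non-ACGTN character "
                f"{seq[pos]!r} at position {pos}"
            )
        self.sequence = seq

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfAnnotation:
    """An annotated ORF, 0-based half-open on the reference."""

    name: str
    start: int
    end: int
    strand: str
    functional_group: FunctionalGroup = FunctionalGroup.UNKNOWN

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"ORF {self.name!r}: end must exceed start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"ORF {self.name!r}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start

    def coding_sequence(self, genome: str) -> str:
        """Coding-strand sequence; reverse complement of the slice for '-' ORFs."""
        s = genome[self.start : self.end]
        return str(Seq(s).reverse_complement()) if self.strand == "-" else s


# ---------------------------------------------------------------------------
# FASTA


def read_consensus_set(path: str | Path) -> list[GenomeRecord]:
    """Read a multi-FASTA of consensus genomes into GenomeRecords."""
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(GenomeRecord(sample_id=rec.id, sequence=str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_consensus_set(records: Sequence[GenomeRecord], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.sample_id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# VCF


def read_variants(path: str | Path) -> VariantMatrix:
    """Read a multi-sample VCF into a VariantMatrix.

    Haploid GT is canonical; diploid GT is collapsed to the allele with higher
    AD support (ties -> ref) with a warning. Missing AD fields yield depth -1
    (unknown) with a single warning. Multiallelic records are preserved;
    filtering is a later stage.
    """
    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    positions: list[int] = []
    refs: list[str] = []
    alts: list[tuple[str, ...]] = []
    classes: list[str] = []
    gt_rows: list[list[int]] = []
    ad_rows: list[list[tuple[int, int]]] = []
    warned_ad = False
    warned_diploid = False
    for line_no, rec in enumerate(vf, start=1):
        try:
            alt_alleles = tuple(a for a in (rec.alts or ()))
            positions.append(rec.pos - 1)  # VCF 1-based -> internal 0-based
            refs.append(rec.ref)
            alts.append(alt_alleles)
            is_snp = len(rec.ref) == 1 and all(len(a) == 1 for a in alt_alleles)
            classes.append("SNP" if is_snp else "indel")
            row_gt: list[int] = []
            row_ad: list[tuple[int, int]] = []
            for s in samples:
                call = rec.samples[s]
                gt = call.get("GT")
                ad = call.get("AD")
                if ad is None or all(a is None for a in ad):
                    if not warned_ad:
                        warnings.warn(
                            f"{path}: no AD field; per-sample depths marked unknown",
                            stacklevel=2,
                        )
                        warned_ad = True
                    ref_d, alt_d = -1, -1
                else:
                    ref_d = int(ad[0] or 0)
                    alt_d = int(sum(a or 0 for a in ad[1:]))
                alleles = [a for a in (gt or ()) if a is not None]
                if not alleles:
                    g = -1
                elif len(alleles) == 1:
                    g = int(alleles[0])
                else:
                    if not warned_diploid:
                        warnings.warn(
                            f"{path}: diploid GT collapsed to the better-supported "
                            "allele (haploid calls are canonical)",
                            stacklevel=2,
                        )
                        warned_diploid = True
                    if len(set(alleles)) == 1:
                        g = int(alleles[0])
                    elif ref_d >= 0 and alt_d > ref_d:
                        g = int(max(alleles))
                    else:
                        g = int(min(alleles))
                row_gt.append(g)
                row_ad.append((ref_d, alt_d))
            gt_rows.append(row_gt)
            ad_rows.append(row_ad)
        except (ValueError, TypeError, KeyError) as exc:  # malformed record
            raise ValueError(f"{path}: malformed VCF record #{line_no}: {exc}") from exc
    vf.close()
    n_sites = len(positions)
    genotypes = (
        np.asarray(gt_rows, dtype=np.int16)
        if n_sites
        else np.empty((0, len(samples)), dtype=np.int16)
    )
    depths = (
        np.asarray(ad_rows, dtype=np.int32)
        if n_sites
        else np.empty((0, len(samples), 2), dtype=np.int32)
    )
    return VariantMatrix(
        positions=np.asarray(positions, dtype=np.int64),
        ref=refs,
        alt=alts,
        variant_class=np.asarray(classes, dtype=object),
        genotypes=genotypes,
        depths=depths,
        sample_ids=samples,
    )


_VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID={contig},length={length}>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Read depth per allele">
"""


def write_variants(
    matrix: VariantMatrix,
    path: str | Path,
    contig: str = "genome",
    contig_length: int | None = None,
) -> None:
    """Write a VariantMatrix as an uncompressed VCF 4.2 text file.

    The emitter is vectorized over samples; the file is valid input for
    :func:`read_variants` (round-trip tested).
    """
    if contig_length is None:
        contig_length = int(matrix.positions.max()) + 1 if len(matrix.positions) else 1
    cols = "\t".join(["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"] + list(matrix.sample_ids))
    lines = [_VCF_HEADER.format(contig=contig, length=contig_length) + cols]
    gt = matrix.genotypes
    dp = matrix.depths
    for i in range(matrix.n_sites):
        alt_field = ",".join(matrix.alt[i]) if matrix.alt[i] else "."
        fields = [
            contig,
            str(int(matrix.positions[i]) + 1),
            ".",
            matrix.ref[i],
            alt_field,
            ".",
            "PASS",
            ".",
            "GT:AD",
        ]
        sample_fields = [
            ("." if gt[i, j] < 0 else str(int(gt[i, j])))
            + (
                f":{dp[i, j, 0]},{dp[i, j, 1]}"
                if dp[i, j, 0] >= 0
                else ":.,."
            )
            for j in range(matrix.n_samples)
        ]
        lines.append("\t".join(fields + sample_fields))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Metadata CSV


def read_metadata(
    path: str | Path, known_samples: Iterable[str] | None = None
) -> list[IsolateMeta]:
    """Read the isolate metadata table (sample_id, year, season, wave)."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    required = {"sample_id", "year", "season", "wave"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicated sample_id {dup!r}")
    metas: list[IsolateMeta] = []
    for _, row in df.iterrows():
        season = None if pd.isna(row["season"]) else Season(str(row["season"]))
        try:
            wave = None if pd.isna(row["wave"]) else Wave(str(row["wave"]))
        except ValueError as exc:
            raise ValueError(f"{path}: unknown wave {row['wave']!r}") from exc
        year = None if pd.isna(row["year"]) else int(row["year"])
        metas.append(IsolateMeta(str(row["sample_id"]), year, season, wave))
    if known_samples is not None:
        known = set(known_samples)
        meta_ids = {m.sample_id for m in metas}
        extra = meta_ids - known
        if extra:
            warnings.warn(
                f"metadata lists samples absent from genotype data: {sorted(extra)[:5]}",
                stacklevel=2,
            )
        absent = known - meta_ids
        if absent:
            raise ValueError(
                f"genotyped samples missing from metadata: {sorted(absent)[:5]}"
            )
    return metas


def write_metadata(metas: Sequence[IsolateMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metas],
            "year": [m.year for m in metas],
            "season": [m.season.value if m.season else None for m in metas],
            "wave": [m.wave.value if m.wave else None for m in metas],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GFF3 ORF annotations


def read_orfs(path: str | Path) -> list[OrfAnnotation]:
    """Read ORF annotations from GFF3 (1-based inclusive -> 0-based half-open)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    orfs: list[OrfAnnotation] = []
    seen: dict[str, tuple[int, int]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("CDS", "gene", "ORF"):
            continue
        name = feat.attributes.get("Name", feat.attributes.get("ID", [feat.id]))[0]
        start, end = feat.start - 1, feat.end  # bijection: internal = GFF3 start - 1
        if name in seen:
            if seen[name] != (start, end):
                raise ValueError(f"{path}: overlapping duplicate ORF name {name!r}")
            continue
        seen[name] = (start, end)
        group = feat.attributes.get("functional_group", ["unknown"])[0]
        orfs.append(
            OrfAnnotation(
                name=name,
                start=start,
                end=end,
                strand=feat.strand if feat.strand in "+-" else "+",
                functional_group=FunctionalGroup(group),
            )
        )
    return orfs


def write_orfs(
    orfs: Sequence[OrfAnnotation], path: str | Path, contig: str = "genome"
) -> None:
    lines = ["##gff-version 3"]
    for o in orfs:
        attrs = f"ID={o.name};Name={o.name};functional_group={o.functional_group.value}"
        lines.append(
            "\t".join(
                [
                    contig,
                    "gvpop",
                    "CDS",
                    str(o.start + 1),
                    str(o.end),
                    ".",
                    o.strand,
                    "0",
                    attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Result tables


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Serialize a result table as TSV (or JSON if the path ends in .json)."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(table.to_dict(orient="list"), indent=1))
    else:
        table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".json":
        return pd.DataFrame(json.loads(path.read_text()))
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Cross-file validation


def validate_cohort(
    fasta: str | Path | None,
    vcf: str | Path,
    metadata: str | Path,
    gff: str | Path | None = None,
) -> dict:
    """Cross-file consistency check; returns a summary dict, raises on errors."""
    matrix = read_variants(vcf)
    metas = read_metadata(metadata, known_samples=matrix.sample_ids)
    summary = {
        "n_samples": matrix.n_samples,
        "n_sites": matrix.n_sites,
        "n_meta": len(metas),
    }
    if fasta is not None:
        genomes = read_consensus_set(fasta)
        g_ids = {g.sample_id for g in genomes}
        absent = set(matrix.sample_ids) - g_ids
        if absent:
            warnings.warn(
                f"samples without consensus genomes: {sorted(absent)[:5]}",
                stacklevel=2,
            )
        summary["n_genomes"] = len(genomes)
        summary["mean_genome_length"] = float(
            np.mean([len(g) for g in genomes])
        )
    if gff is not None:
        orfs = read_orfs(gff)
        summary["n_orfs"] = len(orfs)
    return summary
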