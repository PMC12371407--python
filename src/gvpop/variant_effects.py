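"""Coding-consequence classification and genome feature scanning.

Variants are typed by their effect on ORF structure: synonymous vs
nonsynonymous single-nucleotide variants, start/stop-codon changes, inframe vs
frameshift indels (frameshift = length change not a multiple of three), and
microsatellite indels (whole-unit events inside a tandem repeat of unit length
1-4, labelled Types I-IV). The scanner also locates homologous repeat (hr)
regions — clusters of copies of the 10-bp palindrome TTTACGTAAA that punctuate
granulovirus genomes.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io_formats import OrfAnnotation

__all__ = [
    "Effect",
    "EffectCall",
    "HrRegion",
    "classify_snv",
    "classify_indel",
    "classify_microsatellite",
    "scan_hrs",
    "classify_variant",
    "orf_length_variant_summary",
    "LENGTH_CHANGING_EFFECTS",
    "HR_MOTIF",
]

HR_MOTIF = "TTTACGTAAA"

STOP_CODONS = {"TAA", "TAG", "TGA"}


class Effect(str, enum.Enum):
    SYNONYMOUS_SNV = "synonymous_SNV"
    NONSYNONYMOUS_SNV = "nonsynonymous_SNV"
    TRANSLATION_START_SITE_SNV = "translation_start_site_SNV"
    TERMINATION_SITE_SNV = "termination_site_SNV"
    INFRAME_INSERTION = "inframe_insertion"
    INFRAME_DELETION = "inframe_deletion"
    FRAMESHIFT_INSERTION = "frameshift_insertion"
    FRAMESHIFT_DELETION = "frameshift_deletion"
    MICROSATELLITE_INS = "microsatellite_ins"
    MICROSATELLITE_DEL = "microsatellite_del"
    MICROSATELLITE_FRAMESHIFT_INS = "microsatellite_frameshift_ins"
    MICROSATELLITE_FRAMESHIFT_DEL = "microsatellite_frameshift_del"
    INTERGENIC = "intergenic"


# Categories that change (or can change) the translated ORF length.
LENGTH_CHANGING_EFFECTS = {
    Effect.TRANSLATION_START_SITE_SNV,
    Effect.TERMINATION_SITE_SNV,
    Effect.INFRAME_INSERTION,
    Effect.INFRAME_DELETION,
    Effect.FRAMESHIFT_INSERTION,
    Effect.FRAMESHIFT_DELETION,
    Effect.MICROSATELLITE_INS,
    Effect.MICROSATELLITE_DEL,
    Effect.MICROSATELLITE_FRAMESHIFT_INS,
    Effect.MICROSATELLITE_FRAMESHIFT_DEL,
}


@dataclass(frozen=True)
class EffectCall:
    position: int
    orf: str | None  # None = intergenic
    effect: Effect
    repeat_unit_length: int | None = None
    note: str | None = None

    def __post_init__(self) -> None:
        if "microsatellite" in self.effect.value and self.repeat_unit_length is None:
            raise ValueError("microsatellite categories carry a repeat_unit_length")


@dataclass(frozen=True)
class HrRegion:
    start: int
    end: int
    n_repeats: int
    hit_positions: tuple[int, ...]


def _codon_context(orf: OrfAnnotation, position: int, genome: str) -> tuple[int, int, str]:
    """(codon index, offset within codon, ref codon) on the coding strand."""
    if orf.strand == "+":
        off = position - orf.start
    else:
        off = orf.end - 1 - position
    codon_idx, within = divmod(off, 3)
    cds = orf.coding_sequence(genome)
    codon = cds[3 * codon_idx : 3 * codon_idx + 3]
    return codon_idx, within, codon


def classify_snv(
    position: int,
    ref_base: str,
    alt_base: str,
    orfs: Sequence[OrfAnnotation],
    genome: str,
) -> list[EffectCall]:
    """Classify a single-nucleotide variant against every overlapping ORF.

    The codon is recomputed on the coding strand. Start/stop categories take
    precedence when the affected codon is the ORF's first codon or a reference
    stop codon; otherwise synonymous iff the amino acid is unchanged.
    Positions outside every ORF yield one intergenic call.
    """
    if not (0 <= position < len(genome)):
        raise ValueError(f"position {position} outside genome")
    if genome[position] != ref_base.upper():
        raise ValueError(
            f"ref base mismatch at {position}: genome has {genome[position]!r}, "
            f"variant says {ref_base!r}"
        )
    calls: list[EffectCall] = []
    for orf in orfs:
        if not (orf.start <= position < orf.end):
            continue
        codon_idx, within, codon = _codon_context(orf, position, genome)
        base = alt_base.upper()
        if orf.strand == "-":
            base = str(Seq(base).reverse_complement())
        mutated = codon[:within] + base + codon[within + 1 :]
        if codon_idx == 0:
            effect = Effect.TRANSLATION_START_SITE_SNV
        elif codon in STOP_CODONS:
            effect = Effect.TERMINATION_SITE_SNV
        elif str(Seq(codon).translate()) == str(Seq(mutated).translate()):
            effect = Effect.SYNONYMOUS_SNV
        else:
            effect = Effect.NONSYNONYMOUS_SNV
        calls.append(EffectCall(position=position, orf=orf.name, effect=effect))
    if not calls:
        calls.append(EffectCall(position=position, orf=None, effect=Effect.INTERGENIC))
    return calls


def _trim_alleles(ref: str, alt: str) -> tuple[str, str, int]:
    """Strip the common prefix/suffix of a VCF allele pair.

    Returns (event ref, event alt, offset of the event from the original
    position).
    """
    prefix = 0
    while prefix < min(len(ref), len(alt)) and ref[prefix] == alt[prefix]:
        prefix += 1
    r, a = ref[prefix:], alt[prefix:]
    suffix = 0
    while suffix < min(len(r), len(a)) and r[len(r) - 1 - suffix] == a[len(a) - 1 - suffix]:
        suffix += 1
    if suffix:
        r, a = r[: len(r) - suffix], a[: len(a) - suffix]
    return r, a, prefix


def classify_microsatellite(
    position: int,
    ref_allele: str,
    alt_allele: str,
    genome: str,
    min_copies: int = 3,
) -> int | None:
    """Repeat-unit length (1-4) if the indel is a whole-unit event inside a
    tandem repeat with >= min_copies flanking copies; smallest unit wins;
    None otherwise.
    """
    r, a, off = _trim_alleles(ref_allele.upper(), alt_allele.upper())
    event = r or a  # deleted or inserted sequence
    if not event or (r and a):
        return None
    site = position + off
    for u in (1, 2, 3, 4):
        if len(event) % u:
            continue
        unit = event[:u]
        if event != unit * (len(event) // u):
            continue
        # count tandem copies of `unit` in the reference around the event site
        left = site
        copies = 0
        while left - u >= 0 and genome[left - u : left] == unit:
            left -= u
            copies += 1
        right = site + (len(r) if r else 0)
        while right + u <= len(genome) and genome[right : right + u] == unit:
            right += u
            copies += 1
        if copies >= min_copies:
            return u
    return None


def classify_indel(
    position: int,
    ref_allele: str,
    alt_allele: str,
    orfs: Sequence[OrfAnnotation],
    genome: str,
    min_copies: int = 3,
) -> list[EffectCall]:
    """Classify an insertion/deletion against every overlapping ORF.

    |length difference| mod 3 != 0 is a frameshift; microsatellite context
    (tandem-repeat unit of length 1-4) takes the microsatellite categories.
    Complex substitutions (both trimmed alleles non-empty) are classified by
    net length change with a "complex" note.
    """
    ref_allele, alt_allele = ref_allele.upper(), alt_allele.upper()
    delta = len(alt_allele) - len(ref_allele)
    if delta == 0:
        raise ValueError("classify_indel requires alleles of different length")
    r, a, off = _trim_alleles(ref_allele, alt_allele)
    note = "complex" if (r and a) else None
    is_ins = delta > 0
    frameshift = (abs(delta) % 3) != 0
    unit = None if note else classify_microsatellite(
        position, ref_allele, alt_allele, genome, min_copies=min_copies
    )
    if unit is not None:
        effect = {
            (True, True): Effect.MICROSATELLITE_FRAMESHIFT_INS,
            (True, False): Effect.MICROSATELLITE_INS,
            (False, True): Effect.MICROSATELLITE_FRAMESHIFT_DEL,
            (False, False): Effect.MICROSATELLITE_DEL,
        }[(is_ins, frameshift)]
    else:
        effect = {
            (True, True): Effect.FRAMESHIFT_INSERTION,
            (True, False): Effect.INFRAME_INSERTION,
            (False, True): Effect.FRAMESHIFT_DELETION,
            (False, False): Effect.INFRAME_DELETION,
        }[(is_ins, frameshift)]
    event_start = position + off
    event_end = event_start + max(len(r), 1)
    calls: list[EffectCall] = []
    for orf in orfs:
        if event_start < orf.end and event_end > orf.start:
            calls.append(
                EffectCall(
                    position=position,
                    orf=orf.name,
                    effect=effect,
                    repeat_unit_length=unit,
                    note=note,
                )
            )
    if not calls:
        calls.append(
            EffectCall(position=position, orf=None, effect=Effect.INTERGENIC, note=note)
        )
    return calls


def classify_variant(
    position: int,
    ref_allele: str,
    alt_allele: str,
    orfs: Sequence[OrfAnnotation],
    genome: str,
) -> list[EffectCall]:
    """Dispatch to SNV or indel classification by allele lengths."""
    if len(ref_allele) == 1 and len(alt_allele) == 1:
        return classify_snv(position, ref_allele, alt_allele, orfs, genome)
    return classify_indel(position, ref_allele, alt_allele, orfs, genome)


def scan_hrs(
    genome: str,
    motif: str = HR_MOTIF,
    max_mismatches: int = 1,
    cluster_window: int = 500,
    min_repeats: int = 2,
) -> list[HrRegion]:
    """Locate homologous-repeat regions as clusters of near-exact motif copies.

    Forward-strand scan with <= max_mismatches mismatches per window; hits
    within cluster_window of the previous hit merge into one region; regions
    with fewer than min_repeats hits are dropped. The default motif is its own
    reverse complement, so one strand suffices; a non-palindromic motif draws
    a warning.
    """
    if not genome:
        raise ValueError("empty genome")
    motif = motif.upper()
    if str(Seq(motif).reverse_complement()) != motif:
        warnings.warn(
            "motif is not its own reverse complement; scanning forward strand only",
            stacklevel=2,
        )
    g = np.frombuffer(genome.encode(), dtype=np.uint8)
    m = np.frombuffer(motif.encode(), dtype=np.uint8)
    L, k = len(g), len(m)
    if L < k:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(g, k)
    mism = (windows != m).sum(axis=1)
    hits = np.flatnonzero(mism <= max_mismatches)
    # drop hits overlapping a previous accepted hit (tandem copies only)
    accepted: list[int] = []
    for h in hits:
        if not accepted or h >= accepted[-1] + k:
            accepted.append(int(h))
    regions: list[HrRegion] = []
    cluster: list[int] = []
    for h in accepted + [None]:  # type: ignore[list-item]
        if h is not None and (not cluster or h - cluster[-1] <= cluster_window):
            cluster.append(h)
            continue
        if len(cluster) >= min_repeats:
            regions.append(
                HrRegion(
                    start=cluster[0],
                    end=cluster[-1] + k,
                    n_repeats=len(cluster),
                    hit_positions=tuple(cluster),
                )
            )
        cluster = [h] if h is not None else []
    return regions


def orf_length_variant_summary(
    calls_per_isolate: Mapping[str, Sequence[EffectCall]],
    orfs: Sequence[OrfAnnotation],
) -> pd.DataFrame:
    """Waterfall table of ORF-length-changing variant categories.

    Rows are (orf, sample_id, effect) with one row per category present in
    that cell; the companion marginals are plain groupby counts on the table.
    """
    rows = []
    orf_names = {o.name for o in orfs}
    for sid, calls in calls_per_isolate.items():
        for c in calls:
            if c.orf in orf_names and c.effect in LENGTH_CHANGING_EFFECTS:
                rows.append({"orf": c.orf, "sample_id": sid, "effect": c.effect.value})
    df = pd.DataFrame(rows, columns=["orf", "sample_id", "effect"])
    return df.drop_duplicates().reset_index(drop=True)
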