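"""Retrocopy vs. parental-gene comparison at single-base resolution.

A recently inserted retrocopy is a snapshot of one parental mRNA haplotype.
Differences between a retrocopy and the reference gene sequence therefore
fall into two classes: variants segregating at the parental locus in the
population (the retrocopy simply copied a non-reference haplotype), and
variants that arose after retrotransposition and are unique to the
retrocopy.  This module aligns a retrocopy to the parental mRNA, calls
differences, projects them to genomic coordinates through the exon map, and
classifies each against a population VCF; it can also report which phased
parental haplotype a retrocopy matches best.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum

import pandas as pd
import pysam
from Bio import Align

from .genemodel import GeneModel, revcomp
from .site_char import strip_polya

logger = logging.getLogger(__name__)


class VariantClass(Enum):
    HAPLOTYPE_SHARED = "HAPLOTYPE_SHARED"
    RETROCOPY_SPECIFIC = "RETROCOPY_SPECIFIC"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class RetrocopyVariant:
    """One difference between a retrocopy and the parental mRNA.

    Alleles are VCF-style: indels carry a shared anchor base and
    ``genomic_pos`` refers to the leftmost genomic base of the reference
    allele after left-normalization.
    """

    mrna_pos: int         # 1-based on the parental mRNA
    genomic_pos: int      # projected parental-locus coordinate
    ref: str
    alt: str
    kind: str             # SNV / ins / del
    region: str           # UTR5 / ORF / UTR3
    classification: VariantClass = VariantClass.UNKNOWN

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -2
    a.open_gap_score = -5
    a.extend_gap_score = -1
    a.end_gap_score = 0.0
    return a


def _left_normalize(mrna: str, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-align an anchored indel against homopolymer context (VCF rule)."""
    while len(ref) > 1 or len(alt) > 1:
        if ref[-1] == alt[-1] and pos > 1:
            ref = mrna[pos - 2] + ref[:-1]
            alt = mrna[pos - 2] + alt[:-1]
            pos -= 1
        else:
            break
    # trim identical leading context beyond the single anchor base
    while len(ref) > 1 and len(alt) > 1 and ref[1] == alt[1] and ref[0] == alt[0]:
        ref, alt = ref[0] + ref[2:], alt[0] + alt[2:]
    return pos, ref, alt


def align_and_call(retro_seq: str, gene: GeneModel, *,
                   min_identity: float = 0.90,
                   strip_tail: bool = True) -> list[RetrocopyVariant]:
    """Align a retrocopy to the parental mRNA and call every difference.

    ``retro_seq`` must be oriented to the mRNA strand (TSD removed); the
    polyA tail is stripped here by default so trailing adenosines are not
    called as an insertion.  End-free global alignment (match 1, mismatch
    −2, gap open −5, gap extend −1); truncated termini produce no calls.
    Raises ``ValueError`` below ``min_identity`` aligned identity.
    """
    if len(retro_seq) < 200:
        raise ValueError("retrocopy sequence shorter than 200 bp")
    if strip_tail:
        retro_seq, _ = strip_polya(retro_seq)
    aln = _aligner().align(gene.mrna, retro_seq)[0]
    tgt, qry = aln.indices

    matches = cols = 0
    first = last = None
    for t, q in zip(tgt, qry):
        if t >= 0 and q >= 0:
            cols += 1
            matches += gene.mrna[t] == retro_seq[q]
            if first is None:
                first = t
            last = t
    if cols == 0 or matches / cols < min_identity:
        raise ValueError("not a retrocopy of this gene: identity too low")

    variants: list[RetrocopyVariant] = []
    i = 0
    n = len(tgt)
    prev_t = None
    while i < n:
        t, q = tgt[i], qry[i]
        inside = first is not None and (
            (t >= 0 and first <= t <= last) or (t < 0 and prev_t is not None
                                                and first <= prev_t < last))
        if t >= 0 and q >= 0:
            if inside and gene.mrna[t] != retro_seq[q]:
                variants.append(_make_variant(gene, t + 1, gene.mrna[t],
                                              retro_seq[q], "SNV"))
            prev_t = t
            i += 1
            continue
        if t >= 0 and q < 0 and inside:
            # deletion run in the retrocopy
            j = i
            while j < n and tgt[j] >= 0 and qry[j] < 0:
                j += 1
            run = "".join(gene.mrna[tgt[k]] for k in range(i, j))
            anchor_pos = prev_t + 1 if prev_t is not None else tgt[j - 1] + 2
            if prev_t is not None:
                ref = gene.mrna[prev_t] + run
                alt = gene.mrna[prev_t]
                pos, ref, alt = _left_normalize(gene.mrna, anchor_pos, ref, alt)
                variants.append(_make_variant(gene, pos, ref, alt, "del"))
            prev_t = tgt[j - 1]
            i = j
            continue
        if t < 0 and q >= 0 and inside:
            # insertion run in the retrocopy
            j = i
            while j < n and tgt[j] < 0 and qry[j] >= 0:
                j += 1
            run = "".join(retro_seq[qry[k]] for k in range(i, j))
            if prev_t is not None:
                pos = prev_t + 1
                ref = gene.mrna[prev_t]
                alt = gene.mrna[prev_t] + run
                pos, ref, alt = _left_normalize(gene.mrna, pos, ref, alt)
                variants.append(_make_variant(gene, pos, ref, alt, "ins"))
            i = j
            continue
        if t >= 0:
            prev_t = t
        i += 1
    variants.sort(key=lambda v: v.mrna_pos)
    return variants


def _make_variant(gene: GeneModel, mrna_pos: int, ref: str, alt: str,
                  kind: str) -> RetrocopyVariant:
    mrna_pos = int(mrna_pos)
    if gene.strand == "+":
        genomic = gene.mrna_to_genomic(mrna_pos)
        gref, galt = ref, alt
    else:
        # leftmost genomic base of the reference span, alleles complemented
        genomic = gene.mrna_to_genomic(mrna_pos + len(ref) - 1)
        gref, galt = revcomp(ref), revcomp(alt)
    return RetrocopyVariant(
        mrna_pos=mrna_pos, genomic_pos=int(genomic), ref=gref, alt=galt,
        kind=kind, region=gene.region_of_mrna_pos(mrna_pos),
    )


# ----------------------------------------------------------------------
# Population classification
# ----------------------------------------------------------------------
def load_population_alleles(vcf_path: str, chrom: str | None = None
                            ) -> tuple[set[tuple[str, int, str, str]], set[tuple[str, int]]]:
    """Read a population VCF into (allele set, filtered-position set).

    Multiallelic records are split into biallelic alleles.  Records with a
    non-PASS FILTER contribute their positions to the filtered set instead.
    """
    alleles: set[tuple[str, int, str, str]] = set()
    filtered: set[tuple[str, int]] = set()
    with pysam.VariantFile(vcf_path) as vcf:
        for rec in vcf:
            if chrom is not None and rec.chrom != chrom:
                continue
            ok = (len(rec.filter) == 0
                  or all(f == "PASS" for f in rec.filter.keys()))
            for alt in rec.alts or ():
                if ok:
                    alleles.add((rec.chrom, rec.pos, rec.ref, alt))
                else:
                    filtered.add((rec.chrom, rec.pos))
    return alleles, filtered


def classify_variants(variants: list[RetrocopyVariant], vcf_path: str,
                      gene: GeneModel) -> list[RetrocopyVariant]:
    """Label each retrocopy variant against the population variant table.

    HAPLOTYPE_SHARED requires the identical alternate allele at the
    projected genomic position — positional overlap with a different allele
    does not count.  Positions present only as filtered records are UNKNOWN;
    everything else is RETROCOPY_SPECIFIC.
    """
    alleles, filtered = load_population_alleles(vcf_path)
    out = []
    for v in variants:
        key = (gene.chrom, v.genomic_pos, v.ref, v.alt)
        if key in alleles:
            cls = VariantClass.HAPLOTYPE_SHARED
        elif (gene.chrom, v.genomic_pos) in filtered:
            cls = VariantClass.UNKNOWN
        else:
            cls = VariantClass.RETROCOPY_SPECIFIC
        out.append(replace(v, classification=cls))
    return out


# ----------------------------------------------------------------------
# Haplotype matching
# ----------------------------------------------------------------------
def haplotype_match(retro_variants: list[RetrocopyVariant],
                    haplotypes: pd.DataFrame
                    ) -> tuple[list[str], int | None]:
    """Best-matching parental haplotype(s) for a retrocopy.

    ``haplotypes`` has columns ``pos`` (genomic), ``ref`` and one column per
    haplotype giving its allele at that position.  The retrocopy's allele at
    each table position is the called alternate if a variant was called
    there, the reference otherwise.  Returns (tied best haplotype names,
    mismatch count); (["UNKNOWN"], None) when some called variant position
    is not covered by the table.
    """
    hap_cols = [c for c in haplotypes.columns if c not in ("chrom", "pos", "ref")]
    if not hap_cols:
        raise ValueError("haplotype table has no haplotype columns")
    table_pos = set(haplotypes["pos"].astype(int))
    called = {v.genomic_pos: v for v in retro_variants}
    uncovered = set(called) - table_pos
    if uncovered:
        logger.warning("haplotype table does not cover positions %s",
                       sorted(uncovered))
        return (["UNKNOWN"], None)

    mismatches = dict.fromkeys(hap_cols, 0)
    for _, row in haplotypes.iterrows():
        pos = int(row["pos"])
        retro_allele = called[pos].alt if pos in called else row["ref"]
        for h in hap_cols:
            if str(row[h]) != retro_allele:
                mismatches[h] += 1
    best = min(mismatches.values())
    return ([h for h in hap_cols if mismatches[h] == best], best)


def summarize(variants: list[RetrocopyVariant]) -> pd.DataFrame:
    """Variant table as a DataFrame (one row per difference)."""
    cols = ["mrna_pos", "genomic_pos", "ref", "alt", "kind", "region",
            "classification"]
    return pd.DataFrame([{
        "mrna_pos": v.mrna_pos, "genomic_pos": v.genomic_pos,
        "ref": v.ref, "alt": v.alt, "kind": v.kind, "region": v.region,
        "classification": v.classification.value,
    } for v in variants], columns=cols)
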