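"""Parental gene model: exon structure, spliced mRNA, coordinate projection.

All coordinates are 1-based inclusive (genomic and mRNA alike); conversion to
0-based half-open happens only in the I/O adapters (:mod:`retroseek.cli_io`).
A :class:`GeneModel` ties together the genomic exon intervals of a multi-exon
gene, its spliced mRNA sequence, and the UTR5/ORF/UTR3 partition of that mRNA
— everything the detection and characterization stages need to reason about
an intronless retrocopy of the gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (ACGTN, case-preserving)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """A multi-exon gene locus and its spliced transcript.

    Parameters
    ----------
    chrom : str
        Reference sequence name of the parental locus.
    strand : str
        ``'+'`` or ``'-'``; orientation of the transcript on the reference.
    exons : tuple of (int, int)
        Ordered, non-overlapping genomic exon intervals, 1-based inclusive,
        sorted by start coordinate regardless of strand.
    utr5, orf, utr3 : (int, int)
        Sub-intervals of the mRNA in 1-based mRNA coordinates.  Together they
        partition ``[1, len(mrna)]`` and the ORF length is a multiple of 3.
    mrna : str
        Spliced transcript sequence, 5'→3' on the transcript strand.
    """

    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    utr5: tuple[int, int]
    orf: tuple[int, int]
    utr3: tuple[int, int]
    mrna: str = field(repr=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.exons) < 1:
            raise ValueError("gene needs at least one exon")
        for (s, e) in self.exons:
            if s > e:
                raise ValueError(f"exon interval [{s},{e}] is inverted")
        for (_, e_prev), (s_next, _) in zip(self.exons, self.exons[1:]):
            if s_next <= e_prev:
                raise ValueError("exons must be sorted and non-overlapping")
        n = sum(e - s + 1 for s, e in self.exons)
        if len(self.mrna) != n:
            raise ValueError(
                f"mRNA length {len(self.mrna)} != summed exon length {n}"
            )
        u5, orf, u3 = self.utr5, self.orf, self.utr3
        if not (u5[0] == 1 and u5[1] + 1 == orf[0] and orf[1] + 1 == u3[0]
                and u3[1] == n):
            raise ValueError("utr5/orf/utr3 must partition the mRNA")
        if (orf[1] - orf[0] + 1) % 3 != 0:
            raise ValueError("ORF length must be a multiple of 3")

    # ------------------------------------------------------------------
    # basic geometry
    # ------------------------------------------------------------------
    @property
    def mrna_length(self) -> int:
        return len(self.mrna)

    @property
    def region(self) -> tuple[int, int]:
        """Genomic span of the gene, first exon start to last exon end."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def intron_lengths(self) -> tuple[int, ...]:
        """Lengths of the introns between consecutive exons, in genomic order."""
        return tuple(
            s2 - e1 - 1 for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )

    def exon_index_at(self, pos: int) -> int | None:
        """Genomic-order index of the exon containing genomic ``pos``, or None."""
        for i, (s, e) in enumerate(self.exons):
            if s <= pos <= e:
                return i
        return None

    def overlaps_region(self, start: int, end: int, margin: int = 0) -> bool:
        gs, ge = self.region
        return start <= ge + margin and end >= gs - margin

    # ------------------------------------------------------------------
    # mRNA <-> genome projection
    # ------------------------------------------------------------------
    def mrna_to_genomic(self, pos: int) -> int:
        """Project a 1-based mRNA coordinate onto the genome.

        For a minus-strand gene, mRNA base 1 is the 3'-most genomic base of
        the last exon.
        """
        if not 1 <= pos <= self.mrna_length:
            raise ValueError(f"mRNA position {pos} out of range")
        if self.strand == "+":
            off = pos - 1
            for s, e in self.exons:
                length = e - s + 1
                if off < length:
                    return s + off
                off -= length
        else:
            off = pos - 1
            for s, e in reversed(self.exons):
                length = e - s + 1
                if off < length:
                    return e - off
                off -= length
        raise AssertionError("unreachable")

    def genomic_to_mrna(self, pos: int) -> int | None:
        """Inverse of :meth:`mrna_to_genomic`; None for intronic/outside."""
        acc = 0
        exons = self.exons if self.strand == "+" else tuple(reversed(self.exons))
        for s, e in exons:
            if s <= pos <= e:
                return acc + (pos - s + 1 if self.strand == "+" else e - pos + 1)
            acc += e - s + 1
        return None

    def region_of_mrna_pos(self, pos: int) -> str:
        """Which transcript region (UTR5/ORF/UTR3) an mRNA coordinate lies in."""
        for name, (s, e) in (("UTR5", self.utr5), ("ORF", self.orf),
                             ("UTR3", self.utr3)):
            if s <= pos <= e:
                return name
        raise ValueError(f"mRNA position {pos} out of range")

    def orf_seq(self) -> str:
        return self.mrna[self.orf[0] - 1: self.orf[1]]
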