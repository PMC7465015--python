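"""Insertion-site and retrocopy characterization.

L1-mediated retrotransposition leaves recognizable hallmarks at an
integration site: a short target site duplication (TSD) flanking the insert,
a preference for A/T-rich sequence and for the degenerate TTAAAA nicking
motif, and a polyA tract at the 3' end of the insert.  This module measures
those hallmarks — TSD detection from junction contexts, G/C content of the
site window, motif occurrence, conserved-element proximity, repeat context —
and classifies 5'/3' truncation of the retrocopy relative to the parental
mRNA.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from Bio import Align

from .genemodel import GeneModel, revcomp

# TSD search bounds: duplications shorter than 6 bp are indistinguishable
# from chance in a ~30 bp window; observed canid FGF4 TSDs span 11–17 bp.
MIN_TSD_LEN = 6
MAX_TSD_LEN = 30

L1_MOTIF = "TTAAAA"

_ACGT = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class TSDResult:
    """A detected target site duplication."""

    seq: str          # duplicated sequence (as read at the 3' junction)
    length: int
    mismatches: int


@dataclass
class SiteReport:
    """Characterization of one insertion site (reference forward strand)."""

    name: str
    tsd_seq: str
    tsd_len: int
    flank5: str
    flank3: str
    strand: str
    gc_percent: float
    motif_hits: list[int]
    ecr_count: int | None = None
    repeat_context: str = "none"

    @property
    def window_seq(self) -> str:
        return self.flank5 + self.tsd_seq + self.flank3

    @property
    def motif_hit(self) -> bool:
        return len(self.motif_hits) > 0


@dataclass(frozen=True)
class TruncationReport:
    """Missing 5'/3' extent of a retrocopy relative to the parental mRNA."""

    trunc5: int
    trunc3: int
    orf_intact: bool


# ----------------------------------------------------------------------
# TSD detection
# ----------------------------------------------------------------------
def find_tsd(junction5_context: str, junction3_context: str, *,
             max_mismatch: int = 0, min_len: int = MIN_TSD_LEN,
             max_len: int = MAX_TSD_LEN) -> TSDResult | None:
    """Detect the target site duplication between two junction contexts.

    ``junction5_context`` is reference sequence ending exactly at the 5'
    insertion junction; ``junction3_context`` starts exactly at the 3'
    junction.  Integration by staggered nicking duplicates the target site,
    so the TSD is the longest string that is simultaneously a suffix of the
    5' context and a prefix of the 3' context.

    With ``max_mismatch > 0`` the longest duplication with at most that many
    mismatches is returned; at equal length an exact match wins.  Returns
    ``None`` when no duplication of at least ``min_len`` exists.
    """
    for ctx, side in ((junction5_context, "5'"), (junction3_context, "3'")):
        if len(ctx) < min_len:
            raise ValueError(
                f"{side} junction context shorter than min_len={min_len}"
            )
    hi = min(max_len, len(junction5_context), len(junction3_context))
    for length in range(hi, min_len - 1, -1):
        suffix = junction5_context[-length:]
        prefix = junction3_context[:length]
        mism = sum(a != b for a, b in zip(suffix, prefix))
        if mism <= max_mismatch:
            return TSDResult(seq=prefix, length=length, mismatches=mism)
    return None


def tsd_brute_force(junction5_context: str, junction3_context: str,
                    min_len: int = MIN_TSD_LEN,
                    max_len: int = MAX_TSD_LEN) -> TSDResult | None:
    """Exhaustive reference implementation of exact TSD detection.

    Enumerates every substring pair of the two contexts and keeps the
    longest identical pair anchored at the junctions (ending at the 5'
    junction, starting at the 3' junction).  Quadratic and only meant as an
    independent check of :func:`find_tsd`.
    """
    best: TSDResult | None = None
    n5, n3 = len(junction5_context), len(junction3_context)
    for i in range(n5):
        for j in range(i + 1, n5 + 1):
            sub = junction5_context[i:j]
            length = j - i
            if j != n5 or length < min_len or length > max_len:
                continue  # must terminate at the 5' junction
            for k in range(n3 - length + 1):
                if k != 0:
                    continue  # must begin at the 3' junction
                if junction3_context[k:k + length] == sub:
                    if best is None or length > best.length:
                        best = TSDResult(seq=sub, length=length, mismatches=0)
    return best


# ----------------------------------------------------------------------
# Window statistics
# ----------------------------------------------------------------------
def gc_window(window_seq: str) -> float:
    """G/C percentage of an insertion-site window, half-up to 1 decimal.

    The window is the printed flank5+TSD+flank3 string; no ambiguity-code
    weighting is applied.
    """
    if not window_seq:
        raise ValueError("empty window sequence")
    if not _ACGT.match(window_seq):
        raise ValueError("window sequence must contain only A/C/G/T")
    gc = window_seq.count("G") + window_seq.count("C")
    frac = Decimal(100 * gc) / Decimal(len(window_seq))
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def scan_motif(window_seq: str, motif: str = L1_MOTIF, *,
               both_strands: bool = False) -> list[int] | tuple[list[int], list[int]]:
    """All start offsets (0-based) of ``motif`` in the window.

    Overlapping occurrences are reported.  By default only the reference
    forward strand is scanned — site windows are reported on the forward
    strand irrespective of retrocopy orientation; with ``both_strands`` the
    reverse-complement occurrences are returned as a second list.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    fwd = [m.start() for m in re.finditer(f"(?={re.escape(motif)})", window_seq)]
    if not both_strands:
        return fwd
    rev = [m.start() for m in
           re.finditer(f"(?={re.escape(revcomp(motif))})", window_seq)]
    return fwd, rev


# ----------------------------------------------------------------------
# Conserved-element proximity
# ----------------------------------------------------------------------
def count_ecr(insertion_interval: tuple[str, int, int],
              ecr_intervals: list[tuple[str, int, int]],
              radius: int = 2500) -> int:
    """Number of conserved elements within ``radius`` bp of the site midpoint.

    ``insertion_interval`` and every element are (chrom, start, end),
    1-based inclusive.  The query window is [midpoint − radius,
    midpoint + radius]; overlap means at least one shared base.
    """
    chrom, start, end = insertion_interval
    mid = (start + end) // 2
    lo, hi = mid - radius, mid + radius
    return sum(
        1 for (c, s, e) in ecr_intervals
        if c == chrom and s <= hi and e >= lo
    )


# ----------------------------------------------------------------------
# polyA handling and truncation
# ----------------------------------------------------------------------
def strip_polya(seq: str, min_run: int = 5) -> tuple[str, int]:
    """Remove a trailing adenosine run of at least ``min_run`` bases.

    Returns (stripped sequence, length of the removed tail).  Retrocopies
    carry an untemplated polyA tract that would otherwise be called as an
    insertion against the parental mRNA.
    """
    n = len(seq)
    i = n
    while i > 0 and seq[i - 1] == "A":
        i -= 1
    run = n - i
    if run >= min_run:
        return seq[:i], run
    return seq, 0


def _end_free_aligner(match: float = 1, mismatch: float = -2,
                      gap_open: float = -5, gap_extend: float = -1) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # end-free: terminal truncation and overhangs are not penalized
    aligner.end_gap_score = 0.0
    return aligner


def classify_truncation(retro_seq: str, gene: GeneModel, *,
                        min_identity: float = 0.90) -> TruncationReport:
    """Measure 5'/3' truncation of a retrocopy against the parental mRNA.

    ``retro_seq`` must already be oriented to the mRNA strand and stripped
    of TSD and polyA tail (see :func:`strip_polya`).  After end-free
    alignment, ``trunc5``/``trunc3`` are the unaligned prefix/suffix of the
    parental mRNA.  ``orf_intact`` requires the full ORF to be covered, the
    retrocopy ORF length to remain a multiple of 3, and translation to hit
    no premature stop.
    """
    aligner = _end_free_aligner()
    aln = aligner.align(gene.mrna, retro_seq)[0]
    tgt_idx, qry_idx = aln.indices  # -1 marks a gap

    matches = aligned_cols = 0
    first_t = last_t = None
    for t, q in zip(tgt_idx, qry_idx):
        if t >= 0 and q >= 0:
            aligned_cols += 1
            if gene.mrna[t] == retro_seq[q]:
                matches += 1
            if first_t is None:
                first_t = t
            last_t = t
    if aligned_cols == 0 or matches / aligned_cols < min_identity:
        raise ValueError("not a retrocopy of this gene: alignment identity "
                         f"{matches / aligned_cols if aligned_cols else 0:.2f} < {min_identity}")

    trunc5 = int(first_t)  # 0-based index of first aligned mRNA base
    trunc3 = int(gene.mrna_length - 1 - last_t)

    orf_s, orf_e = gene.orf  # 1-based mRNA coords
    covered = trunc5 < orf_s and (gene.mrna_length - trunc3) >= orf_e
    orf_intact = False
    if covered:
        retro_orf = []
        for t, q in zip(tgt_idx, qry_idx):
            in_orf = t >= 0 and orf_s - 1 <= t <= orf_e - 1
            if in_orf and q >= 0:
                retro_orf.append(retro_seq[q])
            elif t < 0 and q >= 0 and first_t is not None:
                # insertion in the retrocopy: frameshifts the ORF if internal
                pass
        orf_nt = "".join(retro_orf)
        # count retrocopy insertions falling strictly inside the ORF span
        ins_in_orf = 0
        prev_t = None
        for t, q in zip(tgt_idx, qry_idx):
            if t >= 0:
                prev_t = t
            elif q >= 0 and prev_t is not None and orf_s - 1 <= prev_t < orf_e - 1:
                ins_in_orf += 1
        total_len = len(orf_nt) + ins_in_orf
        if total_len % 3 == 0 and len(orf_nt) >= 3 and ins_in_orf % 3 == 0:
            orf_intact = not _has_premature_stop(orf_nt)
    return TruncationReport(trunc5=trunc5, trunc3=trunc3, orf_intact=orf_intact)


_STOPS = {"TAA", "TAG", "TGA"}


def _has_premature_stop(orf_nt: str) -> bool:
    for i in range(0, len(orf_nt) - 3, 3):
        if orf_nt[i:i + 3] in _STOPS:
            return True
    return False


# ----------------------------------------------------------------------
# Report assembly
# ----------------------------------------------------------------------
def characterize_site(name: str, junction5_context: str,
                      junction3_context: str, strand: str, *,
                      flank_len: int = 10,
                      ecr_intervals: list[tuple[str, int, int]] | None = None,
                      insertion_interval: tuple[str, int, int] | None = None,
                      repeat_context: str = "none") -> SiteReport:
    """Full hallmark report for one insertion site.

    Detects the TSD, trims the contexts to ``flank_len`` flanking bases,
    and computes G/C and motif statistics over the flank5+TSD+flank3 window.
    """
    tsd = find_tsd(junction5_context, junction3_context)
    if tsd is None:
        tsd = TSDResult(seq="", length=0, mismatches=0)
        flank5 = junction5_context[-flank_len:]
        flank3 = junction3_context[:flank_len]
    else:
        flank5 = junction5_context[:-tsd.length][-flank_len:]
        flank3 = junction3_context[tsd.length:][:flank_len]
    window = flank5 + tsd.seq + flank3
    ecr = None
    if ecr_intervals is not None and insertion_interval is not None:
        ecr = count_ecr(insertion_interval, ecr_intervals)
    return SiteReport(
        name=name,
        tsd_seq=tsd.seq,
        tsd_len=tsd.length,
        flank5=flank5,
        flank3=flank3,
        strand=strand,
        gc_percent=gc_window(window),
        motif_hits=list(scan_motif(window)),
        ecr_count=ecr,
        repeat_context=repeat_context,
    )
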