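"""Retrocopy detection from discordant read pairs over the parental gene.

Against a reference that lacks the retrocopy, two discordant signal classes
identify an insertion:

* **junction-spanning (exon–exon) pairs** — both mates inside parental
  exons but in *different* exons, with a reference separation far exceeding
  the library insert size: the fragment came from an intronless template.
* **trans-mate pairs** — one mate in the parental gene, the other mate far
  away or on another chromosome: the far mate marks the insertion locus.

A locus is called only when both signal classes support it (the
both-signals rule); trans-mate evidence alone yields a candidate.
Split reads clipped precisely at an exon boundary, whose clipped bases
match the adjacent exon, add junction support.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd
import pysam

from .genemodel import GeneModel, revcomp

logger = logging.getLogger(__name__)


class SignalClass(Enum):
    """Exhaustive, mutually exclusive classification of a read pair."""

    CONCORDANT = "CONCORDANT"
    JUNCTION_SPANNING = "JUNCTION_SPANNING"
    TRANS_MATE = "TRANS_MATE"
    OTHER = "OTHER"


class CallStatus(Enum):
    CONFIDENT = "CONFIDENT"
    CANDIDATE = "CANDIDATE"
    FRAGMENT = "FRAGMENT"


@dataclass(frozen=True)
class MateInfo:
    """Primary placement of one mate."""

    mapped: bool
    chrom: str | None = None
    pos: int | None = None        # 1-based leftmost aligned base
    end: int | None = None        # 1-based rightmost aligned base
    strand: str | None = None     # '+' or '-'
    clip_left: int = 0
    clip_right: int = 0
    seq: str | None = None        # reference-forward SEQ (for split checks)


@dataclass(frozen=True)
class PairRecord:
    """One aligned read pair."""

    pair_id: str
    mate1: MateInfo
    mate2: MateInfo

    @property
    def template_span(self) -> int | None:
        """Outer reference span when both mates share a chromosome."""
        m1, m2 = self.mate1, self.mate2
        if not (m1.mapped and m2.mapped) or m1.chrom != m2.chrom:
            return None
        return max(m1.end, m2.end) - min(m1.pos, m2.pos) + 1


@dataclass(frozen=True)
class ScanParams:
    """Detection thresholds.

    ``k_sd`` sets the insert-size discordance threshold: a same-chromosome
    span above ``insert_mean + k_sd·insert_sd`` is intron-scale, not library
    noise.  Candidate calls need 2 trans-mate pairs; confident calls need 3
    plus 3 units of genome-wide junction support (pairs or split reads).
    ``trans_radius`` excludes local structural noise around the gene from
    trans-mate evidence.
    """

    insert_mean: int = 400
    insert_sd: float = 50.0
    k_sd: float = 4.0
    trans_radius: int = 10_000
    min_trans_candidate: int = 2
    min_trans_confident: int = 3
    min_junction_confident: int = 3
    min_clip: int = 12
    orientation_consensus: float = 0.8
    cluster_window: int | None = None

    @property
    def span_threshold(self) -> float:
        return self.insert_mean + self.k_sd * self.insert_sd

    @property
    def window(self) -> int:
        if self.cluster_window is not None:
            return self.cluster_window
        return int(self.insert_mean + 4 * self.insert_sd)


@dataclass
class MateCluster:
    """Single-linkage cluster of outside mates of trans pairs."""

    chrom: str
    start: int
    end: int
    pairs: list[PairRecord] = field(default_factory=list)

    @property
    def n_trans(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class InsertionCall:
    """A called retrocopy insertion locus."""

    chrom: str
    start: int
    end: int
    n_junction_pairs: int
    n_trans_pairs: int
    orientation: str           # '+', '-', or 'unknown'
    status: CallStatus

    def contains(self, chrom: str, pos: int, slop: int = 0) -> bool:
        return (chrom == self.chrom
                and self.start - slop <= pos <= self.end + slop)


# ----------------------------------------------------------------------
# SAM ingestion
# ----------------------------------------------------------------------
def _mate_info(rec: pysam.AlignedSegment) -> MateInfo:
    if rec.is_unmapped:
        return MateInfo(mapped=False)
    clip_l = clip_r = 0
    cig = rec.cigartuples or []
    if cig and cig[0][0] in (4, 5):
        clip_l = cig[0][1]
    if cig and cig[-1][0] in (4, 5):
        clip_r = cig[-1][1]
    return MateInfo(
        mapped=True,
        chrom=rec.reference_name,
        pos=rec.reference_start + 1,
        end=rec.reference_end,   # pysam: exclusive 0-based == inclusive 1-based
        strand="-" if rec.is_reverse else "+",
        clip_left=clip_l,
        clip_right=clip_r,
        seq=rec.query_sequence,
    )


def read_pairs(sam_path: str) -> list[PairRecord]:
    """Pair primary alignments of a SAM/BAM file by query name."""
    pending: dict[str, pysam.AlignedSegment] = {}
    pairs: list[PairRecord] = []
    with pysam.AlignmentFile(sam_path, check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = rec
                continue
            first, second = (mate, rec) if mate.is_read1 else (rec, mate)
            pairs.append(PairRecord(pair_id=rec.query_name,
                                    mate1=_mate_info(first),
                                    mate2=_mate_info(second)))
    for name, rec in pending.items():
        pairs.append(PairRecord(pair_id=name, mate1=_mate_info(rec),
                                mate2=MateInfo(mapped=False)))
    return pairs


# ----------------------------------------------------------------------
# Classification
# ----------------------------------------------------------------------
def _overlaps_gene(m: MateInfo, gene: GeneModel, margin: int = 0) -> bool:
    return (m.mapped and m.chrom == gene.chrom
            and gene.overlaps_region(m.pos, m.end, margin))


def _exon_index(m: MateInfo, gene: GeneModel) -> int | None:
    """Exon containing the midpoint of the aligned span."""
    if not m.mapped or m.chrom != gene.chrom:
        return None
    return gene.exon_index_at((m.pos + m.end) // 2)


def classify_pair(pair: PairRecord, gene: GeneModel,
                  params: ScanParams) -> SignalClass:
    """Assign one pair to exactly one signal class.

    Junction-spanning: both mates in different parental exons with an
    intron-scale span.  Trans-mate: exactly one mate in the gene region and
    the other beyond ``trans_radius`` (or on another chromosome).
    Concordant: proper FR geometry within the insert-size envelope.
    Anything else — including unmapped mates — is OTHER.
    """
    m1, m2 = pair.mate1, pair.mate2
    if not (m1.mapped and m2.mapped):
        return SignalClass.OTHER

    in1, in2 = _overlaps_gene(m1, gene), _overlaps_gene(m2, gene)
    span = pair.template_span

    if in1 and in2:
        e1, e2 = _exon_index(m1, gene), _exon_index(m2, gene)
        if (e1 is not None and e2 is not None and e1 != e2
                and span is not None and span > params.span_threshold):
            return SignalClass.JUNCTION_SPANNING
    if in1 != in2:
        inside, outside = (m1, m2) if in1 else (m2, m1)
        if outside.chrom != gene.chrom:
            return SignalClass.TRANS_MATE
        gs, ge = gene.region
        dist = max(gs - outside.end, outside.pos - ge, 0)
        if dist > params.trans_radius:
            return SignalClass.TRANS_MATE

    if (m1.chrom == m2.chrom and m1.strand != m2.strand
            and span is not None and span <= params.span_threshold):
        left, right = (m1, m2) if m1.pos <= m2.pos else (m2, m1)
        if left.strand == "+":
            return SignalClass.CONCORDANT
    return SignalClass.OTHER


def count_split_junction_reads(pairs: list[PairRecord], gene: GeneModel,
                               params: ScanParams,
                               boundary_tol: int = 2) -> int:
    """Split-read junction evidence.

    A read soft-clipped at an exon boundary whose clipped bases match the
    adjacent exon's proximal sequence is a junction read: the fragment
    crossed a spliced-out intron.  Counts each qualifying mate once.
    """
    # cDNA in genomic exon order on the reference forward strand
    cdna = "".join(
        gene.mrna[a - 1: b]
        for a, b in _mrna_ranges_in_genomic_order(gene)
    ) if gene.strand == "+" else "".join(
        revcomp(gene.mrna[a - 1: b])
        for a, b in _mrna_ranges_in_genomic_order(gene)
    )
    bounds = []  # per exon (genomic order): (gstart, gend, cstart, cend) 1-based in cdna
    acc = 0
    for (gs, ge) in gene.exons:
        ln = ge - gs + 1
        bounds.append((gs, ge, acc + 1, acc + ln))
        acc += ln

    n = 0
    for pair in pairs:
        for m in (pair.mate1, pair.mate2):
            if not m.mapped or m.chrom != gene.chrom or m.seq is None:
                continue
            if _is_split_junction(m, bounds, cdna, params.min_clip,
                                  boundary_tol):
                n += 1
    return n


def _mrna_ranges_in_genomic_order(gene: GeneModel):
    acc, ranges = 0, []
    for s, e in gene.exons:
        ranges.append((acc + 1, acc + (e - s + 1)))
        acc += e - s + 1
    if gene.strand == "-":
        total = acc
        ranges = [(total - b + 1, total - a + 1) for a, b in ranges]
    return ranges


def _is_split_junction(m: MateInfo, bounds, cdna: str, min_clip: int,
                       tol: int) -> bool:
    for i, (gs, ge, cs, ce) in enumerate(bounds):
        # right clip at the 3' (genomic) edge of exon i -> next exon ahead
        if (i + 1 < len(bounds) and m.clip_right >= min_clip
                and abs(m.end - ge) <= tol):
            clipped = m.seq[len(m.seq) - m.clip_right:]
            want = cdna[ce: ce + len(clipped)]
            if want and clipped[:len(want)] == want:
                return True
        # left clip at the 5' (genomic) edge of exon i -> previous exon
        if (i > 0 and m.clip_left >= min_clip and abs(m.pos - gs) <= tol):
            clipped = m.seq[:m.clip_left]
            want = cdna[max(0, cs - 1 - len(clipped)): cs - 1]
            if want and clipped[-len(want):] == want:
                return True
    return False


# ----------------------------------------------------------------------
# Clustering and calling
# ----------------------------------------------------------------------
def outside_mate(pair: PairRecord, gene: GeneModel) -> MateInfo:
    """The mate of a trans pair that lies away from the gene."""
    if _overlaps_gene(pair.mate1, gene):
        return pair.mate2
    return pair.mate1


def cluster_trans_mates(trans_pairs: list[PairRecord], gene: GeneModel,
                        window: int) -> list[MateCluster]:
    """Single-linkage clustering of outside-mate positions.

    Two mates join a cluster iff they lie on the same chromosome with a
    start-to-start gap of at most ``window``.  Clusters are returned sorted
    by (chrom, start).
    """
    keyed = sorted(
        ((outside_mate(p, gene), p) for p in trans_pairs),
        key=lambda t: (t[0].chrom, t[0].pos),
    )
    clusters: list[MateCluster] = []
    for mate, pair in keyed:
        if (clusters and clusters[-1].chrom == mate.chrom
                and mate.pos - clusters[-1]._last_pos <= window):
            c = clusters[-1]
            c.end = max(c.end, mate.end)
            c.pairs.append(pair)
            c._last_pos = mate.pos
        else:
            c = MateCluster(chrom=mate.chrom, start=mate.pos, end=mate.end,
                            pairs=[pair])
            c._last_pos = mate.pos
            clusters.append(c)
    return clusters


def _cluster_orientation(cluster: MateCluster, gene: GeneModel,
                         consensus: float) -> str:
    """Retrocopy orientation from mate-strand concordance.

    For a sense insertion (same orientation as the parental transcript on
    the reference), the gene-side and outside mates of a trans pair map to
    opposite strands; for an antisense insertion they map to the same
    strand.  Requires ``consensus`` agreement, otherwise 'unknown'.
    """
    votes = Counter()
    for p in cluster.pairs:
        out = outside_mate(p, gene)
        ins = p.mate2 if out is p.mate1 else p.mate1
        if out.strand is None or ins.strand is None:
            continue
        opposite = out.strand != ins.strand
        sense = opposite if gene.strand == "+" else not opposite
        votes["+" if sense else "-"] += 1
    total = sum(votes.values())
    if total == 0:
        return "unknown"
    top, cnt = votes.most_common(1)[0]
    if cnt / total >= consensus and not (len(votes) > 1 and
                                         votes.most_common(2)[1][1] == cnt):
        return top
    return "unknown"


def call_insertions(junction_support: int, clusters: list[MateCluster],
                    gene: GeneModel, params: ScanParams,
                    reference_fragments: list[tuple[str, int, int]] | None = None
                    ) -> list[InsertionCall]:
    """Apply the both-signals rule to clustered evidence.

    Every cluster with at least ``min_trans_candidate`` trans pairs becomes
    a call.  A call is CONFIDENT only when the cluster has
    ``min_trans_confident`` pairs *and* genome-wide junction support reaches
    ``min_junction_confident``; otherwise it is a CANDIDATE.  Clusters
    overlapping an annotated reference retrocopy fragment are labelled
    FRAGMENT.
    """
    calls = []
    for c in clusters:
        if c.n_trans < params.min_trans_candidate:
            continue
        status = CallStatus.CANDIDATE
        if reference_fragments and any(
                fc == c.chrom and fs <= c.end and fe >= c.start
                for fc, fs, fe in reference_fragments):
            status = CallStatus.FRAGMENT
        elif (c.n_trans >= params.min_trans_confident
                and junction_support >= params.min_junction_confident):
            status = CallStatus.CONFIDENT
        calls.append(InsertionCall(
            chrom=c.chrom, start=c.start, end=c.end,
            n_junction_pairs=junction_support, n_trans_pairs=c.n_trans,
            orientation=_cluster_orientation(c, gene,
                                             params.orientation_consensus),
            status=status,
        ))
    return calls


# ----------------------------------------------------------------------
# Whole-sample scan and cohort screen
# ----------------------------------------------------------------------
@dataclass
class ScanResult:
    calls: list[InsertionCall]
    class_counts: dict[str, int]
    junction_support: int


def scan_sam(sam_path: str, gene: GeneModel, params: ScanParams | None = None,
             reference_fragments: list[tuple[str, int, int]] | None = None
             ) -> ScanResult:
    """Classify every pair of one sample and call insertion loci."""
    params = params or ScanParams()
    pairs = read_pairs(sam_path)
    by_class: dict[SignalClass, list[PairRecord]] = {c: [] for c in SignalClass}
    for p in pairs:
        by_class[classify_pair(p, gene, params)].append(p)
    junction_pairs = by_class[SignalClass.JUNCTION_SPANNING]
    # split reads supplement pair evidence; pairs already counted as
    # junction-spanning are excluded so no fragment is counted twice
    split_n = count_split_junction_reads(
        by_class[SignalClass.CONCORDANT] + by_class[SignalClass.OTHER]
        + by_class[SignalClass.TRANS_MATE], gene, params)
    junction_support = len(junction_pairs) + split_n
    clusters = cluster_trans_mates(by_class[SignalClass.TRANS_MATE], gene,
                                   params.window)
    calls = call_insertions(junction_support, clusters, gene, params,
                            reference_fragments)
    counts = {c.value: len(v) for c, v in by_class.items()}
    counts["SPLIT_JUNCTION_READS"] = split_n
    logger.info("scan %s: %s, %d clusters, %d calls", sam_path, counts,
                len(clusters), len(calls))
    return ScanResult(calls=calls, class_counts=counts,
                      junction_support=junction_support)


def screen_cohort(sam_paths: dict[str, str], gene: GeneModel,
                  params: ScanParams | None = None) -> pd.DataFrame:
    """Scan many samples; one row per sample × call.

    Samples with no calls are retained with empty call fields; unreadable
    files are logged and marked ``failed`` without aborting the batch.
    """
    params = params or ScanParams()
    rows = []
    for sample, path in sam_paths.items():
        try:
            result = scan_sam(path, gene, params)
        except (OSError, ValueError) as exc:
            logger.error("sample %s failed: %s", sample, exc)
            rows.append({"sample": sample, "status": "failed"})
            continue
        if not result.calls:
            rows.append({"sample": sample, "status": "no_call"})
        for call in result.calls:
            rows.append({
                "sample": sample, "status": call.status.value,
                "chrom": call.chrom, "start": call.start, "end": call.end,
                "n_junction": call.n_junction_pairs,
                "n_trans": call.n_trans_pairs,
                "orientation": call.orientation,
            })
    return pd.DataFrame(rows, columns=["sample", "status", "chrom", "start",
                                       "end", "n_junction", "n_trans",
                                       "orientation"])
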