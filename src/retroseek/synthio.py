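"""Synthetic genomes with planted retrocopy insertions and simulated alignments.

The detection method consumes paired-end alignments of an individual carrying
a retrocopy, mapped against a reference that lacks it: reads internal to the
retrocopy pile onto the parental gene's exons, pairs straddling a spliced-out
intron become exon–exon discordant, and pairs straddling an insertion
junction become trans-mate discordant.  This module builds exactly that data
from first principles — a random reference with a multi-exon gene, retrocopy
insertion with target site duplication (TSD), polyA tail, optional 5'/3'
truncation and either orientation, and read pairs whose alignments are
derived by coordinate projection rather than by running an aligner.  Every
pair carries a truth label, so detection can be scored against the plant.

Coordinates are 1-based inclusive throughout; SAM/BED writers convert.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pysam

from .genemodel import GeneModel, revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = {"TAA", "TAG", "TGA"}

# truth labels for simulated pairs
CONCORDANT = "concordant"
JUNCTION = "junction_spanning"
TRANS = "trans_mate"
OTHER = "other"

MIN_MAPPABLE = 20  # bp of contiguous reference projection required to place a read


@dataclass(frozen=True)
class SimConfig:
    """Sequencing-library and reproducibility parameters.

    Defaults describe a generic short-read WGS library: 100 bp reads,
    400 ± 50 bp fragments, 20-fold coverage, 1e-3 substitution error.
    """

    read_len: int = 100
    insert_mean: int = 400
    insert_sd: float = 50.0
    coverage: float = 20.0
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.insert_mean <= 2 * self.read_len:
            raise ValueError("insert_mean should exceed 2 × read_len")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")


@dataclass(frozen=True)
class GeneSpec:
    """Blueprint for the parental gene planted in the synthetic reference.

    Default proportions echo a compact three-exon growth-factor gene with a
    ~3.2 kb mRNA whose ORF spans all exons.
    """

    exon_lengths: tuple[int, ...] = (476, 104, 2620)
    intron_lengths: tuple[int, ...] = (1208, 645)
    utr5_len: int = 460
    orf_len: int = 621
    chrom: str = "chr1"
    gene_start: int = 60_001
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.exon_lengths) < 2:
            raise ValueError("need at least 2 exons for exon–exon signals")
        if len(self.intron_lengths) != len(self.exon_lengths) - 1:
            raise ValueError("need one intron fewer than exons")
        if any(x <= 0 for x in self.exon_lengths + self.intron_lengths):
            raise ValueError("exon/intron lengths must be positive")
        if self.orf_len % 3 != 0:
            raise ValueError("ORF length must be a multiple of 3")
        if self.utr5_len + self.orf_len >= sum(self.exon_lengths):
            raise ValueError("UTR5 + ORF must leave room for a 3' UTR")

    @property
    def mrna_len(self) -> int:
        return sum(self.exon_lengths)

    def exon_intervals(self) -> tuple[tuple[int, int], ...]:
        out, pos = [], self.gene_start
        for i, length in enumerate(self.exon_lengths):
            out.append((pos, pos + length - 1))
            pos += length
            if i < len(self.intron_lengths):
                pos += self.intron_lengths[i]
        return tuple(out)


@dataclass(frozen=True)
class InsertionTruth:
    """Ground truth for one planted retrocopy insertion.

    ``target_pos`` is the last reference base duplicated by integration:
    bases ``[target_pos − tsd_len + 1, target_pos]`` appear once in the
    reference and twice — flanking the insert — in the mutated genome.
    """

    target_chrom: str
    target_pos: int
    tsd_len: int = 13
    strand: str = "+"
    trunc5: int = 0
    trunc3: int = 0
    polyA_len: int = 30

    def __post_init__(self) -> None:
        if self.tsd_len < 0:
            raise ValueError("tsd_len must be >= 0")
        if self.trunc5 < 0 or self.trunc3 < 0:
            raise ValueError("truncations must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


@dataclass
class GenomeModel:
    """Reference chromosomes plus the parental gene model."""

    seqs: dict[str, str]
    gene: GeneModel


@dataclass(frozen=True)
class _Piece:
    """A run of the mutated genome with a single reference projection.

    ``orient`` +1 means mutated offsets increase with reference coordinate;
    −1 means the run projects onto the reference reverse strand (retrocopy
    inserted antisense).  ``kind`` is one of ref / exon / polyA / tsd.
    """

    start: int           # 1-based start in mutated coordinates
    length: int
    kind: str
    ref_chrom: str | None
    ref_lo: int | None   # reference interval (1-based inclusive), lo <= hi
    ref_hi: int | None
    orient: int = 1

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass
class MutatedGenome:
    """A genome with planted insertions and its reference projection map."""

    seqs: dict[str, str]
    gene: GeneModel
    ref_lengths: dict[str, int]
    pieces: dict[str, list[_Piece]]
    truths: list[InsertionTruth] = field(default_factory=list)
    alleles: dict[str, str] = field(default_factory=dict)  # per-truth key


# ----------------------------------------------------------------------
# Genome construction
# ----------------------------------------------------------------------
def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _random_orf(rng: np.random.Generator, n: int) -> str:
    """ATG + non-stop codons + TAA, total length n (multiple of 3)."""
    codons = ["ATG"]
    for _ in range(n // 3 - 2):
        while True:
            c = _random_seq(rng, 3)
            if c not in _STOPS:
                break
        codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def build_genome(config: SimConfig, gene_spec: GeneSpec | None = None,
                 chrom_lengths: dict[str, int] | None = None) -> GenomeModel:
    """Generate a reference genome containing one multi-exon gene.

    Deterministic for a given ``config.seed``.  The spliced mRNA is written
    into the gene's exons so that it carries a translatable ORF (ATG …
    in-frame stop only at the end) between real UTRs.
    """
    spec = gene_spec or GeneSpec()
    lengths = chrom_lengths or {"chr1": 200_000, "chr2": 200_000}
    exons = spec.exon_intervals()
    if spec.chrom not in lengths:
        raise ValueError(f"gene chromosome {spec.chrom!r} not in chrom_lengths")
    if exons[-1][1] > lengths[spec.chrom]:
        raise ValueError("gene extends past its chromosome")

    rng = np.random.default_rng(config.seed)
    seqs = {name: _random_seq(rng, n) for name, n in sorted(lengths.items())}

    mrna = (_random_seq(rng, spec.utr5_len)
            + _random_orf(rng, spec.orf_len)
            + _random_seq(rng, spec.mrna_len - spec.utr5_len - spec.orf_len))

    # write the spliced mRNA into the exons (transcript strand aware)
    chrom_list = list(seqs[spec.chrom])
    offset = 0
    exon_iter = exons if spec.strand == "+" else tuple(reversed(exons))
    for s, e in exon_iter:
        piece = mrna[offset: offset + (e - s + 1)]
        if spec.strand == "-":
            piece = revcomp(piece)
        chrom_list[s - 1: e] = piece
        offset += e - s + 1
    seqs[spec.chrom] = "".join(chrom_list)

    gene = GeneModel(
        chrom=spec.chrom, strand=spec.strand, exons=exons,
        utr5=(1, spec.utr5_len),
        orf=(spec.utr5_len + 1, spec.utr5_len + spec.orf_len),
        utr3=(spec.utr5_len + spec.orf_len + 1, spec.mrna_len),
        mrna=mrna,
    )
    return GenomeModel(seqs=seqs, gene=gene)


# ----------------------------------------------------------------------
# Planting retrocopies
# ----------------------------------------------------------------------
def _core_pieces(gene: GeneModel, truth: InsertionTruth) -> tuple[str, list[tuple[int, str, str, int, int, int]]]:
    """Oriented insert core and its projection runs.

    Returns (core_seq, runs) where each run is
    (length, kind, ref_chrom, ref_lo, ref_hi, orient) in core order.
    """
    m = gene.mrna_length
    lo, hi = truth.trunc5 + 1, m - truth.trunc3  # kept mRNA interval
    if lo > hi:
        raise ValueError("truncations remove the whole mRNA")
    # split [lo, hi] at exon boundaries (mRNA coordinates)
    runs_mrna: list[tuple[int, int]] = []
    acc = 0
    for s, e in (gene.exons if gene.strand == "+" else reversed(gene.exons)):
        a, b = acc + 1, acc + (e - s + 1)
        acc = b
        ra, rb = max(a, lo), min(b, hi)
        if ra <= rb:
            runs_mrna.append((ra, rb))
    runs = []
    for a, b in runs_mrna:
        ga, gb = gene.mrna_to_genomic(a), gene.mrna_to_genomic(b)
        orient = 1 if ga <= gb else -1
        runs.append((b - a + 1, "exon", gene.chrom, min(ga, gb), max(ga, gb), orient))
    core = gene.mrna[lo - 1: hi] + "A" * truth.polyA_len
    if truth.polyA_len:
        runs.append((truth.polyA_len, "polyA", None, None, None, 1))
    if truth.strand == "-":
        core = revcomp(core)
        runs = [(ln, kind, c, rl, rh, -o) for ln, kind, c, rl, rh, o in reversed(runs)]
    return core, runs


def plant_retrocopies(genome: GenomeModel, truths: list[InsertionTruth]) -> MutatedGenome:
    """Insert one retrocopy per truth record into a fresh mutated genome.

    Each insertion places the oriented, truncated, polyA-tailed mRNA
    immediately after ``target_pos`` followed by a second copy of the
    target-site bases, so the mutated genome reads
    ``… TSD | insert | TSD …`` while the reference reads ``… TSD …``.
    """
    gene = genome.gene
    by_chrom: dict[str, list[InsertionTruth]] = {}
    for t in truths:
        if t.target_chrom not in genome.seqs:
            raise ValueError(f"unknown chromosome {t.target_chrom!r}")
        n = len(genome.seqs[t.target_chrom])
        if not t.tsd_len < t.target_pos <= n:
            raise ValueError(f"target_pos {t.target_pos} out of bounds")
        gs, ge = gene.region
        if t.target_chrom == gene.chrom and gs <= t.target_pos <= ge:
            raise ValueError("insertion target inside the parental gene")
        by_chrom.setdefault(t.target_chrom, []).append(t)
    for chrom, ts in by_chrom.items():
        ts.sort(key=lambda t: t.target_pos)
        for a, b in zip(ts, ts[1:]):
            if b.target_pos - b.tsd_len <= a.target_pos:
                raise ValueError("insertions too close: TSDs overlap")

    mut = MutatedGenome(seqs={}, gene=gene,
                        ref_lengths={c: len(s) for c, s in genome.seqs.items()},
                        pieces={}, truths=list(truths))
    for chrom, ref in genome.seqs.items():
        ts = by_chrom.get(chrom, [])
        out_parts: list[str] = []
        pieces: list[_Piece] = []
        mut_pos = 1   # next mutated coordinate
        ref_pos = 1   # next reference coordinate
        for t in ts:
            # reference run up to and including target_pos
            seg = ref[ref_pos - 1: t.target_pos]
            if seg:
                pieces.append(_Piece(mut_pos, len(seg), "ref", chrom,
                                     ref_pos, t.target_pos))
                out_parts.append(seg)
                mut_pos += len(seg)
            core, runs = _core_pieces(gene, t)
            out_parts.append(core)
            for ln, kind, c, rl, rh, o in runs:
                pieces.append(_Piece(mut_pos, ln, kind, c, rl, rh, o))
                mut_pos += ln
            tsd_seq = ref[t.target_pos - t.tsd_len: t.target_pos]
            if tsd_seq:
                pieces.append(_Piece(mut_pos, t.tsd_len, "tsd", chrom,
                                     t.target_pos - t.tsd_len + 1, t.target_pos))
                out_parts.append(tsd_seq)
                mut_pos += t.tsd_len
            mut.alleles[f"{chrom}:{t.target_pos}"] = tsd_seq + core + tsd_seq
            ref_pos = t.target_pos + 1
        tail = ref[ref_pos - 1:]
        if tail:
            pieces.append(_Piece(mut_pos, len(tail), "ref", chrom,
                                 ref_pos, len(ref)))
            out_parts.append(tail)
        mut.seqs[chrom] = "".join(out_parts)
        mut.pieces[chrom] = pieces
    return mut


def plant_retrocopy(genome: GenomeModel, gene: GeneModel,
                    truth: InsertionTruth) -> tuple[MutatedGenome, str]:
    """Single-insertion convenience wrapper around :func:`plant_retrocopies`.

    Returns the mutated genome and the inserted allele string
    (TSD + oriented insert + TSD copy).
    """
    if gene is not genome.gene and gene != genome.gene:
        raise ValueError("gene model does not belong to this genome")
    mut = plant_retrocopies(genome, [truth])
    allele = mut.alleles[f"{truth.target_chrom}:{truth.target_pos}"]
    return mut, allele


# ----------------------------------------------------------------------
# Read simulation ("alignment by construction")
# ----------------------------------------------------------------------
@dataclass
class _Mapping:
    """Primary reference placement of one simulated read."""

    mapped: bool
    chrom: str | None = None
    pos: int | None = None          # leftmost reference base (1-based)
    end: int | None = None          # rightmost reference base
    reverse_extra: bool = False     # projection flips the read's strand
    clip_left: int = 0
    clip_right: int = 0
    kind: str = "ref"               # kind of the piece providing most bases


def _map_read(pieces: list[_Piece], starts: list[int], s: int, e: int) -> _Mapping:
    """Project mutated-genome interval [s, e] onto the reference.

    Walks the overlapping pieces, merges runs that continue contiguously in
    the reference, and keeps the longest mappable block as the primary
    alignment; the remainder of the read is soft-clipped.
    """
    i = bisect_right(starts, s) - 1
    blocks: list[tuple[int, int, str, int, int, int, str]] = []
    # (read_off, length, chrom, ref_lo, ref_hi, orient, kind)
    while i < len(pieces) and pieces[i].start <= e:
        p = pieces[i]
        ov_s, ov_e = max(s, p.start), min(e, p.end)
        if ov_s <= ov_e:
            off = ov_s - s
            ln = ov_e - ov_s + 1
            if p.kind == "polyA":
                blocks.append((off, ln, "", 0, 0, 0, "polyA"))
            else:
                d0 = ov_s - p.start
                if p.orient > 0:
                    rlo, rhi = p.ref_lo + d0, p.ref_lo + d0 + ln - 1
                else:
                    rhi = p.ref_hi - d0
                    rlo = rhi - ln + 1
                merged = False
                if blocks:
                    po, pl, pc, plo, phi, por, pk = blocks[-1]
                    if (pc == p.ref_chrom and por == p.orient and por != 0
                            and po + pl == off):
                        if (por > 0 and phi + 1 == rlo) or (por < 0 and plo - 1 == rhi):
                            blocks[-1] = (po, pl + ln, pc, min(plo, rlo),
                                          max(phi, rhi), por,
                                          pk if pk != "tsd" else p.kind)
                            merged = True
                if not merged:
                    blocks.append((off, ln, p.ref_chrom, rlo, rhi, p.orient, p.kind))
        i += 1
    mappable = [b for b in blocks if b[6] != "polyA"]
    if not mappable:
        return _Mapping(mapped=False, kind="polyA")
    off, ln, chrom, rlo, rhi, orient, kind = max(mappable, key=lambda b: b[1])
    if ln < MIN_MAPPABLE:
        return _Mapping(mapped=False, kind=kind)
    read_len = e - s + 1
    return _Mapping(mapped=True, chrom=chrom, pos=rlo, end=rhi,
                    reverse_extra=(orient < 0), clip_left=off,
                    clip_right=read_len - off - ln, kind=kind)


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    n = len(seq)
    k = rng.binomial(n, rate)
    if k == 0:
        return seq
    out = list(seq)
    for pos in rng.integers(0, n, size=k):
        cur = out[pos]
        alts = [b for b in "ACGT" if b != cur]
        out[pos] = alts[rng.integers(0, 3)]
    return "".join(out)


def _truth_label(m1: _Mapping, m2: _Mapping, gene: GeneModel,
                 threshold: float) -> str:
    if not (m1.mapped and m2.mapped):
        return OTHER
    k1, k2 = m1.kind, m2.kind
    in_core1, in_core2 = k1 == "exon", k2 == "exon"
    if in_core1 and in_core2:
        e1 = gene.exon_index_at(m1.pos)
        e2 = gene.exon_index_at(m2.pos)
        if e1 is not None and e2 is not None and e1 != e2:
            span = max(m1.end, m2.end) - min(m1.pos, m2.pos) + 1
            if span > threshold:
                return JUNCTION
        return CONCORDANT
    if in_core1 != in_core2:
        return TRANS
    return CONCORDANT


def simulate_alignments(mut: MutatedGenome, config: SimConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[pysam.AlignmentHeader, list[pysam.AlignedSegment], list[tuple[str, str]]]:
    """Simulate a paired-end library and its reference alignments.

    Fragments are drawn uniformly from the mutated genome; each read's
    alignment is obtained by projecting its coordinates through the
    insertion map (soft-clipping bases that cross junctions or derive from
    the polyA tail).  Returns the SAM header, the aligned segments (sorted
    by coordinate) and per-pair truth labels
    (pair id, concordant/junction_spanning/trans_mate/other).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": n} for c, n in sorted(mut.ref_lengths.items())],
    })
    tids = {c: i for i, c in enumerate(sorted(mut.ref_lengths))}
    threshold = config.insert_mean + 4 * config.insert_sd
    segments: list[pysam.AlignedSegment] = []
    labels: list[tuple[str, str]] = []

    for chrom in sorted(mut.seqs):
        seq = mut.seqs[chrom]
        pieces = mut.pieces[chrom]
        starts = [p.start for p in pieces]
        n = len(seq)
        n_pairs = int(round(config.coverage * n / (2 * config.read_len)))
        flens = rng.normal(config.insert_mean, config.insert_sd, size=n_pairs)
        flens = np.clip(np.rint(flens), 2 * config.read_len, n).astype(int)
        starts_arr = rng.integers(1, n - flens + 2)  # 1-based fragment starts
        for i in range(n_pairs):
            fs, fl = int(starts_arr[i]), int(flens[i])
            fe = fs + fl - 1
            pid = f"sim_{chrom}_{i}"
            r1_s, r1_e = fs, fs + config.read_len - 1
            r2_s, r2_e = fe - config.read_len + 1, fe
            m1 = _map_read(pieces, starts, r1_s, r1_e)
            m2 = _map_read(pieces, starts, r2_s, r2_e)
            # slices kept in mutated-genome forward orientation; read2 is
            # sequenced as their reverse complement but substitution errors
            # are orientation-free
            raw1 = _apply_errors(rng, seq[r1_s - 1: r1_e], config.error_rate)
            raw2 = _apply_errors(rng, seq[r2_s - 1: r2_e], config.error_rate)
            labels.append((pid, _truth_label(m1, m2, mut.gene, threshold)))
            segments.extend(_make_pair(header, tids, pid, raw1, raw2, m1, m2,
                                       config))
    segments.sort(key=lambda a: (a.reference_id if a.reference_id >= 0 else 1 << 30,
                                 a.reference_start if a.reference_start >= 0 else 1 << 30))
    return header, segments, labels


def _make_pair(header, tids, pid, raw1, raw2, m1, m2, config):
    """Build the two SAM records of one simulated pair.

    ``raw1``/``raw2`` are the mutated-genome forward-orientation slices of
    the two read positions; read1 is sequenced forward, read2 reverse, and a
    projection through an antisense insert flips a read's mapping strand.
    """
    recs = []
    for idx, (raw, m, base_rev, other) in enumerate(
            ((raw1, m1, False, m2), (raw2, m2, True, m1))):
        a = pysam.AlignedSegment(header)
        a.query_name = pid
        flag = 0x1 | (0x40 if idx == 0 else 0x80)
        is_rev = base_rev ^ m.reverse_extra
        other_rev = (not base_rev) ^ other.reverse_extra
        if is_rev:
            flag |= 0x10
        if other.mapped and other_rev:
            flag |= 0x20
        if m.mapped:
            a.reference_id = tids[m.chrom]
            a.reference_start = m.pos - 1
            cl, cr = m.clip_left, m.clip_right
            if m.reverse_extra:
                # projection reversed the slice: clips swap ends in ref orientation
                cl, cr = cr, cl
            match_len = len(raw) - cl - cr
            cig = []
            if cl:
                cig.append((4, cl))
            cig.append((0, match_len))
            if cr:
                cig.append((4, cr))
            a.cigartuples = cig
            a.mapping_quality = 60
        else:
            flag |= 0x4
            a.mapping_quality = 0
            if other.mapped:  # placed with its mate per SAM convention
                a.reference_id = tids[other.chrom]
                a.reference_start = other.pos - 1
        if not other.mapped:
            flag |= 0x8
        if other.mapped:
            a.next_reference_id = tids[other.chrom]
            a.next_reference_start = other.pos - 1
        elif m.mapped:
            a.next_reference_id = a.reference_id
            a.next_reference_start = a.reference_start
        if (m.mapped and other.mapped and m.chrom == other.chrom
                and is_rev != other_rev):
            lo = min(m.pos, other.pos)
            hi = max(m.end, other.end)
            tlen = hi - lo + 1
            if (abs(tlen - config.insert_mean) <= 4 * config.insert_sd
                    and ((m.pos <= other.pos and not is_rev)
                         or (other.pos <= m.pos and not other_rev))):
                flag |= 0x2
            a.template_length = tlen if m.pos <= other.pos else -tlen
        # SEQ is stored on the reference forward strand
        stored = revcomp(raw) if (m.mapped and m.reverse_extra) else raw
        a.query_sequence = stored
        a.query_qualities = pysam.qualitystring_to_array("I" * len(stored))
        a.flag = flag
        recs.append(a)
    return recs


# ----------------------------------------------------------------------
# File output
# ----------------------------------------------------------------------
def write_fasta(seqs: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def write_sam(header: pysam.AlignmentHeader,
              segments: list[pysam.AlignedSegment], path: str) -> None:
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for seg in segments:
            out.write(seg)


def write_truth(mut: MutatedGenome, labels: list[tuple[str, str]],
                bed_path: str, tsv_path: str) -> None:
    """Truth BED of insertion TSD intervals and per-pair label TSV."""
    with open(bed_path, "w") as fh:
        for t in sorted(mut.truths, key=lambda t: (t.target_chrom, t.target_pos)):
            start0 = t.target_pos - t.tsd_len  # 0-based half-open
            fh.write(f"{t.target_chrom}\t{start0}\t{t.target_pos}\t"
                     f"retrocopy\t{t.tsd_len}\t{t.strand}\n")
    with open(tsv_path, "w") as fh:
        fh.write("pair_id\tclass\n")
        for pid, lab in labels:
            fh.write(f"{pid}\t{lab}\n")


def simulate_to_dir(config: SimConfig, outdir: str,
                    gene_spec: GeneSpec | None = None,
                    truths: list[InsertionTruth] | None = None,
                    chrom_lengths: dict[str, int] | None = None) -> MutatedGenome:
    """End-to-end convenience: build, plant, simulate, write all outputs."""
    import os
    os.makedirs(outdir, exist_ok=True)
    genome = build_genome(config, gene_spec, chrom_lengths)
    if truths is None:
        truths = [InsertionTruth(target_chrom="chr2", target_pos=100_000,
                                 tsd_len=13)]
    mut = plant_retrocopies(genome, truths)
    header, segments, labels = simulate_alignments(mut, config)
    write_fasta(genome.seqs, os.path.join(outdir, "reference.fa"))
    write_fasta(mut.seqs, os.path.join(outdir, "donor.fa"))
    write_sam(header, segments, os.path.join(outdir, "alignments.sam"))
    write_truth(mut, labels, os.path.join(outdir, "truth.bed"),
                os.path.join(outdir, "truth_pairs.tsv"))
    with open(os.path.join(outdir, "gene.tsv"), "w") as fh:
        g = mut.gene
        fh.write("chrom\tstrand\texon_starts\texon_ends\tutr5\torf\tutr3\n")
        fh.write("\t".join([
            g.chrom, g.strand,
            ",".join(str(s) for s, _ in g.exons),
            ",".join(str(e) for _, e in g.exons),
            f"{g.utr5[0]}-{g.utr5[1]}", f"{g.orf[0]}-{g.orf[1]}",
            f"{g.utr3[0]}-{g.utr3[1]}"]) + "\n")
    return mut
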