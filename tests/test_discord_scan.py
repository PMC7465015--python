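"""Pair classification, trans-mate clustering, and the both-signals rule."""

import os

import pysam
import pytest

from retroseek import discord_scan, synthio
from retroseek.discord_scan import (CallStatus, MateCluster, MateInfo,
                                    PairRecord, ScanParams, SignalClass)

from conftest import simulate_and_scan

PARAMS = ScanParams()


def _mate(chrom, pos, end=None, strand="+", mapped=True):
    if not mapped:
        return MateInfo(mapped=False)
    return MateInfo(mapped=True, chrom=chrom, pos=pos,
                    end=end if end is not None else pos + 99, strand=strand)


def _pair(m1, m2, pid="p"):
    return PairRecord(pair_id=pid, mate1=m1, mate2=m2)


# ----------------------------------------------------------------------
# classify_pair
# ----------------------------------------------------------------------
def test_exon_to_exon_pair_is_junction_spanning(toy_genome):
    g = toy_genome.gene
    (e1s, e1e), _, (e3s, e3e) = g.exons
    pair = _pair(_mate(g.chrom, e1s + 10, strand="+"),
                 _mate(g.chrom, e3s + 10, strand="-"))
    assert discord_scan.classify_pair(pair, g, PARAMS) is SignalClass.JUNCTION_SPANNING


def test_same_exon_proper_pair_is_concordant(toy_genome):
    g = toy_genome.gene
    e3s = g.exons[2][0]
    pair = _pair(_mate(g.chrom, e3s + 10, strand="+"),
                 _mate(g.chrom, e3s + 300, strand="-"))
    assert discord_scan.classify_pair(pair, g, PARAMS) is SignalClass.CONCORDANT


def test_cross_chromosome_mate_is_trans(toy_genome):
    g = toy_genome.gene
    pair = _pair(_mate(g.chrom, g.exons[0][0] + 5),
                 _mate("chr2", 40_000, strand="-"))
    assert discord_scan.classify_pair(pair, g, PARAMS) is SignalClass.TRANS_MATE


def test_far_same_chromosome_mate_is_trans(toy_genome):
    g = toy_genome.gene
    far = g.region[1] + PARAMS.trans_radius + 5_000
    pair = _pair(_mate(g.chrom, g.exons[0][0] + 5), _mate(g.chrom, far))
    assert discord_scan.classify_pair(pair, g, PARAMS) is SignalClass.TRANS_MATE


def test_nearby_outside_mate_is_not_trans(toy_genome):
    g = toy_genome.gene
    near = g.region[1] + 500
    pair = _pair(_mate(g.chrom, g.exons[2][1] - 150, strand="+"),
                 _mate(g.chrom, near, strand="-"))
    assert discord_scan.classify_pair(pair, g, PARAMS) is not SignalClass.TRANS_MATE


def test_unmapped_mate_never_raises(toy_genome):
    g = toy_genome.gene
    pair = _pair(_mate(g.chrom, g.exons[0][0]), _mate("", 0, mapped=False))
    assert discord_scan.classify_pair(pair, g, PARAMS) is SignalClass.OTHER


def test_every_pair_gets_exactly_one_class(toy_genome, sim_config, tmp_path):
    truth = synthio.InsertionTruth(target_chrom="chr2", target_pos=30_000)
    mut = synthio.plant_retrocopies(toy_genome, [truth])
    header, segments, labels = synthio.simulate_alignments(mut, sim_config)
    sam = tmp_path / "x.sam"
    synthio.write_sam(header, segments, str(sam))
    pairs = discord_scan.read_pairs(str(sam))
    assert len(pairs) == len(labels)
    for p in pairs:
        cls = discord_scan.classify_pair(p, toy_genome.gene, PARAMS)
        assert isinstance(cls, SignalClass)


# ----------------------------------------------------------------------
# clustering
# ----------------------------------------------------------------------
def _trans_pair(gene, out_chrom, out_pos, pid, out_strand="+"):
    return _pair(_mate(gene.chrom, gene.exons[0][0] + 5, strand="-"),
                 _mate(out_chrom, out_pos, strand=out_strand), pid=pid)


def test_chain_linkage_joins_nearby_mates(toy_genome):
    g = toy_genome.gene
    pairs = [_trans_pair(g, "chr2", p, f"p{i}")
             for i, p in enumerate([10_000, 10_150, 10_400])]
    clusters = discord_scan.cluster_trans_mates(pairs, g, window=300)
    assert len(clusters) == 1 and clusters[0].n_trans == 3


def test_distant_mates_split_into_two_clusters(toy_genome):
    g = toy_genome.gene
    pairs = [_trans_pair(g, "chr2", p, f"p{i}")
             for i, p in enumerate([10_000, 12_000])]
    clusters = discord_scan.cluster_trans_mates(pairs, g, window=300)
    assert [c.start for c in clusters] == [10_000, 12_000]


def test_empty_input_gives_empty_cluster_list(toy_genome):
    assert discord_scan.cluster_trans_mates([], toy_genome.gene, 300) == []


def test_two_planted_insertions_give_two_clusters(toy_genome, sim_config,
                                                  tmp_path):
    truths = [synthio.InsertionTruth(target_chrom="chr2", target_pos=20_000,
                                     tsd_len=12),
              synthio.InsertionTruth(target_chrom="chr2", target_pos=45_000,
                                     tsd_len=15)]
    _, _, result = simulate_and_scan(toy_genome, truths, sim_config, tmp_path)
    confident = [c for c in result.calls if c.status is CallStatus.CONFIDENT]
    assert len(confident) == 2
    assert confident[0].contains("chr2", 20_000)
    assert confident[1].contains("chr2", 45_000)


# ----------------------------------------------------------------------
# calling rules
# ----------------------------------------------------------------------
def _cluster(gene, n, chrom="chr2", start=10_000):
    pairs = [_trans_pair(gene, chrom, start + 30 * i, f"c{i}")
             for i in range(n)]
    return MateCluster(chrom=chrom, start=start, end=start + 30 * n + 99,
                       pairs=pairs)


def test_trans_only_cluster_is_candidate_not_confident(toy_genome):
    g = toy_genome.gene
    calls = discord_scan.call_insertions(0, [_cluster(g, 5)], g, PARAMS)
    assert len(calls) == 1 and calls[0].status is CallStatus.CANDIDATE


def test_two_trans_pairs_give_candidate(toy_genome):
    g = toy_genome.gene
    calls = discord_scan.call_insertions(10, [_cluster(g, 2)], g, PARAMS)
    assert len(calls) == 1 and calls[0].status is CallStatus.CANDIDATE


def test_single_trans_pair_is_not_called(toy_genome):
    g = toy_genome.gene
    assert discord_scan.call_insertions(10, [_cluster(g, 1)], g, PARAMS) == []


def test_both_signals_give_confident(toy_genome):
    g = toy_genome.gene
    calls = discord_scan.call_insertions(3, [_cluster(g, 3)], g, PARAMS)
    assert calls[0].status is CallStatus.CONFIDENT


def test_reference_fragment_overlap_downgrades_to_fragment(toy_genome):
    g = toy_genome.gene
    calls = discord_scan.call_insertions(
        5, [_cluster(g, 5)], g, PARAMS,
        reference_fragments=[("chr2", 9_000, 10_050)])
    assert calls[0].status is CallStatus.FRAGMENT


def test_raising_min_trans_never_adds_confident_calls(toy_genome):
    g = toy_genome.gene
    clusters = [_cluster(g, n, start=10_000 + 5_000 * n) for n in (2, 3, 5, 8)]
    prev = None
    for min_trans in (2, 3, 4, 5, 6, 9):
        params = ScanParams(min_trans_confident=min_trans)
        calls = discord_scan.call_insertions(10, clusters, g, params)
        n_conf = sum(c.status is CallStatus.CONFIDENT for c in calls)
        if prev is not None:
            assert n_conf <= prev
        prev = n_conf


def test_orientation_tie_reports_unknown(toy_genome):
    g = toy_genome.gene
    pairs = [_trans_pair(g, "chr2", 10_000 + 30 * i, f"t{i}",
                         out_strand="+" if i % 2 else "-")
             for i in range(4)]
    cluster = MateCluster(chrom="chr2", start=10_000, end=10_200, pairs=pairs)
    calls = discord_scan.call_insertions(5, [cluster], g, PARAMS)
    assert calls[0].orientation == "unknown"


# ----------------------------------------------------------------------
# cohort screening
# ----------------------------------------------------------------------
def _write_sample(genome, truths, config, path):
    mut = synthio.plant_retrocopies(genome, truths)
    header, segments, _ = synthio.simulate_alignments(mut, config)
    synthio.write_sam(header, segments, str(path))


def test_screen_cohort_flags_exactly_the_carriers(toy_genome, sim_config,
                                                  tmp_path):
    truth = [synthio.InsertionTruth(target_chrom="chr2", target_pos=30_000)]
    _write_sample(toy_genome, truth, sim_config, tmp_path / "carrier1.sam")
    _write_sample(toy_genome, truth, sim_config, tmp_path / "carrier2.sam")
    _write_sample(toy_genome, [], sim_config, tmp_path / "clean.sam")
    table = discord_scan.screen_cohort({
        "carrier1": str(tmp_path / "carrier1.sam"),
        "carrier2": str(tmp_path / "carrier2.sam"),
        "clean": str(tmp_path / "clean.sam"),
    }, toy_genome.gene)
    conf = table[table["status"] == "CONFIDENT"]
    assert sorted(conf["sample"]) == ["carrier1", "carrier2"]
    assert (table[table["sample"] == "clean"]["status"] == "no_call").all()


def test_empty_sam_yields_zero_calls_but_lists_sample(tmp_path, toy_genome):
    sam = tmp_path / "empty.sam"
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 60_000}]})
    with pysam.AlignmentFile(str(sam), "w", header=header):
        pass
    table = discord_scan.screen_cohort({"s1": str(sam)}, toy_genome.gene)
    assert list(table["sample"]) == ["s1"]
    assert list(table["status"]) == ["no_call"]


def test_unreadable_file_marks_sample_failed(tmp_path, toy_genome):
    table = discord_scan.screen_cohort(
        {"bad": str(tmp_path / "missing.sam")}, toy_genome.gene)
    assert list(table["status"]) == ["failed"]


def test_screen_is_deterministic(toy_genome, sim_config, tmp_path):
    truth = [synthio.InsertionTruth(target_chrom="chr2", target_pos=30_000)]
    _write_sample(toy_genome, truth, sim_config, tmp_path / "s.sam")
    paths = {"s": str(tmp_path / "s.sam")}
    a = discord_scan.screen_cohort(paths, toy_genome.gene)
    b = discord_scan.screen_cohort(paths, toy_genome.gene)
    assert a.equals(b)
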