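"""Retrocopy-vs-parental variant calling and haplotype classification."""

import numpy as np
import pandas as pd
import pytest

from retroseek import cli_io, haplocmp
from retroseek.haplocmp import VariantClass

from conftest import FGF4_INDEL, FGF4_UTR3_SNVS


def test_identical_retrocopy_yields_no_variants(toy_genome):
    assert haplocmp.align_and_call(toy_genome.gene.mrna, toy_genome.gene) == []


def test_polya_tail_not_called_as_insertion(toy_genome):
    retro = toy_genome.gene.mrna + "A" * 40
    assert haplocmp.align_and_call(retro, toy_genome.gene) == []


def test_short_input_rejected(toy_genome):
    with pytest.raises(ValueError, match="200"):
        haplocmp.align_and_call("ACGT" * 40, toy_genome.gene)


def test_low_identity_rejected(toy_genome):
    rng = np.random.default_rng(0)
    junk = "".join(rng.choice(list("ACGT"), size=3000))
    with pytest.raises(ValueError, match="identity"):
        haplocmp.align_and_call(junk, toy_genome.gene)


def test_planted_variants_round_trip(toy_genome):
    """Planted substitutions and indels are recovered at the right
    positions with the right alleles and regions, across seeds."""
    gene = toy_genome.gene
    rng = np.random.default_rng(99)
    n_ok = 0
    for _ in range(50):
        m = list(gene.mrna)
        planted = {}
        # three substitutions in distinct regions, away from the termini
        for lo, hi, region in ((20, gene.utr5[1], "UTR5"),
                               (gene.orf[0] + 3, gene.orf[1] - 3, "ORF"),
                               (gene.utr3[0], gene.utr3[1] - 40, "UTR3")):
            p = int(rng.integers(lo, hi))
            alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[m[p - 1]]
            planted[p] = (m[p - 1], alt, region)
            m[p - 1] = alt
        retro = "".join(m)
        called = haplocmp.align_and_call(retro, gene)
        got = {v.mrna_pos: (v.ref, v.alt, v.region) for v in called
               if v.kind == "SNV"}
        if got == planted and len(called) == 3:
            n_ok += 1
        # idempotence: identical call set on a second run
        assert haplocmp.align_and_call(retro, gene) == called
    assert n_ok == 50


def test_planted_deletion_recovered(toy_genome):
    gene = toy_genome.gene
    m = list(gene.mrna)
    # delete one base mid-UTR3, avoiding homopolymer ambiguity at the site
    p = gene.utr3[0] + 200
    while m[p - 1] == m[p] or m[p - 2] == m[p - 1]:
        p += 1
    removed = m.pop(p - 1)
    called = haplocmp.align_and_call("".join(m), gene)
    assert len(called) == 1
    v = called[0]
    assert v.kind == "del" and v.region == "UTR3"
    assert v.ref == gene.mrna[p - 2] + removed and v.alt == gene.mrna[p - 2]
    assert v.mrna_pos == p - 1


def test_planted_insertion_recovered(toy_genome):
    gene = toy_genome.gene
    m = list(gene.mrna)
    p = gene.utr3[0] + 500
    while m[p - 1] == "C" or m[p] == "C":
        p += 1
    m.insert(p, "C")
    called = haplocmp.align_and_call("".join(m), gene)
    assert len(called) == 1 and called[0].kind == "ins"
    assert called[0].alt.endswith("C")


def test_indel_left_normalization_in_homopolymer():
    # deleting any A of the AAAA run normalizes to the leftmost anchored
    # representation: anchor T before the run, deletion of its first A
    got = haplocmp._left_normalize("CCTAAAAGCC", 5, "AA", "A")
    assert got == (3, "TA", "T")


# ----------------------------------------------------------------------
# population classification
# ----------------------------------------------------------------------
def _plant_fgf4_retro(gene):
    """Apply the six published UTR3 SNVs and the single-base deletion."""
    m = list(gene.mrna)
    for gpos, ref, alt in FGF4_UTR3_SNVS:
        p = gene.genomic_to_mrna(gpos)
        assert m[p - 1] == ref
        m[p - 1] = alt
    del_pos = gene.genomic_to_mrna(FGF4_INDEL[0])
    del m[del_pos]  # the base after the anchor
    return "".join(m) + "A" * 30


def test_all_published_snvs_classified_haplotype_shared(fgf4_like_gene,
                                                        tmp_path):
    gene = fgf4_like_gene
    variants = haplocmp.align_and_call(_plant_fgf4_retro(gene), gene)
    assert len(variants) == 7
    vcf = tmp_path / "pop.vcf"
    cli_io.write_vcf([("chr18", v.genomic_pos, v.ref, v.alt)
                      for v in variants], str(vcf))
    classified = haplocmp.classify_variants(variants, str(vcf), gene)
    assert all(v.classification is VariantClass.HAPLOTYPE_SHARED
               for v in classified)


def test_missing_indel_flips_to_retrocopy_specific(fgf4_like_gene, tmp_path):
    gene = fgf4_like_gene
    variants = haplocmp.align_and_call(_plant_fgf4_retro(gene), gene)
    vcf = tmp_path / "pop.vcf"
    cli_io.write_vcf([("chr18", v.genomic_pos, v.ref, v.alt)
                      for v in variants if v.kind == "SNV"], str(vcf))
    classified = haplocmp.classify_variants(variants, str(vcf), gene)
    specific = [v for v in classified
                if v.classification is VariantClass.RETROCOPY_SPECIFIC]
    assert len(specific) == 1
    assert specific[0].genomic_pos == FGF4_INDEL[0]
    assert (specific[0].ref, specific[0].alt) == FGF4_INDEL[1:]


def test_empty_vcf_makes_everything_retrocopy_specific(fgf4_like_gene,
                                                       tmp_path):
    gene = fgf4_like_gene
    variants = haplocmp.align_and_call(_plant_fgf4_retro(gene), gene)
    vcf = tmp_path / "empty.vcf"
    cli_io.write_vcf([], str(vcf))
    classified = haplocmp.classify_variants(variants, str(vcf), gene)
    assert all(v.classification is VariantClass.RETROCOPY_SPECIFIC
               for v in classified)


def test_classification_partitions_the_variant_set(fgf4_like_gene, tmp_path):
    gene = fgf4_like_gene
    variants = haplocmp.align_and_call(_plant_fgf4_retro(gene), gene)
    vcf = tmp_path / "half.vcf"
    cli_io.write_vcf([("chr18", v.genomic_pos, v.ref, v.alt)
                      for v in variants[:3]], str(vcf))
    classified = haplocmp.classify_variants(variants, str(vcf), gene)
    counts = {c: sum(v.classification is c for v in classified)
              for c in VariantClass}
    assert sum(counts.values()) == len(variants)
    assert counts[VariantClass.HAPLOTYPE_SHARED] == 3


def test_same_position_different_allele_is_not_shared(fgf4_like_gene,
                                                      tmp_path):
    gene = fgf4_like_gene
    variants = haplocmp.align_and_call(_plant_fgf4_retro(gene), gene)
    snv = next(v for v in variants if v.kind == "SNV")
    other = {"A": "T", "C": "G", "G": "C", "T": "A"}[snv.alt]
    vcf = tmp_path / "wrong_allele.vcf"
    cli_io.write_vcf([("chr18", snv.genomic_pos, snv.ref, other)], str(vcf))
    classified = haplocmp.classify_variants([snv], str(vcf), gene)
    assert classified[0].classification is VariantClass.RETROCOPY_SPECIFIC


# ----------------------------------------------------------------------
# haplotype matching
# ----------------------------------------------------------------------
def _hap_table(gene, hap_alleles):
    rows = []
    for i, (gpos, ref, alt) in enumerate(FGF4_UTR3_SNVS):
        row = {"chrom": gene.chrom, "pos": gpos, "ref": ref}
        for name, alleles in hap_alleles.items():
            row[name] = alleles[i]
        rows.append(row)
    return pd.DataFrame(rows)


def test_retrocopy_matches_its_source_haplotype(fgf4_like_gene):
    gene = fgf4_like_gene
    alts = [alt for _, _, alt in FGF4_UTR3_SNVS]
    refs = [ref for _, ref, _ in FGF4_UTR3_SNVS]
    table = _hap_table(gene, {
        "H1": refs,                      # reference haplotype
        "H2": alts,                      # the haplotype the retrocopy copied
        "H3": alts[:3] + refs[3:],       # recombinant
        "H4": refs[:1] + alts[1:],
    })
    m = list(gene.mrna)
    for gpos, ref, alt in FGF4_UTR3_SNVS:
        m[gene.genomic_to_mrna(gpos) - 1] = alt
    variants = haplocmp.align_and_call("".join(m), gene)
    best, mism = haplocmp.haplotype_match(variants, table)
    assert best == ["H2"] and mism == 0


def test_post_insertion_mutation_costs_one_mismatch(fgf4_like_gene):
    gene = fgf4_like_gene
    alts = [alt for _, _, alt in FGF4_UTR3_SNVS]
    refs = [ref for _, ref, _ in FGF4_UTR3_SNVS]
    table = _hap_table(gene, {"H1": refs, "H2": alts})
    m = list(gene.mrna)
    for gpos, ref, alt in FGF4_UTR3_SNVS[:-1]:  # one site stays reference
        m[gene.genomic_to_mrna(gpos) - 1] = alt
    variants = haplocmp.align_and_call("".join(m), gene)
    best, mism = haplocmp.haplotype_match(variants, table)
    assert best == ["H2"] and mism == 1


def test_single_haplotype_trivially_matches(fgf4_like_gene):
    gene = fgf4_like_gene
    refs = [ref for _, ref, _ in FGF4_UTR3_SNVS]
    table = _hap_table(gene, {"only": refs})
    best, mism = haplocmp.haplotype_match([], table)
    assert best == ["only"] and mism == 0


def test_uncovered_variant_position_reports_unknown(fgf4_like_gene):
    gene = fgf4_like_gene
    refs = [ref for _, ref, _ in FGF4_UTR3_SNVS]
    table = _hap_table(gene, {"H1": refs}).iloc[:2]  # drop coverage
    m = list(gene.mrna)
    gpos, ref, alt = FGF4_UTR3_SNVS[-1]
    m[gene.genomic_to_mrna(gpos) - 1] = alt
    variants = haplocmp.align_and_call("".join(m), gene)
    best, mism = haplocmp.haplotype_match(variants, table)
    assert best == ["UNKNOWN"] and mism is None
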