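"""Shared fixtures: compact synthetic genomes and an FGF4-like gene model."""

from __future__ import annotations

import os

import numpy as np
import pytest

from retroseek import discord_scan, synthio
from retroseek.genemodel import GeneModel

# small chromosomes keep simulate+scan rounds fast while leaving room for
# insertions far outside the trans-exclusion radius around the gene
TOY_CHROMS = {"chr1": 60_000, "chr2": 60_000}
TOY_GENE = synthio.GeneSpec(gene_start=5_001)


@pytest.fixture
def sim_config() -> synthio.SimConfig:
    return synthio.SimConfig(seed=7, coverage=20)


@pytest.fixture
def toy_genome(sim_config) -> synthio.GenomeModel:
    return synthio.build_genome(sim_config, gene_spec=TOY_GENE,
                                chrom_lengths=TOY_CHROMS)


def simulate_and_scan(genome, truths, config, tmpdir,
                      params: discord_scan.ScanParams | None = None):
    """Plant, simulate, write SAM, scan — the full detection round trip."""
    mut = synthio.plant_retrocopies(genome, truths)
    header, segments, labels = synthio.simulate_alignments(mut, config)
    sam = os.path.join(str(tmpdir), "sim.sam")
    synthio.write_sam(header, segments, sam)
    result = discord_scan.scan_sam(sam, genome.gene,
                                   params or discord_scan.ScanParams())
    return mut, labels, result


def make_fgf4_like_gene(seed: int = 42) -> GeneModel:
    """Synthetic stand-in for the canine FGF4 locus on chr18.

    Three exons with real CFA18-scale coordinates and a 3.2 kb mRNA whose 3'
    UTR covers the genomic positions of the six known retrocopy UTR3 SNVs
    and the red-wolf indel context; reference bases at those positions are
    forced to the published reference alleles.  The sequence elsewhere is
    random — only the coordinate frame and the variant-site bases matter.
    """
    rng = np.random.default_rng(seed)
    exons = ((48_412_100, 48_412_575), (48_413_784, 48_413_887),
             (48_414_533, 48_417_152))
    n = 3200

    def rand(k: int) -> str:
        return "".join(rng.choice(list("ACGT"), size=k))

    orf = ["ATG"]
    for _ in range(205):
        while True:
            c = rand(3)
            if c not in ("TAA", "TAG", "TGA"):
                break
        orf.append(c)
    orf.append("TAA")
    mrna = rand(460) + "".join(orf) + rand(n - 1081)
    forced = {1448: "A", 1453: "C", 1633: "A", 1656: "T", 1709: "G",
              2585: "G", 1732: "T", 1733: "C", 1734: "A", 1735: "G"}
    m = list(mrna)
    for p, b in forced.items():
        m[p - 1] = b
    return GeneModel(chrom="chr18", strand="+", exons=exons,
                     utr5=(1, 460), orf=(461, 1081), utr3=(1082, 3200),
                     mrna="".join(m))


# the six published UTR3 SNVs (genomic pos, ref, alt) and the red-wolf indel
FGF4_UTR3_SNVS = [
    (48_415_400, "A", "C"), (48_415_405, "C", "A"), (48_415_585, "A", "G"),
    (48_415_608, "T", "C"), (48_415_661, "G", "A"), (48_416_537, "G", "A"),
]
FGF4_INDEL = (48_415_685, "CA", "C")


@pytest.fixture
def fgf4_like_gene() -> GeneModel:
    return make_fgf4_like_gene()
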