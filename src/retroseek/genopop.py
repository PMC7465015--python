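"""In-silico PCR support and population genotyping arithmetic.

Two assay geometries matter for retrocopy work.  An exon–exon PCR places
primers in different exons of the parental gene: the genomic allele yields a
product containing the intervening introns, while an intronless retrocopy
yields a product shortened by exactly the summed intron length — the
diagnostic size difference.  A three-primer assay combines a shared primer
at one end of the insertion with allele-specific primers so that
insertion-present and insertion-absent alleles amplify at different sizes.
Genotype tables (copies 0/1/2 per individual) are summarized into allele
frequencies with Wilson score intervals, which behave sensibly at the small
cohort sizes typical of breed panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .genemodel import GeneModel, revcomp


# ----------------------------------------------------------------------
# Amplicon sizing
# ----------------------------------------------------------------------
def exon_exon_product_sizes(gene: GeneModel, primer5_pos: int,
                            primer3_pos: int) -> tuple[int, int]:
    """Product sizes of an exon–exon assay on genomic vs. spliced template.

    Primer positions are 1-based mRNA coordinates of the outermost template
    bases (5' end of the forward primer site, 3' end of the reverse primer
    site).  Both primers must sit in different exons, else the assay cannot
    discriminate a retrocopy.  Returns (genomic_size, spliced_size); their
    difference equals the summed length of the skipped introns.
    """
    if primer5_pos >= primer3_pos:
        raise ValueError("forward primer must precede reverse primer on mRNA")
    e5 = _exon_of_mrna_pos(gene, primer5_pos)
    e3 = _exon_of_mrna_pos(gene, primer3_pos)
    if e5 == e3:
        raise ValueError("primers lie in the same exon: assay cannot "
                         "discriminate an intronless template")
    spliced = primer3_pos - primer5_pos + 1
    lo, hi = sorted((e5, e3))
    genomic = spliced + sum(gene.intron_lengths[lo:hi])
    return genomic, spliced


def _exon_of_mrna_pos(gene: GeneModel, pos: int) -> int:
    """Transcript-order exon index containing an mRNA coordinate."""
    acc = 0
    exons = gene.exons if gene.strand == "+" else tuple(reversed(gene.exons))
    for i, (s, e) in enumerate(exons):
        acc += e - s + 1
        if pos <= acc:
            # convert to genomic-order index so intron slicing works
            return i if gene.strand == "+" else len(exons) - 1 - i
    raise ValueError(f"mRNA position {pos} outside the transcript")


@dataclass(frozen=True)
class PrimerAssay:
    """A (up to three-primer) PCR assay with expected product sizes.

    ``products`` maps allele name → amplicon size in bp.
    """

    name: str
    primers: tuple[str, ...]
    products: dict[str, int]

    def __post_init__(self) -> None:
        for p in self.primers:
            if not p or any(b not in "ACGT" for b in p):
                raise ValueError(f"primer {p!r} must be non-empty A/C/G/T")
        two_shortest = sum(sorted(len(p) for p in self.primers)[:2])
        for allele, size in self.products.items():
            if size <= two_shortest:
                raise ValueError(
                    f"product for {allele!r} ({size} bp) not longer than "
                    f"two primers")


def predict_product_size(template: str, fwd_primer: str,
                         rev_primer: str) -> int | None:
    """Amplicon size of a primer pair on a template, or None.

    The forward primer anneals to the template as given; the reverse primer
    anneals as its reverse complement downstream of the forward site.
    Exact matching only — thermodynamics are out of scope.
    """
    f = template.find(fwd_primer)
    if f < 0:
        return None
    r = template.find(revcomp(rev_primer), f + len(fwd_primer))
    if r < 0:
        return None
    return r + len(rev_primer) - f


def three_primer_assay(name: str, absent_template: str, present_template: str,
                       shared: str, flank_rev: str, insert_rev: str
                       ) -> PrimerAssay:
    """Build a three-primer presence/absence assay from the two alleles.

    ``shared`` is the common forward primer in the 5' flank; ``flank_rev``
    the reverse primer in the 3' flank (amplifies the insertion-absent
    allele); ``insert_rev`` the reverse primer at the insert's 3' end
    (amplifies the insertion-present allele at a different size).
    """
    absent = predict_product_size(absent_template, shared, flank_rev)
    present = predict_product_size(present_template, shared, insert_rev)
    products = {}
    if absent is not None:
        products["absent"] = absent
    if present is not None:
        products["present"] = present
    if not products:
        raise ValueError("no primer pair amplifies either allele")
    return PrimerAssay(name=name, primers=(shared, flank_rev, insert_rev),
                       products=products)


# ----------------------------------------------------------------------
# Allele frequencies
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class FrequencyEstimate:
    n: int          # individuals
    het: int
    homalt: int
    frequency: float
    ci_low: float
    ci_high: float


def allele_frequency(copies: list[int] | pd.Series,
                     alpha: float = 0.05) -> FrequencyEstimate:
    """Insertion allele frequency with a Wilson score interval.

    ``copies`` holds the called number of insertion alleles per individual
    (0, 1 or 2).  Frequency = (het + 2·homalt) / (2n).
    """
    copies = list(copies)
    if not copies:
        raise ValueError("empty cohort")
    if any(c not in (0, 1, 2) for c in copies):
        raise ValueError("copy numbers must be 0, 1 or 2")
    n = len(copies)
    het = sum(c == 1 for c in copies)
    homalt = sum(c == 2 for c in copies)
    count = het + 2 * homalt
    lo, hi = proportion_confint(count, 2 * n, alpha=alpha, method="wilson")
    return FrequencyEstimate(n=n, het=het, homalt=homalt,
                             frequency=count / (2 * n),
                             ci_low=float(lo), ci_high=float(hi))


def screen_summary(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-(breed, marker) frequency report.

    Input columns: ``individual, breed, marker, copies``.  Unknown breed
    labels pass through verbatim.  Output: one row per breed × marker with
    n, het, homalt, frequency (percent, 1 decimal) and the Wilson 95% CI.
    """
    required = {"individual", "breed", "marker", "copies"}
    missing = required - set(genotypes.columns)
    if missing:
        raise ValueError(f"genotype table missing columns: {sorted(missing)}")
    rows = []
    if len(genotypes):
        for (breed, marker), grp in genotypes.groupby(["breed", "marker"],
                                                      sort=True):
            est = allele_frequency(grp["copies"].astype(int))
            rows.append({
                "breed": breed, "marker": marker, "n": est.n,
                "het": est.het, "homalt": est.homalt,
                "frequency_pct": round(100 * est.frequency, 1),
                "ci_low_pct": round(100 * est.ci_low, 1),
                "ci_high_pct": round(100 * est.ci_high, 1),
            })
    return pd.DataFrame(rows, columns=["breed", "marker", "n", "het",
                                       "homalt", "frequency_pct",
                                       "ci_low_pct", "ci_high_pct"])
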