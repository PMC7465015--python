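"""Published canid FGF4 retrocopy insertion sites.

Seven polymorphic FGF4 retrocopies (FGF4L1–FGF4L7) have been characterized
in dogs and red wolves; for each, the genomic interval of the target site
duplication (TSD), the TSD sequence, ten bases of flanking sequence on each
side, the retrocopy strand, and the count of evolutionarily conserved
regions (ECR) within 2.5 kb of the site are known.  The table ships with the
package and is the standard worked input for the site-characterization
stage: junction contexts reconstructed from flank+TSD strings exercise the
TSD finder exactly as a de novo breakpoint assembly would.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_COLUMNS = ["name", "chrom", "start", "end", "strand",
            "flank5", "tsd", "flank3", "ecr", "method"]


def load_sites() -> pd.DataFrame:
    """Load the packaged FGF4 insertion-site table.

    Returns a DataFrame with one row per retrocopy (FGF4L1..FGF4L7) and
    columns ``name, chrom, start, end, strand, flank5, tsd, flank3, ecr,
    method``.  All sequences are printed on the reference forward strand;
    ``strand`` records the orientation of the inserted retrocopy.
    """
    ref = resources.files("retroseek.data") / "fgf4_insertion_sites.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"start": int, "end": int})
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"insertion-site table missing columns: {missing}")
    return df


def window_sequence(row: pd.Series) -> str:
    """flank5 + TSD + flank3 — the insertion-site window used for G/C and
    motif characterization."""
    return row["flank5"] + row["tsd"] + row["flank3"]


def junction_contexts(row: pd.Series) -> tuple[str, str]:
    """Reconstruct the two junction contexts of an insertion site.

    The 5' junction context is the reference sequence ending at the 5'
    insertion junction (upstream flank followed by the duplicated target
    site); the 3' junction context begins at the 3' junction (the second
    TSD copy followed by downstream flank).  These are the inputs the TSD
    finder sees when breakpoints are assembled from real data.
    """
    return row["flank5"] + row["tsd"], row["tsd"] + row["flank3"]
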