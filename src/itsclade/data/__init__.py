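"""Bundled data: published field-survey clade counts.

The TSV holds the read counts per clade and sample from the NW Pacific
*Synechococcus* amplicon survey (8 station/depth samples, 11 SC5.1 clades
plus a *Prochlorococcus* outgroup row).  The counts are inputs for the
composition arithmetic; percentages and totals are always recomputed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from itsclade.stats import CompositionTable

# reads surviving the published screening: QC-passed minus two chimera
# passes and the low-similarity / short-read filters
FIELD_ATTRITION = {
    "qc_passed": 6003,
    "chimera": 65,
    "low_similarity": 103,
    "short": 49,
}


def load_field_counts() -> CompositionTable:
    """The published clade x sample count matrix as a CompositionTable."""
    with resources.files(__package__).joinpath("field_clade_counts.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", index_col="clade")
    outgroup = df.loc["Prochlorococcus"]
    counts = df.drop(index="Prochlorococcus").astype(int)
    return CompositionTable(counts=counts, outgroup_counts=outgroup.astype(int))
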