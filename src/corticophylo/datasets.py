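"""Packaged reference fixtures.

Two small TSVs ship with the package:

* the published 10-tumor corticotroph cohort table (clinical features plus the
  recurrent-SNV gene list per tumor), kept verbatim — including one known gene
  symbol typo and trailing commas — so ingestion normalization is exercised on
  real input;
* the four tumor-group CNV profiles (carcinoma, Crooke cell adenoma, silent
  adenomas, Cushing disease adenomas) assembled from the published gain/loss
  region lists.  The silent-adenoma profile stores both the 17q12 and 17q22
  labels, as the source lists both for the same shared pattern.
"""

from __future__ import annotations

from importlib import resources

from .cnv import CnvMatrix, read_cnv_table
from .cohort_io import CohortTable, read_cohort_table

__all__ = [
    "load_corticotroph_cohort",
    "load_corticotroph_cnv_groups",
    "RECURRENT_GENE_PANEL",
]

#: The six genes recurrently altered across the cohort, in the order the
#: oncoplot panel uses before carrier-count sorting.
RECURRENT_GENE_PANEL = ("USP8", "TP53", "AURKA", "EGFR", "HSD3B1", "CDKN1A")


def _data_path(name: str):
    return resources.files("corticophylo").joinpath("data", name)


def load_corticotroph_cohort() -> CohortTable:
    """The 10-tumor clinical table (ages, diagnoses, diameters, SNV genes)."""
    with resources.as_file(_data_path("corticotroph_cohort.tsv")) as p:
        return read_cohort_table(p)


def load_corticotroph_cnv_groups() -> CnvMatrix:
    """Cytoband gain/loss profiles of the four tumor groups."""
    with resources.as_file(_data_path("corticotroph_cnv_groups.tsv")) as p:
        return read_cnv_table(p)
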