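"""Packaged reference tables: the published ovine DRB1 exon 2 allele
frequencies (33 alleles, 109 rams) and the published allele-specific primer
panel. Both ship as plain TSV under ``transcistor/data``.
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

import pandas as pd

from .population_stats import FrequencyTable
from .primer_design import PrimerPanel, read_primer_table

__all__ = [
    "table1_path",
    "table2_path",
    "load_allele_frequencies",
    "allele_frequency_table",
    "load_published_primers",
]

#: study cohort size behind the published frequency table
PUBLISHED_N_INDIVIDUALS = 109


def table1_path() -> Path:
    return Path(str(files("transcistor.data") / "table1_alleles.tsv"))


def table2_path() -> Path:
    return Path(str(files("transcistor.data") / "table2_primers.tsv"))


def load_allele_frequencies() -> pd.DataFrame:
    """The published frequency table as a DataFrame
    (allele_accession, frequency_percent, number, ipd_name)."""
    return pd.read_csv(table1_path(), sep="\t", comment="#",
                       dtype={"number": str})


def allele_frequency_table() -> FrequencyTable:
    """The published spectrum as a :class:`FrequencyTable` with integer
    chromosome counts re-derived from the printed percentages at n=109."""
    df = load_allele_frequencies()
    return FrequencyTable.from_percentages(
        df["allele_accession"].tolist(),
        df["frequency_percent"].tolist(),
        PUBLISHED_N_INDIVIDUALS,
    )


def load_published_primers(coord_policy: str = "anchor3") -> PrimerPanel:
    """The published primer panel.

    Three printed rows carry a one-off span misprint; the default
    ``anchor3`` policy repairs them from the 3' coordinate (use
    ``coord_policy="strict"`` to see the raising behaviour).
    """
    return read_primer_table(table2_path(), coord_policy=coord_policy)
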