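"""Bundled example datasets.

Small published summaries from an amplicon survey of lactic acid
bacteria (LAB) in koumiss and human fecal samples, shipped as TSV so the
toolkit's arithmetic (target-read proportions, presence/absence,
richness) can be exercised and demonstrated without any download:

* six degenerate LAB-specific 16S primer pairs (L1-L6) with position
  labels and approximate product sizes; the L4 forward entry is flagged
  ``suspect_duplicate`` because it is identical to the 957r reverse
  sequence as published — almost certainly a typesetting artifact, kept
  verbatim rather than corrected;
* per-sample/per-primer sequencing read totals and target-read counts;
* species-level relative abundances (%) per sample x primer condition.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .seqio import SequenceRecord

__all__ = ["lab_primer_pairs", "survey_read_counts", "species_abundance",
           "lab_primer_records"]


def _data_path(name: str):
    return resources.files("primerscope.data").joinpath(name)


def lab_primer_pairs() -> pd.DataFrame:
    """The six LAB-specific primer pairs (columns: pair, role, position,
    sequence, product_size, note)."""
    with resources.as_file(_data_path("lab_primers.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def lab_primer_records() -> list[SequenceRecord]:
    """The twelve primer sequences as records named ``<pair>_<role>``."""
    df = lab_primer_pairs()
    return [SequenceRecord(f"{row.pair}_{row.role}", row.sequence)
            for row in df.itertuples()]


def survey_read_counts() -> pd.DataFrame:
    """Read totals and target-read counts per sample x primer condition."""
    with resources.as_file(_data_path("survey_read_counts.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def species_abundance() -> pd.DataFrame:
    """Species-level relative abundance (%) per fecal sample x primer,
    indexed by binomial; columns are '<sample>/<primer>' conditions."""
    with resources.as_file(_data_path("species_abundance.tsv")) as path:
        return pd.read_csv(path, sep="\t", index_col="species")
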