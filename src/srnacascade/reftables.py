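"""Published reference tables bundled with the package.

These TSVs transcribe the printed summary tables of the barley TaDREB3
sRNA-profiling study this pipeline re-implements: per-length size
distributions for the two libraries, the group-comparison statistics, the
known-miRNA expression profile, the novel-miRNA candidate table and the
degradome cleavage calls. They carry the raw printed integers (and the
printed derived columns, kept for cross-checking); every derived quantity is
recomputed from the raw integers by `pipeline.verify_paper_tables`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

# raw totals of the two non-chloroplast read streams (control, transgenic);
# their ratio is the published cross-library normalization factor (~1.3832)
NONCP_TOTAL_CONTROL = 3575645
NONCP_TOTAL_TRANSGENIC = 2585109


def _load(name: str) -> pd.DataFrame:
    with resources.files("srnacascade.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def size_distribution_tables() -> dict[str, pd.DataFrame]:
    """Per-length unique-read/read-count tables (three thresholds) for the
    control ("gp") and transgenic ("tadreb3") libraries, totals row included."""
    return {"gp": _load("size_distribution_gp.tsv"),
            "tadreb3": _load("size_distribution_tadreb3.tsv")}


def group_comparison_table() -> pd.DataFrame:
    """Per-stream, per-threshold group statistics: unique/total counts,
    sample-specific and common reads, |log2|>=1 counts and derived ratios."""
    return _load("group_comparison.tsv")


def known_mirna_table() -> pd.DataFrame:
    """Known-miRNA profile: per-miRNA raw counts and printed normalized/log2
    columns. `combined_star_row` marks the rows that pool a mature and a
    mature* sequence; their printed derived cells do not follow from their own
    printed counts (see verify_paper_tables)."""
    return _load("known_mirna.tsv")


def novel_mirna_table() -> pd.DataFrame:
    """Novel-candidate table: sequences, counts, normalized/log2, hairpin MFE
    (computed by an external thermodynamic folder; consumed as given) and
    source accession."""
    return _load("novel_mirna.tsv")


def degradome_table() -> pd.DataFrame:
    """Degradome validation calls: guiding miRNA, printed cleavage-position
    label and tag sequence (29 entries over 20 miRNAs)."""
    return _load("degradome_calls.tsv")
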