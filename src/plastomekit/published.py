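"""Accessors for the published study tables packaged with this project.

The packaged tables record, for 33 bamboo and outgroup grass plastomes,
the printed region lengths (total, LSC, SSC, IR), NCBI accessions and —
for the 18 newly assembled genomes — the sequencing metadata (read
counts, library preparation, single/paired-end, mean coverage, number of
scaffolded contigs).  A second table catalogues the four rare structural
marker events used as phylogenetic characters, and a third the primer
sequences used to confirm the mitochondrial-like insertion by PCR.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .variants import VariantRecord


def _data_path(fname: str):
    return resources.files("plastomekit.data").joinpath(fname)


def load_region_table() -> pd.DataFrame:
    """Region lengths and sequencing metadata for all 33 plastomes."""
    with resources.as_file(_data_path("region_lengths.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def region_sum_violations(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Rows for which total != LSC + SSC + 2*IR (expected: none)."""
    if df is None:
        df = load_region_table()
    bad = df[df.total_len != df.lsc_len + df.ssc_len + 2 * df.ir_len]
    return bad


def newly_assembled(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """The subset of genomes assembled from raw reads (have read counts)."""
    if df is None:
        df = load_region_table()
    return df[df.n_reads.notna()]


def total_length_range(df: pd.DataFrame | None = None) -> tuple[int, int]:
    """(min, max) total plastome length over the newly assembled genomes."""
    sub = newly_assembled(df)
    return int(sub.total_len.min()), int(sub.total_len.max())


def load_marker_events() -> pd.DataFrame:
    """The four rare structural events used as clade markers."""
    with resources.as_file(_data_path("marker_events.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def marker_event_records() -> list[VariantRecord]:
    """Marker events as VariantRecord objects (coordinates unresolved)."""
    df = load_marker_events()
    out = []
    for _, row in df.iterrows():
        taxa = tuple(t.strip().replace(" ", "_").replace(".", "")
                     for t in row.taxa.split(";"))
        out.append(VariantRecord(
            kind=row.kind, locus=row.locus, start=0, end=0,
            length=int(row.length_bp), taxa=taxa,
        ))
    return out


def parianinae_insert_arithmetic() -> dict:
    """Accounting for the two-part mitochondrial-like insertion.

    The insertion shared by both Parianinae genomes is 2,706 bp; the
    longer genome carries an extra 3' extension.  Only an extension of
    2,232 bp is arithmetically consistent with the stated 4,938 bp
    total; the alternative printed extension figure of 1,242 bp is
    flagged as internally inconsistent and not used.
    """
    df = load_marker_events()
    shared = int(df.loc[df.event == "parianinae_shared_insert", "length_bp"].iloc[0])
    ext = int(df.loc[df.event == "parianinae_3prime_extension", "length_bp"].iloc[0])
    total = shared + ext
    alt_ext = 1242
    return {
        "shared_bp": shared,
        "extension_bp": ext,
        "total_bp": total,
        "inconsistent_extension_bp": alt_ext,
        "inconsistent_total_bp": shared + alt_ext,
        "alt_figure_consistent": shared + alt_ext == total,
    }


def inversion_flank_motifs() -> tuple[str, str]:
    """The imperfect 8 bp inverted-repeat motifs flanking the inversion."""
    df = load_marker_events()
    note = df.loc[df.event == "olyrinae_inversion", "notes"].iloc[0]
    up, down = note.split("inverted repeat ")[1].split(" / ")
    return up.strip(), down.strip()


def load_primers() -> pd.DataFrame:
    with resources.as_file(_data_path("primers.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def demo_tree_newick() -> str:
    """A rooted topology over all 33 study taxa for synapomorphy mapping."""
    return _data_path("demo_tree.nwk").read_text().strip()
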