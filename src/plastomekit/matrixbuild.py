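"""Phylogenomic character-matrix construction from aligned plastomes.

Builds taxa x columns matrices from aligned genomes (with one inverted
repeat already excluded to avoid over-representing repeat sequence),
strips alignment columns containing gaps, removes columns inside
detected inversions (false homology), and extracts/concatenates the
protein-coding partition normalised to the coding strand.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import seq as sq
from .genome import Feature
from .variants import VariantRecord, anchor_align

_COMP_MAP = {c: sq.complement(c) for c in "ACGTRYSWKMBDHVN"}
_COMP_MAP.update({c.lower(): sq.complement(c).lower() for c in "ACGTRYSWKMBDHVN"})
_COMP_MAP["-"] = "-"
_COMP_MAP["N"] = "N"


@dataclass
class CharacterMatrix:
    """An aligned taxa x columns matrix with per-column masks.

    ``masks`` holds boolean vectors (gapped, inversion, coding);
    ``coding_block`` numbers each coding column by the CDS it belongs
    to, in genome order (-1 for non-coding), and ``coding_strand``
    gives that CDS's strand, so the coding partition can be extracted
    after any column-dropping operation.
    """

    taxa: list[str]
    rows: np.ndarray                        # (n_taxa, n_cols) of single chars
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    coding_block: np.ndarray | None = None
    coding_strand: list[str] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return self.rows.shape[1]

    def row(self, taxon: str) -> str:
        return "".join(self.rows[self.taxa.index(taxon)])

    def _take(self, keep: np.ndarray) -> "CharacterMatrix":
        return CharacterMatrix(
            taxa=list(self.taxa),
            rows=self.rows[:, keep],
            masks={k: v[keep] for k, v in self.masks.items()},
            coding_block=(self.coding_block[keep]
                          if self.coding_block is not None else None),
            coding_strand=list(self.coding_strand),
        )

    # -- writers -----------------------------------------------------------
    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, t in enumerate(self.taxa):
                fh.write(f">{t}\n{''.join(self.rows[i])}\n")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.taxa)} {self.n_columns}\n")
            for i, t in enumerate(self.taxa):
                fh.write(f"{t.replace(' ', '_')}  {''.join(self.rows[i])}\n")

    def write_partitions(self, path) -> None:
        """Coding/non-coding partition file in plain RAxML-style text."""
        coding = self.masks.get("coding")
        if coding is None:
            raise ValueError("matrix has no coding mask")
        with open(path, "w") as fh:
            fh.write(f"DNA, coding = {_ranges_str(np.nonzero(coding)[0])}\n")
            fh.write(f"DNA, noncoding = {_ranges_str(np.nonzero(~coding)[0])}\n")


def _ranges_str(idx: np.ndarray) -> str:
    """1-based 'a-b, c-d' range list for a sorted index vector."""
    if idx.size == 0:
        return "none"
    parts = []
    start = prev = int(idx[0])
    for v in idx[1:]:
        v = int(v)
        if v == prev + 1:
            prev = v
            continue
        parts.append(f"{start + 1}-{prev + 1}")
        start = prev = v
    parts.append(f"{start + 1}-{prev + 1}")
    return ", ".join(parts)


def assemble_matrix(aligned: dict[str, str],
                    annotations: list[Feature] | None = None,
                    ref_taxon: str | None = None) -> CharacterMatrix:
    """Build a matrix from pre-aligned sequences (IRa already excluded).

    ``annotations`` are features of the reference taxon in ungapped
    reference coordinates; CDS features initialise the coding mask.
    """
    taxa = list(aligned)
    if not taxa:
        raise ValueError("no sequences")
    lengths = {len(s) for s in aligned.values()}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
    rows = np.array([list(aligned[t]) for t in taxa], dtype="<U1")
    n_cols = rows.shape[1]
    gapped = (rows == "-").any(axis=0)

    coding = np.zeros(n_cols, dtype=bool)
    coding_block = np.full(n_cols, -1, dtype=np.int64)
    coding_strand: list[str] = []
    if annotations:
        ref = ref_taxon or taxa[0]
        ref_row = rows[taxa.index(ref)]
        # map ungapped reference positions to alignment columns
        notgap = ref_row != "-"
        col_of_pos = np.nonzero(notgap)[0]
        cds = sorted((f for f in annotations if f.kind == "CDS"),
                     key=lambda f: f.start)
        for bi, f in enumerate(cds):
            if f.end > col_of_pos.size:
                raise ValueError(f"feature {f.name} outside alignment")
            cols = col_of_pos[f.start:f.end]
            coding[cols] = True
            coding_block[cols] = bi
            coding_strand.append(f.strand)
    masks = {"gapped": gapped,
             "inversion": np.zeros(n_cols, dtype=bool),
             "coding": coding}
    return CharacterMatrix(taxa, rows, masks, coding_block, coding_strand)


def strip_gapped_columns(matrix: CharacterMatrix) -> CharacterMatrix:
    """Keep exactly the columns with no gap in any taxon (idempotent)."""
    return matrix._take(~matrix.masks["gapped"])


def mask_inversions(matrix: CharacterMatrix,
                    records: list[VariantRecord],
                    ref_taxon: str | None = None) -> CharacterMatrix:
    """Remove all columns overlapping any inversion record.

    Record intervals are interpreted on the ungapped reference row
    (``ref_start``/``ref_end`` if set, else ``start``/``end``).
    """
    if not records:
        return matrix._take(np.ones(matrix.n_columns, dtype=bool))
    ref = ref_taxon or matrix.taxa[0]
    ref_row = matrix.rows[matrix.taxa.index(ref)]
    col_of_pos = np.nonzero(ref_row != "-")[0]
    drop = np.zeros(matrix.n_columns, dtype=bool)
    for r in records:
        s = r.ref_start if r.ref_start is not None else r.start
        e = r.ref_end if r.ref_end is not None else r.end
        if not (0 <= s <= e <= col_of_pos.size):
            raise ValueError(f"inversion record {s}-{e} outside matrix")
        drop[col_of_pos[s:e]] = True
    out = matrix._take(~drop)
    return out


def extract_coding(matrix: CharacterMatrix,
                   annotations: list[Feature] | None = None,
                   ref_taxon: str | None = None) -> CharacterMatrix:
    """Concatenate CDS columns in genome order, on the coding strand.

    Minus-strand genes have their column block reverse-complemented for
    every taxon so the concatenation reads in coding orientation.
    """
    if matrix.coding_block is None or not matrix.masks["coding"].any():
        if annotations is None:
            raise ValueError("no CDS features available")
        matrix = assemble_matrix(
            {t: "".join(matrix.rows[i]) for i, t in enumerate(matrix.taxa)},
            annotations, ref_taxon)
    blocks = []
    n_blocks = int(matrix.coding_block.max()) + 1
    for bi in range(n_blocks):
        cols = np.nonzero(matrix.coding_block == bi)[0]
        if cols.size == 0:
            continue
        sub = matrix.rows[:, cols]
        if matrix.coding_strand[bi] == "-":
            sub = np.vectorize(_COMP_MAP.get)(sub)[:, ::-1]
        blocks.append((bi, sub))
    if not blocks:
        raise ValueError("no coding columns in matrix")
    rows = np.concatenate([b for _, b in blocks], axis=1)
    n_cols = rows.shape[1]
    gapped = (rows == "-").any(axis=0)
    coding_block = np.concatenate(
        [np.full(b.shape[1], bi, dtype=np.int64) for bi, b in blocks])
    masks = {"gapped": gapped,
             "inversion": np.zeros(n_cols, dtype=bool),
             "coding": np.ones(n_cols, dtype=bool)}
    return CharacterMatrix(list(matrix.taxa), rows, masks, coding_block,
                           list(matrix.coding_strand))


# ---------------------------------------------------------------------------
# reference-guided multiple alignment of near-identical genomes


def reference_guided_msa(reference: str, queries: dict[str, str],
                         ref_name: str = "reference",
                         k: int = 21) -> dict[str, str]:
    """Stack pairwise anchor alignments into a reference-frame MSA.

    Each query is anchor-aligned to the reference; query insertions get
    taxon-specific extra columns (other taxa gapped), deletions become
    gaps in the query row.  Suitable for near-identical genomes that
    differ by structural variants, not for deep divergence.
    """
    per_taxon: dict[str, tuple[np.ndarray, list[tuple[int, str]]]] = {}
    n = len(reference)
    for name, qseq in queries.items():
        chain = anchor_align(qseq, reference, k=k)
        row = np.full(n, "-", dtype="<U1")
        inserts: list[tuple[int, str]] = []
        for b in chain.blocks:
            row[b.tstart:b.tend] = list(qseq[b.qstart:b.qend])
        for a, b, qgap, tgap in chain.gaps():
            qs, qe = a.qend, b.qstart
            ts, te = a.tend, b.tstart
            m = min(qgap, tgap)
            if m > 0:   # substituted/unaligned stretch: pack left
                row[ts:ts + m] = list(qseq[qs:qs + m])
            if qgap > tgap:
                inserts.append((te, qseq[qs + m:qe]))
        per_taxon[name] = (row, inserts)

    # collect insertion columns per reference position
    ins_at: dict[int, list[tuple[str, str]]] = {}
    for name, (_, inserts) in per_taxon.items():
        for pos, s in inserts:
            ins_at.setdefault(pos, []).append((name, s))

    out_rows = {ref_name: []}
    for name in queries:
        out_rows[name] = []
    for pos in range(n + 1):
        for name_i, s in ins_at.get(pos, ()):
            width = len(s)
            out_rows[ref_name].append("-" * width)
            for name in queries:
                out_rows[name].append(s if name == name_i else "-" * width)
        if pos < n:
            out_rows[ref_name].append(reference[pos])
            for name, (row, _) in per_taxon.items():
                out_rows[name].append(row[pos])
    return {name: "".join(parts) for name, parts in out_rows.items()}
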