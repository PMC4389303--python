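"""Readers/writers for the standard formats used by the pipeline.

FASTA and FASTQ go through Biopython; GFF3 and the TSV reports are
simple columnar text.
"""
from __future__ import annotations

import csv
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import Feature, Plastome
from .synthetic import Contig, ContigSet, Read, ReadSet
from .variants import VariantRecord


def write_fasta(path, records: dict[str, str]) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_fastq(path, reads: ReadSet) -> list[Path]:
    """Write reads; paired sets go to sibling _1/_2 files."""
    path = Path(path)
    if reads.pairing == "paired":
        paths = [path.with_name(path.stem + "_1.fastq"),
                 path.with_name(path.stem + "_2.fastq")]
        mates = ([], [])
        for m1, m2 in reads.pairs():
            mates[0].append(m1)
            mates[1].append(m2)
        for p, ms in zip(paths, mates):
            _write_fastq_one(p, ms)
        return paths
    _write_fastq_one(path, reads.reads)
    return [path]


def _write_fastq_one(path, reads: list[Read]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path, pairing: str = "single") -> ReadSet:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        reads.append(Read(rec.id, str(rec.seq).upper(), qual, -1, "?"))
    rl = max((len(r.sequence) for r in reads), default=0)
    return ReadSet(reads, pairing=pairing, read_len=rl)


def write_gff3(path, plastome: Plastome) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {plastome.name} 1 {len(plastome)}\n")
        for i, f in enumerate(plastome.features_sorted()):
            attrs = f"ID={f.name}.{i};Name={f.name}"
            fh.write("\t".join([
                plastome.name, "plastomekit", f.kind,
                str(f.start + 1), str(f.end), ".", f.strand, ".", attrs,
            ]) + "\n")


def read_gff3(path) -> list[Feature]:
    feats = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
            name = attrs.get("Name") or attrs.get("ID") or cols[2]
            feats.append(Feature(name, cols[2], cols[6],
                                 int(cols[3]) - 1, int(cols[4])))
    return feats


def write_contigs_fasta(path, contigs: ContigSet) -> None:
    write_fasta(path, {c.id: c.sequence for c in contigs.contigs})


def read_contigs_fasta(path) -> ContigSet:
    seqs = read_fasta(path)
    contigs = [Contig(name, s, -1, -1) for name, s in seqs.items()]
    return ContigSet(contigs, genome_len=sum(len(s) for s in seqs.values()))


def write_variants_tsv(path, records: list[VariantRecord]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["kind", "locus", "start", "end", "length", "taxa",
                    "flank_repeat_len", "ref_start", "ref_end"])
        for r in records:
            w.writerow([r.kind, r.locus, r.start, r.end, r.length,
                        ";".join(r.taxa),
                        "" if r.flank_repeat_len is None else r.flank_repeat_len,
                        "" if r.ref_start is None else r.ref_start,
                        "" if r.ref_end is None else r.ref_end])


def read_variants_tsv(path) -> list[VariantRecord]:
    out = []
    with open(path) as fh:
        rd = csv.DictReader(fh, delimiter="\t")
        for row in rd:
            out.append(VariantRecord(
                kind=row["kind"], locus=row["locus"],
                start=int(row["start"]), end=int(row["end"]),
                length=int(row["length"]),
                taxa=tuple(row["taxa"].split(";")),
                flank_repeat_len=(int(row["flank_repeat_len"])
                                  if row["flank_repeat_len"] else None),
                ref_start=int(row["ref_start"]) if row["ref_start"] else None,
                ref_end=int(row["ref_end"]) if row["ref_end"] else None))
    return out
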