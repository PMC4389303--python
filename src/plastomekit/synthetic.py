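"""Synthetic plastomes, planted structural variants, contigs and reads.

The generator emulates the statistical structure of bamboo plastome
sequencing projects so that every downstream stage can be exercised
against known truth: quadripartite genomes of 135-144 kb (LSC ~79.5-83.3
kb, SSC ~12.4-13.7 kb, IR ~19.8-25.0 kb), ~61% AT background with less
AT-rich (~55%) foreign inserts, 99-100 bp single- or paired-end reads at
15-500x coverage, and contig sets broken at the single-copy/IR
junctions the way de Bruijn assemblers leave them.

Gene annotations are drawn from a packaged, ordered list of 80
canonical grass plastid genes so that intergenic spacers carry
meaningful names such as "rpl23-ndhB".
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd

from . import seq as sq
from .genome import Feature, Plastome
from .variants import VariantRecord


class InfeasibleSpecError(ValueError):
    """Raised when the requested genes cannot fit in the given regions."""


@dataclass(frozen=True)
class PlastomeSpec:
    """Parameters of a synthetic quadripartite plastome.

    Defaults sit in the middle of the observed bamboo ranges; the AT
    fraction matches the ~61% background of grass plastomes.
    """

    lsc_len: int = 81_000
    ssc_len: int = 12_900
    ir_len: int = 21_800
    at_fraction: float = 0.61
    n_genes: int = 80
    seed: int = 0
    min_spacer: int = 100

    @property
    def total_len(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len

    def validate(self) -> None:
        if min(self.lsc_len, self.ssc_len, self.ir_len) <= 0:
            raise ValueError("region lengths must be positive")
        if not self.ir_len < self.ssc_len + self.lsc_len:
            raise ValueError("IR longer than both single-copy regions combined")
        if not 0.0 <= self.at_fraction <= 1.0:
            raise ValueError("at_fraction must be in [0, 1]")
        if self.n_genes < 0:
            raise ValueError("n_genes must be non-negative")


@dataclass(frozen=True)
class VariantSpec:
    """A structural edit to plant: insertion, deletion or inversion.

    ``locus`` is either a spacer name ("geneA-geneB") or an integer
    coordinate on the genome being edited.  Insertions draw a random
    payload at ``payload_at_fraction`` unless ``payload`` is given.
    Inversions may carry a degenerate ``flank_repeat`` motif, planted
    literally upstream with its reverse complement downstream.
    """

    kind: str
    locus: str | int
    length: int
    payload_at_fraction: float = 0.55
    flank_repeat: str | None = None
    payload: str | None = None

    def __post_init__(self):
        if self.kind not in ("insertion", "deletion", "inversion"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.length <= 0:
            raise ValueError("variant length must be positive")
        if not 0.0 <= self.payload_at_fraction <= 1.0:
            raise ValueError("payload_at_fraction must be in [0, 1]")


@dataclass(frozen=True)
class Read:
    id: str
    sequence: str
    quality: str
    origin_start: int          # truth: 0-based start on the source circle
    origin_strand: str


@dataclass
class ReadSet:
    reads: list[Read]
    pairing: str = "single"    # single | paired
    read_len: int = 100
    insert_size: int = 500
    insert_sd: int = 50
    genome_len: int = 0

    def __len__(self) -> int:
        return len(self.reads)

    def pairs(self):
        """Iterate mate pairs (paired sets store mates adjacently)."""
        if self.pairing != "paired":
            raise ValueError("not a paired read set")
        for i in range(0, len(self.reads), 2):
            yield self.reads[i], self.reads[i + 1]


@dataclass(frozen=True)
class Contig:
    id: str
    sequence: str
    origin_start: int          # truth interval on the source circle
    origin_end: int            # may exceed genome length (wraps)
    strand: str = "+"


@dataclass
class ContigSet:
    contigs: list[Contig]      # in truth (circle) order
    genome_len: int
    overlap: int = 0

    def __len__(self) -> int:
        return len(self.contigs)


def load_gene_table() -> pd.DataFrame:
    p = resources.files("plastomekit.data").joinpath("grass_plastid_genes.tsv")
    with resources.as_file(p) as fp:
        return pd.read_csv(fp, sep="\t")


def _select_genes(n_genes: int) -> dict[str, pd.DataFrame]:
    table = load_gene_table()
    by_region = {r: table[table.region == r].reset_index(drop=True)
                 for r in ("LSC", "IR", "SSC")}
    total = len(table)
    if n_genes >= total:
        return by_region
    out = {}
    for r, sub in by_region.items():
        k = round(n_genes * len(sub) / total)
        out[r] = sub.iloc[:k].reset_index(drop=True)
    return out


def _place_genes(genes: pd.DataFrame, region_len: int, min_spacer: int,
                 rng: np.random.Generator) -> list[tuple[str, str, str, int, int]]:
    """Lay out genes in order with randomly sized spacers between them."""
    lengths = genes.length.tolist()
    n = len(lengths)
    free = region_len - sum(lengths) - (n + 1) * min_spacer
    if free < 0:
        raise InfeasibleSpecError(
            f"{n} genes totalling {sum(lengths)} bp (+ spacers) exceed "
            f"region of {region_len} bp")
    extra = rng.multinomial(free, np.full(n + 1, 1.0 / (n + 1)))
    placements = []
    pos = 0
    for i, row in genes.iterrows():
        pos += min_spacer + int(extra[i])
        placements.append((row["name"], row["kind"], row["strand"],
                           pos, pos + int(row["length"])))
        pos += int(row["length"])
    return placements


def _different_base(*avoid: str) -> str:
    return next(b for b in "ACGT" if b not in avoid)


def generate_plastome(spec: PlastomeSpec) -> Plastome:
    """Generate a random quadripartite plastome satisfying the spec.

    IRa is the exact reverse complement of IRb; IRb features are
    mirrored into IRa with flipped strand.  Deterministic for a fixed
    seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    by_region = _select_genes(spec.n_genes)

    lsc = sq.random_dna(spec.lsc_len, spec.at_fraction, rng)
    irb = sq.random_dna(spec.ir_len, spec.at_fraction, rng)
    ssc = sq.random_dna(spec.ssc_len, spec.at_fraction, rng)
    # make the IR boundaries non-extensible, so the truth intervals are
    # exactly the maximal inverted-repeat pair of the circle
    if lsc[-1] == sq.complement(lsc[0]):
        lsc = lsc[:-1] + _different_base(lsc[-1], sq.complement(lsc[0]))
    if ssc[0] == sq.complement(ssc[-1]):
        ssc = _different_base(ssc[0], sq.complement(ssc[-1])) + ssc[1:]
    ira = sq.revcomp(irb)
    sequence = lsc + irb + ssc + ira

    o_irb = spec.lsc_len
    o_ssc = o_irb + spec.ir_len
    o_ira = o_ssc + spec.ssc_len
    regions = {
        "LSC": (0, o_irb),
        "IRb": (o_irb, o_ssc),
        "SSC": (o_ssc, o_ira),
        "IRa": (o_ira, spec.total_len),
    }

    features: list[Feature] = []
    irb_feats: list[Feature] = []
    for region, origin, rlen in (("LSC", 0, spec.lsc_len),
                                 ("IR", o_irb, spec.ir_len),
                                 ("SSC", o_ssc, spec.ssc_len)):
        for name, kind, strand, s, e in _place_genes(
                by_region[region], rlen, spec.min_spacer, rng):
            f = Feature(name, kind, strand, origin + s, origin + e)
            features.append(f)
            if region == "IR":
                irb_feats.append(f)
    # mirror IRb features into IRa
    for f in irb_feats:
        s = o_ira + (o_ssc - f.end)
        e = o_ira + (o_ssc - f.start)
        features.append(Feature(f.name, f.kind,
                                "-" if f.strand == "+" else "+", s, e))
    p = Plastome(sequence=sequence, regions=regions,
                 features=sorted(features, key=lambda f: f.start),
                 name=f"synthetic_seed{spec.seed}")
    p.validate()
    return p


# ---------------------------------------------------------------------------
# variant planting


def _resolve_point(plastome: Plastome, locus: str | int) -> tuple[int, str]:
    if isinstance(locus, (int, np.integer)):
        return int(locus), f"pos{int(locus)}"
    s, e = plastome.spacer(locus)
    return (s + e) // 2, locus


def _mirror_point(plastome: Plastome, pos: int) -> int | None:
    """Map a position in IRb to its mirror in IRa (or vice versa)."""
    b0, b1 = plastome.region("IRb")
    a0, a1 = plastome.region("IRa")
    if b0 <= pos < b1:
        return a0 + (b1 - pos)
    if a0 <= pos < a1:
        return b0 + (a1 - pos)
    return None


def plant_variants(plastome: Plastome, specs: list[VariantSpec],
                   seed: int = 0) -> tuple[Plastome, list[VariantRecord]]:
    """Apply structural edits and return the edited genome plus truth.

    Insertions that fall inside an inverted repeat are mirrored into the
    other IR copy (reverse-complemented) so the IR identity invariant is
    preserved; the mirrored copy gets its own truth record.  Truth
    records carry exact post-edit coordinates (for deletions, the
    breakpoint) and the pre-edit interval in ``ref_start``/``ref_end``.
    """
    rng = np.random.default_rng(seed)
    n = len(plastome.sequence)

    # (start, end, replacement, record-template) in original coordinates
    edits: list[tuple[int, int, str, dict]] = []
    for vs in specs:
        if vs.kind == "insertion":
            pos, locus = _resolve_point(plastome, vs.locus)
            payload = vs.payload if vs.payload is not None else sq.random_dna(
                vs.length, vs.payload_at_fraction, rng)
            if len(payload) != vs.length:
                raise ValueError("payload length does not match spec length")
            edits.append((pos, pos, payload,
                          dict(kind="insertion", locus=locus, length=vs.length)))
            mpos = _mirror_point(plastome, pos) if plastome.regions else None
            if mpos is not None:
                edits.append((mpos, mpos, sq.revcomp(payload),
                              dict(kind="insertion", locus=locus + "(IR mirror)",
                                   length=vs.length)))
        elif vs.kind == "deletion":
            if isinstance(vs.locus, (int, np.integer)):
                s = int(vs.locus)
            else:
                a, b = plastome.spacer(vs.locus)
                s = (a + b) // 2 - vs.length // 2
            e = s + vs.length
            if not (0 <= s < e <= n):
                raise ValueError("deletion interval outside genome")
            locus = vs.locus if isinstance(vs.locus, str) else f"pos{s}"
            edits.append((s, e, "", dict(kind="deletion", locus=locus,
                                         length=vs.length)))
        else:  # inversion
            if isinstance(vs.locus, (int, np.integer)):
                s = int(vs.locus)
                locus = f"pos{s}"
            else:
                a, b = plastome.spacer(vs.locus)
                pad = len(vs.flank_repeat) if vs.flank_repeat else 0
                if b - a < vs.length + 2 * pad:
                    raise ValueError(
                        f"spacer {vs.locus} ({b - a} bp) too small for a "
                        f"{vs.length} bp inversion")
                s = (a + b) // 2 - vs.length // 2
                locus = vs.locus
            e = s + vs.length
            segment = plastome.sequence[s:e]
            if vs.flank_repeat:
                motif = vs.flank_repeat.upper()
                replacement = motif + sq.revcomp(segment) + sq.revcomp(motif)
                flank_len = len(motif)
            else:
                replacement = sq.revcomp(segment)
                flank_len = None
            edits.append((s, e, replacement,
                          dict(kind="inversion", locus=locus, length=vs.length,
                               flank_repeat_len=flank_len)))

    edits.sort(key=lambda t: (t[0], t[1]))
    for (s1, e1, *_), (s2, _, *_) in zip(edits, edits[1:]):
        if s2 < e1:
            raise ValueError("overlapping variant intervals")

    # apply edits left to right, tracking the coordinate shift
    out = []
    records: list[VariantRecord] = []
    prev = 0
    shift = 0
    for s, e, repl, meta in edits:
        out.append(plastome.sequence[prev:s])
        out.append(repl)
        prev = e
        kind = meta["kind"]
        if kind == "insertion":
            records.append(VariantRecord(
                start=s + shift, end=s + shift + meta["length"],
                ref_start=s, ref_end=s, taxa=(plastome.name,), **meta))
        elif kind == "deletion":
            records.append(VariantRecord(
                start=s + shift, end=s + shift,
                ref_start=s, ref_end=e, taxa=(plastome.name,), **meta))
        else:
            pad = meta.get("flank_repeat_len") or 0
            records.append(VariantRecord(
                start=s + shift + pad, end=s + shift + pad + meta["length"],
                ref_start=s, ref_end=e, taxa=(plastome.name,), **meta))
        shift += len(repl) - (e - s)
    out.append(plastome.sequence[prev:])
    new_seq = "".join(out)

    new_feats = _shift_features(plastome.features, edits)
    new_regions = _shift_regions(plastome.regions, edits)
    edited = Plastome(sequence=new_seq, regions=new_regions,
                      features=new_feats, name=plastome.name + "+variants")
    return edited, records


def _edit_delta(edits, pos: int) -> int:
    """Total length change from edits entirely before ``pos``."""
    d = 0
    for s, e, repl, _ in edits:
        if e <= pos:
            d += len(repl) - (e - s)
    return d


def _shift_features(features, edits) -> list[Feature]:
    out = []
    for f in features:
        drop = False
        inv_edit = None
        for s, e, repl, meta in edits:
            kind = meta["kind"]
            if kind == "insertion":
                if f.start < s < f.end:
                    drop = True       # insertion disrupts the feature
            elif kind == "inversion" and s <= f.start and f.end <= e:
                inv_edit = (s, e, repl, meta)
            elif f.start < e and s < f.end:
                drop = True           # deleted or straddling an edit
        if drop:
            continue
        if inv_edit is not None:
            s, e, repl, meta = inv_edit
            pad = meta.get("flank_repeat_len") or 0
            base = s + _edit_delta(edits, s) + pad
            out.append(replace(f, start=base + (e - f.end),
                               end=base + (e - f.start),
                               strand="-" if f.strand == "+" else "+"))
        else:
            ds = _edit_delta(edits, f.start)
            out.append(replace(f, start=f.start + ds, end=f.end + ds))
    return sorted(out, key=lambda f: f.start)


def _shift_regions(regions, edits):
    if regions is None:
        return None
    # an edit spanning a region boundary invalidates the region table
    bounds = sorted({b for iv in regions.values() for b in iv})
    for s, e, _, _ in edits:
        if any(s < b < e for b in bounds):
            return None
    out = {}
    for name, (s, e) in regions.items():
        # edits strictly inside the region stretch it via the end shift
        out[name] = (s + _edit_delta(edits, s), e + _edit_delta(edits, e))
    return out


# ---------------------------------------------------------------------------
# reads and contigs


def simulate_reads(plastome: Plastome | str, coverage: float,
                   read_len: int = 100, pairing: str = "single",
                   error_rate: float = 0.0, seed: int = 0,
                   insert_size: int = 500, insert_sd: int = 50) -> ReadSet:
    """Uniform shotgun reads from the circle, i.i.d. substitution errors.

    Read count is coverage * genome_len / read_len (rounded); read start
    positions are uniform on the circle with wrap-around; strands are
    random.  Quality strings are constant high quality.
    """
    genome = plastome.sequence if isinstance(plastome, Plastome) else plastome
    n = len(genome)
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not 0.0 <= error_rate <= 0.05:
        raise ValueError("error_rate must be in [0, 0.05]")
    if read_len > n:
        raise ValueError("read length exceeds genome length")
    if pairing not in ("single", "paired"):
        raise ValueError(f"unknown pairing {pairing!r}")

    rng = np.random.default_rng(seed)
    g2 = genome + genome
    n_reads = round(coverage * n / read_len)
    qual = "I" * read_len
    reads: list[Read] = []

    if pairing == "single":
        starts = rng.integers(0, n, size=n_reads)
        strands = rng.integers(0, 2, size=n_reads)
        for i in range(n_reads):
            p = int(starts[i])
            s = g2[p:p + read_len]
            strand = "+-"[int(strands[i])]
            if strand == "-":
                s = sq.revcomp(s)
            if error_rate > 0:
                s = sq.mutate(s, error_rate, rng)
            reads.append(Read(f"r{i:07d}", s, qual, p, strand))
    else:
        n_pairs = n_reads // 2
        starts = rng.integers(0, n, size=n_pairs)
        inserts = np.clip(
            np.rint(rng.normal(insert_size, insert_sd, size=n_pairs)).astype(int),
            2 * read_len, n)
        strands = rng.integers(0, 2, size=n_pairs)
        for i in range(n_pairs):
            p = int(starts[i])
            ins = int(inserts[i])
            left = g2[p:p + read_len]
            right = sq.revcomp(g2[p + ins - read_len:p + ins])
            if int(strands[i]):   # fragment sampled from the other strand
                m1 = (right, (p + ins - read_len) % n, "-")
                m2 = (left, p, "+")
            else:
                m1 = (left, p, "+")
                m2 = (right, (p + ins - read_len) % n, "-")
            for mate, (s, o_start, o_strand) in enumerate(
                    (m1, m2), start=1):
                if error_rate > 0:
                    s = sq.mutate(s, error_rate, rng)
                reads.append(Read(f"r{i:07d}/{mate}", s, qual, o_start, o_strand))
    return ReadSet(reads, pairing=pairing, read_len=read_len,
                   insert_size=insert_size, insert_sd=insert_sd, genome_len=n)


def fragment_plastome(plastome: Plastome, break_policy: str = "at_IR_boundaries",
                      seed: int = 0, k: int = 6, overlap: int = 0) -> ContigSet:
    """Break the circle into contigs, mimicking de Bruijn assembly output.

    ``at_IR_boundaries`` breaks at the four single-copy/IR junctions
    (the places short-read assemblers cannot cross), yielding the LSC,
    IRb, SSC and IRa as separate contigs.  ``random_k`` breaks at k
    random positions.  Each contig may be extended by ``overlap`` bases
    past its end (wrapping) to give adjacent contigs shared sequence.
    """
    n = len(plastome.sequence)
    g2 = plastome.sequence + plastome.sequence
    if break_policy == "at_IR_boundaries":
        b = [plastome.region(r)[0] for r in ("LSC", "IRb", "SSC", "IRa")]
    elif break_policy == "random_k":
        rng = np.random.default_rng(seed)
        if not 1 <= k <= n:
            raise ValueError("k must be in [1, genome length]")
        b = sorted(int(x) for x in rng.choice(n, size=k, replace=False))
    else:
        raise ValueError(f"unknown break policy {break_policy!r}")
    contigs = []
    for i, start in enumerate(b):
        end = b[i + 1] if i + 1 < len(b) else b[0] + n
        end += overlap
        if end - start > n:
            end = start + n
        contigs.append(Contig(f"contig{i:02d}", g2[start:end], start, end))
    return ContigSet(contigs, genome_len=n, overlap=overlap)


def reassemble_contigs(cs: ContigSet) -> str:
    """Concatenate contigs in truth order, collapsing declared overlaps.

    Round-trip helper: returns a rotation of the original circle.
    """
    parts = []
    for c in cs.contigs:
        keep = (c.origin_end - c.origin_start) - cs.overlap
        parts.append(c.sequence[:keep])
    return "".join(parts)
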