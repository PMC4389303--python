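"""Anchored pairwise genome alignment and structural-variant detection.

Whole plastomes from close relatives are nearly collinear, so a light
anchor-chaining aligner is sufficient to expose the rare large events
that carry phylogenetic signal: insertions, deletions and local
inversions.  Anchors are k-mers that occur exactly once in each
sequence; the forward-strand anchors are chained by longest collinear
subsequence and merged into blocks, while reverse-strand anchors are
grouped per diagonal so that an inverted segment shows up as a
minus-strand block sitting in a gap between plus-strand blocks.

Short inverted-repeat motifs flanking an inversion (a stem-loop
recombination signature) are scanned with IUPAC set-intersection
matching, and detected events can be mapped onto a phylogeny to test
whether the taxa sharing them form a clade.
"""
from __future__ import annotations

import bisect
from collections import Counter
from dataclasses import dataclass

import dendropy

from . import seq as sq
from .genome import Feature, gene_base_name


@dataclass(frozen=True)
class Block:
    """A maximal run of co-diagonal anchors: query/target intervals."""

    qstart: int
    qend: int
    tstart: int
    tend: int
    strand: str

    @property
    def qlen(self) -> int:
        return self.qend - self.qstart


@dataclass
class AlignmentChain:
    """Collinear plus-strand blocks plus per-diagonal minus-strand blocks."""

    blocks: list[Block]
    minus_blocks: list[Block]
    query_len: int
    target_len: int
    k: int

    def query_coverage(self) -> float:
        return sum(b.qlen for b in self.blocks) / max(1, self.query_len)

    def gaps(self) -> list[tuple[Block, Block, int, int]]:
        """(left, right, query_gap, target_gap) between consecutive blocks."""
        out = []
        for a, b in zip(self.blocks, self.blocks[1:]):
            out.append((a, b, b.qstart - a.qend, b.tstart - a.tend))
        return out


@dataclass(frozen=True)
class VariantRecord:
    """A structural mutation: insertion, deletion or inversion.

    ``start``/``end`` are coordinates on the query genome (for a
    deletion the query breakpoint, start == end); ``ref_start``/
    ``ref_end``, when set, locate the event on the target/reference.
    ``taxa`` is the set of taxa sharing the derived state.
    """

    kind: str
    locus: str
    start: int
    end: int
    length: int
    taxa: tuple[str, ...] = ("query",)
    flank_repeat_len: int | None = None
    ref_start: int | None = None
    ref_end: int | None = None

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("variant length must be positive")
        if not self.taxa:
            raise ValueError("variant taxa must be non-empty")


def _unique_kmers(s: str, k: int) -> dict[str, int]:
    counts: Counter = Counter()
    for i in range(len(s) - k + 1):
        counts[s[i:i + k]] += 1
    # second pass records the position of each singleton
    out = {}
    for i in range(len(s) - k + 1):
        km = s[i:i + k]
        if counts[km] == 1:
            out[km] = i
    return out


def _chain_lis(matches: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain of matches increasing in both coordinates.

    ``matches`` must be sorted by query position (unique positions).
    Patience-sorting LIS on the target coordinate, O(m log m).
    """
    if not matches:
        return []
    tails: list[int] = []       # smallest tail target-pos for each length
    tails_idx: list[int] = []
    parent = [-1] * len(matches)
    for i, (_, t) in enumerate(matches):
        j = bisect.bisect_left(tails, t)
        if j == len(tails):
            tails.append(t)
            tails_idx.append(i)
        else:
            tails[j] = t
            tails_idx[j] = i
        parent[i] = tails_idx[j - 1] if j > 0 else -1
    chain = []
    i = tails_idx[-1]
    while i >= 0:
        chain.append(matches[i])
        i = parent[i]
    chain.reverse()
    return chain


def _merge_blocks(chain: list[tuple[int, int]], k: int, strand: str,
                  max_join: int | None = None) -> list[Block]:
    """Merge same-diagonal anchors (allowing small same-size gaps) into blocks."""
    if max_join is None:
        max_join = 3 * k  # absorbs isolated substitutions that break anchors
    blocks: list[Block] = []
    if not chain:
        return blocks
    q0, t0 = chain[0]
    qp, tp = q0, t0
    for q, t in chain[1:]:
        same_diag = (q - qp) == (t - tp)
        if same_diag and q - qp <= max_join:
            qp, tp = q, t
        else:
            blocks.append(Block(q0, qp + k, t0, tp + k, strand))
            q0, t0 = q, t
            qp, tp = q, t
    blocks.append(Block(q0, qp + k, t0, tp + k, strand))
    return blocks


def shared_unique_matches(query: str, target: str, k: int) -> list[tuple[int, int]]:
    """Positions of k-mers unique in both sequences, sorted by query."""
    qk = _unique_kmers(query, k)
    tk = _unique_kmers(target, k)
    matches = [(qp, tk[km]) for km, qp in qk.items() if km in tk]
    matches.sort()
    return matches


def anchor_align(query: str, target: str, k: int = 21) -> AlignmentChain:
    """Chain unique shared k-mers between two genomes.

    Plus-strand anchors are chained globally (longest collinear chain);
    minus-strand anchors (query vs reverse complement of target) are
    merged per diagonal and reported separately so local inversions are
    visible between plus-strand blocks.
    """
    if len(query) < k or len(target) < k:
        raise ValueError(f"both sequences must be at least k={k} long")
    plus = shared_unique_matches(query, target, k)
    blocks = _merge_blocks(_chain_lis(plus), k, "+")

    trc = sq.revcomp(target)
    minus = shared_unique_matches(query, trc, k)
    tn = len(target)
    # group by diagonal in reverse-complement coordinates, then convert
    # each run to forward target coordinates
    minus_blocks: list[Block] = []
    for blk in _merge_blocks(sorted(minus), k, "-"):
        # blk.tstart/tend are in revcomp coords; map back to forward
        fstart, fend = tn - blk.tend, tn - blk.tstart
        minus_blocks.append(Block(blk.qstart, blk.qend, fstart, fend, "-"))
    return AlignmentChain(blocks, minus_blocks, len(query), len(target), k)


def _locus_name(features: list[Feature] | None, pos: int) -> str:
    """Name a position by its nearest flanking annotated genes."""
    if not features:
        return f"pos{pos}"
    feats = sorted(features, key=lambda f: f.start)
    left = None
    right = None
    for f in feats:
        if f.end <= pos:
            left = f
        if f.start >= pos and right is None:
            right = f
    if left is not None and right is not None:
        if left.name == right.name:
            return gene_base_name(left.name)
        return f"{gene_base_name(left.name)}-{gene_base_name(right.name)}"
    if left is not None:   # wraps the origin
        return f"{gene_base_name(left.name)}-{gene_base_name(feats[0].name)}"
    if right is not None:
        return f"{gene_base_name(feats[-1].name)}-{gene_base_name(right.name)}"
    return f"pos{pos}"


def detect_indels(chain: AlignmentChain, annotations: list[Feature] | None = None,
                  min_len: int = 100) -> list[VariantRecord]:
    """Emit insertions/deletions from inter-block gaps of the plus chain.

    A gap that is >= ``min_len`` on exactly one sequence is an indel;
    gaps large on both sides are left to inversion/replacement handling.
    Annotations are target-genome features used for spacer naming.
    """
    records = []
    for a, b, qgap, tgap in chain.gaps():
        # breakpoints are ambiguous when junction bases repeat, which can
        # make the shorter gap slightly negative; net length is qgap - tgap
        if qgap >= min_len and tgap < min_len:
            length = qgap - tgap
            start = a.qend + min(tgap, 0)
            records.append(VariantRecord(
                kind="insertion", locus=_locus_name(annotations, a.tend),
                start=start, end=start + length, length=length,
                ref_start=min(a.tend, b.tstart), ref_end=b.tstart,
            ))
        elif tgap >= min_len and qgap < min_len:
            length = tgap - qgap
            bp = min(a.qend, b.qstart)
            records.append(VariantRecord(
                kind="deletion", locus=_locus_name(annotations, (a.tend + b.tstart) // 2),
                start=bp, end=bp, length=length,
                ref_start=a.tend + min(qgap, 0), ref_end=b.tstart,
            ))
    return records


def detect_inversions(query: str, target: str, min_len: int = 50,
                      k: int = 21, annotations: list[Feature] | None = None,
                      chain: AlignmentChain | None = None) -> list[VariantRecord]:
    """Report minus-strand blocks sitting in gaps between plus blocks."""
    if chain is None:
        chain = anchor_align(query, target, k=k)
    records = []
    for a, b, qgap, tgap in chain.gaps():
        if qgap < min_len or tgap < min_len:
            continue
        inside = [m for m in chain.minus_blocks
                  if a.qend - k <= m.qstart and m.qend <= b.qstart + k
                  and a.tend - k <= m.tstart and m.tend <= b.tstart + k]
        if not inside:
            continue
        qs = min(m.qstart for m in inside)
        qe = max(m.qend for m in inside)
        ts = min(m.tstart for m in inside)
        te = max(m.tend for m in inside)
        if qe - qs >= min_len:
            records.append(VariantRecord(
                kind="inversion", locus=_locus_name(annotations, ts),
                start=qs, end=qe, length=qe - qs,
                ref_start=ts, ref_end=te,
            ))
    return records


def find_inverted_flanks(sequence: str, inversion: tuple[int, int],
                         max_flank: int = 30) -> tuple[int, tuple[str, str]]:
    """Longest inverted-repeat flank around an inversion interval.

    Returns the largest f <= max_flank such that the f bases immediately
    5' of the inversion and the f bases immediately 3' of it are reverse
    complements under IUPAC compatibility (codes match iff their base
    sets intersect), together with the two motifs.  f = 0 is allowed.
    """
    start, end = inversion
    n = len(sequence)
    if not (0 <= start <= end <= n):
        raise ValueError("inversion interval outside sequence")
    f = 0
    while f < max_flank:
        i_up = start - 1 - f
        i_down = end + f
        if i_up < 0 or i_down >= n:
            break
        up = sequence[i_up]
        down = sequence[i_down]
        if not sq.iupac_compatible(up, sq.complement(down)):
            break
        f += 1
    return f, (sequence[start - f:start], sequence[end:end + f])


def left_align_indel(rec: VariantRecord, query: str,
                     target: str | None = None) -> VariantRecord:
    """Normalise an ambiguous indel to its left-most representation.

    When the bases flanking an indel repeat, the same edit has several
    equivalent coordinate representations; shifting left until the
    context breaks gives a canonical one (the usual VCF-style
    normalisation).  Inversions are returned unchanged.
    """
    if rec.kind == "insertion":
        start, end = rec.start, rec.end
        ref_point = rec.ref_start
        while start > 0 and query[start - 1] == query[end - 1]:
            start -= 1
            end -= 1
            if ref_point is not None:
                ref_point -= 1
        return VariantRecord(kind=rec.kind, locus=rec.locus, start=start,
                             end=end, length=rec.length, taxa=rec.taxa,
                             flank_repeat_len=rec.flank_repeat_len,
                             ref_start=ref_point, ref_end=ref_point)
    if rec.kind == "deletion" and target is not None \
            and rec.ref_start is not None:
        rs, re_, bp = rec.ref_start, rec.ref_end, rec.start
        while rs > 0 and bp > 0 and target[rs - 1] == target[re_ - 1]:
            rs -= 1
            re_ -= 1
            bp -= 1
        return VariantRecord(kind=rec.kind, locus=rec.locus, start=bp,
                             end=bp, length=rec.length, taxa=rec.taxa,
                             flank_repeat_len=rec.flank_repeat_len,
                             ref_start=rs, ref_end=re_)
    return rec


@dataclass(frozen=True)
class SynapomorphyAssignment:
    record: VariantRecord
    status: str                     # synapomorphy | autapomorphy | homoplastic/conflicting
    clade: tuple[str, ...]          # leaves of the minimal covering clade
    branch: str                     # label of the subtending branch


def map_synapomorphies(records: list[VariantRecord],
                       tree: "dendropy.Tree | str") -> list[SynapomorphyAssignment]:
    """Assign each variant to a branch of a rooted tree.

    A record whose taxa are exactly the leaves of a clade marks that
    clade's subtending branch (a synapomorphy; an autapomorphy if a
    single taxon).  Otherwise the record is flagged homoplastic/
    conflicting and the minimal covering clade is reported.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    tree.is_rooted = True
    leaf_names = {lf.taxon.label.replace(" ", "_") for lf in tree.leaf_node_iter()}

    out = []
    for rec in records:
        taxa = {t.replace(" ", "_") for t in rec.taxa}
        unknown = taxa - leaf_names
        if unknown:
            raise KeyError(f"taxa not in tree: {sorted(unknown)}")
        mrca = tree.mrca(taxon_labels=[
            lf.taxon.label for lf in tree.leaf_node_iter()
            if lf.taxon.label.replace(" ", "_") in taxa])
        clade = tuple(sorted(
            lf.taxon.label.replace(" ", "_") for lf in mrca.leaf_iter()))
        branch = "+".join(clade)
        if set(clade) == taxa:
            status = "autapomorphy" if len(taxa) == 1 else "synapomorphy"
        else:
            status = "homoplastic/conflicting"
        out.append(SynapomorphyAssignment(rec, status, clade, branch))
    return out
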