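"""Assembly finishing: scaffolding, gap closure, and read-based assessment.

Short-read de Bruijn assemblers leave a plastome in segments because
they cannot build across the large inverted repeats.  This module
re-creates the manual finishing workflow: contigs are ordered and
oriented against an annotated reference by unique-anchor placement,
remaining junctions and gaps are closed with evidence sequences (reads
or contigs) that overlap a flank by at least ``min_overlap`` bases with
zero mismatches and are anchored at one end of the evidence sequence,
and the finished circle is assessed by mapping the reads back and
recording depth and base-level inconsistencies.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np

from . import seq as sq
from .genome import Plastome
from .synthetic import ContigSet, ReadSet


class UnscaffoldableError(ValueError):
    """No contig could be placed against the reference."""


@dataclass(frozen=True)
class Placement:
    contig_id: str
    contig_index: int
    ref_start: int
    ref_end: int               # may exceed reference length (wraps)
    strand: str
    n_anchors: int


@dataclass
class Scaffold:
    placements: list[Placement]          # sorted by ref_start
    gaps: list[int]                      # estimated gap after each placement
    unplaced: list[str]
    ref_len: int


@dataclass
class FinishResult:
    plastome: Plastome
    closed: bool
    open_gaps: list[str] = field(default_factory=list)
    ambiguities: list[str] = field(default_factory=list)


@dataclass
class AssemblyReport:
    mean_depth: float
    per_position_depth: np.ndarray
    inconsistencies: list[tuple[int, str, str, int]]   # pos, ref, majority, depth
    n_mapped: int
    n_reads: int


# ---------------------------------------------------------------------------
# scaffolding


def _circular_kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    """k-mer -> start positions on the circle (one entry per circle position)."""
    n = len(seq)
    s2 = seq + seq[:k - 1]
    idx: dict[str, list[int]] = defaultdict(list)
    for i in range(n):
        idx[s2[i:i + k]].append(i)
    return idx


def scaffold_contigs(contigs: ContigSet, reference: Plastome | str,
                     anchor_k: int = 25, min_anchors: int = 3) -> Scaffold:
    """Place each contig on the reference circle by unique shared anchors.

    A contig's placement is the modal offset (diagonal) of k-mers that
    occur exactly once in the contig and once per strand on the
    reference circle; the strand with the larger anchor support wins
    (ties prefer '+').  Contigs with insufficient unique anchors are
    reported unplaced.
    """
    if anchor_k < 15:
        raise ValueError("anchor_k must be >= 15")
    if not contigs.contigs:
        raise ValueError("empty contig set")
    refseq = reference.sequence if isinstance(reference, Plastome) else reference
    n = len(refseq)
    fwd = {km: pos[0] for km, pos in _circular_kmer_index(refseq, anchor_k).items()
           if len(pos) == 1}
    rc = sq.revcomp(refseq)
    rev = {km: pos[0] for km, pos in _circular_kmer_index(rc, anchor_k).items()
           if len(pos) == 1}

    placements = []
    unplaced = []
    for ci, contig in enumerate(contigs.contigs):
        cseq = contig.sequence
        ckmers = Counter(cseq[i:i + anchor_k]
                         for i in range(len(cseq) - anchor_k + 1))
        votes_f: Counter = Counter()
        votes_r: Counter = Counter()
        for i in range(len(cseq) - anchor_k + 1):
            km = cseq[i:i + anchor_k]
            if ckmers[km] != 1:
                continue
            if km in fwd:
                votes_f[(fwd[km] - i) % n] += 1
            if km in rev:
                votes_r[(rev[km] - i) % n] += 1
        best_f = votes_f.most_common(1)[0] if votes_f else (None, 0)
        best_r = votes_r.most_common(1)[0] if votes_r else (None, 0)
        if max(best_f[1], best_r[1]) < min_anchors:
            unplaced.append(contig.id)
            continue
        if best_f[1] >= best_r[1]:
            start = best_f[0]
            placements.append(Placement(contig.id, ci, start,
                                        start + len(cseq), "+", best_f[1]))
        else:
            # contig lies on the reverse strand: its first base maps to
            # position (n - rc_offset - len) on the forward circle
            rc_off = best_r[0]
            start = (n - rc_off - len(cseq)) % n
            placements.append(Placement(contig.id, ci, start,
                                        start + len(cseq), "-", best_r[1]))
    if not placements:
        raise UnscaffoldableError("no contig could be anchored to the reference")
    placements.sort(key=lambda p: p.ref_start)
    gaps = []
    for a, b in zip(placements, placements[1:] + placements[:1]):
        gaps.append((b.ref_start - a.ref_end) % n)
    return Scaffold(placements, gaps, unplaced, n)


# ---------------------------------------------------------------------------
# gap closure


def _oriented(contigs: ContigSet, placement: Placement) -> str:
    s = contigs.contigs[placement.contig_index].sequence
    return s if placement.strand == "+" else sq.revcomp(s)


class _EvidenceIndex:
    """Evidence sequences keyed by their first ``min_overlap``-mer.

    Both orientations of every evidence sequence are indexed, so an
    overlap anchored at either terminus can be found.
    """

    def __init__(self, reads: ReadSet | None, extra: list[tuple[str, str]] | None,
                 min_overlap: int, max_indexed_len: int = 5000):
        self.k = min_overlap
        self.by_prefix: dict[str, list[tuple[str, str]]] = defaultdict(list)
        self.max_len = 0
        self.mates: dict[str, str] = {}
        seqs: list[tuple[str, str]] = []
        if reads is not None:
            for r in reads.reads:
                seqs.append((r.id, r.sequence))
            if reads.pairing == "paired":
                for m1, m2 in reads.pairs():
                    self.mates[m1.id] = m2.sequence
                    self.mates[m2.id] = m1.sequence
        for eid, s in (extra or []):
            seqs.append((eid, s[:max_indexed_len]))
        for eid, s in seqs:
            if len(s) < min_overlap:
                continue
            self.max_len = max(self.max_len, len(s))
            self.by_prefix[s[:min_overlap]].append((eid, s))
            rs = sq.revcomp(s)
            self.by_prefix[rs[:min_overlap]].append((eid + "'", rs))

    def candidates(self, flank: str):
        """Evidence overlapping the flank suffix, anchored at evidence start.

        Yields (evidence_id, overlap_len, extension) for zero-mismatch,
        end-anchored overlaps of at least ``min_overlap`` bases.
        """
        lo = max(0, len(flank) - self.max_len)
        hi = len(flank) - self.k
        for t in range(lo, hi + 1):
            seed = flank[t:t + self.k]
            for eid, s in self.by_prefix.get(seed, ()):
                ov = len(flank) - t
                if ov > len(s):
                    continue
                if s[:ov] == flank[-ov:] and len(s) > ov:
                    yield eid, ov, s[ov:]


def _find_join(left: str, right: str, min_overlap: int,
               window: int = 1000) -> int:
    """Largest zero-mismatch overlap: suffix of ``left`` == prefix of ``right``."""
    if len(left) < min_overlap or len(right) < min_overlap:
        return 0
    seed = left[-min_overlap:]
    best = 0
    start = 0
    win = right[:window]
    while True:
        x = win.find(seed, start)
        if x < 0:
            break
        ov = x + min_overlap
        if ov <= len(left) and left[-ov:] == right[:ov]:
            best = max(best, ov)
        start = x + 1
    return best


def _mate_consistent(evidence_id: str, index: _EvidenceIndex, flank: str,
                     read_pos: int, reads: ReadSet) -> bool:
    """Check the downstream mate maps upstream within 3 sd of the insert size."""
    rid = evidence_id.rstrip("'")
    mate = index.mates.get(rid)
    if mate is None:
        return True          # unpaired evidence (or contig): no mate test
    lo = max(0, read_pos + reads.read_len - (reads.insert_size + 3 * reads.insert_sd))
    hi = read_pos + reads.read_len
    region = flank[lo:hi]
    return mate in region or sq.revcomp(mate) in region


def close_gaps(scaffold: Scaffold, contigs: ContigSet,
               reads: ReadSet | None = None, min_overlap: int = 20,
               max_rounds: int | None = None) -> FinishResult:
    """Close scaffold junctions until the circular map is complete.

    A flank is extended by an evidence sequence only when the overlap is
    at least ``min_overlap`` bases long, contains zero mismatches and is
    anchored at a terminus of the evidence; paired reads must place
    their mate at a consistent position and orientation.  Among
    admissible evidences, one whose extension immediately joins the next
    contig is preferred; otherwise the longest overlap wins (ties by
    evidence id).  Conflicting evidence with no closing candidate leaves
    the gap open and flagged.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    unplaced_ids = set(scaffold.unplaced)
    extra = [(c.id, c.sequence) for c in contigs.contigs if c.id in unplaced_ids]
    index = _EvidenceIndex(reads, extra, min_overlap)

    placements = scaffold.placements
    assembly = _oriented(contigs, placements[0])
    first_seq = assembly
    open_gaps: list[str] = []
    ambiguities: list[str] = []

    for j in range(len(placements)):
        closing_circle = j == len(placements) - 1
        right = first_seq if closing_circle else _oriented(contigs, placements[j + 1])
        est_gap = scaffold.gaps[j]
        label = (f"{placements[j].contig_id}->"
                 f"{placements[(j + 1) % len(placements)].contig_id}")
        if max_rounds is None:
            limit = (est_gap + 3 * (reads.read_len if reads else min_overlap)) + 200
        else:
            limit = max_rounds
        joined = False
        rounds = 0
        extended = 0
        while rounds < limit:
            rounds += 1
            ov = _find_join(assembly, right, min_overlap)
            if ov >= min_overlap:
                if closing_circle:
                    assembly = assembly[:len(assembly) - ov]
                else:
                    assembly = assembly + right[ov:]
                joined = True
                break
            cands = sorted(index.candidates(assembly),
                           key=lambda c: (-c[1], c[0]))
            if reads is not None and reads.pairing == "paired":
                cands = [c for c in cands if _mate_consistent(
                    c[0], index, assembly, len(assembly) - c[1], reads)]
            if not cands:
                break
            # prefer an evidence whose extension closes the junction now
            chosen = None
            for eid, ovl, ext in cands:
                if _find_join(assembly + ext, right, min_overlap) >= min_overlap:
                    chosen = (eid, ovl, ext)
                    break
            if chosen is None:
                top_ov = cands[0][1]
                top = [c for c in cands if c[1] == top_ov]
                prefixes = {c[2][:30] for c in top}
                if len(prefixes) > 1:
                    # column consensus among all candidates
                    groups: Counter = Counter(c[2][:30] for c in cands)
                    best, cnt = groups.most_common(1)[0]
                    if cnt <= len(cands) / 2:
                        ambiguities.append(label)
                        break
                    top = [c for c in cands if c[2][:30] == best]
                chosen = max(top, key=lambda c: len(c[2]))
            eid, ovl, ext = chosen
            assembly += ext
            extended += len(ext)
            if extended > est_gap + 5 * (reads.read_len if reads else 100) + 1000:
                break   # runaway extension: treat as unclosable
        if not joined:
            if label not in ambiguities:
                open_gaps.append(label)
            if not closing_circle:
                assembly += "N" * max(est_gap, 1) + right

    closed = not open_gaps and not ambiguities
    plastome = Plastome(sequence=assembly, regions=None, features=[],
                        name="finished", flags=() if closed else ("incomplete",))
    return FinishResult(plastome, closed, open_gaps, ambiguities)


# ---------------------------------------------------------------------------
# assessment


def _map_read(seq: str, genome2: str, n: int, seed_idx: dict[str, list[int]],
              seed_k: int, read_len: int, max_mismatch: int):
    """Best exact-or-near-exact placement of one oriented read."""
    best = None
    offsets = (0, read_len // 2, max(0, read_len - seed_k))
    for off in offsets:
        km = seq[off:off + seed_k]
        for p in seed_idx.get(km, ()):
            start = (p - off) % n
            window = genome2[start:start + len(seq)]
            if window == seq:
                return 0, start, []
            mm = [i for i, (a, b) in enumerate(zip(window, seq)) if a != b]
            if len(mm) <= max_mismatch and (best is None or len(mm) < best[0]):
                best = (len(mm), start, mm)
    return best


def assess_assembly(plastome: Plastome | str, reads: ReadSet,
                    max_mismatch: int = 2, seed_k: int = 20) -> AssemblyReport:
    """Map reads back to the finished circle and profile depth/consistency.

    Mapping is exact-substring first with a <=``max_mismatch`` rescue;
    unmapped reads are ignored (in real data they may be organellar
    transfers or nuclear reads).  A position where the majority of
    covering reads disagree with the assembly is an inconsistency.
    """
    genome = plastome.sequence if isinstance(plastome, Plastome) else plastome
    n = len(genome)
    genome2 = genome + genome
    seed_idx: dict[str, list[int]] = defaultdict(list)
    s2 = genome + genome[:seed_k - 1]
    for i in range(n):
        seed_idx[s2[i:i + seed_k]].append(i)

    starts: list[int] = []
    lens: list[int] = []
    mismatch_bases: dict[int, Counter] = defaultdict(Counter)
    n_mapped = 0
    for r in reads.reads:
        hit = None
        for oriented in (r.sequence, sq.revcomp(r.sequence)):
            h = _map_read(oriented, genome2, n, seed_idx, seed_k,
                          len(oriented), max_mismatch)
            if h is not None and (hit is None or h[0] < hit[0][0]):
                hit = (h, oriented)
            if hit is not None and hit[0][0] == 0:
                break
        if hit is None:
            continue
        (nmm, start, mmpos), oriented = hit
        n_mapped += 1
        starts.append(start)
        lens.append(len(oriented))
        for i in mmpos:
            mismatch_bases[(start + i) % n][oriented[i]] += 1

    depth = np.zeros(n + 1, dtype=np.int64)
    for start, L in zip(starts, lens):
        if start + L <= n:
            depth[start] += 1
            depth[start + L] -= 1
        else:
            depth[start] += 1
            depth[n] -= 1
            depth[0] += 1
            depth[(start + L) % n] -= 1
    depth = np.cumsum(depth[:n])

    inconsistencies = []
    for pos in sorted(mismatch_bases):
        alt, cnt = mismatch_bases[pos].most_common(1)[0]
        d = int(depth[pos])
        if cnt > d / 2:
            inconsistencies.append((pos, genome[pos], alt, d))
    mean_depth = float(depth.mean()) if n else 0.0
    return AssemblyReport(mean_depth, depth, inconsistencies, n_mapped,
                          len(reads.reads))
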