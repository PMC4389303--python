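"""Quadripartite structure: IR detection, canonical arrangement, annotation.

The two inverted repeats of a plastome are located as the maximal pair
of disjoint intervals whose sequences are reverse complements (up to a
small mismatch allowance), the circle is rotated/reflected into the
canonical LSC-IRb-SSC-IRa order, and annotations are lifted over from
an annotated reference by local alignment at a minimum similarity.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, replace

import edlib
import pandas as pd

from . import seq as sq
from .genome import Feature, Plastome, reflect_plastome, rotate_plastome


@dataclass(frozen=True)
class IRPair:
    """Detected inverted-repeat intervals on the circle.

    Intervals are (start, end) with end possibly exceeding the sequence
    length when a copy wraps the origin.  ``ira``/``irb`` follow the
    canonical convention: IRb is the copy adjacent to the 3' end of the
    LSC (the longer single-copy segment).
    """

    ira: tuple[int, int]
    irb: tuple[int, int]
    n_mismatches: int

    @property
    def length(self) -> int:
        return self.irb[1] - self.irb[0]


def _longest_circular_run(values: list[int], n: int, max_gap: int) -> list[int]:
    """Longest run of near-consecutive values on a circle of size n."""
    vs = sorted(set(values))
    if not vs:
        return []
    # find the largest circular gap; the run cannot cross it
    gaps = [(vs[(i + 1) % len(vs)] - v) % n for i, v in enumerate(vs)]
    cut = max(range(len(vs)), key=lambda i: gaps[i])
    ordered = vs[cut + 1:] + vs[:cut + 1]
    best: list[int] = []
    cur = [ordered[0]]
    for prev, v in zip(ordered, ordered[1:]):
        if (v - prev) % n <= max_gap:
            cur.append(v)
        else:
            if len(cur) > len(best):
                best = cur
            cur = [v]
    return cur if len(cur) > len(best) else best


def detect_inverted_repeats(sequence: str, min_ir_len: int = 1000,
                            k: int = 25, max_mismatch_frac: float = 0.001
                            ) -> IRPair | None:
    """Find the maximal inverted-repeat pair on a circular sequence.

    Seed k-mers of the sequence are matched against its reverse
    complement; matches belonging to one inverted-repeat pair share a
    constant anti-diagonal (sum of the two forward start positions), so
    the dominant anti-diagonal group locates the pair, which is then
    extended outward with a bounded mismatch allowance.  Returns None
    when no pair of length >= ``min_ir_len`` exists (some plastomes
    genuinely lack IRs).
    """
    n = len(sequence)
    if n < 4 * min_ir_len:
        raise ValueError("sequence shorter than 4 * min_ir_len")
    s2 = sequence + sequence[:k - 1]
    rc = sq.revcomp(sequence)
    rc2 = rc + rc[:k - 1]
    rpos: dict[str, list[int]] = defaultdict(list)
    for j in range(n):
        rpos[rc2[j:j + k]].append(j)

    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        km = s2[i:i + k]
        hits = rpos.get(km)
        if not hits or len(hits) > 4:
            continue
        for j in hits:
            u = (n - j - k) % n       # forward start of the partner k-mer
            c = (i + u) % n           # anti-diagonal
            groups[c].append(i)

    for c, _ in sorted(((c, len(v)) for c, v in groups.items()),
                       key=lambda t: -t[1])[:8]:
        run = _longest_circular_run(groups[c], n, max_gap=3 * k)
        if len(run) < 10:
            continue
        i0, i1 = run[0], run[-1]
        length = (i1 - i0) % n + k
        if length < min_ir_len // 2:
            continue
        # copy A = [i0, i0+length); copy B = [c - i1, c - i1 + length)
        a = (i0 % n, i0 % n + length)
        b = ((c - i1) % n, (c - i1) % n + length)
        if length > n - 2 * k:
            # the whole circle is one palindromic hairpin (e.g. a sequence
            # of the form X + revcomp(X)): the copies are the two halves,
            # cut at the hairpin apexes given by the anti-diagonal
            h = n // 2
            p0 = ((c + k) // 2 - h) % n
            return _label_pair(sequence, (p0, p0 + h),
                               ((p0 + h) % n, (p0 + h) % n + h), 0)
        pair = _extend_pair(sequence, a, b, max_mismatch_frac)
        if pair is None:
            continue
        a, b, mm = pair
        if a[1] - a[0] < min_ir_len:
            continue
        if _intervals_overlap(a, b, n):
            continue
        return _label_pair(sequence, a, b, mm)
    return None


def _intervals_overlap(a, b, n) -> bool:
    pos = set()
    for s, e in (a,):
        pos.update(p % n for p in range(s, e))
    return any(p % n in pos for p in range(b[0], b[1]))


def _extend_pair(sequence: str, a, b, max_mismatch_frac):
    """Extend matched intervals outward, exact-first with bounded bridging.

    Extension proceeds while bases pair exactly; an isolated mismatch is
    crossed only when at least 14 of the following 15 steps pair exactly
    and the overall mismatch budget (``max_mismatch_frac`` of the pair
    length) is not exceeded.  Identical repeats therefore stop exactly
    at their true boundaries.
    """
    n = len(sequence)

    def base(p):
        return sequence[p % n]

    a0, a1 = a
    b0, b1 = b
    if a1 - a0 != b1 - b0:
        return None
    mm = sum(1 for t in range(a1 - a0)
             if base(a0 + t) != sq.complement(base(b1 - 1 - t)))
    if mm > max(1, int(max_mismatch_frac * (a1 - a0))):
        return None

    def pair_ok(pa, pb):
        return base(pa) == sq.complement(base(pb))

    # outward extension, left end of copy a paired with right end of copy b
    while ((a0 - b1) % n) >= 2:
        budget = max(1, int(max_mismatch_frac * (a1 - a0 + 1)))
        if pair_ok(a0 - 1, b1):
            a0 -= 1
            b1 += 1
            continue
        ahead = sum(pair_ok(a0 - 2 - t, b1 + 1 + t) for t in range(15))
        if mm + 1 <= budget and ahead >= 14 and ((a0 - b1) % n) >= 32:
            mm += 1
            a0 -= 1
            b1 += 1
            continue
        break
    # outward extension, right end of copy a paired with left end of copy b
    while ((b0 - a1) % n) >= 2:
        budget = max(1, int(max_mismatch_frac * (a1 - a0 + 1)))
        if pair_ok(a1, b0 - 1):
            a1 += 1
            b0 -= 1
            continue
        ahead = sum(pair_ok(a1 + 1 + t, b0 - 2 - t) for t in range(15))
        if mm + 1 <= budget and ahead >= 14 and ((b0 - a1) % n) >= 32:
            mm += 1
            a1 += 1
            b0 -= 1
            continue
        break
    return (a0 % n, a0 % n + (a1 - a0)), (b0 % n, b0 % n + (b1 - b0)), mm


def _label_pair(sequence: str, a, b, mm) -> IRPair:
    """Label copies IRa/IRb by adjacency to the longer single-copy segment."""
    n = len(sequence)
    gap_ab = (b[0] - a[1]) % n       # single-copy segment after copy a
    gap_ba = (a[0] - b[1]) % n       # single-copy segment after copy b
    # the longer gap is the LSC; the copy that follows it is IRb
    if gap_ab >= gap_ba:
        irb, ira = b, a              # LSC sits between a-end and b-start
    else:
        irb, ira = a, b
    return IRPair(ira=ira, irb=irb, n_mismatches=mm)


def canonicalize(plastome: Plastome, min_ir_len: int = 1000,
                 marker_gene: str = "psbA") -> Plastome:
    """Rotate/reflect the circle into canonical LSC-IRb-SSC-IRa order.

    The origin is placed at the first base of the LSC.  The strand is
    chosen so the designated orientation marker gene lies on '+'; when
    the marker is not annotated, the lexicographically smaller of the
    two candidate arrangements is chosen (both rules are idempotent and
    invariant under rotation/reflection of the input).  Genomes without
    detectable IRs are returned unchanged with a 'no-IR' flag.
    """
    pair = detect_inverted_repeats(plastome.sequence, min_ir_len=min_ir_len)
    if pair is None:
        return replace(plastome, flags=plastome.flags + ("no-IR",))
    n = len(plastome.sequence)

    def arrange(p: Plastome) -> Plastome:
        pr = detect_inverted_repeats(p.sequence, min_ir_len=min_ir_len)
        gap_after_ira = (pr.irb[0] - pr.ira[1]) % n or n  # LSC length
        lsc_start = pr.ira[1] % n
        q = rotate_plastome(p, lsc_start)
        ir_len = pr.length
        lsc_len = gap_after_ira
        ssc_len = n - lsc_len - 2 * ir_len
        q.regions = {
            "LSC": (0, lsc_len),
            "IRb": (lsc_len, lsc_len + ir_len),
            "SSC": (lsc_len + ir_len, lsc_len + ir_len + ssc_len),
            "IRa": (lsc_len + ir_len + ssc_len, n),
        }
        return q

    fwd = arrange(plastome)
    rev = arrange(reflect_plastome(plastome))
    marker_f = [f for f in fwd.features if f.name == marker_gene]
    marker_r = [f for f in rev.features if f.name == marker_gene]
    if marker_f or marker_r:
        chosen = fwd if (marker_f and marker_f[0].strand == "+") else (
            rev if (marker_r and marker_r[0].strand == "+") else fwd)
    else:
        chosen = fwd if fwd.sequence <= rev.sequence else rev
    chosen.name = plastome.name
    chosen.validate()
    return chosen


def region_table(plastomes: dict[str, Plastome]) -> pd.DataFrame:
    """Per-genome region lengths in the printed-table layout."""
    rows = []
    for name, p in plastomes.items():
        rl = p.region_lengths()
        rows.append({"taxon": name, "total_len": len(p),
                     "lsc_len": rl["LSC"], "ssc_len": rl["SSC"],
                     "ir_len": rl["IRb"]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# annotation transfer


def _cigar_identity(cigar: str) -> tuple[float, int]:
    """Percent identity and aligned span from an extended cigar string."""
    num = ""
    counts: Counter = Counter()
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            counts[ch] += int(num)
            num = ""
    aligned = sum(counts.values())
    matches = counts["="]
    return (matches / aligned if aligned else 0.0), aligned


@dataclass
class TransferReport:
    plastome: Plastome
    transferred: list[Feature]
    untransferred: list[str]


def transfer_annotations(target: Plastome, reference: Plastome,
                         min_similarity: float = 0.70,
                         min_span_frac: float = 0.90) -> TransferReport:
    """Lift annotations from a reference onto an unannotated assembly.

    Each reference feature's sequence is locally aligned against the
    target (both strands, circular via doubling); the feature transfers
    iff percent identity over the aligned span is >= ``min_similarity``
    and the span covers >= ``min_span_frac`` of the feature.  A
    near-equal secondary hit (within 0.5% identity of the best) is also
    transferred, which places IR-duplicated features in both copies.
    """
    n = len(target.sequence)
    t2 = target.sequence + target.sequence
    transferred: list[Feature] = []
    untransferred: list[str] = []
    seen: set[tuple[str, int, int]] = set()

    for f in sorted(reference.features, key=lambda x: (x.start, x.name)):
        fseq = reference.sequence[f.start:f.end]
        hits = []
        for strand_flip, query in ((False, fseq), (True, sq.revcomp(fseq))):
            res = edlib.align(query, t2, mode="HW", task="path")
            if res["editDistance"] < 0:
                continue
            ident, aligned = _cigar_identity(res["cigar"])
            s, e = res["locations"][0]
            hits.append((ident, aligned, s % n, (s % n) + (e + 1 - s),
                         strand_flip))
        hits.sort(key=lambda h: -h[0])
        placed = False
        accepted = []
        if hits:
            best = hits[0]
            for h in hits:
                if (h[0] >= min_similarity and h[1] >= min_span_frac * f.length
                        and h[0] >= best[0] - 0.005):
                    accepted.append(h)
            if len(accepted) > 1:
                # keep at most one hit per location
                uniq = {}
                for h in accepted:
                    uniq.setdefault((h[2] // 10, h[3] // 10), h)
                accepted = list(uniq.values())
            # search for a second, IR-mirrored copy of the best hit
            if len(accepted) == 1:
                h = accepted[0]
                masked = t2[:h[2]] + "N" * (h[3] - h[2]) + t2[h[3]:]
                for strand_flip, query in ((False, fseq), (True, sq.revcomp(fseq))):
                    res = edlib.align(query, masked, mode="HW", task="path")
                    if res["editDistance"] < 0:
                        continue
                    ident, aligned = _cigar_identity(res["cigar"])
                    s, e = res["locations"][0]
                    if (ident >= min_similarity and ident >= h[0] - 0.005
                            and aligned >= min_span_frac * f.length):
                        accepted.append((ident, aligned, s % n,
                                         (s % n) + (e + 1 - s), strand_flip))
        for ident, aligned, s, e, strand_flip in accepted:
            if e > n:
                continue          # hit wraps the canonical origin: skip
            strand = f.strand if not strand_flip else ("-" if f.strand == "+" else "+")
            key = (f.name, s, strand)
            if key not in seen:
                seen.add(key)
                transferred.append(Feature(f.name, f.kind, strand, s, e))
            placed = True
        if not placed:
            untransferred.append(f.name)

    annotated = replace(target,
                        features=sorted(transferred, key=lambda x: x.start))
    return TransferReport(annotated, transferred, untransferred)
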