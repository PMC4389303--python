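"""Verification of putative foreign (mitochondrial-like) insertions.

A large insertion in a plastome that resembles mitochondrial sequence
deserves scrutiny before being called a horizontal transfer: it could
be an assembly artifact.  The checks implemented here mirror the
verification battery used for organellar HGT candidates: classify the
insert's origin against plastid and mitochondrial sequence panels,
profile mapped-read depth across the insertion boundaries, contrast
base composition inside and outside the insert, and predict whether
junction-spanning PCR primer pairs would amplify.
"""
from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from . import seq as sq
from .finishing import AssemblyReport


@dataclass(frozen=True)
class OriginCall:
    best_source: str          # plastid_panel | mito_panel | unclassified
    identity: float
    aligned_span: int
    best_hit: str | None = None


@dataclass(frozen=True)
class JunctionReport:
    upstream_depth: float
    downstream_depth: float
    genome_mean_depth: float
    depth_ratio_up: float
    depth_ratio_down: float
    upstream_suspect: bool
    downstream_suspect: bool


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str
    max_product: int = 5000

    def __post_init__(self):
        for p in (self.forward, self.reverse):
            if not 18 <= len(p) <= 30:
                raise ValueError("primer lengths must be 18-30 bp")
            if any(b.upper() not in sq.IUPAC_SETS for b in p):
                raise ValueError(f"invalid IUPAC code in primer {p!r}")


@dataclass(frozen=True)
class PcrProduct:
    length: int
    start: int                # 5' end of the forward-annealing primer
    end: int                  # position after the 5' end of the reverse primer
    fwd_primer: str
    rev_primer: str


def fixture_panels() -> tuple[dict[str, str], dict[str, str]]:
    """The packaged synthetic (plastid-like, mito-like) sequence panels.

    Small generated stand-ins for curated organellar sequence sets:
    plastid-like records at ~61% AT and mitochondrial-like records at
    ~55% AT.  Useful for demonstrations and tests; real analyses should
    supply curated FASTA panels.
    """
    from importlib import resources

    from .io import read_fasta
    d = resources.files("plastomekit.data")
    with resources.as_file(d.joinpath("synthetic_plastid_panel.fasta")) as p:
        plastid = read_fasta(p)
    with resources.as_file(d.joinpath("synthetic_mito_panel.fasta")) as p:
        mito = read_fasta(p)
    return plastid, mito


def _best_panel_hit(insert: str, panel: dict[str, str]) -> tuple[float, int, str]:
    """Best local-alignment identity of the insert against a panel."""
    best = (0.0, 0, "")
    for name, target in panel.items():
        for query in (insert, sq.revcomp(insert)):
            if len(query) > len(target):
                # align the shorter sequence into the longer one
                res = edlib.align(target, query, mode="HW", task="locations")
                span = len(target)
            else:
                res = edlib.align(query, target, mode="HW", task="locations")
                span = len(query)
            d = res["editDistance"]
            if d < 0:
                continue
            ident = max(0.0, 1.0 - d / span)
            if ident > best[0]:
                best = (ident, span, name)
    return best


def classify_insert_origin(insert: str, plastid_panel: dict[str, str],
                           mito_panel: dict[str, str],
                           min_identity: float = 0.70,
                           min_span: int = 100) -> OriginCall:
    """Call the insert's origin by its best hit across the two panels."""
    if not insert:
        raise ValueError("empty insert")
    if not plastid_panel or not mito_panel:
        raise ValueError("both panels must be non-empty")
    p_ident, p_span, p_name = _best_panel_hit(insert, plastid_panel)
    m_ident, m_span, m_name = _best_panel_hit(insert, mito_panel)
    if m_ident >= p_ident:
        source, ident, span, hit = "mito_panel", m_ident, m_span, m_name
    else:
        source, ident, span, hit = "plastid_panel", p_ident, p_span, p_name
    if ident < min_identity or span < min_span:
        return OriginCall("unclassified", ident, span, None)
    return OriginCall(source, ident, span, hit)


def junction_coverage(report: AssemblyReport, insert: tuple[int, int],
                      window: int = 100,
                      suspect_ratio: float = 0.25) -> JunctionReport:
    """Mean depth in windows centred on the insert boundaries.

    A boundary whose depth ratio against the genome-wide mean falls
    below ``suspect_ratio`` is flagged as a possible assembly artifact.
    """
    depth = report.per_position_depth
    n = len(depth)
    if window > n:
        raise ValueError("window exceeds genome length")
    s, e = insert
    if not (0 <= s < e <= n):
        raise ValueError("insert interval outside genome")

    def window_mean(center: int) -> float:
        idx = (np.arange(center - window // 2, center + (window + 1) // 2)) % n
        return float(depth[idx].mean())

    up = window_mean(s)
    down = window_mean(e)
    mean = report.mean_depth
    r_up = up / mean if mean > 0 else 0.0
    r_down = down / mean if mean > 0 else 0.0
    return JunctionReport(up, down, mean, r_up, r_down,
                          upstream_suspect=r_up < suspect_ratio,
                          downstream_suspect=r_down < suspect_ratio)


def composition_contrast(genome: str, insert: tuple[int, int]) -> tuple[float, float]:
    """(AT fraction of insert, AT fraction of the rest) by exact counts."""
    s, e = insert
    n = len(genome)
    if not (0 <= s < e <= n):
        raise ValueError("insert interval outside genome")
    if e - s == 0:
        raise ValueError("zero-length insert")
    if e - s == n:
        raise ValueError("insert equals the whole genome; the rest is empty")
    ins = genome[s:e]
    rest = genome[:s] + genome[e:]
    return sq.at_fraction(ins), sq.at_fraction(rest)


# ---------------------------------------------------------------------------
# in-silico PCR


def _anneal_sites(template2: np.ndarray, primer: str, n: int,
                  max_mismatch: int) -> list[int]:
    """Start positions (0..n-1) where the primer anneals on the + strand.

    IUPAC-compatible matching with at most ``max_mismatch`` mismatches
    overall and none within the 3'-terminal 3 bases.
    """
    m = len(primer)
    pb = sq.encode_bits(primer)
    L = len(template2)
    if L < m:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(template2, m)[:n]
    ok = (windows & pb) != 0
    mism = m - ok.sum(axis=1)
    exact3 = ok[:, -3:].all(axis=1)
    hits = np.nonzero((mism <= max_mismatch) & exact3)[0]
    return [int(h) for h in hits]


def insilico_pcr(template: str, pair: PrimerPair,
                 max_mismatch: int = 0) -> list[PcrProduct]:
    """Predict products of a primer pair on a circular template.

    A product is reported for every convergent pair of annealing sites
    within ``max_product``: one primer annealing on the plus strand and
    the other on the minus strand downstream of it.  Product length is
    the distance between the two primer 5' ends, inclusive.
    """
    n = len(template)
    t2 = sq.encode_bits(template + template)
    sites: list[tuple[str, str, int, int]] = []   # (primer, strand, start, len)
    for name, p in (("forward", pair.forward), ("reverse", pair.reverse)):
        for s in _anneal_sites(t2, p, n, max_mismatch):
            sites.append((name, "+", s, len(p)))
        for s in _anneal_sites(t2, sq.revcomp(p), n, max_mismatch):
            # primer anneals to the minus strand over [s, s+len)
            sites.append((name, "-", s, len(p)))

    products = []
    seen = set()
    plus = [st for st in sites if st[1] == "+"]
    minus = [st for st in sites if st[1] == "-"]
    for pname, _, ps, plen in plus:
        for mname, _, ms, mlen in minus:
            # allow the minus site to be reached across the origin
            for shift in (0, n):
                m_start = ms + shift
                if m_start < ps:
                    continue
                length = (m_start + mlen) - ps
                if length < max(plen, mlen) or length > pair.max_product:
                    continue
                key = (ps % n, (m_start + mlen - 1) % n, pname, mname)
                if key in seen:
                    continue
                seen.add(key)
                products.append(PcrProduct(length, ps % n,
                                           (m_start + mlen) % n,
                                           pname, mname))
    products.sort(key=lambda p: (p.start, p.length))
    return products
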