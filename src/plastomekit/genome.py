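"""Domain types for circular plastid genomes.

A grass plastome is a circular chromosome with a quadripartite layout:
a large single-copy region (LSC), inverted repeat B (IRb), a small
single-copy region (SSC) and inverted repeat A (IRa), where IRa is the
exact (or near-exact) reverse complement of IRb.  The canonical
arrangement used throughout this package starts the circle at the first
base of the LSC and runs LSC, IRb, SSC, IRa.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

from . import seq as sq

REGION_ORDER = ("LSC", "IRb", "SSC", "IRa")


def gene_base_name(name: str) -> str:
    """Gene symbol without a tRNA anticodon suffix (trnQ-UUG -> trnQ)."""
    return name.split("-")[0] if name.startswith("trn") else name


@dataclass(frozen=True)
class Feature:
    """An annotated element on the canonical circle.

    ``start``/``end`` are 0-based half-open coordinates; ``strand`` is
    '+' or '-'.  ``kind`` is one of {gene, CDS, tRNA, rRNA}.
    """

    name: str
    kind: str
    strand: str
    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"feature {self.name}: empty or inverted interval")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.name}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Plastome:
    """A circular plastome: sequence, quadripartite regions, annotations.

    ``regions`` maps region names (LSC, IRb, SSC, IRa) to 0-based
    half-open intervals on the canonical circle; it is ``None`` for
    assemblies whose structure has not yet been resolved.
    """

    sequence: str
    regions: dict[str, tuple[int, int]] | None = None
    features: list[Feature] = field(default_factory=list)
    name: str = "plastome"
    flags: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.sequence)

    # -- regions -----------------------------------------------------------
    def region(self, name: str) -> tuple[int, int]:
        if self.regions is None:
            raise ValueError(f"{self.name}: regions not resolved")
        return self.regions[name]

    def region_seq(self, name: str) -> str:
        s, e = self.region(name)
        return sq.circular_slice(self.sequence, s, e)

    def region_lengths(self) -> dict[str, int]:
        out = {}
        for name in REGION_ORDER:
            s, e = self.region(name)
            out[name] = e - s
        return out

    def validate(self) -> None:
        """Check the structural invariants of a resolved plastome."""
        if self.regions is not None:
            spans = [self.regions[r] for r in REGION_ORDER]
            total = sum(e - s for s, e in spans)
            if total != len(self.sequence):
                raise ValueError("regions do not tile the circle")
            for (s1, e1), (s2, _) in zip(spans, spans[1:]):
                if e1 != s2:
                    raise ValueError("regions overlap or leave gaps")
        for f in self.features:
            if not (0 <= f.start < f.end <= len(self.sequence)):
                raise ValueError(f"feature {f.name} outside sequence")

    def is_ir_mirrored(self) -> bool:
        """True iff IRa equals the reverse complement of IRb exactly."""
        return sq.revcomp(self.region_seq("IRa")) == self.region_seq("IRb")

    # -- features ----------------------------------------------------------
    def features_sorted(self) -> list[Feature]:
        return sorted(self.features, key=lambda f: (f.start, f.end))

    def feature_by_name(self, name: str) -> Feature:
        for f in self.features_sorted():
            if f.name == name:
                return f
        raise KeyError(f"feature {name!r} not annotated on {self.name}")

    def spacers(self) -> list[tuple[str, str, int, int]]:
        """Intergenic spacers as (left gene, right gene, start, end)."""
        feats = self.features_sorted()
        out = []
        for f, g in zip(feats, feats[1:]):
            if g.start > f.end:
                out.append((f.name, g.name, f.end, g.start))
        return out

    def spacer(self, locus: str) -> tuple[int, int]:
        """Resolve a spacer name like 'rpl23-ndhB' to its interval.

        The gene pair is matched unordered against consecutive annotated
        features; the first occurrence in genome order wins (relevant for
        IR-duplicated spacers).
        """
        parts = locus.split("-")
        if len(parts) < 2:
            raise KeyError(f"{locus!r} is not a 'geneA-geneB' spacer name")
        pairs = [("-".join(parts[:i]), "-".join(parts[i:]))
                 for i in range(1, len(parts))]
        for ln, rn, s, e in self.spacers():
            for a, b in pairs:
                if ({ln, rn} == {a, b}
                        or {gene_base_name(ln), gene_base_name(rn)}
                        == {gene_base_name(a), gene_base_name(b)}):
                    return s, e
        raise KeyError(f"spacer {locus!r} not found on {self.name}")


def rotate_plastome(p: Plastome, offset: int) -> Plastome:
    """Rotate the circle so original position ``offset`` becomes base 0.

    Features that would span the new origin are dropped (rotations used
    in practice cut inside intergenic sequence).
    """
    n = len(p.sequence)
    offset %= n
    seq2 = sq.rotate(p.sequence, offset)
    feats = []
    for f in p.features:
        s = (f.start - offset) % n
        e = s + f.length
        if e <= n:
            feats.append(replace(f, start=s, end=e))
    regions = None
    if p.regions is not None:
        regions = {}
        for name, (s, e) in p.regions.items():
            s2 = (s - offset) % n
            regions[name] = (s2, s2 + (e - s))
        if any(e > n for _, e in regions.values()):
            # a region now wraps the origin; boundaries are no longer
            # representable as plain intervals
            regions = None
    return replace(p, sequence=seq2, features=feats, regions=regions)


def reflect_plastome(p: Plastome) -> Plastome:
    """Reverse-complement the circle, remapping features accordingly."""
    n = len(p.sequence)
    feats = [
        replace(f, start=n - f.end, end=n - f.start,
                strand="-" if f.strand == "+" else "+")
        for f in p.features
    ]
    return replace(p, sequence=sq.revcomp(p.sequence), features=feats, regions=None)
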