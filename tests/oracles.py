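"""Independent brute-force oracles shared by unit and acceptance tests.

Each function re-derives, by direct enumeration, a quantity the package
computes with a faster algorithm; the implementations here deliberately
share no code with the package internals.
"""
import numpy as np

from plastomekit import seq as sq

PRIMER_FWD = "GGGTCTCATCTGAAGGGAGGCAGGC"
PRIMER_REV = "GTGAGGCAGGTTCTCATGGTTCGG"


def brute_force_flank(s, start, end, max_flank):
    """Longest IUPAC-compatible inverted flank by direct scan."""
    best = 0
    for f in range(1, max_flank + 1):
        if start - f < 0 or end + f > len(s):
            break
        up = s[start - f:start]
        down = s[end:end + f]
        if all(sq.iupac_compatible(a, b)
               for a, b in zip(up, sq.revcomp(down))):
            best = f
    return best


def brute_force_pcr(template, pair, max_mismatch):
    """All-pairs convergent primer-site scan on the doubled template."""
    n = len(template)
    t2 = template + template

    def sites(primer):
        m = len(primer)
        out = []
        for i in range(n):
            w = t2[i:i + m]
            mm = sum(not sq.iupac_compatible(a, b)
                     for a, b in zip(primer, w))
            if mm <= max_mismatch and all(
                    sq.iupac_compatible(a, b)
                    for a, b in zip(primer[-3:], w[-3:])):
                out.append((i, m))
        return out

    plus = sites(pair.forward) + sites(pair.reverse)
    minus = [(i, m) for p in (pair.forward, pair.reverse)
             for (i, m) in sites(sq.revcomp(p))]
    found = set()
    for ps, plen in plus:
        for ms, mlen in minus:
            for shift in (0, n):
                start = ms + shift
                if start < ps:
                    continue
                length = start + mlen - ps
                if max(plen, mlen) <= length <= pair.max_product:
                    found.add((ps % n, length))
    return sorted(found)


def plant_primer_sites(rng, n, fwd, rev, gap):
    """Template with a convergent primer-site pair ``gap`` bp apart (5'-5')."""
    t = sq.random_dna(n, 0.6, rng)
    pos = n // 3
    rev_site = sq.revcomp(rev)
    tpl = (t[:pos] + fwd + t[pos + len(fwd):pos + gap - len(rev)]
           + rev_site + t[pos + gap:])
    return tpl[:n], pos


def random_tree(rng, n_leaves=10):
    """Random rooted topology via sequential random joins (newick text)."""
    nodes = [f"T{i}" for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


def clades_brute_force(newick):
    """All clades (leaf sets) by direct parenthesis parsing."""
    clades = []
    stack = []
    token = ""
    for ch in newick:
        if ch == "(":
            stack.append([])
        elif ch in ",);":
            if token:
                for lv in stack:
                    lv.append(token)
                token = ""
            if ch == ")":
                clades.append(frozenset(stack.pop()))
        else:
            token += ch
    return clades
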