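"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written against Biopython's translation
machinery and plain itertools enumeration, independent of the package's
precomputed tables and dynamic-programming code paths.
"""

from __future__ import annotations

import itertools

from Bio.Seq import Seq

BASES = "ACGT"


def aa_of(codon: str) -> str:
    return str(Seq(codon).translate())


def ng86_sites(codon: str) -> float:
    """Synonymous-site count of one codon: per position, synonymous
    single-nt changes over changes that do not create a stop."""
    syn = 0.0
    for pos in range(3):
        n_syn = n_valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if aa_of(mut) == "*":
                continue
            n_valid += 1
            if aa_of(mut) == aa_of(codon):
                n_syn += 1
        if n_valid:
            syn += n_syn / n_valid
    return syn


def ng86_differences(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair by enumerating all mutational
    pathways; pathways through stop codons are excluded unless every
    pathway hits a stop, in which case all are used with stop steps
    counted as non-synonymous."""
    diff = [p for p in range(3) if c1[p] != c2[p]]
    stopfree, all_paths = [], []
    for order in itertools.permutations(diff):
        cur = c1
        s = n = 0
        hit_stop = False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if aa_of(nxt) == "*":
                hit_stop = True
                n += 1
            elif aa_of(cur) != "*" and aa_of(nxt) == aa_of(cur):
                s += 1
            else:
                n += 1
            cur = nxt
        all_paths.append((s, n))
        if not hit_stop:
            stopfree.append((s, n))
    use = stopfree if stopfree else all_paths
    return (
        sum(p[0] for p in use) / len(use),
        sum(p[1] for p in use) / len(use),
    )


def global_alignment_score_bruteforce(s1: str, s2: str, sub, gap_open: int, gap_extend: int) -> float:
    """Optimal global alignment score by exhaustive enumeration of all
    monotone alignments (tiny inputs only).

    A gap of length L costs ``gap_open + L * gap_extend``.  Alignments
    are enumerated as interleavings of match/insert/delete moves.
    """
    best = [float("-inf")]

    def rec(i: int, j: int, score: float, prev: str) -> None:
        if i == len(s1) and j == len(s2):
            best[0] = max(best[0], score)
            return
        if i < len(s1) and j < len(s2):
            rec(i + 1, j + 1, score + sub[s1[i], s2[j]], "m")
        if i < len(s1):
            cost = gap_extend + (0 if prev == "d" else gap_open)
            rec(i + 1, j, score - cost, "d")
        if j < len(s2):
            cost = gap_extend + (0 if prev == "i" else gap_open)
            rec(i, j + 1, score - cost, "i")

    rec(0, 0, 0.0, "m")
    return best[0]


def rbh_bruteforce(scores, ids1, ids2) -> set[tuple[str, str]]:
    """Reciprocal unique-argmax scan over a dense score matrix."""
    out = set()
    n1, n2 = scores.shape
    for i in range(n1):
        row = [scores[i, j] for j in range(n2)]
        m = max(row)
        if row.count(m) != 1:
            continue
        j = row.index(m)
        col = [scores[x, j] for x in range(n1)]
        cm = max(col)
        if col.count(cm) == 1 and col.index(cm) == i:
            out.add((ids1[i], ids2[j]))
    return out


def triangles_bruteforce(r12, r13, r23) -> set[tuple[str, str, str]]:
    """All (a, b, c) with (a,b), (a,c) and (b,c) present."""
    out = set()
    for a, b in r12:
        for a2, c in r13:
            if a2 == a and (b, c) in r23:
                out.add((a, b, c))
    return out
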