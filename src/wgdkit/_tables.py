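"""Precomputed codon tables shared by the Ka/Ks estimators and the
forward simulator.

Codons are indexed 0..63 with bases A,C,G,T = 0,1,2,3 and
``index = 16*b1 + 4*b2 + b3``.  All site and difference tables follow the
Nei–Gojobori conventions: a position's synonymous-site fraction is the
number of synonymous single-nucleotide changes over the number of changes
not creating a stop codon, and multi-hit codon pairs average over all
minimal mutational pathways that avoid stop codons.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np

from .seqio import GENETIC_CODE

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}

CODON_STR = [a + b + c for a in BASES for b in BASES for c in BASES]
AA_BY_IDX = np.array([GENETIC_CODE[c] for c in CODON_STR])
IS_STOP = AA_BY_IDX == "*"
SENSE_IDX = np.flatnonzero(~IS_STOP)

#: transitions: A<->G (0<->2), C<->T (1<->3)
def is_transition(b1: int, b2: int) -> bool:
    return abs(b1 - b2) == 2


def codon_index(codon: str) -> int:
    return 16 * _BASE_IDX[codon[0]] + 4 * _BASE_IDX[codon[1]] + _BASE_IDX[codon[2]]


def codon_bases(idx: int) -> tuple[int, int, int]:
    return (idx >> 4) & 3, (idx >> 2) & 3, idx & 3


def _mutate(idx: int, pos: int, base: int) -> int:
    shift = (2 - pos) * 2
    return (idx & ~(3 << shift)) | (base << shift)


def codon_str_to_indices(s: str) -> np.ndarray:
    """Vectorised codon-string -> index array (no gaps allowed)."""
    lut = np.full(256, -1, dtype=np.int64)
    for b, i in _BASE_IDX.items():
        lut[ord(b)] = i
    arr = lut[np.frombuffer(s.encode(), dtype=np.uint8)]
    if (arr < 0).any():
        raise ValueError("non-ACGT character in codon string")
    arr = arr.reshape(-1, 3)
    return 16 * arr[:, 0] + 4 * arr[:, 1] + arr[:, 2]


_STR_TO_IDX_LUT = None


def _syn_sites() -> tuple[np.ndarray, np.ndarray]:
    syn = np.zeros(64)
    nonsyn = np.zeros(64)
    for idx in range(64):
        if IS_STOP[idx]:
            syn[idx] = nonsyn[idx] = np.nan
            continue
        bases = codon_bases(idx)
        for pos in range(3):
            n_syn = n_valid = 0
            for b in range(4):
                if b == bases[pos]:
                    continue
                j = _mutate(idx, pos, b)
                if IS_STOP[j]:
                    continue
                n_valid += 1
                if AA_BY_IDX[j] == AA_BY_IDX[idx]:
                    n_syn += 1
            if n_valid:
                syn[idx] += n_syn / n_valid
                nonsyn[idx] += 1 - n_syn / n_valid
            # a sense codon always has a non-stop alternative at each position
    return syn, nonsyn


SYN_SITES, NONSYN_SITES = _syn_sites()


def _degeneracy() -> np.ndarray:
    """Per-codon per-position fold class: 0, 2 or 4 (3-fold counted as 2)."""
    deg = np.zeros((64, 3), dtype=np.int64)
    for idx in range(64):
        if IS_STOP[idx]:
            continue
        bases = codon_bases(idx)
        for pos in range(3):
            n_syn = sum(
                1
                for b in range(4)
                if b != bases[pos]
                and not IS_STOP[j := _mutate(idx, pos, b)]
                and AA_BY_IDX[j] == AA_BY_IDX[idx]
            )
            deg[idx, pos] = 4 if n_syn == 3 else (0 if n_syn == 0 else 2)
    return deg


DEGENERACY = _degeneracy()


@lru_cache(maxsize=None)
def pathways(i: int, j: int) -> tuple[tuple[tuple[tuple[int, bool, bool], ...], int], ...]:
    """Minimal mutational pathways between two sense codons.

    Returns a tuple of ``(steps, n_transitions)`` over stop-free pathways,
    each step a ``(position, is_transition, is_synonymous)`` triple.  If
    every pathway passes through a stop codon, all pathways are returned
    instead (stop steps counted as non-synonymous).
    """
    bi, bj = codon_bases(i), codon_bases(j)
    diff = [p for p in range(3) if bi[p] != bj[p]]
    valid, invalid = [], []
    for order in itertools.permutations(diff):
        cur = i
        steps = []
        hit_stop = False
        for p in order:
            nxt = _mutate(cur, p, bj[p])
            syn = (not IS_STOP[nxt]) and (not IS_STOP[cur]) and AA_BY_IDX[nxt] == AA_BY_IDX[cur]
            steps.append((p, is_transition(codon_bases(cur)[p], bj[p]), syn))
            if IS_STOP[nxt] and nxt != j:
                hit_stop = True
            cur = nxt
        entry = (tuple(steps), sum(1 for s in steps if s[1]))
        (invalid if hit_stop else valid).append(entry)
    return tuple(valid if valid else invalid)


def _diff_tables() -> tuple[np.ndarray, np.ndarray]:
    """NG86 pathway-averaged synonymous/non-synonymous difference counts."""
    sd = np.zeros((64, 64))
    nd = np.zeros((64, 64))
    for i in range(64):
        if IS_STOP[i]:
            sd[i, :] = nd[i, :] = np.nan
            continue
        for j in range(64):
            if IS_STOP[j]:
                sd[i, j] = nd[i, j] = np.nan
                continue
            if i == j:
                continue
            paths = pathways(i, j)
            s = n = 0.0
            for steps, _ in paths:
                for _, _, syn in steps:
                    if syn:
                        s += 1
                    else:
                        n += 1
            sd[i, j] = s / len(paths)
            nd[i, j] = n / len(paths)
    return sd, nd


SD_TABLE, ND_TABLE = _diff_tables()


def _proposal_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single-nucleotide mutation proposals per codon.

    For each codon, the 9 possible point mutations (3 per position, in
    base order) with their target codon index, transition flag and
    selective class (0 = stop, 1 = synonymous, 2 = non-synonymous).
    """
    neigh = np.zeros((64, 9), dtype=np.int64)
    is_ts = np.zeros((64, 9), dtype=bool)
    cls = np.zeros((64, 9), dtype=np.int8)
    for idx in range(64):
        bases = codon_bases(idx)
        slot = 0
        for pos in range(3):
            for b in range(4):
                if b == bases[pos]:
                    continue
                j = _mutate(idx, pos, b)
                neigh[idx, slot] = j
                is_ts[idx, slot] = is_transition(bases[pos], b)
                if IS_STOP[j]:
                    cls[idx, slot] = 0
                elif AA_BY_IDX[j] == AA_BY_IDX[idx]:
                    cls[idx, slot] = 1
                else:
                    cls[idx, slot] = 2
                slot += 1
    return neigh, is_ts, cls


PROP_NEIGH, PROP_IS_TS, PROP_CLS = _proposal_tables()
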