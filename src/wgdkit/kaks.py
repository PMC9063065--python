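"""Ka/Ks estimation for codon-aligned sequence pairs.

Two estimators are provided and tagged in every output:

``NG86``
    Nei–Gojobori counting: fractional synonymous/non-synonymous sites per
    codon, pathway-averaged difference counts for multi-hit codons
    (stop-codon pathways excluded), and a Jukes–Cantor multiple-hit
    correction ``d = -(3/4) ln(1 - (4/3) p)``.

``LPB_kappa``
    A transition/transversion-aware Li–Pamilo–Bianchi estimator: codon
    positions are classified by degeneracy (0-, 2-, 4-fold), transitional
    and transversional difference proportions per class are corrected
    with the Kimura two-parameter model, and Ka/Ks are assembled as

        Ks = (L2*A2 + L4*A4) / (L2 + L4) + B4
        Ka = A0 + (L0*B0 + L2*B2) / (L0 + L2)

    where ``A`` and ``B`` are the K2P transitional and transversional
    distances per class.  The supplied (or K2P-estimated) kappa weights
    the mutational pathways of multi-hit codons, which apportions
    ambiguous differences between degeneracy classes.  This serves as the
    package's surrogate for maximum-likelihood LPB variants implemented
    in external Ka/Ks calculators.

Gapped codon columns are dropped pairwise before any counting.  omega is
reported as missing (``None``) when Ks is zero or unestimable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from ._tables import (
    DEGENERACY,
    ND_TABLE,
    NONSYN_SITES,
    SD_TABLE,
    SYN_SITES,
    codon_str_to_indices,
    pathways,
)
from .codonaln import CodonAlignment

log = logging.getLogger(__name__)

#: fallback transition/transversion rate ratio when unestimable
KAPPA_FALLBACK = 2.0


@dataclass(frozen=True)
class SiteCounts:
    """Nei–Gojobori site and difference counts for one aligned pair.

    On alignments of realistic length the difference counts stay below
    the corresponding site counts; on degenerate one- or two-codon
    alignments pathway averaging can push ``Sd`` above ``S`` (the classic
    p > 3/4 regime), which the Jukes–Cantor step then reports as an
    undefined estimate rather than an error here.
    """

    S: float
    N: float
    Sd: float
    Nd: float

    def __post_init__(self) -> None:
        if min(self.S, self.N, self.Sd, self.Nd) < 0:
            raise ValueError("negative site or difference count")


@dataclass(frozen=True)
class KaKsEstimate:
    id_1: str
    id_2: str
    ka: float | None
    ks: float | None
    omega: float | None
    kappa: float
    method: str
    status: str  # ok | saturated | undefined
    counts: SiteCounts | None = None


def _pair_indices(aln: CodonAlignment) -> tuple[np.ndarray, np.ndarray]:
    pairs = aln.ungapped_codon_pairs()
    if not pairs:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    i1 = codon_str_to_indices("".join(p[0] for p in pairs))
    i2 = codon_str_to_indices("".join(p[1] for p in pairs))
    return i1, i2


def count_sites_ng86(aln: CodonAlignment) -> SiteCounts:
    """NG86 site and difference counts over the ungapped codon columns.

    Sites are averaged over the two sequences, so S + N equals three times
    the number of codon columns exactly.
    """
    i1, i2 = _pair_indices(aln)
    if i1.size == 0:
        raise ValueError(f"{aln.id_1}/{aln.id_2}: no ungapped codon columns")
    S = 0.5 * (SYN_SITES[i1].sum() + SYN_SITES[i2].sum())
    N = 0.5 * (NONSYN_SITES[i1].sum() + NONSYN_SITES[i2].sum())
    Sd = float(SD_TABLE[i1, i2].sum())
    Nd = float(ND_TABLE[i1, i2].sum())
    return SiteCounts(float(S), float(N), Sd, Nd)


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def kaks_ng86(
    counts: SiteCounts, id_1: str = "", id_2: str = "", kappa: float = float("nan")
) -> KaKsEstimate:
    """Jukes–Cantor-corrected Ka/Ks from NG86 counts.

    Status is ``undefined`` when either proportion reaches the correction
    boundary p >= 3/4.
    """
    if counts.S <= 0 or counts.N <= 0:
        return KaKsEstimate(id_1, id_2, None, None, None, kappa, "NG86", "undefined", counts)
    ka = _jukes_cantor(counts.Nd / counts.N)
    ks = _jukes_cantor(counts.Sd / counts.S)
    if ka is None or ks is None:
        return KaKsEstimate(id_1, id_2, ka, ks, None, kappa, "NG86", "undefined", counts)
    omega = ka / ks if ks > 0 else None
    return KaKsEstimate(id_1, id_2, ka, ks, omega, kappa, "NG86", "ok", counts)


def estimate_kappa(aln: CodonAlignment) -> float:
    """Transition/transversion rate ratio from fourfold-degenerate sites.

    Fits the Kimura two-parameter model to third positions whose codons
    are fourfold degenerate in both sequences.  Falls back to
    ``KAPPA_FALLBACK`` (with a warning) when fewer than 10 such sites are
    available or the K2P logarithms are undefined.
    """
    i1, i2 = _pair_indices(aln)
    four = (DEGENERACY[i1, 2] == 4) & (DEGENERACY[i2, 2] == 4)
    n = int(four.sum())
    if n < 10:
        log.warning("%s/%s: %d fourfold sites, using kappa fallback", aln.id_1, aln.id_2, n)
        return KAPPA_FALLBACK
    b1 = i1[four] & 3
    b2 = i2[four] & 3
    diff = b1 != b2
    ts = diff & (np.abs(b1 - b2) == 2)
    P = float(ts.sum()) / n
    Q = float((diff & ~ts).sum()) / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        log.warning("%s/%s: K2P saturated at fourfold sites, kappa fallback", aln.id_1, aln.id_2)
        return KAPPA_FALLBACK
    alpha_t = -0.5 * math.log(w1) + 0.25 * math.log(w2)
    beta_t = -0.25 * math.log(w2)
    if beta_t <= 0 or alpha_t <= 0:
        return KAPPA_FALLBACK
    return alpha_t / beta_t


def _k2p_class(P: float, Q: float) -> tuple[float, float] | None:
    """K2P transitional (A) and transversional (B) distances; None if saturated."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return None
    A = -0.5 * math.log(w1) + 0.25 * math.log(w2)
    B = -0.5 * math.log(w2)
    return max(A, 0.0), max(B, 0.0)


def kaks_lpb(aln: CodonAlignment, kappa: float | None = None) -> KaKsEstimate:
    """Kappa-aware Li–Pamilo–Bianchi Ka/Ks estimate (method ``LPB_kappa``)."""
    i1, i2 = _pair_indices(aln)
    if i1.size == 0:
        raise ValueError(f"{aln.id_1}/{aln.id_2}: no ungapped codon columns")
    if kappa is None:
        kappa = estimate_kappa(aln)

    # degeneracy-class site totals, averaged over the two sequences
    L = {d: 0.0 for d in (0, 2, 4)}
    deg1 = DEGENERACY[i1]
    deg2 = DEGENERACY[i2]
    for d in (0, 2, 4):
        L[d] = 0.5 * float((deg1 == d).sum() + (deg2 == d).sum())

    # kappa-weighted pathway apportionment of differences
    ts = {d: 0.0 for d in (0, 2, 4)}
    tv = {d: 0.0 for d in (0, 2, 4)}
    for c1, c2, dg1, dg2 in zip(i1, i2, deg1, deg2):
        if c1 == c2:
            continue
        paths = pathways(int(c1), int(c2))
        weights = [kappa ** n_ts for _, n_ts in paths]
        total_w = sum(weights)
        for (steps, _), w in zip(paths, weights):
            for pos, is_ts, _ in steps:
                share = w / total_w
                sink = ts if is_ts else tv
                sink[int(dg1[pos])] += 0.5 * share
                sink[int(dg2[pos])] += 0.5 * share

    A = {}
    B = {}
    for d in (0, 2, 4):
        if L[d] <= 0:
            A[d] = B[d] = 0.0
            continue
        res = _k2p_class(ts[d] / L[d], tv[d] / L[d])
        if res is None:
            return KaKsEstimate(aln.id_1, aln.id_2, None, None, None, kappa,
                                "LPB_kappa", "saturated")
        A[d], B[d] = res

    counts = count_sites_ng86(aln)
    if L[2] + L[4] <= 0 or L[0] + L[2] <= 0:
        return KaKsEstimate(aln.id_1, aln.id_2, None, None, None, kappa,
                            "LPB_kappa", "undefined", counts)
    ks = (L[2] * A[2] + L[4] * A[4]) / (L[2] + L[4]) + B[4]
    ka = A[0] + (L[0] * B[0] + L[2] * B[2]) / (L[0] + L[2])
    omega = ka / ks if ks > 0 else None
    return KaKsEstimate(aln.id_1, aln.id_2, ka, ks, omega, kappa, "LPB_kappa", "ok", counts)


def estimate_pair(aln: CodonAlignment, method: str = "LPB_kappa") -> KaKsEstimate:
    """Estimate Ka/Ks for one codon alignment with the chosen method."""
    if method == "NG86":
        counts = count_sites_ng86(aln)
        return kaks_ng86(counts, aln.id_1, aln.id_2, kappa=estimate_kappa(aln))
    if method == "LPB_kappa":
        return kaks_lpb(aln)
    raise ValueError(f"unknown method {method!r}")


def estimates_to_frame(estimates: Iterable[KaKsEstimate]) -> pd.DataFrame:
    """Tabulate estimates in the per-pair TSV layout."""
    rows = []
    for e in estimates:
        c = e.counts
        rows.append(
            (e.id_1, e.id_2, e.method,
             c.S if c else np.nan, c.N if c else np.nan,
             c.Sd if c else np.nan, c.Nd if c else np.nan,
             e.kappa,
             np.nan if e.ka is None else e.ka,
             np.nan if e.ks is None else e.ks,
             np.nan if e.omega is None else e.omega,
             e.status)
        )
    return pd.DataFrame(
        rows,
        columns=["id_1", "id_2", "method", "S", "N", "Sd", "Nd",
                 "kappa", "ka", "ks", "omega", "status"],
    )
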