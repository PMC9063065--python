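"""Per-cluster Ka/Ks selection scans over 1:1:1 ortholog clusters.

For each ortholog cluster and species pair, an inter-species codon
alignment is built and omega (Ka/Ks) computed per species orientation.
Two orientations are supported:

``symmetric`` (default)
    The single pairwise omega is reported for both species axes.  This
    is the directly measurable quantity; it cannot separate the two
    lineages' rates.

``outgroup``
    Per-branch Ka and Ks are apportioned from the three pairwise
    distances with a third species as outgroup
    (``ka_sp1 = (ka_12 + ka_1o - ka_2o) / 2``, likewise Ks), giving each
    species its own rate since the split.  Required to detect
    species-divergent selection.

Clusters are classified from their two omegas: positive selection in
both species (both >= 1), species-divergent (one >= 1, the other under
intense purifying selection <= 0.7), conserved in both (< 1), otherwise
mixed.  Clusters whose omega is unestimable are labelled missing.
A user-supplied table of reference proteins for genes of interest
(immunity, stress response, shell formation, ...) can be joined onto the
results by local-alignment similarity at an 80 % cut-off.
"""

from __future__ import annotations

import logging
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import codonaln, kaks
from .homology import OrthologCluster, align_pair
from .seqio import CodingSequence, ProteinRecord

log = logging.getLogger(__name__)

POS_THRESH = 1.0
CONS_THRESH = 0.7

LABELS = ("positive_both", "divergent_sp1", "divergent_sp2",
          "conserved_both", "mixed", "missing")


def classify_selection(
    omega_sp1: float | None,
    omega_sp2: float | None,
    pos_thresh: float = POS_THRESH,
    cons_thresh: float = CONS_THRESH,
) -> str:
    """Selection-regime label for one cluster's per-species omegas.

    Pure, total function: ``positive_both`` iff both >= ``pos_thresh``;
    ``divergent_spX`` iff species X is >= ``pos_thresh`` and the other
    <= ``cons_thresh``; ``conserved_both`` iff both < ``pos_thresh``;
    any other finite combination is ``mixed``; a missing omega gives
    ``missing``.
    """
    def bad(o):
        return o is None or (isinstance(o, float) and math.isnan(o))

    if bad(omega_sp1) or bad(omega_sp2):
        return "missing"
    o1, o2 = float(omega_sp1), float(omega_sp2)
    if o1 >= pos_thresh and o2 >= pos_thresh:
        return "positive_both"
    if o1 >= pos_thresh and o2 <= cons_thresh:
        return "divergent_sp1"
    if o2 >= pos_thresh and o1 <= cons_thresh:
        return "divergent_sp2"
    if o1 < pos_thresh and o2 < pos_thresh:
        return "conserved_both"
    return "mixed"


def _estimate(cds1: CodingSequence, cds2: CodingSequence, method: str) -> kaks.KaKsEstimate:
    return kaks.estimate_pair(codonaln.align_codons(cds1, cds2), method)


def pairwise_cluster_omega(
    clusters: Sequence[OrthologCluster],
    cds_by_species: Mapping[str, Mapping[str, CodingSequence]],
    species_pair: tuple[str, str],
    method: str = "LPB_kappa",
    orientation: str = "symmetric",
    outgroup: str | None = None,
    pos_thresh: float = POS_THRESH,
    cons_thresh: float = CONS_THRESH,
) -> pd.DataFrame:
    """Per-cluster omega for one species pair, plus selection labels.

    Returns a frame with cluster member ids, ``omega_sp1``/``omega_sp2``
    (NaN when unestimable) and the regime ``label``.  With
    ``orientation="outgroup"`` the per-branch rates are derived from the
    three pairwise estimates through ``outgroup``.
    """
    if orientation not in ("symmetric", "outgroup"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if orientation == "outgroup" and not outgroup:
        raise ValueError("outgroup species required for outgroup orientation")
    sp1, sp2 = species_pair
    rows = []
    for ci, cl in enumerate(clusters):
        try:
            c1 = cds_by_species[sp1][cl.member(sp1)]
            c2 = cds_by_species[sp2][cl.member(sp2)]
        except KeyError as exc:
            warnings.warn(f"cluster {ci}: missing CDS {exc}; skipped", stacklevel=2)
            continue
        if orientation == "symmetric":
            est = _estimate(c1, c2, method)
            o1 = o2 = np.nan if est.omega is None else est.omega
            ksym = np.nan if est.ks is None else est.ks
        else:
            co = cds_by_species[outgroup][cl.member(outgroup)]
            e12 = _estimate(c1, c2, method)
            e1o = _estimate(c1, co, method)
            e2o = _estimate(c2, co, method)
            o1, o2 = _branch_omegas(e12, e1o, e2o)
            ksym = np.nan if e12.ks is None else e12.ks
        rows.append(
            (f"c{ci:04d}", cl.member(sp1), cl.member(sp2), o1, o2, ksym,
             classify_selection(o1, o2, pos_thresh, cons_thresh))
        )
    return pd.DataFrame(
        rows,
        columns=["cluster", f"id_{sp1}", f"id_{sp2}",
                 "omega_sp1", "omega_sp2", "ks_pair", "label"],
    )


def _branch_omegas(
    e12: kaks.KaKsEstimate, e1o: kaks.KaKsEstimate, e2o: kaks.KaKsEstimate
) -> tuple[float, float]:
    """Distance-based apportionment of Ka and Ks onto the two ingroup
    branches; NaN where a rate is unestimable or non-positive."""
    ests = (e12, e1o, e2o)
    if any(e.status != "ok" or e.ka is None or e.ks is None for e in ests):
        return (np.nan, np.nan)
    ka1 = (e12.ka + e1o.ka - e2o.ka) / 2.0
    ka2 = (e12.ka + e2o.ka - e1o.ka) / 2.0
    ks1 = (e12.ks + e1o.ks - e2o.ks) / 2.0
    ks2 = (e12.ks + e2o.ks - e1o.ks) / 2.0
    o1 = ka1 / ks1 if ks1 > 0 and ka1 >= 0 else np.nan
    o2 = ka2 / ks2 if ks2 > 0 and ka2 >= 0 else np.nan
    return (o1, o2)


def label_counts(records: pd.DataFrame) -> pd.Series:
    """Cluster counts per selection label (zero-filled, partitioning)."""
    counts = records["label"].value_counts()
    return counts.reindex(LABELS, fill_value=0)


def tag_genes_of_interest(
    records: pd.DataFrame,
    interest_table: pd.DataFrame,
    proteins_by_id: Mapping[str, ProteinRecord],
    min_similarity: float = 80.0,
) -> pd.DataFrame:
    """Join a genes-of-interest table onto cluster records.

    ``interest_table`` needs columns ``name``, ``category`` and
    ``sequence`` (reference protein).  A cluster is tagged with a
    category when any member aligns locally to a reference with
    similarity >= ``min_similarity`` %; among competing references the
    highest similarity wins (category name breaks exact ties).
    """
    out = records.copy()
    out["interest_tag"] = pd.NA
    out["interest_ref"] = pd.NA
    if len(interest_table) == 0:
        warnings.warn("empty genes-of-interest table: nothing tagged", stacklevel=2)
        return out
    refs = [
        (str(r["name"]), str(r["category"]), ProteinRecord(str(r["name"]), str(r["sequence"])))
        for _, r in interest_table.iterrows()
    ]
    member_cols = [c for c in records.columns if c.startswith("id_")]
    for i, row in out.iterrows():
        best: tuple[float, str, str] | None = None
        for col in member_cols:
            prot = proteins_by_id.get(row[col])
            if prot is None:
                continue
            for name, category, ref in refs:
                hit, _ = align_pair(prot, ref, mode="local")
                if hit.similarity_pct < min_similarity:
                    continue
                # higher similarity wins; exact ties resolved by category name
                if (
                    best is None
                    or hit.similarity_pct > best[0]
                    or (hit.similarity_pct == best[0] and category < best[1])
                ):
                    best = (hit.similarity_pct, category, name)
        if best is not None:
            out.loc[i, "interest_tag"] = best[1]
            out.loc[i, "interest_ref"] = best[2]
    return out
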