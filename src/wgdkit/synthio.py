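"""Synthetic data generators for every input the pipeline consumes.

Three scenario families are emulated, each a pure function of its
scenario (seed included):

* **Paranomes** whose duplicate-pair Ks ages mix an exponential
  small-scale-duplication background with log-normal WGD bursts, for the
  mixture-dating recovery experiments.
* **Three-species 1:1:1 ortholog clusters** with planted omega regimes
  (purifying, positive, species-divergent) on a rooted three-taxon tree,
  species 3 serving as outgroup.
* **Diploid short-read sequencing** of a genome with known size,
  heterozygosity and repeat structure, emitted as FASTQ or directly as a
  k-mer depth spectrum.

Sequence evolution is a codon-level accept/reject mutation process:
point mutations are proposed uniformly over sites with transition rate
kappa (transversions 1), mutations creating stop codons are rejected,
synonymous changes fix freely and non-synonymous changes fix with
probability proportional to omega.  Each branch carries two Poisson
substitution quotas — synonymous events with mean ``target_ks/2 x
synonymous sites`` and non-synonymous events with mean ``omega x
target_ks/2 x non-synonymous sites`` (Nei-Gojobori site counts of the
ancestor) — and evolves, classes interleaved at the omega-paced
acceptance rates, until both are met.  The planted Ks and Ka are thus
the realised substitution counts per site.  This is approximate
above Ks ~ 3, where synonymous saturation makes any counting-based
ground truth soft; the affected pairs lie beyond the analysis truncation
anyway.

Every truth table is sufficient to score the downstream stage without
re-deriving ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._tables import (
    CODON_STR,
    NONSYN_SITES,
    PROP_CLS,
    PROP_IS_TS,
    PROP_NEIGH,
    SENSE_IDX,
    SYN_SITES,
)
from .seqio import CodingSequence

_CODON_ARR = np.array(CODON_STR)


# ---------------------------------------------------------------------------
# scenarios


@dataclass(frozen=True)
class EvolutionScenario:
    """A paranome with an SSD background and planted WGD bursts.

    ``wgd_events`` lists ``(median_ks, sigma_ln, n_pairs)`` per burst;
    pair ages are drawn log-normally so that burst recovery by the
    log-normal mixture fit is a well-posed parameter-recovery experiment.
    Defaults plant the two bursts reported for the blue mussel paranome
    (median Ks 0.6132 and 1.8196) over 1500 background pairs.
    """

    seed: int = 0
    n_background_pairs: int = 1500
    background_rate: float = 1.0
    wgd_events: tuple[tuple[float, float, int], ...] = (
        (0.6132, 0.25, 800),
        (1.8196, 0.25, 800),
    )
    omega_background: float = 0.1
    codon_length: int = 300
    kappa: float = 2.0

    def __post_init__(self) -> None:
        if self.n_background_pairs < 0 or self.codon_length < 1:
            raise ValueError("invalid scenario counts")
        for med, sig, n in self.wgd_events:
            if not (0 < med < 5) or sig <= 0 or n < 0:
                raise ValueError(f"invalid WGD event ({med}, {sig}, {n})")


@dataclass(frozen=True)
class OrthologScenario:
    """Three-species 1:1:1 ortholog clusters with planted omega regimes.

    ``regimes`` maps an ``(omega_sp1, omega_sp2)`` pair to its cluster
    fraction; fractions must sum to 1.  Species 1 and 2 each sit
    ``divergence_ks/2`` from their common ancestor; species 3 is an
    outgroup at ``divergence_ks`` from that ancestor, evolving under
    ``omega_outgroup``.
    """

    seed: int = 0
    n_clusters: int = 200
    divergence_ks: float = 0.3
    regimes: tuple[tuple[tuple[float, float], float], ...] = (
        ((0.2, 0.2), 1 / 3),
        ((1.5, 1.5), 1 / 3),
        ((1.5, 0.2), 1 / 3),
    )
    codon_length: int = 500
    kappa: float = 2.0
    omega_outgroup: float = 0.2
    species: tuple[str, str, str] = ("sp1", "sp2", "sp3")

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.regimes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"regime fractions sum to {total}, expected 1")


@dataclass(frozen=True)
class SequencingScenario:
    """Diploid short-read sequencing of a synthetic genome.

    ``heterozygosity`` is the per-base allelic difference rate between
    the two haplotypes; ``coverage`` is total depth (both haplotypes
    combined); ``repeat_fraction`` of the genome consists of a unit
    repeated ``repeat_copy_number`` times.
    """

    seed: int = 0
    genome_size: int = 1_000_000
    heterozygosity: float = 0.01
    coverage: float = 40.0
    read_length: int = 150
    error_rate: float = 0.002
    repeat_fraction: float = 0.0
    repeat_copy_number: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.heterozygosity <= 0.1:
            raise ValueError("heterozygosity must be in [0, 0.1]")
        if self.coverage <= 0 or self.genome_size < self.read_length:
            raise ValueError("invalid coverage or genome size")


# ---------------------------------------------------------------------------
# forward codon evolution


def _evolve_branches(
    ancestors: np.ndarray,
    syn_targets: np.ndarray,
    non_targets: np.ndarray,
    omega: np.ndarray,
    kappa: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve each row of ``ancestors`` to planted substitution counts.

    ``ancestors`` is a (branches, codons) codon-index matrix; a copy is
    evolved and returned.  Proposals are uniform over codon positions
    with within-site weights (kappa for the transition, 1 per
    transversion); stop-codon mutants are always rejected.  Synonymous
    changes accept with probability ``1/max(1, omega)`` and
    non-synonymous with ``omega/max(1, omega)`` — but only while the
    corresponding per-branch event quota (``syn_targets`` /
    ``non_targets``) is unmet, so each branch realises exactly its
    planted synonymous and non-synonymous substitution counts with the
    two classes interleaved at the omega-paced rates.
    """
    M = np.array(ancestors, dtype=np.int64, copy=True)
    n_branches, L = M.shape
    w = np.where(PROP_IS_TS, kappa, 1.0)
    cumw = np.cumsum(w, axis=1)
    total_w = cumw[:, -1].copy()  # identical for all codons: 3*kappa + 6
    scale = np.maximum(1.0, omega)
    p_syn = 1.0 / scale
    p_non = omega / scale

    syn_count = np.zeros(n_branches, dtype=np.int64)
    non_count = np.zeros(n_branches, dtype=np.int64)

    def unmet(idx):
        return (syn_count[idx] < syn_targets[idx]) | (non_count[idx] < non_targets[idx])

    active = np.flatnonzero(unmet(np.arange(n_branches)))
    while active.size:
        pos = rng.integers(0, L, size=active.size)
        u = rng.random(active.size)
        u2 = rng.random(active.size)
        cur = M[active, pos]
        j = (cumw[cur] < (u * total_w[cur])[:, None]).sum(axis=1)
        cls = PROP_CLS[cur, j]
        acc_syn = (cls == 1) & (u2 < p_syn[active]) & (syn_count[active] < syn_targets[active])
        acc_non = (cls == 2) & (u2 < p_non[active]) & (non_count[active] < non_targets[active])
        accept = acc_syn | acc_non
        upd = np.flatnonzero(accept)
        M[active[upd], pos[upd]] = PROP_NEIGH[cur[upd], j[upd]]
        syn_count[active] += acc_syn
        non_count[active] += acc_non
        active = active[unmet(active)]
    return M


def _random_ancestors(rng: np.random.Generator, n: int, n_codons: int) -> np.ndarray:
    return rng.choice(SENSE_IDX, size=(n, n_codons))


def _to_nt(row: np.ndarray) -> str:
    return "".join(_CODON_ARR[row])


def _event_targets(
    rng: np.random.Generator,
    ancestors: np.ndarray,
    t_per_branch: np.ndarray,
    omega: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson substitution quotas: synonymous events at ``t`` per
    synonymous site, non-synonymous at ``omega * t`` per non-synonymous
    site (NG86 site counts of the ancestor)."""
    s_sites = SYN_SITES[ancestors].sum(axis=1)
    n_sites = NONSYN_SITES[ancestors].sum(axis=1)
    return (
        rng.poisson(t_per_branch * s_sites),
        rng.poisson(omega * t_per_branch * n_sites),
    )


def evolve_pair(
    ancestor: CodingSequence,
    target_ks: float,
    omega: float,
    kappa: float = 2.0,
    seed: int = 0,
) -> tuple[CodingSequence, CodingSequence]:
    """Evolve two descendants of ``ancestor`` to a planted pairwise Ks."""
    if target_ks < 0:
        raise ValueError("target_ks must be >= 0")
    from ._tables import codon_str_to_indices

    rng = np.random.default_rng(seed)
    anc = codon_str_to_indices(ancestor.nt)
    ancestors = np.vstack([anc, anc])
    om = np.full(2, float(omega))
    syn_t, non_t = _event_targets(rng, ancestors, np.full(2, target_ks / 2.0), om)
    M = _evolve_branches(ancestors, syn_t, non_t, om, kappa, rng)
    return (
        CodingSequence(f"{ancestor.id}_a", _to_nt(M[0])),
        CodingSequence(f"{ancestor.id}_b", _to_nt(M[1])),
    )


# ---------------------------------------------------------------------------
# paranome


def simulate_paranome(
    scn: EvolutionScenario,
) -> tuple[list[CodingSequence], pd.DataFrame]:
    """Generate a paranome of duplicate pairs with planted Ks ages.

    Returns the coding sequences (two per pair) and a truth table with
    one row per pair: ids, origin (``background`` or ``wgd_<i>``) and the
    planted (drawn) Ks age.
    """
    rng = np.random.default_rng(scn.seed)
    ages = [rng.exponential(1.0 / scn.background_rate, size=scn.n_background_pairs)]
    origins = ["background"] * scn.n_background_pairs
    for i, (med, sig, n) in enumerate(scn.wgd_events, start=1):
        ages.append(rng.lognormal(mean=np.log(med), sigma=sig, size=n))
        origins += [f"wgd_{i}"] * n
    ks = np.concatenate(ages) if ages else np.empty(0)
    n_pairs = ks.size

    ancestors = _random_ancestors(rng, n_pairs, scn.codon_length)
    anc2 = np.repeat(ancestors, 2, axis=0)
    t = np.repeat(ks / 2.0, 2)
    om = np.full(2 * n_pairs, scn.omega_background)
    syn_t, non_t = _event_targets(rng, anc2, t, om)
    M = _evolve_branches(anc2, syn_t, non_t, om, scn.kappa, rng)

    seqs: list[CodingSequence] = []
    rows = []
    for p in range(n_pairs):
        ida, idb = f"dup{p:05d}a", f"dup{p:05d}b"
        seqs.append(CodingSequence(ida, _to_nt(M[2 * p])))
        seqs.append(CodingSequence(idb, _to_nt(M[2 * p + 1])))
        rows.append((ida, idb, origins[p], float(ks[p])))
    truth = pd.DataFrame(rows, columns=["id_a", "id_b", "origin", "planted_ks"])
    truth["omega"] = scn.omega_background
    truth["n_codons"] = scn.codon_length
    return seqs, truth


# ---------------------------------------------------------------------------
# orthologs


def simulate_orthologs(
    scn: OrthologScenario,
) -> tuple[dict[str, list[CodingSequence]], pd.DataFrame]:
    """Generate planted 1:1:1 ortholog clusters across three species.

    Returns per-species coding sequences and a truth table with cluster
    id, member ids, the planted per-species omegas and the planted
    selection-regime label.
    """
    from .selscan import classify_selection

    rng = np.random.default_rng(scn.seed)
    n = scn.n_clusters
    # largest-remainder apportionment of clusters to regimes, then shuffle
    fracs = np.array([f for _, f in scn.regimes])
    counts = np.floor(fracs * n).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(fracs * n - counts))
    counts[order[:rem]] += 1
    regime_idx = np.repeat(np.arange(len(scn.regimes)), counts)
    rng.shuffle(regime_idx)

    omegas = np.array([pair for pair, _ in scn.regimes])
    omega1 = omegas[regime_idx, 0]
    omega2 = omegas[regime_idx, 1]

    ancestors = _random_ancestors(rng, n, scn.codon_length)
    half = scn.divergence_ks / 2.0
    anc3 = np.vstack([ancestors, ancestors, ancestors])
    t = np.concatenate([np.full(n, half), np.full(n, half), np.full(n, 2 * half)])
    om = np.concatenate([omega1, omega2, np.full(n, scn.omega_outgroup)])
    syn_t, non_t = _event_targets(rng, anc3, t, om)
    M = _evolve_branches(anc3, syn_t, non_t, om, scn.kappa, rng)

    s1, s2, s3 = scn.species
    seqs: dict[str, list[CodingSequence]] = {s1: [], s2: [], s3: []}
    rows = []
    for c in range(n):
        ids = {sp: f"c{c:04d}_{sp}" for sp in scn.species}
        seqs[s1].append(CodingSequence(ids[s1], _to_nt(M[c])))
        seqs[s2].append(CodingSequence(ids[s2], _to_nt(M[n + c])))
        seqs[s3].append(CodingSequence(ids[s3], _to_nt(M[2 * n + c])))
        rows.append(
            (f"c{c:04d}", ids[s1], ids[s2], ids[s3],
             float(omega1[c]), float(omega2[c]),
             classify_selection(float(omega1[c]), float(omega2[c])))
        )
    truth = pd.DataFrame(
        rows,
        columns=["cluster", f"id_{s1}", f"id_{s2}", f"id_{s3}",
                 "omega_sp1", "omega_sp2", "label"],
    )
    return seqs, truth


# ---------------------------------------------------------------------------
# sequencing reads


_NT = np.frombuffer(b"ACGT", dtype=np.uint8)


def make_diploid_genome(scn: SequencingScenario) -> tuple[np.ndarray, np.ndarray]:
    """Two haplotypes as base-index (0..3) arrays.

    Haplotype 1 is random sequence, optionally with a repeated unit
    occupying ``repeat_fraction`` of its length; haplotype 2 differs at
    ``heterozygosity`` of positions.
    """
    rng = np.random.default_rng(scn.seed)
    G = scn.genome_size
    n_rep = int(round(G * scn.repeat_fraction))
    unit_len = max(n_rep // scn.repeat_copy_number, 0)
    unique = rng.integers(0, 4, size=G - unit_len * scn.repeat_copy_number, dtype=np.uint8)
    parts = [unique]
    if unit_len:
        unit = rng.integers(0, 4, size=unit_len, dtype=np.uint8)
        parts += [unit] * scn.repeat_copy_number
    hap1 = np.concatenate(parts)
    hap2 = hap1.copy()
    n_snp = rng.binomial(G, scn.heterozygosity)
    if n_snp:
        pos = rng.choice(G, size=n_snp, replace=False)
        hap2[pos] = (hap2[pos] + rng.integers(1, 4, size=n_snp, dtype=np.uint8)) % 4
    return hap1, hap2


def simulate_read_matrix(scn: SequencingScenario) -> np.ndarray:
    """Sample error-bearing reads as a (n_reads, read_length) base-index
    matrix, uniformly over both haplotypes."""
    rng = np.random.default_rng(scn.seed)
    hap1, hap2 = make_diploid_genome(scn)
    G, rl = scn.genome_size, scn.read_length
    n_reads = int(round(scn.coverage * G / rl))
    starts = rng.integers(0, G - rl + 1, size=n_reads)
    which = rng.integers(0, 2, size=n_reads)
    idx = starts[:, None] + np.arange(rl)[None, :]
    reads = np.where(which[:, None] == 0, hap1[idx], hap2[idx])
    if scn.error_rate > 0:
        mask = rng.random(reads.shape) < scn.error_rate
        n_err = int(mask.sum())
        reads[mask] = (reads[mask] + rng.integers(1, 4, size=n_err, dtype=np.uint8)) % 4
    return reads.astype(np.uint8)


def simulate_reads(scn: SequencingScenario, fastq_path: str | Path | None = None):
    """Simulate reads; write FASTQ if a path is given, else return the
    read matrix.  Output is byte-identical for a fixed scenario."""
    reads = simulate_read_matrix(scn)
    if fastq_path is None:
        return reads
    qual = "I" * scn.read_length
    with open(fastq_path, "w") as fh:
        for i in range(reads.shape[0]):
            seq = _NT[reads[i]].tobytes().decode()
            fh.write(f"@read{i:07d}\n{seq}\n+\n{qual}\n")
    return reads


def simulate_spectrum(scn: SequencingScenario, k: int = 17):
    """Simulate sequencing and count k-mers directly (no read I/O)."""
    from .kmerprof import spectrum_from_matrix

    return spectrum_from_matrix(simulate_read_matrix(scn), k)
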