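"""End-to-end workflows: WGD dating, ortholog selection scan, genome survey.

Each run writes its primary tables/JSON atomically (temp file + rename),
plus a run manifest recording the subcommand, every parameter and seed,
and the package version, so a rerun with the same manifest reproduces
the primary outputs byte for byte (plots exempt).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
import time
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__, codonaln, homology, kaks, kmerprof, ksmix, selscan, seqio

log = logging.getLogger(__name__)


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_manifest(out_dir: Path, subcommand: str, params: Mapping) -> Path:
    manifest = {
        "subcommand": subcommand,
        "parameters": {k: _jsonable(v) for k, v in params.items()},
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    path = out_dir / f"{subcommand}_manifest.json"
    _atomic_write(path, json.dumps(manifest, indent=2))
    return path


def _jsonable(v):
    if dataclasses.is_dataclass(v) and not isinstance(v, type):
        return dataclasses.asdict(v)
    if isinstance(v, Path):
        return str(v)
    return v


def compute_kaks_for_pairs(
    cds_by_id: Mapping[str, seqio.CodingSequence],
    pair_ids: Sequence[tuple[str, str]],
    method: str = "NG86",
) -> pd.DataFrame:
    """Codon-align and estimate Ka/Ks for each id pair."""
    ests = []
    for a, b in pair_ids:
        aln = codonaln.align_codons(cds_by_id[a], cds_by_id[b])
        ests.append(kaks.estimate_pair(aln, method))
    return kaks.estimates_to_frame(ests)


def run_wgd(
    cds_path: str | Path,
    out_dir: str | Path,
    seed: int = 0,
    method: str = "NG86",
    min_similarity: float = 70.0,
    min_coverage: float = 80.0,
    min_len: int = 30,
    ks_min: float = ksmix.KS_MIN_DEFAULT,
    ks_max: float = ksmix.KS_MAX_DEFAULT,
    k_range: Sequence[int] = (1, 2, 3, 4, 5),
    n_restarts: int = 10,
    plot: bool = False,
) -> dict:
    """Paranome WGD-dating workflow.

    CDS FASTA -> translated proteome -> duplicate pairs (similarity /
    mutual-coverage / length filters) -> per-pair Ka/Ks -> truncated Ks
    distribution -> BIC-selected log-normal mixture -> peak table.
    Writes ``pairs.tsv``, ``kaks.tsv``, ``mixture.json``, ``peaks.tsv``
    (and optionally ``ks_histogram.png``) under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = dict(
        cds_path=str(cds_path), seed=seed, method=method,
        min_similarity=min_similarity, min_coverage=min_coverage,
        min_len=min_len, ks_min=ks_min, ks_max=ks_max,
        k_range=list(k_range), n_restarts=n_restarts,
    )
    write_manifest(out, "wgd", params)

    cds = seqio.read_fasta(cds_path, "nt")
    cds_by_id = {c.id: c for c in cds}
    proteome = [seqio.translate(c) for c in cds]
    pairs = homology.find_duplicate_pairs(
        proteome, min_similarity=min_similarity,
        min_coverage=min_coverage, min_len=min_len,
    )
    _atomic_write(out / "pairs.tsv",
                  homology.pairs_to_frame(pairs).to_csv(sep="\t", index=False))
    if not pairs:
        raise RuntimeError("no duplicate pairs retained; nothing to date")

    table = compute_kaks_for_pairs(cds_by_id, [p.key for p in pairs], method)
    _atomic_write(out / "kaks.tsv", table.to_csv(sep="\t", index=False))

    dist = ksmix.build_ks_distribution(table, ks_min=ks_min, ks_max=ks_max)
    fit, model_table = ksmix.select_components(
        dist, k_range=k_range, seed=seed, n_restarts=n_restarts
    )
    peaks = ksmix.report_peaks(fit)
    report = {
        "n_pairs": len(pairs),
        "n_ks_retained": dist.n,
        "excluded": dist.n_excluded,
        "model_table": model_table.to_dict(orient="records"),
        "chosen_k": fit.k,
        "weights": fit.weights.tolist(),
        "mu_ln": fit.mu.tolist(),
        "sigma_ln": fit.sigma.tolist(),
        "medians": fit.medians.tolist(),
        "seed": seed,
    }
    _atomic_write(out / "mixture.json", json.dumps(report, indent=2))
    _atomic_write(out / "peaks.tsv", peaks.to_csv(sep="\t", index=False))
    if plot:
        plot_ks_histogram(dist, fit, out / "ks_histogram.png")
    return {"pairs": pairs, "kaks": table, "dist": dist, "fit": fit, "peaks": peaks}


def run_selscan(
    cds_paths: Mapping[str, str | Path],
    out_dir: str | Path,
    seed: int = 0,
    method: str = "NG86",
    orientation: str = "symmetric",
    outgroup: str | None = None,
    interest_table: pd.DataFrame | None = None,
    pos_thresh: float = selscan.POS_THRESH,
    cons_thresh: float = selscan.CONS_THRESH,
    plot: bool = False,
) -> dict:
    """1:1:1 ortholog selection-scan workflow for three species.

    Per-species CDS FASTA -> proteomes -> pairwise RBH -> triangle-closed
    1:1:1 clusters -> per-cluster omegas for the first two species ->
    regime labels (optionally tagged with genes of interest).  Writes
    ``clusters.tsv`` and ``selection.tsv`` under ``out_dir``.
    """
    if len(cds_paths) != 3:
        raise ValueError("exactly three species required")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    species = tuple(cds_paths)
    write_manifest(out, "selscan", dict(
        cds_paths={k: str(v) for k, v in cds_paths.items()}, seed=seed,
        method=method, orientation=orientation, outgroup=outgroup,
        pos_thresh=pos_thresh, cons_thresh=cons_thresh,
    ))

    cds = {sp: {c.id: c for c in seqio.read_fasta(p, "nt")} for sp, p in cds_paths.items()}
    prot = {sp: [seqio.translate(c) for c in d.values()] for sp, d in cds.items()}
    s1, s2, s3 = species
    rbh = {
        (s1, s2): homology.reciprocal_best_hits(prot[s1], prot[s2]),
        (s1, s3): homology.reciprocal_best_hits(prot[s1], prot[s3]),
        (s2, s3): homology.reciprocal_best_hits(prot[s2], prot[s3]),
    }
    clusters = homology.build_111_clusters(rbh, species)
    cl_frame = pd.DataFrame(
        [{sp: c.member(sp) for sp in species} for c in clusters]
    )
    _atomic_write(out / "clusters.tsv", cl_frame.to_csv(sep="\t", index=False))
    if not clusters:
        raise RuntimeError("no 1:1:1 ortholog clusters found")

    records = selscan.pairwise_cluster_omega(
        clusters, cds, (s1, s2), method=method, orientation=orientation,
        outgroup=outgroup, pos_thresh=pos_thresh, cons_thresh=cons_thresh,
    )
    if interest_table is not None:
        prots_flat = {p.id: p for plist in prot.values() for p in plist}
        records = selscan.tag_genes_of_interest(records, interest_table, prots_flat)
    _atomic_write(out / "selection.tsv", records.to_csv(sep="\t", index=False))
    summary = selscan.label_counts(records)
    _atomic_write(out / "selection_summary.tsv", summary.to_csv(sep="\t", header=False))
    if plot:
        plot_omega_scatter(records, out / "omega_scatter.png", species=(s1, s2))
    return {"clusters": clusters, "records": records, "summary": summary}


def run_kmer(
    source: str | Path | kmerprof.KmerSpectrum,
    out_dir: str | Path,
    k: int = 17,
    from_histogram: bool = False,
    error_cutoff: int | None = None,
    repeat_mult: float = 2.5,
    plot: bool = False,
) -> kmerprof.GenomeProfile:
    """Genome-survey workflow: count (or import) a k-mer spectrum and fit
    the diploid genome profile.  Writes ``spectrum_k<k>.hist`` and
    ``profile_k<k>.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_manifest(out, "kmer", dict(
        source=str(source) if not isinstance(source, kmerprof.KmerSpectrum) else "<spectrum>",
        k=k, from_histogram=from_histogram, error_cutoff=error_cutoff,
        repeat_mult=repeat_mult,
    ))
    if isinstance(source, kmerprof.KmerSpectrum):
        spec = source
    elif from_histogram:
        spec = kmerprof.read_histogram(source, k)
    else:
        from Bio import SeqIO as _SeqIO

        fmt = "fastq" if str(source).endswith(("fastq", "fq")) else "fasta"
        spec = kmerprof.count_kmers(
            (str(r.seq) for r in _SeqIO.parse(str(source), fmt)), k
        )
    kmerprof.write_histogram(spec, out / f"spectrum_k{k}.hist")
    profile = kmerprof.fit_spectrum(spec, error_cutoff=error_cutoff, repeat_mult=repeat_mult)
    profile.to_json(out / f"profile_k{k}.json")
    if plot:
        plot_spectrum(spec, profile, out / f"spectrum_k{k}.png")
    return profile


# ---------------------------------------------------------------------------
# plots


def plot_ks_histogram(dist, fit, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np
    from scipy.stats import norm

    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.hist(dist.values, bins=60, density=True, color="0.8", edgecolor="0.5")
    x = np.linspace(dist.ks_min, dist.ks_max, 400)
    dens = np.zeros_like(x)
    for w, m, s in zip(fit.weights, fit.mu, fit.sigma):
        comp = w * norm.pdf(np.log(x), m, s) / x
        dens += comp
        ax.plot(x, comp, lw=1, ls="--")
    ax.plot(x, dens, lw=2, color="C3")
    for med in fit.medians:
        ax.axvline(med, color="C0", lw=1, alpha=0.6)
    ax.set_xlabel("Ks")
    ax.set_ylabel("density")
    ax.set_title(f"Ks age distribution (n={dist.n}, k={fit.k})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_omega_scatter(records, path, species=("sp1", "sp2")) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colours = {
        "positive_both": "tab:blue", "divergent_sp1": "tab:red",
        "divergent_sp2": "tab:orange", "conserved_both": "0.6",
        "mixed": "tab:green", "missing": "0.9",
    }
    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    for label, sub in records.groupby("label"):
        ax.scatter(sub["omega_sp1"], sub["omega_sp2"], s=12,
                   color=colours.get(label, "k"), label=label, alpha=0.8)
    ax.axhline(1.0, color="k", lw=0.5)
    ax.axvline(1.0, color="k", lw=0.5)
    ax.set_xlabel(f"Ka/Ks ({species[0]})")
    ax.set_ylabel(f"Ka/Ks ({species[1]})")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_spectrum(spec, profile, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(spec.depths, spec.counts, lw=1, color="0.3")
    ax.axvline(profile.het_peak_depth, color="C0", ls="--", lw=1, label="het peak")
    ax.axvline(profile.hom_peak_depth, color="C3", ls="--", lw=1, label="hom peak")
    ax.set_xlim(0, profile.hom_peak_depth * 4)
    ax.set_xlabel("depth")
    ax.set_ylabel("distinct k-mers")
    ax.set_title(
        f"k={profile.k}: size {profile.genome_size / 1e6:.2f} Mb, "
        f"het {profile.heterozygosity_pct:.2f}%, "
        f"repeats {100 * profile.repeat_fraction:.1f}%"
    )
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
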